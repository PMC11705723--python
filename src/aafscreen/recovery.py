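"""Ground-truth recovery experiments on synthetic screens.

The synthetic generator exists so that every pipeline stage has a
recoverable target; this module packages the standard recovery experiments:
midpoint (potency) recovery under replicate noise, ZIP null and
injected-interaction calibration, two-way-ANOVA type-I calibration and
Tukey power, and the end-to-end chemoresistance ranking in which one
ascites condition carries a strong resistance phenotype.

Each experiment runs the ordinary pipeline on generated data and returns
summary metrics; the experiment sizes default to the scales used in the
package's own validation runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import pipeline
from .stats import anova2_tukey
from .synergy import zip_delta
from .synthetic import (
    ConditionEffect,
    CurveTruth,
    DrugSpec,
    ScreenConfig,
    TruthSet,
    default_truth,
    generate_combination_grid,
    generate_screen,
    half_log_grid,
)

__all__ = [
    "midpoint_recovery",
    "zip_null_noiseless",
    "zip_epsilon_noiseless",
    "zip_epsilon_sign_recovery",
    "anova_null_calibration",
    "tukey_power",
    "resistant_condition_ranking",
    "best_treatment_tables",
]


def _single_curve_config(seed: int, noise_cv: float = 0.05) -> ScreenConfig:
    return ScreenConfig(
        cell_lines=("X",), media_conditions=("media",),
        drugs=(DrugSpec("d1", half_log_grid(1e-8, 8)),),
        replicates_technical=3, replicates_biological=2,
        noise_cv=noise_cv, seed=seed,
    )


def midpoint_recovery(n_seeds: int = 200, noise_cv: float = 0.05,
                      seed: int = 0) -> dict:
    """Fit the default 8-dose, 6-replicate design over many seeds and
    measure recovery of the true midpoint e.

    Returns the median relative error of e-hat, and the 2.5/97.5 percentile
    interval of the per-seed ratio e-hat / e-true.
    """
    master = np.random.default_rng(seed)
    ratios = []
    for k in range(n_seeds):
        sub = int(master.integers(0, 2**31 - 1))
        cfg = _single_curve_config(seed=sub, noise_cv=noise_cv)
        rng = np.random.default_rng(sub)
        e_true = 10.0 ** rng.uniform(-7.0, -6.0)
        truth = TruthSet(
            curves={("X", "d1"): CurveTruth(b=rng.uniform(0.8, 1.6), e=e_true)},
            condition_effects={("X", "media"): ConditionEffect()},
        )
        wells, _ = generate_screen(cfg, truth)
        fits = pipeline.fit_screen(pipeline.screen_viability(wells))
        ratios.append(float(fits["e"].iloc[0]) / e_true)
    ratios = np.asarray(ratios)
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return {
        "median_rel_err": float(np.median(np.abs(ratios - 1.0))),
        "ratio_interval": (float(lo), float(hi)),
        "ratios": ratios,
    }


def _random_marginal_truth(rng) -> TruthSet:
    return TruthSet(
        curves={
            ("X", "da"): CurveTruth(b=rng.uniform(0.7, 1.8),
                                    e=10.0 ** rng.uniform(-7.0, -5.0),
                                    d=rng.uniform(60.0, 100.0)),
            ("X", "db"): CurveTruth(b=rng.uniform(0.7, 1.8),
                                    e=10.0 ** rng.uniform(-7.0, -5.0),
                                    d=rng.uniform(60.0, 100.0)),
        },
        condition_effects={("X", "media"): ConditionEffect()},
    )


def zip_null_noiseless(n_grids: int = 500, seed: int = 0) -> np.ndarray:
    """ZIP summaries of noiseless Bliss-independent factorial grids with
    random marginals (the zero-interaction null)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_grids):
        truth = _random_marginal_truth(rng)
        grid = generate_combination_grid(
            truth, "X", "media", "da", "db", design="factorial", epsilon=0.0,
        )
        out.append(zip_delta(grid).summary)
    return np.asarray(out)


def _clip_free_truth() -> TruthSet:
    # partial-efficacy marginals keep the Bliss surface inside [0.12, 0.90]
    # on the mid-range grid below, so a +/-0.10 shift survives the [0, 1]
    # clip unchanged
    return TruthSet(
        curves={("X", "da"): CurveTruth(1.0, 1e-6, 70.0),
                ("X", "db"): CurveTruth(1.0, 2e-6, 70.0)},
        condition_effects={("X", "media"): ConditionEffect()},
    )


def _clip_free_grids():
    ca = 1e-6 * 10.0 ** np.arange(-1.0, 1.51, 0.5)
    cb = 2e-6 * 10.0 ** np.arange(-1.0, 1.51, 0.5)
    return ca, cb


def zip_epsilon_noiseless(epsilon: float) -> float:
    """ZIP summary of the noiseless factorial grid carrying a uniform
    Bliss deviation ``epsilon`` (clip-free scenario)."""
    ca, cb = _clip_free_grids()
    grid = generate_combination_grid(
        _clip_free_truth(), "X", "media", "da", "db",
        conc_a=ca, conc_b=cb, design="factorial", epsilon=epsilon,
    )
    return zip_delta(grid).summary


def zip_epsilon_sign_recovery(epsilon: float = 0.10, n_seeds: int = 200,
                              noise_cv: float = 0.05, n_replicates: int = 3,
                              seed: int = 0) -> dict:
    """Fraction of noisy seeds in which the ZIP summary carries the sign of
    the injected interaction (half the seeds at +epsilon, half at -)."""
    master = np.random.default_rng(seed)
    ca, cb = _clip_free_grids()
    truth = _clip_free_truth()
    correct, summaries = 0, []
    for k in range(n_seeds):
        eps = epsilon if k % 2 == 0 else -epsilon
        grid = generate_combination_grid(
            truth, "X", "media", "da", "db", conc_a=ca, conc_b=cb,
            design="factorial", epsilon=eps, noise_cv=noise_cv,
            n_replicates=n_replicates,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        s = zip_delta(grid).summary
        summaries.append(s)
        correct += int(np.sign(s) == np.sign(eps))
    return {"fraction_correct_sign": correct / n_seeds,
            "summaries": np.asarray(summaries)}


def _balanced_dss_table(rng, shift: dict | None = None, sd: float = 3.0,
                        reps: int = 2) -> pd.DataFrame:
    cells = ["SKOV3", "OVCAR3", "OVCAR5", "OVCAR8", "NCI"]
    conds = ["media", "A1", "A9", "A16", "A18", "A19"]
    cell_eff = dict(zip(cells, [4.0, 2.0, 0.0, -2.0, -4.0]))
    rows = []
    for cell in cells:
        for cond in conds:
            mu = 50.0 + cell_eff[cell] + (shift or {}).get(cond, 0.0)
            for _ in range(reps):
                rows.append({"cell_line": cell, "condition": cond,
                             "dss": mu + rng.normal(0.0, sd)})
    return pd.DataFrame(rows)


def anova_null_calibration(n_sims: int = 500, alpha: float = 0.05,
                           seed: int = 0) -> dict:
    """Type-I error of the AAF-factor F test under a true null (additive
    cell-line effects only)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        table, _ = anova2_tukey(_balanced_dss_table(rng))
        rejections += int(table.loc["condition", "PR(>F)"] < alpha)
    rate = rejections / n_sims
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n_sims))
    return {"rejection_rate": rate, "mc_se": mc_se, "alpha": alpha}


def tukey_power(n_sims: int = 200, shift_in_sd: float = 3.0, sd: float = 3.0,
                seed: int = 0) -> float:
    """Fraction of seeds in which Tukey HSD flags an AAF level shifted by
    ``shift_in_sd`` residual SDs against the media control."""
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(n_sims):
        df = _balanced_dss_table(rng, shift={"A19": -shift_in_sd * sd}, sd=sd)
        _, tukey = anova2_tukey(df)
        row = tukey[
            ((tukey["level_a"] == "A19") & (tukey["level_b"] == "media"))
            | ((tukey["level_a"] == "media") & (tukey["level_b"] == "A19"))
        ]
        detected += int(bool(row["reject"].iloc[0]))
    return detected / n_sims


def resistant_condition_ranking(n_seeds: int = 50, seed: int = 0,
                                resistant: str = "A19") -> dict:
    """End-to-end chemoresistance reproduction across seeds.

    Each seed generates the full default screen (the resistant condition
    carries a 10x midpoint shift and 50-point efficacy loss in every cell
    line), runs normalisation, fitting and DSS, and checks that the
    resistant condition has the lowest DSS for every (cell line, drug).
    """
    master = np.random.default_rng(seed)
    all_lowest = []
    for _ in range(n_seeds):
        sub = int(master.integers(0, 2**31 - 1))
        cfg = ScreenConfig(seed=sub)
        truth = default_truth(cfg, resistant_condition=resistant)
        wells, _ = generate_screen(cfg, truth)
        fits = pipeline.fit_screen(pipeline.screen_viability(wells))
        wide = pipeline.dss_wide(fits)
        lowest = True
        for cell in cfg.cell_lines:
            sub_tab = wide.loc[cell]
            is_min = sub_tab.loc[resistant] <= sub_tab.min(axis=0) + 1e-12
            lowest &= bool(is_min.all())
        all_lowest.append(lowest)
    return {"fraction_all_drugs_lowest": float(np.mean(all_lowest)),
            "n_seeds": n_seeds}


def best_treatment_tables(seed: int = 0) -> dict:
    """Produce the per-condition best-treatment table twice from the same
    screen and report whether the nomination is deterministic."""
    cfg = ScreenConfig(seed=seed)
    truth = default_truth(cfg)
    wells, _ = generate_screen(cfg, truth)
    fits = pipeline.fit_screen(pipeline.screen_viability(wells))
    tables = []
    for _ in range(2):
        combos = pipeline.run_combination_screen(cfg, truth, fits, seed=seed)
        tables.append(pipeline.nominate_best_treatments(combos))
    return {
        "table": tables[0],
        "deterministic": tables[0].equals(tables[1]),
        "n_conditions": int(tables[0]["condition_id"].nunique()),
    }
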
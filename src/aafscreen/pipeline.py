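"""End-to-end helpers gluing the pipeline stages together.

These are the steps the analysis drivers, the tests and the acceptance
checks share: normalise a screen, fit every (cell line, condition, drug)
titration, score DSS over each drug's tested window, derive priming doses,
run the combination screen and nominate best treatments per condition.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import plates, synergy
from .doseresp import LL4Fit, dss, fit_ll4, ic_p
from .synthetic import ScreenConfig, TruthSet, generate_combination_grid

__all__ = [
    "screen_viability",
    "fit_screen",
    "dss_wide",
    "average_ic20",
    "run_combination_screen",
    "nominate_best_treatments",
]


def screen_viability(wells: pd.DataFrame, mode: str = "controls") -> pd.DataFrame:
    """Normalise a well table to percent viability (control- or
    vehicle-based) and aggregate technical/biological replicates."""
    if mode == "controls":
        points = plates.normalize_controls(wells)
    elif mode == "vehicle":
        points = plates.normalize_vehicle(wells)
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return plates.aggregate_replicates(points)


def fit_screen(
    points: pd.DataFrame,
    t: float = 10.0,
    variant: int = 2,
    ic_levels: tuple = (20.0, 50.0),
) -> pd.DataFrame:
    """Fit LL4 curves and score DSS per (cell line, condition, drug).

    The integration window of each drug is the log10 span of its tested
    concentrations.  IC values that are not reached within the fitted model
    range are reported as NaN.
    """
    mono = points[points["drug1"] != ""]
    if "conc2_M" in mono.columns:
        mono = mono[mono["conc2_M"] == 0.0]
    rows = []
    for (cell, cond, drug), grp in mono.groupby(
        ["cell_line", "condition", "drug1"], sort=True
    ):
        doses = grp["conc1_M"].to_numpy(dtype=float)
        viab = grp["viability_pct"].to_numpy(dtype=float)
        pos = doses > 0
        doses, viab = doses[pos], viab[pos]
        x_min = math.log10(doses.min())
        x_max = math.log10(doses.max())
        fit = fit_ll4(doses, viab)
        row = {
            "cell_line": cell, "condition": cond, "drug": drug,
            "b": fit.b, "c": fit.c, "d": fit.d, "e": fit.e,
            "converged": fit.converged, "residual_sd": fit.residual_sd,
            "x_min": x_min, "x_max": x_max,
        }
        for p in ic_levels:
            try:
                row[f"ic{p:g}"] = ic_p(fit, p)
            except ValueError:
                row[f"ic{p:g}"] = np.nan
        row["dss"] = (
            dss(fit, x_min, x_max, t=t, variant=variant).dss
            if fit.converged else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def dss_wide(fits: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready wide table: (cell line x condition) rows, drug columns."""
    out = fits.pivot_table(index=["cell_line", "condition"], columns="drug",
                           values="dss")
    out.columns.name = None
    return out


def average_ic20(fits: pd.DataFrame, drug: str, cell_line: str) -> float:
    """Priming dose of a drug in a cell line: the mean of its per-condition
    IC20 estimates across media and AAF conditions (conditions whose curves
    never reach 20% inhibition are skipped)."""
    sub = fits[(fits["drug"] == drug) & (fits["cell_line"] == cell_line)]
    vals = sub["ic20"].dropna()
    if vals.empty:
        raise ValueError(
            f"IC20 of {drug!r} unreachable in every condition of {cell_line!r}"
        )
    return float(vals.mean())


def run_combination_screen(
    config: ScreenConfig,
    truth: TruthSet,
    mono_fits: pd.DataFrame,
    noise_cv: float | None = None,
    n_replicates: int = 3,
    t: float = 10.0,
    variant: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Anchored combination screen of every (SCD primer x novel partner).

    For each condition, each standard-of-care drug is fixed at its average
    IC20 (priming dose, shared across that cell line's conditions) and each
    novel drug titrated against it.  Scores per combination: DSS of the
    combined titration, CR versus the priming monotherapy, ZIP summary and
    the 100-VUS analogue.
    """
    noise = config.noise_cv if noise_cv is None else noise_cv
    soc = [d.name for d in config.drugs if d.role == "standard_of_care"]
    novel = [d.name for d in config.drugs if d.role == "novel"]
    fit_lookup = mono_fits.set_index(["cell_line", "condition", "drug"])
    rows = []
    grid_seed = seed
    for cell in config.cell_lines:
        for primer in soc:
            try:
                anchor = average_ic20(mono_fits, primer, cell)
            except ValueError:
                continue
            for cond in config.media_conditions:
                mono = fit_lookup.loc[(cell, cond, primer)]
                if not bool(mono["converged"]) or not np.isfinite(mono["dss"]):
                    continue
                primer_fit = LL4Fit(
                    b=float(mono["b"]), c=float(mono["c"]),
                    d=float(mono["d"]), e=float(mono["e"]),
                    residual_sd=float(mono["residual_sd"]), converged=True,
                    n_points=0,
                )
                for partner in novel:
                    grid_seed += 1
                    grid = generate_combination_grid(
                        truth, cell, cond, primer, partner,
                        conc_a=np.array([anchor]), design="anchored",
                        noise_cv=noise, n_replicates=n_replicates,
                        seed=grid_seed,
                    )
                    row = _score_anchored_grid(
                        grid, float(mono["dss"]), primer_fit, t=t, variant=variant
                    )
                    row.update({
                        "cell_line": cell, "condition": cond,
                        "primer": primer, "partner": partner,
                        "treatment": f"{partner}+{primer}",
                        "anchor_conc_M": anchor,
                    })
                    rows.append(row)
    return pd.DataFrame(rows)


def _score_anchored_grid(grid, dss_mono: float, primer_fit: LL4Fit, t: float,
                         variant: int) -> dict:
    """DSS/CR/ZIP/VUS scores of one anchored combination grid."""
    pos_b = grid.conc_b > 0
    doses = grid.conc_b[pos_b]
    combo_viab = grid.viability[1, pos_b]  # the single priming row
    fit = fit_ll4(doses, combo_viab, fix_lower_at_zero=False)
    x_min, x_max = math.log10(doses.min()), math.log10(doses.max())
    if fit.converged:
        dss_combo = dss(fit, x_min, x_max, t=t, variant=variant).dss
    else:
        dss_combo = np.nan
    out = {"dss": dss_combo, "converged": fit.converged}
    if np.isfinite(dss_combo):
        out["cr"] = synergy.combination_ratio(dss_combo, dss_mono).cr
    else:
        out["cr"] = np.nan
    out["dss_mono"] = dss_mono
    try:
        out["zip_summary"] = synergy.zip_delta(grid, fit_a=primer_fit).summary
    except ValueError:
        out["zip_summary"] = np.nan
    out["vus_score"] = synergy.vus(grid).score
    return out


def nominate_best_treatments(
    combo_scores: pd.DataFrame,
    criterion: str = "cr",
) -> pd.DataFrame:
    """Rank treatments per condition and nominate the best one.

    Conditions are (cell line x medium); the treatment label couples the
    titrated partner with its primer.  Returns one row per condition with
    the winning treatment and its criterion value.
    """
    scores = combo_scores.dropna(subset=[criterion]).copy()
    scores["condition_id"] = scores["cell_line"] + ":" + scores["condition"]
    scores["n_drugs"] = 2
    ranked = synergy.rank_treatments(
        scores, criterion=criterion, condition_col="condition_id",
        treatment_col="treatment",
    )
    best = synergy.best_treatments(ranked, condition_col="condition_id")
    keep = ["condition_id", "cell_line", "condition", "treatment", criterion, "dss"]
    return best[[c for c in keep if c in best.columns]]
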
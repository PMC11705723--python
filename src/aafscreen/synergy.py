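"""Combination scoring: ZIP synergy, 100-VUS surface scores, combination
ratios, synergy calls and per-condition treatment ranking.

Two combination designs are supported.  A *factorial* grid crosses full
titrations of both drugs (each axis carrying a zero-dose level so the
marginals are recoverable from the grid itself).  An *anchored* grid holds a
priming drug at one fixed dose (its average IC20 in the screens) while the
partner is titrated -- the design used for the combination screens, whose
priming marginal must come from the monotherapy fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .doseresp import LL4Fit, fit_ll4

__all__ = [
    "CombinationGrid",
    "ZIPResult",
    "VUSResult",
    "CRRecord",
    "combination_ratio",
    "zip_delta",
    "vus",
    "synergy_call",
    "rank_treatments",
    "best_treatments",
]


@dataclass
class CombinationGrid:
    """Dose-pair viability matrix indexed (conc_a x conc_b), percent scale.

    ``conc_a`` and ``conc_b`` are molar vectors that must each include a
    zero-dose level; an anchored design has exactly one positive ``conc_a``
    level (the priming dose).
    """

    drug_a: str
    drug_b: str
    conc_a: np.ndarray
    conc_b: np.ndarray
    viability: np.ndarray
    design: str = "factorial"
    cell_line: str = ""
    condition: str = ""
    true_inhibition: np.ndarray | None = None

    def __post_init__(self):
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.design not in ("factorial", "anchored"):
            raise ValueError(f"unknown design {self.design!r}")
        for name, v in (("conc_a", self.conc_a), ("conc_b", self.conc_b)):
            if not np.any(v == 0.0):
                raise ValueError(
                    f"{name} lacks a zero-dose level; marginals unrecoverable"
                )
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.viability.shape != (self.conc_a.size, self.conc_b.size):
            raise ValueError("viability matrix does not match dose grids")
        if self.design == "anchored" and np.count_nonzero(self.conc_a > 0) != 1:
            raise ValueError("anchored design requires exactly one priming dose")

    @property
    def inhibition_fraction(self) -> np.ndarray:
        """Observed inhibition on the [0, 1] scale."""
        return (100.0 - self.viability) / 100.0


@dataclass(frozen=True)
class ZIPResult:
    """Zero-interaction-potency deltas (percent scale) over positive-dose
    cells, with the mean delta as summary."""

    delta: np.ndarray
    summary: float
    fit_a: LL4Fit | None
    fit_b: LL4Fit | None
    design: str
    directions_used: int


@dataclass(frozen=True)
class VUSResult:
    """Normalised volume under the viability surface; ``score = 100 - vus``
    so that high values mean an effective combination."""

    vus: float
    score: float

    def __post_init__(self):
        if not (-1e-9 <= self.score <= 100.0 + 1e-9):
            raise ValueError(f"100-VUS out of range: {self.score}")


@dataclass(frozen=True)
class CRRecord:
    """Combination ratio of a combination versus a monotherapy comparator."""

    condition: str
    combo: str
    comparator: str
    dss_combo: float
    dss_mono: float

    @property
    def cr(self) -> float:
        return (self.dss_combo + 100.0) / (self.dss_mono + 100.0)


def combination_ratio(
    dss_combo: float,
    dss_mono: float,
    condition: str = "",
    combo: str = "",
    comparator: str = "",
) -> CRRecord:
    """CR = (DSS_combo + 100) / (DSS_mono + 100).

    Both scores are augmented by 100 so the ratio stays defined (and equals
    1) when one or both DSS are zero; CR > 1 means the combination improves
    on the comparator monotherapy.
    """
    for name, v in (("dss_combo", dss_combo), ("dss_mono", dss_mono)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} out of [0, 100]: {v}")
    return CRRecord(condition=condition, combo=combo, comparator=comparator,
                    dss_combo=float(dss_combo), dss_mono=float(dss_mono))


def _fit_marginal(doses, viability) -> LL4Fit:
    fit = fit_ll4(doses, viability, fix_lower_at_zero=True)
    return fit


def _directional_fit(x, y, floor):
    """Fit y = f + (top - f) / (1 + (m/x)^lam) along one grid direction.

    ``floor`` is the fitted single-agent effect of the fixed partner drug,
    used to initialise the curve's baseline; both asymptotes stay free
    within generous bounds so the smoother can represent a uniformly
    Bliss-shifted surface without bias.  Returns predicted values at x, or
    None when the fit fails.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        return None
    lx = np.log(x)

    def resid(theta):
        lam, lm, f, top = theta
        pred = f + (top - f) / (1.0 + np.exp(-lam * (lx - lm)))
        return pred - y

    f_lo = max(-0.25, floor - 0.5)
    f_hi = min(1.25, floor + 0.5)
    top0 = float(np.clip(np.max(y), floor + 1e-3, 1.25))
    lm0 = float(np.median(lx))
    lower = [0.05, lx.min() - 15.0, f_lo, f_lo + 1e-6]
    upper = [25.0, lx.max() + 15.0, f_hi, 1.25]
    best = None
    n_success = 0
    for lam0, shift in ((1.0, 0.0), (0.5, 0.0), (2.0, 0.0), (1.0, -2.0), (1.0, 2.0)):
        t0 = np.clip([lam0, lm0 + shift, floor, top0], lower, upper)
        try:
            res = least_squares(resid, t0, bounds=(lower, upper), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=5000)
        except Exception:
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
        n_success += res.success
        if best.cost < 1e-14 or n_success >= 2:
            break
    if best is None or not best.success:
        return None
    lam, lm, f, top = best.x
    return f + (top - f) / (1.0 + np.exp(-lam * (lx - lm)))


def zip_delta(
    grid: CombinationGrid,
    fit_a: LL4Fit | None = None,
    fit_b: LL4Fit | None = None,
) -> ZIPResult:
    """ZIP synergy deltas of a combination grid.

    The zero-interaction reference at each positive dose pair is the Bliss
    expectation ``y1 + y2 - y1*y2`` built from the fitted monotherapy
    marginals.  The observed response is smoothed by directional logistic
    refits (one per fixed dose of the partner drug, baseline pinned at that
    partner's fitted single-agent effect); a factorial grid averages the two
    directions, an anchored grid has only one.  ``delta`` is
    (observed - expected) x 100 and ``summary`` its mean over defined cells.
    """
    pos_a = grid.conc_a > 0
    pos_b = grid.conc_b > 0
    inh = grid.inhibition_fraction
    izero_a = int(np.flatnonzero(~pos_a)[0])
    izero_b = int(np.flatnonzero(~pos_b)[0])

    if fit_a is None:
        if np.count_nonzero(pos_a) < 3:
            raise ValueError(
                "marginal for drug_a unfittable from the grid; supply fit_a"
            )
        fit_a = _fit_marginal(grid.conc_a[pos_a], grid.viability[pos_a, izero_b])
    if fit_b is None:
        if np.count_nonzero(pos_b) < 3:
            raise ValueError(
                "marginal for drug_b unfittable from the grid; supply fit_b"
            )
        fit_b = _fit_marginal(grid.conc_b[pos_b], grid.viability[izero_a, pos_b])
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("monotherapy marginal fit did not converge")

    ya = fit_a.inhibition(grid.conc_a[pos_a]) / 100.0
    yb = fit_b.inhibition(grid.conc_b[pos_b]) / 100.0
    y_zip = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]

    obs = inh[np.ix_(pos_a, pos_b)]
    xa = grid.conc_a[pos_a]
    xb = grid.conc_b[pos_b]

    smoothed = []
    # direction 1: titrate drug_b within each row of fixed drug_a
    if xb.size >= 3:
        rows = np.full_like(obs, np.nan)
        ok = True
        for i in range(xa.size):
            pred = _directional_fit(xb, obs[i, :], floor=float(ya[i]))
            if pred is None:
                ok = False
                break
            rows[i, :] = pred
        if ok:
            smoothed.append(rows)
    # direction 2: titrate drug_a within each column of fixed drug_b
    if grid.design == "factorial" and xa.size >= 3:
        cols = np.full_like(obs, np.nan)
        ok = True
        for j in range(xb.size):
            pred = _directional_fit(xa, obs[:, j], floor=float(yb[j]))
            if pred is None:
                ok = False
                break
            cols[:, j] = pred
        if ok:
            smoothed.append(cols)

    if not smoothed:
        raise ValueError("no directional refit succeeded; cannot score ZIP")
    observed = np.mean(smoothed, axis=0)
    delta = (observed - y_zip) * 100.0
    return ZIPResult(
        delta=delta, summary=float(np.mean(delta)), fit_a=fit_a, fit_b=fit_b,
        design=grid.design, directions_used=len(smoothed),
    )


def vus(grid: CombinationGrid) -> VUSResult:
    """100-VUS surface score of a combination grid.

    The viability surface over the positive-dose cells is integrated by the
    iterated trapezoid rule in (log10 conc_a, log10 conc_b) space and
    normalised by the volume of the enclosing cube (100% viability over the
    axis spans).  Anchored grids fall back to the 1-D normalised-AUC
    analogue along the titrated drug.
    """
    pos_a = grid.conc_a > 0
    pos_b = grid.conc_b > 0
    v = grid.viability[np.ix_(pos_a, pos_b)]
    la = np.log10(grid.conc_a[pos_a])
    lb = np.log10(grid.conc_b[pos_b])
    if lb.size < 2:
        raise ValueError("need >= 2 positive levels along conc_b")
    span_b = lb[-1] - lb[0]
    if grid.design == "anchored" or la.size < 2:
        if grid.design == "factorial":
            raise ValueError(
                "factorial scoring needs >= 2 positive levels per axis; use "
                "the anchored (1-D) mode"
            )
        row = v[0, :]
        auc = np.trapezoid(row, lb)
        vus_val = 100.0 * auc / (100.0 * span_b)
    else:
        span_a = la[-1] - la[0]
        vol = np.trapezoid(np.trapezoid(v, lb, axis=1), la)
        vus_val = 100.0 * vol / (100.0 * span_a * span_b)
    vus_val = float(np.clip(vus_val, 0.0, 100.0))
    return VUSResult(vus=vus_val, score=100.0 - vus_val)


def synergy_call(
    scores: pd.DataFrame,
    percentile: float = 95.0,
    cr_cutoff: float = 0.75,
    reference_col: str = "reference",
    zip_col: str = "zip_summary",
    cr_col: str = "cr",
    min_population: int = 20,
) -> pd.DataFrame:
    """Label synergistic and non-improving combinations.

    Per reference-drug population (e.g. all carboplatin combinations across
    conditions), the synergy threshold is the empirical ``percentile`` of the
    ZIP summaries (linear-interpolation / type-7 convention); entries
    strictly above it are flagged ``synergistic``.  Entries with
    CR < ``cr_cutoff`` are flagged ``non_improvement``.  Populations smaller
    than ``min_population`` are marked percentile-unstable.
    """
    if scores.empty:
        raise ValueError("empty score table")
    out = scores.copy()
    out["zip_threshold"] = np.nan
    out["percentile_unstable"] = False
    for ref, idx in out.groupby(reference_col).groups.items():
        vals = out.loc[idx, zip_col].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"empty reference population {ref!r}")
        thr = float(np.percentile(vals, percentile))
        out.loc[idx, "zip_threshold"] = thr
        if vals.size < min_population:
            out.loc[idx, "percentile_unstable"] = True
    out["synergistic"] = out[zip_col] > out["zip_threshold"]
    if cr_col in out.columns:
        out["non_improvement"] = out[cr_col] < cr_cutoff
    return out


def rank_treatments(
    scores: pd.DataFrame,
    criterion: str = "cr",
    condition_col: str = "condition",
    treatment_col: str = "treatment",
    dss_col: str = "dss",
    n_drugs_col: str = "n_drugs",
) -> pd.DataFrame:
    """Rank treatments within each condition by the chosen criterion.

    Descending sort on ``criterion`` (CR or DSS) with deterministic
    tie-breaks: higher DSS, then fewer drugs, then lexicographic treatment
    label.  Ranks are 1..n within each condition; the rank-1 entry is the
    nominated best treatment.
    """
    if criterion not in scores.columns:
        raise ValueError(f"criterion column {criterion!r} missing")
    out = scores.copy()
    if n_drugs_col not in out.columns:
        out[n_drugs_col] = 1
    if dss_col not in out.columns:
        out[dss_col] = out[criterion]
    out = out.sort_values(
        by=[condition_col, criterion, dss_col, n_drugs_col, treatment_col],
        ascending=[True, False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = out.groupby(condition_col, sort=False).cumcount() + 1
    return out


def best_treatments(ranked: pd.DataFrame, condition_col: str = "condition") -> pd.DataFrame:
    """Extract the rank-1 nomination per condition from a ranked table."""
    best = ranked[ranked["rank"] == 1].drop(columns=["rank"])
    return best.sort_values(condition_col).reset_index(drop=True)
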
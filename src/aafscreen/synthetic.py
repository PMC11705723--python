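"""Synthetic viability-screen generator with known ground truth.

Emulates the study design of an ovarian-cancer drug screen in which five
cell lines are cultured either in plain media or in media conditioned 1:1
with patient-derived acellular ascites fluid (AAF): 30 (cell line x medium)
conditions, 11 drugs (2 standard-of-care + 9 repurposed), 8-point half-log
single-agent titrations, anchored combinations with a priming drug fixed at
its IC20, and 3 technical x 2 biological replicates per data point on
384-well plates read out as luminescence RFU.

Every generated well is traceable to a ground-truth log-logistic curve, so
downstream fitting, scoring and statistics can be checked for recovery.
Condition-specific chemoresistance is injected phenomenologically at the
curve level: an AAF multiplies the midpoint of every drug's curve
(``resistance_shift``) and caps its maximal inhibition
(``efficacy_loss``, a rising viability floor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synergy import CombinationGrid

__all__ = [
    "DrugSpec",
    "ScreenConfig",
    "CurveTruth",
    "ConditionEffect",
    "TruthSet",
    "MarkerTruth",
    "MarkerTable",
    "default_drugs",
    "default_config",
    "default_truth",
    "default_marker_truth",
    "generate_screen",
    "generate_combination_grid",
    "generate_marker_table",
    "half_log_grid",
]

_ROWS = "ABCDEFGHIJKLMNOP"
_NOMINAL_RFU = 10_000.0  # plate-reader signal of a fully viable well

DEFAULT_CELL_LINES = ("SKOV3", "OVCAR3", "OVCAR5", "OVCAR8", "NCI")
DEFAULT_CONDITIONS = ("media", "A1", "A9", "A16", "A18", "A19")


def _lognormal_sigma(cv: float) -> float:
    """Log-normal sigma giving a multiplicative coefficient of variation cv."""
    return math.sqrt(math.log1p(cv * cv))


def half_log_grid(c_min: float, n: int = 8) -> tuple[float, ...]:
    """n concentrations ascending from c_min in half-log (sqrt(10)) steps."""
    return tuple(c_min * 10.0 ** (0.5 * k) for k in range(n))


@dataclass(frozen=True)
class DrugSpec:
    """A screened compound: name, molar titration grid, and its role
    (``standard_of_care`` or ``novel``/repurposed)."""

    name: str
    concentrations: tuple[float, ...]
    role: str = "novel"

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0 or np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError(
                f"{self.name}: concentration grid must be strictly positive "
                "and strictly increasing"
            )
        if self.role not in ("standard_of_care", "novel"):
            raise ValueError(f"unknown drug role {self.role!r}")


def default_drugs() -> tuple[DrugSpec, ...]:
    """The 11-drug library: carboplatin + paclitaxel (standard of care) and
    nine repurposed compounds on 8-point half-log grids.

    Repurposed drugs span roughly 1 uM - 3 mM (the clinically relevant
    micromolar-to-millimolar window); paclitaxel is titrated in the
    nanomolar range it is active in.
    """
    soc = [
        DrugSpec("carboplatin", half_log_grid(1e-6), "standard_of_care"),
        DrugSpec("paclitaxel", half_log_grid(1e-9), "standard_of_care"),
    ]
    novel = [
        DrugSpec(name, half_log_grid(1e-6), "novel")
        for name in (
            "rapamycin", "niclosamide", "fludarabine", "ruxolitinib",
            "acetylcysteine", "idelalisib", "trametinib", "nilotinib",
            "WP1066",
        )
    ]
    return tuple(soc + novel)


@dataclass(frozen=True)
class ScreenConfig:
    """Design of a synthetic screen (the study layout by default)."""

    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    media_conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    drugs: tuple[DrugSpec, ...] = field(default_factory=default_drugs)
    replicates_technical: int = 3
    replicates_biological: int = 2
    noise_cv: float = 0.05
    control_counts: dict = field(
        default_factory=lambda: {
            "neg_control": 12, "pos_control": 12,
            "vehicle_high": 6, "vehicle_low": 6,
        }
    )
    bio_rep_cv: float = 0.05  # lognormal CV of per-biological-replicate e
    seed: int = 0

    def __post_init__(self):
        if self.replicates_technical < 1 or self.replicates_biological < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        wells = (
            len(self.drugs) * max(len(d.concentrations) for d in self.drugs)
            * self.replicates_technical + sum(self.control_counts.values())
        )
        if wells > 384:
            raise ValueError(f"plate layout needs {wells} wells (> 384)")

    def drug(self, name: str) -> DrugSpec:
        for d in self.drugs:
            if d.name == name:
                return d
        raise KeyError(f"no drug named {name!r} in config")


@dataclass(frozen=True)
class CurveTruth:
    """True single-agent curve for a (cell line, drug): Hill slope ``b``,
    midpoint ``e`` (molar) and maximal inhibition ``d`` (%), baseline 0."""

    b: float
    e: float
    d: float = 100.0

    def __post_init__(self):
        if not (self.b > 0 and self.e > 0 and 0.0 <= self.d <= 100.0):
            raise ValueError(f"invalid curve truth {self}")


@dataclass(frozen=True)
class ConditionEffect:
    """Chemoresistance injected by a medium condition: the midpoint of every
    curve is multiplied by ``resistance_shift`` and its maximal inhibition
    reduced by ``efficacy_loss`` percentage points (floored at 0)."""

    resistance_shift: float = 1.0
    efficacy_loss: float = 0.0

    def __post_init__(self):
        if self.resistance_shift <= 0 or self.efficacy_loss < 0:
            raise ValueError(f"invalid condition effect {self}")


@dataclass(frozen=True)
class TruthSet:
    """Ground truth of a synthetic screen.

    ``curves`` maps (cell_line, drug) to the media-condition curve;
    ``condition_effects`` maps (cell_line, condition) to the resistance
    perturbation; ``interactions`` maps (cell_line, condition, drug_a,
    drug_b) to a Bliss-deviation epsilon on the [0, 1] inhibition scale
    (missing pairs are independent, epsilon = 0).
    """

    curves: dict
    condition_effects: dict
    interactions: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for key, eff in self.condition_effects.items():
            if not isinstance(eff, ConditionEffect):
                raise TypeError(f"condition effect for {key} has wrong type")
        for key, eps in self.interactions.items():
            if not (-1.0 <= eps <= 1.0):
                raise ValueError(f"interaction epsilon for {key} out of [-1, 1]")

    def curve(self, cell_line: str, drug: str) -> CurveTruth:
        try:
            return self.curves[(cell_line, drug)]
        except KeyError:
            raise KeyError(
                f"truth entry missing for cell line {cell_line!r} and drug "
                f"{drug!r}"
            ) from None

    def effect(self, cell_line: str, condition: str) -> ConditionEffect:
        try:
            return self.condition_effects[(cell_line, condition)]
        except KeyError:
            raise KeyError(
                f"truth entry missing for cell line {cell_line!r} in "
                f"condition {condition!r}"
            ) from None

    def effective_params(self, cell_line: str, condition: str, drug: str):
        """(b, d, e) after applying the condition's resistance effect."""
        cur = self.curve(cell_line, drug)
        eff = self.effect(cell_line, condition)
        d = max(cur.d - eff.efficacy_loss, 0.0)
        return cur.b, d, cur.e * eff.resistance_shift

    def epsilon(self, cell_line: str, condition: str, drug_a: str, drug_b: str) -> float:
        return self.interactions.get((cell_line, condition, drug_a, drug_b), 0.0)

    def expected_inhibition(self, cell_line, condition, drug, conc) -> np.ndarray:
        """Noise-free inhibition fraction in [0, 1] at molar dose(s) conc."""
        b, d, e = self.effective_params(cell_line, condition, drug)
        conc = np.asarray(conc, dtype=float)
        out = np.zeros(conc.shape)
        pos = conc > 0
        out[pos] = (d / 100.0) / (1.0 + (e / conc[pos]) ** b)
        return out if out.shape else float(out)

    def expected_viability(self, cell_line, condition, drug, conc) -> np.ndarray:
        return 100.0 * (1.0 - self.expected_inhibition(cell_line, condition, drug, conc))


def default_config(seed: int = 0, noise_cv: float = 0.05) -> ScreenConfig:
    return ScreenConfig(seed=seed, noise_cv=noise_cv)


def default_truth(
    config: ScreenConfig,
    seed: int | None = None,
    resistant_condition: str | None = "A19",
    resistant_effect: ConditionEffect = ConditionEffect(10.0, 50.0),
) -> TruthSet:
    """Draw a plausible ground truth for a screen configuration.

    Midpoints sit in the central decades of each drug's titration, Hill
    slopes near 1, full maximal inhibition for standard-of-care drugs and
    85-100% for the repurposed ones.  Ordinary AAF conditions carry mild
    resistance (midpoint shift 1-3x, efficacy loss up to 20 points);
    ``resistant_condition`` (the carcinosarcoma-ascites analogue) carries a
    strong shift in every cell line.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    curves = {}
    for cell in config.cell_lines:
        for drug in config.drugs:
            conc = np.asarray(drug.concentrations)
            center = math.sqrt(conc.min() * conc.max())
            e = center * 10.0 ** rng.uniform(-0.75, 0.75)
            b = rng.uniform(0.8, 1.6)
            d = 100.0 if drug.role == "standard_of_care" else rng.uniform(85.0, 100.0)
            curves[(cell, drug.name)] = CurveTruth(b=b, e=e, d=d)
    effects = {}
    for cell in config.cell_lines:
        for cond in config.media_conditions:
            if cond == "media":
                effects[(cell, cond)] = ConditionEffect()
            elif cond == resistant_condition:
                effects[(cell, cond)] = resistant_effect
            else:
                effects[(cell, cond)] = ConditionEffect(
                    resistance_shift=10.0 ** rng.uniform(0.0, 0.5),
                    efficacy_loss=rng.uniform(0.0, 20.0),
                )
    return TruthSet(curves=curves, condition_effects=effects,
                    seed=config.seed if seed is None else seed)


def _well_address(idx: int) -> tuple[str, str, int]:
    row, col = _ROWS[idx // 24], idx % 24 + 1
    return f"{row}{col:02d}", row, col


def generate_screen(config: ScreenConfig, truth: TruthSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full single-agent screen as long-format well records.

    One plate per (cell line, condition, biological replicate).  Each plate
    carries the treatment wells (drugs x doses x technical replicates),
    negative controls (untreated, full viability), positive controls (full
    kill) and vehicle-gradient wells at the high/low DMSO percentages.  The
    raw signal is ``RFU = plate_gain * viability_fraction * exp(N(0, sigma))``
    with sigma set from ``noise_cv``; the plate gain is drawn once per plate
    (uniform in [0.8, 1.2] x nominal) to exercise per-plate normalisation.

    Returns ``(wells, plates)``: the well table (including the exact
    expected ``true_viability`` of every well) and the per-plate gain truth.
    """
    for cell in config.cell_lines:
        for drug in config.drugs:
            truth.curve(cell, drug.name)
        for cond in config.media_conditions:
            truth.effect(cell, cond)

    rng = np.random.default_rng(config.seed)
    sigma = _lognormal_sigma(config.noise_cv)
    sigma_bio = _lognormal_sigma(config.bio_rep_cv)
    wells_rows: list[dict] = []
    plate_rows: list[dict] = []

    for cell in config.cell_lines:
        for cond in config.media_conditions:
            for bio in range(1, config.replicates_biological + 1):
                plate_id = f"{cell}:{cond}:b{bio}"
                gain = rng.uniform(0.8, 1.2) * _NOMINAL_RFU
                plate_rows.append({"plate_id": plate_id, "gain": gain})
                plate: list[tuple] = []  # (role, drug, conc, tech, v_true)
                for role, count in config.control_counts.items():
                    v = 0.0 if role == "pos_control" else 100.0
                    for k in range(count):
                        plate.append((role, "", 0.0, k + 1, v))
                for drug in config.drugs:
                    # biological replicates perturb the true midpoint
                    # (passage effects); technical replicates share it
                    bmult = math.exp(rng.normal(0.0, sigma_bio)) if sigma_bio > 0 else 1.0
                    b, d, e = truth.effective_params(cell, cond, drug.name)
                    e_bio = e * bmult
                    for conc in drug.concentrations:
                        frac = (d / 100.0) / (1.0 + (e_bio / conc) ** b)
                        v = 100.0 * (1.0 - frac)
                        for tech in range(1, config.replicates_technical + 1):
                            plate.append((drug.name, conc, tech, v))
                # controls were appended as 5-tuples, treatments as 4-tuples;
                # normalise and emit in plate order
                noise = (
                    np.exp(rng.normal(0.0, sigma, size=len(plate)))
                    if sigma > 0 else np.ones(len(plate))
                )
                for idx, entry in enumerate(plate):
                    if len(entry) == 5:
                        role, drug_name, conc, tech, v = entry
                    else:
                        drug_name, conc, tech, v = entry
                        role = "treatment"
                    well, row, col = _well_address(idx)
                    wells_rows.append({
                        "plate_id": plate_id, "well": well, "row": row,
                        "col": col, "cell_line": cell, "condition": cond,
                        "bio_rep": bio, "tech_rep": tech, "drug1": drug_name,
                        "conc1_M": conc, "drug2": "", "conc2_M": 0.0,
                        "role": role,
                        "rfu": gain * (v / 100.0) * noise[idx],
                        "true_viability": v,
                    })
    wells = pd.DataFrame(wells_rows)
    plates = pd.DataFrame(plate_rows)
    return wells, plates


def combination_doses(truth: TruthSet, cell_line: str, drug: str,
                      n: int = 6, shift_decades: float = 1.0) -> np.ndarray:
    """Default combination titration for a drug: six half-log doses ending at
    the media-condition midpoint, shifted ``shift_decades`` down relative to
    a midpoint-centred single-agent window."""
    cur = truth.curve(cell_line, drug)
    top = cur.e * 10.0 ** (1.5 - shift_decades)
    return top * 10.0 ** (-0.5 * np.arange(n)[::-1])


def generate_combination_grid(
    truth: TruthSet,
    cell_line: str,
    condition: str,
    drug_a: str,
    drug_b: str,
    conc_a: np.ndarray | None = None,
    conc_b: np.ndarray | None = None,
    design: str = "anchored",
    anchor_p: float = 20.0,
    epsilon: float | None = None,
    noise_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> CombinationGrid:
    """Generate a dose-pair viability grid with a known expected surface.

    The noise-free expected inhibition fraction at (x1, x2) is the Bliss
    surface ``y1 + y2 - y1*y2`` plus ``epsilon`` wherever both doses are
    positive, clipped to [0, 1]; viability noise is multiplicative
    log-normal as in :func:`generate_screen` and averaged over
    ``n_replicates``.  An anchored design fixes ``drug_a`` at its true
    IC``anchor_p`` in this condition (the priming dose); a factorial design
    crosses full titrations.  Zero-dose levels are prepended automatically.
    """
    b_a, d_a, e_a = truth.effective_params(cell_line, condition, drug_a)
    if epsilon is None:
        epsilon = truth.epsilon(cell_line, condition, drug_a, drug_b)
    if not (-1.0 <= epsilon <= 1.0):
        raise ValueError(f"epsilon out of [-1, 1]: {epsilon}")

    if conc_b is None:
        conc_b = combination_doses(truth, cell_line, drug_b)
    conc_b = np.asarray(conc_b, dtype=float)
    if design == "anchored":
        if conc_a is not None:
            conc_a = np.asarray(conc_a, dtype=float)
            if conc_a.size != 1 or conc_a[0] <= 0:
                raise ValueError("anchored design takes one positive priming dose")
            anchor = float(conc_a[0])
        else:
            if not (0.0 < anchor_p < d_a):
                raise ValueError(
                    f"priming IC{anchor_p:g} not reached (max inhibition {d_a:g}%)"
                )
            anchor = e_a * (anchor_p / (d_a - anchor_p)) ** (1.0 / b_a)
        conc_a = np.array([anchor])
    elif design == "factorial":
        if conc_a is None:
            conc_a = combination_doses(truth, cell_line, drug_a)
        conc_a = np.asarray(conc_a, dtype=float)
    else:
        raise ValueError(f"unknown design {design!r}")

    ca = np.concatenate(([0.0], conc_a))
    cb = np.concatenate(([0.0], conc_b))
    ya = truth.expected_inhibition(cell_line, condition, drug_a, ca)
    yb = truth.expected_inhibition(cell_line, condition, drug_b, cb)
    bliss = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    both = (ca[:, None] > 0) & (cb[None, :] > 0)
    y_true = np.clip(bliss + epsilon * both, 0.0, 1.0)
    v_true = 100.0 * (1.0 - y_true)

    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = _lognormal_sigma(noise_cv)
        reps = v_true[None, :, :] * np.exp(
            rng.normal(0.0, sigma, size=(n_replicates,) + v_true.shape)
        )
        v_obs = reps.mean(axis=0)
    else:
        v_obs = v_true.copy()

    return CombinationGrid(
        drug_a=drug_a, drug_b=drug_b, conc_a=ca, conc_b=cb,
        viability=v_obs, design=design, cell_line=cell_line,
        condition=condition, true_inhibition=y_true,
    )


# --------------------------------------------------------------------------
# phospho-marker tables

DEFAULT_MARKERS = (
    "STAT1_pY701", "STAT3_pY705", "STAT5_pY694", "STAT6_pY641", "JAK2",
    "AKT_pT308", "AKT_pS473", "S6RP_pS235_236", "NFkB_pS529", "NFkB_pS536",
    "MAPKAPK2_pT334", "p38_pT180_Y182", "SAPK_JNK", "ATF2_pT71", "MEK1_pS298",
    "CDC2_pT161", "HistoneH3_pS10", "VAV_pY174", "RB_pS807_811", "GSK3A",
    "GSK3B", "ERK1_2_pT202_Y204", "mTOR_pS2448", "PLCg2_pY759", "SRC_pY418",
    "ZAP70_pY319", "LCK_pY505", "CREB_pS133", "p53_pS15", "AMPK_pT172",
    "PTEN_pS380",
)


@dataclass(frozen=True)
class MarkerTruth:
    """Ground truth for a phospho-marker median-fluorescence table: 31
    markers, per-marker mean log2 fold-change under AAF stimulation,
    marker-marker correlation targets and per-marker noise SD."""

    markers: tuple = DEFAULT_MARKERS
    mean_fold: dict = field(default_factory=dict)  # marker -> log2 FC
    correlations: tuple = ()  # (marker_i, marker_j, rho)
    noise_sd: dict = field(default_factory=dict)  # marker -> SD of log2 FC
    igg_base: float = 100.0
    seed: int = 0

    def __post_init__(self):
        for mi, mj, rho in self.correlations:
            if mi not in self.markers or mj not in self.markers:
                raise ValueError(f"correlation target names unknown marker: {mi}, {mj}")
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"|rho| must be <= 1, got {rho}")

    def correlation_matrix(self) -> np.ndarray:
        m = len(self.markers)
        idx = {name: i for i, name in enumerate(self.markers)}
        corr = np.eye(m)
        for mi, mj, rho in self.correlations:
            corr[idx[mi], idx[mj]] = corr[idx[mj], idx[mi]] = rho
        eig = np.linalg.eigvalsh(corr)
        if eig.min() < -1e-10:
            raise ValueError(
                "infeasible correlation target set (matrix not positive "
                f"semi-definite; min eigenvalue {eig.min():.3g})"
            )
        return corr


def default_marker_truth(seed: int = 0) -> MarkerTruth:
    """Fold-change and correlation structure echoing the AAF-stimulation
    profile: strong STAT3/STAT5 activation with r = 0.88, tightly coupled
    MAPKAPK2/p38 (r = 0.98), moderate AKT/S6RP coupling (r = 0.62)."""
    mean_fold = {m: 0.3 for m in DEFAULT_MARKERS}
    mean_fold.update({
        "STAT3_pY705": 2.0, "STAT5_pY694": 1.6, "STAT1_pY701": 1.0,
        "STAT6_pY641": 1.2, "S6RP_pS235_236": 1.8, "AKT_pS473": 1.2,
        "AKT_pT308": 1.0, "MAPKAPK2_pT334": 0.8, "p38_pT180_Y182": 0.8,
        "MEK1_pS298": 0.7, "CDC2_pT161": 1.0,
    })
    # STAT1-STAT5 filled in so the JAK/STAT block stays positive
    # semi-definite alongside the two reported pairs
    correlations = (
        ("STAT3_pY705", "STAT5_pY694", 0.88),
        ("STAT3_pY705", "STAT1_pY701", 0.65),
        ("STAT1_pY701", "STAT5_pY694", 0.60),
        ("MAPKAPK2_pT334", "p38_pT180_Y182", 0.98),
        ("AKT_pS473", "S6RP_pS235_236", 0.62),
    )
    noise_sd = {m: 0.5 for m in DEFAULT_MARKERS}
    return MarkerTruth(mean_fold=mean_fold, correlations=correlations,
                       noise_sd=noise_sd, seed=seed)


@dataclass(frozen=True)
class MarkerTable:
    """A median-fluorescence table (stimulation rows x marker columns, plus
    an IgG control column and an unstimulated control row) with a flag for
    whether sample correlations are estimable with any reliability."""

    table: pd.DataFrame
    correlation_reliable: bool
    control_row: str = "media"
    igg_col: str = "IgG"


def generate_marker_table(
    mtruth: MarkerTruth,
    n_samples: int,
    seed: int | None = None,
) -> MarkerTable:
    """Median-fluorescence table whose sample correlations converge to the
    targets as ``n_samples`` grows.

    Stimulated rows carry log2 fold-changes drawn from a multivariate normal
    with the target correlation structure; fluorescence is
    ``igg_base * 2**fold``.  The correlation feasibility check runs before
    any sampling.  Tables with fewer than 10 stimulated samples are flagged
    as unreliable for correlation recovery.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 stimulated samples")
    corr = mtruth.correlation_matrix()  # raises if infeasible
    rng = np.random.default_rng(mtruth.seed if seed is None else seed)
    markers = list(mtruth.markers)
    means = np.array([mtruth.mean_fold.get(m, 0.0) for m in markers])
    sds = np.array([mtruth.noise_sd.get(m, 0.5) for m in markers])

    # eigendecomposition root (tolerates semi-definite targets)
    eigval, eigvec = np.linalg.eigh(corr)
    root = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    z = rng.standard_normal((n_samples, len(markers))) @ root.T
    folds = means[None, :] + sds[None, :] * z

    rows = [f"A{i + 1}" for i in range(n_samples)]
    fluor = mtruth.igg_base * 2.0 ** folds
    table = pd.DataFrame(fluor, index=rows, columns=markers)
    table.loc["media"] = mtruth.igg_base  # unstimulated baseline, fold 0
    table["IgG"] = mtruth.igg_base
    return MarkerTable(table=table, correlation_reliable=n_samples >= 10)
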
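"""Plate-level quality control and conversion of raw RFU to percent viability.

Works on the long-format well table (one row per well; columns ``plate_id``,
``well``, ``cell_line``, ``condition``, ``drug1``/``conc1_M`` (and optional
``drug2``/``conc2_M``), ``role``, ``rfu``).  Two normalisation modes are
provided, matching the two experiment types: control-based (negative = 100%
viability, positive = full kill) for the DSS screens, and vehicle-based
(reference = the high/low DMSO vehicle wells) for the concentration-response
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlateQC",
    "z_prime",
    "plate_qc",
    "normalize_controls",
    "normalize_vehicle",
    "aggregate_replicates",
]

#: default Z' pass cutoff, standard high-throughput-screening practice
DEFAULT_Z_PRIME_CUTOFF = 0.5


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    mu_neg: float
    sd_neg: float
    mu_pos: float
    sd_pos: float
    z_prime: float
    pass_flag: bool


def z_prime(neg_rfu, pos_rfu) -> float:
    """Z' = 1 - 3 (sd_pos + sd_neg) / |mu_pos - mu_neg| (<= 1 always)."""
    neg = np.asarray(neg_rfu, dtype=float)
    pos = np.asarray(pos_rfu, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("need >= 2 wells in each control group")
    mu_n, mu_p = neg.mean(), pos.mean()
    if mu_n == mu_p:
        raise ValueError("control means are equal; plate signal is unusable")
    sd_n = neg.std(ddof=1)
    sd_p = pos.std(ddof=1)
    return float(1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n))


def plate_qc(wells: pd.DataFrame, cutoff: float = DEFAULT_Z_PRIME_CUTOFF) -> pd.DataFrame:
    """Per-plate control statistics, Z' and pass flag."""
    rows = []
    for plate_id, grp in wells.groupby("plate_id", sort=True):
        neg = grp.loc[grp["role"] == "neg_control", "rfu"].to_numpy()
        pos = grp.loc[grp["role"] == "pos_control", "rfu"].to_numpy()
        if neg.size == 0 or pos.size == 0:
            raise ValueError(f"plate {plate_id!r} is missing control wells")
        zp = z_prime(neg, pos)
        rows.append(PlateQC(
            plate_id=plate_id, mu_neg=float(neg.mean()),
            sd_neg=float(neg.std(ddof=1)), mu_pos=float(pos.mean()),
            sd_pos=float(pos.std(ddof=1)), z_prime=zp,
            pass_flag=bool(zp >= cutoff),
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


_POINT_COLS = [
    "plate_id", "well", "cell_line", "condition", "bio_rep", "tech_rep",
    "drug1", "conc1_M", "drug2", "conc2_M", "role",
]


def _carry_columns(grp: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in _POINT_COLS if c in grp.columns]
    return grp[cols].copy()


def normalize_controls(wells: pd.DataFrame) -> pd.DataFrame:
    """Percent viability by per-plate control normalisation.

    ``viability_pct = 100 (rfu - mu_pos) / (mu_neg - mu_pos)`` where the
    negative controls are untreated (100% viability) and the positive
    controls a full kill (0%).  Values are not clipped: information outside
    [0, 100] is preserved for fitting.  Fails naming the plate when a
    control role is absent.
    """
    frames = []
    for plate_id, grp in wells.groupby("plate_id", sort=True):
        neg = grp.loc[grp["role"] == "neg_control", "rfu"]
        pos = grp.loc[grp["role"] == "pos_control", "rfu"]
        if neg.empty or pos.empty:
            missing = "neg_control" if neg.empty else "pos_control"
            raise ValueError(f"plate {plate_id!r} has no {missing} wells")
        mu_n, mu_p = neg.mean(), pos.mean()
        if mu_n == mu_p:
            raise ValueError(f"plate {plate_id!r}: control means are equal")
        out = _carry_columns(grp)
        out["viability_pct"] = 100.0 * (grp["rfu"] - mu_p) / (mu_n - mu_p)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def normalize_vehicle(wells: pd.DataFrame, reference: str = "mean_of_means") -> pd.DataFrame:
    """Percent viability relative to the vehicle ('0 M') reference.

    The zero-dose reference per plate is the mean of the high-DMSO and
    low-DMSO vehicle-well means (``reference="mean_of_means"``), or the
    grand mean of all vehicle wells (``reference="grand_mean"``); each
    well's relative viability is ``100 * rfu / reference``.  For
    water-solvent drugs with no vehicle gradient the untreated negative
    controls serve as the reference (the vehicle ratio is identically 1,
    alias 100% viability).
    """
    if reference not in ("mean_of_means", "grand_mean"):
        raise ValueError(f"unknown reference rule {reference!r}")
    frames = []
    for plate_id, grp in wells.groupby("plate_id", sort=True):
        high = grp.loc[grp["role"] == "vehicle_high", "rfu"]
        low = grp.loc[grp["role"] == "vehicle_low", "rfu"]
        if high.empty or low.empty:
            neg = grp.loc[grp["role"] == "neg_control", "rfu"]
            if neg.empty:
                raise ValueError(
                    f"plate {plate_id!r} has no vehicle wells and no "
                    "untreated controls to normalise against"
                )
            ref = neg.mean()
        elif reference == "mean_of_means":
            ref = (high.mean() + low.mean()) / 2.0
        else:
            ref = pd.concat([high, low]).mean()
        if ref <= 0:
            raise ValueError(f"plate {plate_id!r}: nonpositive vehicle reference")
        out = _carry_columns(grp)
        out["viability_pct"] = 100.0 * grp["rfu"] / ref
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def aggregate_replicates(points: pd.DataFrame, policy: str = "mean") -> pd.DataFrame:
    """Collapse replicates to one viability per (condition, drug, dose).

    Returns mean viability with SD and n attached; single replicates pass
    through with n = 1 and SD = NaN.
    """
    if policy not in ("mean", "median"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    keys = [c for c in ("cell_line", "condition", "drug1", "conc1_M",
                        "drug2", "conc2_M") if c in points.columns]
    treated = points[points["role"] == "treatment"] if "role" in points.columns else points
    agg = treated.groupby(keys, sort=True)["viability_pct"].agg(
        viability_pct=policy, viability_sd="std", n="size"
    ).reset_index()
    return agg
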
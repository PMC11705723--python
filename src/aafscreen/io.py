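"""CSV/YAML round-tripping of screen tables, truth sets and configs.

The long-format plate CSV carries one row per well with columns
``plate_id, well, row, col, cell_line, condition, drug1, conc1_M, drug2,
conc2_M, role, rfu`` (generated tables add ``bio_rep``, ``tech_rep`` and
``true_viability``).  The screen config is a flat YAML mapping::

    cell_lines: [SKOV3, ...]
    media_conditions: [media, A1, ...]
    drugs:
      - {name: carboplatin, role: standard_of_care, concentrations: [1e-6, ...]}
    replicates_technical: 3
    replicates_biological: 2
    noise_cv: 0.05
    control_counts: {neg_control: 12, pos_control: 12,
                     vehicle_high: 6, vehicle_low: 6}
    seed: 0
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .synthetic import (
    ConditionEffect,
    CurveTruth,
    DrugSpec,
    ScreenConfig,
    TruthSet,
)

__all__ = [
    "write_wells", "read_wells",
    "write_truth", "read_truth",
    "write_config", "read_config",
]

WELL_COLUMNS = [
    "plate_id", "well", "row", "col", "cell_line", "condition", "bio_rep",
    "tech_rep", "drug1", "conc1_M", "drug2", "conc2_M", "role", "rfu",
    "true_viability",
]


def write_wells(wells: pd.DataFrame, path) -> None:
    cols = [c for c in WELL_COLUMNS if c in wells.columns]
    wells[cols].to_csv(path, index=False)


def read_wells(path) -> pd.DataFrame:
    wells = pd.read_csv(path, keep_default_na=False, na_values=[])
    for col in ("drug1", "drug2"):
        if col in wells.columns:
            wells[col] = wells[col].astype(str)
    return wells


def write_truth(truth: TruthSet, path) -> None:
    """Serialise a truth set as a single tidy CSV (three record kinds)."""
    rows = []
    for (cell, drug), cur in sorted(truth.curves.items()):
        rows.append({"kind": "curve", "cell_line": cell, "key1": drug,
                     "key2": "", "b": cur.b, "e": cur.e, "d": cur.d,
                     "value": ""})
    for (cell, cond), eff in sorted(truth.condition_effects.items()):
        rows.append({"kind": "condition_effect", "cell_line": cell,
                     "key1": cond, "key2": "", "b": "", "e": "", "d": "",
                     "value": f"{eff.resistance_shift}|{eff.efficacy_loss}"})
    for (cell, cond, da, db), eps in sorted(truth.interactions.items()):
        rows.append({"kind": "interaction", "cell_line": cell, "key1": cond,
                     "key2": f"{da}|{db}", "b": "", "e": "", "d": "",
                     "value": eps})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth(path) -> TruthSet:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    curves, effects, interactions = {}, {}, {}
    for _, r in df.iterrows():
        if r["kind"] == "curve":
            curves[(r["cell_line"], r["key1"])] = CurveTruth(
                b=float(r["b"]), e=float(r["e"]), d=float(r["d"]))
        elif r["kind"] == "condition_effect":
            shift, loss = str(r["value"]).split("|")
            effects[(r["cell_line"], r["key1"])] = ConditionEffect(
                resistance_shift=float(shift), efficacy_loss=float(loss))
        elif r["kind"] == "interaction":
            da, db = str(r["key2"]).split("|")
            interactions[(r["cell_line"], r["key1"], da, db)] = float(r["value"])
        else:
            raise ValueError(f"unknown truth record kind {r['kind']!r}")
    return TruthSet(curves=curves, condition_effects=effects,
                    interactions=interactions)


def write_config(config: ScreenConfig, path) -> None:
    doc = {
        "cell_lines": list(config.cell_lines),
        "media_conditions": list(config.media_conditions),
        "drugs": [
            {"name": d.name, "role": d.role,
             "concentrations": [float(c) for c in d.concentrations]}
            for d in config.drugs
        ],
        "replicates_technical": config.replicates_technical,
        "replicates_biological": config.replicates_biological,
        "noise_cv": config.noise_cv,
        "bio_rep_cv": config.bio_rep_cv,
        "control_counts": dict(config.control_counts),
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path) -> ScreenConfig:
    doc = yaml.safe_load(Path(path).read_text())
    drugs = tuple(
        DrugSpec(name=d["name"], role=d.get("role", "novel"),
                 concentrations=tuple(float(c) for c in d["concentrations"]))
        for d in doc["drugs"]
    )
    return ScreenConfig(
        cell_lines=tuple(doc["cell_lines"]),
        media_conditions=tuple(doc["media_conditions"]),
        drugs=drugs,
        replicates_technical=int(doc.get("replicates_technical", 3)),
        replicates_biological=int(doc.get("replicates_biological", 2)),
        noise_cv=float(doc.get("noise_cv", 0.05)),
        bio_rep_cv=float(doc.get("bio_rep_cv", 0.05)),
        control_counts=dict(doc.get("control_counts"))
        if doc.get("control_counts") else ScreenConfig().control_counts,
        seed=int(doc.get("seed", 0)),
    )
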
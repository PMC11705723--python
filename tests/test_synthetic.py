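"""Ground-truth screen, combination-grid and marker-table generation."""

import numpy as np
import pytest

from aafscreen import io as aio
from aafscreen.synthetic import (
    ConditionEffect,
    CurveTruth,
    DrugSpec,
    MarkerTruth,
    ScreenConfig,
    TruthSet,
    default_marker_truth,
    default_truth,
    generate_combination_grid,
    generate_marker_table,
    generate_screen,
    half_log_grid,
)


def single_drug_truth(b=1.0, e=1e-6, d=100.0, cell="X", drug="d1",
                      conditions=("media",), **effects):
    eff = {(cell, c): effects.get(c, ConditionEffect()) for c in conditions}
    return TruthSet(curves={(cell, drug): CurveTruth(b=b, e=e, d=d)},
                    condition_effects=eff)


def single_drug_config(seed=0, noise_cv=0.0, conditions=("media",), **kw):
    return ScreenConfig(
        cell_lines=("X",), media_conditions=conditions,
        drugs=(DrugSpec("d1", half_log_grid(1e-8, 8)),),
        noise_cv=noise_cv, bio_rep_cv=0.0, seed=seed, **kw,
    )


class TestScreenGeneration:
    def test_midpoint_well_has_exactly_half_viability(self):
        truth = single_drug_truth(e=1e-6)
        cfg = ScreenConfig(
            cell_lines=("X",), media_conditions=("media",),
            drugs=(DrugSpec("d1", (1e-7, 1e-6, 1e-5)),),
            noise_cv=0.0, bio_rep_cv=0.0, seed=0,
        )
        wells, _ = generate_screen(cfg, truth)
        mid = wells[(wells["conc1_M"] == 1e-6)]
        assert np.allclose(mid["true_viability"], 50.0)

    def test_seeded_generation_is_byte_identical(self):
        cfg = single_drug_config(seed=42, noise_cv=0.05)
        truth = single_drug_truth()
        a = generate_screen(cfg, truth)[0].to_csv(index=False)
        b = generate_screen(cfg, truth)[0].to_csv(index=False)
        assert a == b

    def test_well_count_matches_design(self):
        cfg = ScreenConfig(
            cell_lines=("X", "Y"), media_conditions=("media", "A1"),
            drugs=(DrugSpec("d1", half_log_grid(1e-8, 8)),
                   DrugSpec("d2", half_log_grid(1e-7, 6))),
            replicates_technical=3, replicates_biological=2, seed=1,
        )
        truth = TruthSet(
            curves={(c, d): CurveTruth(1.0, 1e-6) for c in "XY"
                    for d in ("d1", "d2")},
            condition_effects={(c, m): ConditionEffect() for c in "XY"
                               for m in ("media", "A1")},
        )
        wells, plates = generate_screen(cfg, truth)
        n_plates = 2 * 2 * 2
        per_plate = (8 + 6) * 3 + sum(cfg.control_counts.values())
        assert len(plates) == n_plates
        assert len(wells) == n_plates * per_plate
        treat = wells[wells["role"] == "treatment"]
        assert len(treat) == n_plates * (8 + 6) * 3

    def test_missing_truth_entry_is_a_descriptive_failure(self):
        cfg = single_drug_config()
        truth = TruthSet(curves={}, condition_effects={})
        with pytest.raises(KeyError, match="truth entry missing"):
            generate_screen(cfg, truth)

    def test_noise_model_produces_stated_cv(self):
        # 6 same-plate technical replicates per dose at noise_cv = 0.05:
        # most per-dose sample CVs land in [0.02, 0.08]
        cfg = ScreenConfig(
            cell_lines=("W", "X", "Y", "Z"), media_conditions=("media",),
            drugs=tuple(DrugSpec(f"d{k}", half_log_grid(1e-8, 8))
                        for k in range(5)),
            replicates_technical=6, replicates_biological=1,
            noise_cv=0.05, bio_rep_cv=0.0, seed=0,
        )
        truth = TruthSet(
            curves={(c, f"d{k}"): CurveTruth(1.0, 10.0 ** (-6.5 + 0.2 * k))
                    for c in "WXYZ" for k in range(5)},
            condition_effects={(c, "media"): ConditionEffect() for c in "WXYZ"},
        )
        wells, _ = generate_screen(cfg, truth)
        treat = wells[wells["role"] == "treatment"]
        cv = treat.groupby(["cell_line", "drug1", "conc1_M"])["rfu"].apply(
            lambda s: s.std(ddof=1) / s.mean()
        )
        frac = np.mean((cv >= 0.02) & (cv <= 0.08))
        assert frac >= 0.90

    def test_resistance_shift_doubles_ic50_crossing(self):
        truth = single_drug_truth(
            conditions=("media", "A1", "A2"),
            A1=ConditionEffect(resistance_shift=2.0),
            A2=ConditionEffect(resistance_shift=4.0),
        )

        def crossing(cond):
            conc = np.logspace(-9, -3, 20_001)
            v = truth.expected_viability("X", cond, "d1", conc)
            return conc[np.argmin(np.abs(v - 50.0))]

        assert crossing("A1") / crossing("media") == pytest.approx(2.0, rel=1e-3)
        assert crossing("A2") / crossing("A1") == pytest.approx(2.0, rel=1e-3)

    def test_efficacy_loss_raises_viability_floor(self):
        truth = single_drug_truth(conditions=("media", "A1"),
                                  A1=ConditionEffect(efficacy_loss=40.0))
        v = truth.expected_viability("X", "A1", "d1", np.array([1.0]))
        assert v[0] == pytest.approx(40.0, abs=1e-3)


class TestCombinationGrids:
    truth = TruthSet(
        curves={("X", "da"): CurveTruth(1.0, 1e-6),
                ("X", "db"): CurveTruth(1.0, 2e-6)},
        condition_effects={("X", "media"): ConditionEffect()},
    )

    def test_bliss_independence_of_half_inhibitions(self):
        g = generate_combination_grid(
            self.truth, "X", "media", "da", "db",
            conc_a=np.array([1e-6]), conc_b=np.array([2e-6]),
            design="anchored", epsilon=0.0,
        )
        # y1 = y2 = 0.5 -> combined 0.75
        assert g.true_inhibition[1, 1] == pytest.approx(0.75)

    def test_epsilon_only_acts_when_both_doses_positive(self):
        g = generate_combination_grid(
            self.truth, "X", "media", "da", "db",
            conc_a=np.array([1e-6]), conc_b=np.array([2e-6]),
            design="anchored", epsilon=0.2,
        )
        assert g.true_inhibition[0, 0] == pytest.approx(0.0)
        assert g.true_inhibition[1, 1] == pytest.approx(0.95)

    def test_epsilon_addition_formula(self):
        # y1 = 0.3, y2 = 0.4, eps = 0.1 -> 0.58 + 0.1
        truth = TruthSet(
            curves={("X", "da"): CurveTruth(1.0, 1e-6),
                    ("X", "db"): CurveTruth(1.0, 1e-6)},
            condition_effects={("X", "media"): ConditionEffect()},
        )
        xa = 1e-6 * (0.3 / 0.7)  # dose where y = 0.3
        xb = 1e-6 * (0.4 / 0.6)
        g = generate_combination_grid(
            truth, "X", "media", "da", "db",
            conc_a=np.array([xa]), conc_b=np.array([xb]),
            design="anchored", epsilon=0.1,
        )
        assert g.true_inhibition[1, 1] == pytest.approx(0.68, abs=1e-12)

    def test_anchor_defaults_to_true_ic20(self):
        g = generate_combination_grid(self.truth, "X", "media", "da", "db",
                                      design="anchored", anchor_p=20.0)
        anchor = g.conc_a[g.conc_a > 0][0]
        assert anchor == pytest.approx(1e-6 * (20.0 / 80.0))

    def test_grid_without_zero_level_rejected(self):
        from aafscreen.synergy import CombinationGrid
        with pytest.raises(ValueError, match="zero-dose"):
            CombinationGrid(
                drug_a="a", drug_b="b", conc_a=np.array([1e-7, 1e-6]),
                conc_b=np.array([0.0, 1e-6]),
                viability=np.full((2, 2), 50.0),
            )


class TestMarkerTables:
    def test_target_correlation_recovered_at_large_n(self):
        mt = default_marker_truth(seed=11)
        table = generate_marker_table(mt, n_samples=500)
        fc = np.log2(
            table.table.drop(columns=["IgG"]).drop(index="media")
            / mt.igg_base
        )
        r = np.corrcoef(fc["STAT3_pY705"], fc["STAT5_pY694"])[0, 1]
        assert r == pytest.approx(0.88, abs=0.05)

    def test_null_targets_give_near_zero_correlations(self):
        mt = MarkerTruth(seed=3)  # no correlation targets
        table = generate_marker_table(mt, n_samples=1000)
        fc = table.table.drop(columns=["IgG"]).drop(index="media")
        r = np.corrcoef(fc.to_numpy().T)
        off = r[~np.eye(r.shape[0], dtype=bool)]
        assert np.max(np.abs(off)) < 0.15

    def test_small_sample_flagged_unreliable(self):
        table = generate_marker_table(default_marker_truth(), n_samples=3)
        assert not table.correlation_reliable
        assert len(table.table) == 4  # 3 stimulations + control row

    def test_infeasible_targets_fail_before_sampling(self):
        mt = MarkerTruth(
            markers=("m1", "m2", "m3"),
            correlations=(("m1", "m2", 0.95), ("m1", "m3", 0.95),
                          ("m2", "m3", -0.9)),
        )
        with pytest.raises(ValueError, match="infeasible"):
            generate_marker_table(mt, n_samples=10)


class TestRoundTrips:
    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = single_drug_config(seed=9, noise_cv=0.07)
        path = tmp_path / "config.yaml"
        aio.write_config(cfg, path)
        assert aio.read_config(path) == cfg

    def test_truth_csv_roundtrip(self, tmp_path):
        cfg = ScreenConfig(seed=4)
        truth = default_truth(cfg)
        truth = TruthSet(curves=truth.curves,
                         condition_effects=truth.condition_effects,
                         interactions={("SKOV3", "A1", "carboplatin",
                                        "rapamycin"): 0.15})
        path = tmp_path / "truth.csv"
        aio.write_truth(truth, path)
        back = aio.read_truth(path)
        assert back.curves == truth.curves
        assert back.condition_effects == truth.condition_effects
        assert back.interactions == truth.interactions

    def test_wells_csv_roundtrip(self, tmp_path):
        cfg = single_drug_config(seed=2, noise_cv=0.05)
        wells, _ = generate_screen(cfg, single_drug_truth())
        path = tmp_path / "wells.csv"
        aio.write_wells(wells, path)
        back = aio.read_wells(path)
        assert back["rfu"].to_numpy() == pytest.approx(wells["rfu"].to_numpy())
        assert (back["role"] == wells["role"]).all()
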
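"""Combination ratio, ZIP deltas, 100-VUS and treatment ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.interpolate import RegularGridInterpolator

from aafscreen.synergy import (
    CombinationGrid,
    best_treatments,
    combination_ratio,
    rank_treatments,
    synergy_call,
    vus,
    zip_delta,
)
from aafscreen.synthetic import (
    ConditionEffect,
    CurveTruth,
    TruthSet,
    generate_combination_grid,
)


def two_drug_truth(b1=1.0, e1=1e-6, d1=100.0, b2=1.0, e2=2e-6, d2=100.0):
    return TruthSet(
        curves={("X", "da"): CurveTruth(b1, e1, d1),
                ("X", "db"): CurveTruth(b2, e2, d2)},
        condition_effects={("X", "media"): ConditionEffect()},
    )


class TestCombinationRatio:
    @pytest.mark.parametrize("combo,mono,expected", [
        (40.0, 40.0, 1.0),
        (0.0, 0.0, 1.0),   # the case the +100 augmentation exists for
        (50.0, 0.0, 1.5),
    ])
    def test_worked_values(self, combo, mono, expected):
        assert combination_ratio(combo, mono).cr == pytest.approx(expected)

    def test_out_of_range_dss_rejected(self):
        with pytest.raises(ValueError):
            combination_ratio(120.0, 50.0)

    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0.5, 30))
    def test_bounds_and_monotonicity(self, combo, mono, bump):
        cr = combination_ratio(combo, mono).cr
        assert 0.5 <= cr <= 2.0
        if combo + bump <= 100:
            assert combination_ratio(combo + bump, mono).cr > cr
        if mono + bump <= 100:
            assert combination_ratio(combo, mono + bump).cr < cr


class TestZIP:
    def test_noiseless_bliss_grid_scores_zero(self):
        g = generate_combination_grid(
            two_drug_truth(), "X", "media", "da", "db",
            design="factorial", epsilon=0.0,
        )
        assert abs(zip_delta(g).summary) < 1e-6

    def test_uniform_epsilon_recovered_on_clip_free_grid(self):
        # partial-efficacy marginals keep the shifted surface inside [0, 1]
        truth = two_drug_truth(d1=70.0, d2=70.0)
        ca = 1e-6 * 10.0 ** np.arange(-1.0, 1.51, 0.5)
        cb = 2e-6 * 10.0 ** np.arange(-1.0, 1.51, 0.5)
        for eps in (0.10, -0.10):
            g = generate_combination_grid(
                truth, "X", "media", "da", "db", conc_a=ca, conc_b=cb,
                design="factorial", epsilon=eps,
            )
            assert zip_delta(g).summary == pytest.approx(100 * eps, abs=0.5)

    def test_all_zero_response_grid_scores_zero(self):
        ca = np.array([0.0, 1e-8, 1e-7, 1e-6])
        cb = np.array([0.0, 1e-8, 1e-7, 1e-6])
        g = CombinationGrid(drug_a="a", drug_b="b", conc_a=ca, conc_b=cb,
                            viability=np.full((4, 4), 100.0))
        assert zip_delta(g).summary == pytest.approx(0.0, abs=1e-6)

    def test_anchored_design_uses_single_direction(self):
        truth = two_drug_truth()
        g = generate_combination_grid(truth, "X", "media", "da", "db",
                                      design="anchored", epsilon=0.0)
        from aafscreen.doseresp import LL4Fit
        fit_a = LL4Fit(b=1.0, c=0.0, d=100.0, e=1e-6, residual_sd=0.0,
                       converged=True, n_points=8)
        res = zip_delta(g, fit_a=fit_a)
        assert res.directions_used == 1
        assert res.delta.shape == (1, np.count_nonzero(g.conc_b > 0))
        assert abs(res.summary) < 1e-6


class TestVUS:
    def make_grid(self, viability, na=4, nb=4, design="factorial"):
        ca = np.concatenate(([0.0], np.logspace(-8, -6, na)))
        cb = np.concatenate(([0.0], np.logspace(-8, -6, nb)))
        v = np.full((na + 1, nb + 1), float(viability)) \
            if np.isscalar(viability) else viability
        return CombinationGrid(drug_a="a", drug_b="b", conc_a=ca, conc_b=cb,
                               viability=v, design=design)

    def test_full_viability_scores_zero(self):
        assert vus(self.make_grid(100.0)).score == pytest.approx(0.0)

    def test_full_kill_scores_100(self):
        assert vus(self.make_grid(0.0)).score == pytest.approx(100.0)

    def test_bilinear_surface_matches_refined_oracle(self):
        ca = np.array([0.0, 1e-8, 1e-5])
        cb = np.array([0.0, 1e-8, 1e-5])
        v = np.array([
            [100.0, 100.0, 100.0],
            [100.0, 100.0, 0.0],
            [100.0, 0.0, 0.0],
        ])
        g = CombinationGrid(drug_a="a", drug_b="b", conc_a=ca, conc_b=cb,
                            viability=v)
        # oracle: dense trapezoid over the bilinear interpolant
        la, lb = np.log10(ca[1:]), np.log10(cb[1:])
        interp = RegularGridInterpolator((la, lb), v[1:, 1:])
        fa = np.linspace(la[0], la[-1], 1001)
        fb = np.linspace(lb[0], lb[-1], 1001)
        grid_pts = np.array(np.meshgrid(fa, fb, indexing="ij"))
        dense = interp(grid_pts.reshape(2, -1).T).reshape(1001, 1001)
        vol = np.trapezoid(np.trapezoid(dense, fb, axis=1), fa)
        expected = 100.0 - 100.0 * vol / (100.0 * (la[-1] - la[0]) * (lb[-1] - lb[0]))
        assert vus(g).score == pytest.approx(expected, abs=1e-6)

    def test_pointwise_dominance_monotonicity(self, rng):
        for _ in range(200):
            base = rng.uniform(0.0, 100.0, size=(5, 5))
            lower = np.clip(base - rng.uniform(0.0, 30.0, size=(5, 5)), 0, None)
            s_hi = vus(self.make_grid(lower)).score
            s_lo = vus(self.make_grid(base)).score
            assert s_hi >= s_lo - 1e-12

    def test_anchored_grid_uses_1d_analogue(self):
        ca = np.array([0.0, 1e-7])
        cb = np.concatenate(([0.0], np.logspace(-8, -6, 5)))
        v = np.vstack([np.full(6, 100.0), np.full(6, 40.0)])
        g = CombinationGrid(drug_a="a", drug_b="b", conc_a=ca, conc_b=cb,
                            viability=v, design="anchored")
        assert vus(g).score == pytest.approx(60.0)

    def test_single_level_factorial_axis_fails(self):
        ca = np.array([0.0, 1e-7])
        cb = np.concatenate(([0.0], np.logspace(-8, -6, 5)))
        g = CombinationGrid(drug_a="a", drug_b="b", conc_a=ca, conc_b=cb,
                            viability=np.full((2, 6), 50.0), design="factorial")
        with pytest.raises(ValueError, match="1-D"):
            vus(g)


class TestSynergyCalls:
    def test_percentile_threshold_and_labels(self):
        df = pd.DataFrame({
            "reference": ["carboplatin"] * 100,
            "zip_summary": np.arange(1.0, 101.0),
            "cr": np.linspace(0.5, 1.5, 100),
        })
        out = synergy_call(df)
        thr = np.percentile(np.arange(1.0, 101.0), 95)  # type-7
        assert out["zip_threshold"].iloc[0] == pytest.approx(thr)
        assert out["synergistic"].sum() == np.sum(np.arange(1.0, 101.0) > thr)

    def test_equal_summaries_give_no_calls(self):
        df = pd.DataFrame({"reference": ["x"] * 30, "zip_summary": [5.0] * 30})
        assert synergy_call(df)["synergistic"].sum() == 0

    @pytest.mark.parametrize("cr,flag", [(0.74, True), (0.75, False)])
    def test_non_improvement_boundary_is_strict(self, cr, flag):
        df = pd.DataFrame({
            "reference": ["x"] * 25, "zip_summary": np.arange(25.0),
            "cr": [cr] + [1.0] * 24,
        })
        assert bool(synergy_call(df)["non_improvement"].iloc[0]) is flag

    def test_small_population_flagged(self):
        df = pd.DataFrame({"reference": ["x"] * 5,
                           "zip_summary": np.arange(5.0)})
        assert synergy_call(df)["percentile_unstable"].all()

    def test_empty_table_fails(self):
        with pytest.raises(ValueError, match="empty"):
            synergy_call(pd.DataFrame(columns=["reference", "zip_summary"]))


class TestRanking:
    def test_single_treatment_ranks_first(self):
        df = pd.DataFrame({"condition": ["c"], "treatment": ["t"],
                           "cr": [1.1], "dss": [30.0]})
        out = rank_treatments(df)
        assert out["rank"].tolist() == [1]

    def test_descending_sort_on_criterion(self):
        df = pd.DataFrame({
            "condition": ["c"] * 3,
            "treatment": ["t1", "t2", "t3"],
            "cr": [1.25, 0.97, 1.12],
            "dss": [10.0, 20.0, 30.0],
        })
        out = rank_treatments(df)
        assert out.sort_values("rank")["cr"].tolist() == [1.25, 1.12, 0.97]

    def test_dss_breaks_cr_ties(self):
        df = pd.DataFrame({
            "condition": ["c"] * 2, "treatment": ["t_lo", "t_hi"],
            "cr": [1.2, 1.2], "dss": [30.0, 40.0],
        })
        out = rank_treatments(df).sort_values("rank")
        assert out["treatment"].tolist() == ["t_hi", "t_lo"]

    def test_fewer_drugs_then_label_break_remaining_ties(self):
        df = pd.DataFrame({
            "condition": ["c"] * 3,
            "treatment": ["z_combo", "a_combo", "mono"],
            "cr": [1.2] * 3, "dss": [40.0] * 3,
            "n_drugs": [2, 2, 1],
        })
        out = rank_treatments(df).sort_values("rank")
        assert out["treatment"].tolist() == ["mono", "a_combo", "z_combo"]

    def test_best_treatment_extraction(self):
        df = pd.DataFrame({
            "condition": ["c1", "c1", "c2"],
            "treatment": ["t1", "t2", "t3"],
            "cr": [1.3, 1.1, 0.9], "dss": [1.0, 2.0, 3.0],
        })
        best = best_treatments(rank_treatments(df))
        assert best["treatment"].tolist() == ["t1", "t3"]
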
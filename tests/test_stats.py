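"""ANOVA and Holm-Sidak post-hoc machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import fibralign as fa


class TestOneWayAnova:
    def test_identical_groups_give_f_zero(self):
        f, p = fa.one_way_anova([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert f == 0.0 and p == 1.0

    def test_hand_computed_sums_of_squares(self):
        # SSB = 1, SSW = 1, df = (1, 2) -> F = 2
        f, p = fa.one_way_anova([np.array([0.0, 1.0]), np.array([1.0, 2.0])])
        assert f == pytest.approx(2.0, rel=1e-12)

    def test_matches_scipy_on_random_groups(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc, 1.0, size=9) for loc in (0.0, 0.3, 1.0)]
        f, p = fa.one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_within_variance_unequal_means_is_infinite_f(self):
        f, p = fa.one_way_anova([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert np.isinf(f) and p == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fa.one_way_anova([np.array([1.0]), np.array([1.0, 2.0])])

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1, size=7) for m in (0.0, 0.5)]
        f0, _ = fa.one_way_anova(groups)
        f_shift, _ = fa.one_way_anova([g + 42.0 for g in groups])
        f_scale, _ = fa.one_way_anova([g * 3.5 for g in groups])
        assert f_shift == pytest.approx(f0, rel=1e-9)
        assert f_scale == pytest.approx(f0, rel=1e-9)

    def test_type_i_error_calibration(self):
        """Null rejection rate at alpha = 0.05 stays near 0.05."""
        rng = np.random.default_rng(2026)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = [rng.normal(0.0, 1.0, size=8) for _ in range(3)]
            _, p = fa.one_way_anova(groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestHolmSidak:
    def test_single_p_unchanged(self):
        assert fa.holm_sidak(np.array([0.03]))[0] == pytest.approx(0.03, abs=1e-12)

    def test_two_p_hand_case(self):
        # 1 - 0.99^2 = 0.0199; the larger p keeps 1 - 0.96^1 = 0.04
        adj = fa.holm_sidak(np.array([0.01, 0.04]))
        assert adj == pytest.approx([0.0199, 0.04], abs=1e-12)

    def test_ties_hand_case(self):
        # all 0.5: first step 1 - 0.5^3 = 0.875, running max keeps all there
        adj = fa.holm_sidak(np.array([0.5, 0.5, 0.5]))
        assert adj == pytest.approx([0.875] * 3, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fa.holm_sidak(np.array([0.5, 1.5]))

    def test_all_ones_fixed_point(self):
        assert np.all(fa.holm_sidak(np.array([1.0, 1.0, 1.0])) == 1.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8), st.randoms())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_adjustment_properties(self, pvals, rnd):
        """Adjusted >= raw, within [0, 1], step-down monotone, order-equivariant."""
        p = np.array(pvals)
        adj = fa.holm_sidak(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = np.array(rnd.sample(range(p.size), p.size))
        assert np.allclose(fa.holm_sidak(p[perm]), adj[perm], atol=1e-12)


class TestCompareConditions:
    @staticmethod
    def _table(samples: dict) -> pd.DataFrame:
        rows = [
            {"condition": c, "oi_percent": v}
            for c, vals in samples.items()
            for v in vals
        ]
        return pd.DataFrame(rows)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            fa.compare_conditions(self._table({"a": [1.0, 2.0, 3.0]}))

    def test_unknown_label_rejected(self):
        t = self._table({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            fa.compare_conditions(t, conditions=["a", "zzz"])

    def test_identical_groups_f_zero(self):
        t = self._table({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        cmp_ = fa.compare_conditions(t)
        assert cmp_.f_statistic == 0.0 and cmp_.p_value == 1.0

    def test_pairwise_adjustment_invariants(self):
        rng = np.random.default_rng(3)
        t = self._table(
            {c: rng.normal(m, 5.0, size=8) for c, m in
             [("serum-free", 40.0), ("PDGF", 70.0), ("TGFb", 68.0)]}
        )
        cmp_ = fa.compare_conditions(t)
        assert len(cmp_.pairwise) == 3
        for _, p_raw, p_adj in cmp_.pairwise:
            assert p_adj >= p_raw - 1e-12 and 0.0 <= p_adj <= 1.0
        frame = cmp_.to_frame()
        assert set(["group_a", "group_b", "p_raw", "p_holm_sidak"]) <= set(frame.columns)

    def test_condition_ordering_from_generator_concentration(self):
        """Alignment-driven OI separates a weakly from two strongly guided groups."""
        rng = np.random.default_rng(7)
        oi = {"weak": [], "strong1": [], "strong2": []}
        for label, kappa in [("weak", 2.0), ("strong1", 20.0), ("strong2", 20.0)]:
            for k in range(8):
                spec = fa.FibrilFieldSpec(
                    image_size_px=(128, 128), mean_angle_deg=-90.0,
                    dispersion_kappa=kappa, n_fibrils=50,
                    seed=int(rng.integers(2**31)),
                )
                dist = fa.orientation_distribution(fa.generate_fibril_field(spec))
                oi[label].append(fa.orientation_index(dist, 90.0).oi_percent)
        t = self._table(oi)
        cmp_ = fa.compare_conditions(t)
        means = {c: np.mean(v) for c, v in oi.items()}
        assert means["weak"] < means["strong1"]
        assert means["weak"] < means["strong2"]
        assert abs(means["strong1"] - means["strong2"]) < 15.0
        assert cmp_.p_value < 0.05
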
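"""ANOVA/Tukey, antagonist reversal, and resource-equation sample sizes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from itertools import combinations

import isobolab as ib
from isobolab.errors import ComputationError, ValidationError


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        f, dfb, dfw, p = ib.one_way_anova([(1, 2, 3), (1, 2, 3)])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_sums_of_squares(self):
        # SSB = 13.5, SSW = 4, MSW = 1 -> F = 13.5 on (1, 4) df
        f, dfb, dfw, p = ib.one_way_anova([(1, 2, 3), (4, 5, 6)])
        assert (dfb, dfw) == (1, 4)
        assert f == pytest.approx(13.5)

    def test_group_order_irrelevant(self):
        groups = [(1.0, 2.5, 3.1), (4.0, 5.5, 4.2), (2.2, 2.9, 3.3)]
        out1 = ib.one_way_anova(groups)
        out2 = ib.one_way_anova(groups[::-1])
        assert out1[0] == pytest.approx(out2[0])
        assert out1[3] == pytest.approx(out2[3])

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValidationError):
            ib.one_way_anova([(1, 2)])
        with pytest.raises(ValidationError):
            ib.one_way_anova([(1, 2), (3,)])
        with pytest.raises(ComputationError):
            ib.one_way_anova([(1, 1), (2, 2)])

    @given(
        data=st.lists(
            st.lists(st.floats(-50, 100), min_size=3, max_size=6),
            min_size=2,
            max_size=5,
        )
    )
    def test_sum_of_squares_identity(self, data):
        """SST = SSB + SSW, and F computed from that decomposition."""
        gs = [np.array(g) for g in data]
        grand = np.concatenate(gs).mean()
        sst = sum(np.sum((g - grand) ** 2) for g in gs)
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
        ssw = sum(np.sum((g - g.mean()) ** 2) for g in gs)
        assert sst == pytest.approx(ssb + ssw, rel=1e-9, abs=1e-9)
        if ssw == 0:
            return
        f, dfb, dfw, _ = ib.one_way_anova(gs)
        assert f == pytest.approx((ssb / dfb) / (ssw / dfw), rel=1e-9, abs=1e-12)


class TestTukeyHSD:
    def test_identical_groups_all_p_one(self):
        table = ib.tukey_hsd([(1, 2, 3), (1, 2, 3), (1, 2, 3)])
        assert np.allclose(table["p_adj"], 1.0)
        assert not table["significant"].any()

    def test_two_groups_reduce_to_t_test(self):
        """With two groups, q = sqrt(2)|t| and Tukey p equals the t-test p."""
        from scipy import stats as sps

        a, b = (10.0, 12.0, 11.0, 13.0), (15.0, 16.0, 14.5, 17.0)
        table = ib.tukey_hsd([a, b])
        t, p = sps.ttest_ind(a, b)
        assert table.loc[0, "q"] == pytest.approx(np.sqrt(2) * abs(t))
        assert table.loc[0, "p_adj"] == pytest.approx(p, rel=1e-6)

    def test_shifted_group_flagged_against_permutation_reference(self):
        """Only pairs involving the shifted group are significant, agreeing
        with a 10,000-permutation max-q reference at the same alpha."""
        rng = np.random.default_rng(7)
        groups = [
            rng.normal(10, 1, 6),
            rng.normal(10, 1, 6),
            rng.normal(16, 1, 6),
        ]
        table = ib.tukey_hsd(groups, alpha=0.05)
        flagged = {
            (r.group_a, r.group_b) for r in table.itertuples() if r.significant
        }
        assert flagged == {(0, 2), (1, 2)}

        def pair_qs(gs):
            k = len(gs)
            n = sum(len(g) for g in gs)
            msw = sum(np.sum((g - g.mean()) ** 2) for g in gs) / (n - k)
            return {
                (i, j): abs(gs[i].mean() - gs[j].mean())
                / np.sqrt(msw / 2 * (1 / len(gs[i]) + 1 / len(gs[j])))
                for i, j in combinations(range(k), 2)
            }

        obs = pair_qs(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        null_max = np.empty(10_000)
        for b in range(10_000):
            perm = rng.permutation(pooled)
            split = np.split(perm, np.cumsum(sizes)[:-1])
            null_max[b] = max(pair_qs(split).values())
        for (i, j), q in obs.items():
            p_perm = (null_max >= q).mean()
            assert (p_perm < 0.05) == ((i, j) in flagged)

    def test_tukey_p_within_permutation_error_of_reference(self):
        """Adjusted p values agree with the permutation reference within
        Monte-Carlo resolution on a moderate-effect fixture."""
        rng = np.random.default_rng(11)
        groups = [rng.normal(10, 2, 6), rng.normal(12.5, 2, 6), rng.normal(10.5, 2, 6)]
        table = ib.tukey_hsd(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]

        def maxq(gs):
            k, n = len(gs), sum(len(g) for g in gs)
            msw = sum(np.sum((g - g.mean()) ** 2) for g in gs) / (n - k)
            return max(
                abs(gs[i].mean() - gs[j].mean())
                / np.sqrt(msw / 2 * (1 / len(gs[i]) + 1 / len(gs[j])))
                for i, j in combinations(range(k), 2)
            )

        null = np.empty(5_000)
        for b in range(5_000):
            perm = rng.permutation(pooled)
            null[b] = maxq(np.split(perm, np.cumsum(sizes)[:-1]))
        for row in table.itertuples():
            p_perm = float((null >= row.q).mean())
            assert row.p_adj == pytest.approx(p_perm, abs=0.05)


class TestAntagonistParticipation:
    def test_no_reversal(self):
        res = ib.antagonist_participation(63.56, 63.56)
        assert res.percent_reversal == pytest.approx(0.0)
        assert not res.exceeds_full_reversal

    def test_partial_reversal(self):
        assert ib.antagonist_participation(63.56, 34.96).percent_reversal == pytest.approx(
            45.0, abs=0.01
        )

    def test_negative_residual_flagged_as_beyond_full_reversal(self):
        res = ib.antagonist_participation(63.56, -21.0)
        assert res.percent_reversal == pytest.approx(133.0, abs=0.1)
        assert res.exceeds_full_reversal

    def test_nonpositive_combination_effect_rejected(self):
        with pytest.raises(ComputationError):
            ib.antagonist_participation(0.0, 10.0)

    @given(E=st.floats(1, 100), r=st.floats(-100, 200))
    def test_reversal_round_trip(self, E, r):
        residual = E * (1 - r / 100)
        res = ib.antagonist_participation(E, residual)
        assert res.percent_reversal == pytest.approx(r, abs=1e-8)


class TestResourceEquation:
    @pytest.mark.parametrize("K,expected", [(1, (11, 21)), (3, (5, 8)), (5, (3, 5))])
    def test_reference_values(self, K, expected):
        b = ib.resource_equation(K)
        assert (b.mnapg, b.MNAPG) == expected

    def test_invalid_K(self):
        for K in (0, -1, 2.5):
            with pytest.raises(ValidationError):
                ib.resource_equation(K)

    @given(K=st.integers(1, 30))
    def test_df_bounds_and_minimality(self, K):
        b = ib.resource_equation(K)
        assert K * (b.mnapg - 1) >= 10
        assert K * (b.mnapg - 2) < 10  # minimality
        assert K * (b.MNAPG - 1) >= 20
        assert b.mnapg <= b.MNAPG
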
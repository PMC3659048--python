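import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from devtx import de
from devtx.de import (
    PairwiseDEResult,
    bh_fdr,
    call_de,
    collective_preferential,
    fisher_de,
    fold_change,
    pairwise_de,
    stage_preferential,
)
from devtx.simulate import planted_preferential_counts


def fisher_oracle(a, ta, b, tb):
    """Exact two-sided Fisher p by rational enumeration over the support."""
    k, m = a + b, ta + tb
    a_min, a_max = max(0, k - tb), min(k, ta)
    weights = {
        i: math.comb(k, i) * math.comb(m - k, ta - i) for i in range(a_min, a_max + 1)
    }
    total = sum(weights.values())
    obs = weights[a]
    return float(Fraction(sum(w for w in weights.values() if w <= obs), total))


class TestFisher:
    def test_identical_zero_tables(self):
        assert fisher_de(0, 1000, 0, 1000) == 1.0

    @pytest.mark.parametrize(
        "a,ta,b,tb",
        [(5, 100, 0, 100), (3, 50, 10, 60), (25, 60, 5, 40), (17, 40, 23, 60), (1, 10, 9, 10)],
    )
    def test_matches_rational_enumeration(self, a, ta, b, tb):
        assert fisher_de(a, ta, b, tb) == pytest.approx(fisher_oracle(a, ta, b, tb), abs=1e-12)

    def test_large_table_path_agrees_with_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(50):
            ta, tb = rng.integers(10_000, 1_000_000, size=2)
            a, b = int(rng.integers(0, 2000)), int(rng.integers(0, 2000))
            mine = fisher_de(a, int(ta), b, int(tb))
            ref = fisher_exact([[a, int(ta) - a], [b, int(tb) - b]])[1]
            # both sides sum float pmf tails; agreement to the tie-guard level
            assert mine == pytest.approx(ref, rel=1e-6, abs=1e-300)

    @given(
        st.integers(1, 40), st.integers(1, 40), st.data()
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_in_library_order(self, ta, tb, data):
        a = data.draw(st.integers(0, ta))
        b = data.draw(st.integers(0, tb))
        assert fisher_de(a, ta, b, tb) == pytest.approx(fisher_de(b, tb, a, ta), abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_de(5, 4, 0, 10)
        with pytest.raises(ValueError):
            fisher_de(-1, 4, 0, 10)


class TestBHFDR:
    def test_step_up_example(self):
        assert bh_fdr([0.005, 0.03, 0.5]) == pytest.approx([0.015, 0.045, 0.5])

    def test_all_ones_and_singleton(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert bh_fdr([0.123]) == pytest.approx([0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_matches_definition_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = rng.random(int(rng.integers(1, 200)))
            q = bh_fdr(p)
            n = len(p)
            order = np.argsort(p, kind="stable")
            expected = np.empty(n)
            running = 1.0
            for rank in range(n - 1, -1, -1):  # step-up from the largest p
                i = order[rank]
                running = min(running, p[i] * n / (rank + 1))
                expected[i] = running
            assert q == pytest.approx(expected, abs=1e-12)

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.random(100))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-15).all()


class TestCallDE:
    def test_joint_conditions(self):
        assert call_de(np.array([5e-4]), np.array([5.0]))[0]
        assert not call_de(np.array([5e-4]), np.array([3.0]))[0]
        # the looser 2-fold convention
        assert call_de(np.array([5e-4]), np.array([3.0]), fc_cut=2)[0]
        assert not call_de(np.array([0.5]), np.array([10.0]))[0]

    def test_fold_change_stabilised(self):
        f = fold_change(np.array([0.0]), np.array([1.0]), eps=1e-3)
        assert f[0] == pytest.approx(1.001 / 1e-3)
        assert fold_change(np.array([2.0]), np.array([8.0]))[0] == pytest.approx(
            fold_change(np.array([8.0]), np.array([2.0]))[0]
        )


def manual_pairwise(rpkm, fdr_values):
    """Build a PairwiseDEResult with prescribed per-pair FDRs."""
    stages = list(rpkm.columns)
    lookup = {}
    rows = []
    for i, sa in enumerate(stages):
        for sb in stages[i + 1:]:
            fdr = pd.Series(fdr_values, index=rpkm.index, dtype=float)
            lookup[(sa, sb)] = fdr
            rows.append(
                pd.DataFrame(
                    {
                        "gene": rpkm.index,
                        "stage_a": sa,
                        "stage_b": sb,
                        "p": fdr,
                        "fdr": fdr,
                        "fold": 1.0,
                        "direction": "tie",
                        "is_de": False,
                    }
                )
            )
    return PairwiseDEResult(pd.concat(rows, ignore_index=True), lookup, stages)


class TestStagePreferential:
    def test_single_high_stage_called(self):
        rpkm = pd.DataFrame(
            [[10, 1, 1, 1, 1, 1, 1, 1, 1]],
            index=["g"],
            columns=[f"s{i}" for i in range(9)],
        )
        calls = stage_preferential(manual_pairwise(rpkm, 1e-5), rpkm)
        assert calls["gene"].tolist() == ["g"]
        assert calls["preferred_stage"].tolist() == ["s0"]

    def test_insufficient_fold_blocks_call(self):
        rpkm = pd.DataFrame(
            [[10, 6, 1, 1, 1, 1, 1, 1, 1]],
            index=["g"],
            columns=[f"s{i}" for i in range(9)],
        )
        assert stage_preferential(manual_pairwise(rpkm, 1e-5), rpkm).empty

    def test_tie_blocks_call(self):
        rpkm = pd.DataFrame([[5, 5, 1]], index=["g"], columns=["a", "b", "c"])
        assert stage_preferential(manual_pairwise(rpkm, 1e-5), rpkm).empty

    def test_high_fdr_blocks_call(self):
        rpkm = pd.DataFrame([[10, 1, 1]], index=["g"], columns=["a", "b", "c"])
        assert stage_preferential(manual_pairwise(rpkm, 0.5), rpkm).empty

    def test_invariant_under_permutation_of_other_stages(self):
        counts, totals, rpkm, truth = planted_preferential_counts(
            n_flat=60, n_planted=12, seed=4
        )
        res = pairwise_de(counts, totals, rpkm)
        calls = stage_preferential(res, rpkm).set_index("gene")["preferred_stage"]
        # permute the non-preferred stage columns of one planted gene's profile
        gene = truth.dropna().index[0]
        stage = truth[gene]
        others = [s for s in rpkm.columns if s != stage]
        perm = list(np.random.default_rng(0).permutation(others))
        rpkm2 = rpkm.copy()
        counts2 = counts.copy()
        rpkm2.loc[gene, others] = rpkm.loc[gene, perm].to_numpy()
        counts2.loc[gene, others] = counts.loc[gene, perm].to_numpy()
        res2 = pairwise_de(counts2, totals, rpkm2)
        calls2 = stage_preferential(res2, rpkm2).set_index("gene")["preferred_stage"]
        assert calls.get(gene) == calls2.get(gene) == stage

    def test_planted_cohort_recovery(self):
        counts, totals, rpkm, truth = planted_preferential_counts(
            n_flat=90, n_planted=10, seed=2
        )
        res = pairwise_de(counts, totals, rpkm)
        calls = stage_preferential(res, rpkm).set_index("gene")["preferred_stage"]
        planted = truth.dropna()
        recovered = sum(calls.get(g) == s for g, s in planted.items())
        assert recovered >= 9
        assert sum(g not in planted.index for g in calls.index) <= 1


class TestCollectivePreferential:
    def make(self, profile):
        stages = [f"s{i}" for i in range(9)]
        rpkm = pd.DataFrame([profile], index=["g"], columns=stages)
        return rpkm, manual_pairwise(rpkm, 1e-5)

    def test_high_subset_included(self):
        rpkm, pw = self.make([8, 9, 10, 2, 2, 2, 2, 2, 2])
        assert collective_preferential(rpkm, ["s0", "s1", "s2"], pw) == ["g"]

    def test_dip_in_subset_excluded(self):
        rpkm, pw = self.make([8, 1, 10, 2, 2, 2, 2, 2, 2])
        assert collective_preferential(rpkm, ["s0", "s1", "s2"], pw) == []

    def test_improper_subset_rejected(self):
        rpkm, pw = self.make([1] * 9)
        with pytest.raises(ValueError):
            collective_preferential(rpkm, list(rpkm.columns), pw)

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(8)
        stages = [f"s{i}" for i in range(6)]
        rpkm = pd.DataFrame(
            rng.exponential(2.0, size=(200, 6)),
            index=[f"g{i}" for i in range(200)],
            columns=stages,
        )
        fdr = 1e-5
        pw = manual_pairwise(rpkm, fdr)
        subset = ["s1", "s2"]
        got = collective_preferential(rpkm, subset, pw, fold_cut=2.0)
        outside = [s for s in stages if s not in subset]
        expected = []
        for g in rpkm.index:
            mn = rpkm.loc[g, subset].min()
            if all(mn >= 2.0 * rpkm.at[g, t] and mn > rpkm.at[g, t] for t in outside):
                expected.append(g)
        assert got == sorted(expected)


def test_null_poisson_type_one_error_control():
    """On equal-rate Poisson counts the BH-adjusted call rate stays tiny."""
    rng = np.random.default_rng(5)
    counts = rng.poisson(100, size=(500, 2)).astype(int)
    p = np.array([de.fisher_de(a, 1_000_000, b, 1_000_000) for a, b in counts])
    q = bh_fdr(p)
    assert (q < 0.001).mean() <= 0.002
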
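"""Moderated-t DE, Holm adjustment, signed consensus, gene-name-sampling null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from survsig import (
    consensus_genes,
    consensus_null_p,
    holm_adjust,
    median_center_by_group,
    moderated_t_de,
)
from survsig.consensus import DEResult

from conftest import make_cohort


def _de(gene, direction, significant=True):
    lfc = 1.0 if direction == "up" else -1.0
    return DEResult(gene=gene, log_fc=lfc, t_mod=lfc * 5, df_total=20, p=0.001,
                    p_holm=0.01, direction=direction, significant=significant)


def _two_group_cohort(n_genes=50, n1=15, n2=15, shift_genes=(), shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = n1 + n2
    X = rng.normal(7, 1, (n_genes, n))
    labels = np.array(["low"] * n1 + ["high"] * n2)
    for g in shift_genes:
        X[g, labels == "high"] += shift
    return make_cohort(X, rng.exponential(5, n), np.ones(n, dtype=int)), labels


class TestHolm:
    def test_hand_step_down_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06], atol=1e-15
        )

    def test_single_p_identity(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal(self):
        np.testing.assert_allclose(holm_adjust([0.01] * 4), [0.04] * 4)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_statsmodels_and_permutation_invariant(self, ps):
        mine = holm_adjust(ps)
        ref = multipletests(ps, method="holm")[1]
        np.testing.assert_allclose(mine, ref, atol=1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        np.testing.assert_allclose(holm_adjust(np.asarray(ps)[perm]), mine[perm], atol=1e-12)
        # adjusted values are >= raw and monotone in the sorted order
        assert np.all(mine >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(mine[order]) >= -1e-15)


class TestModeratedT:
    def test_unmoderated_equals_pooled_two_sample_t(self):
        cohort, labels = _two_group_cohort(n_genes=5, seed=1)
        results, params = moderated_t_de(cohort, labels, moderated=False)
        assert params.d0 == 0.0
        X = cohort.expr.to_numpy()
        for i, r in enumerate(results):
            t_ref, p_ref = sps.ttest_ind(X[i, labels == "high"], X[i, labels == "low"])
            assert r.t_mod == pytest.approx(t_ref, rel=1e-10)
            assert r.p == pytest.approx(p_ref, rel=1e-10)

    def test_planted_de_recovered_with_direction(self):
        """Genes shifted by 2 sigma at n=30/30 come out significant with the
        right sign."""
        up, down = [0, 1, 2], [3, 4]
        cohort, labels = _two_group_cohort(n_genes=200, n1=30, n2=30,
                                           shift_genes=up, shift=2.0, seed=2)
        X = cohort.expr.to_numpy()
        for g in down:
            X[g, labels == "high"] -= 2.0
        cohort = make_cohort(X, cohort.times, cohort.events)
        results, _ = moderated_t_de(cohort, labels)
        by_gene = {r.gene: r for r in results}
        for g in up:
            assert by_gene[f"g{g}"].significant and by_gene[f"g{g}"].direction == "up"
        for g in down:
            assert by_gene[f"g{g}"].significant and by_gene[f"g{g}"].direction == "down"

    def test_direction_flips_with_label_swap(self):
        cohort, labels = _two_group_cohort(n_genes=20, seed=3)
        a, _ = moderated_t_de(cohort, labels)
        swapped = np.where(labels == "high", "low", "high")
        b, _ = moderated_t_de(cohort, swapped)
        for ra, rb in zip(a, b):
            assert ra.log_fc == pytest.approx(-rb.log_fc)
            assert ra.p == pytest.approx(rb.p, rel=1e-12)
            assert (ra.direction == "up") == (rb.direction == "down")

    def test_moderation_shrinks_variance_outliers(self):
        """The moderated statistic borrows strength: a gene with a freak
        small sample variance no longer dominates."""
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (100, 20))
        X[0] = rng.normal(0, 0.01, 20)  # tiny variance, tiny mean difference
        X[0, 10:] += 0.02
        labels = np.array(["low"] * 10 + ["high"] * 10)
        cohort = make_cohort(X, rng.exponential(1, 20), np.ones(20, dtype=int))
        mod, params = moderated_t_de(cohort, labels)
        raw, _ = moderated_t_de(cohort, labels, moderated=False)
        assert params.d0 > 0
        assert abs(mod[0].t_mod) < abs(raw[0].t_mod)

    def test_degenerate_group_sizes_error(self):
        cohort, labels = _two_group_cohort(n_genes=5, n1=1, n2=29, seed=5)
        with pytest.raises(ValueError):
            moderated_t_de(cohort, labels)


class TestConsensusGenes:
    def test_hand_enumeration(self):
        lists = {
            "c1": [_de("A", "up"), _de("B", "up")],
            "c2": [_de("A", "up"), _de("C", "down")],
            "c3": [_de("C", "down")],
        }
        cons = consensus_genes(lists, min_support=2)
        assert cons.observed_size == 2
        assert cons.member_set == {"A": "up", "C": "down"}
        assert cons.n_up == 1 and cons.n_down == 1

    def test_disjoint_lists_empty(self):
        lists = {"c1": [_de("A", "up")], "c2": [_de("B", "up")], "c3": [_de("C", "up")]}
        assert consensus_genes(lists).observed_size == 0

    def test_direction_conflict_excluded(self):
        lists = {"c1": [_de("A", "up")], "c2": [_de("A", "down")]}
        assert consensus_genes(lists).observed_size == 0

    def test_one_direction_can_still_reach_support(self):
        lists = {
            "c1": [_de("A", "up")], "c2": [_de("A", "up")], "c3": [_de("A", "down")],
        }
        cons = consensus_genes(lists)
        assert cons.member_set == {"A": "up"}

    def test_non_significant_entries_ignored(self):
        lists = {"c1": [_de("A", "up", significant=False)], "c2": [_de("A", "up")]}
        assert consensus_genes(lists).observed_size == 0

    def test_cohort_order_symmetry(self):
        lists = {
            "c1": [_de("A", "up"), _de("B", "down")],
            "c2": [_de("A", "up"), _de("B", "down")],
            "c3": [_de("B", "down")],
        }
        a = consensus_genes(lists)
        b = consensus_genes(dict(reversed(list(lists.items()))))
        assert a.member_set == b.member_set and a.observed_size == b.observed_size


class TestConsensusNull:
    def test_observed_zero_gives_p_one(self):
        assert consensus_null_p([(3, 2), (4, 1)], list("ABCDEFGHIJ"), 0, n_iter=10) == 1.0

    def test_deterministic_given_seed(self):
        args = ([(3, 2), (2, 3)], list("ABCDEFGHIJ"), 2)
        assert consensus_null_p(*args, n_iter=2000, seed=9) == consensus_null_p(
            *args, n_iter=2000, seed=9
        )

    def test_monotone_in_observed_size(self):
        universe = [f"g{i}" for i in range(20)]
        counts = [(5, 5), (5, 5), (5, 5)]
        ps = [consensus_null_p(counts, universe, k, n_iter=3000, seed=1) for k in range(6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_list_larger_than_universe_errors(self):
        with pytest.raises(ValueError):
            consensus_null_p([(6, 5)], list("ABCDEFGHIJ"), 1, n_iter=10)


class TestMedianCenter:
    def test_constant_vector_all_zero(self):
        out = median_center_by_group([3.0, 3.0, 3.0], ["TNBC", "HER2+", "TNBC"])
        assert all(np.all(v == 0) for v in out.values())

    def test_centered_median_zero_odd_n(self):
        x = [1.0, 5.0, 2.0, 9.0, 4.0]
        out = median_center_by_group(x, ["a", "a", "b", "b", "b"])
        pooled = np.concatenate(list(out.values()))
        assert np.median(pooled) == 0.0

    def test_group_means_shift_identity(self):
        rng = np.random.default_rng(7)
        x = rng.normal(5, 2, 30)
        groups = list(rng.choice(["TNBC", "HER2+", "ER/PR+"], 30))
        out = median_center_by_group(x, groups)
        med = np.median(x)
        for g in set(groups):
            raw_mean = x[np.array([l == g for l in groups])].mean()
            assert out[g].mean() == pytest.approx(raw_mean - med, rel=1e-12)

    def test_missing_label_errors(self):
        with pytest.raises(ValueError):
            median_center_by_group([1.0, 2.0], ["a", None])
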
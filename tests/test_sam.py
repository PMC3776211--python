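"""SAM statistics, permutation FDR, duplicate collapsing, median centring."""
import logging

import numpy as np
import pandas as pd
import pytest

import rapatest as rt
from rapatest.sam import (SAM, collapse_duplicates, median_center,
                          permutation_fdr, sam_multiclass, sam_two_class,
                          tune_delta)


def toy_matrix(seed=0, n_genes=60, groups=(4, 4), shift_first=0.0):
    rng = np.random.default_rng(seed)
    cols = [f"g{gi}_s{j}" for gi, n in enumerate(groups) for j in range(n)]
    X = rng.normal(8, 0.5, (n_genes, len(cols)))
    if shift_first:
        X[:5, : groups[0]] += shift_first
    m = pd.DataFrame(X, index=[f"G{i:03d}" for i in range(n_genes)], columns=cols)
    grp = pd.Series([f"grp{gi}" for gi, n in enumerate(groups) for _ in range(n)],
                    index=cols)
    return m, grp


class TestTwoClass:
    def test_identical_means_null_d(self):
        m, grp = toy_matrix()
        base = m.iloc[:, :4].to_numpy()
        m.iloc[:, 4:] = base  # identical values in both groups
        d, s0 = sam_two_class(m, m.columns[:4], m.columns[4:], s0_mode=0.1)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_hand_oracle_fixed_s0_zero(self):
        # two genes, values chosen so the pooled-SE t-numerator is hand-checkable
        m = pd.DataFrame({"a1": [1.0, 5.0], "a2": [2.0, 6.0],
                          "b1": [3.0, 4.0], "b2": [5.0, 8.0]},
                         index=["gx", "gy"])
        d, s0 = sam_two_class(m, ["a1", "a2"], ["b1", "b2"], s0_mode=0.0)
        for gene in ("gx", "gy"):
            xa = m.loc[gene, ["a1", "a2"]].to_numpy()
            xb = m.loc[gene, ["b1", "b2"]].to_numpy()
            num = xa.mean() - xb.mean()
            sp2 = (((xa - xa.mean()) ** 2).sum()
                   + ((xb - xb.mean()) ** 2).sum()) / 2
            se = np.sqrt(sp2 * (0.5 + 0.5))
            assert d[gene] == pytest.approx(num / se)

    def test_label_swap_negates_d(self):
        m, grp = toy_matrix(seed=3, shift_first=2.0)
        d1, s0 = sam_two_class(m, m.columns[:4], m.columns[4:], s0_mode=0.2)
        d2, _ = sam_two_class(m, m.columns[4:], m.columns[:4], s0_mode=0.2)
        np.testing.assert_allclose(d1, -d2, atol=1e-12)

    def test_small_group_rejected(self):
        m, _ = toy_matrix()
        with pytest.raises(ValueError):
            sam_two_class(m, m.columns[:1], m.columns[1:])

    def test_zero_variance_with_zero_s0_rejected(self):
        m, _ = toy_matrix()
        m.iloc[0, :] = 5.0
        with pytest.raises(ValueError, match="s0"):
            sam_two_class(m, m.columns[:4], m.columns[4:], s0_mode=0.0)


class TestMulticlass:
    def test_equal_means_near_zero(self):
        m, grp = toy_matrix(groups=(4, 4, 4))
        d, s0, _ = sam_multiclass(m, grp, s0_mode=0.5)
        # with no group structure the F-like statistic stays small
        assert d.abs().median() < 1.5

    def test_two_group_ranking_matches_abs_d(self):
        m, grp = toy_matrix(seed=5, shift_first=1.5)
        d2, s0 = sam_two_class(m, m.columns[:4], m.columns[4:], s0_mode=0.3)
        dm, _, _ = sam_multiclass(m, grp, s0_mode=0.3)
        # identical scale machinery: multiclass equals |two-class d| at K=2
        np.testing.assert_allclose(dm.to_numpy(), d2.abs().to_numpy(), rtol=1e-9)

    def test_within_group_sample_order_invariant(self):
        m, grp = toy_matrix(seed=7, groups=(4, 5))
        d1, _, _ = sam_multiclass(m, grp, s0_mode=0.3)
        shuffled = m[list(m.columns[[1, 0, 3, 2]]) + list(m.columns[4:])]
        d2, _, _ = sam_multiclass(shuffled, grp, s0_mode=0.3)
        np.testing.assert_allclose(d1, d2)

    def test_singleton_group_rejected(self):
        m, grp = toy_matrix(groups=(4, 4))
        grp.iloc[-1] = "grp2"
        with pytest.raises(ValueError, match="singleton"):
            sam_multiclass(m, grp)


class TestPermutationFDR:
    def test_huge_delta_zero_calls(self):
        m, grp = toy_matrix(seed=1, shift_first=2.0)
        res = permutation_fdr(m, grp, delta=100.0, n_perm=100, seed=0)
        assert res.significant == [] and res.estimated_fdr == 0.0

    def test_same_seed_identical_result(self):
        m, grp = toy_matrix(seed=2, shift_first=1.5, groups=(5, 5))
        a = permutation_fdr(m, grp, delta=0.5, n_perm=100, seed=9)
        b = permutation_fdr(m, grp, delta=0.5, n_perm=100, seed=9)
        assert a.significant_up == b.significant_up
        assert a.estimated_fdr == b.estimated_fdr
        np.testing.assert_array_equal(a.expected_null, b.expected_null)

    def test_exhaustive_enumeration_logged(self, caplog):
        m, grp = toy_matrix(groups=(3, 3))
        with caplog.at_level(logging.INFO, logger="rapatest.sam"):
            res = permutation_fdr(m, grp, delta=0.5, n_perm=100, seed=0)
        assert "enumerating" in caplog.text.lower()
        assert res.n_permutations == 20  # C(6,3) arrangements

    def test_tuned_delta_controls_null_calls(self):
        """On pure-null matrices the tuned screen calls (almost) nothing."""
        false_calls, total = 0, 0
        for rep in range(5):
            spec = rt.SyntheticExpressionSpec(seed=300 + rep,
                                              effect_size_log2=0.0)
            m, g, _ = rt.generate_expression(spec)
            res = SAM(m, g.set_index(pd.Index(g["sample_id"]))["group"]
                      if isinstance(g, pd.DataFrame) else g,
                      statistic="multiclass").fit(
                fdr_target=0.10, n_perm=100, seed=rep)
            false_calls += len(res.significant)
            total += m.shape[0]
        assert false_calls / total <= 0.10

    def test_signature_recovery_two_class(self, expression_default):
        matrix, groups, truth = expression_default
        cols = (list(groups[groups == "Limbic"].index)
                + list(groups[groups == "Control"].index))
        res = SAM(matrix[cols], groups[cols]).fit(fdr_target=0.10,
                                                  n_perm=200, seed=0)
        limbic_truth = set(truth["shared_up"]) | set(truth["shared_down"]) \
            | set(truth["limbic_only"])
        recovered = limbic_truth & set(res.significant)
        assert len(recovered) / len(limbic_truth) >= 0.8
        assert res.estimated_fdr < 0.10


class TestCollapseDuplicates:
    @staticmethod
    def result_with_probes():
        m, grp = toy_matrix(seed=4, shift_first=2.5, groups=(5, 5))
        return permutation_fdr(m, grp, delta=0.3, n_perm=100, seed=1)

    def test_identity_without_duplicates(self):
        res = self.result_with_probes()
        mapping = {p: p for p in res.d.index}
        out = collapse_duplicates(res, mapping)
        assert set(out.d.index) == set(res.d.index)
        assert sorted(out.significant) == sorted(res.significant)

    def test_keeps_max_abs_d(self):
        res = self.result_with_probes()
        probes = list(res.d.index)
        mapping = {p: "GENE_A" if p in probes[:2] else p for p in probes}
        d0, d1 = res.d[probes[0]], res.d[probes[1]]
        out = collapse_duplicates(res, mapping)
        assert out.d["GENE_A"] == (d0 if abs(d0) >= abs(d1) else d1)

    def test_never_increases_significant_count(self, rng):
        res = self.result_with_probes()
        probes = list(res.d.index)
        for trial in range(5):
            gene_ids = rng.integers(0, 30, len(probes))
            mapping = {p: f"GENE{g}" for p, g in zip(probes, gene_ids)}
            out = collapse_duplicates(res, mapping)
            assert len(out.significant) <= len(res.significant)

    def test_unmapped_probe_rejected(self):
        res = self.result_with_probes()
        with pytest.raises(KeyError, match="unmapped"):
            collapse_duplicates(res, {})


class TestMedianCenter:
    def test_constant_gene_all_zero(self):
        m = pd.DataFrame({"a": [5.0], "b": [5.0], "c": [5.0]}, index=["g"])
        np.testing.assert_allclose(median_center(m).to_numpy(), 0.0)

    def test_row_arithmetic(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        np.testing.assert_allclose(median_center(m).to_numpy(),
                                   [[-1.0, 0.0, 1.0]])

    def test_idempotent(self):
        m, _ = toy_matrix(seed=6)
        once = median_center(m)
        twice = median_center(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy())

    def test_per_gene_median_is_zero(self):
        m, _ = toy_matrix(seed=8)
        np.testing.assert_allclose(median_center(m).median(axis=1), 0.0,
                                   atol=1e-12)


def test_sam_model_rejects_duplicated_genes():
    m, grp = toy_matrix()
    m2 = pd.concat([m, m.iloc[[0]]])
    with pytest.raises(ValueError, match="duplicated"):
        SAM(m2, grp)
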
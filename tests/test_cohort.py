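"""Synthetic cohort and expression generators."""
import numpy as np
import pandas as pd
import pytest

import rapatest as rt
from rapatest.io import write_cohort_bundle
from rapatest.ldh import Condition


class TestCohortGenerator:
    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rt.SyntheticCohortSpec(n_control=0, n_mci=0, n_ad=0)

    def test_zero_triplicate_noise_exact_replicates(self):
        spec = rt.SyntheticCohortSpec(n_control=2, n_mci=0, n_ad=2, seed=1,
                                      triplicate_cv=0.0, histogram_events=2000)
        coh = rt.generate_cohort(spec)
        for assay in coh.assays.values():
            for reps in assay.plate.values():
                assert len(set(reps)) == 1

    def test_blunted_ad_invariant_enforced(self):
        with pytest.raises(ValueError, match="pdt_ratio"):
            rt.SyntheticCohortSpec(pdt_ratio_control=1.1, pdt_ratio_ad=1.5)

    def test_byte_identical_files_same_seed(self, tmp_path):
        spec = rt.SyntheticCohortSpec(n_control=3, n_mci=1, n_ad=3, seed=17,
                                      histogram_events=2000)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort_bundle(rt.generate_cohort(spec), d1)
        write_cohort_bundle(rt.generate_cohort(spec), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_different_seed_different_cohort(self):
        spec_a = rt.SyntheticCohortSpec(n_control=3, n_mci=0, n_ad=3, seed=1,
                                        histogram_events=2000)
        spec_b = rt.SyntheticCohortSpec(n_control=3, n_mci=0, n_ad=3, seed=2,
                                        histogram_events=2000)
        ta = rt.generate_cohort(spec_a).truth_frame()
        tb = rt.generate_cohort(spec_b).truth_frame()
        assert not np.allclose(ta["pdt_baseline"], tb["pdt_baseline"])

    def test_truth_recorded_for_every_subject(self, small_cohort):
        for s in small_cohort.subjects:
            truth = small_cohort.assays[s.id].truth
            assert truth["pdt_baseline"] > 0
            assert set(truth) >= {"pdt_ratio", "g1_ratio",
                                  "fractions_untreated", "fractions_treated"}
            assert Condition.SEED in small_cohort.assays[s.id].plate

    def test_ages_within_printed_range(self, small_cohort):
        ages = [s.age for s in small_cohort.subjects]
        assert min(ages) >= 57 and max(ages) <= 95

    def test_calibration_mean_and_cv_at_n1000(self):
        """Generated baseline PDTs converge to the spec mean within 3 SE."""
        spec = rt.SyntheticCohortSpec(n_control=1000, n_mci=0, n_ad=0, seed=23,
                                      histogram_events=1000)
        tf = rt.generate_cohort(spec).truth_frame()
        pdt = tf["pdt_baseline"]
        se = pdt.std() / np.sqrt(len(pdt))
        assert abs(pdt.mean() - spec.mean_pdt_baseline) < 3 * se
        assert pdt.std() / pdt.mean() == pytest.approx(
            spec.between_subject_cv, abs=0.03)

    def test_apoe4_independent_response(self):
        """Carriers and non-carriers draw from the same response distribution."""
        spec = rt.SyntheticCohortSpec(n_control=500, n_mci=0, n_ad=500, seed=31,
                                      histogram_events=1000)
        tf = rt.generate_cohort(spec).truth_frame()
        # a null two-sample comparison fluctuates at the 1-2 SE scale by
        # construction; dependence would show up as a large standardised gap
        for dx in ("Control", "AD"):
            grp = tf[tf["diagnosis"] == dx]
            car = grp[grp["apoe4"]]["pdt_ratio"]
            non = grp[~grp["apoe4"]]["pdt_ratio"]
            se = np.sqrt(car.var() / len(car) + non.var() / len(non))
            assert abs(car.mean() - non.mean()) < 3.5 * se


class TestExpressionGenerator:
    def test_null_generator_equal_group_means(self):
        spec = rt.SyntheticExpressionSpec(seed=2, effect_size_log2=0.0,
                                          gene_noise_sd=0.5)
        m, g, truth = rt.generate_expression(spec)
        groups = g.set_index("sample_id")["group"]
        gm = m.T.groupby(groups).mean().T
        # grand-mean differences stay at sampling-noise scale
        spread = (gm.max(axis=1) - gm.min(axis=1)).mean()
        assert spread < 0.5

    def test_signature_shifts_present(self, expression_default):
        m, groups, truth = expression_default
        gm = m.T.groupby(groups).mean().T
        up = truth["shared_up"]
        assert ((gm.loc[up, "Limbic"] - gm.loc[up, "Control"]).mean()
                == pytest.approx(1.5, abs=0.3))
        down = truth["shared_down"]
        assert ((gm.loc[down, "Neocortical"] - gm.loc[down, "Control"]).mean()
                == pytest.approx(-1.5, abs=0.3))
        neo = truth["neocortical_only"]
        assert ((gm.loc[neo, "Limbic"] - gm.loc[neo, "Control"]).abs().mean()
                < 0.4)

    def test_determinism(self):
        spec = rt.SyntheticExpressionSpec(seed=77)
        m1, g1, t1 = rt.generate_expression(spec)
        m2, g2, t2 = rt.generate_expression(spec)
        pd.testing.assert_frame_equal(m1, m2)
        assert t1 == t2

    def test_signature_overflow_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            rt.SyntheticExpressionSpec(n_panel=100, signature_shared_up=90,
                                       signature_shared_down=20)

    def test_default_tier_sizes(self):
        spec = rt.SyntheticExpressionSpec()
        assert (spec.signature_shared_up, spec.signature_shared_down,
                spec.signature_limbic_only,
                spec.signature_neocortical_only) == (33, 22, 17, 81)
        assert spec.n_panel == 1165
        assert (spec.n_control, spec.n_limbic, spec.n_neocortical) == (5, 19, 22)

    def test_truth_sets_disjoint(self, expression_default):
        _, _, truth = expression_default
        all_genes = sum((list(v) for v in truth.values()), [])
        assert len(all_genes) == len(set(all_genes)) == 153
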
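"""Association machinery: LMD traits, Tukey/min-P, PPD permutation, HWE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from facegeo.association import (
    COMPARISONS,
    bonferroni,
    bonferroni_threshold,
    extract_region,
    geometric_permutation_test,
    hwe_test,
    landmark_distances,
    minp_permutation_correction,
    normality_filter,
    tukey_hsd,
    two_stage_pipeline,
)
from facegeo.registration import LANDMARK_NAMES, MOUTH_LANDMARKS
from facegeo.superimposition import AlignedShapeSet, partial_gpa


class TestLandmarkDistances:
    def test_fifteen_landmarks_give_105_pairs(self, template):
        d = landmark_distances(template.landmarks)
        assert len(d) == 105

    def test_two_point_distance(self):
        d = landmark_distances({"a": [0, 0, 0], "b": [0, 3, 4]})
        assert len(d) == 1
        assert d["a - b"] == pytest.approx(5.0)

    def test_rigid_motion_invariance(self, template, rng):
        base = landmark_distances(template.landmarks)
        R = Rotation.random(random_state=3).as_matrix()
        t = rng.standard_normal(3) * 100
        moved = {k: v @ R.T + t for k, v in template.landmarks.items()}
        assert np.abs(landmark_distances(moved) - base).max() < 1e-9

    def test_mouth_landmarks_are_the_five_named(self):
        assert set(MOUTH_LANDMARKS) == {"LLipCn", "RLipCn", "ULipP", "Stm", "LLipP"}
        assert set(MOUTH_LANDMARKS) <= set(LANDMARK_NAMES)


class TestNormalityFilter:
    def test_gaussian_traits_usually_retained(self):
        kept = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            m = pd.DataFrame({"t": r.standard_normal(300)})
            kept += "t" in normality_filter(m).retained
        assert kept >= 18

    def test_exponential_traits_removed(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            m = pd.DataFrame({"t": r.exponential(size=300)})
            assert "t" not in normality_filter(m).retained

    def test_alpha_zero_retains_everything(self, rng):
        m = pd.DataFrame(rng.exponential(size=(100, 4)),
                         columns=list("abcd"))
        assert normality_filter(m, alpha=0.0).retained == list("abcd")

    def test_constant_trait_excluded_with_diagnostic(self, rng):
        m = pd.DataFrame({"c": np.ones(50), "g": rng.standard_normal(50)})
        with pytest.warns(UserWarning, match="constant"):
            res = normality_filter(m)
        assert res.excluded_constant == ["c"]


class TestTukey:
    def test_strong_separation_detected(self, rng):
        v = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                            rng.normal(10, 1, 30)])
        codes = np.repeat([0, 1, 2], 30)
        p = tukey_hsd(v, codes)
        assert p["AA:BB"] < 1e-6 and p["BB:AB"] < 1e-6
        assert p["AA:AB"] > 0.05

    def test_identical_groups_give_p_near_one(self, rng):
        base = rng.standard_normal(200)
        v = np.concatenate([base, base, base])
        codes = np.repeat([0, 1, 2], 200)
        assert all(p > 0.9 for p in tukey_hsd(v, codes).values())

    def test_symmetric_under_group_relabel(self, rng):
        v = rng.standard_normal(90)
        codes = np.repeat([0, 1, 2], 30)
        p1 = tukey_hsd(v, codes)
        swapped = codes.copy()
        swapped[codes == 0], swapped[codes == 2] = 2, 0
        p2 = tukey_hsd(v, swapped)
        assert p1["AA:BB"] == pytest.approx(p2["AA:BB"])
        assert p1["AA:AB"] == pytest.approx(p2["BB:AB"])

    def test_matches_studentized_range_formula(self, rng):
        """Independent oracle: Tukey-Kramer p from the q distribution."""
        v = rng.standard_normal(75) + np.repeat([0.0, 0.5, 1.0], 25)
        codes = np.repeat([0, 1, 2], 25)
        got = tukey_hsd(v, codes)
        groups = [v[codes == c] for c in range(3)]
        ns = [len(g) for g in groups]
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / (75 - 3)
        for label, (a, b) in COMPARISONS:
            q = abs(groups[a].mean() - groups[b].mean()) / np.sqrt(
                mse / 2 * (1 / ns[a] + 1 / ns[b]))
            expected = stats.studentized_range.sf(q, 3, 72)
            assert got[label] == pytest.approx(expected, rel=1e-6)

    def test_small_group_omitted_with_warning(self, rng):
        v = rng.standard_normal(41)
        codes = np.array([0] * 20 + [1] * 20 + [2])
        with pytest.warns(UserWarning, match="below n=2"):
            p = tukey_hsd(v, codes)
        assert set(p) == {"AA:AB"}

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd(np.ones(30), np.repeat([0, 1, 2], 10))


class TestMinP:
    def test_corrected_never_below_raw(self, rng):
        m = pd.DataFrame(rng.standard_normal((60, 10)))
        m.columns = [f"t{i}" for i in range(10)]
        codes = np.repeat([0, 1, 2], 20)
        out = minp_permutation_correction(m, codes, n_perm=200, seed=1)
        assert (out.corrected_p >= out.raw_p - 1e-12).all()

    def test_single_trait_correction_close_to_raw(self, rng):
        effect = np.repeat([0.0, 0.0, 1.0], 40)
        m = pd.DataFrame({"t": rng.standard_normal(120) + effect})
        codes = np.repeat([0, 1, 2], 40)
        out = minp_permutation_correction(m, codes, n_perm=2000, seed=2)
        row = out[out.comparison == "AA:BB"].iloc[0]
        # with one trait the min-p null is the raw-p null: corrected ~ raw
        assert row.corrected_p == pytest.approx(max(row.raw_p, 1 / 2001), abs=0.02)

    def test_null_trait_corrected_to_one(self, rng):
        m = pd.DataFrame({"null": rng.standard_normal(90),
                          "sig": rng.standard_normal(90) + np.repeat([0, 0, 3], 30)})
        codes = np.repeat([0, 1, 2], 30)
        out = minp_permutation_correction(m, codes, n_perm=300, seed=3)
        null_row = out[(out.trait == "null") & (out.comparison == "AA:BB")].iloc[0]
        assert null_row.corrected_p > 0.5

    def test_requires_minimum_permutations(self, rng):
        m = pd.DataFrame({"t": rng.standard_normal(30)})
        with pytest.raises(ValueError):
            minp_permutation_correction(m, np.repeat([0, 1, 2], 10), n_perm=10)


def _aligned_from_array(X):
    Xc = X - X.mean(axis=1, keepdims=True)
    return AlignedShapeSet(Xc, Xc.mean(axis=0))


class TestGeometricPermutation:
    def test_add_one_rule_for_extreme_observation(self, rng):
        X = rng.standard_normal((60, 20, 3)) * 0.01
        X[:20, :10, 2] += 5.0           # non-rigid group difference
        labels = np.array([0] * 20 + [1] * 40)
        al = _aligned_from_array(X)
        res = geometric_permutation_test(al, labels, (0, 1), n_perm=4999, seed=0)
        assert res.nominal_p == pytest.approx(1 / 5000)
        assert res.p_unsmoothed == 0.0

    def test_pair_order_invariance(self, cohort_small):
        al = partial_gpa(cohort_small.dense_shapes(), ids=cohort_small.ids)
        codes = np.array([i.genotype_codes["rs642961"]
                          for i in cohort_small.individuals])
        r1 = geometric_permutation_test(al, codes, (0, 1), n_perm=200, seed=9)
        r2 = geometric_permutation_test(al, codes, (1, 0), n_perm=200, seed=9)
        assert r1.nominal_p == r2.nominal_p
        assert r1.ppd == pytest.approx(r2.ppd)

    def test_type_one_error_calibrated(self, rng):
        """Null rejection rate at alpha=0.05 within its binomial CI."""
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            X = r.standard_normal((40, 15, 3))
            labels = np.array([0] * 20 + [1] * 20)
            res = geometric_permutation_test(
                _aligned_from_array(X), labels, (0, 1), n_perm=199, seed=rep)
            rejections += res.nominal_p <= 0.05
        assert 0.020 * n_rep <= rejections <= 0.085 * n_rep

    def test_small_group_flagged(self, rng):
        X = rng.standard_normal((25, 10, 3))
        labels = np.array([0] * 5 + [1] * 20)
        res = geometric_permutation_test(_aligned_from_array(X), labels, (0, 1),
                                         n_perm=100, seed=1)
        assert res.flagged_small

    def test_empty_group_rejected(self, rng):
        X = rng.standard_normal((10, 5, 3))
        with pytest.raises(ValueError):
            geometric_permutation_test(_aligned_from_array(X),
                                       np.zeros(10), (0, 1), n_perm=100)

    def test_sex_stratification_isolated(self, cohort_small):
        """Results in one stratum are unaffected by the other stratum."""
        fem = cohort_small.subset_ids(sex="female")
        pos = [cohort_small.ids.index(i) for i in fem]
        shapes = cohort_small.dense_shapes()
        codes = np.array([cohort_small.individuals[p].genotype_codes["rs642961"]
                          for p in pos])
        al1 = partial_gpa(shapes[pos], ids=fem)
        r1 = geometric_permutation_test(al1, codes, (0, 1), n_perm=300, seed=4)
        mutated = shapes.copy()
        male_pos = [i for i in range(len(shapes)) if i not in pos]
        mutated[male_pos] *= 10.0       # corrupt the other stratum
        al2 = partial_gpa(mutated[pos], ids=fem)
        r2 = geometric_permutation_test(al2, codes, (0, 1), n_perm=300, seed=4)
        assert r1.nominal_p == r2.nominal_p
        assert r1.ppd == pytest.approx(r2.ppd)


class TestRegionExtraction:
    def test_full_index_set_is_identity(self, cohort_small):
        al = partial_gpa(cohort_small.dense_shapes()[:8])
        sub = extract_region(al, np.arange(al.n_points))
        assert np.array_equal(sub.shapes, al.shapes)

    def test_region_ppd_ignores_outside_points(self, cohort_small, rng):
        al = partial_gpa(cohort_small.dense_shapes()[:8])
        region = cohort_small.effect_indices
        sub1 = extract_region(al, region)
        perturbed = al.shapes.copy()
        outside = np.setdiff1d(np.arange(al.n_points), region)
        perturbed[:, outside] += rng.standard_normal((len(outside), 3)) * 9
        sub2 = extract_region(
            AlignedShapeSet(perturbed, perturbed.mean(axis=0)), region)
        assert np.array_equal(sub1.shapes, sub2.shapes)

    def test_empty_region_rejected(self, cohort_small):
        al = partial_gpa(cohort_small.dense_shapes()[:4])
        with pytest.raises(ValueError):
            extract_region(al, [])


class TestHWE:
    def test_exact_hwe_counts_give_zero_statistic(self):
        chi2, p = hwe_test((49, 42, 9))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_heterozygote_extreme(self):
        chi2, p = hwe_test((0, 100, 0))
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-20

    def test_invariant_to_allele_swap(self):
        a = hwe_test((30, 50, 20))
        b = hwe_test((20, 50, 30))
        assert a[0] == pytest.approx(b[0])

    def test_monomorphic_warns(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            chi2, p = hwe_test((50, 0, 0))
        assert p == 1.0


class TestBonferroni:
    def test_worked_examples(self):
        assert bonferroni(7e-5, 12) == pytest.approx(8.4e-4)
        assert bonferroni(1e-5, 12) == pytest.approx(1.2e-4)
        assert bonferroni(0.2, 10) == 1.0

    def test_thresholds_to_two_significant_figures(self):
        assert bonferroni_threshold(0.05, 60) == pytest.approx(0.00083)
        assert bonferroni_threshold(0.05, 12) == pytest.approx(0.0042)


class TestTwoStage:
    @pytest.fixture(scope="class")
    def report(self, cohort_small):
        return two_stage_pipeline(
            cohort_small, n_perm_lmd=150, n_perm_geom_stage1=150,
            n_perm_stage2=300, region="mouth", schemes=("lmd", "lmg", "dg"),
            seed=0)

    def test_stage_one_family_size(self, cohort_small, report):
        assert report.n_tests_stage1 == len(cohort_small.config.snps) * 3 * 2 == 60
        assert report.threshold_stage1 == pytest.approx(0.00083)

    def test_stage_two_family_size(self, report):
        assert report.n_tests_stage2 == len(report.advanced) * 6

    def test_hwe_reported_for_every_snp(self, cohort_small, report):
        assert set(report.hwe.snp) == {s.name for s in cohort_small.config.snps}

    def test_geom_results_have_valid_pvalues(self, report):
        assert ((report.geom_stage1.nominal_p > 0)
                & (report.geom_stage1.nominal_p <= 1)).all()

    def test_lmd_corrected_at_least_raw(self, report):
        df = report.lmd_stage1
        assert (df.corrected_p >= df.raw_p - 1e-12).all()
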
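"""Cohort analytics: exposure similarity, PCA, age regression, Mann-Whitney,
SV proportions, region-restricted spectra."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutspect import (
    SBS96,
    ExposureProfile,
    GenomeAccessor,
    LabeledIntervals,
    MutationCatalog,
    MutationRecord,
    SampleMeta,
    SVRecord,
    age_regression,
    compare_cohorts,
    pca_spectra,
    region_subset_spectrum,
    similarity_to_exposure,
    summarize_by_cohort,
    sv_class_proportions,
)
from mutspect.synthetic_data import CohortSpec, simulate_cohorts

from .oracles import mw_exact_oracle


def _cat(counts, sid="s"):
    return MutationCatalog(sid, SBS96, np.asarray(counts, dtype=int))


class TestSimilarity:
    def test_proportional_sample_scores_one(self, syn_sigs):
        prof = ExposureProfile("E", syn_sigs.column("SYN1"), SBS96)
        cat = _cat(np.round(syn_sigs.column("SYN1") * 1e6))
        df = similarity_to_exposure([cat], prof)
        assert df.loc[0, "similarity"] == pytest.approx(1.0, abs=1e-6)

    def test_scaling_and_permutation_invariance(self, syn_sigs, rng):
        counts = rng.integers(0, 50, 96)
        counts[0] += 1  # non-zero
        prof = ExposureProfile("E", syn_sigs.column("SYN2"), SBS96)
        s1 = similarity_to_exposure([_cat(counts)], prof).loc[0, "similarity"]
        s2 = similarity_to_exposure([_cat(counts * 13)], prof).loc[0, "similarity"]
        assert s1 == pytest.approx(s2, abs=1e-12)
        perm = rng.permutation(96)
        prof_p = ExposureProfile("E", syn_sigs.column("SYN2")[perm], SBS96)
        s3 = similarity_to_exposure([_cat(counts[perm])], prof_p).loc[0, "similarity"]
        assert s1 == pytest.approx(s3, abs=1e-12)

    def test_hand_computed_micro_example(self):
        # 4 informative categories, hand cosines
        def vec(v):
            x = np.zeros(96)
            x[:4] = v
            return x

        prof = ExposureProfile("E", vec([1, 1, 0, 0]), SBS96)
        cats = [_cat(vec([1, 1, 0, 0]) * 10, "a"),
                _cat(vec([1, 0, 1, 0]) * 10, "b"),
                _cat(vec([0, 0, 1, 1]) * 10, "c")]
        df = similarity_to_exposure(cats, prof)
        assert df["similarity"].tolist() == pytest.approx([1.0, 0.5, 0.0], abs=1e-12)

    def test_empty_catalog_skipped_with_warning(self, syn_sigs):
        prof = ExposureProfile("E", syn_sigs.column("SYN1"), SBS96)
        with pytest.warns(UserWarning, match="empty"):
            df = similarity_to_exposure([_cat(np.zeros(96), "z")], prof)
        assert df.loc[0, "skipped"]

    def test_exposed_cohort_scores_above_unexposed(self, syn_sigs, rng):
        expo = syn_sigs.column("SYN5")
        bg = 0.5 * syn_sigs.column("SYN1") + 0.5 * syn_sigs.column("SYN2")
        prof = ExposureProfile("E", expo, SBS96)
        for _ in range(5):
            a = [_cat(rng.multinomial(2000, 0.5 * bg + 0.5 * expo), f"a{i}")
                 for i in range(20)]
            b = [_cat(rng.multinomial(2000, bg), f"b{i}") for i in range(20)]
            med_a = similarity_to_exposure(a, prof)["similarity"].median()
            med_b = similarity_to_exposure(b, prof)["similarity"].median()
            assert med_a > med_b

    def test_mean_vs_pooled_profiles(self, syn_sigs):
        c1 = _cat(np.round(syn_sigs.column("SYN1") * 100), "r1")
        c2 = _cat(np.round(syn_sigs.column("SYN2") * 300), "r2")
        mean_prof = ExposureProfile.from_catalogs("E", [c1, c2], method="mean")
        pooled = ExposureProfile.from_catalogs("E", [c1, c2], method="pooled")
        # pooled profile tilts toward the larger replicate
        assert not np.allclose(mean_prof.spectrum, pooled.spectrum)


class TestPCA:
    def test_duplicated_samples_error(self):
        X = np.tile(np.linspace(0, 1, 96), (4, 1))
        with pytest.raises(ValueError, match="identical"):
            pca_spectra(X)

    def test_lossless_reconstruction(self, rng):
        X = rng.random((4, 3))
        res = pca_spectra(X)
        recon = res.scores @ res.loadings.T + X.mean(axis=0)
        assert np.allclose(recon, X, atol=1e-10)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_translation_invariance_of_scores(self, rng):
        X = rng.random((6, 8))
        shifted = X + 0.37
        a, b = pca_spectra(X), pca_spectra(shifted)
        assert np.allclose(a.scores, b.scores, atol=1e-9)

    def test_pc1_separates_exposure_clusters(self, syn_sigs, rng):
        from sklearn.metrics import silhouette_score

        expo = syn_sigs.column("SYN5")
        bg = 0.5 * syn_sigs.column("SYN1") + 0.5 * syn_sigs.column("SYN2")
        X = np.vstack(
            [rng.multinomial(3000, 0.6 * bg + 0.4 * expo) / 3000 for _ in range(15)]
            + [rng.multinomial(3000, bg) / 3000 for _ in range(15)]
        )
        res = pca_spectra(X)
        labels = np.array([0] * 15 + [1] * 15)
        assert silhouette_score(res.scores[:, :1], labels) > 0

    def test_sign_convention(self, rng):
        X = rng.random((5, 7))
        res = pca_spectra(X)
        for k in range(res.loadings.shape[1]):
            j = np.argmax(np.abs(res.loadings[:, k]))
            assert res.loadings[j, k] > 0


class TestAgeRegression:
    def _scores(self, ages, values, cohort="C"):
        meta = [SampleMeta(f"s{i}", cohort, a) for i, a in enumerate(ages)]
        scores = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(ages))],
             "similarity": values, "skipped": False}
        )
        return scores, meta

    def test_noiseless_line_recovered(self):
        ages = np.array([40, 50, 60, 70, 80.0])
        scores, meta = self._scores(ages, 0.001 * ages + 0.2)
        res = age_regression(scores, meta, "C")
        assert res.slope == pytest.approx(0.001, abs=1e-12)
        assert res.intercept == pytest.approx(0.2, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_age_rejected(self):
        scores, meta = self._scores([50, 50, 50], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="constant age"):
            age_regression(scores, meta, "C")

    def test_null_slope_pvalues_roughly_uniform(self, rng):
        """With no true age effect, slope p-values are ~U(0,1) (KS check on a
        scaled-down replicate grid; the full 500-replicate calibration runs in
        the acceptance suite)."""
        pvals = []
        for _ in range(200):
            ages = rng.uniform(40, 80, 50)
            vals = rng.normal(0.5, 0.1, 50)
            scores, meta = self._scores(ages, vals)
            pvals.append(age_regression(scores, meta, "C").slope_pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_positive_slope_power(self, rng):
        detected = 0
        for _ in range(40):
            ages = rng.uniform(40, 80, 100)
            vals = 0.004 * ages + rng.normal(0.3, 0.05, 100)
            scores, meta = self._scores(ages, vals)
            detected += age_regression(scores, meta, "C").slope > 0
        assert detected >= 38  # >= 95%


class TestMannWhitney:
    def test_textbook_separation(self):
        u, p, method = compare_cohorts([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert method == "exact"
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)

    def test_identical_groups_p_one(self):
        u, p, method = compare_cohorts([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("m,n", [(2, 2), (3, 3), (2, 5), (4, 4), (3, 6), (5, 5)])
    def test_exact_p_matches_enumeration(self, m, n, rng):
        """Exact two-sided p agrees with the rank-sum enumeration oracle for
        every group-size split with m+n <= 10, with and without ties."""
        for trial in range(5):
            a = rng.integers(0, 6, m).astype(float)  # small support -> ties
            b = rng.integers(0, 6, n).astype(float)
            u, p, method = compare_cohorts(a, b)
            u_o, p_o = mw_exact_oracle(a, b)
            assert method == "exact"
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_large_sample_power(self, rng):
        rejections = 0
        for _ in range(40):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)  # shift = 1 SD
            _, p, method = compare_cohorts(a, b)
            rejections += p < 0.05
            assert method == "normal"
        assert rejections >= 36  # > 0.9 power

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_cohorts([1.0], [2.0, 3.0])


class TestSVProportions:
    def _sv(self, sid, cls):
        return SVRecord(sid, cls, "chr1", 100, "chr1" if cls != "TRA" else "chr2",
                        5000, support=10)

    def test_known_fractions(self):
        records = [self._sv("s1", "TRA")] * 5 + [self._sv("s1", "DEL")] * 5
        df = sv_class_proportions(records, {"s1": "A"})
        tra = df[(df.cohort == "A") & (df.svclass == "TRA")].iloc[0]
        assert tra["fraction"] == pytest.approx(0.5)

    def test_single_class_cohort(self):
        records = [self._sv("s1", "INV")] * 4
        df = sv_class_proportions(records, {"s1": "A"})
        by = df.set_index("svclass")["fraction"]
        assert by["INV"] == 1.0
        assert by[["DEL", "DUP", "TRA"]].sum() == 0.0

    def test_fractions_sum_to_one_and_match_tally(self, rng):
        classes = np.array(["DEL", "DUP", "INV", "TRA"])
        records = []
        cohort_of = {}
        for i in range(60):
            sid = f"s{i}"
            cohort_of[sid] = "A" if i < 30 else "B"
            for cls in rng.choice(classes, rng.integers(1, 8)):
                records.append(self._sv(sid, str(cls)))
        df = sv_class_proportions(records, cohort_of)
        for cohort, grp in df.groupby("cohort"):
            assert grp["fraction"].sum() == pytest.approx(1.0)
            brute = sum(1 for r in records if cohort_of[r.sample_id] == cohort)
            assert grp["count"].sum() == brute


class TestRegionSubset:
    def test_all_records_inside_equals_full(self, ref100k, syn_sigs):
        from mutspect.synthetic_data import SampleSpec, simulate_sample

        sample = simulate_sample(ref100k, syn_sigs,
                                 SampleSpec("s", {"SYN1": 1.0}, 200), seed=9)
        genome = {ref100k.chrom: ref100k.sequence}
        everything = LabeledIntervals.from_tuples(
            "all", [(ref100k.chrom, 0, len(ref100k.sequence))])
        res = region_subset_spectrum(sample.records, everything, genome, SBS96)
        assert (res.subset_catalog.counts == res.full_catalog.counts).all()
        assert not res.empty

    def test_no_records_inside_flags_empty(self, ref100k):
        region = LabeledIntervals.from_tuples("tiny", [(ref100k.chrom, 0, 10)])
        rec = MutationRecord(ref100k.chrom, 50_000, ref100k.sequence[49_999],
                             "A" if ref100k.sequence[49_999] != "A" else "C", "s")
        res = region_subset_spectrum([rec], region, {ref100k.chrom: ref100k.sequence},
                                     SBS96)
        assert res.empty
        assert res.subset_catalog.n_total == 0

    def test_engineered_in_region_enrichment(self, ref100k):
        """Region built to hold only C>A mutations while the genome-wide set is
        half C>A, half T>C: the in-region C>A fraction doubles."""
        genome = {ref100k.chrom: ref100k.sequence}
        ca_pos = [int(p) for p in ref100k.candidates_sbs("A[C>A]A")[:40]]
        tc_pos = [int(p) for p in ref100k.candidates_sbs("A[T>C]A")[:40]]
        records = [MutationRecord(ref100k.chrom, p + 1, "C", "A", "s") for p in ca_pos]
        records += [MutationRecord(ref100k.chrom, p + 1, "T", "C", "s") for p in tc_pos]
        region = LabeledIntervals.from_tuples(
            "cancer_genes", [(ref100k.chrom, p, p + 1) for p in ca_pos])
        res = region_subset_spectrum(records, region, genome, SBS96,
                                     focus_categories=["A[C>A]A"])
        assert res.subset_class_fractions["C>A"] == pytest.approx(1.0)
        assert res.full_class_fractions["C>A"] == pytest.approx(0.5)
        assert res.subset_category_fractions["A[C>A]A"] == pytest.approx(1.0)


class TestSimulatedCohortsIntegration:
    def test_age_trend_and_cohort_contrast(self, syn_sigs):
        specs = [
            CohortSpec("EXPOSED", 50, exposure_slope=0.01, baseline_admixture=0.2),
            CohortSpec("CLEAN", 50, exposure_slope=0.0, baseline_admixture=0.0),
        ]
        sim = simulate_cohorts(specs, syn_sigs, seed=42)
        cats = [MutationCatalog(sid, SBS96, sim.spectra.loc[sid].to_numpy())
                for sid in sim.spectra.index]
        prof = ExposureProfile("E", syn_sigs.column("SYN5"), SBS96)
        scores = similarity_to_exposure(cats, prof)
        summary = summarize_by_cohort(scores, sim.meta).set_index("cohort")
        assert summary.loc["EXPOSED", "median"] > summary.loc["CLEAN", "median"]
        res = age_regression(scores, sim.meta, "EXPOSED")
        assert res.slope > 0
        a = scores.set_index("sample_id").loc[
            [m.sample_id for m in sim.meta if m.cohort == "EXPOSED"], "similarity"]
        b = scores.set_index("sample_id").loc[
            [m.sample_id for m in sim.meta if m.cohort == "CLEAN"], "similarity"]
        _, p, _ = compare_cohorts(a, b)
        assert p < 1e-3
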
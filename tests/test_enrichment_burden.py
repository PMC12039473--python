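"""Exact enrichment test, multiplicity control and burden arithmetic."""

import math

import numpy as np
import pytest

from stillkit.cohort_io import SampleMeta, VariantKey
from stillkit.enrichment_burden import (
    age_bracket_partition,
    bonferroni_threshold,
    carrier_proportion,
    chip_prevalence_by_bracket,
    fisher_enrichment,
    fisher_enrichment_many,
    joint_origin_carriers,
    multi_variant_histogram,
    run_enrichment,
    variants_per_gene,
)
from stillkit.cohort_io import AnnotatedVariant, PopulationRef
from stillkit.variant_pipeline import (
    CarrierObservation,
    ClassifiedVariant,
    ORIGIN_GERMLINE,
    ORIGIN_SOMATIC,
)


def hypergeom_tail_oracle(k, n, K, N):
    """Upper-tail hypergeometric probability by direct enumeration.

    P(X >= k) where X counts carriers among n draws without replacement
    from a pool of n + N individuals of whom k + K are carriers.
    Computed from binomial coefficients, independent of scipy.
    """
    M, good, draws = n + N, k + K, n
    denom = math.comb(M, draws)
    total = 0
    for j in range(k, min(good, draws) + 1):
        total += math.comb(good, j) * math.comb(M - good, draws - j)
    return total / denom


class TestFisherEnrichment:
    def test_zero_cohort_carriers_never_enriched(self):
        assert fisher_enrichment(0, 60, 100, 590_031) == 1.0

    def test_agrees_with_enumeration_oracle(self):
        # spot grid over cohort/reference sizes, tolerance 1e-12
        assert fisher_enrichment(2, 60, 5, 1000) == pytest.approx(
            hypergeom_tail_oracle(2, 60, 5, 1000), abs=1e-12
        )
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 61))
            N = int(rng.integers(1, 1001))
            k = int(rng.integers(0, n + 1))
            K = int(rng.integers(0, N + 1))
            assert fisher_enrichment(k, n, K, N) == pytest.approx(
                hypergeom_tail_oracle(k, n, K, N), abs=1e-12
            ), (k, n, K, N)

    def test_p_nonincreasing_in_k(self):
        for K in (0, 3, 50):
            ps = [fisher_enrichment(k, 60, K, 1000) for k in range(0, 61)]
            assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_vectorised_matches_scalar(self):
        k = np.array([0, 1, 2, 5])
        K = np.array([10, 10, 3, 0])
        many = fisher_enrichment_many(k, 60, K, 1000)
        for i in range(k.size):
            assert many[i] == pytest.approx(
                fisher_enrichment(int(k[i]), 60, int(K[i]), 1000), abs=1e-12
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(5, 3, 0, 10)
        with pytest.raises(ValueError):
            fisher_enrichment(1, 60, 11, 10)


class TestBonferroni:
    def test_study_family_threshold(self):
        # 0.05 / 142 prints as 3.52e-4 at 3 significant figures
        t = bonferroni_threshold(0.05, 142)
        assert f"{t:.3g}" == "0.000352"

    def test_single_test_keeps_alpha(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_transcriptome_family_arithmetic(self):
        assert bonferroni_threshold(0.05, 81) == pytest.approx(6.17e-4, rel=1e-3)

    def test_zero_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestRunEnrichment:
    def _key(self, i):
        return VariantKey("chr1", i + 1, "A", "G")

    def test_family_size_is_joint_unique_count(self):
        case = {self._key(i): 1 for i in range(89)}
        control = {self._key(200 + i): 1 for i in range(53)}
        ref = {}
        res = run_enrichment(case, control, ref, n_case=60, n_control=49)
        assert res[0].m == 142
        assert res[0].threshold == pytest.approx(0.05 / 142)

    def test_empty_sets_give_empty_result(self):
        assert run_enrichment({}, {}, {}, 60, 49) == []

    def test_each_cohort_uses_own_n(self):
        case = {self._key(1): 2}
        control = {self._key(2): 2}
        res = run_enrichment(case, control, {}, n_case=60, n_control=49)
        by_cohort = {r.cohort: r for r in res}
        assert by_cohort["case"].n == 60
        assert by_cohort["control"].n == 49

    def test_absent_reference_row_means_zero_carriers(self):
        res = run_enrichment({self._key(1): 1}, {}, {}, 60, 49)
        assert res[0].K == 0 and res[0].N == 590_031


class TestProportions:
    @pytest.mark.parametrize(
        "num,den,pct",
        [
            (18, 60, 30.0),
            (5, 49, 10.2),
            (14, 60, 23.3),
            (17, 49, 34.7),
            (13, 59, 22.0),
            (2, 43, 4.7),
            (31, 60, 51.7),
            (12, 60, 20.0),
            (0, 49, 0.0),
        ],
    )
    def test_printed_ratios_reproduce(self, num, den, pct):
        assert carrier_proportion(num, den).percent == pct

    def test_half_up_rounding(self):
        # 1/16 = 6.25% rounds up, not to even
        assert carrier_proportion(1, 16).percent == 6.3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            carrier_proportion(1, 0)
        with pytest.raises(ValueError):
            carrier_proportion(5, 3)


class TestVariantsPerGene:
    def test_simple_ratio(self):
        assert variants_per_gene({"chip": 10}, {"chip": 20}) == {"chip": 0.50}

    def test_zero_variants(self):
        assert variants_per_gene({"chip": 0}, {"chip": 20}) == {"chip": 0.00}

    def test_unknown_panel_rejected(self):
        with pytest.raises(ValueError):
            variants_per_gene({"mystery": 1}, {"chip": 20})

    def test_matches_bruteforce_on_synthetic_panels(self, cohort, panel_genes):
        from stillkit.variant_pipeline import prioritize_variants

        classified = prioritize_variants(
            cohort.germline_calls, cohort.somatic_calls,
            cohort.annotations, panel_genes,
        )
        sizes = {p: len(cohort.panels[p])
                 for p in ("chip", "autoinflammation", "interferonopathy")}
        counts = {p: sum(1 for cv in classified if cv.annotation.panel == p)
                  for p in sizes}
        got = variants_per_gene(counts, sizes)
        for p in sizes:
            assert got[p] == pytest.approx(counts[p] / sizes[p], abs=0.005)


class TestHistogram:
    def test_bins_partition_cohort(self):
        h = multi_variant_histogram([2, 3, 1, 0])
        assert h.bins == {"0": 1, "1": 1, "2": 1, "3+": 1}
        assert sum(h.bins.values()) == h.n == 4

    def test_study_multi_variant_proportion(self):
        counts = [2] * 31 + [1] * 24 + [0] * 5  # 31 of 60 carry >= 2
        h = multi_variant_histogram(counts)
        assert h.prop_multi.percent == 51.7

    def test_three_plus_proportion(self):
        counts = [3] * 9 + [0] * 21  # 9 of 30 carry >= 3
        h = multi_variant_histogram(counts)
        assert carrier_proportion(h.bins["3+"], h.n).percent == 30.0


def _cv(key, origin, carriers, panel="chip", gene="G1"):
    ann = AnnotatedVariant(key, gene, panel, "missense", 0.001, 25.0)
    return ClassifiedVariant(
        key, ann, origin, tuple(CarrierObservation(s) for s in carriers)
    )


class TestJointCarriers:
    def test_single_origin_carrier_not_counted(self):
        k1 = VariantKey("chr1", 1, "A", "G")
        classified = [_cv(k1, ORIGIN_GERMLINE, ["S1"])]
        joint, prop = joint_origin_carriers(classified, ["S1", "S2"])
        assert joint == [] and prop.percent == 0.0

    def test_study_proportion(self):
        samples = [f"S{i}" for i in range(60)]
        classified = []
        for i in range(14):  # 14 joint carriers of 60 -> 23.3%
            kg = VariantKey("chr1", 100 + i, "A", "G")
            ks = VariantKey("chr2", 100 + i, "C", "T")
            classified.append(_cv(kg, ORIGIN_GERMLINE, [samples[i]]))
            classified.append(_cv(ks, ORIGIN_SOMATIC, [samples[i]]))
        joint, prop = joint_origin_carriers(classified, samples)
        assert len(joint) == 14 and prop.percent == 23.3

    def test_planted_joint_carriers_recovered(self, cohort, panel_genes):
        from stillkit.variant_pipeline import prioritize_variants

        classified = prioritize_variants(
            cohort.germline_calls, cohort.somatic_calls,
            cohort.annotations, panel_genes,
        )
        exome = cohort.exome_samples
        joint, _ = joint_origin_carriers(classified, exome)
        assert set(joint) == cohort.truth.joint_carriers


class TestAgeBrackets:
    def _meta(self, ages):
        return {
            f"S{i}": SampleMeta(f"S{i}", "AOSD2", age, "F")
            for i, age in enumerate(ages)
        }

    def test_bracket_bounds_are_closed(self):
        labels = age_bracket_partition(self._meta([29, 30, 49, 50, 80]))
        assert list(labels.values()) == ["19-29", "30-49", "30-49", "50-80", "50-80"]

    def test_age_outside_brackets_unbracketed(self):
        labels = age_bracket_partition(self._meta([18, 81]))
        assert set(labels.values()) == {"unbracketed"}

    def test_overlapping_brackets_rejected(self):
        with pytest.raises(ValueError):
            age_bracket_partition(self._meta([25]), brackets=((19, 35), (30, 49)))

    def test_synthetic_prevalence_matches_planted_rates(self, cohort, panel_genes):
        # per-bracket somatic prevalence within the binomial 99% CI of the
        # configured planting rate
        from scipy.stats import binom
        from stillkit.variant_pipeline import prioritize_variants
        from stillkit.synthetic_cohort import SimConfig

        cfg = SimConfig()
        classified = prioritize_variants(
            cohort.germline_calls, cohort.somatic_calls,
            cohort.annotations, panel_genes,
        )
        case_meta = {s: m for s, m in cohort.meta.items()
                     if s in set(cohort.exome_samples) and m.cohort.startswith("AOSD")}
        prev = chip_prevalence_by_bracket(classified, case_meta, cfg.age_brackets)
        for i, (lo, hi) in enumerate(cfg.age_brackets):
            label = f"{lo}-{hi}"
            if label not in prev:
                continue
            p = prev[label]
            rate = cfg.somatic_rate_case[i] * cfg.somatic_chip_fraction
            lo_ci = binom.ppf(0.005, p.denominator, rate)
            hi_ci = binom.ppf(0.995, p.denominator, rate)
            assert lo_ci <= p.numerator <= hi_ci, (label, p)
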
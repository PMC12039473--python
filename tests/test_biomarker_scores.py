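"""Serum IFN score, severity bands, rank statistics and stratification."""

import itertools
import math

import numpy as np
import pytest

from stillkit.biomarker_scores import (
    compare_groups,
    ifn_score_serum,
    median_iqr,
    paired_change,
    rank_test,
    sas_band,
    score_vs_score_regression,
    star_label,
    stratify_by_variant_count,
)
from stillkit.cohort_io import IFN_CHEMOKINES


def _chem(value):
    return dict.fromkeys(IFN_CHEMOKINES, value)


class TestSerumIfnScore:
    def test_round_concentration_gives_round_score(self):
        # all five at 9,999 pg/mL -> log10(10^4) = 4
        assert ifn_score_serum(_chem(9_999.0)) == pytest.approx(4.0)

    def test_zero_concentrations_give_zero(self):
        assert ifn_score_serum(_chem(0.0)) == 0.0

    def test_missing_analyte_error_names_it(self):
        chem = _chem(100.0)
        del chem["CCL8"]
        with pytest.raises(ValueError, match="CCL8"):
            ifn_score_serum(chem)

    def test_strictly_monotone_in_each_analyte(self):
        base = _chem(1000.0)
        s0 = ifn_score_serum(base)
        for a in IFN_CHEMOKINES:
            bumped = dict(base)
            bumped[a] += 10.0
            assert ifn_score_serum(bumped) > s0

    def test_case_scores_exceed_control_across_seeded_replicates(self):
        # the planted case/control chemokine shift is detectable in >= 95%
        # of replicates via the median serum score
        from stillkit.synthetic_cohort import DEFAULT_ANALYTES, sample_analyte

        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(20_000 + seed)
            case = np.median([
                np.mean([math.log10(v + 1) for v in
                         [sample_analyte(DEFAULT_ANALYTES[a], True, 1, rng)[0]
                          for a in IFN_CHEMOKINES]])
                for _ in range(106)
            ])
            control = np.median([
                np.mean([math.log10(v + 1) for v in
                         [sample_analyte(DEFAULT_ANALYTES[a], False, 1, rng)[0]
                          for a in IFN_CHEMOKINES]])
                for _ in range(30)
            ])
            hits += case > control
        assert hits >= 95


class TestSasBand:
    @pytest.mark.parametrize("sas,band", [
        (0, "mild"), (2, "mild"), (3, "moderate"), (4, "moderate"),
        (5, "severe"), (7, "severe"),
    ])
    def test_band_boundaries(self, sas, band):
        assert sas_band(sas) == band

    def test_bands_partition_full_range(self):
        assert [sas_band(s) for s in range(8)] == (
            ["mild"] * 3 + ["moderate"] * 2 + ["severe"] * 3
        )

    def test_out_of_range_rejected(self):
        for bad in (-1, 8):
            with pytest.raises(ValueError):
                sas_band(bad)


class TestStarLabel:
    @pytest.mark.parametrize("p,stars", [
        (0.06, "ns"), (0.05, "ns"), (0.049, "*"),
        (0.01, "*"), (0.0099, "**"), (0.0075, "**"),
        (0.001, "**"), (0.0009, "***"),
        (0.0001, "***"), (0.00009, "****"),
    ])
    def test_step_function_boundaries(self, p, stars):
        assert star_label(p) == stars


def rank_test_oracle(a, b):
    """Two-sided rank-sum p by brute-force permutation of group labels.

    U is computed by direct pairwise comparison (independent of the
    implementation's rank-based formula).
    """
    def u_stat(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    pooled = list(a) + list(b)
    n1 = len(a)
    mu = n1 * len(b) / 2
    obs = abs(u_stat(a, b) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        hits += abs(u_stat(ga, gb) - mu) >= obs - 1e-12
    return hits / total


class TestRankTest:
    def test_identical_samples_give_p_one(self):
        assert rank_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_complete_separation_exact_p(self):
        # 2 extreme assignments of 20 -> p = 0.1
        assert rank_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_mode_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for n1, n2 in [(1, 3), (2, 4), (3, 3), (4, 5), (5, 5), (3, 7)]:
            a = list(np.round(rng.normal(0, 1, n1), 1))
            b = list(np.round(rng.normal(0.5, 1, n2), 1))  # ties likely
            assert rank_test(a, b) == pytest.approx(rank_test_oracle(a, b), abs=1e-12)

    def test_approximation_close_to_exact_at_switchover(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            a = list(rng.normal(0, 1, 6))
            b = list(rng.normal(0.8, 1, 6))
            exact = rank_test(a, b)  # combined n = 12 -> exact
            # the asymptotic form (scipy's, continuity-corrected) should be
            # within 0.02 of the exact enumeration at the switchover size
            from scipy.stats import mannwhitneyu
            asym = mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic").pvalue
            assert exact == pytest.approx(asym, abs=0.02)

    def test_matches_scipy_exact_when_tie_free(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(23)
        a = list(rng.normal(0, 1, 5))
        b = list(rng.normal(1, 1, 5))
        assert rank_test(a, b) == pytest.approx(
            mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue,
            abs=1e-12,
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_test([], [1.0])


class TestCompareGroups:
    def test_group_vs_itself_not_significant(self):
        groups = {"A": [1.0, 2.0, 3.0, 4.0]}
        (cmp_,) = compare_groups(groups, "specks", [("A", "A")])
        assert cmp_.p_value == 1.0
        assert cmp_.stars == "ns"

    def test_planted_specks_shift_reaches_four_stars(self):
        # case median x5 at n = 60 vs 30 is overwhelmingly significant
        rng = np.random.default_rng(30)
        hits = 0
        for _ in range(20):
            case = list(rng.lognormal(math.log(250), 1.0, 60))
            control = list(rng.lognormal(math.log(50), 1.0, 30))
            (cmp_,) = compare_groups(
                {"AOSD": case, "HC": control}, "specks", [("AOSD", "HC")]
            )
            hits += cmp_.stars == "****"
        assert hits >= 16

    def test_iqr_uses_linear_interpolation(self):
        med, (q1, q3) = median_iqr([1, 2, 3, 4])
        assert med == 2.5
        assert q1 == pytest.approx(1.75)
        assert q3 == pytest.approx(3.25)


class TestPairedChange:
    def test_no_change_gives_p_one(self):
        pre = {"a": 1.0, "b": 2.0, "c": 3.0}
        res = paired_change(pre, dict(pre))
        assert res.p_value == 1.0 and res.median_change == 0.0

    def test_sign_flip_preserves_p(self):
        rng = np.random.default_rng(31)
        pre = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(10, 100, 15))}
        post = {k: v * 0.5 + float(rng.normal(0, 1)) for k, v in pre.items()}
        down = paired_change(pre, post)
        flipped = {k: 2 * pre[k] - post[k] for k in pre}  # mirror the changes
        up = paired_change(pre, flipped)
        assert down.p_value == pytest.approx(up.p_value)
        assert down.direction == "decrease" and up.direction == "increase"

    def test_planted_reduction_significant_in_most_replicates(self):
        # a 60% reduction at n = 15 is detected at the 0.01 level >= 90% of runs
        rng = np.random.default_rng(32)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            pre = {f"s{i}": float(v)
                   for i, v in enumerate(rng.lognormal(math.log(300), 1.0, 15))}
            post = {k: v * 0.4 * float(rng.lognormal(0, 0.25)) for k, v in pre.items()}
            hits += paired_change(pre, post).p_value < 0.01
        assert hits >= 0.90 * n_rep

    def test_unmatched_ids_rejected(self):
        with pytest.raises(ValueError):
            paired_change({"a": 1.0}, {"b": 1.0})


class TestScoreVsScore:
    def test_perfect_correlation(self):
        serum = {f"s{i}": float(i) for i in range(5)}
        expr = {f"s{i}": 2.0 * i + 1 for i in range(5)}
        fit = score_vs_score_regression(serum, expr)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(33)
        ids = [f"s{i}" for i in range(27)]
        x = rng.normal(4.5, 0.4, 27)
        y = 0.5 * x + rng.normal(0, 0.3, 27)
        fit = score_vs_score_regression(dict(zip(ids, x)), dict(zip(ids, y)))
        X = np.column_stack([np.ones(27), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_null_p_uniform(self):
        # under independence the slope p-value is uniform (KS check)
        from scipy.stats import kstest

        rng = np.random.default_rng(34)
        ids = [f"s{i}" for i in range(27)]
        ps = []
        for _ in range(300):
            x = dict(zip(ids, rng.normal(0, 1, 27)))
            y = dict(zip(ids, rng.normal(0, 1, 27)))
            ps.append(score_vs_score_regression(x, y).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            score_vs_score_regression({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})

    def test_latent_interferon_activity_links_scores(self, cohort):
        # planted latent activity couples serum and expression scores
        from stillkit.biomarker_scores import ifn_score_serum
        from stillkit.expression_analysis import ifn_scores_expression

        expr_samples = [s for s in cohort.expression.columns if s.startswith("AOSD2")]
        serum = {
            s: ifn_score_serum(cohort.biomarkers[s].chemokines)
            for s in expr_samples if s in cohort.biomarkers
        }
        escore = ifn_scores_expression(
            cohort.expression, cohort.truth.ifn_genes, list(serum)
        )
        fit = score_vs_score_regression(serum, escore.to_dict())
        assert fit.slope > 0


class TestStratifyByVariantCount:
    def test_all_zero_counts_single_bin_no_test(self):
        burden = {f"s{i}": 0 for i in range(10)}
        marker = {f"s{i}": float(i) for i in range(10)}
        res = stratify_by_variant_count(burden, marker)
        assert res.omnibus_p is None
        assert res.bins[0].n == 10
        assert all(b.n == 0 for b in res.bins[1:])

    def test_counts_three_and_seven_share_top_bin(self):
        burden = {"a": 3, "b": 7, "c": 0}
        marker = {"a": 1.0, "b": 2.0, "c": 3.0}
        res = stratify_by_variant_count(burden, marker)
        top = {b.label: b for b in res.bins}["3+"]
        assert top.n == 2

    def test_planted_monotone_trend_detected(self):
        rng = np.random.default_rng(36)
        hits = 0
        for _ in range(20):
            burden, marker = {}, {}
            for i in range(120):
                c = int(rng.integers(0, 5))
                burden[f"s{i}"] = c
                marker[f"s{i}"] = float(rng.lognormal(math.log(50) + 0.6 * min(c, 3), 0.5))
            res = stratify_by_variant_count(burden, marker)
            hits += res.omnibus_p < 0.05
        assert hits >= 18

    def test_pairwise_tests_cover_nonempty_bins(self):
        burden = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 2}
        marker = dict.fromkeys("abcde", 1.0)
        res = stratify_by_variant_count(burden, marker)
        assert set(res.pairwise) == {("0", "1"), ("0", "2"), ("1", "2")}
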
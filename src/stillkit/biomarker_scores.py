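"""Serological scores, severity bands and nonparametric group statistics.

The serological type I IFN score combines five interferon-responsive
chemokines (CXCL10, CCL2, CCL8, CCL19, CXCL11) into a single number;
the default formula is the arithmetic mean of log10(pg/mL + 1), which
is strictly monotone in each analyte and lands in the 4-5 range for
concentrations in the 10^3-10^5 pg/mL span.  Group comparisons use
two-sided Mann-Whitney rank tests (exact enumeration at small combined
sample size, tie-corrected normal approximation otherwise), paired
pre/post treatment contrasts use the Wilcoxon signed-rank test, and
variant-burden stratification uses a Kruskal-Wallis omnibus across the
{0, 1, 2, 3+} carrier bins.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import kruskal, norm, rankdata, wilcoxon

from .cohort_io import IFN_CHEMOKINES
from .expression_analysis import RegressionResult, ols_fit

#: Combined sample size at or below which the rank test enumerates exactly.
EXACT_RANK_TEST_N = 12


# ---------------------------------------------------------------------------
# Scores and bands
# ---------------------------------------------------------------------------

def ifn_score_serum(
    chemokines: Mapping[str, float],
    analytes: Sequence[str] = IFN_CHEMOKINES,
) -> float:
    """Serological type I IFN score: mean of log10(concentration + 1).

    All five chemokine concentrations (pg/mL) must be present and
    non-negative; a missing analyte is an error naming it.
    """
    missing = [a for a in analytes if a not in chemokines or chemokines[a] is None]
    if missing:
        raise ValueError(f"missing chemokine(s) for IFN score: {missing}")
    vals = [chemokines[a] for a in analytes]
    if any(v < 0 for v in vals):
        raise ValueError("chemokine concentrations must be >= 0")
    return float(np.mean([math.log10(v + 1.0) for v in vals]))


SAS_BANDS = {"mild": (0, 2), "moderate": (3, 4), "severe": (5, 7)}


def sas_band(sas: int) -> str:
    """Band a Still Activity Score: mild 0-2, moderate 3-4, severe 5-7."""
    if not isinstance(sas, (int, np.integer)) or isinstance(sas, bool):
        raise ValueError(f"SAS must be an integer, got {sas!r}")
    for band, (lo, hi) in SAS_BANDS.items():
        if lo <= sas <= hi:
            return band
    raise ValueError(f"SAS {sas} outside 0..7")


def star_label(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a, with 0.5 credit for ties."""
    ranks = rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    return r_a - a.size * (a.size + 1) / 2.0


def rank_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact when the combined sample size is <= 12: the null distribution
    of U is enumerated over all group assignments of the pooled values
    (midranks make this correct under ties), and the p-value is the
    probability of a U at least as far from its null mean n_a*n_b/2 as
    observed.  Larger samples use the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= EXACT_RANK_TEST_N:
        pooled = np.concatenate([a, b])
        dev = abs(u - mu)
        total = 0
        hits = 0
        idx = range(n1 + n2)
        for combo in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= dev - 1e-12:
                hits += 1
        return hits / total
    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0  # all observations identical
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


@dataclass(frozen=True)
class GroupComparison:
    """Pairwise group contrast for one analyte."""

    group_a: str
    group_b: str
    analyte: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    p_value: float
    stars: str


def median_iqr(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Median and interquartile range, quartiles by linear interpolation."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    analyte: str,
    pairs: Sequence[tuple[str, str]],
) -> list[GroupComparison]:
    """Median/IQR summaries and rank-test p for each requested group pair."""
    out = []
    for ga, gb in pairs:
        va = np.asarray(values_by_group[ga], dtype=float)
        vb = np.asarray(values_by_group[gb], dtype=float)
        med_a, iqr_a = median_iqr(va)
        med_b, iqr_b = median_iqr(vb)
        p = rank_test(va, vb)
        out.append(
            GroupComparison(
                group_a=ga, group_b=gb, analyte=analyte,
                n_a=va.size, n_b=vb.size,
                median_a=med_a, median_b=med_b,
                iqr_a=iqr_a, iqr_b=iqr_b,
                p_value=p, stars=star_label(p),
            )
        )
    return out


@dataclass(frozen=True)
class PairedChange:
    """Pre/post treatment contrast with a Wilcoxon signed-rank p."""

    n: int
    median_change: float
    direction: str  # {decrease, increase, none}
    p_value: float


def paired_change(
    pre: Mapping[str, float], post: Mapping[str, float]
) -> PairedChange:
    """Median change and signed-rank p for matched pre/post measurements.

    Sample ids must match exactly between timepoints.  The test is
    exact for n <= 12 without zero differences, otherwise the normal
    approximation is used; if every difference is zero, p = 1.
    """
    if set(pre) != set(post):
        raise ValueError("pre/post sample ids do not match")
    ids = sorted(pre)
    if not ids:
        raise ValueError("no paired samples")
    diffs = np.array([post[s] - pre[s] for s in ids], dtype=float)
    median_change = float(np.median(diffs))
    if np.all(diffs == 0):
        return PairedChange(len(ids), 0.0, "none", 1.0)
    nonzero = diffs[diffs != 0]
    method = "exact" if (
        nonzero.size <= EXACT_RANK_TEST_N
        and np.unique(np.abs(nonzero)).size == nonzero.size
    ) else "approx"
    p = float(wilcoxon(diffs, zero_method="wilcox", method=method).pvalue)
    direction = "decrease" if median_change < 0 else ("increase" if median_change > 0 else "none")
    return PairedChange(len(ids), median_change, direction, p)


def score_vs_score_regression(
    serum_scores: Mapping[str, float],
    expression_scores: Mapping[str, float],
) -> RegressionResult:
    """OLS of the expression IFN score on the serum IFN score, paired by sample."""
    common = sorted(set(serum_scores) & set(expression_scores))
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired scores, got {len(common)}")
    x = [serum_scores[s] for s in common]
    y = [expression_scores[s] for s in common]
    return ols_fit(x, y)


# ---------------------------------------------------------------------------
# Variant-burden stratification
# ---------------------------------------------------------------------------

BURDEN_BINS = ("0", "1", "2", "3+")


@dataclass
class StratifiedBin:
    label: str
    n: int
    median: float | None
    iqr: tuple[float, float] | None


@dataclass
class StratifiedResult:
    bins: list[StratifiedBin]
    omnibus_p: float | None  # Kruskal-Wallis across non-empty bins
    pairwise: dict[tuple[str, str], float]


def stratify_by_variant_count(
    burden: Mapping[str, int],
    biomarker: Mapping[str, float],
) -> StratifiedResult:
    """Summarise a biomarker across samples binned by variant count.

    Bins are carrier counts {0, 1, 2, 3+}.  Empty bins are reported
    with n = 0 and excluded from the tests; the omnibus Kruskal-Wallis
    and pairwise rank tests run over the non-empty bins (omnibus is
    ``None`` with fewer than two non-empty bins).
    """
    common = sorted(set(burden) & set(biomarker))
    groups: dict[str, list[float]] = {b: [] for b in BURDEN_BINS}
    for sid in common:
        c = burden[sid]
        if c < 0:
            raise ValueError(f"negative variant count for {sid}")
        label = str(c) if c < 3 else "3+"
        groups[label].append(float(biomarker[sid]))
    bins = []
    for label in BURDEN_BINS:
        vals = groups[label]
        if vals:
            med, iqr = median_iqr(vals)
            bins.append(StratifiedBin(label, len(vals), med, iqr))
        else:
            bins.append(StratifiedBin(label, 0, None, None))
    nonempty = [b.label for b in bins if b.n > 0]
    omnibus = None
    if len(nonempty) >= 2:
        samples = [groups[l] for l in nonempty]
        if len({v for vals in samples for v in vals}) > 1:
            omnibus = float(kruskal(*samples).pvalue)
        else:
            omnibus = 1.0  # all observations identical
    pairwise = {}
    for la, lb in itertools.combinations(nonempty, 2):
        pairwise[(la, lb)] = rank_test(groups[la], groups[lb])
    return StratifiedResult(bins=bins, omnibus_p=omnibus, pairwise=pairwise)
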
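"""Population-enrichment testing and cohort burden summaries.

Each cohort-unique variant is tested for carrier excess against a
population reference (by default gnomAD v4.0.0 European non-Finnish,
590,031 individuals) with a one-sided Fisher exact test on the 2x2
carrier table, Bonferroni-corrected across the joint family of
case-unique plus control-unique variants (alpha / m).

Burden summaries cover per-sample variant counts, carrier proportions
(exact integer ratios with half-up percentages), panel-normalised
variants-per-gene frequencies, the multi-variant histogram
{0, 1, 2, 3+}, joint germline+somatic carriers, and age-bracketed
prevalence of somatic variants in clonal-hematopoiesis genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .cohort_io import PopulationRef, RunConfig, SampleMeta, VariantKey
from .variant_pipeline import (
    ORIGIN_GERMLINE,
    ORIGIN_SOMATIC,
    ClassifiedVariant,
)

DEFAULT_REF_N = 590_031


# ---------------------------------------------------------------------------
# Exact test and multiplicity
# ---------------------------------------------------------------------------

def fisher_enrichment(k: int, n: int, K: int, N: int) -> float:
    """One-sided (greater-in-cohort) Fisher exact p for a carrier 2x2 table.

    The table is ``[[k, n-k], [K, N-K]]``: ``k`` of ``n`` cohort members
    carry the variant versus ``K`` of ``N`` reference individuals.  The
    p-value is the upper hypergeometric tail P(X >= k) with margins
    fixed, i.e. the probability of drawing at least ``k`` carriers when
    ``n`` individuals are sampled from the pooled ``n + N`` with
    ``k + K`` total carriers.
    """
    if not (0 <= k <= n) or not (0 <= K <= N) or n < 1 or N < 1:
        raise ValueError(f"invalid 2x2 counts k={k} n={n} K={K} N={N}")
    return float(hypergeom.sf(k - 1, n + N, k + K, n))


def fisher_enrichment_many(
    k: np.ndarray, n: int, K: np.ndarray, N: int
) -> np.ndarray:
    """Vectorised :func:`fisher_enrichment` over aligned carrier arrays."""
    k = np.asarray(k, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    if (k < 0).any() or (k > n).any() or (K < 0).any() or (K > N).any():
        raise ValueError("invalid 2x2 counts in array input")
    return hypergeom.sf(k - 1, n + N, k + K, n)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m for a family of m tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return alpha / m


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-variant enrichment test outcome."""

    key: VariantKey
    cohort: str  # which cohort's n the test used, e.g. "case"/"control"
    k: int
    n: int
    K: int
    N: int
    p_value: float
    threshold: float
    m: int

    @property
    def significant(self) -> bool:
        return self.p_value < self.threshold


def run_enrichment(
    case_unique: Mapping[VariantKey, int],
    control_unique: Mapping[VariantKey, int],
    pop_ref: Mapping[VariantKey, PopulationRef],
    n_case: int,
    n_control: int,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every cohort-unique variant against the population reference.

    ``case_unique`` / ``control_unique`` map each unique variant to its
    carrier count within the respective cohort.  The Bonferroni family
    is the joint set, m = |case_unique| + |control_unique|; each
    variant is tested with its own cohort's size.  A variant absent
    from the reference is tested with K = 0 carriers (out of the
    default reference size).
    """
    m = len(case_unique) + len(control_unique)
    if m == 0:
        return []
    threshold = bonferroni_threshold(alpha, m)
    results: list[EnrichmentResult] = []
    for cohort, table, n in (
        ("case", case_unique, n_case),
        ("control", control_unique, n_control),
    ):
        for key in sorted(table):
            ref = pop_ref.get(key)
            K = ref.carriers if ref is not None else 0
            N = ref.n_individuals if ref is not None else DEFAULT_REF_N
            k = table[key]
            p = fisher_enrichment(k, n, K, N)
            results.append(EnrichmentResult(key, cohort, k, n, K, N, p, threshold, m))
    return results


# ---------------------------------------------------------------------------
# Proportions and burden summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Proportion:
    """An exact integer ratio with its half-up percentage (1 d.p.)."""

    numerator: int
    denominator: int
    percent: float

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator} ({self.percent}%)"


def carrier_proportion(numerator: int, denominator: int) -> Proportion:
    """Exact ratio with the percentage rounded half-up to 1 decimal place."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= numerator <= denominator:
        raise ValueError(f"numerator {numerator} outside [0, {denominator}]")
    pct = Decimal(numerator * 100) / Decimal(denominator)
    return Proportion(
        numerator,
        denominator,
        float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)),
    )


def variants_per_gene(
    variant_count_by_panel: Mapping[str, int],
    panel_sizes: Mapping[str, int],
) -> dict[str, float]:
    """Panel-normalised variant frequency: variants per gene, 2 d.p. half-up."""
    out = {}
    for panel, count in variant_count_by_panel.items():
        if panel not in panel_sizes:
            raise ValueError(f"unknown panel {panel!r}")
        size = panel_sizes[panel]
        if size < 1:
            raise ValueError(f"panel {panel!r} has size {size} < 1")
        freq = Decimal(count) / Decimal(size)
        out[panel] = float(freq.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return out


@dataclass(frozen=True)
class MultiVariantHistogram:
    """Per-sample variant-count histogram binned {0, 1, 2, 3+}."""

    bins: Mapping[str, int]  # keys "0", "1", "2", "3+"
    n: int
    prop_zero: Proportion
    prop_multi: Proportion  # >= 2 variants


def multi_variant_histogram(per_sample_counts: Sequence[int]) -> MultiVariantHistogram:
    """Bin per-sample variant counts into {0, 1, 2, 3+} with proportions."""
    counts = list(per_sample_counts)
    if any(c < 0 for c in counts):
        raise ValueError("variant counts must be >= 0")
    bins = {"0": 0, "1": 0, "2": 0, "3+": 0}
    for c in counts:
        bins[str(c) if c < 3 else "3+"] += 1
    n = len(counts)
    return MultiVariantHistogram(
        bins=bins,
        n=n,
        prop_zero=carrier_proportion(bins["0"], max(n, 1)),
        prop_multi=carrier_proportion(bins["2"] + bins["3+"], max(n, 1)),
    )


def per_sample_variant_counts(
    classified: Iterable[ClassifiedVariant],
    sample_ids: Iterable[str],
    origins: tuple[str, ...] | None = None,
    panels: tuple[str, ...] | None = None,
) -> dict[str, int]:
    """Count classified variants carried by each sample.

    ``origins`` / ``panels`` restrict which variants count; ``None``
    means no restriction.  Samples carrying nothing get count 0.
    """
    counts = {sid: 0 for sid in sample_ids}
    for cv in classified:
        if origins is not None and cv.origin not in origins:
            continue
        if panels is not None and cv.annotation.panel not in panels:
            continue
        for sid in cv.carrier_ids:
            if sid in counts:
                counts[sid] += 1
    return counts


def joint_origin_carriers(
    classified: Iterable[ClassifiedVariant],
    sample_ids: Iterable[str],
) -> tuple[list[str], Proportion]:
    """Samples carrying >= 1 putative germline AND >= 1 putative somatic variant."""
    sample_ids = list(sample_ids)
    classified = list(classified)
    germline = per_sample_variant_counts(classified, sample_ids, origins=(ORIGIN_GERMLINE,))
    somatic = per_sample_variant_counts(classified, sample_ids, origins=(ORIGIN_SOMATIC,))
    joint = sorted(s for s in sample_ids if germline[s] > 0 and somatic[s] > 0)
    return joint, carrier_proportion(len(joint), len(sample_ids))


# ---------------------------------------------------------------------------
# Age brackets
# ---------------------------------------------------------------------------

UNBRACKETED = "unbracketed"


def _bracket_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def age_bracket_partition(
    meta: Mapping[str, SampleMeta],
    brackets: Sequence[tuple[int, int]] = ((19, 29), (30, 49), (50, 80)),
) -> dict[str, str]:
    """Assign each sample to a closed age bracket (outside -> "unbracketed")."""
    brackets = [tuple(b) for b in brackets]
    for (lo, hi) in brackets:
        if lo > hi:
            raise ValueError(f"bracket [{lo},{hi}] inverted")
    for (_, hi), (lo2, _) in zip(brackets, brackets[1:]):
        if lo2 <= hi:
            raise ValueError("brackets overlap or are unordered")
    out = {}
    for sid, m in meta.items():
        label = UNBRACKETED
        for lo, hi in brackets:
            if lo <= m.age <= hi:
                label = _bracket_label(lo, hi)
                break
        out[sid] = label
    return out


def chip_prevalence_by_bracket(
    classified: Iterable[ClassifiedVariant],
    meta: Mapping[str, SampleMeta],
    brackets: Sequence[tuple[int, int]] = ((19, 29), (30, 49), (50, 80)),
) -> dict[str, Proportion]:
    """Per-bracket prevalence of somatic variants in clonal-hematopoiesis genes.

    Prevalence is the carrier proportion, within each age bracket, of
    samples carrying >= 1 putative somatic variant in the CHIP panel.
    """
    labels = age_bracket_partition(meta, brackets)
    counts = per_sample_variant_counts(
        classified, meta.keys(), origins=(ORIGIN_SOMATIC,), panels=("chip",)
    )
    out: dict[str, Proportion] = {}
    bracket_names = [_bracket_label(*b) for b in brackets] + [UNBRACKETED]
    for name in bracket_names:
        members = [s for s, lab in labels.items() if lab == name]
        if not members:
            continue
        carriers = sum(1 for s in members if counts[s] > 0)
        out[name] = carrier_proportion(carriers, len(members))
    return out


# ---------------------------------------------------------------------------
# Aggregate burden summary
# ---------------------------------------------------------------------------

@dataclass
class BurdenSummary:
    """Cohort burden overview assembled from classified variants."""

    per_sample_counts: dict[str, int]
    histogram: MultiVariantHistogram
    mutation_negative: Proportion
    carriers_any: Proportion
    variants_per_gene: dict[str, float]
    joint_carriers: list[str]
    joint_proportion: Proportion
    chip_by_bracket: dict[str, Proportion]


def burden_summary(
    classified: Sequence[ClassifiedVariant],
    meta: Mapping[str, SampleMeta],
    panel_sizes: Mapping[str, int],
    brackets: Sequence[tuple[int, int]] = ((19, 29), (30, 49), (50, 80)),
) -> BurdenSummary:
    """Assemble the full burden summary for one cohort's samples."""
    sample_ids = sorted(meta)
    counts = per_sample_variant_counts(classified, sample_ids)
    hist = multi_variant_histogram([counts[s] for s in sample_ids])
    n = len(sample_ids)
    negatives = sum(1 for s in sample_ids if counts[s] == 0)
    by_panel: dict[str, int] = {p: 0 for p in panel_sizes}
    for cv in classified:
        if cv.annotation.panel in by_panel:
            by_panel[cv.annotation.panel] += 1
    joint, joint_prop = joint_origin_carriers(classified, sample_ids)
    return BurdenSummary(
        per_sample_counts=counts,
        histogram=hist,
        mutation_negative=carrier_proportion(negatives, n),
        carriers_any=carrier_proportion(n - negatives, n),
        variants_per_gene=variants_per_gene(by_panel, panel_sizes),
        joint_carriers=joint,
        joint_proportion=joint_prop,
        chip_by_bracket=chip_prevalence_by_bracket(classified, meta, brackets),
    )
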
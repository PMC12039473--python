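"""Rare-variant filtering and germline/somatic origin classification.

Germline candidates are panel variants that are rare (population allele
frequency < 1%, strict; absence from the reference counts as rare),
potentially pathogenic (CADD > 20, strict) and protein-altering
(missense or nonsense).  Somatic candidates additionally require a
69x total-read-depth floor and >= 5 alternate reads, the alt-read rule
being waived for variants with prior somatic evidence in COSMIC (the
depth floor and CADD threshold are never waived).

Origin is assigned from caller concordance: a variant seen by the
somatic-style caller alone is putative somatic; seen by both callers it
is putative somatic only with COSMIC evidence, otherwise of uncertain
origin; seen by the germline-style caller alone it is putative germline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cohort_io import (
    AnnotatedVariant,
    RunConfig,
    VariantCall,
    VariantKey,
)

logger = logging.getLogger("stillkit")

ORIGIN_GERMLINE = "putative_germline"
ORIGIN_SOMATIC = "putative_somatic"
ORIGIN_UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class CarrierObservation:
    """One sample carrying a classified variant, with read support."""

    sample_id: str
    total_depth: int | None = None
    alt_depth: int | None = None

    @property
    def vaf(self) -> float | None:
        if not self.total_depth or self.alt_depth is None:
            return None
        return self.alt_depth / self.total_depth


@dataclass(frozen=True)
class ClassifiedVariant:
    """A filtered variant with an origin label and its carrier list."""

    key: VariantKey
    annotation: AnnotatedVariant
    origin: str
    carriers: tuple[CarrierObservation, ...]
    zygosity_flag: str = "het"  # {het, biallelic_flagged}

    def __post_init__(self) -> None:
        if self.origin not in (ORIGIN_GERMLINE, ORIGIN_SOMATIC, ORIGIN_UNCERTAIN):
            raise ValueError(f"unknown origin {self.origin!r}")
        if not self.carriers:
            raise ValueError("carriers must be non-empty")

    @property
    def carrier_ids(self) -> tuple[str, ...]:
        return tuple(c.sample_id for c in self.carriers)


def _passes_annotation(
    ann: AnnotatedVariant, panel: set[str], cfg: RunConfig
) -> bool:
    """Shared rare/pathogenic/panel predicate for both filters.

    Both thresholds are strict: pop_af < 1% and CADD > 20 exclude the
    boundary, and a missing pop_af is treated as rare (absence from the
    reference cannot make a variant common).
    """
    if ann.gene not in panel:
        return False
    if ann.consequence not in ("missense", "nonsense"):
        return False
    if ann.pop_af is not None and ann.pop_af >= cfg.pop_af_max:
        return False
    if ann.cadd is None or ann.cadd <= cfg.cadd_min:
        return False
    return True


def filter_germline(
    calls: Iterable[VariantCall],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    panel: set[str],
    cfg: RunConfig | None = None,
) -> list[VariantCall]:
    """Apply the germline rare-variant filter to germline-caller calls.

    Returns the retained calls.  Heterozygous calls pass as-is;
    homozygous-alt calls are retained but flagged downstream (the study
    design anticipates none).  Calls lacking an annotation record are
    excluded and logged.
    """
    cfg = cfg or RunConfig()
    kept: list[VariantCall] = []
    for call in calls:
        ann = annotations.get(call.key)
        if ann is None:
            logger.warning("no annotation for %s; excluded", call.key)
            continue
        if _passes_annotation(ann, panel, cfg):
            kept.append(call)
    return kept


def filter_somatic(
    calls: Iterable[VariantCall],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    panel: set[str],
    cfg: RunConfig | None = None,
) -> list[VariantCall]:
    """Apply the somatic filter to somatic-caller calls.

    Requires total depth >= 69, CADD > 20 and >= 5 alternate reads; the
    alt-read requirement is waived when the variant has prior somatic
    evidence in COSMIC.  Calls with missing depth are excluded and
    logged.  Panel membership and the rare/protein-altering predicates
    apply as in :func:`filter_germline`.
    """
    cfg = cfg or RunConfig()
    kept: list[VariantCall] = []
    for call in calls:
        ann = annotations.get(call.key)
        if ann is None:
            logger.warning("no annotation for %s; excluded", call.key)
            continue
        if not _passes_annotation(ann, panel, cfg):
            continue
        if call.total_depth is None or call.alt_depth is None:
            logger.warning("missing depth for %s in %s; excluded", call.key, call.sample_id)
            continue
        if call.total_depth < cfg.somatic_depth_min:
            continue
        if call.alt_depth < cfg.somatic_alt_min and not ann.cosmic_somatic:
            continue
        kept.append(call)
    return kept


def classify_origin(
    in_somatic_caller: bool,
    in_germline_caller: bool,
    cosmic_evidence: bool,
) -> str:
    """Assign a variant origin from caller concordance and COSMIC evidence.

    ============== =============== ======= ====================
    somatic caller germline caller COSMIC  origin
    ============== =============== ======= ====================
    yes            no              any     putative_somatic
    yes            yes             yes     putative_somatic
    yes            yes             no      uncertain
    no             yes             any     putative_germline
    ============== =============== ======= ====================

    A variant seen by neither caller is unobservable and raises
    ``ValueError``.
    """
    if not in_somatic_caller and not in_germline_caller:
        raise ValueError("variant observed by no caller")
    if in_somatic_caller and not in_germline_caller:
        return ORIGIN_SOMATIC
    if in_somatic_caller and in_germline_caller:
        return ORIGIN_SOMATIC if cosmic_evidence else ORIGIN_UNCERTAIN
    return ORIGIN_GERMLINE


def prioritize_variants(
    germline_calls: Iterable[VariantCall],
    somatic_calls: Iterable[VariantCall],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    panel: set[str],
    cfg: RunConfig | None = None,
) -> list[ClassifiedVariant]:
    """Filter both call sets and classify every surviving variant.

    Caller concordance for classification uses the raw (pre-filter)
    call sets: a filtered somatic candidate also reported by the
    germline caller at the same site is "seen by both".  Carriers are
    aggregated per variant; read support comes from the caller that
    determined the origin (the somatic caller for somatic/uncertain
    variants, the germline caller otherwise).  Output is sorted by
    variant key for determinism.
    """
    cfg = cfg or RunConfig()
    germline_calls = list(germline_calls)
    somatic_calls = list(somatic_calls)
    seen_germline = {c.key for c in germline_calls}
    seen_somatic = {c.key for c in somatic_calls}

    g_kept = filter_germline(germline_calls, annotations, panel, cfg)
    s_kept = filter_somatic(somatic_calls, annotations, panel, cfg)

    candidates: dict[VariantKey, dict[str, VariantCall]] = {}
    for call in s_kept + g_kept:  # somatic read support wins on overlap
        candidates.setdefault(call.key, {}).setdefault(call.sample_id, call)

    out: list[ClassifiedVariant] = []
    for key in sorted(candidates):
        ann = annotations[key]
        origin = classify_origin(
            in_somatic_caller=key in seen_somatic,
            in_germline_caller=key in seen_germline,
            cosmic_evidence=ann.cosmic_somatic,
        )
        per_sample = candidates[key]
        carriers = tuple(
            CarrierObservation(sid, per_sample[sid].total_depth, per_sample[sid].alt_depth)
            for sid in sorted(per_sample)
        )
        flag = (
            "biallelic_flagged"
            if any(c.genotype == "hom_alt" for c in per_sample.values())
            else "het"
        )
        out.append(ClassifiedVariant(key, ann, origin, carriers, flag))
    return out


_PRIORITIZED_COLS = [
    "chrom", "pos", "ref", "alt", "gene", "panel", "consequence",
    "pop_af", "cadd", "cosmic", "origin", "zygosity", "carriers",
]


def write_prioritized(path, classified: Sequence[ClassifiedVariant]) -> None:
    """Write classified variants as a TSV, one row per variant.

    Carriers are serialised ``sample:alt/total`` separated by ``;`` so
    per-sample VAFs survive the round trip.
    """
    import pandas as pd

    rows = []
    for cv in sorted(classified, key=lambda c: c.key):
        carriers = ";".join(
            f"{c.sample_id}:{'' if c.alt_depth is None else c.alt_depth}"
            f"/{'' if c.total_depth is None else c.total_depth}"
            for c in cv.carriers
        )
        a = cv.annotation
        rows.append({
            "chrom": cv.key.chrom, "pos": cv.key.pos, "ref": cv.key.ref,
            "alt": cv.key.alt, "gene": a.gene, "panel": a.panel,
            "consequence": a.consequence, "pop_af": a.pop_af, "cadd": a.cadd,
            "cosmic": a.cosmic_somatic, "origin": cv.origin,
            "zygosity": cv.zygosity_flag, "carriers": carriers,
        })
    pd.DataFrame(rows, columns=_PRIORITIZED_COLS).to_csv(path, sep="\t", index=False)


def read_prioritized(path) -> list[ClassifiedVariant]:
    """Read back a prioritized-variant TSV written by :func:`write_prioritized`."""
    import pandas as pd

    from .cohort_io import AnnotatedVariant

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        key = VariantKey(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        ann = AnnotatedVariant(
            key=key, gene=str(row["gene"]), panel=str(row["panel"]),
            consequence=str(row["consequence"]),
            pop_af=None if pd.isna(row["pop_af"]) else float(row["pop_af"]),
            cadd=None if pd.isna(row["cadd"]) else float(row["cadd"]),
            cosmic_somatic=bool(row["cosmic"]),
        )
        carriers = []
        for item in str(row["carriers"]).split(";"):
            sid, _, depths = item.partition(":")
            alt_s, _, tot_s = depths.partition("/")
            carriers.append(CarrierObservation(
                sid,
                total_depth=int(tot_s) if tot_s else None,
                alt_depth=int(alt_s) if alt_s else None,
            ))
        out.append(ClassifiedVariant(
            key, ann, str(row["origin"]), tuple(carriers), str(row["zygosity"])
        ))
    return out


def unique_to_cohort(
    case_variants: set[VariantKey], control_variants: set[VariantKey]
) -> tuple[set[VariantKey], set[VariantKey], set[VariantKey]]:
    """Partition two cohorts' variant sets into unique and shared parts.

    Returns ``(case_unique, control_unique, shared)``.  The partition
    satisfies |case_unique| + |shared| = |case_variants| and
    symmetrically for controls.
    """
    shared = case_variants & control_variants
    return case_variants - shared, control_variants - shared, shared
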
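"""Domain types, file formats and run configuration.

This module defines the shared record types used across the pipeline
(variant keys and calls, annotations, sample metadata, biomarker panels,
population reference counts) and the readers/writers for the external
formats the pipeline touches: VCF for call sets, TSV for panels,
annotations and the population reference, CSV for clinical and biomarker
tables, YAML for run configuration.

Coordinates are 1-based fully-closed VCF convention on GRCh38 contigs
named ``chr1``..``chrX``.  Multi-allelic VCF records are decomposed into
biallelic keys before anything downstream sees them; AD depth fields are
attributed per alternate allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("stillkit")

_ALLELE_CHARS = set("ACGT")

#: The three mutually exclusive primary gene subpanels.
PRIMARY_PANELS = ("chip", "autoinflammation", "interferonopathy")
#: All recognised panel labels (transcriptome-derived panel may overlap none).
ALL_PANELS = PRIMARY_PANELS + ("transcriptome170", "none")

GERMLINE_CALLER = "germline_caller"
SOMATIC_CALLER = "somatic_caller"

COHORTS = ("AOSD1", "AOSD2", "AOSD3", "HC", "sJIA", "SchS", "CAPS", "FMF")

#: Serum chemokines combined into the serological type I IFN score.
IFN_CHEMOKINES = ("CXCL10", "CCL2", "CCL8", "CCL19", "CXCL11")

#: Default multiplex cytokine targets (13-plex).
CYTOKINES = (
    "IL-1b", "IL-6", "IL-10", "IL-12p70", "IL-18", "IL-23",
    "IFN-a2", "IFN-g", "TNF-a", "IL-8", "IL-17A", "IL-33", "MCP-1",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic variant identified by GRCh38 coordinates and alleles.

    Ordering is lexicographic on (chrom, pos, ref, alt), which makes
    sorted outputs deterministic across runs.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _ALLELE_CHARS:
                raise ValueError(f"allele {allele!r} is not over {{A,C,G,T}}")

    def __str__(self) -> str:  # chr1:123:A>G
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantCall:
    """One variant observation in one sample from one caller."""

    key: VariantKey
    sample_id: str
    caller: str  # GERMLINE_CALLER or SOMATIC_CALLER
    genotype: str = "na"  # {het, hom_alt, na}
    total_depth: int | None = None
    alt_depth: int | None = None

    def __post_init__(self) -> None:
        if self.caller not in (GERMLINE_CALLER, SOMATIC_CALLER):
            raise ValueError(f"unknown caller tag {self.caller!r}")
        if self.genotype not in ("het", "hom_alt", "na"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if (
            self.total_depth is not None
            and self.alt_depth is not None
            and self.alt_depth > self.total_depth
        ):
            raise ValueError(
                f"alt_depth {self.alt_depth} > total_depth {self.total_depth}"
            )

    @property
    def vaf(self) -> float | None:
        """Variant allele fraction: alt reads over total reads."""
        if not self.total_depth or self.alt_depth is None:
            return None
        return self.alt_depth / self.total_depth


@dataclass(frozen=True)
class AnnotatedVariant:
    """Variant-level annotations: panel, consequence, popAF, CADD, registries.

    ``pop_af`` is the European non-Finnish allele frequency; ``None`` means
    the variant is absent from the reference, which is distinct from 0.
    """

    key: VariantKey
    gene: str
    panel: str  # one of ALL_PANELS
    consequence: str  # {missense, nonsense, other}
    pop_af: float | None = None
    cadd: float | None = None
    cosmic_somatic: bool = False
    clinvar_label: str = ""
    infevers_label: str = ""

    def __post_init__(self) -> None:
        if self.panel not in ALL_PANELS:
            raise ValueError(f"unknown panel {self.panel!r}")
        if self.consequence not in ("missense", "nonsense", "other"):
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.pop_af is not None and not 0.0 <= self.pop_af <= 1.0:
            raise ValueError(f"pop_af {self.pop_af} outside [0,1]")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"cadd {self.cadd} < 0")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical metadata."""

    sample_id: str
    cohort: str
    age: float
    sex: str  # {M, F}
    sas: int | None = None  # Still Activity Score, integer 0-7
    crp: float | None = None  # mg/L
    treatment_arm: str = "na"  # {canakinumab, placebo, na}
    timepoint: str = "na"  # {pre, post, na}

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.sas is not None and not 0 <= self.sas <= 7:
            raise ValueError(f"SAS {self.sas} outside 0..7")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class BiomarkerPanel:
    """Per-sample serum measurements: specks (events/uL) and analytes (pg/mL)."""

    sample_id: str
    asc_nlrp3_specks: float | None = None
    asc_only_specks: float | None = None
    cytokines: Mapping[str, float] = field(default_factory=dict)
    chemokines: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, conc in list(self.cytokines.items()) + list(self.chemokines.items()):
            if conc is not None and conc < 0:
                raise ValueError(f"negative concentration for {name}: {conc}")
        for v in (self.asc_nlrp3_specks, self.asc_only_specks):
            if v is not None and v < 0:
                raise ValueError("specks events/uL must be >= 0")


@dataclass(frozen=True)
class PopulationRef:
    """Carrier count for one variant in the population reference.

    The default reference is gnomAD v4.0.0 European non-Finnish
    (590,031 individuals), consumed purely as a count table.
    """

    key: VariantKey
    carriers: int
    n_individuals: int = 590_031

    def __post_init__(self) -> None:
        if not 0 <= self.carriers <= self.n_individuals:
            raise ValueError(
                f"carriers {self.carriers} outside [0, {self.n_individuals}]"
            )


@dataclass
class RunConfig:
    """Every numeric threshold used by the pipeline, plus paths and seed.

    Defaults are the study thresholds: rare means population AF < 1%,
    potentially pathogenic means CADD > 20 (both strict), the somatic
    depth floor is 69x total reads with >= 5 alt reads (COSMIC-confirmed
    variants are exempt from the alt-read rule only), DE genes require
    |log2FC| > 1 and adjusted p < 0.001, and enrichment uses
    Bonferroni-corrected alpha = 0.05.
    """

    pop_af_max: float = 0.01
    cadd_min: float = 20.0
    somatic_depth_min: int = 69
    somatic_alt_min: int = 5
    de_log2fc: float = 1.0
    de_padj: float = 0.001
    alpha: float = 0.05
    age_brackets: tuple[tuple[int, int], ...] = ((19, 29), (30, 49), (50, 80))
    enrichment_count_mode: str = "carriers"  # or "alleles"
    shared_gene_mode: str = "union"  # {union, at_least_2, intersection}
    n_clusters: int = 7
    ifn_pseudocount: float = 1.0
    rng_seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pop_af_max", "cadd_min", "somatic_depth_min",
                     "somatic_alt_min", "de_log2fc", "de_padj", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        brackets = [tuple(b) for b in self.age_brackets]
        for (lo, hi) in brackets:
            if lo > hi:
                raise ValueError(f"bracket [{lo},{hi}] is inverted")
        for (_, hi), (lo2, _) in zip(brackets, brackets[1:]):
            if lo2 <= hi:
                raise ValueError("age brackets must be non-overlapping and ordered")
        self.age_brackets = tuple(brackets)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "age_brackets" in raw:
            raw["age_brackets"] = tuple(tuple(b) for b in raw["age_brackets"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["age_brackets"] = [list(b) for b in self.age_brackets]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def read_variant_calls(path: str | Path, caller: str) -> list[VariantCall]:
    """Read a VCF call set into per-sample :class:`VariantCall` records.

    Multi-allelic records are split into biallelic keys; the AD field is
    attributed per alternate allele (AD[0] is the reference depth,
    AD[i] the i-th alternate).  Samples with a missing or hom-ref
    genotype at a site contribute no call for that site.  Missing depth
    fields leave depths as ``None`` (the call is retained).

    Raises ``ValueError`` naming the offending record for malformed
    rows, and ``FileNotFoundError`` if the path does not exist.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[VariantCall] = []
    for rec in vcf:
        try:
            gts = rec.genotypes  # [[a0, a1, phased], ...]
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            try:
                dp = rec.format("DP")
            except KeyError:
                dp = None
            for alt_index, alt in enumerate(rec.ALT, start=1):
                key = VariantKey(rec.CHROM, rec.POS, rec.REF, alt)
                for si, sample in enumerate(samples):
                    alleles = [a for a in gts[si][:-1] if a >= 0]
                    n_alt = sum(1 for a in alleles if a == alt_index)
                    if n_alt == 0:
                        continue
                    genotype = "hom_alt" if n_alt == len(alleles) and len(alleles) > 1 else "het"
                    alt_depth = total_depth = None
                    if ad is not None and ad[si][0] >= 0:
                        row = [int(x) for x in ad[si] if x >= 0]
                        if alt_index < len(row):
                            alt_depth = row[alt_index]
                    if dp is not None and int(dp[si][0]) >= 0:
                        total_depth = int(dp[si][0])
                    elif ad is not None and ad[si][0] >= 0:
                        total_depth = int(sum(x for x in ad[si] if x >= 0))
                    if (alt_depth is None) != (total_depth is None):
                        # keep whichever is present; VariantCall allows partial
                        pass
                    calls.append(
                        VariantCall(
                            key=key,
                            sample_id=sample,
                            caller=caller,
                            genotype=genotype,
                            total_depth=total_depth,
                            alt_depth=alt_depth,
                        )
                    )
        except ValueError as exc:
            raise ValueError(
                f"malformed record at {rec.CHROM}:{rec.POS} in {path}: {exc}"
            ) from exc
    return calls


def vcf_samples(path: str | Path) -> list[str]:
    """Sample ids present in a VCF's header, in column order."""
    from cyvcf2 import VCF

    return list(VCF(str(path)).samples)


def write_vcf(
    path: str | Path,
    calls: Sequence[VariantCall],
    samples: Sequence[str],
) -> None:
    """Write calls as a minimal uncompressed VCFv4.2 with GT:DP:AD."""
    by_key: dict[VariantKey, dict[str, VariantCall]] = {}
    for c in calls:
        by_key.setdefault(c.key, {})[c.sample_id] = c
    contigs = sorted({k.chrom for k in by_key})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stillkit\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for key in sorted(by_key):
            cols = [key.chrom, str(key.pos), ".", key.ref, key.alt, ".", "PASS", ".", "GT:DP:AD"]
            for s in samples:
                call = by_key[key].get(s)
                if call is None:
                    cols.append("0/0:.:.")
                    continue
                gt = "1/1" if call.genotype == "hom_alt" else "0/1"
                dp = "." if call.total_depth is None else str(call.total_depth)
                if call.alt_depth is None or call.total_depth is None:
                    ad = "."
                else:
                    ad = f"{call.total_depth - call.alt_depth},{call.alt_depth}"
                cols.append(f"{gt}:{dp}:{ad}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _key_from_row(row) -> VariantKey:
    return VariantKey(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))


def read_panels(path: str | Path) -> dict[str, set[str]]:
    """Read a TSV of (gene, subpanel) into panel -> gene-set.

    The three primary subpanels must be mutually exclusive; a gene listed
    in two of them is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "subpanel"} <= set(df.columns):
        raise ValueError(f"panel file {path} must have columns gene, subpanel")
    panels: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        panel = row["subpanel"]
        if panel not in ALL_PANELS:
            raise ValueError(f"unknown subpanel {panel!r} in {path}")
        panels.setdefault(panel, set()).add(row["gene"])
    seen: dict[str, str] = {}
    for panel in PRIMARY_PANELS:
        for gene in panels.get(panel, ()):  # mutual exclusivity check
            if gene in seen:
                raise ValueError(
                    f"gene {gene} appears in both {seen[gene]} and {panel}; "
                    "primary subpanels must be mutually exclusive"
                )
            seen[gene] = panel
    return panels


def write_panels(path: str | Path, panels: Mapping[str, Iterable[str]]) -> None:
    rows = [
        {"gene": g, "subpanel": p}
        for p in sorted(panels)
        for g in sorted(panels[p])
    ]
    pd.DataFrame(rows, columns=["gene", "subpanel"]).to_csv(path, sep="\t", index=False)


_ANNOT_COLS = [
    "chrom", "pos", "ref", "alt", "gene", "panel", "consequence",
    "pop_af", "cadd", "cosmic", "clinvar", "infevers",
]


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotatedVariant]:
    """Read the variant annotation TSV keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} missing columns {sorted(missing)}")
    out: dict[VariantKey, AnnotatedVariant] = {}
    for _, row in df.iterrows():
        key = _key_from_row(row)
        out[key] = AnnotatedVariant(
            key=key,
            gene=str(row["gene"]),
            panel=str(row["panel"]),
            consequence=str(row["consequence"]),
            pop_af=None if pd.isna(row["pop_af"]) else float(row["pop_af"]),
            cadd=None if pd.isna(row["cadd"]) else float(row["cadd"]),
            cosmic_somatic=bool(row["cosmic"]),
            clinvar_label="" if pd.isna(row["clinvar"]) else str(row["clinvar"]),
            infevers_label="" if pd.isna(row["infevers"]) else str(row["infevers"]),
        )
    return out


def write_annotations(path: str | Path, ann: Mapping[VariantKey, AnnotatedVariant]) -> None:
    rows = []
    for key in sorted(ann):
        a = ann[key]
        rows.append({
            "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
            "gene": a.gene, "panel": a.panel, "consequence": a.consequence,
            "pop_af": a.pop_af, "cadd": a.cadd, "cosmic": a.cosmic_somatic,
            "clinvar": a.clinvar_label, "infevers": a.infevers_label,
        })
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, sep="\t", index=False)


def read_population_ref(path: str | Path) -> dict[VariantKey, PopulationRef]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    need = {"chrom", "pos", "ref", "alt", "carriers", "n_individuals"}
    if not need <= set(df.columns):
        raise ValueError(f"population reference {path} missing {sorted(need - set(df.columns))}")
    out = {}
    for _, row in df.iterrows():
        key = _key_from_row(row)
        out[key] = PopulationRef(key, int(row["carriers"]), int(row["n_individuals"]))
    return out


def write_population_ref(path: str | Path, ref: Mapping[VariantKey, PopulationRef]) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt,
         "carriers": ref[k].carriers, "n_individuals": ref[k].n_individuals}
        for k in sorted(ref)
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "carriers", "n_individuals"]).to_csv(
        path, sep="\t", index=False
    )


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for _, row in df.iterrows():
        out[str(row["sample_id"])] = SampleMeta(
            sample_id=str(row["sample_id"]),
            cohort=str(row["cohort"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            sas=None if pd.isna(row.get("sas")) else int(row["sas"]),
            crp=None if pd.isna(row.get("crp")) else float(row["crp"]),
            treatment_arm=str(row.get("treatment_arm", "na")),
            timepoint=str(row.get("timepoint", "na")),
        )
    return out


def write_sample_meta(path: str | Path, meta: Mapping[str, SampleMeta]) -> None:
    rows = []
    for sid in sorted(meta):
        m = meta[sid]
        rows.append({
            "sample_id": m.sample_id, "cohort": m.cohort, "age": m.age,
            "sex": m.sex, "sas": m.sas, "crp": m.crp,
            "treatment_arm": m.treatment_arm, "timepoint": m.timepoint,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_biomarkers(path: str | Path) -> dict[str, BiomarkerPanel]:
    """Read the wide biomarker CSV (one row per sample, one column per analyte)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        return {}
    out = {}
    cyt_cols = [c for c in df.columns if c.startswith("cyt_")]
    chem_cols = [c for c in df.columns if c.startswith("chem_")]
    for _, row in df.iterrows():
        out[str(row["sample_id"])] = BiomarkerPanel(
            sample_id=str(row["sample_id"]),
            asc_nlrp3_specks=None if pd.isna(row.get("asc_nlrp3_specks")) else float(row["asc_nlrp3_specks"]),
            asc_only_specks=None if pd.isna(row.get("asc_only_specks")) else float(row["asc_only_specks"]),
            cytokines={c[4:]: float(row[c]) for c in cyt_cols if not pd.isna(row[c])},
            chemokines={c[5:]: float(row[c]) for c in chem_cols if not pd.isna(row[c])},
        )
    return out


def write_biomarkers(path: str | Path, panels: Mapping[str, BiomarkerPanel]) -> None:
    cyt_names = sorted({a for p in panels.values() for a in p.cytokines})
    chem_names = sorted({a for p in panels.values() for a in p.chemokines})
    rows = []
    for sid in sorted(panels):
        p = panels[sid]
        row = {
            "sample_id": p.sample_id,
            "asc_nlrp3_specks": p.asc_nlrp3_specks,
            "asc_only_specks": p.asc_only_specks,
        }
        for a in cyt_names:
            row[f"cyt_{a}"] = p.cytokines.get(a)
        for a in chem_names:
            row[f"chem_{a}"] = p.chemokines.get(a)
        rows.append(row)
    cols = ["sample_id", "asc_nlrp3_specks", "asc_only_specks"]
    cols += [f"cyt_{a}" for a in cyt_names] + [f"chem_{a}" for a in chem_names]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix (TSV, gene as first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene rows: {dupes}")
    return df


def write_expression_matrix(path: str | Path, expr: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    need = {"gene", "log2fc", "padj"}
    if not need <= set(df.columns):
        raise ValueError(f"DE table {path} missing {sorted(need - set(df.columns))}")
    return df


def write_de_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tables(paths: Mapping[str, str | Path]) -> dict:
    """Read every annotation-side input named in ``paths``.

    Recognised keys: ``annotations``, ``sample_meta``, ``biomarkers``,
    ``population_ref``, ``panels``, ``expression``, ``de_table``.
    Returns a dict with the same keys mapped to typed tables.
    """
    readers = {
        "annotations": read_annotations,
        "sample_meta": read_sample_meta,
        "biomarkers": read_biomarkers,
        "population_ref": read_population_ref,
        "panels": read_panels,
        "expression": read_expression_matrix,
        "de_table": read_de_table,
    }
    out = {}
    for name, path in paths.items():
        if name not in readers:
            raise ValueError(f"unknown table kind {name!r}")
        out[name] = readers[name](path)
    return out


def male_x_flags(
    calls: Iterable[VariantCall], meta: Mapping[str, SampleMeta]
) -> set[tuple[VariantKey, str]]:
    """Flag (variant, sample) pairs on chrX in biological males.

    VAF on male X is reported as-is; no ploidy correction is applied,
    the flag only marks calls where a high VAF is expected for a
    hemizygous variant.
    """
    flags = set()
    for c in calls:
        if c.key.chrom in ("chrX", "X"):
            m = meta.get(c.sample_id)
            if m is not None and m.sex == "M":
                flags.add((c.key, c.sample_id))
    return flags
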
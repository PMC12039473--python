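"""Synthetic study generator with planted ground truth.

Emulates the complete data footprint of a case/control exome +
transcriptome + serum-biomarker study of adult-onset Still disease:
call sets from a germline-style and a somatic-style caller, variant
annotations (population allele frequency, CADD, COSMIC, registry
labels), mutually exclusive virtual gene panels, a population carrier
reference, clinical metadata, serum biomarker panels, an expression
matrix and a differential-expression table.  Every planted signal is
recorded in a :class:`SimTruth` object so downstream stages have a
recoverable answer.

The generative model, chosen to mirror what the analysis assumes
rather than the sequencing process itself:

- read support is binomial at the true allele fraction, with total
  depth drawn from a clamped negative binomial around a 142x mean;
- germline variants are heterozygous (true VAF 0.5); somatic clones
  have low fractional VAF drawn uniformly;
- population reference carrier counts are binomial draws over 590,031
  individuals; designated enriched variants are planted in a fixed
  number of case samples while their reference carrier probability is
  divided by the configured odds factor;
- biomarker concentrations are log-normal per group, location
  calibrated so medians match the configured group medians;
- expression has a monotone cluster gradient on the signature genes
  and a latent interferon activity shared between serum chemokines and
  interferon-response gene expression.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import (
    CYTOKINES,
    GERMLINE_CALLER,
    IFN_CHEMOKINES,
    SOMATIC_CALLER,
    AnnotatedVariant,
    BiomarkerPanel,
    PopulationRef,
    SampleMeta,
    VariantCall,
    VariantKey,
    write_annotations,
    write_biomarkers,
    write_de_table,
    write_expression_matrix,
    write_panels,
    write_population_ref,
    write_sample_meta,
    write_vcf,
)

_BASES = "ACGT"


def _sigma_from_iqr(q1: float, q3: float) -> float:
    """Log-normal sigma implied by an observed [q1, q3] interquartile range."""
    return math.log(q3 / q1) / (2 * 0.6744897501960817)


@dataclass(frozen=True)
class AnalyteModel:
    """Log-normal group model for one analyte: medians and log-scale spread."""

    case_median: float
    control_median: float
    case_sigma: float = 1.0
    control_sigma: float = 0.8


#: Default biomarker models.  Specks and IL-18 locations/spreads are
#: calibrated to the observed cohort medians and IQRs (ASC/NLRP3 specks
#: 236.5 [56.2-1693.0] vs 48.1 [22.9-79.1] events/uL; IL-18
#: 9013 [886-18209] pg/mL); the rest use plausible pg/mL spans with
#: modest case shifts.
DEFAULT_ANALYTES: dict[str, AnalyteModel] = {
    "asc_nlrp3_specks": AnalyteModel(236.5, 48.1,
                                     _sigma_from_iqr(56.2, 1693.0),
                                     _sigma_from_iqr(22.9, 79.1)),
    "asc_only_specks": AnalyteModel(310.0, 62.0, 2.2, 0.9),
    "IL-1b": AnalyteModel(12.0, 10.0, 1.0, 1.0),
    "IL-6": AnalyteModel(85.0, 8.0, 1.4, 0.9),
    "IL-10": AnalyteModel(9.0, 4.0, 1.1, 0.8),
    "IL-12p70": AnalyteModel(6.0, 2.5, 1.0, 0.8),
    "IL-18": AnalyteModel(9013.0, 320.0, _sigma_from_iqr(886.0, 18209.0), 1.0),
    "IL-23": AnalyteModel(45.0, 9.0, 1.2, 0.9),
    "IFN-a2": AnalyteModel(14.0, 4.0, 1.2, 0.8),
    "IFN-g": AnalyteModel(60.0, 12.0, 1.3, 0.9),
    "TNF-a": AnalyteModel(25.0, 18.0, 0.9, 0.8),
    "IL-8": AnalyteModel(55.0, 40.0, 1.0, 0.9),
    "IL-17A": AnalyteModel(8.0, 6.0, 0.9, 0.8),
    "IL-33": AnalyteModel(15.0, 12.0, 0.9, 0.8),
    "MCP-1": AnalyteModel(220.0, 180.0, 0.8, 0.7),
    # chemokines: case medians chosen so mean log10(x+1) serum scores land
    # in the observed 4-5 band for cases vs ~4.2 for controls
    "CXCL10": AnalyteModel(45000.0, 14000.0, 0.8, 0.6),
    "CCL2": AnalyteModel(38000.0, 16000.0, 0.8, 0.6),
    "CCL8": AnalyteModel(36000.0, 15000.0, 0.8, 0.6),
    "CCL19": AnalyteModel(40000.0, 17000.0, 0.8, 0.6),
    "CXCL11": AnalyteModel(42000.0, 13000.0, 0.8, 0.6),
}


@dataclass
class SimConfig:
    """Tunable parameters of the synthetic study.

    Defaults mirror the study conditions: 60 exome cases vs 49
    controls, a 106-case biomarker cohort vs 30 controls, mean
    sequencing depth 142x, three mutually exclusive panels totalling
    139 genes plus a 170-gene transcriptome-derived panel, and
    age-graded somatic planting rates that rise toward the oldest
    bracket.
    """

    # cohort sizes
    n_cases: int = 60            # exome cases (split AOSD2/AOSD3)
    n_controls: int = 49         # exome controls (HC)
    n_biomarker_extra_cases: int = 46   # AOSD1, biomarkers only (106 total)
    n_biomarker_controls: int = 30
    n_expression_cases: int = 27        # AOSD2 subset with RNA
    n_expression_controls: int = 10
    n_treatment_per_arm: int = 15       # canakinumab / placebo trial subset

    # panels
    panel_sizes: dict = field(default_factory=lambda: {
        "chip": 60, "autoinflammation": 50, "interferonopathy": 29,
        "transcriptome170": 170,
    })

    # germline planting
    germline_mean_case: float = 1.55    # pass-filter variants per case
    germline_mean_control: float = 1.16
    noise_mean: float = 2.0             # fail-filter variants per sample
    n_shared_variants: int = 4          # appear in both cohorts
    panel_weights: tuple[float, float, float] = (0.45, 0.35, 0.20)

    # enrichment planting
    n_enriched: int = 10
    enriched_case_carriers: int = 4
    enriched_odds_factor: float = 50.0
    baseline_carrier_q: tuple[float, float] = (1e-4, 2e-3)  # log-uniform span

    # somatic planting
    somatic_rate_case: tuple[float, float, float] = (0.20, 0.30, 0.50)
    somatic_rate_control: tuple[float, float, float] = (0.02, 0.05, 0.30)
    age_brackets: tuple[tuple[int, int], ...] = ((19, 29), (30, 49), (50, 80))
    somatic_vaf_range: tuple[float, float] = (0.08, 0.30)
    somatic_chip_fraction: float = 0.9
    somatic_cosmic_prob: float = 0.2
    n_uncertain: int = 3       # both callers, no COSMIC evidence
    n_both_cosmic: int = 2     # both callers, COSMIC -> putative somatic

    # sequencing depth
    depth_mean: float = 142.0
    depth_dispersion: float = 30.0
    depth_floor: int = 60
    depth_ceiling: int = 400

    # population reference
    ref_n_individuals: int = 590_031

    # biomarkers
    analytes: dict = field(default_factory=lambda: dict(DEFAULT_ANALYTES))
    ifn_latent_beta: float = 0.5      # serum chemokine loading on latent IFN
    ifn_latent_gamma: float = 0.6     # expression loading on latent IFN
    treatment_reduction: float = 0.4  # post = pre * reduction (canakinumab)

    # expression
    n_background_genes: int = 120
    n_ifn_genes: int = 28
    n_clusters: int = 7
    cluster_effect: float = 2.0
    expression_noise: float = 0.5
    de_fraction_up: float = 162 / 170

    rng_seed: int = 0


@dataclass
class SimTruth:
    """Planted ground truth of one simulated study."""

    origin: dict[str, str]             # str(VariantKey) -> germline/somatic/uncertain
    somatic_vaf: dict[str, float]      # str(key) -> true clone VAF
    enriched: set[str]                 # str(key) of planted enriched variants
    group: dict[str, str]              # sample -> case/control
    joint_carriers: set[str]           # samples with >=1 germline and >=1 somatic
    somatic_carriers_by_bracket: dict[str, list[str]]
    biomarker_shift: dict[str, float]  # analyte -> log-median case-control shift
    de_genes: set[str]
    signature_genes: list[str]         # the planted shared-pathway gene set
    ifn_genes: list[str]
    clusters: dict[str, int]           # expression sample -> planted cluster
    treatment_pairs: dict[str, list[str]]  # arm -> sample ids (pre ids)

    def to_json(self) -> dict:
        return {
            "origin": self.origin,
            "somatic_vaf": self.somatic_vaf,
            "enriched": sorted(self.enriched),
            "group": self.group,
            "joint_carriers": sorted(self.joint_carriers),
            "somatic_carriers_by_bracket": self.somatic_carriers_by_bracket,
            "biomarker_shift": self.biomarker_shift,
            "de_genes": sorted(self.de_genes),
            "signature_genes": self.signature_genes,
            "ifn_genes": self.ifn_genes,
            "clusters": self.clusters,
            "treatment_pairs": self.treatment_pairs,
        }


@dataclass
class SimCohort:
    """All generated tables plus the planted truth."""

    exome_samples: list[str]  # every sequenced sample, carriers or not
    germline_calls: list[VariantCall]
    somatic_calls: list[VariantCall]
    annotations: dict[VariantKey, AnnotatedVariant]
    panels: dict[str, set[str]]
    pop_ref: dict[VariantKey, PopulationRef]
    meta: dict[str, SampleMeta]
    biomarkers: dict[str, BiomarkerPanel]
    expression: pd.DataFrame
    de_table: pd.DataFrame
    pathway_sets: list[set[str]]
    truth: SimTruth

    @property
    def case_ids(self) -> list[str]:
        return sorted(s for s, g in self.truth.group.items() if g == "case")

    @property
    def control_ids(self) -> list[str]:
        return sorted(s for s, g in self.truth.group.items() if g == "control")

    def write(self, outdir: str | Path) -> None:
        """Emit every table in the formats the readers consume, plus truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(outdir / "germline.vcf", self.germline_calls, self.exome_samples)
        write_vcf(outdir / "somatic.vcf", self.somatic_calls, self.exome_samples)
        write_annotations(outdir / "annotations.tsv", self.annotations)
        write_panels(outdir / "panels.tsv", self.panels)
        write_population_ref(outdir / "population_ref.tsv", self.pop_ref)
        write_sample_meta(outdir / "sample_meta.csv", self.meta)
        write_biomarkers(outdir / "biomarkers.csv", self.biomarkers)
        write_expression_matrix(outdir / "expression.tsv", self.expression)
        write_de_table(outdir / "de_table.tsv", self.de_table)
        with open(outdir / "ifn_genes.txt", "w") as fh:
            fh.write("\n".join(self.truth.ifn_genes) + "\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth.to_json(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Generator internals
# ---------------------------------------------------------------------------

class _VariantFactory:
    """Hands out fresh unique SNV keys, one locus pool per gene."""

    def __init__(self, genes_by_panel: Mapping[str, list[str]], rng: np.random.Generator):
        self.rng = rng
        self.gene_locus: dict[str, tuple[str, int]] = {}
        self.counter: dict[str, int] = {}
        all_genes = [g for gs in genes_by_panel.values() for g in gs]
        for i, gene in enumerate(all_genes):
            chrom = "chrX" if gene.endswith("X") else f"chr{(i % 22) + 1}"
            self.gene_locus[gene] = (chrom, 1_000_000 * (i + 1))
            self.counter[gene] = 0

    def new_key(self, gene: str) -> VariantKey:
        chrom, base = self.gene_locus[gene]
        self.counter[gene] += 1
        pos = base + self.counter[gene]
        ref, alt = self.rng.choice(list(_BASES), size=2, replace=False)
        return VariantKey(chrom, int(pos), str(ref), str(alt))


def _draw_depth(cfg: SimConfig, rng: np.random.Generator, size: int | None = None):
    r = cfg.depth_dispersion
    p = r / (r + cfg.depth_mean)
    d = rng.negative_binomial(r, p, size=size)
    return np.clip(d, cfg.depth_floor, cfg.depth_ceiling)


def _lognormal(rng, median: float, sigma: float, size=None):
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=size)


def simulate_cohort(cfg: SimConfig | None = None) -> SimCohort:
    """Generate the full synthetic study with planted ground truth.

    Deterministic given ``cfg.rng_seed``: the same configuration always
    produces byte-identical outputs.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)

    # --- gene panels -------------------------------------------------------
    genes_by_panel: dict[str, list[str]] = {}
    prefixes = {"chip": "CHG", "autoinflammation": "AIG",
                "interferonopathy": "IFG", "transcriptome170": "TRG"}
    for panel, size in cfg.panel_sizes.items():
        names = [f"{prefixes[panel]}{i:03d}" for i in range(1, size + 1)]
        if panel == "interferonopathy" and names:
            names[-1] += "X"  # one X-linked interferonopathy gene
        genes_by_panel[panel] = names
    panels = {p: set(gs) for p, gs in genes_by_panel.items()}
    primary_genes = {p: genes_by_panel[p] for p in ("chip", "autoinflammation", "interferonopathy")}
    factory = _VariantFactory(genes_by_panel, rng)

    # --- samples -----------------------------------------------------------
    case_ids = [f"AOSD2_S{i:02d}" for i in range(1, cfg.n_cases // 2 + 1)]
    case_ids += [f"AOSD3_S{i:02d}" for i in range(1, cfg.n_cases - cfg.n_cases // 2 + 1)]
    control_ids = [f"HC_S{i:02d}" for i in range(1, cfg.n_controls + 1)]

    meta: dict[str, SampleMeta] = {}
    group: dict[str, str] = {}
    for sid in case_ids:
        cohort = "AOSD2" if sid.startswith("AOSD2") else "AOSD3"
        meta[sid] = SampleMeta(
            sample_id=sid, cohort=cohort,
            age=float(rng.integers(19, 81)),
            sex=str(rng.choice(["M", "F"])),
            sas=int(np.clip(rng.integers(0, 8), 0, 7)),
            crp=float(np.round(_lognormal(rng, 35.0, 0.9), 1)),
        )
        group[sid] = "case"
    for sid in control_ids:
        meta[sid] = SampleMeta(
            sample_id=sid, cohort="HC",
            age=float(rng.integers(19, 81)),
            sex=str(rng.choice(["M", "F"])),
            sas=0,
            crp=float(np.round(_lognormal(rng, 2.0, 0.7), 1)),
        )
        group[sid] = "control"

    # --- germline variants -------------------------------------------------
    annotations: dict[VariantKey, AnnotatedVariant] = {}
    pop_ref: dict[VariantKey, PopulationRef] = {}
    germline_calls: list[VariantCall] = []
    somatic_calls: list[VariantCall] = []
    origin: dict[str, str] = {}
    somatic_vaf: dict[str, float] = {}
    germline_carriers: dict[str, set[str]] = {}  # sample -> variant strs

    panel_names = ("chip", "autoinflammation", "interferonopathy")
    weights = np.asarray(cfg.panel_weights) / np.sum(cfg.panel_weights)
    q_lo, q_hi = cfg.baseline_carrier_q

    def _baseline_q() -> float:
        return float(np.exp(rng.uniform(math.log(q_lo), math.log(q_hi))))

    def _annotate_pass(key: VariantKey, gene: str, panel: str,
                       cosmic: bool = False) -> None:
        pop_af = None if rng.random() < 0.3 else float(rng.uniform(0.0, 0.009))
        consequence = "nonsense" if rng.random() < 0.05 else "missense"
        annotations[key] = AnnotatedVariant(
            key=key, gene=gene, panel=panel, consequence=consequence,
            pop_af=pop_af, cadd=float(rng.uniform(20.5, 40.0)),
            cosmic_somatic=cosmic,
        )

    def _annotate_fail(key: VariantKey, gene: str, panel: str) -> None:
        # exactly one predicate fails: too common, low CADD, or non-coding
        mode = int(rng.integers(0, 3))
        pop_af = float(rng.uniform(0.02, 0.3)) if mode == 0 else float(rng.uniform(0.0, 0.009))
        cadd = float(rng.uniform(1.0, 19.5)) if mode == 1 else float(rng.uniform(20.5, 40.0))
        consequence = "other" if mode == 2 else "missense"
        annotations[key] = AnnotatedVariant(
            key=key, gene=gene, panel=panel, consequence=consequence,
            pop_af=pop_af, cadd=cadd, cosmic_somatic=False,
        )

    def _emit_germline(key: VariantKey, sid: str) -> None:
        depth = int(_draw_depth(cfg, rng))
        alt = int(rng.binomial(depth, 0.5))
        germline_calls.append(VariantCall(
            key=key, sample_id=sid, caller=GERMLINE_CALLER, genotype="het",
            total_depth=depth, alt_depth=min(alt, depth),
        ))
        germline_carriers.setdefault(sid, set()).add(str(key))

    def _random_primary_gene() -> tuple[str, str]:
        panel = str(rng.choice(panel_names, p=weights))
        gene = str(rng.choice(primary_genes[panel]))
        return gene, panel

    # enriched variants: fixed carrier count in cases, depressed reference q
    enriched: set[str] = set()
    for _ in range(cfg.n_enriched):
        gene, panel = _random_primary_gene()
        key = factory.new_key(gene)
        _annotate_pass(key, gene, panel)
        carriers = rng.choice(case_ids, size=cfg.enriched_case_carriers, replace=False)
        for sid in carriers:
            _emit_germline(key, sid)
        case_freq = cfg.enriched_case_carriers / cfg.n_cases
        q_ref = case_freq / cfg.enriched_odds_factor
        pop_ref[key] = PopulationRef(
            key, int(rng.binomial(cfg.ref_n_individuals, q_ref)), cfg.ref_n_individuals
        )
        enriched.add(str(key))
        origin[str(key)] = "germline"

    # background germline variants, unique per sample
    for sid in case_ids + control_ids:
        mean = cfg.germline_mean_case if group[sid] == "case" else cfg.germline_mean_control
        for _ in range(int(rng.poisson(mean))):
            gene, panel = _random_primary_gene()
            key = factory.new_key(gene)
            _annotate_pass(key, gene, panel)
            pop_ref[key] = PopulationRef(
                key, int(rng.binomial(cfg.ref_n_individuals, _baseline_q())),
                cfg.ref_n_individuals,
            )
            _emit_germline(key, sid)
            origin[str(key)] = "germline"
        # filter-failing noise variants
        for _ in range(int(rng.poisson(cfg.noise_mean))):
            gene, panel = _random_primary_gene()
            key = factory.new_key(gene)
            _annotate_fail(key, gene, panel)
            pop_ref[key] = PopulationRef(
                key, int(rng.binomial(cfg.ref_n_individuals, _baseline_q())),
                cfg.ref_n_individuals,
            )
            depth = int(_draw_depth(cfg, rng))
            alt = int(rng.binomial(depth, 0.5))
            germline_calls.append(VariantCall(
                key=key, sample_id=sid, caller=GERMLINE_CALLER, genotype="het",
                total_depth=depth, alt_depth=min(alt, depth),
            ))

    # shared variants: one case and one control carrier each
    for _ in range(cfg.n_shared_variants):
        gene, panel = _random_primary_gene()
        key = factory.new_key(gene)
        _annotate_pass(key, gene, panel)
        pop_ref[key] = PopulationRef(
            key, int(rng.binomial(cfg.ref_n_individuals, _baseline_q())),
            cfg.ref_n_individuals,
        )
        _emit_germline(key, str(rng.choice(case_ids)))
        _emit_germline(key, str(rng.choice(control_ids)))
        origin[str(key)] = "germline"

    # --- somatic variants --------------------------------------------------
    somatic_carriers: dict[str, set[str]] = {}
    somatic_by_bracket: dict[str, list[str]] = {
        f"{lo}-{hi}": [] for lo, hi in cfg.age_brackets
    }

    def _bracket_index(age: float) -> int | None:
        for i, (lo, hi) in enumerate(cfg.age_brackets):
            if lo <= age <= hi:
                return i
        return None

    def _emit_somatic(sid: str, vaf: float, cosmic: bool) -> VariantKey:
        if rng.random() < cfg.somatic_chip_fraction:
            gene, panel = str(rng.choice(primary_genes["chip"])), "chip"
        else:
            gene, panel = _random_primary_gene()
        key = factory.new_key(gene)
        _annotate_pass(key, gene, panel, cosmic=cosmic)
        pop_ref[key] = PopulationRef(key, 0, cfg.ref_n_individuals)
        depth = int(_draw_depth(cfg, rng))
        alt = int(rng.binomial(depth, vaf))
        somatic_calls.append(VariantCall(
            key=key, sample_id=sid, caller=SOMATIC_CALLER, genotype="na",
            total_depth=depth, alt_depth=min(alt, depth),
        ))
        somatic_vaf[str(key)] = vaf
        somatic_carriers.setdefault(sid, set()).add(str(key))
        return key

    for sid in case_ids + control_ids:
        idx = _bracket_index(meta[sid].age)
        if idx is None:
            continue
        rate = (cfg.somatic_rate_case if group[sid] == "case"
                else cfg.somatic_rate_control)[idx]
        if rng.random() < rate:
            vaf = float(rng.uniform(*cfg.somatic_vaf_range))
            key = _emit_somatic(sid, vaf, cosmic=rng.random() < cfg.somatic_cosmic_prob)
            origin[str(key)] = "somatic"
            lo, hi = cfg.age_brackets[idx]
            somatic_by_bracket[f"{lo}-{hi}"].append(sid)

    # variants seen by both callers: COSMIC-backed ones are truly somatic,
    # the rest are of uncertain origin
    for n, cosmic, label in ((cfg.n_both_cosmic, True, "somatic"),
                             (cfg.n_uncertain, False, "uncertain")):
        for _ in range(n):
            sid = str(rng.choice(case_ids))
            vaf = float(rng.uniform(0.3, 0.5))
            key = _emit_somatic(sid, vaf, cosmic=cosmic)
            origin[str(key)] = label
            # the germline caller reports the same site in the same sample
            depth = int(_draw_depth(cfg, rng))
            alt = int(rng.binomial(depth, vaf))
            germline_calls.append(VariantCall(
                key=key, sample_id=sid, caller=GERMLINE_CALLER, genotype="het",
                total_depth=depth, alt_depth=min(alt, depth),
            ))
            if label == "uncertain":
                somatic_carriers[sid].discard(str(key))

    joint = {
        sid for sid in case_ids + control_ids
        if germline_carriers.get(sid) and somatic_carriers.get(sid)
    }

    # --- biomarker cohort ---------------------------------------------------
    bm_case_ids = list(case_ids)
    bm_case_ids += [f"AOSD1_S{i:02d}" for i in range(1, cfg.n_biomarker_extra_cases + 1)]
    bm_control_ids = [f"HCB_S{i:02d}" for i in range(1, cfg.n_biomarker_controls + 1)]
    for sid in bm_case_ids:
        if sid not in meta:
            meta[sid] = SampleMeta(
                sample_id=sid, cohort="AOSD1",
                age=float(rng.integers(19, 81)), sex=str(rng.choice(["M", "F"])),
                sas=int(np.clip(rng.integers(0, 8), 0, 7)),
                crp=float(np.round(_lognormal(rng, 35.0, 0.9), 1)),
            )
            group[sid] = "case"
    for sid in bm_control_ids:
        meta[sid] = SampleMeta(
            sample_id=sid, cohort="HC",
            age=float(rng.integers(19, 81)), sex=str(rng.choice(["M", "F"])),
            sas=0, crp=float(np.round(_lognormal(rng, 2.0, 0.7), 1)),
        )
        group[sid] = "control"

    # latent interferon activity shared by serum chemokines and expression
    ifn_latent = {sid: float(rng.normal(0.0, 1.0)) for sid in bm_case_ids + bm_control_ids}

    biomarkers: dict[str, BiomarkerPanel] = {}

    def _draw_panel(sid: str, is_case: bool) -> BiomarkerPanel:
        cyt: dict[str, float] = {}
        chem: dict[str, float] = {}
        nlrp3: float | None = None
        asc_only: float | None = None
        u = ifn_latent[sid]
        for analyte, model in cfg.analytes.items():
            median = model.case_median if is_case else model.control_median
            sigma = model.case_sigma if is_case else model.control_sigma
            mu = math.log(median)
            if analyte in IFN_CHEMOKINES:
                mu += cfg.ifn_latent_beta * u
            val = float(np.round(rng.lognormal(mu, sigma), 2))
            if analyte == "asc_nlrp3_specks":
                nlrp3 = val
            elif analyte == "asc_only_specks":
                asc_only = val
            elif analyte in IFN_CHEMOKINES:
                chem[analyte] = val
            else:
                cyt[analyte] = val
        return BiomarkerPanel(
            sample_id=sid, asc_nlrp3_specks=nlrp3, asc_only_specks=asc_only,
            cytokines=cyt, chemokines=chem,
        )

    for sid in bm_case_ids:
        biomarkers[sid] = _draw_panel(sid, is_case=True)
    for sid in bm_control_ids:
        biomarkers[sid] = _draw_panel(sid, is_case=False)

    # --- treatment trial (AOSD3 subset, pre/post specks) --------------------
    aosd3 = [s for s in case_ids if s.startswith("AOSD3")]
    trial = list(rng.choice(aosd3, size=min(len(aosd3), 2 * cfg.n_treatment_per_arm),
                            replace=False))
    arms = {"canakinumab": trial[: cfg.n_treatment_per_arm],
            "placebo": trial[cfg.n_treatment_per_arm:]}
    for arm, members in arms.items():
        for sid in members:
            meta[sid] = SampleMeta(
                sample_id=sid, cohort=meta[sid].cohort, age=meta[sid].age,
                sex=meta[sid].sex, sas=meta[sid].sas, crp=meta[sid].crp,
                treatment_arm=arm, timepoint="pre",
            )
            pre = biomarkers[sid].asc_nlrp3_specks
            mult = cfg.treatment_reduction if arm == "canakinumab" else 1.0
            post_val = float(np.round(pre * mult * float(rng.lognormal(0.0, 0.25)), 2))
            post_id = f"{sid}_post"
            meta[post_id] = SampleMeta(
                sample_id=post_id, cohort=meta[sid].cohort, age=meta[sid].age,
                sex=meta[sid].sex, sas=meta[sid].sas, crp=meta[sid].crp,
                treatment_arm=arm, timepoint="post",
            )
            group[post_id] = "case"
            biomarkers[post_id] = BiomarkerPanel(
                sample_id=post_id, asc_nlrp3_specks=post_val,
                asc_only_specks=biomarkers[sid].asc_only_specks,
                cytokines=dict(biomarkers[sid].cytokines),
                chemokines=dict(biomarkers[sid].chemokines),
            )

    # --- expression matrix and DE table -------------------------------------
    signature = list(genes_by_panel["transcriptome170"])
    ifn_genes = [f"ISG{i:03d}" for i in range(1, cfg.n_ifn_genes + 1)]
    background = [f"BKG{i:03d}" for i in range(1, cfg.n_background_genes + 1)]
    all_genes = signature + ifn_genes + background

    expr_cases = [s for s in case_ids if s.startswith("AOSD2")][: cfg.n_expression_cases]
    expr_controls = [f"HCE_S{i:02d}" for i in range(1, cfg.n_expression_controls + 1)]
    for sid in expr_controls:
        meta[sid] = SampleMeta(
            sample_id=sid, cohort="HC",
            age=float(rng.integers(19, 81)), sex=str(rng.choice(["M", "F"])),
            sas=0, crp=float(np.round(_lognormal(rng, 2.0, 0.7), 1)),
        )
        group[sid] = "control"
        ifn_latent[sid] = float(rng.normal(-0.5, 0.8))
    expr_samples = expr_cases + expr_controls

    # monotone cluster -> disease-activity gradient: lower cluster index,
    # higher signature expression and higher SAS
    n_k = cfg.n_clusters
    clusters: dict[str, int] = {}
    shuffled = list(expr_samples)
    rng.shuffle(shuffled)
    for i, sid in enumerate(shuffled):
        clusters[sid] = (i % n_k) + 1
    # controls drift to the low-activity clusters
    for sid in expr_controls:
        clusters[sid] = int(rng.integers(n_k - 1, n_k + 1))

    sign_up = np.where(rng.random(len(signature)) < cfg.de_fraction_up, 1.0, -1.0)
    base = rng.uniform(3.0, 8.0, size=len(all_genes))
    expr = np.zeros((len(all_genes), len(expr_samples)))
    sas_by_sample: dict[str, int] = {}
    for j, sid in enumerate(expr_samples):
        c = clusters[sid]
        level = (n_k - c) / (n_k - 1)  # 1 for cluster 1, 0 for cluster n_k
        profile = base.copy()
        profile[: len(signature)] += sign_up * cfg.cluster_effect * level
        ifn_block = slice(len(signature), len(signature) + len(ifn_genes))
        profile[ifn_block] += cfg.ifn_latent_gamma * ifn_latent[sid]
        profile += rng.normal(0.0, cfg.expression_noise, size=profile.shape)
        expr[:, j] = np.maximum(profile, 0.0)
        sas = int(np.clip(round(3.0 * level + rng.normal(0.0, 0.4)), 0, 7))
        sas_by_sample[sid] = sas
        m = meta[sid]
        meta[sid] = SampleMeta(
            sample_id=sid, cohort=m.cohort, age=m.age, sex=m.sex,
            sas=sas, crp=m.crp, treatment_arm=m.treatment_arm,
            timepoint=m.timepoint,
        )
    expression = pd.DataFrame(np.round(expr, 4), index=all_genes, columns=expr_samples)

    # DE table: signature genes pass the strict thresholds, background does not
    de_rows = []
    de_genes: set[str] = set()
    for i, g in enumerate(signature):
        lfc = float(sign_up[i] * rng.uniform(1.2, 4.0))
        de_rows.append({"gene": g, "log2fc": round(lfc, 3),
                        "padj": float(rng.uniform(1e-12, 5e-4))})
        de_genes.add(g)
    for g in ifn_genes:  # modest, below threshold
        de_rows.append({"gene": g, "log2fc": round(float(rng.uniform(-0.9, 0.9)), 3),
                        "padj": float(rng.uniform(0.002, 0.9))})
    for g in background:
        de_rows.append({"gene": g, "log2fc": round(float(rng.uniform(-0.8, 0.8)), 3),
                        "padj": float(rng.uniform(0.01, 1.0))})
    de_table = pd.DataFrame(de_rows, columns=["gene", "log2fc", "padj"])

    # three "top pathway" gene sets whose union covers the signature
    thirds = np.array_split(np.array(signature), 3)
    pathway_sets = []
    for i, part in enumerate(thirds):
        extra = list(rng.choice(background, size=8, replace=False))
        overlap = list(thirds[(i + 1) % 3][:5])  # sets genuinely overlap
        pathway_sets.append(set(part) | set(extra) | set(overlap))

    truth = SimTruth(
        origin=origin,
        somatic_vaf=somatic_vaf,
        enriched=enriched,
        group=group,
        joint_carriers=joint,
        somatic_carriers_by_bracket=somatic_by_bracket,
        biomarker_shift={
            a: math.log(m.case_median) - math.log(m.control_median)
            for a, m in cfg.analytes.items()
        },
        de_genes=de_genes,
        signature_genes=signature,
        ifn_genes=ifn_genes,
        clusters=clusters,
        treatment_pairs={arm: sorted(members) for arm, members in arms.items()},
    )
    return SimCohort(
        exome_samples=sorted(case_ids + control_ids),
        germline_calls=germline_calls,
        somatic_calls=somatic_calls,
        annotations=annotations,
        panels=panels,
        pop_ref=pop_ref,
        meta=meta,
        biomarkers=biomarkers,
        expression=expression,
        de_table=de_table,
        pathway_sets=pathway_sets,
        truth=truth,
    )


def sample_analyte(
    model: AnalyteModel,
    is_case: bool,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` concentrations from one group's log-normal analyte model."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    median = model.case_median if is_case else model.control_median
    sigma = model.case_sigma if is_case else model.control_sigma
    return rng.lognormal(math.log(median), sigma, size=n)


# ---------------------------------------------------------------------------
# Null model for enrichment calibration
# ---------------------------------------------------------------------------

def simulate_null_enrichment(
    m: int,
    n_case: int = 60,
    ref_n: int = 590_031,
    q_range: tuple[float, float] = (1e-5, 1e-3),
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[VariantKey, int], dict[VariantKey, PopulationRef]]:
    """Draw an m-variant family with no true enrichment.

    Every variant's case carrier count and reference carrier count are
    binomial draws from the same per-variant carrier probability, so
    any rejection by the enrichment procedure is a false positive.
    Returns ``(case_carriers, pop_ref)`` keyed by synthetic variant
    keys, ready for :func:`stillkit.enrichment_burden.run_enrichment`.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = q_range
    q = np.exp(rng.uniform(math.log(lo), math.log(hi), size=m))
    k = rng.binomial(n_case, q)
    K = rng.binomial(ref_n, q)
    case_carriers: dict[VariantKey, int] = {}
    pop_ref: dict[VariantKey, PopulationRef] = {}
    bases = ["A", "C", "G", "T"]
    for i in range(m):
        ref, alt = bases[i % 4], bases[(i + 1) % 4]
        key = VariantKey("chr1", i + 1, ref, alt)
        case_carriers[key] = int(k[i])
        pop_ref[key] = PopulationRef(key, int(K[i]), ref_n)
    return case_carriers, pop_ref
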
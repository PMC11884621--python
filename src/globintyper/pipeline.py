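"""End-to-end orchestration: genotyping and population analytics.

Stage order per sample: read assignment -> length-based SV calling (with
breakpoint refinement) -> alignment and small-variant calling -> catalog
annotation -> within-amplicon phasing -> paralog/conversion analysis.
Population stage: haplotype matrix -> haplogroups -> LD -> TFBS ->
variant/burden association -> group phenotype and survival comparisons.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Panel, MiniReference, load_panel
from .simulate import (
    AlleleCatalog,
    AlleleEvent,
    SVAlleleDef,
    SmallAlleleDef,
    SimRead,
    read_fastq,
)
from .svcalling import (
    Breakpoint,
    InsufficientSplitReadsError,
    ReadAssignment,
    SVCall,
    assign_read,
    call_svs,
    refine_breakpoint,
    _parse_cigar,
)
from .smallvar import (
    AlleleAnnotation,
    VariantCall,
    align_read,
    adjusted_reference,
    annotate_alleles,
    build_pileup,
    call_small_variants,
    diplotype_string,
    lift_observation,
    observe_read,
    FILTER_PASS,
)
from .phasing import (
    ConversionCall,
    PhasedHaplotype,
    assign_paralog,
    detect_conversion,
    phase_sample_amplicon,
    unit_diagnostics,
)
from .analytics import (
    HaplotypeMatrix,
    build_matrix,
    compute_ld,
    dedup_and_cluster,
    ld_blocks,
    scan_tfbs,
)
from .assoc import bh_fdr, burden_score, group_compare, gwas_glm, km_logrank
from .varutils import variant_key

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with documented defaults.

    None of the thresholds below are dictated by the assay itself except
    ``min_depth`` (the hard >= 20 read depth rule for PASS small variants);
    the rest are exposed so a panel can be re-tuned.
    """

    # inputs
    panel_tsv: str | None = None
    reference: str | None = None
    fastq_dir: str | None = None
    phenotypes: str | None = None
    outdir: str = "globintyper_out"
    seed: int = 0
    # read assignment
    assign_window: int = 50
    # SV calling
    length_tolerance: int = 100
    sv_min_depth: int = 10
    sv_min_support: int = 3
    min_split_reads: int = 3
    # small variants
    min_depth: int = 20
    het_window: tuple[float, float] = (0.25, 0.75)
    hom_min: float = 0.9
    min_alt_frac: float = 0.2
    min_alt_reads: int = 5
    min_identity: float = 0.7
    # phasing / conversion
    min_reads_per_cluster: int = 3
    conversion_min_run: int = 3
    # population analytics
    region: str = "HBG"
    k_groups: int | None = None
    maf_min: float = 0.01
    r2_threshold: float = 0.8
    beneficial_alleles: tuple[str, ...] = ("mod_bcl11a", "mod_myb", "hbg2_prom", "mod_klf1_rare")

    def parameter_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "het_window" in raw:
            raw["het_window"] = tuple(raw["het_window"])
        if "beneficial_alleles" in raw:
            raw["beneficial_alleles"] = tuple(raw["beneficial_alleles"])
        return cls(**raw)


@dataclass
class SampleResult:
    """Everything the genotyping stage produces for one sample."""

    sample_id: str
    n_reads: int
    n_assigned: int
    sv_calls: list[SVCall]
    small_calls: list[VariantCall]
    phased: dict[str, tuple[PhasedHaplotype, PhasedHaplotype]]
    conversions: list[ConversionCall]
    annotations: list[AlleleAnnotation]
    paralog_labels: dict[str, list[str]] = field(default_factory=dict)

    def diplotype(self, catalog_names: set[str] | None = None) -> str:
        return diplotype_string(self.annotations, catalog_names)


def _infer_duplication_event(
    read: str, amp_ref: str, contig: str, offset: int
) -> AlleleEvent | None:
    """Tandem-duplication interval from the largest insertion run of one read."""
    import edlib

    res = edlib.align(read, amp_ref, mode="NW", task="path")
    rpos = best = 0
    at = None
    for length, op in _parse_cigar(res["cigar"]):
        if op == "I" and length > best:
            best, at = length, rpos
        if op in ("=", "X", "D"):
            rpos += length
    if at is None or at - best < 0:
        return None
    return AlleleEvent("duplication", contig, offset + at - best, offset + at, name="inferred_dup")


def _events_for_call(
    call: SVCall, amp, catalog: AlleleCatalog | None, contig_seq: str, read_seqs: list[str]
) -> list[AlleleEvent] | None:
    if call.matched_catalog_allele and catalog is not None:
        try:
            allele = catalog.get(call.matched_catalog_allele)
        except KeyError:
            allele = None
        if isinstance(allele, SVAlleleDef):
            return list(allele.events)
    if call.length_shift < 0 and call.breakpoint is not None:
        bp = call.breakpoint
        return [AlleleEvent("large_deletion", amp.contig, bp.left, bp.right, name="inferred_del")]
    if call.length_shift > 0 and read_seqs:
        ev = _infer_duplication_event(
            read_seqs[0], contig_seq[amp.start : amp.end], amp.contig, amp.start
        )
        return [ev] if ev is not None else None
    return None


def genotype_sample(
    sample_id: str,
    reads: list[SimRead],
    panel: Panel,
    ref_seqs: dict[str, str],
    catalog: AlleleCatalog | None = None,
    cfg: RunConfig | None = None,
    mini: MiniReference | None = None,
) -> SampleResult:
    """Run the full genotyping stage for one sample's reads."""
    cfg = cfg or RunConfig()
    by_amp: dict[str, list[ReadAssignment]] = {}
    n_assigned = 0
    for r in reads:
        a = assign_read(r.seq, panel, window=cfg.assign_window, read_id=r.read_id)
        if a.assigned:
            by_amp.setdefault(a.amplicon_id, []).append(a)
            n_assigned += 1
    sv_calls = call_svs(
        by_amp, panel, sample_id,
        length_tolerance=cfg.length_tolerance, min_depth=cfg.sv_min_depth,
        het_window=cfg.het_window, hom_min=cfg.hom_min, min_support=cfg.sv_min_support,
    )

    small_calls: list[VariantCall] = []
    phased: dict[str, tuple[PhasedHaplotype, PhasedHaplotype]] = {}
    conversions: list[ConversionCall] = []
    paralog_labels: dict[str, list[str]] = {}
    for amp in panel.amplicons:
        rs = by_amp.get(amp.id, [])
        if len(rs) < cfg.sv_min_depth:
            continue
        contig_seq = ref_seqs[amp.contig]
        amp_ref = contig_seq[amp.start : amp.end]
        amp_calls = [c for c in sv_calls if c.amplicon_id == amp.id and c.read_ids]
        clustered_ids: set[str] = set()
        for call in amp_calls:
            clustered_ids.update(call.read_ids)
            if call.length_shift < 0 and call.genotype is not None:
                seqs = [r.seq for r in rs if r.read_id in set(call.read_ids) and r.seq]
                try:
                    call.breakpoint = refine_breakpoint(
                        seqs, amp_ref, contig_offset=amp.start, contig=amp.contig,
                        min_reads=cfg.min_split_reads,
                    )
                except InsufficientSplitReadsError as exc:
                    call.no_call_reason = str(exc)

        observations = []
        id2seq = {r.read_id: r.seq for r in rs if r.seq}
        ref_cluster = [r for r in rs if r.read_id not in clustered_ids and r.seq]
        for r in ref_cluster:
            aln = align_read(r.seq, amp_ref, read_id=r.read_id, min_identity=cfg.min_identity)
            if aln is not None:
                observations.append(observe_read(r.seq, amp_ref, aln))
        for call in amp_calls:
            if call.genotype is None:
                continue
            seqs = [id2seq[i] for i in call.read_ids if i in id2seq]
            events = _events_for_call(call, amp, catalog, contig_seq, seqs)
            if events is None:
                logger.info(
                    "%s/%s: shifted cluster (%+d bp) excluded from pileup, no event model",
                    sample_id, amp.id, call.length_shift,
                )
                continue
            try:
                adj_ref, inv = adjusted_reference(contig_seq, events, amp)
            except ValueError:
                continue
            for rid, seq in zip(call.read_ids, seqs):
                aln = align_read(seq, adj_ref, read_id=rid, min_identity=cfg.min_identity)
                if aln is not None:
                    obs = observe_read(seq, adj_ref, aln)
                    observations.append(lift_observation(obs, inv, len(amp_ref)))

        pileup = build_pileup(observations, amp_ref, contig=amp.contig, offset=amp.start)
        calls = call_small_variants(
            pileup, contig_seq=contig_seq,
            min_depth=cfg.min_depth, het_window=cfg.het_window, hom_min=cfg.hom_min,
            min_alt_frac=cfg.min_alt_frac, min_alt_reads=cfg.min_alt_reads,
            sample_id=sample_id, amplicon_id=amp.id,
        )
        for c in calls:
            if c.filter == FILTER_PASS:
                paralog_labels[c.key] = assign_paralog(c, amp, other_calls=calls)
        h1, h2, _ = phase_sample_amplicon(
            calls, observations, amp, sample_id, min_reads_per_cluster=cfg.min_reads_per_cluster
        )
        phased[amp.id] = (h1, h2)
        # decorate het PASS calls with phased genotypes
        if "unphased" not in h1.flags and "no_het_sites" not in h1.flags:
            for c in calls:
                if c.filter == FILTER_PASS and c.is_het:
                    a1, a2 = h1.allele_of(c.key), h2.allele_of(c.key)
                    if a1 is not None and a2 is not None:
                        c.phased_gt = f"{a1}|{a2}"
                        c.phase_set = amp.id
        small_calls.extend(calls)

        pair = mini.pair_for(amp.contig) if mini is not None else None
        if pair is not None and len(amp.genes) == 2:
            unit_label = {"a": amp.genes[0].id, "b": amp.genes[1].id}
            for hap in (h1, h2):
                for unit in ("a", "b"):
                    donor = unit_label["b" if unit == "a" else "a"]
                    conversions.extend(
                        detect_conversion(
                            hap, unit_diagnostics(pair, unit),
                            min_run=cfg.conversion_min_run,
                            contig=amp.contig, donor_label=donor,
                        )
                    )

    annotations = annotate_alleles(small_calls, sv_calls, catalog, sample_id) if catalog else []
    return SampleResult(
        sample_id, len(reads), n_assigned, sv_calls, small_calls,
        phased, conversions, annotations, paralog_labels,
    )


def genotype_cohort(
    reads_by_sample: dict[str, list[SimRead]],
    panel: Panel,
    ref_seqs: dict[str, str],
    catalog: AlleleCatalog | None = None,
    cfg: RunConfig | None = None,
    mini: MiniReference | None = None,
) -> dict[str, SampleResult]:
    results = {}
    for sid in sorted(reads_by_sample):
        results[sid] = genotype_sample(
            sid, reads_by_sample[sid], panel, ref_seqs, catalog, cfg, mini
        )
    logger.info("genotyped %d samples", len(results))
    return results


# ---------------------------------------------------------------------------
# Population stage
# ---------------------------------------------------------------------------

def dosage_matrix(results: dict[str, SampleResult], catalog: AlleleCatalog | None = None) -> pd.DataFrame:
    """Samples x variants dosage matrix (small-variant keys + SV allele names)."""
    rows = {}
    for sid, res in results.items():
        d: dict[str, int] = {}
        for c in res.small_calls:
            if c.filter == FILTER_PASS:
                d[c.key] = 2 if c.genotype == "1/1" else 1
        for a in res.annotations:
            if a.source == "sv":
                d[a.allele_name] = 2 if a.zygosity == "hom" else 1
        rows[sid] = d
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    return df.sort_index()


@dataclass
class PopulationResult:
    matrix: HaplotypeMatrix
    unique_haplotypes: pd.DataFrame
    haplogroups: list
    row_groups: np.ndarray
    ld: object
    blocks: list
    tfbs_hits: list
    association: pd.DataFrame
    assoc_skipped: dict
    burden: object
    group_hbf: object | None
    survival: object | None
    sample_groups: pd.Series
    excluded_no_phenotype: int


def run_population(
    results: dict[str, SampleResult],
    phenotypes: pd.DataFrame,
    panel: Panel,
    ref_seqs: dict[str, str],
    catalog: AlleleCatalog | None = None,
    cfg: RunConfig | None = None,
) -> PopulationResult:
    """Population analytics over genotyped samples with phenotypes.

    Builds the region haplotype matrix, haplogroups (Hap_s1..), LD and
    blocks, the TFBS screen over matrix loci, per-variant HbF association
    with age+sex covariates and BH-FDR, the beneficial-allele burden trend,
    Hap_s1-carrier HbF contrast and haplogroup transfusion-free survival.
    """
    cfg = cfg or RunConfig()
    pheno = phenotypes.set_index("sample_id")
    unknown = [s for s in pheno.index if s not in results]
    if unknown and len(unknown) == len(pheno):
        raise ValueError(f"phenotype table matches no genotyped sample: {unknown[:10]}")
    common = [s for s in sorted(results) if s in pheno.index]
    excluded = len(results) - len(common)
    if excluded:
        logger.info("run_population: %d samples lack phenotypes, excluded", excluded)

    region = cfg.region
    phased_pairs = {
        sid: results[sid].phased[region] for sid in common if region in results[sid].phased
    }
    matrix = build_matrix(phased_pairs, region=region)
    uniq, groups, row_groups = dedup_and_cluster(matrix, k=cfg.k_groups)
    ld = compute_ld(matrix, maf_min=cfg.maf_min)
    blocks = ld_blocks(ld.r2, r2_threshold=cfg.r2_threshold)

    # TFBS screen over the region's segregating loci
    amp = panel.get(region)
    pseudo = []
    for key in matrix.df.columns:
        contig, pos, rest = key.split(":")
        ref, alt = rest.split(">")
        pseudo.append(VariantCall(contig, int(pos), ref, alt, "0/1", 0.5, 0, 0, "PASS"))
    tfbs_hits = scan_tfbs(ref_seqs[amp.contig], pseudo, region_offset=0)

    # association
    dosages = dosage_matrix(results, catalog).reindex(common).fillna(0).astype(int)
    hbf = pheno.loc[common, "hbf"]
    covars = pheno.loc[common, [c for c in ("age", "sex") if c in pheno.columns]]
    association, skipped = gwas_glm(
        dosages, hbf, covariates=covars if len(covars.columns) else None, maf_min=cfg.maf_min
    )

    beneficial = []
    for name in cfg.beneficial_alleles:
        if catalog is not None:
            try:
                allele = catalog.get(name)
                beneficial.append(allele.key if isinstance(allele, SmallAlleleDef) else name)
                continue
            except KeyError:
                pass
        beneficial.append(name)
    burden = burden_score(dosages, beneficial, phenotype=hbf)

    # per-sample haplogroup: a sample carrying a Hap_s1 haplotype counts as
    # Hap_s1, else Hap_s2, etc. (dominant-group assignment)
    label_by_row = {}
    for idx, g in zip(matrix.df.index, row_groups):
        label_by_row.setdefault(idx[0], []).append(int(g))
    sample_groups = pd.Series(
        {sid: f"Hap_s{min(gs) + 1}" for sid, gs in label_by_row.items()}
    ).sort_index()

    group_hbf = None
    survival = None
    if sample_groups.nunique() >= 2:
        carriers = sample_groups.index[sample_groups == "Hap_s1"]
        others = sample_groups.index[sample_groups != "Hap_s1"]
        if len(carriers) >= 2 and len(others) >= 2:
            vals = pd.concat([hbf.loc[carriers], hbf.loc[others]])
            labels = ["Hap_s1"] * len(carriers) + ["other"] * len(others)
            group_hbf = group_compare(vals.to_numpy(), labels, test="unpaired_t")
        surv = pheno.loc[sample_groups.index]
        try:
            survival = km_logrank(
                surv["age_first_transfusion"], surv["transfused"], sample_groups.loc[surv.index]
            )
        except ValueError as exc:
            logger.info("survival comparison skipped: %s", exc)
    else:
        logger.info("survival comparison skipped: fewer than 2 haplogroups")

    return PopulationResult(
        matrix, uniq, groups, row_groups, ld, blocks, tfbs_hits,
        association, skipped, burden, group_hbf, survival, sample_groups, excluded,
    )


# ---------------------------------------------------------------------------
# File-based runs
# ---------------------------------------------------------------------------

def load_reference_seqs(path: str | Path) -> dict[str, str]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def load_allele_catalog(path: str | Path) -> AlleleCatalog:
    """Read the allele catalog TSV (see AlleleCatalog.to_tsv for the schema).

    Structural alleles are reconstructed as single-interval events from
    their spans; crossover alleles cannot be reconstructed from a span and
    are kept for length-shift matching only.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    small, svs = [], []
    for _, row in df.iterrows():
        t = row["type"]
        if t in ("SNV", "small_indel"):
            small.append(
                SmallAlleleDef(row["name"], row["contig"], int(row["pos"]), row["ref"], row["alt"])
            )
        else:
            lo = int(row["pos"])
            hi = lo + int(row["ref"])
            kind = {"deletion": "large_deletion", "duplication": "duplication"}.get(t)
            if kind is None:
                continue
            svs.append(
                SVAlleleDef(
                    row["name"], t,
                    (AlleleEvent(kind, row["contig"], lo, hi, name=row["name"]),),
                )
            )
    return AlleleCatalog(small=small, svs=svs)


def run_genotyping(config: RunConfig) -> dict[str, SampleResult]:
    """Config-driven genotyping: read panel/reference/FASTQs, write artifacts."""
    from .vcfio import (
        write_haplotype_tsv,
        write_small_variant_vcf,
        write_sv_report_tsv,
        write_sv_vcf,
    )

    if not (config.panel_tsv and config.reference and config.fastq_dir):
        raise ValueError("run_genotyping needs panel_tsv, reference and fastq_dir")
    panel = load_panel(config.panel_tsv, config.reference)
    ref_seqs = load_reference_seqs(config.reference)
    catalog_path = Path(config.fastq_dir).parent / "allele_catalog.tsv"
    catalog = load_allele_catalog(catalog_path) if catalog_path.exists() else None
    if catalog is not None:
        panel = _attach_catalog_shifts(panel, catalog)
    fastqs = sorted(Path(config.fastq_dir).glob("*.fastq"))
    if not fastqs:
        raise ValueError(f"no FASTQ files under {config.fastq_dir}")
    reads_by_sample = {f.stem: read_fastq(f) for f in fastqs}
    for sid, rr in reads_by_sample.items():
        if not rr:
            raise ValueError(f"empty FASTQ for sample {sid}")
    results = genotype_cohort(reads_by_sample, panel, ref_seqs, catalog, config)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = {k: len(v) for k, v in ref_seqs.items()}
    phased_out = {}
    all_sv = []
    for sid, res in results.items():
        write_small_variant_vcf(outdir / f"{sid}.small.vcf", res.small_calls, sid, contigs)
        write_sv_vcf(outdir / f"{sid}.sv.vcf", res.sv_calls, sid, panel, contigs)
        all_sv.extend(res.sv_calls)
        phased_out[sid] = {a: list(p) for a, p in res.phased.items()}
    write_sv_report_tsv(outdir / "sv_report.tsv", all_sv)
    write_haplotype_tsv(outdir / "haplotypes.tsv", phased_out)
    manifest = dict(
        seed=config.seed, parameter_hash=config.parameter_hash(),
        n_samples=len(results),
        n_reads=int(sum(r.n_reads for r in results.values())),
        n_assigned=int(sum(r.n_assigned for r in results.values())),
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results


def _attach_catalog_shifts(panel: Panel, catalog: AlleleCatalog) -> Panel:
    """Derive per-amplicon expected length shifts for catalog SVs when absent."""
    if panel.sv_catalog:
        return panel
    from .panel import SVCatalogEntry

    entries = []
    for s in catalog.svs:
        for amp in panel.amplicons:
            if amp.contig != s.contig:
                continue
            lo, hi = s.span()
            if amp.start < lo and hi < amp.end:
                shift = sum(
                    (len(e.alt_seq) - (e.end - e.start)) if e.kind != "duplication" else (e.end - e.start)
                    for e in s.events
                )
                entries.append(SVCatalogEntry(s.name, amp.id, shift, s.sv_class))
    return Panel(panel.amplicons, panel.reference, entries)
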
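"""VCF 4.3 / BED / TSV writers for calls and simulator truth.

Internally everything is 0-based half-open; VCF output is 1-based. Small
variants carry GT/DP/AF (phased GT with a PS tag naming the amplicon once
phasing succeeded); structural calls are written as symbolic <DEL>/<DUP>
records with END and SVLEN.
"""

from __future__ import annotations

from pathlib import Path

from .smallvar import VariantCall
from .svcalling import SVCall

VCF_VERSION = "VCFv4.3"


def _vcf_header(contigs: dict[str, int] | None, sample_ids: list[str], sv: bool = False) -> str:
    lines = [f"##fileformat={VCF_VERSION}", "##source=globintyper"]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FILTER=<ID=PASS,Description="All filters passed">')
    lines.append('##FILTER=<ID=LOW_DEPTH,Description="Depth below the minimum of 20 reads">')
    lines.append('##FILTER=<ID=AMBIGUOUS,Description="Allele fraction outside genotype windows">')
    if sv:
        lines.append('##INFO=<ID=END,Number=1,Type=Integer,Description="End of the variant">')
        lines.append('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length shift of the SV">')
        lines.append('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">')
        lines.append('##INFO=<ID=ALLELE,Number=1,Type=String,Description="Matched catalog allele">')
        lines.append('##ALT=<ID=DEL,Description="Deletion">')
        lines.append('##ALT=<ID=DUP,Description="Duplication">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">')
    lines.append('##FORMAT=<ID=PS,Number=1,Type=String,Description="Phase set (amplicon id)">')
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    for s in sample_ids:
        cols += f"\t{s}"
    lines.append(cols)
    return "\n".join(lines) + "\n"


def write_small_variant_vcf(
    path: str | Path,
    calls: list[VariantCall],
    sample_id: str,
    contigs: dict[str, int] | None = None,
) -> None:
    """One sample's small-variant calls; phased GT when the phaser assigned haplotypes."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, [sample_id]))
        for c in sorted(calls, key=lambda c: (c.contig, c.pos, c.alt)):
            gt = c.phased_gt or c.genotype
            fmt = "GT:DP:AF"
            val = f"{gt}:{c.depth}:{c.allele_fraction:.4g}"
            if c.phase_set:
                fmt += ":PS"
                val += f":{c.phase_set}"
            fh.write(
                f"{c.contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\t{c.filter}\t.\t{fmt}\t{val}\n"
            )


def write_sv_vcf(
    path: str | Path,
    sv_calls: list[SVCall],
    sample_id: str,
    panel,
    contigs: dict[str, int] | None = None,
) -> None:
    """Symbolic <DEL>/<DUP> records; dropout and no-call records go to the TSV report."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, [sample_id], sv=True))
        for c in sorted(sv_calls, key=lambda c: c.amplicon_id):
            if c.sv_class == "dropout" or c.genotype is None:
                continue
            amp = panel.get(c.amplicon_id)
            if c.breakpoint is not None:
                pos, end = c.breakpoint.left, c.breakpoint.right
            else:
                pos, end = amp.start, amp.start + abs(c.length_shift)
            alt = "<DEL>" if c.length_shift < 0 else "<DUP>"
            gt = "1/1" if c.genotype == "hom" else "0/1"
            allele = c.matched_catalog_allele or "."
            fh.write(
                f"{amp.contig}\t{pos + 1}\t.\tN\t{alt}\t.\tPASS\t"
                f"END={end};SVLEN={c.length_shift};SVTYPE={c.sv_class.upper()};ALLELE={allele}\t"
                f"GT:DP\t{gt}:{c.total_reads}\n"
            )


def write_sv_report_tsv(path: str | Path, sv_calls: list[SVCall]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tamplicon_id\tclass\tlength_shift\tgenotype\tsupporting_reads\t"
            "total_reads\tmatched_allele\tbp_left\tbp_right\tmicrohomology\tno_call_reason\n"
        )
        for c in sv_calls:
            bp = c.breakpoint
            fh.write(
                f"{c.sample_id}\t{c.amplicon_id}\t{c.sv_class}\t{c.length_shift}\t"
                f"{c.genotype or '.'}\t{c.supporting_reads}\t{c.total_reads}\t"
                f"{c.matched_catalog_allele or '.'}\t"
                f"{bp.left if bp else '.'}\t{bp.right if bp else '.'}\t"
                f"{bp.microhomology_len if bp else '.'}\t{c.no_call_reason or '.'}\n"
            )


def write_haplotype_tsv(path: str | Path, phased: dict) -> None:
    """sample, amplicon, hap index, allele string over the amplicon's loci."""
    with open(path, "w") as fh:
        fh.write("sample_id\tamplicon_id\thap\tloci\talleles\tsupport\tflags\n")
        for sid in sorted(phased):
            for amp_id in sorted(phased[sid]):
                for h in phased[sid][amp_id]:
                    fh.write(
                        f"{sid}\t{amp_id}\t{h.haplotype_index}\t"
                        f"{','.join(h.loci) or '.'}\t"
                        f"{''.join(str(int(a)) for a in h.alleles) or '.'}\t"
                        f"{h.supporting_reads}\t{','.join(h.flags) or '.'}\n"
                    )


# ---------------------------------------------------------------------------
# Simulator truth
# ---------------------------------------------------------------------------

def write_truth_vcf(truth, mini, path: str | Path) -> None:
    """Phased multi-sample truth VCF over all planted small variants."""
    contigs = {name: len(seq) for name, seq in mini.contigs.items()}
    sample_ids = [s.sample_id for s in truth.samples]
    loci: dict[tuple[str, int, str, str], dict[str, list[int]]] = {}
    for s in truth.samples:
        for contig, pos, ref, alt, hap in s.small_variants:
            loci.setdefault((contig, pos, ref, alt), {}).setdefault(s.sample_id, []).append(hap)
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, sample_ids))
        for (contig, pos, ref, alt) in sorted(loci):
            carriers = loci[(contig, pos, ref, alt)]
            gts = []
            for sid in sample_ids:
                haps = carriers.get(sid, [])
                gts.append(f"{1 if 0 in haps else 0}|{1 if 1 in haps else 0}")
            fh.write(
                f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_truth_sv_bed(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in truth.samples:
            for sv in s.svs:
                fh.write(
                    f"{sv.contig}\t{sv.start}\t{sv.end}\t{sv.name}\t{s.sample_id}\t"
                    f"hap{sv.hap + 1}\t{sv.sv_class}\n"
                )
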
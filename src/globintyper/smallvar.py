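"""Per-amplicon read alignment, pileup and diploid SNV/indel calling.

Reads assigned to an amplicon are globally aligned to the amplicon
reference (banded edit-distance alignment), their differences extracted as
left-normalized variant records, and genotyped per column by allele
fraction with a hard depth filter: no PASS call is ever emitted below the
minimum depth of 20 reads.

Reads from a length-shifted (structural-variant) cluster are aligned
against an SV-adjusted reference and their observations lifted back to
amplicon coordinates, so that e.g. an SNV in trans to a large deletion
still genotypes as heterozygous: the deletion-carrying reads count as
reference-allele coverage over the deleted interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .panel import Amplicon
from .simulate import AlleleEvent, AlleleCatalog, SVAlleleDef, apply_events
from .varutils import left_normalize, variant_key


@dataclass
class Alignment:
    """A CIGAR-like global alignment of one read against a reference."""

    read_id: str
    ops: list[tuple[int, str]]  # (length, op) with ops in =, X, I, D
    edit_distance: int
    identity: float


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def align_read(read: str, amplicon_ref: str, read_id: str = "", min_identity: float = 0.7) -> Alignment | None:
    """Globally align a read to its amplicon reference.

    Returns None (read flagged, excluded from pileup) when alignment
    identity falls below ``min_identity``. Gap placement from the aligner is
    not relied upon: indels are left-normalized downstream at the variant
    representation layer.
    """
    res = edlib.align(read, amplicon_ref, mode="NW", task="path")
    dist = res["editDistance"]
    identity = 1.0 - dist / max(len(read), len(amplicon_ref))
    if identity < min_identity:
        return None
    return Alignment(read_id, list(_parse_cigar(res["cigar"])), dist, identity)


@dataclass
class ReadObservation:
    """One read's variant observations and covered interval, in reference coords."""

    read_id: str
    variants: dict[str, tuple[int, str, str]]  # key -> (pos, ref, alt)
    covered: tuple[int, int]


def _merge_indel_clusters(
    ops: list[tuple[int, str]], read: str, ref: str, merge_window: int = 10
) -> list[tuple[str, int, int, int, int]]:
    """Rewrite the op list as (op, ref_len, read_len, ref_pos, read_pos)
    records, merging indel clusters that admit an equal-cost single-indel
    representation.

    Unit-cost aligners may split one deletion next to a repeat into several
    gaps separated by a few (re-)matched bases; the placements tie on edit
    distance, but only the contiguous representation normalizes onto the
    catalogued allele. A cluster of gaps separated by <= ``merge_window``
    aligned bases is collapsed when the spanned reference and read segments
    differ by exactly one contiguous indel (common prefix plus suffix covers
    the shorter segment).
    """
    recs: list[tuple[str, int, int, int, int]] = []
    rpos = qpos = 0
    for length, op in ops:
        rl = length if op in ("=", "X", "D") else 0
        ql = length if op in ("=", "X", "I") else 0
        recs.append((op, rl, ql, rpos, qpos))
        rpos += rl
        qpos += ql

    out: list[tuple[str, int, int, int, int]] = []
    i = 0
    while i < len(recs):
        op = recs[i][0]
        if op not in ("D", "I"):
            out.append(recs[i])
            i += 1
            continue
        # extend the cluster across indels separated by short aligned runs
        last = i
        j = i
        while j + 1 < len(recs):
            nxt = recs[j + 1]
            if nxt[0] in ("D", "I"):
                last = j + 1
                j += 1
            elif nxt[0] in ("=", "X") and nxt[1] <= merge_window:
                j += 1
            else:
                break
        if last == i:
            out.append(recs[i])
            i += 1
            continue
        _, rl0, ql0, rp, qp = recs[i]
        lop, lrl, lql, lrp, lqp = recs[last]
        r_end, q_end = lrp + lrl, lqp + lql
        R, Q = ref[rp:r_end], read[qp:q_end]
        short, longer = (Q, R) if len(R) > len(Q) else (R, Q)
        p = 0
        while p < len(short) and short[p] == longer[p]:
            p += 1
        s = 0
        while s < len(short) - p and short[-1 - s] == longer[-1 - s]:
            s += 1
        if len(R) != len(Q) and p + s == len(short):
            out.append(("merged", len(R), len(Q), rp, qp))
        else:
            out.extend(recs[i : last + 1])  # no equal-cost single indel; keep as-is
        i = last + 1
    return out


def observe_read(read: str, ref: str, aln: Alignment) -> ReadObservation:
    """Extract left-normalized variant records from an alignment."""
    variants: dict[str, tuple[int, str, str]] = {}

    def add(p: int, r: str, a: str) -> None:
        p, r, a = left_normalize(ref, p, r, a)
        variants[variant_key("", p, r, a)] = (p, r, a)

    for op, ref_len, read_len, rpos, qpos in _merge_indel_clusters(aln.ops, read, ref):
        if op == "=":
            continue
        if op == "X":
            for i in range(ref_len):
                p = rpos + i
                variants[variant_key("", p, ref[p], read[qpos + i])] = (p, ref[p], read[qpos + i])
        elif op in ("D", "I", "merged"):
            add(rpos, ref[rpos : rpos + ref_len], read[qpos : qpos + read_len])
    return ReadObservation(aln.read_id, variants, (0, len(ref)))


def adjusted_reference(
    contig_seq: str, events: list[AlleleEvent], amplicon: Amplicon
) -> tuple[str, np.ndarray]:
    """The amplicon reference with SV events applied, plus the inverse map.

    Returns the adjusted amplicon sequence and an array mapping each
    adjusted-local position back to the amplicon-local reference position
    (-1 for bases with no reference equivalent, e.g. a duplication's second
    copy or donor-derived sequence).
    """
    mutated, coord = apply_events(contig_seq, events)
    inv = np.full(len(mutated), -1, dtype=np.int64)
    valid = coord[:-1] >= 0
    inv[coord[:-1][valid]] = np.arange(len(contig_seq))[valid]
    # adjusted span of the amplicon boundaries
    s = amplicon.start
    while s < amplicon.end and coord[s] < 0:
        s += 1
    e = amplicon.end
    while e > s and coord[e] < 0:
        e -= 1
    adj_s, adj_e = int(coord[s]), int(coord[e])
    inv_local = inv[adj_s:adj_e].copy()
    np.subtract(inv_local, amplicon.start, out=inv_local, where=inv_local >= 0)
    return mutated[adj_s:adj_e], inv_local


def lift_observation(obs: ReadObservation, inv_map: np.ndarray, ref_len: int) -> ReadObservation:
    """Lift an observation from SV-adjusted coordinates to amplicon coordinates.

    Variant records at positions without a reference equivalent are dropped
    (a duplication's second copy repeats the first copy's observations).
    The covered interval becomes the full reference span between the
    outermost mapped positions, so deleted intervals count as covered.
    """
    mapped = inv_map[inv_map >= 0]
    if mapped.size == 0:
        return ReadObservation(obs.read_id, {}, (0, 0))
    lo, hi = int(mapped.min()), int(mapped.max()) + 1
    variants: dict[str, tuple[int, str, str]] = {}
    for _, (p, r, a) in obs.variants.items():
        if p >= len(inv_map) or inv_map[p] < 0:
            continue
        lp = int(inv_map[p])
        key = variant_key("", lp, r, a)
        variants[key] = (lp, r, a)
    return ReadObservation(obs.read_id, variants, (max(0, lo), min(ref_len, hi)))


# ---------------------------------------------------------------------------
# Pileup and genotyping
# ---------------------------------------------------------------------------

@dataclass
class PileupColumn:
    """Allele counts at one reference column (indels keyed by their alleles)."""

    contig: str
    pos: int
    ref_base: str
    counts: dict[str, int]  # allele string (or "ref") -> read count
    depth: int


@dataclass
class Pileup:
    """Per-amplicon observation summary feeding the genotyper."""

    contig: str
    offset: int  # amplicon start on the contig
    ref: str  # amplicon-local reference
    depth: np.ndarray  # per-position covering-read count
    alt_counts: dict[str, int]  # local variant key -> supporting reads
    alt_records: dict[str, tuple[int, str, str]]
    n_reads: int

    def columns(self) -> list[PileupColumn]:
        by_pos: dict[int, dict[str, int]] = {}
        for key, n in self.alt_counts.items():
            pos, r, a = self.alt_records[key]
            by_pos.setdefault(pos, {})[f"{r}>{a}"] = n
        cols = []
        for pos in sorted(by_pos):
            counts = dict(by_pos[pos])
            depth = int(self.depth[pos])
            counts["ref"] = max(0, depth - sum(counts.values()))
            cols.append(PileupColumn(self.contig, self.offset + pos, self.ref[pos], counts, depth))
        return cols


def build_pileup(
    observations: list[ReadObservation], ref: str, contig: str = "", offset: int = 0
) -> Pileup:
    depth = np.zeros(len(ref) + 1, dtype=np.int64)
    alt_counts: dict[str, int] = {}
    alt_records: dict[str, tuple[int, str, str]] = {}
    for obs in observations:
        s, e = obs.covered
        depth[s] += 1
        depth[e] -= 1
        for key, rec in obs.variants.items():
            alt_counts[key] = alt_counts.get(key, 0) + 1
            alt_records.setdefault(key, rec)
    return Pileup(contig, offset, ref, np.cumsum(depth)[:-1], alt_counts, alt_records, len(observations))


FILTER_PASS = "PASS"
FILTER_LOW_DEPTH = "LOW_DEPTH"
FILTER_AMBIGUOUS = "AMBIGUOUS"


@dataclass
class VariantCall:
    contig: str
    pos: int  # 0-based on the contig
    ref: str
    alt: str
    genotype: str  # "0/1" | "1/1" | "./."
    allele_fraction: float
    depth: int
    alt_count: int
    filter: str
    sample_id: str = ""
    amplicon_id: str = ""
    phase_set: str | None = None
    phased_gt: str | None = None  # e.g. "0|1" once phasing assigns haplotypes

    @property
    def key(self) -> str:
        return variant_key(self.contig, self.pos, self.ref, self.alt)

    @property
    def is_het(self) -> bool:
        return self.genotype == "0/1"


def call_small_variants(
    pileup: Pileup,
    contig_seq: str | None = None,
    min_depth: int = 20,
    het_window: tuple[float, float] = (0.25, 0.75),
    hom_min: float = 0.9,
    min_alt_frac: float = 0.2,
    min_alt_reads: int = 5,
    sample_id: str = "",
    amplicon_id: str = "",
) -> list[VariantCall]:
    """Genotype candidate columns of a per-sample, per-amplicon pileup.

    Alt alleles need fraction >= ``min_alt_frac`` and >= ``min_alt_reads``
    supporting reads; genotype is assigned by fraction window (het) or
    ``hom_min`` (hom). Columns below ``min_depth`` are emitted as non-PASS
    LOW_DEPTH records — the pipeline's hard depth rule. Columns where more
    than two alleles pass threshold are AMBIGUOUS. Variant positions are
    re-normalized against the full contig when ``contig_seq`` is given.
    """
    calls: list[VariantCall] = []
    by_pos: dict[int, list[str]] = {}
    for key in pileup.alt_counts:
        by_pos.setdefault(pileup.alt_records[key][0], []).append(key)
    for pos in sorted(by_pos):
        depth = int(pileup.depth[pos])
        passing = []
        for key in by_pos[pos]:
            n = pileup.alt_counts[key]
            frac = n / depth if depth else 0.0
            if frac >= min_alt_frac and n >= min_alt_reads:
                passing.append((key, n, frac))
        if not passing:
            continue
        multi = len(passing) >= 2  # >= 3 alleles at the column incl. reference
        for key, n, frac in passing:
            _, r, a = pileup.alt_records[key]
            cpos = pileup.offset + pos
            if contig_seq is not None:
                cpos, r, a = left_normalize(contig_seq, cpos, r, a)
            if depth < min_depth:
                filt, gt = FILTER_LOW_DEPTH, "./."
            elif multi:
                filt, gt = FILTER_AMBIGUOUS, "./."
            elif het_window[0] <= frac <= het_window[1]:
                filt, gt = FILTER_PASS, "0/1"
            elif frac >= hom_min:
                filt, gt = FILTER_PASS, "1/1"
            else:
                filt, gt = FILTER_AMBIGUOUS, "./."
            calls.append(
                VariantCall(
                    pileup.contig, cpos, r, a, gt, round(frac, 4), depth, n, filt,
                    sample_id=sample_id, amplicon_id=amplicon_id,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Catalog annotation
# ---------------------------------------------------------------------------

@dataclass
class AlleleAnnotation:
    """A catalogued allele observed in one sample, with zygosity."""

    sample_id: str
    allele_name: str
    zygosity: str  # het | hom
    source: str  # small | sv
    flagged: bool = False
    note: str = ""


def annotate_alleles(
    calls: list[VariantCall],
    sv_calls,
    catalog: AlleleCatalog,
    sample_id: str = "",
) -> list[AlleleAnnotation]:
    """Match PASS small-variant calls and SV calls against the allele catalog.

    An allele reported by several amplicons (e.g. an alpha-unit deletion
    seen by both the unit amplicon and the spanning amplicon) is collapsed
    to one annotation. Disagreeing zygosity between sources is resolved in
    favour of the deeper-covered amplicon and flagged: when a whole-cluster
    deletion removes one haplotype's product from an internal amplicon, the
    surviving spanning amplicon still sees both haplotypes, so its fractions
    are the trustworthy ones. A catalogued spanning deletion corroborated by
    dropout of its linked internal amplicon keeps the spanning genotype.
    """
    best_depth: dict[str, int] = {}
    ann: dict[str, AlleleAnnotation] = {}

    def put(name: str, zyg: str, source: str, depth: int) -> None:
        if name not in ann:
            ann[name] = AlleleAnnotation(sample_id, name, zyg, source)
            best_depth[name] = depth
            return
        if ann[name].zygosity != zyg:
            if depth > best_depth[name]:
                ann[name].zygosity = zyg
                ann[name].source = source
                best_depth[name] = depth
            ann[name].flagged = True
            ann[name].note = "zygosity conflict between amplicons; deeper amplicon kept"

    small_names = catalog.small_by_key()
    for c in calls:
        if c.filter != FILTER_PASS:
            continue
        name = small_names.get(c.key)
        if name is None:
            continue
        put(name, "hom" if c.genotype == "1/1" else "het", "small", c.depth)
    for sv in sv_calls:
        name = getattr(sv, "matched_catalog_allele", None)
        if name is None or sv.genotype is None:
            continue
        put(name, sv.genotype, "sv", sv.total_reads)
    return sorted(ann.values(), key=lambda a: a.allele_name)


def diplotype_string(annotations: list[AlleleAnnotation], catalog_names: set[str] | None = None) -> str:
    parts = []
    for a in sorted(annotations, key=lambda x: x.allele_name):
        if catalog_names is not None and a.allele_name not in catalog_names:
            continue
        parts.append(f"{a.allele_name}:{a.zygosity}")
    return ";".join(parts)
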
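"""Read-to-amplicon assignment and length-based structural variant calling.

In an amplicon assay every CCS read is a full-length PCR product, so two
cheap observables carry almost all the structural signal: which primer pair
the read's termini match, and how long the read is. A read whose length
deviates from the amplicon's expected product length by more than the
tolerance indicates a deletion (shorter) or duplication (longer) on that
haplotype; complete absence of reads for an amplicon that is otherwise
covered (dropout) indicates loss of a primer site, as with whole-cluster
deletions detected by gap-PCR. Split-read alignment then refines deletion
breakpoints to base-pair resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .panel import Amplicon, Panel, revcomp
from .varutils import encode, sliding_hamming

UNASSIGNED = "UNASSIGNED"


@dataclass
class ReadAssignment:
    read_id: str
    amplicon_id: str  # UNASSIGNED when no unique primer-pair match
    orientation: str  # '+' | '-' | '.'
    fwd_mismatches: int
    rev_mismatches: int
    read_length: int
    ambiguous: bool = False
    seq: str | None = None  # plus-strand sequence, kept for downstream alignment

    @property
    def assigned(self) -> bool:
        return self.amplicon_id != UNASSIGNED


def _min_ham(window: np.ndarray, primer: np.ndarray) -> int:
    d = sliding_hamming(window, primer)
    return int(d.min()) if d.size else 10**6


def assign_read(
    read: str,
    panel: Panel,
    window: int = 50,
    read_id: str = "",
    keep_seq: bool = True,
) -> ReadAssignment:
    """Assign one read to an amplicon by terminal primer matching.

    Scans a window at each read end against every primer pair in both
    orientations (windowed Hamming match); the read is assigned to the
    unique amplicon whose forward and reverse primers match opposite ends
    within the pair's mismatch budget. Equally good matches to two amplicons
    leave the read unassigned with the ambiguity flag set.
    """
    arr = encode(read)
    n = len(arr)
    longest_primer = max(
        max(len(a.primer_pair.fwd_seq), len(a.primer_pair.rev_seq)) for a in panel.amplicons
    )
    if n < 2 * longest_primer:
        return ReadAssignment(read_id, UNASSIGNED, ".", -1, -1, n)
    w = min(window + longest_primer, n)
    head, tail = arr[:w], arr[n - w :]

    best: tuple[int, str, str, int, int] | None = None  # (score, amp, orient, fmm, rmm)
    n_best = 0
    for amp in panel.amplicons:
        pp = amp.primer_pair
        fwd = encode(pp.fwd_seq)
        rev = encode(pp.rev_seq)
        fwd_rc = encode(revcomp(pp.fwd_seq))
        rev_rc = encode(revcomp(pp.rev_seq))
        for orient, (d1, d2) in (
            ("+", (_min_ham(head, fwd), _min_ham(tail, rev_rc))),
            ("-", (_min_ham(head, rev), _min_ham(tail, fwd_rc))),
        ):
            if d1 <= pp.max_mismatch and d2 <= pp.max_mismatch:
                score = d1 + d2
                if best is None or score < best[0]:
                    best = (score, amp.id, orient, d1, d2)
                    n_best = 1
                elif score == best[0] and amp.id != best[1]:
                    n_best += 1
    if best is None:
        return ReadAssignment(read_id, UNASSIGNED, ".", -1, -1, n)
    if n_best > 1:
        return ReadAssignment(read_id, UNASSIGNED, ".", -1, -1, n, ambiguous=True)
    score, amp_id, orient, d1, d2 = best
    seq = None
    if keep_seq:
        seq = read if orient == "+" else revcomp(read)
    # normalize mismatch reporting to the (fwd, rev) primer order
    fmm, rmm = (d1, d2) if orient == "+" else (d2, d1)
    return ReadAssignment(read_id, amp_id, orient, fmm, rmm, n, seq=seq)


def assign_reads(reads, panel: Panel, window: int = 50) -> list[ReadAssignment]:
    """Assign a batch of reads (any iterable of objects with read_id/seq)."""
    return [assign_read(r.seq, panel, window=window, read_id=r.read_id) for r in reads]


SVCALL_CLASSES = ("deletion", "duplication", "dropout", "novel")


@dataclass
class SVCall:
    sample_id: str
    amplicon_id: str
    sv_class: str  # deletion | duplication | dropout | novel
    length_shift: int  # observed - expected, bp (0 for dropout)
    genotype: str | None  # 'het' | 'hom' | None when undetermined
    supporting_reads: int
    total_reads: int
    matched_catalog_allele: str | None = None
    read_ids: list[str] = field(default_factory=list)
    breakpoint: "Breakpoint | None" = None
    no_call_reason: str | None = None


@dataclass
class Breakpoint:
    """A left-normalized deletion breakpoint: deleted interval [left, right)."""

    contig: str
    left: int
    right: int
    microhomology_len: int
    n_split_reads: int

    @property
    def size(self) -> int:
        return self.right - self.left

    def __post_init__(self) -> None:
        if self.right <= self.left:
            raise ValueError("breakpoint needs right > left")


class InsufficientSplitReadsError(ValueError):
    pass


def _length_clusters(lengths: np.ndarray, gap: int) -> list[np.ndarray]:
    """1-D clustering: sort and split where consecutive lengths differ by > gap."""
    order = np.argsort(lengths, kind="stable")
    s = lengths[order]
    splits = np.flatnonzero(np.diff(s) > gap) + 1
    return [order[idx] for idx in np.split(np.arange(len(s)), splits)]


def call_svs(
    assignments: dict[str, list[ReadAssignment]],
    panel: Panel,
    sample_id: str,
    length_tolerance: int = 100,
    min_depth: int = 10,
    het_window: tuple[float, float] = (0.25, 0.75),
    hom_min: float = 0.9,
    min_support: int = 3,
) -> list[SVCall]:
    """Call structural variants per amplicon from read-length deviation.

    ``assignments`` maps amplicon id -> that sample's assigned reads. Reads
    are binned into a REF-like cluster (|observed - expected| <= tolerance)
    and shifted clusters (gap clustering at the tolerance); each shifted
    cluster with enough support becomes a call, matched against the panel's
    structural-allele catalog by length shift and sign-compatible class.
    Amplicons with reads below ``min_depth`` produce a no-call record; an
    amplicon with no reads at all, in a sample whose other amplicons are
    covered, produces a dropout call (interpreted jointly with catalogued
    spanning deletions downstream).
    """
    calls: list[SVCall] = []
    counts = {a.id: len(assignments.get(a.id, [])) for a in panel.amplicons}
    covered = [c for c in counts.values() if c >= min_depth]
    for amp in panel.amplicons:
        rs = assignments.get(amp.id, [])
        total = len(rs)
        if total == 0:
            if len(covered) >= max(1, len(panel.amplicons) - 1):
                calls.append(
                    SVCall(sample_id, amp.id, "dropout", 0, "hom", 0, 0)
                )
            continue
        if total < min_depth:
            calls.append(
                SVCall(
                    sample_id, amp.id, "novel", 0, None, 0, total,
                    no_call_reason=f"coverage {total} < min_depth {min_depth}",
                )
            )
            continue
        lengths = np.array([r.read_length for r in rs])
        shifts = lengths - amp.expected_length
        ref_like = np.abs(shifts) <= length_tolerance
        n_ref = int(ref_like.sum())
        shifted_idx = np.flatnonzero(~ref_like)
        if shifted_idx.size == 0:
            continue
        for cluster in _length_clusters(shifts[shifted_idx], length_tolerance):
            idx = shifted_idx[cluster]
            if idx.size < min_support:
                continue
            shift = int(round(float(np.median(shifts[idx]))))
            frac = idx.size / total
            # genotype from the cluster's own read fraction, so compound
            # heterozygotes (two shifted clusters, no REF-like reads) work
            if frac >= hom_min:
                gt = "hom"
            elif het_window[0] <= frac <= het_window[1]:
                gt = "het"
            else:
                gt = None
            matched = None
            sv_class = "deletion" if shift < 0 else "duplication"
            for entry in panel.catalog_for(amp.id):
                if abs(shift - entry.length_shift) <= length_tolerance and (
                    (entry.length_shift < 0) == (shift < 0)
                ):
                    matched = entry.allele_name
                    if entry.sv_class in ("deletion", "duplication"):
                        sv_class = entry.sv_class
                    break
            if matched is None:
                sv_class = "novel"
            calls.append(
                SVCall(
                    sample_id, amp.id, sv_class, shift, gt, int(idx.size), total,
                    matched_catalog_allele=matched,
                    read_ids=[rs[j].read_id for j in idx],
                )
            )
    return calls


def refine_breakpoint(
    sv_reads: list[str],
    amplicon_ref: str,
    contig_offset: int = 0,
    contig: str = "",
    min_reads: int = 3,
    max_reads: int = 6,
) -> Breakpoint:
    """Refine a deletion breakpoint from supporting reads by split alignment.

    Each read (plus-strand sequence) is globally aligned to the amplicon
    reference; the largest deletion run in the alignment path gives that
    read's breakpoints, which are left-normalized (leftmost equivalent
    placement; the ambiguity span is the junction microhomology). The
    per-read breakpoints are aggregated by majority. Coordinates are
    reported on the reference contig when ``contig_offset`` (the amplicon's
    start) is given.
    """
    if len(sv_reads) < min_reads:
        raise InsufficientSplitReadsError(
            f"insufficient split reads: {len(sv_reads)} < {min_reads}"
        )
    ref_arr = encode(amplicon_ref)
    m = len(ref_arr)
    votes: dict[tuple[int, int], int] = {}
    mh_by_bp: dict[tuple[int, int], int] = {}
    for read in sv_reads[:max_reads]:
        bp = _split_read_deletion(encode(read), ref_arr)
        if bp is None:
            continue
        votes[bp[:2]] = votes.get(bp[:2], 0) + 1
        mh_by_bp[bp[:2]] = bp[2]
    if not votes:
        raise InsufficientSplitReadsError("no read produced a consistent split alignment")
    (left, right), n = max(votes.items(), key=lambda kv: (kv[1], -kv[0][0]))
    return Breakpoint(
        contig=contig,
        left=contig_offset + left,
        right=contig_offset + right,
        microhomology_len=mh_by_bp[(left, right)],
        n_split_reads=sum(votes.values()),
    )


def _split_read_deletion(
    read: np.ndarray, ref: np.ndarray, anchor_len: int = 400
) -> tuple[int, int, int] | None:
    """One read's deletion breakpoints by two-anchor split alignment.

    A prefix anchor and a suffix anchor of the read are placed on the
    reference by infix alignment, giving two mapping offsets; their
    difference is the deletion size — robust even when the deleted interval
    joins two paralogous units, where a single global alignment would
    scatter the gap across the homology. The switch point from the prefix
    to the suffix mapping is chosen to minimize total mismatches; the
    leftmost optimal switch gives the left-normalized breakpoint and the
    span of optimal switch points is the junction microhomology.
    """
    n = len(read)
    k = min(anchor_len, n // 3)
    if k < 50:
        return None
    res1 = edlib.align(read[:k].tobytes(), ref.tobytes(), mode="HW", task="locations")
    res2 = edlib.align(read[n - k :].tobytes(), ref.tobytes(), mode="HW", task="locations")
    if not res1["locations"] or not res2["locations"]:
        return None
    s1 = res1["locations"][0][0] or 0  # leftmost best placement of the prefix
    e2 = res2["locations"][-1][1]  # rightmost best placement of the suffix (inclusive end)
    delta1 = s1
    delta2 = (e2 + 1) - n
    size = delta2 - delta1
    if size <= 0:
        return None
    # fast path: rigid per-base comparison under each offset — exact for
    # reads without indel errors
    idx1 = np.arange(n) + delta1
    idx2 = np.arange(n) + delta2
    ok1 = (idx1 >= 0) & (idx1 < len(ref))
    ok2 = (idx2 >= 0) & (idx2 < len(ref))
    agree1 = np.zeros(n, dtype=bool)
    agree2 = np.zeros(n, dtype=bool)
    agree1[ok1] = read[ok1] == ref[idx1[ok1]]
    agree2[ok2] = read[ok2] == ref[idx2[ok2]]
    rigid = np.concatenate([[0], np.cumsum(~agree1)]) + np.concatenate(
        [np.cumsum((~agree2)[::-1])[::-1], [0]]
    )
    if rigid.min() <= 0.02 * n:
        opt = np.flatnonzero(rigid == rigid.min())
        b0 = int(opt[0])
        return b0 + delta1, b0 + delta2, int(opt[-1] - opt[0])
    # Banded offset DP around each mapping: read indels shift the effective
    # offset by +-1 per event, so track edit cost over a small offset band
    # (distance-transform per step) instead of a rigid per-base comparison.
    P, dP = _offset_band_costs(read, ref, delta1, forward=True)
    S, dS = _offset_band_costs(read, ref, delta2, forward=False)
    cost = P + S
    best = int(cost.min())
    if best > 0.1 * n:
        return None
    opt = np.flatnonzero(cost == best)
    b0 = int(opt[0])
    mh = int(opt[-1] - opt[0])
    return b0 + delta1 + int(dP[b0]), b0 + delta2 + int(dS[b0]), mh


_BAND_W = 5


def _offset_band_costs(
    read: np.ndarray, ref: np.ndarray, delta: int, forward: bool, W: int = _BAND_W
) -> tuple[np.ndarray, np.ndarray]:
    """Min edit cost of mapping read[:b] (forward) or read[b:] (backward)
    at offsets delta-W..delta+W; returns per-b best cost and best offset shift."""
    n = len(read)
    m = len(ref)
    width = 2 * W + 1
    # mismatch table: mis[d, j] = read[j] != ref[j + delta + d - W]
    mis = np.ones((width, n), dtype=np.int32)
    for d in range(width):
        idx = np.arange(n) + delta + d - W
        ok = (idx >= 0) & (idx < m)
        mis[d, ok] = (read[ok] != ref[idx[ok]]).astype(np.int32)
    INF = 10**9
    cur = np.full(width, INF, dtype=np.int64)
    cur[W] = 0
    best = np.empty(n + 1, dtype=np.int64)
    best_d = np.empty(n + 1, dtype=np.int64)
    rng = range(n) if forward else range(n - 1, -1, -1)

    def record(b: int) -> None:
        j = int(np.argmin(cur))
        best[b] = cur[j]
        best_d[b] = j - W

    record(0 if forward else n)
    for j in rng:
        # distance transform over the offset band (indel cost 1 per shift)
        for i in range(1, width):
            if cur[i - 1] + 1 < cur[i]:
                cur[i] = cur[i - 1] + 1
        for i in range(width - 2, -1, -1):
            if cur[i + 1] + 1 < cur[i]:
                cur[i] = cur[i + 1] + 1
        cur = cur + mis[:, j]
        record(j + 1 if forward else j)
    return best, best_d


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""
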
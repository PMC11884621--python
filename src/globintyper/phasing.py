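"""Within-amplicon haplotype phasing by minimum-error-correction clustering.

Amplicon CCS reads span the full fragment, so diploid phasing reduces to
2-clustering the reads over their alleles at heterozygous sites under the
minimum-error-correction (MEC) objective: find two consensus haplotypes
minimizing the total number of base flips needed to make every read
consistent with one of them. Small instances are solved exactly by
bipartition enumeration; larger ones by consensus-pair seeding from read
rows plus iterative refinement. Phasing across different amplicons is not
attempted — long-range PCR products are independent molecules.

The same per-amplicon haplotypes drive paralog-specific variant assignment
(HBA1 vs HBA2, HBG1 vs HBG2) and gene-conversion tract detection over the
paralog-diagnostic positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iterproduct

import numpy as np

from .panel import Amplicon, GeneInterval, ParalogPair
from .smallvar import VariantCall, ReadObservation, FILTER_PASS
from .varutils import variant_key

MISSING = -1


@dataclass
class PhaseResult:
    """Outcome of MEC 2-clustering of reads over het sites."""

    labels: np.ndarray  # per-read cluster index 0/1
    consensus: np.ndarray  # 2 x n_sites, values 0/1
    cost: int
    switch_confidence: float
    cluster_sizes: tuple[int, int]
    phased: bool
    reason: str | None = None


def _consensus_for(M: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Majority allele per site over observed entries; ties -> 0 (reference)."""
    S = M.shape[1]
    cons = np.zeros(S, dtype=np.int8)
    sub = M[rows]
    obs = sub != MISSING
    ones = ((sub == 1) & obs).sum(axis=0)
    zeros = ((sub == 0) & obs).sum(axis=0)
    cons[ones > zeros] = 1
    return cons


def _partition_cost(M: np.ndarray, labels: np.ndarray) -> tuple[int, np.ndarray]:
    cons = np.vstack(
        [_consensus_for(M, np.flatnonzero(labels == k)) for k in (0, 1)]
    )
    obs = M != MISSING
    cost = int(((M != cons[labels]) & obs).sum())
    return cost, cons


def _read_distances(M: np.ndarray, cons: np.ndarray) -> np.ndarray:
    obs = M != MISSING
    return np.stack([((M != c) & obs).sum(axis=1) for c in cons], axis=1)


def cluster_reads_by_hets(
    read_allele_matrix: np.ndarray,
    min_reads_per_cluster: int = 3,
    method: str = "auto",
    exact_max_reads: int = 12,
    max_seeds: int = 30,
    max_iter: int = 25,
) -> PhaseResult:
    """Partition reads into two allele clusters minimizing MEC cost.

    ``read_allele_matrix`` is reads x het-sites with entries 0 (ref allele),
    1 (alt allele) or -1 (site not observed). Deterministic and invariant to
    read input order: ties are broken by preferring the lexicographically
    smaller consensus pair, and cluster 1 is the lexicographically smaller
    consensus.
    """
    M = np.asarray(read_allele_matrix, dtype=np.int8)
    if M.ndim != 2 or M.shape[1] < 1:
        raise ValueError("need a reads x sites matrix with >= 1 het site")
    R = M.shape[0]
    if method == "auto":
        method = "exact" if R <= exact_max_reads else "greedy"

    best: tuple[int, tuple, np.ndarray, np.ndarray] | None = None

    def consider(labels: np.ndarray) -> None:
        nonlocal best
        cost, cons = _partition_cost(M, labels)
        key = (cost, tuple(cons[0]), tuple(cons[1]))
        if best is None or key < (best[0], best[1][0], best[1][1]):
            best = (cost, (tuple(cons[0]), tuple(cons[1])), labels.copy(), cons)

    if method == "exact":
        for bits in range(2 ** max(0, R - 1)):
            labels = np.zeros(R, dtype=np.int8)
            for i in range(R - 1):
                labels[i + 1] = (bits >> i) & 1
            consider(labels)
    elif method == "greedy":
        rows, counts = np.unique(M, axis=0, return_counts=True)
        order = np.lexsort(tuple(rows.T) + (-counts,))
        rows = rows[order][:max_seeds]
        seeds = []
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                seeds.append((rows[i], rows[j]))
        if not seeds:  # all reads identical
            seeds = [(rows[0], rows[0])]
        for c1, c2 in seeds:
            cons = np.vstack([np.where(c1 == MISSING, 0, c1), np.where(c2 == MISSING, 0, c2)]).astype(np.int8)
            labels = np.zeros(R, dtype=np.int8)
            for _ in range(max_iter):
                d = _read_distances(M, cons)
                new_labels = (d[:, 1] < d[:, 0]).astype(np.int8)
                if np.array_equal(new_labels, labels):
                    break
                labels = new_labels
                _, cons = _partition_cost(M, labels)
            consider(labels)
    else:
        raise ValueError(f"unknown method {method!r}")

    assert best is not None
    cost, _, labels, cons = best
    # order clusters: lexicographically smaller consensus is cluster 1 (index 0)
    if tuple(cons[1]) < tuple(cons[0]):
        labels = 1 - labels
        cons = cons[::-1]
    # genotype consistency: at every het site the two haplotypes must differ;
    # where MEC left them equal, flip the allele on the weaker-supported cluster
    sizes = (int((labels == 0).sum()), int((labels == 1).sum()))
    weaker = 0 if sizes[0] <= sizes[1] else 1
    equal_sites = np.flatnonzero(cons[0] == cons[1])
    cons[weaker, equal_sites] = 1 - cons[weaker, equal_sites]

    obs_total = int((M != MISSING).sum())
    conf = 1.0 - cost / obs_total if obs_total else 0.0
    phased = min(sizes) >= min_reads_per_cluster
    reason = None if phased else (
        f"cluster sizes {sizes} below min_reads_per_cluster={min_reads_per_cluster}"
    )
    return PhaseResult(labels, cons, cost, conf, sizes, phased, reason)


@dataclass
class PhasedHaplotype:
    """One haplotype of one sample over one amplicon's PASS variant loci."""

    sample_id: str
    amplicon_id: str
    haplotype_index: int  # 1 or 2
    loci: list[str]  # contig-coordinate variant keys, position-ordered
    alleles: np.ndarray  # 0/1 per locus
    supporting_reads: int
    flags: tuple[str, ...] = ()

    def allele_of(self, key: str) -> int | None:
        try:
            return int(self.alleles[self.loci.index(key)])
        except ValueError:
            return None

    def carried_keys(self) -> set[str]:
        return {k for k, a in zip(self.loci, self.alleles) if a == 1}


def phase_sample_amplicon(
    calls: list[VariantCall],
    observations: list[ReadObservation],
    amplicon: Amplicon,
    sample_id: str,
    min_reads_per_cluster: int = 3,
) -> tuple[PhasedHaplotype, PhasedHaplotype, PhaseResult | None]:
    """Phase one sample's PASS calls on one amplicon from its read observations.

    Homozygous-alt loci are set on both haplotypes; heterozygous loci are
    resolved by MEC clustering of the reads. With no heterozygous site the
    two haplotypes are identical and flagged ``no_het_sites``; with too few
    reads in a cluster the sample is flagged ``unphased`` for this amplicon.
    """
    pass_calls = sorted(
        (c for c in calls if c.filter == FILTER_PASS), key=lambda c: (c.pos, c.alt)
    )
    loci = [c.key for c in pass_calls]
    het_idx = [i for i, c in enumerate(pass_calls) if c.is_het]

    base = np.zeros(len(loci), dtype=np.int8)
    for i, c in enumerate(pass_calls):
        if c.genotype == "1/1":
            base[i] = 1

    def mk(idx: int, alleles: np.ndarray, support: int, flags: tuple[str, ...]) -> PhasedHaplotype:
        return PhasedHaplotype(sample_id, amplicon.id, idx, list(loci), alleles, support, flags)

    if not het_idx:
        flags = ("no_het_sites",)
        n = len(observations)
        return mk(1, base.copy(), n, flags), mk(2, base.copy(), n, flags), None

    # reads x het sites matrix in amplicon-local keys
    local_keys = []
    for i in het_idx:
        c = pass_calls[i]
        local_keys.append(variant_key("", c.pos - amplicon.start, c.ref, c.alt))
    M = np.full((len(observations), len(het_idx)), MISSING, dtype=np.int8)
    for r, obs in enumerate(observations):
        s, e = obs.covered
        for j, (i, lk) in enumerate(zip(het_idx, local_keys)):
            pos = pass_calls[i].pos - amplicon.start
            if lk in obs.variants:
                M[r, j] = 1
            elif s <= pos < e:
                M[r, j] = 0
    informative = np.flatnonzero((M != MISSING).any(axis=1))
    result = cluster_reads_by_hets(M[informative], min_reads_per_cluster=min_reads_per_cluster)

    flags: tuple[str, ...] = () if result.phased else ("unphased",)
    haps = []
    for k in (0, 1):
        alleles = base.copy()
        for j, i in enumerate(het_idx):
            alleles[i] = result.consensus[k, j]
        haps.append(mk(k + 1, alleles, result.cluster_sizes[k], flags))
    return haps[0], haps[1], result


# ---------------------------------------------------------------------------
# Paralog assignment and gene conversion
# ---------------------------------------------------------------------------

def assign_paralog(
    variant: VariantCall,
    amplicon: Amplicon,
    other_calls: list[VariantCall] | None = None,
) -> list[str]:
    """Label(s) of the annotated gene/unit interval(s) containing a variant.

    With ``other_calls`` supplied and the amplicon annotated with a paralog
    pair (two equal-length units), a variant whose homologous twin — same
    ref/alt at the same unit-relative offset of the other unit — was also
    called is reported in both genes.
    """
    containing = [g for g in amplicon.genes if g.start <= variant.pos < g.end]
    if not containing:
        return ["intergenic"]
    labels = [g.id for g in containing]
    units = [g for g in amplicon.genes if (g.end - g.start) == (amplicon.genes[0].end - amplicon.genes[0].start)]
    if other_calls is not None and len(amplicon.genes) == 2:
        g1, g2 = amplicon.genes
        if g1.end - g1.start == g2.end - g2.start:
            home = containing[0]
            other = g2 if home.id == g1.id else g1
            offset = variant.pos - home.start
            twin_pos = other.start + offset
            for c in other_calls:
                if (
                    c.filter == FILTER_PASS
                    and c.pos == twin_pos
                    and c.ref == variant.ref
                    and c.alt == variant.alt
                ):
                    return sorted({home.id, other.id})
    return labels


@dataclass
class ConversionCall:
    """A gene-conversion tract: a run of diagnostic sites carrying the donor allele."""

    amplicon_id: str
    haplotype_index: int
    tract_start: int  # contig coords, first switched diagnostic site
    tract_end: int  # one past the last switched diagnostic site
    n_diagnostic_switched: int
    donor_paralog: str


def unit_diagnostics(
    pair: ParalogPair, unit: str
) -> list[tuple[int, str, str]]:
    """Diagnostic sites for one unit as (contig position, own allele, donor allele)."""
    base_a, base_b = pair.unit_a[0], pair.unit_b[0]
    out = []
    for off, allele_a, allele_b in pair.diagnostic_positions:
        if unit == "a":
            out.append((base_a + off, allele_a, allele_b))
        else:
            out.append((base_b + off, allele_b, allele_a))
    return out


def detect_conversion(
    haplotype: PhasedHaplotype,
    diagnostic_positions: list[tuple[int, str, str]],
    min_run: int = 3,
    contig: str = "",
    donor_label: str = "",
) -> list[ConversionCall]:
    """Report maximal runs of >= ``min_run`` diagnostic sites switched to the donor allele.

    A haplotype is "switched" at a diagnostic site when it carries the
    variant own-allele -> donor-allele there. Isolated switched sites below
    the run threshold are treated as point variants, not conversion. Tract
    bounds are the outermost switched diagnostic positions; true bounds are
    only resolvable to within the flanking inter-diagnostic intervals.
    """
    carried = haplotype.carried_keys()
    switched = [
        (pos, variant_key(contig, pos, own, donor) in carried)
        for pos, own, donor in diagnostic_positions
    ]
    calls: list[ConversionCall] = []
    run: list[int] = []
    for pos, sw in switched + [(-1, False)]:
        if sw:
            run.append(pos)
        else:
            if len(run) >= min_run:
                calls.append(
                    ConversionCall(
                        haplotype.amplicon_id,
                        haplotype.haplotype_index,
                        run[0],
                        run[-1] + 1,
                        len(run),
                        donor_label,
                    )
                )
            run = []
    return calls
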
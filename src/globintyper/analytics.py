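"""Population haplotype analytics: 0/1 matrix, haplogroups, LD, TFBS scan.

Phased per-amplicon haplotypes across a cohort form a matrix with one row
per haplotype (two per phased sample) and one 0/1 column per variant locus.
Rows are de-duplicated and hierarchically clustered (Pearson-correlation
distance, complete linkage — the same scheme the heatmap tooling of the
field applies to such matrices) into haplogroups labelled Hap_s1, Hap_s2,
... by descending size. Linkage disequilibrium is computed directly from
phased haplotype counts, and variants are screened for created/destroyed
binding motifs of five key erythroid regulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage as _linkage
from scipy.spatial.distance import squareform

from .panel import revcomp
from .phasing import PhasedHaplotype

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeMatrix:
    """Rows = haplotypes (sample, hap index), columns = variant loci, cells 0/1."""

    df: pd.DataFrame  # MultiIndex rows (sample_id, hap); columns variant keys
    excluded_samples: list[str] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return len(self.df)

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=np.int8)


def build_matrix(
    phased_haplotypes: dict[str, tuple[PhasedHaplotype, PhasedHaplotype]],
    region: str | None = None,
    drop_monomorphic: bool = True,
) -> HaplotypeMatrix:
    """Assemble the population 0/1 haplotype matrix for one amplicon.

    Samples flagged unphased for the region are excluded (and counted);
    columns are the union of variant loci over included haplotypes, ordered
    by position. Columns with no alternate allele in the population are
    dropped by default — every retained locus segregates.
    """
    rows = {}
    excluded = []
    for sid, (h1, h2) in sorted(phased_haplotypes.items()):
        if region is not None and h1.amplicon_id != region:
            continue
        if "unphased" in h1.flags:
            excluded.append(sid)
            continue
        for h in (h1, h2):
            rows[(sid, h.haplotype_index)] = dict(zip(h.loci, (int(a) for a in h.alleles)))
    if excluded:
        logger.info("build_matrix: excluded %d unphased samples", len(excluded))
    all_loci = sorted(
        {k for r in rows.values() for k in r},
        key=lambda k: (k.split(":")[0], int(k.split(":")[1])),
    )
    data = np.zeros((len(rows), len(all_loci)), dtype=np.int8)
    col = {k: j for j, k in enumerate(all_loci)}
    for i, (key, alleles) in enumerate(rows.items()):
        for k, a in alleles.items():
            data[i, col[k]] = a
    df = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(list(rows.keys()), names=["sample_id", "hap"]),
        columns=all_loci,
    )
    if drop_monomorphic and len(df.columns):
        df = df.loc[:, df.sum(axis=0) > 0]
    return HaplotypeMatrix(df, excluded)


@dataclass
class Haplogroup:
    label: str  # Hap_s1 is the largest
    member_ids: list[tuple[str, int]]  # (sample_id, hap index)
    consensus: np.ndarray
    size: int


def pearson_distance_matrix(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; undefined pairs set to the maximum (2.0)."""
    X = np.asarray(X, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    D = 1.0 - C
    bad = ~np.isfinite(D)
    if bad.any():
        logger.warning(
            "pearson distance undefined for %d pairs (constant rows); set to maximum",
            int(bad.sum() - np.isnan(np.diag(D)).sum()),
        )
        D[bad] = 2.0
    np.fill_diagonal(D, 0.0)
    # guard tiny negative values from float error
    D[D < 0] = 0.0
    return D


def choose_k_by_gap(Z: np.ndarray, k_max: int = 8) -> int:
    """Pick the group count with the largest relative merge-height gap.

    Cutting an n-leaf dendrogram into k groups removes the k-1 highest
    merges; the preferred k maximizes (h[n-k] - h[n-k-1]) / h[n-k] over
    k = 2..k_max, i.e. the biggest relative jump between successive merge
    heights.
    """
    n = Z.shape[0] + 1
    h = Z[:, 2]
    best_k, best_gap = 2, -1.0
    for k in range(2, min(k_max, n - 1) + 1):
        top = h[n - k]  # height of the merge that would reduce k to k-1 groups
        below = h[n - k - 1] if n - k - 1 >= 0 else 0.0
        gap = (top - below) / top if top > 0 else 0.0
        if gap > best_gap:
            best_k, best_gap = k, gap
    return best_k


def dedup_and_cluster(
    matrix: HaplotypeMatrix,
    linkage: str = "complete",
    distance: str = "pearson",
    k: int | None = None,
    k_max: int = 8,
) -> tuple[pd.DataFrame, list[Haplogroup], np.ndarray]:
    """De-duplicate haplotype rows and cluster the unique rows into haplogroups.

    Exact-duplicate rows are collapsed with multiplicity; unique rows are
    clustered by agglomerative ``linkage`` on 1 - Pearson correlation (or
    Hamming, ``distance='hamming'``). Group count is ``k`` when given, else
    chosen by the largest relative merge-height gap. Groups are mapped back
    to all haplotypes and labelled Hap_s1, Hap_s2, ... by descending total
    (redundant) membership. Returns (unique-haplotype table with
    multiplicity, haplogroups, per-row group labels aligned to matrix rows).
    """
    X = matrix.values()
    uniq, inverse, counts = np.unique(X, axis=0, return_inverse=True, return_counts=True)
    n_unique = uniq.shape[0]
    uniq_df = pd.DataFrame(uniq, columns=matrix.df.columns)
    uniq_df.insert(0, "multiplicity", counts)
    if n_unique < 2:
        groups = [
            Haplogroup("Hap_s1", list(matrix.df.index), uniq[0] if n_unique else np.array([]), len(X))
        ]
        return uniq_df, groups, np.zeros(len(X), dtype=int)

    if distance == "pearson":
        D = pearson_distance_matrix(uniq)
    elif distance == "hamming":
        D = (uniq[:, None, :] != uniq[None, :, :]).mean(axis=2).astype(float)
        np.fill_diagonal(D, 0.0)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Z = _linkage(squareform(D, checks=False), method=linkage)
    kk = k if k is not None else choose_k_by_gap(Z, k_max=k_max)
    kk = min(kk, n_unique)
    uniq_labels = cut_tree(Z, n_clusters=kk).ravel()
    row_labels = uniq_labels[inverse]

    # relabel by descending redundant size; ties by first appearance
    sizes = pd.Series(row_labels).value_counts()
    order = list(sizes.sort_values(ascending=False).index)
    remap = {old: new for new, old in enumerate(order)}
    row_groups = np.array([remap[l] for l in row_labels])
    groups = []
    index = list(matrix.df.index)
    for g in range(len(order)):
        members = [index[i] for i in np.flatnonzero(row_groups == g)]
        member_rows = X[row_groups == g]
        consensus = (member_rows.mean(axis=0) >= 0.5).astype(np.int8)
        groups.append(Haplogroup(f"Hap_s{g + 1}", members, consensus, len(members)))
    return uniq_df, groups, row_groups


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    r2: pd.DataFrame
    dprime: pd.DataFrame
    excluded_loci: list[str]


def compute_ld(matrix: HaplotypeMatrix, maf_min: float = 0.01) -> LDResult:
    """Pairwise r-squared and D' from phased haplotype counts.

    For loci A, B with alt-allele frequencies p_A, p_B and joint alt-alt
    frequency p_AB: D = p_AB - p_A p_B; r2 = D^2 / (p_A (1-p_A) p_B (1-p_B));
    D' = D / D_max. Loci with minor allele frequency below ``maf_min`` are
    excluded and recorded.
    """
    X = matrix.values().astype(float)
    freqs = X.mean(axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    keep = maf >= maf_min
    excluded = [c for c, k in zip(matrix.df.columns, keep) if not k]
    X = X[:, keep]
    cols = [c for c, k in zip(matrix.df.columns, keep) if k]
    n = X.shape[0]
    p = X.mean(axis=0)
    pab = (X.T @ X) / n
    D = pab - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, D**2 / denom, np.nan)
    # D_max for D>=0 is min(p_A(1-p_B), (1-p_A)p_B)
    dmax_pos = np.minimum(p[:, None] * (1 - p)[None, :], (1 - p)[:, None] * p[None, :])
    dmax_neg = np.minimum(p[:, None] * p[None, :], (1 - p)[:, None] * (1 - p)[None, :])
    dmax = np.where(D >= 0, dmax_pos, dmax_neg)
    with np.errstate(invalid="ignore", divide="ignore"):
        dprime = np.where(dmax > 0, np.abs(D) / dmax, np.nan)
    np.fill_diagonal(r2, 1.0)
    np.fill_diagonal(dprime, 1.0)
    return LDResult(
        pd.DataFrame(r2, index=cols, columns=cols),
        pd.DataFrame(dprime, index=cols, columns=cols),
        excluded,
    )


def ld_blocks(r2: pd.DataFrame, r2_threshold: float = 0.8) -> list[list[str]]:
    """Maximal runs of consecutive loci whose pairwise r2 all reach the threshold."""
    cols = list(r2.columns)
    R = r2.to_numpy()
    blocks: list[list[str]] = []
    i = 0
    n = len(cols)
    while i < n:
        j = i
        while j + 1 < n and np.all(R[i : j + 2, i : j + 2] >= r2_threshold):
            j += 1
        if j > i:
            blocks.append(cols[i : j + 1])
            i = j + 1
        else:
            i += 1
    return blocks


# ---------------------------------------------------------------------------
# TFBS scan
# ---------------------------------------------------------------------------

#: IUPAC consensus motifs of the five key erythroid regulators screened here.
#: Consensi follow the commonly used literature forms: GATA1 WGATAR; the
#: KLF1 CACCC-box 9-mer; the NF-Y CCAAT box; the TAL1/SCL E-box; and the
#: BCL11A TGACCA half-site.
ERYTHROID_MOTIFS: dict[str, str] = {
    "GATA1": "WGATAR",
    "KLF1": "CCMCRCCCN",
    "NFY": "CCAAT",
    "TAL1": "CANNTG",
    "BCL11A": "TGACCA",
}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match(seq: str, motif: str) -> bool:
    if len(seq) != len(motif):
        return False
    return all(b in _IUPAC[m] for b, m in zip(seq, motif))


@dataclass
class MotifHit:
    variant_key: str
    factor: str
    window_start: int  # contig coords
    window_end: int
    effect: str  # created | destroyed
    strand: str  # + | -


def scan_tfbs(
    region_seq: str,
    variants,
    motif_set: dict[str, str] | None = None,
    region_offset: int = 0,
) -> list[MotifHit]:
    """Screen SNVs for erythroid-regulator binding sites created or destroyed.

    For every variant and motif, each window overlapping the variant is
    tested on both strands with the reference and the alternate base: a
    window matching the consensus with ref but not alt is a destroyed site;
    the converse is a created site. Variants whose window would run past the
    region edge, and non-SNV variants, are skipped (logged).
    """
    motifs = ERYTHROID_MOTIFS if motif_set is None else motif_set
    hits: list[MotifHit] = []
    for v in variants:
        pos, ref, alt = v.pos - region_offset, v.ref, v.alt
        if len(ref) != 1 or len(alt) != 1:
            logger.debug("scan_tfbs: skipping non-SNV %s", getattr(v, "key", v))
            continue
        for factor, motif in motifs.items():
            m = len(motif)
            for w0 in range(pos - m + 1, pos + 1):
                if w0 < 0 or w0 + m > len(region_seq):
                    logger.debug("scan_tfbs: window off region edge at %d", w0)
                    continue
                refwin = region_seq[w0 : w0 + m]
                if refwin[pos - w0] != ref:
                    continue
                altwin = refwin[: pos - w0] + alt + refwin[pos - w0 + 1 :]
                for strand, rw, aw in (("+", refwin, altwin), ("-", revcomp(refwin), revcomp(altwin))):
                    ref_hit = iupac_match(rw, motif)
                    alt_hit = iupac_match(aw, motif)
                    if ref_hit == alt_hit:
                        continue
                    hits.append(
                        MotifHit(
                            getattr(v, "key", str(v)),
                            factor,
                            region_offset + w0,
                            region_offset + w0 + m,
                            "destroyed" if ref_hit else "created",
                            strand,
                        )
                    )
    return hits
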
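"""Haplotype matrix, haplogroup clustering, LD and the TFBS screen."""

import numpy as np
import pandas as pd
import pytest

from globintyper import (
    build_matrix,
    compute_ld,
    dedup_and_cluster,
    ld_blocks,
    scan_tfbs,
)
from globintyper.analytics import HaplotypeMatrix
from globintyper.phasing import PhasedHaplotype
from globintyper.smallvar import VariantCall


def _hap(sid, idx, loci, alleles, amp="HBG", flags=()):
    return PhasedHaplotype(sid, amp, idx, list(loci), np.array(alleles, dtype=np.int8), 20, flags)


def _matrix(rows, loci=None, prefix="S"):
    rows = np.asarray(rows, dtype=np.int8)
    loci = loci or [f"gamma:{100 * (j + 1)}:A>C" for j in range(rows.shape[1])]
    index = pd.MultiIndex.from_tuples(
        [(f"{prefix}{i // 2}", i % 2 + 1) for i in range(len(rows))],
        names=["sample_id", "hap"],
    )
    return HaplotypeMatrix(pd.DataFrame(rows, index=index, columns=loci))


class TestBuildMatrix:
    LOCI = ["gamma:500:A>C", "gamma:900:G>T"]

    def test_two_rows_per_phased_sample(self):
        phased = {
            f"S{i}": (
                _hap(f"S{i}", 1, self.LOCI, [1, 0]),
                _hap(f"S{i}", 2, self.LOCI, [0, 1]),
            )
            for i in range(3)
        }
        m = build_matrix(phased, region="HBG")
        assert m.n_haplotypes == 6
        assert list(m.df.columns) == self.LOCI

    def test_unphased_samples_excluded_and_counted(self):
        phased = {
            "S0": (_hap("S0", 1, self.LOCI, [1, 0]), _hap("S0", 2, self.LOCI, [0, 1])),
            "S1": (
                _hap("S1", 1, self.LOCI, [1, 0], flags=("unphased",)),
                _hap("S1", 2, self.LOCI, [0, 1], flags=("unphased",)),
            ),
        }
        m = build_matrix(phased, region="HBG")
        assert m.n_haplotypes == 2 and m.excluded_samples == ["S1"]

    def test_identical_haplotypes_give_identical_rows(self):
        phased = {"S0": (_hap("S0", 1, self.LOCI, [1, 1]), _hap("S0", 2, self.LOCI, [1, 1]))}
        m = build_matrix(phased, region="HBG")
        assert np.array_equal(m.values()[0], m.values()[1])


def brute_force_complete_linkage(D):
    """Hand agglomeration oracle: returns merge order as frozensets."""
    clusters = [frozenset([i]) for i in range(len(D))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(D[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((frozenset(clusters[i]), frozenset(clusters[j]), d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


class TestDedupAndCluster:
    def test_identical_rows_collapse_to_one_group(self):
        m = _matrix([[1, 0, 1]] * 8)
        uniq, groups, labels = dedup_and_cluster(m)
        assert len(uniq) == 1 and uniq["multiplicity"].iloc[0] == 8
        assert len(groups) == 1 and groups[0].size == 8

    def test_dedup_preserves_total_multiplicity(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 2, size=(60, 5))
        m = _matrix(rows)
        uniq, groups, labels = dedup_and_cluster(m)
        assert uniq["multiplicity"].sum() == 60
        assert sum(g.size for g in groups) == 60

    def test_planted_clades_recovered_exactly(self):
        # three founder haplotypes with small mutation noise -> ARI == 1
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(5)
        founders = np.zeros((3, 12), np.int8)
        founders[0, :5] = 1
        founders[1, 5:9] = 1
        founders[2, 9:] = 1
        rows, truth = [], []
        for _ in range(300):
            f = int(rng.integers(0, 3))
            r = founders[f].copy()
            flip = rng.random(12) < 0.02
            r[flip] ^= 1
            rows.append(r)
            truth.append(f)
        m = _matrix(np.array(rows))
        _, groups, labels = dedup_and_cluster(m)
        assert len(groups) == 3
        assert adjusted_rand_score(truth, labels) == 1.0
        # labels ordered by descending size: Hap_s1 is the largest
        sizes = [g.size for g in groups]
        assert sizes == sorted(sizes, reverse=True)

    def test_merge_order_matches_brute_force_oracle(self):
        # hand-computable toy matrix: verify the dendrogram against an
        # exhaustive complete-linkage agglomeration
        from scipy.cluster.hierarchy import linkage as sp_linkage
        from scipy.spatial.distance import squareform

        from globintyper.analytics import pearson_distance_matrix

        rows = np.array(
            [[1, 0, 0], [1, 1, 0], [0, 0, 1], [0, 1, 1]], dtype=np.int8
        )
        D = pearson_distance_matrix(rows)
        Z = sp_linkage(squareform(D, checks=False), method="complete")
        oracle = brute_force_complete_linkage(D)
        # same sequence of merge heights
        assert np.allclose(sorted(Z[:, 2]), sorted(m[2] for m in oracle))

    def test_clustering_invariant_to_row_permutation(self):
        rng = np.random.default_rng(7)
        rows = np.vstack([
            np.tile([1, 1, 0, 0, 0], (10, 1)),
            np.tile([0, 0, 1, 1, 0], (8, 1)),
            np.tile([0, 0, 0, 0, 1], (6, 1)),
        ])
        m1 = _matrix(rows)
        perm = rng.permutation(len(rows))
        m2 = HaplotypeMatrix(m1.df.iloc[perm])
        _, g1, l1 = dedup_and_cluster(m1)
        _, g2, l2 = dedup_and_cluster(m2)
        as_sets = lambda gs: {frozenset(g.member_ids) for g in gs}
        assert as_sets(g1) == as_sets(g2)

    def test_explicit_k_override(self):
        rng = np.random.default_rng(9)
        rows = rng.integers(0, 2, size=(40, 6))
        m = _matrix(rows)
        _, groups, _ = dedup_and_cluster(m, k=4)
        assert len(groups) == 4


def brute_force_r2(X, i, j):
    """r2 by direct haplotype counting."""
    n = len(X)
    pa, pb = X[:, i].mean(), X[:, j].mean()
    pab = ((X[:, i] == 1) & (X[:, j] == 1)).mean()
    D = pab - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    return D * D / denom


class TestLD:
    def test_duplicated_column_in_perfect_ld(self):
        rng = np.random.default_rng(11)
        col = rng.integers(0, 2, size=50)
        m = _matrix(np.column_stack([col, col, 1 - col]))
        ld = compute_ld(m, maf_min=0.0)
        assert ld.r2.iloc[0, 1] == pytest.approx(1.0)
        assert ld.r2.iloc[0, 2] == pytest.approx(1.0)  # complement is also perfect LD

    def test_worked_two_locus_example(self):
        # haplotype counts AB=40, ab=40, Ab=10, aB=10 (alt allele = "A"/"B")
        rows = (
            [[1, 1]] * 40 + [[0, 0]] * 40 + [[1, 0]] * 10 + [[0, 1]] * 10
        )
        m = _matrix(np.array(rows))
        ld = compute_ld(m, maf_min=0.0)
        # direct evaluation: p_A = p_B = 0.5, p_AB = 0.4 -> D = 0.15, r2 = 0.36
        assert ld.r2.iloc[0, 1] == pytest.approx(0.36)
        assert ld.dprime.iloc[0, 1] == pytest.approx(0.6)

    def test_matches_brute_force_counting_oracle(self):
        rng = np.random.default_rng(13)
        X = rng.integers(0, 2, size=(200, 12))
        m = _matrix(X)
        ld = compute_ld(m, maf_min=0.0)
        for i in range(12):
            for j in range(12):
                if i != j:
                    assert ld.r2.iloc[i, j] == pytest.approx(brute_force_r2(X, i, j))

    def test_independent_loci_have_low_r2(self):
        rng = np.random.default_rng(15)
        X = (rng.random((2000, 10)) < 0.3).astype(np.int8)
        m = _matrix(X)
        ld = compute_ld(m)
        off = ld.r2.to_numpy()[~np.eye(10, dtype=bool)]
        assert np.all(off < 0.05)
        # E[r2] under independence is on the 1/(2n) scale
        assert off.mean() < 10 / 2000

    def test_maf_filter_excludes_rare_loci(self):
        rows = np.zeros((100, 2), dtype=np.int8)
        rows[:50, 0] = 1
        rows[0, 1] = 1  # MAF 0.01 locus
        m = _matrix(rows)
        ld = compute_ld(m, maf_min=0.05)
        assert len(ld.excluded_loci) == 1 and ld.r2.shape == (1, 1)

    def test_blocks_are_maximal_high_ld_runs(self):
        rng = np.random.default_rng(17)
        col1 = rng.integers(0, 2, size=400)
        col2 = rng.integers(0, 2, size=400)
        X = np.column_stack([col1, col1, col1, col2, col2])
        m = _matrix(X)
        ld = compute_ld(m, maf_min=0.0)
        blocks = ld_blocks(ld.r2, r2_threshold=0.8)
        assert [len(b) for b in blocks] == [3, 2]


class TestScanTFBS:
    def _variant(self, seq, pos, alt):
        return VariantCall("c", pos, seq[pos], alt, "0/1", 0.5, 40, 20, "PASS")

    def test_variant_outside_motif_windows_no_hit(self):
        seq = "TTTTTTTTTTTTTTTTTTTTTTTT"
        v = self._variant(seq, 12, "G")
        hits = scan_tfbs(seq, [v], motif_set={"GATA1": "WGATAR"})
        assert hits == []

    def test_gata1_site_destroyed_by_final_base_change(self):
        seq = "CCCCCC" + "TGATAA" + "CCCCCC"  # WGATAR match at offset 6
        v = self._variant(seq, 11, "C")  # final A -> C breaks the consensus
        hits = scan_tfbs(seq, [v], motif_set={"GATA1": "WGATAR"})
        assert any(h.effect == "destroyed" and h.factor == "GATA1" for h in hits)
        h = [x for x in hits if x.effect == "destroyed"][0]
        assert h.window_start <= 11 < h.window_end

    def test_site_created_by_variant(self):
        seq = "CCCCCC" + "TGATCA" + "CCCCCC"  # one base off the consensus
        v = self._variant(seq, 10, "A")  # TGATCA -> TGATAA matches WGATAR
        hits = scan_tfbs(seq, [v], motif_set={"GATA1": "WGATAR"})
        assert any(h.effect == "created" for h in hits)

    def test_reverse_strand_motif_reported_on_minus(self):
        from globintyper import revcomp

        site = "TGATAA"
        seq = "GGGGGG" + revcomp(site) + "GGGGGG"
        pos = 6 + 1  # inside the reverse-complemented site
        ref = seq[pos]
        # breaking the site on the minus strand
        alt = [b for b in "ACGT" if b != ref][0]
        hits = scan_tfbs(seq, [self._variant(seq, pos, alt)], motif_set={"GATA1": "WGATAR"})
        minus = [h for h in hits if h.strand == "-"]
        assert minus and all(h.factor == "GATA1" for h in minus)

    def test_edge_variant_skipped(self):
        seq = "TGATAA"
        v = self._variant(seq, 0, "C")
        # windows would run past the region edge on one side; no crash
        hits = scan_tfbs(seq, [v], motif_set={"GATA1": "WGATAR"})
        assert all(0 <= h.window_start for h in hits)
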
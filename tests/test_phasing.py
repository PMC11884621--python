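"""MEC phasing, paralog assignment and conversion detection."""

from itertools import product as iterproduct

import numpy as np
import pytest

from globintyper import (
    cluster_reads_by_hets,
    detect_conversion,
    assign_paralog,
    unit_diagnostics,
)
from globintyper.phasing import MISSING, phase_sample_amplicon
from globintyper.smallvar import FILTER_PASS, VariantCall, ReadObservation
from globintyper.varutils import variant_key


def brute_force_mec(M: np.ndarray) -> int:
    """Exhaustive bipartition oracle: minimum error-correction cost."""
    R, S = M.shape
    best = None
    for bits in iterproduct([0, 1], repeat=R):
        labels = np.array(bits)
        cost = 0
        for k in (0, 1):
            sub = M[labels == k]
            for j in range(S):
                col = sub[:, j]
                col = col[col != MISSING]
                ones = int((col == 1).sum())
                zeros = len(col) - ones
                cost += min(ones, zeros)
        if best is None or cost < best:
            best = cost
    return best


class TestMECClustering:
    def test_equals_brute_force_on_small_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(40):
            R = int(rng.integers(2, 9))
            S = int(rng.integers(1, 7))
            M = rng.integers(0, 2, size=(R, S)).astype(np.int8)
            # sprinkle missing entries
            mask = rng.random((R, S)) < 0.1
            M[mask] = MISSING
            res = cluster_reads_by_hets(M, min_reads_per_cluster=1)
            assert res.cost == brute_force_mec(M), f"trial {trial}"

    def test_greedy_matches_exact_on_clean_instances(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            S = int(rng.integers(2, 6))
            h1 = rng.integers(0, 2, size=S).astype(np.int8)
            h2 = (1 - h1).astype(np.int8)
            reads = np.vstack([h1] * 6 + [h2] * 6)
            flip = rng.random(reads.shape) < 0.05
            reads = np.where(flip, 1 - reads, reads).astype(np.int8)
            exact = cluster_reads_by_hets(reads, method="exact", min_reads_per_cluster=1)
            greedy = cluster_reads_by_hets(reads, method="greedy", min_reads_per_cluster=1)
            assert greedy.cost == exact.cost

    def test_perfect_partition_of_error_free_reads(self):
        rng = np.random.default_rng(2)
        h1 = np.array([0, 1, 0], dtype=np.int8)
        h2 = np.array([1, 0, 1], dtype=np.int8)
        order = rng.permutation(40)
        M = np.vstack([h1] * 20 + [h2] * 20)[order]
        res = cluster_reads_by_hets(M)
        assert res.cost == 0 and res.phased
        assert res.cluster_sizes == (20, 20)
        # truth labels recovered up to cluster swap
        truth = (order >= 20).astype(int)
        agree = (res.labels == truth).mean()
        assert agree in (0.0, 1.0)

    def test_switch_error_zero_across_simulated_samples(self):
        # 5 het sites, depth 50, 1% allele-flip noise, 100 samples
        rng = np.random.default_rng(3)
        for _ in range(100):
            h1 = rng.integers(0, 2, size=5).astype(np.int8)
            h2 = (1 - h1).astype(np.int8)
            reads = np.vstack([h1] * 25 + [h2] * 25)
            flip = rng.random(reads.shape) < 0.01
            reads = np.where(flip, 1 - reads, reads).astype(np.int8)
            res = cluster_reads_by_hets(reads)
            got = {tuple(res.consensus[0]), tuple(res.consensus[1])}
            assert got == {tuple(h1), tuple(h2)}

    def test_output_invariant_to_read_order(self):
        rng = np.random.default_rng(4)
        M = rng.integers(0, 2, size=(30, 4)).astype(np.int8)
        res1 = cluster_reads_by_hets(M)
        perm = rng.permutation(30)
        res2 = cluster_reads_by_hets(M[perm])
        assert np.array_equal(res1.consensus, res2.consensus)
        assert res1.cost == res2.cost

    def test_haplotypes_differ_at_every_het_site(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            M = rng.integers(0, 2, size=(12, 5)).astype(np.int8)
            res = cluster_reads_by_hets(M, min_reads_per_cluster=1)
            assert np.all(res.consensus[0] != res.consensus[1])


class TestPhaseSampleAmplicon:
    def _call(self, amp, local_pos, genotype, ref="A", alt="C"):
        return VariantCall(
            amp.contig, amp.start + local_pos, ref, alt, genotype, 0.5, 40, 20, FILTER_PASS
        )

    def test_homozygous_sample_flagged_no_het_sites(self, panel):
        amp = panel.get("MOD")
        calls = [self._call(amp, 500, "1/1")]
        obs = [ReadObservation(f"r{i}", {}, (0, amp.expected_length)) for i in range(30)]
        h1, h2, res = phase_sample_amplicon(calls, obs, amp, "s")
        assert "no_het_sites" in h1.flags and res is None
        assert np.array_equal(h1.alleles, h2.alleles)
        assert h1.alleles.tolist() == [1]

    def test_perfect_phasing_from_reads(self, panel, mini):
        amp = panel.get("MOD")
        ref = mini.contigs[amp.contig][amp.start : amp.end]
        sites = [400, 900, 1400]
        calls = [self._call(amp, p, "0/1", ref=ref[p]) for p in sites]
        keys = [variant_key("", p, ref[p], "C") for p in sites]
        obs = []
        for i in range(20):  # hap1 carries all three alts
            obs.append(ReadObservation(f"a{i}", {k: (p, ref[p], "C") for k, p in zip(keys, sites)}, (0, len(ref))))
        for i in range(20):
            obs.append(ReadObservation(f"b{i}", {}, (0, len(ref))))
        h1, h2, res = phase_sample_amplicon(calls, obs, amp, "s")
        assert res.cost == 0 and res.phased
        assert {tuple(h1.alleles), tuple(h2.alleles)} == {(0, 0, 0), (1, 1, 1)}

    def test_thin_cluster_flagged_unphased(self, panel, mini):
        amp = panel.get("MOD")
        ref = mini.contigs[amp.contig][amp.start : amp.end]
        p = 700
        calls = [self._call(amp, p, "0/1", ref=ref[p])]
        key = variant_key("", p, ref[p], "C")
        obs = [ReadObservation(f"a{i}", {key: (p, ref[p], "C")}, (0, len(ref))) for i in range(2)]
        obs += [ReadObservation(f"b{i}", {}, (0, len(ref))) for i in range(28)]
        h1, h2, res = phase_sample_amplicon(calls, obs, amp, "s", min_reads_per_cluster=3)
        assert not res.phased and "unphased" in h1.flags


class TestAssignParalog:
    def _vc(self, amp, pos, ref="A", alt="C"):
        return VariantCall(amp.contig, pos, ref, alt, "0/1", 0.5, 40, 20, FILTER_PASS)

    def test_unit_containment(self, panel):
        amp = panel.get("HBA")
        g2, g1 = amp.genes  # HBA2 (unit a), HBA1 (unit b)
        assert assign_paralog(self._vc(amp, g2.start + 100), amp) == ["HBA2"]
        assert assign_paralog(self._vc(amp, g1.start + 100), amp) == ["HBA1"]

    def test_spacer_variant_is_intergenic(self, panel):
        amp = panel.get("HBA")
        g2, g1 = amp.genes
        spacer_pos = g2.end + 10
        assert spacer_pos < g1.start
        assert assign_paralog(self._vc(amp, spacer_pos), amp) == ["intergenic"]

    def test_homologous_twin_reported_in_both_genes(self, panel, catalog):
        amp = panel.get("HBA")
        a2 = catalog.get("hba2_c369")
        a1 = catalog.get("hba1_c369")
        assert a1.pos - amp.genes[1].start == a2.pos - amp.genes[0].start  # same offset
        c2 = self._vc(amp, a2.pos, a2.ref, a2.alt)
        c1 = self._vc(amp, a1.pos, a1.ref, a1.alt)
        assert assign_paralog(c2, amp, other_calls=[c1, c2]) == ["HBA1", "HBA2"]
        # without the twin call: single-unit label
        assert assign_paralog(c2, amp, other_calls=[c2]) == ["HBA2"]


class TestDetectConversion:
    def _hap(self, amp, carried_keys, loci):
        from globintyper.phasing import PhasedHaplotype

        alleles = np.array([1 if k in carried_keys else 0 for k in loci], dtype=np.int8)
        return PhasedHaplotype("s", amp.id, 1, list(loci), alleles, 20)

    def test_unswitched_haplotype_yields_no_call(self, panel, mini):
        amp = panel.get("HBG")
        pair = mini.pair_for("gamma")
        diags = unit_diagnostics(pair, "b")
        hap = self._hap(amp, set(), [])
        assert detect_conversion(hap, diags, contig="gamma", donor_label="HBG2") == []

    def test_six_site_tract_reported_once(self, panel, mini):
        amp = panel.get("HBG")
        pair = mini.pair_for("gamma")
        diags = unit_diagnostics(pair, "b")
        keys = [variant_key("gamma", pos, own, donor) for pos, own, donor in diags[:6]]
        hap = self._hap(amp, set(keys), keys)
        calls = detect_conversion(hap, diags, contig="gamma", donor_label="HBG2")
        assert len(calls) == 1
        c = calls[0]
        assert c.n_diagnostic_switched == 6
        assert c.tract_start == diags[0][0] and c.tract_end == diags[5][0] + 1
        assert c.donor_paralog == "HBG2"

    def test_isolated_switches_below_run_threshold_ignored(self, panel, mini):
        amp = panel.get("HBG")
        pair = mini.pair_for("gamma")
        diags = unit_diagnostics(pair, "b")
        # two isolated switched sites (positions 0 and 5)
        keys = [variant_key("gamma", *diags[0]), variant_key("gamma", *diags[5])]
        hap = self._hap(amp, set(keys), keys)
        assert detect_conversion(hap, diags, min_run=3, contig="gamma") == []

    def test_pipeline_detects_planted_conversion(self, panel, mini, catalog):
        from globintyper import conversion_allele, simulate_ccs_reads
        from globintyper.simulate import apply_events, in_silico_pcr
        from globintyper.pipeline import genotype_sample

        conv = conversion_allele(mini, "gamma", n_sites=6)
        hap2 = dict(mini.contigs)
        hap2["gamma"] = apply_events(mini.contigs["gamma"], [conv])[0]
        sub = panel.subset(["HBG"])
        r0, _ = simulate_ccs_reads(in_silico_pcr(mini.contigs, sub), 20, 0.002, 0, 0, seed=2, read_prefix="a")
        r1, _ = simulate_ccs_reads(in_silico_pcr(hap2, sub), 20, 0.002, 0, 0, seed=3, read_prefix="b")
        res = genotype_sample("CONV", r0 + r1, sub, mini.contigs, catalog, mini=mini)
        assert len(res.conversions) == 1
        c = res.conversions[0]
        assert c.n_diagnostic_switched == 6 and c.donor_paralog == "HBG2"
        # tract bounds within one inter-diagnostic interval of the truth tract
        assert conv.start <= c.tract_start and c.tract_end <= conv.end
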
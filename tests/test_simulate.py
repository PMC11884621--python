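"""Read simulator: event application, in-silico PCR, CCS errors, cohorts."""

import numpy as np
import pytest

from globintyper import (
    AlleleEvent,
    apply_events,
    in_silico_pcr,
    simulate_ccs_reads,
    simulate_cohort,
    revcomp,
)
from globintyper.simulate import write_fastq


class TestApplyEvents:
    def test_empty_event_list_is_identity(self):
        seq = "ACGTACGTAA"
        out, coord = apply_events(seq, [])
        assert out == seq
        assert list(coord) == list(range(len(seq) + 1))

    def test_single_snv_changes_exactly_one_position(self, mini):
        ref = mini.contigs["mod"]
        ev = AlleleEvent("SNV", "mod", 500, 501, "T" if ref[500] != "T" else "G", name="x")
        out, coord = apply_events(ref, [ev])
        diffs = [i for i, (a, b) in enumerate(zip(ref, out)) if a != b]
        assert diffs == [500]
        assert len(out) == len(ref)

    def test_large_deletion_length_arithmetic(self, mini):
        ref = mini.contigs["gamma"]
        ev = AlleleEvent("large_deletion", "gamma", 1600, 6500, name="d")
        out, coord = apply_events(ref, [ev])
        assert len(out) == len(ref) - 4900
        assert np.all(coord[1600:6500] == -1)
        # unaffected positions map onto identical bases
        assert out[coord[100]] == ref[100]
        assert out[coord[7000]] == ref[7000]

    def test_duplication_and_insertion_lengths(self, mini):
        ref = mini.contigs["mod"]
        dup = AlleleEvent("duplication", "mod", 200, 300, name="dup")
        out, _ = apply_events(ref, [dup])
        assert len(out) == len(ref) + 100
        assert out[200:400] == ref[200:300] * 2
        ins = AlleleEvent("small_indel", "mod", 50, 50, "TTT", name="ins")
        out2, _ = apply_events(ref, [ins])
        assert len(out2) == len(ref) + 3

    def test_overlapping_events_rejected(self, mini):
        ref = mini.contigs["mod"]
        e1 = AlleleEvent("large_deletion", "mod", 100, 2000, name="a")
        e2 = AlleleEvent("SNV", "mod", 500, 501, "A", name="b")
        with pytest.raises(ValueError, match="overlapping"):
            apply_events(ref, [e1, e2])

    def test_conversion_swaps_diagnostic_alleles(self, mini):
        from globintyper import conversion_allele

        ev = conversion_allele(mini, "gamma", n_sites=6)
        pair = mini.pair_for("gamma")
        out, _ = apply_events(mini.contigs["gamma"], [ev])
        switched = 0
        for off, a_allele, b_allele in pair.diagnostic_positions:
            pos = pair.unit_b[0] + off
            if ev.start <= pos < ev.end:
                assert out[pos] == a_allele  # unit B now carries unit A's allele
                switched += 1
        assert switched == 6


class TestInSilicoPCR:
    def test_intact_haplotype_yields_expected_lengths(self, mini, panel):
        products = dict(in_silico_pcr(mini.contigs, panel))
        assert set(products) == {a.id for a in panel.amplicons}
        for a in panel.amplicons:
            assert len(products[a.id]) == a.expected_length

    def test_internal_deletion_shortens_product_exactly(self, mini, panel):
        ev = AlleleEvent("large_deletion", "gamma", 1600, 6500, name="d")
        hap = dict(mini.contigs)
        hap["gamma"] = apply_events(mini.contigs["gamma"], [ev])[0]
        products = dict(in_silico_pcr(hap, panel))
        assert len(products["HBG"]) == panel.get("HBG").expected_length - 4900

    def test_primer_site_loss_drops_amplicon(self, mini, panel, catalog):
        sea = catalog.get("SEA_del").events[0]
        hap = dict(mini.contigs)
        hap["alpha"] = apply_events(mini.contigs["alpha"], [sea])[0]
        products = dict(in_silico_pcr(hap, panel))
        assert "HBA" not in products  # both HBA primer sites removed
        assert len(products["HBA_SPAN"]) == panel.get("HBA_SPAN").expected_length - 8300


class TestCCSReads:
    def test_zero_error_reads_equal_product(self, mini, panel):
        products = in_silico_pcr(mini.contigs, panel.subset(["MOD"]))
        reads, _ = simulate_ccs_reads(products, depth=10, sub_rate=0, ins_rate=0, del_rate=0, seed=1)
        prod = products[0][1]
        assert len(reads) == 10
        for r in reads:
            assert r.seq == prod or revcomp(r.seq) == prod

    def test_substitution_count_within_binomial_bounds(self, mini, panel):
        # product ~8135 bp at sub_rate 0.005 -> ~40.7 subs/read on average
        products = in_silico_pcr(mini.contigs, panel.subset(["HBA"]))
        prod = products[0][1]
        n, rate, n_reads = len(prod), 0.005, 200
        reads, _ = simulate_ccs_reads(products, depth=n_reads, sub_rate=rate, seed=2,
                                      ins_rate=0, del_rate=0)
        subs = []
        for r in reads:
            fwd = sum(a != b for a, b in zip(r.seq, prod))
            rev = sum(a != b for a, b in zip(revcomp(r.seq), prod))
            subs.append(min(fwd, rev))
        mean = np.mean(subs)
        expect = n * rate
        sigma = np.sqrt(n * rate * (1 - rate) / n_reads)
        assert abs(mean - expect) <= 3 * sigma

    def test_fixed_depth_read_count(self, mini, panel):
        products = in_silico_pcr(mini.contigs, panel) + in_silico_pcr(mini.contigs, panel.subset(["MOD"]))
        assert len(products) == 5
        reads, counts = simulate_ccs_reads(products, depth=30, seed=0)
        assert len(reads) == 150
        assert all(c == 30 for _, c in counts)

    def test_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            simulate_ccs_reads([("A", "ACGT" * 100)], depth=5, sub_rate=0.2)


class TestCohort:
    def test_same_seed_byte_identical_fastq(self, tmp_path):
        paths = []
        for i in range(2):
            sim = simulate_cohort(3, seed=9, depth=5, sub_rate=0.004)
            p = tmp_path / f"run{i}.fastq"
            write_fastq([r for rr in sim.reads.values() for r in rr], p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_frequency_one_allele_on_every_haplotype(self):
        freqs = {"mod_bcl11a": 1.0}
        sim = simulate_cohort(10, allele_frequencies=freqs, seed=1,
                              use_founders=False, generate_reads=False)
        for s in sim.truth.samples:
            assert s.catalog_dosage["mod_bcl11a"] == 2

    def test_null_phenotype_independent_of_genotype(self):
        from globintyper.simulate import PhenotypeModel
        import statsmodels.api as sm

        model = PhenotypeModel(hbf_effects={}, survival_loghr={})
        sim = simulate_cohort(400, seed=5, phenotype_model=model, generate_reads=False)
        d = np.array([s.catalog_dosage["mod_bcl11a"] for s in sim.truth.samples], float)
        y = sim.phenotypes["hbf"].to_numpy()
        fit = sm.OLS(y, sm.add_constant(d)).fit()
        lo, hi = fit.conf_int()[1]
        assert lo <= 0 <= hi

    def test_planted_hbf_effect_recovered_from_truth_dosages(self):
        # refit on truth genotypes: beta = 2.0 g/L per allele within 3 SE
        from globintyper.simulate import PhenotypeModel
        import statsmodels.api as sm

        model = PhenotypeModel(hbf_effects={"mod_bcl11a": 2.0}, hbf_sigma=3.0,
                               survival_loghr={})
        freqs = {"mod_bcl11a": 0.2}
        sim = simulate_cohort(500, allele_frequencies=freqs, seed=11,
                              phenotype_model=model, use_founders=False,
                              generate_reads=False)
        d = np.array([s.catalog_dosage["mod_bcl11a"] for s in sim.truth.samples], float)
        y = sim.phenotypes["hbf"].to_numpy()
        fit = sm.OLS(y, sm.add_constant(d)).fit()
        assert abs(fit.params[1] - 2.0) <= 3 * fit.bse[1]

    def test_truth_variants_recoverable_from_mutated_sequence(self):
        # brute-force oracle: every planted SNV is visible at its coordinate-
        # mapped position and nothing else changes (SNV-only haplotypes)
        snv_only = {
            "hba2_c369": 0.5, "hbg_snv3": 0.5, "mod_snv4": 0.5, "mod_bcl11a": 0.5,
        }
        sim = simulate_cohort(6, allele_frequencies=snv_only, seed=13,
                              use_founders=False, generate_reads=False)
        for s in sim.truth.samples:
            for h in range(2):
                by_contig = {}
                for ev in s.hap_events[h]:
                    by_contig.setdefault(ev.contig, []).append(ev)
                for contig, evs in by_contig.items():
                    ref = sim.mini.contigs[contig]
                    out, coord = apply_events(ref, evs)
                    planted = {
                        pos for (c, pos, _r, _a, hh) in s.small_variants
                        if c == contig and hh == h
                    }
                    diffs = {i for i, (a, b) in enumerate(zip(ref, out)) if a != b}
                    assert diffs == planted
                    for (c, pos, r, a, hh) in s.small_variants:
                        if c == contig and hh == h:
                            assert out[coord[pos]] == a and ref[pos] == r

    def test_ensure_het_gives_every_sample_a_het_site(self, panel):
        sim = simulate_cohort(30, seed=17, ensure_het_amplicon="HBG", generate_reads=False)
        amp = panel.get("HBG")
        for s in sim.truth.samples:
            keys = [set(), set()]
            for (c, pos, r, a, h) in s.small_variants:
                if c == amp.contig and amp.start <= pos < amp.end:
                    keys[h].add((pos, r, a))
            assert keys[0] != keys[1]
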
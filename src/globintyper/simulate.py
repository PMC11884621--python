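"""Diploid cohort simulator: thalassemia-like alleles, in-silico PCR, CCS reads.

The generator emulates the data this assay sees: diploid samples over a
small reference with two paralogous globin-like clusters, carrying SNV /
small-indel / large-deletion / duplication / crossover / conversion alleles
at configurable population frequencies; multiplex long-range PCR products
per haplotype; full-length CCS reads with independent per-base errors at
HiFi-like rates; and phenotypes (HbF, transfusion-free survival, ferritin)
generated from an additive genetic model plus noise. Every sample ships
with machine-readable truth so callers can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    MiniReference,
    Panel,
    ParalogPair,
    build_mini_reference,
    default_panel,
    revcomp,
)
from .varutils import decode, encode, left_normalize, sliding_hamming, variant_key

EVENT_KINDS = ("SNV", "small_indel", "large_deletion", "duplication", "crossover", "conversion")


@dataclass(frozen=True)
class AlleleEvent:
    """One mutational event on a reference haplotype (0-based half-open)."""

    kind: str
    contig: str
    start: int
    end: int
    alt_seq: str = ""
    donor: tuple[int, int] | None = None  # donor interval for conversion/crossover
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "SNV":
            if self.end != self.start + 1 or len(self.alt_seq) != 1:
                raise ValueError(f"{self.name}: SNV must be single-base")
        elif self.kind != "small_indel" and self.start >= self.end:
            raise ValueError(f"{self.name}: span event needs start < end")
        if self.kind == "conversion":
            assert self.donor is not None
            if self.donor[1] - self.donor[0] != self.end - self.start:
                raise ValueError(f"{self.name}: conversion donor length mismatch")


def apply_events(reference_hap: str, events: list[AlleleEvent]) -> tuple[str, np.ndarray]:
    """Apply sorted, non-overlapping events to one contig sequence.

    Returns the mutated sequence and a coordinate map of length
    ``len(reference_hap) + 1`` where entry i is the position of reference
    base i in the mutated sequence, or -1 if that base was deleted or
    replaced; the final entry maps the end sentinel.
    """
    events = sorted(events, key=lambda e: (e.start, e.end))
    for a, b in zip(events, events[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping events: {a.name!r} and {b.name!r}")
    n = len(reference_hap)
    coord = np.full(n + 1, -1, dtype=np.int64)
    pieces: list[str] = []
    cur = 0  # reference cursor
    out = 0  # output cursor

    def emit_identity(upto: int) -> None:
        nonlocal cur, out
        if upto > cur:
            pieces.append(reference_hap[cur:upto])
            coord[cur:upto] = np.arange(out, out + (upto - cur))
            out += upto - cur
            cur = upto

    for ev in events:
        emit_identity(ev.start)
        if ev.kind == "SNV":
            pieces.append(ev.alt_seq)
            coord[ev.start] = out
            out += 1
        elif ev.kind in ("small_indel", "large_deletion"):
            # deletion when end > start with empty alt; insertion when start == end
            if ev.alt_seq:
                pieces.append(ev.alt_seq)
                out += len(ev.alt_seq)
            # deleted bases keep coord -1
        elif ev.kind == "duplication":
            seg = reference_hap[ev.start : ev.end]
            pieces.append(seg + seg)
            coord[ev.start : ev.end] = np.arange(out, out + len(seg))  # first copy
            out += 2 * len(seg)
        elif ev.kind in ("crossover", "conversion"):
            assert ev.donor is not None
            seg = reference_hap[ev.donor[0] : ev.donor[1]]
            pieces.append(seg)
            if ev.kind == "conversion":
                # same-length replacement: positions keep their offsets
                coord[ev.start : ev.end] = np.arange(out, out + len(seg))
            out += len(seg)
        cur = ev.end
    emit_identity(n)
    coord[n] = out
    return "".join(pieces), coord


# ---------------------------------------------------------------------------
# Allele catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmallAlleleDef:
    """A catalogued SNV or small indel, stored left-normalized (VCF-style)."""

    name: str
    contig: str
    pos: int
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "small_indel"

    @property
    def key(self) -> str:
        return variant_key(self.contig, self.pos, self.ref, self.alt)

    def to_events(self) -> list[AlleleEvent]:
        if self.kind == "SNV":
            return [AlleleEvent("SNV", self.contig, self.pos, self.pos + 1, self.alt, name=self.name)]
        if len(self.ref) > len(self.alt):  # deletion; alt is a prefix of ref after normalization
            k = len(self.alt)
            return [
                AlleleEvent(
                    "small_indel", self.contig, self.pos + k, self.pos + len(self.ref), "", name=self.name
                )
            ]
        k = len(self.ref)
        return [
            AlleleEvent(
                "small_indel", self.contig, self.pos + k, self.pos + k, self.alt[k:], name=self.name
            )
        ]


@dataclass(frozen=True)
class SVAlleleDef:
    """A catalogued structural allele with its defining event(s)."""

    name: str
    sv_class: str
    events: tuple[AlleleEvent, ...]

    @property
    def contig(self) -> str:
        return self.events[0].contig

    def span(self) -> tuple[int, int]:
        return (min(e.start for e in self.events), max(e.end for e in self.events))


@dataclass
class AlleleCatalog:
    """The shipped allele catalog: small variants plus structural alleles."""

    small: list[SmallAlleleDef]
    svs: list[SVAlleleDef]

    def __post_init__(self) -> None:
        names = [a.name for a in self.small] + [s.name for s in self.svs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate allele names in catalog")

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.small] + [s.name for s in self.svs]

    def small_by_key(self) -> dict[str, str]:
        return {a.key: a.name for a in self.small}

    def get(self, name: str) -> SmallAlleleDef | SVAlleleDef:
        for a in self.small:
            if a.name == name:
                return a
        for s in self.svs:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for a in self.small:
            rows.append(dict(name=a.name, type=a.kind, contig=a.contig, pos=a.pos, ref=a.ref, alt=a.alt))
        for s in self.svs:
            lo, hi = s.span()
            rows.append(dict(name=s.name, type=s.sv_class, contig=s.contig, pos=lo, ref=str(hi - lo), alt="."))
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _pick_offset(pair: ParalogPair, candidate: int) -> int:
    """Advance a unit offset until it avoids the pair's diagnostic sites."""
    diag = {d[0] for d in pair.diagnostic_positions}
    while candidate in diag or candidate + 1 in diag or candidate - 1 in diag:
        candidate += 2
    return candidate


def _snv(mini: MiniReference, name: str, contig: str, pos: int) -> SmallAlleleDef:
    ref = mini.contigs[contig][pos]
    alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
    return SmallAlleleDef(name, contig, pos, ref, alt)


def _deletion(mini: MiniReference, name: str, contig: str, pos: int, length: int) -> SmallAlleleDef:
    seq = mini.contigs[contig]
    p, r, a = left_normalize(seq, pos - 1, seq[pos - 1 : pos + length], seq[pos - 1])
    return SmallAlleleDef(name, contig, p, r, a)


def _insertion(mini: MiniReference, name: str, contig: str, pos: int, ins: str) -> SmallAlleleDef:
    seq = mini.contigs[contig]
    p, r, a = left_normalize(seq, pos - 1, seq[pos - 1], seq[pos - 1] + ins)
    return SmallAlleleDef(name, contig, p, r, a)


def default_allele_catalog(mini: MiniReference) -> AlleleCatalog:
    """The default 23-allele catalog over the mini-reference.

    Mirrors a routine-PCR-style panel: 13 SNVs and 4 small indels across the
    alpha-like, gamma-like and modifier contigs, plus 6 structural alleles
    (two alpha-unit deletions, one duplication, a whole-cluster deletion, an
    unequal-crossover rearrangement and a gamma intergenic deletion). The
    paired ``hba2_c369`` / ``hba1_c369`` SNVs sit at homologous offsets of
    the two alpha units, exercising paralog-specific assignment.
    """
    ap = mini.pair_for("alpha")
    gp = mini.pair_for("gamma")
    assert ap is not None and gp is not None
    a0, b0 = ap.unit_a[0], ap.unit_b[0]
    g_a0, g_b0 = gp.unit_a[0], gp.unit_b[0]

    off369 = _pick_offset(ap, 800)
    small = [
        # alpha cluster
        _snv(mini, "hba2_c369", "alpha", a0 + off369),
        _snv(mini, "hba1_c369", "alpha", b0 + off369),
        _snv(mini, "hba2_snv2", "alpha", a0 + _pick_offset(ap, 2100)),
        _snv(mini, "hba1_snv2", "alpha", b0 + _pick_offset(ap, 2900)),
        _deletion(mini, "hba_del3", "alpha", a0 + _pick_offset(ap, 3100), 3),
        _insertion(mini, "hba_ins1", "alpha", b0 + _pick_offset(ap, 1500), "T"),
        # gamma cluster
        _snv(mini, "hbg2_prom", "gamma", g_a0 + _pick_offset(gp, 180)),
        _snv(mini, "hbg1_prom", "gamma", g_b0 + _pick_offset(gp, 180) + 20),
        _snv(mini, "hbg_snv3", "gamma", g_a0 + _pick_offset(gp, 1800)),
        _snv(mini, "hbg_snv4", "gamma", g_b0 + _pick_offset(gp, 2400)),
        _deletion(mini, "hbg_del4", "gamma", g_a0 + _pick_offset(gp, 2600), 4),
        # modifier contig
        _snv(mini, "mod_bcl11a", "mod", 500),
        _snv(mini, "mod_myb", "mod", 900),
        _snv(mini, "mod_klf1_rare", "mod", 1300),
        _snv(mini, "mod_snv4", "mod", 1700),
        _snv(mini, "mod_snv5", "mod", 2100),
        _deletion(mini, "mod_del2", "mod", 2350, 2),
    ]
    svs = [
        SVAlleleDef(
            "a3.7_del", "deletion",
            (AlleleEvent("large_deletion", "alpha", 650, 4350, name="a3.7_del"),),
        ),
        SVAlleleDef(
            "a4.2_del", "deletion",
            (AlleleEvent("large_deletion", "alpha", 600, 4800, name="a4.2_del"),),
        ),
        SVAlleleDef(
            "anti3.7_dup", "duplication",
            (AlleleEvent("duplication", "alpha", 650, 4350, name="anti3.7_dup"),),
        ),
        SVAlleleDef(
            "SEA_del", "deletion",
            (AlleleEvent("large_deletion", "alpha", 300, 8600, name="SEA_del"),),
        ),
        SVAlleleDef(
            "HK_crossover", "crossover",
            (AlleleEvent("crossover", "alpha", 4100, 4300, donor=(600, 1300), name="HK_crossover"),),
        ),
        SVAlleleDef(
            "g4.9_del", "deletion",
            (AlleleEvent("large_deletion", "gamma", 1600, 6500, name="g4.9_del"),),
        ),
    ]
    return AlleleCatalog(small=small, svs=svs)


def conversion_allele(mini: MiniReference, contig: str = "gamma", n_sites: int = 6) -> AlleleEvent:
    """A gene-conversion event on unit B covering ``n_sites`` diagnostic sites.

    The tract on unit B is replaced by the homologous unit-A segment, so the
    haplotype carries the donor paralog's alleles across the tract —
    emulating HBG1-to-HBG2 conversion.
    """
    pair = mini.pair_for(contig)
    assert pair is not None
    diags = pair.diagnostic_positions
    if len(diags) < n_sites:
        raise ValueError("not enough diagnostic sites for requested tract")
    lo_off = diags[0][0]
    hi_off = diags[n_sites - 1][0] + 1
    start = pair.unit_b[0] + lo_off
    end = pair.unit_b[0] + hi_off
    donor = (pair.unit_a[0] + lo_off, pair.unit_a[0] + hi_off)
    return AlleleEvent("conversion", contig, start, end, donor=donor, name=f"{contig}_conv{n_sites}")


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def in_silico_pcr(
    hap_seqs: dict[str, str] | str,
    panel: Panel,
    max_product_len: int = 30_000,
) -> list[tuple[str, str]]:
    """Amplify each panel amplicon from a haplotype.

    ``hap_seqs`` maps contig name -> haplotype sequence (a bare string is
    treated as the sequence for every amplicon's contig). A product is
    emitted per amplicon whose forward primer and reverse-primer complement
    are both found (within the pair's mismatch budget, correct orientation,
    product no longer than ``max_product_len``); loss of a primer site drops
    the amplicon — a valid outcome recorded by the caller, emulating
    deletion-induced dropout.
    """
    encoded: dict[str, np.ndarray] = {}
    products: list[tuple[str, str]] = []
    for amp in panel.amplicons:
        if isinstance(hap_seqs, str):
            seq = hap_seqs
        else:
            seq = hap_seqs.get(amp.contig, "")
        if amp.contig not in encoded:
            encoded[amp.contig] = encode(seq) if seq else np.empty(0, dtype=np.uint8)
        arr = encoded[amp.contig]
        pp = amp.primer_pair
        fwd = encode(pp.fwd_seq)
        revc = encode(revcomp(pp.rev_seq))
        d_f = sliding_hamming(arr, fwd)
        if d_f.size == 0 or d_f.min() > pp.max_mismatch:
            continue
        f_start = int(np.argmin(d_f))  # leftmost best site
        d_r = sliding_hamming(arr[f_start:], revc)
        if d_r.size == 0:
            continue
        ok = np.flatnonzero(d_r <= pp.max_mismatch)
        if ok.size == 0:
            continue
        # rightmost acceptable site within the product-length budget
        ok = ok[ok + len(revc) <= max_product_len]
        if ok.size == 0:
            continue
        r_end = f_start + int(ok[-1]) + len(revc)
        if r_end - f_start >= len(fwd) + len(revc):
            products.append((amp.id, decode(arr[f_start:r_end])))
    return products


# ---------------------------------------------------------------------------
# CCS read generation
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    read_id: str
    seq: str
    qual: str


def _mutate_read(arr: np.ndarray, sub: float, ins: float, dele: float, rng: np.random.Generator) -> np.ndarray:
    n = len(arr)
    out = arr
    nsub = rng.binomial(n, sub) if sub > 0 else 0
    if nsub:
        out = out.copy()
        pos = rng.choice(n, size=nsub, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=nsub).astype(np.uint8)) % 4
    ndel = rng.binomial(n, dele) if dele > 0 else 0
    if ndel:
        pos = rng.choice(n, size=ndel, replace=False)
        out = np.delete(out, pos)
    nins = rng.binomial(n + 1, ins) if ins > 0 else 0
    if nins:
        pos = rng.choice(len(out) + 1, size=nins, replace=True)
        out = np.insert(out, pos, rng.integers(0, 4, size=nins).astype(np.uint8))
    return out


def simulate_ccs_reads(
    products: list[tuple[str, str]],
    depth: int,
    sub_rate: float = 0.003,
    ins_rate: float = 5e-4,
    del_rate: float = 5e-4,
    seed: int | np.random.Generator = 0,
    depth_mode: str = "fixed",
    read_prefix: str = "read",
) -> tuple[list[SimRead], list[tuple[str, int]]]:
    """Generate full-length CCS-like reads from PCR products.

    Each product yields ``depth`` reads (or Poisson(depth) in ``poisson``
    mode) with independent per-base substitutions and short indels; half the
    reads are reverse-complemented. Base qualities are constant, encoding
    the configured total error rate. Returns the reads plus, per product,
    the read count emitted (origin truth, in product order).
    """
    for r in (sub_rate, ins_rate, del_rate):
        if not 0 <= r <= 0.05:
            raise ValueError("error rates must be in [0, 0.05]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total_rate = sub_rate + ins_rate + del_rate
    q = 60 if total_rate == 0 else min(60, int(round(-10 * np.log10(total_rate))))
    qchar = chr(33 + q)
    reads: list[SimRead] = []
    counts: list[tuple[str, int]] = []
    k = 0
    for amp_id, product in products:
        arr = encode(product)
        n_reads = depth if depth_mode == "fixed" else max(1, int(rng.poisson(depth)))
        counts.append((amp_id, n_reads))
        for _ in range(n_reads):
            out = _mutate_read(arr, sub_rate, ins_rate, del_rate, rng)
            if rng.random() < 0.5:
                out = (3 - out)[::-1]
            reads.append(SimRead(f"{read_prefix}{k:06d}", decode(out), qchar * len(out)))
            k += 1
    return reads, counts


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path: str | Path) -> list[SimRead]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append(SimRead(rec.id, str(rec.seq).upper(), "".join(chr(33 + q) for q in quals)))
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeModel:
    """Additive genetic model for the simulated phenotypes.

    HbF (g/L) and ferritin (ug/L) are intercept + sum(effect x dosage) +
    Gaussian noise; transfusion-free survival times are exponential with a
    per-sample hazard scaled by exp(sum(log-HR x dosage)), right-censored at
    a uniform follow-up age. Founder-haplotype effects use keys
    ``founder:<name>``.
    """

    hbf_intercept: float = 6.0
    hbf_sigma: float = 2.0
    hbf_effects: dict[str, float] = field(
        default_factory=lambda: {
            "mod_bcl11a": 2.0,
            "mod_myb": 1.5,
            "mod_klf1_rare": 4.0,
            "hbg2_prom": 1.8,
            "founder:F1": 4.0,
        }
    )
    ferritin_intercept: float = 2500.0
    ferritin_sigma: float = 700.0
    ferritin_effects: dict[str, float] = field(
        default_factory=lambda: {"founder:F1": -600.0, "mod_bcl11a": -250.0}
    )
    survival_base_hazard: float = 0.25  # events per year at zero dosage
    survival_loghr: dict[str, float] = field(
        default_factory=lambda: {
            "mod_bcl11a": -0.30,
            "mod_myb": -0.20,
            "mod_klf1_rare": -0.60,
            "hbg2_prom": -0.25,
            "founder:F1": -0.70,
        }
    )
    censor_range: tuple[float, float] = (2.0, 30.0)


DEFAULT_ALLELE_FREQUENCIES: dict[str, float] = {
    # alpha structural alleles (mutually exclusive per haplotype)
    "a3.7_del": 0.06,
    "a4.2_del": 0.03,
    "anti3.7_dup": 0.015,
    "SEA_del": 0.06,
    "HK_crossover": 0.01,
    # gamma structural allele
    "g4.9_del": 0.005,
    # small alleles
    "hba2_c369": 0.03,
    "hba1_c369": 0.02,
    "hba2_snv2": 0.03,
    "hba1_snv2": 0.02,
    "hba_del3": 0.02,
    "hba_ins1": 0.02,
    "hbg2_prom": 0.10,
    "hbg1_prom": 0.06,
    "hbg_snv3": 0.08,
    "hbg_snv4": 0.05,
    "hbg_del4": 0.03,
    "mod_bcl11a": 0.25,
    "mod_myb": 0.20,
    "mod_klf1_rare": 0.005,
    "mod_snv4": 0.10,
    "mod_snv5": 0.08,
    "mod_del2": 0.04,
}


@dataclass(frozen=True)
class FounderConfig:
    """Founder haplotypes for one amplicon's non-catalog structural SNP set.

    Each haplotype draws a founder by frequency and carries that founder's
    allele subset over ``loci``, plus rare per-locus mutation noise —
    a planted clade structure for haplogroup recovery tests.
    """

    amplicon_id: str
    loci: tuple[SmallAlleleDef, ...]
    founders: dict[str, frozenset[str]]
    frequencies: dict[str, float]
    noise_rate: float = 0.01


def default_founder_config(mini: MiniReference, panel: Panel) -> FounderConfig:
    """Three gamma-fragment founder haplotypes (F1 high-HbF-like, F2, F3 ~reference)."""
    gp = mini.pair_for("gamma")
    assert gp is not None
    offsets = [300, 560, 820, 1080, 1340, 1600, 1860, 2120, 2380, 2640, 2900, 3160]
    loci = []
    for i, off in enumerate(offsets):
        unit0 = gp.unit_a if i % 2 == 0 else gp.unit_b
        pos = unit0[0] + _pick_offset(gp, off) + 37  # keep clear of catalog positions
        loci.append(_snv(mini, f"hbgstr_{i + 1}", "gamma", pos))
    founders = {
        "F1": frozenset({"hbgstr_1", "hbgstr_2", "hbgstr_4", "hbgstr_6", "hbgstr_8"}),
        "F2": frozenset({"hbgstr_3", "hbgstr_5", "hbgstr_7", "hbgstr_11"}),
        "F3": frozenset({"hbgstr_9", "hbgstr_10", "hbgstr_12"}),
    }
    freqs = {"F1": 0.40, "F2": 0.35, "F3": 0.25}
    return FounderConfig("HBG", tuple(loci), founders, freqs)


@dataclass
class SVTruth:
    name: str
    contig: str
    start: int
    end: int
    sv_class: str
    hap: int


@dataclass
class SampleTruth:
    sample_id: str
    hap_events: tuple[list[AlleleEvent], list[AlleleEvent]]
    small_variants: list[tuple[str, int, str, str, int]]  # contig, pos, ref, alt, hap
    svs: list[SVTruth]
    catalog_dosage: dict[str, int]
    founder_labels: tuple[str, str] | None = None
    phenotype: dict | None = None

    def diplotype(self, catalog_names: set[str] | None = None) -> str:
        """Canonical truth diplotype string over (a subset of) catalog alleles."""
        parts = []
        for name in sorted(self.catalog_dosage):
            if catalog_names is not None and name not in catalog_names:
                continue
            d = self.catalog_dosage[name]
            if d:
                parts.append(f"{name}:{'hom' if d == 2 else 'het'}")
        return ";".join(parts)


@dataclass
class TruthSet:
    samples: list[SampleTruth]

    def by_id(self) -> dict[str, SampleTruth]:
        return {s.sample_id: s for s in self.samples}


@dataclass
class CohortSim:
    """Everything a simulated cohort run produces."""

    mini: MiniReference
    panel: Panel
    catalog: AlleleCatalog
    reads: dict[str, list[SimRead]]  # sample_id -> reads
    truth: TruthSet
    phenotypes: pd.DataFrame
    manifest: dict


def _hap_allele_draw(
    catalog: AlleleCatalog,
    freqs: dict[str, float],
    rng: np.random.Generator,
) -> list[str]:
    """Draw one haplotype's allele names: categorical over alpha SVs, Bernoulli elsewhere."""
    names: list[str] = []
    alpha_svs = [s for s in catalog.svs if s.contig == "alpha"]
    probs = np.array([freqs.get(s.name, 0.0) for s in alpha_svs])
    if probs.sum() > 1:
        raise ValueError("alpha SV frequencies sum to > 1")
    u = rng.random()
    acc = 0.0
    for s, p in zip(alpha_svs, probs):
        acc += p
        if u < acc:
            names.append(s.name)
            break
    for s in catalog.svs:
        if s.contig != "alpha" and rng.random() < freqs.get(s.name, 0.0):
            names.append(s.name)
    for a in catalog.small:
        if rng.random() < freqs.get(a.name, 0.0):
            names.append(a.name)
    return names


def _events_overlap(ev: AlleleEvent, svs: list[AlleleEvent]) -> bool:
    for sv in svs:
        if ev.contig == sv.contig and ev.start < sv.end and sv.start < ev.start + max(1, ev.end - ev.start):
            return True
    return False


def simulate_cohort(
    n_samples: int,
    allele_frequencies: dict[str, float] | None = None,
    phenotype_model: PhenotypeModel | None = None,
    seed: int = 0,
    *,
    mini: MiniReference | None = None,
    panel: Panel | None = None,
    catalog: AlleleCatalog | None = None,
    depth: int = 20,
    depth_mode: str = "fixed",
    sub_rate: float = 0.003,
    ins_rate: float = 5e-4,
    del_rate: float = 5e-4,
    founders: FounderConfig | None = None,
    use_founders: bool = True,
    ensure_het_amplicon: str | None = None,
    extra_hap_events: dict[str, list[tuple[int, AlleleEvent]]] | None = None,
    max_product_len: int = 30_000,
    generate_reads: bool = True,
) -> CohortSim:
    """Simulate a diploid cohort with reads, truth and phenotypes.

    ``depth`` is the per-product (per-haplotype, per-amplicon) read count;
    a het sample therefore sees ~2x ``depth`` reads per amplicon. With
    ``ensure_het_amplicon`` set, a sample drawn homozygous across that
    amplicon's loci has a designated common SNP toggled onto haplotype 1 so
    every sample is phaseable there (recorded in truth like any allele).
    ``extra_hap_events`` plants additional events: sample_id -> list of
    (hap_index, event).
    """
    rng = np.random.default_rng(seed)
    mini = mini or build_mini_reference(seed=101)
    panel = panel or default_panel(mini)
    catalog = catalog or default_allele_catalog(mini)
    freqs = dict(DEFAULT_ALLELE_FREQUENCIES if allele_frequencies is None else allele_frequencies)
    for name, f in freqs.items():
        if not 0 <= f <= 1:
            raise ValueError(f"frequency for {name} not in [0,1]")
    model = phenotype_model or PhenotypeModel()
    if founders is None and use_founders:
        founders = default_founder_config(mini, panel)
    founder_locus_defs = {l.name: l for l in (founders.loci if founders else ())}
    panel_amp_ids = {a.id for a in panel.amplicons}

    # designated ensure-het locus: first founder structural locus if available,
    # else the first catalog small allele on that amplicon's contig
    ensure_locus: SmallAlleleDef | None = None
    if ensure_het_amplicon:
        amp = panel.get(ensure_het_amplicon)
        if founders and founders.amplicon_id == ensure_het_amplicon:
            ensure_locus = founders.loci[0]
        else:
            for a in catalog.small:
                if a.contig == amp.contig and amp.start <= a.pos < amp.end:
                    ensure_locus = a
                    break
        if ensure_locus is None:
            raise ValueError(f"no locus available to ensure heterozygosity on {ensure_het_amplicon}")

    samples: list[SampleTruth] = []
    reads: dict[str, list[SimRead]] = {}
    pheno_rows = []
    for i in range(n_samples):
        sid = f"S{i:04d}"
        hap_names: list[set[str]] = []
        hap_founder: list[str] = []
        for _h in range(2):
            names = set(_hap_allele_draw(catalog, freqs, rng))
            if founders:
                fnames = list(founders.founders)
                fprobs = np.array([founders.frequencies[f] for f in fnames])
                fprobs = fprobs / fprobs.sum()
                fl = fnames[rng.choice(len(fnames), p=fprobs)]
                hap_founder.append(fl)
                carried = set(founders.founders[fl])
                for l in founders.loci:  # mutation noise
                    if rng.random() < founders.noise_rate:
                        carried ^= {l.name}
                names |= carried
            hap_names.append(names)
        if ensure_locus is not None:
            amp = panel.get(ensure_het_amplicon)
            amp_loci = {l.name for l in (founders.loci if founders else ())} | {
                a.name for a in catalog.small if a.contig == amp.contig and amp.start <= a.pos < amp.end
            }
            if (hap_names[0] & amp_loci) == (hap_names[1] & amp_loci):
                hap_names[0] ^= {ensure_locus.name}

        hap_events: tuple[list[AlleleEvent], list[AlleleEvent]] = ([], [])
        small_truth: list[tuple[str, int, str, str, int]] = []
        sv_truth: list[SVTruth] = []
        dosage: dict[str, int] = {n: 0 for n in catalog.names}
        for h in range(2):
            sv_events: list[AlleleEvent] = []
            for name in sorted(hap_names[h]):
                if name in founder_locus_defs:
                    continue
                allele = catalog.get(name)
                if isinstance(allele, SVAlleleDef):
                    sv_events.extend(allele.events)
            applied: set[str] = set()
            for name in sorted(hap_names[h]):
                if name in founder_locus_defs:
                    d = founder_locus_defs[name]
                else:
                    allele = catalog.get(name)
                    if isinstance(allele, SVAlleleDef):
                        hap_events[h].extend(allele.events)
                        lo, hi = allele.span()
                        sv_truth.append(SVTruth(name, allele.contig, lo, hi, allele.sv_class, h))
                        dosage[name] += 1
                        applied.add(name)
                        continue
                    d = allele
                evs = d.to_events()
                if any(_events_overlap(ev, sv_events) for ev in evs):
                    continue  # masked by a structural allele on the same haplotype
                hap_events[h].extend(evs)
                small_truth.append((d.contig, d.pos, d.ref, d.alt, h))
                if name in dosage:
                    dosage[name] += 1
                applied.add(name)
            if extra_hap_events and sid in extra_hap_events:
                for hh, ev in extra_hap_events[sid]:
                    if hh == h:
                        hap_events[h].append(ev)

        # expand founder-structure dosages for phenotype/association truth
        for name in founder_locus_defs:
            dosage[name] = sum(1 for h in range(2) if name in hap_names[h])

        # phenotype generation
        def _dos(key: str) -> int:
            if key.startswith("founder:"):
                fl = key.split(":", 1)[1]
                return sum(1 for x in hap_founder if x == fl) if hap_founder else 0
            return dosage.get(key, 0)

        hbf = model.hbf_intercept + sum(b * _dos(k) for k, b in model.hbf_effects.items())
        hbf += rng.normal(0, model.hbf_sigma)
        hbf = max(hbf, 0.0)
        ferr = model.ferritin_intercept + sum(b * _dos(k) for k, b in model.ferritin_effects.items())
        ferr = max(ferr + rng.normal(0, model.ferritin_sigma), 0.0)
        lhr = sum(b * _dos(k) for k, b in model.survival_loghr.items())
        hazard = model.survival_base_hazard * np.exp(lhr)
        t_event = rng.exponential(1.0 / hazard)
        censor = rng.uniform(*model.censor_range)
        transfused = bool(t_event <= censor)
        age_ft = float(min(t_event, censor))
        age = float(rng.uniform(3, 40))
        sex = int(rng.integers(0, 2))
        pheno = dict(
            sample_id=sid, hbf=round(float(hbf), 3), age_first_transfusion=round(age_ft, 3),
            transfused=int(transfused), ferritin=round(float(ferr), 1), age=round(age, 1), sex=sex,
        )
        pheno_rows.append(pheno)

        samples.append(
            SampleTruth(
                sample_id=sid,
                hap_events=hap_events,
                small_variants=sorted(small_truth),
                svs=sv_truth,
                catalog_dosage=dosage,
                founder_labels=tuple(hap_founder) if hap_founder else None,
                phenotype=pheno,
            )
        )

        # sequence generation: apply events per contig per haplotype, PCR, reads
        if not generate_reads:
            continue
        sample_reads: list[SimRead] = []
        for h in range(2):
            by_contig: dict[str, list[AlleleEvent]] = {}
            for ev in hap_events[h]:
                by_contig.setdefault(ev.contig, []).append(ev)
            hap_seqs = {}
            for contig, refseq in mini.contigs.items():
                evs = by_contig.get(contig, [])
                hap_seqs[contig] = apply_events(refseq, evs)[0] if evs else refseq
            products = in_silico_pcr(hap_seqs, panel, max_product_len=max_product_len)
            rr, _counts = simulate_ccs_reads(
                products, depth, sub_rate, ins_rate, del_rate, seed=rng,
                depth_mode=depth_mode, read_prefix=f"{sid}:h{h}:",
            )
            sample_reads.extend(rr)
        reads[sid] = sample_reads

    phenotypes = pd.DataFrame(pheno_rows)
    manifest = dict(
        n_samples=n_samples, seed=seed, depth=depth, depth_mode=depth_mode,
        sub_rate=sub_rate, ins_rate=ins_rate, del_rate=del_rate,
        allele_frequencies=freqs, amplicons=sorted(panel_amp_ids),
        founders=bool(founders), ensure_het_amplicon=ensure_het_amplicon,
    )
    return CohortSim(mini, panel, catalog, reads, TruthSet(samples), phenotypes, manifest)


def write_cohort(sim: CohortSim, outdir: str | Path) -> None:
    """Write FASTQ per sample, reference FASTA, panel TSV/BED, truth and manifest."""
    from .vcfio import write_truth_vcf, write_truth_sv_bed
    from .panel import write_panel_tsv

    outdir = Path(outdir)
    (outdir / "fastq").mkdir(parents=True, exist_ok=True)
    sim.mini.write_fasta(outdir / "reference.fa")
    write_panel_tsv(sim.panel, outdir / "panel.tsv")
    sim.panel.to_bed(outdir / "panel.bed")
    sim.catalog.to_tsv(outdir / "allele_catalog.tsv")
    for sid, rr in sim.reads.items():
        write_fastq(rr, outdir / "fastq" / f"{sid}.fastq")
    write_truth_vcf(sim.truth, sim.mini, outdir / "truth.vcf")
    write_truth_sv_bed(sim.truth, outdir / "truth_sv.bed")
    sim.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(sim.manifest, fh, indent=2)
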
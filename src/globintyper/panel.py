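"""Amplicon panel model and synthetic mini-reference.

A targeted long-range-PCR panel is a set of amplicons, each defined by a
primer pair and a reference interval, multiplexed over a small reference.
The globin clusters contain highly homologous paralogous units (HBA1/HBA2,
HBG1/HBG2); the synthetic mini-reference built here emulates that geometry
with two clusters, each carrying a paralog pair that differs only at a
fixed set of diagnostic positions, so that paralog disambiguation, gene
conversion and deletion calling can be exercised end to end.

Coordinates are 0-based half-open internally; VCF output is 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DNA_ALPHABET = "ACGT"
_DNA_RE = re.compile(r"^[ACGT]+$")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


class PanelError(ValueError):
    """Raised when a panel definition fails validation; message lists all problems."""


@dataclass(frozen=True)
class PrimerPair:
    """A long-range PCR primer pair.

    ``rev_seq`` is given 5'->3' on the reverse strand, i.e. its reverse
    complement appears at the 3' end of the plus-strand product.
    """

    name: str
    fwd_seq: str
    rev_seq: str
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        for label, seq in (("fwd", self.fwd_seq), ("rev", self.rev_seq)):
            if not seq or not _DNA_RE.match(seq):
                raise PanelError(f"primer {self.name}/{label}: not a non-empty ACGT string")
            if len(seq) < 18:
                raise PanelError(f"primer {self.name}/{label}: length {len(seq)} < 18")
        if self.max_mismatch < 0:
            raise PanelError(f"primer {self.name}: max_mismatch must be >= 0")


@dataclass(frozen=True)
class GeneInterval:
    """An annotated gene/paralog-unit interval inside an amplicon (reference coords)."""

    id: str
    start: int
    end: int


@dataclass
class Amplicon:
    """One amplicon: primer pair + reference interval + annotated units."""

    id: str
    primer_pair: PrimerPair
    contig: str
    start: int
    end: int
    genes: list[GeneInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PanelError(f"amplicon {self.id}: end ({self.end}) <= start ({self.start})")
        for g in self.genes:
            if not (self.start <= g.start < g.end <= self.end):
                raise PanelError(
                    f"amplicon {self.id}: gene {g.id} [{g.start},{g.end}) not nested "
                    f"within [{self.start},{self.end})"
                )

    @property
    def expected_length(self) -> int:
        """Expected product length in bp (end - start, by construction)."""
        return self.end - self.start


SV_CLASSES = ("deletion", "duplication", "crossover")


@dataclass(frozen=True)
class SVCatalogEntry:
    """A known structural allele: expected length shift on a given amplicon.

    ``linked_dropout`` lists amplicon ids whose primer sites the allele
    removes entirely (gap-PCR style interpretation: the shortened product on
    the spanning amplicon plus dropout of the internal amplicons together
    identify the allele, e.g. an --SEA-like whole-cluster deletion).
    """

    allele_name: str
    amplicon_id: str
    length_shift: int
    sv_class: str
    linked_dropout: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise PanelError(f"sv catalog {self.allele_name}: bad class {self.sv_class!r}")


@dataclass
class Panel:
    """A validated amplicon panel plus structural-allele catalog."""

    amplicons: list[Amplicon]
    reference: str | None = None  # FASTA path, if file-backed
    sv_catalog: list[SVCatalogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        errors: list[str] = []
        ids = [a.id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            errors.append("duplicate amplicon ids")
        seen_pairs: dict[tuple[str, str], str] = {}
        for a in self.amplicons:
            key = (a.primer_pair.fwd_seq, a.primer_pair.rev_seq)
            if key in seen_pairs:
                errors.append(
                    f"amplicons {seen_pairs[key]} and {a.id} share both primer sequences"
                )
            seen_pairs[key] = a.id
        known = set(ids)
        for entry in self.sv_catalog:
            if entry.amplicon_id not in known:
                errors.append(
                    f"sv catalog {entry.allele_name}: unknown amplicon {entry.amplicon_id}"
                )
        if errors:
            raise PanelError("; ".join(errors))

    def get(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def subset(self, amplicon_ids: list[str]) -> "Panel":
        """A new panel restricted to the given amplicons (catalog filtered to match)."""
        keep = set(amplicon_ids)
        return Panel(
            amplicons=[a for a in self.amplicons if a.id in keep],
            reference=self.reference,
            sv_catalog=[e for e in self.sv_catalog if e.amplicon_id in keep],
        )

    def catalog_for(self, amplicon_id: str) -> list[SVCatalogEntry]:
        return [e for e in self.sv_catalog if e.amplicon_id == amplicon_id]

    def to_bed(self, path: str | Path) -> None:
        """Export amplicon intervals as BED (0-based half-open)."""
        with open(path, "w") as fh:
            for a in self.amplicons:
                fh.write(f"{a.contig}\t{a.start}\t{a.end}\t{a.id}\n")


PANEL_TSV_COLUMNS = ["amplicon_id", "contig", "start", "end", "fwd_primer", "rev_primer", "genes"]


def _parse_genes(cell: str) -> list[GeneInterval]:
    # format: "id:start-end;id:start-end" or "." for none
    if not cell or cell in (".", "nan"):
        return []
    out = []
    for tok in str(cell).split(";"):
        name, span = tok.split(":")
        s, e = span.split("-")
        out.append(GeneInterval(name, int(s), int(e)))
    return out


def load_panel(panel_tsv: str | Path, reference: str | Path) -> Panel:
    """Load a panel from a TSV definition plus its FASTA reference.

    Required TSV columns: amplicon_id, contig, start, end, fwd_primer,
    rev_primer, genes (semicolon list ``id:start-end`` or ``.``). Optional:
    max_mismatch. Coordinates are 0-based half-open; expected product length
    is end - start. Validation problems are aggregated and reported together,
    each naming the offending row.
    """
    import pyfaidx

    df = pd.read_csv(panel_tsv, sep="\t", dtype=str)
    missing = [c for c in PANEL_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"panel TSV missing columns: {missing}")
    fasta = pyfaidx.Fasta(str(reference))
    contig_lens = {name: len(fasta[name]) for name in fasta.keys()}

    errors: list[str] = []
    amplicons: list[Amplicon] = []
    for i, row in df.iterrows():
        rowname = f"row {i} ({row['amplicon_id']})"
        try:
            start, end = int(row["start"]), int(row["end"])
            if row["contig"] not in contig_lens:
                raise PanelError(f"{rowname}: contig {row['contig']!r} not in reference")
            if end <= start:
                raise PanelError(f"{rowname}: end <= start")
            if end > contig_lens[row["contig"]]:
                raise PanelError(f"{rowname}: interval exceeds contig length")
            mm = int(row["max_mismatch"]) if "max_mismatch" in df.columns and pd.notna(row.get("max_mismatch")) else 2
            pp = PrimerPair(
                name=row["amplicon_id"],
                fwd_seq=str(row["fwd_primer"]).upper(),
                rev_seq=str(row["rev_primer"]).upper(),
                max_mismatch=mm,
            )
            amplicons.append(
                Amplicon(
                    id=row["amplicon_id"],
                    primer_pair=pp,
                    contig=row["contig"],
                    start=start,
                    end=end,
                    genes=_parse_genes(row["genes"]),
                )
            )
        except (PanelError, ValueError) as exc:
            msg = str(exc)
            errors.append(msg if rowname in msg else f"{rowname}: {msg}")
    if errors:
        raise PanelError("panel load failed: " + "; ".join(errors))
    return Panel(amplicons=amplicons, reference=str(reference))


def write_panel_tsv(panel: Panel, path: str | Path) -> None:
    rows = []
    for a in panel.amplicons:
        genes = ";".join(f"{g.id}:{g.start}-{g.end}" for g in a.genes) or "."
        rows.append(
            dict(
                amplicon_id=a.id,
                contig=a.contig,
                start=a.start,
                end=a.end,
                fwd_primer=a.primer_pair.fwd_seq,
                rev_primer=a.primer_pair.rev_seq,
                genes=genes,
                max_mismatch=a.primer_pair.max_mismatch,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Synthetic mini-reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParalogPair:
    """Two equal-length homologous units on one contig plus their diagnostic sites.

    Diagnostic sites are unit-relative offsets where the two copies carry
    different fixed alleles; they are what allows paralog-specific calling
    and gene-conversion detection.
    """

    contig: str
    unit_a: tuple[int, int]
    unit_b: tuple[int, int]
    diagnostic_positions: tuple[tuple[int, str, str], ...]  # (offset, allele_a, allele_b)

    def __post_init__(self) -> None:
        la = self.unit_a[1] - self.unit_a[0]
        lb = self.unit_b[1] - self.unit_b[0]
        if la != lb:
            raise PanelError(f"paralog units on {self.contig} differ in length ({la} vs {lb})")
        offsets = [d[0] for d in self.diagnostic_positions]
        if offsets != sorted(set(offsets)):
            raise PanelError("diagnostic positions must be strictly increasing")
        for off, a, b in self.diagnostic_positions:
            if a == b:
                raise PanelError(f"diagnostic offset {off}: alleles identical")


@dataclass
class MiniReference:
    """Named contigs plus paralog-pair annotations for the synthetic reference."""

    contigs: dict[str, str]
    paralog_pairs: list[ParalogPair]

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def pair_for(self, contig: str) -> ParalogPair | None:
        for p in self.paralog_pairs:
            if p.contig == contig:
                return p
        return None


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=n))


def _make_paralog_contig(
    rng: np.random.Generator,
    contig: str,
    unit_len: int,
    n_diagnostic: int,
    flank_len: int,
    spacer_len: int,
) -> tuple[str, ParalogPair]:
    unit_a = _random_dna(rng, unit_len)
    if n_diagnostic:
        offsets = np.sort(rng.choice(unit_len, size=n_diagnostic, replace=False))
    else:
        offsets = np.array([], dtype=int)
    b = list(unit_a)
    diags = []
    for off in offsets:
        a_allele = unit_a[off]
        choices = [c for c in DNA_ALPHABET if c != a_allele]
        b_allele = choices[rng.integers(len(choices))]
        b[off] = b_allele
        diags.append((int(off), a_allele, b_allele))
    unit_b = "".join(b)
    left = _random_dna(rng, flank_len)
    spacer = _random_dna(rng, spacer_len)
    right = _random_dna(rng, flank_len)
    seq = left + unit_a + spacer + unit_b + right
    a_iv = (flank_len, flank_len + unit_len)
    b_iv = (flank_len + unit_len + spacer_len, flank_len + 2 * unit_len + spacer_len)
    return seq, ParalogPair(contig, a_iv, b_iv, tuple(diags))


# Layout constants chosen so the default panel's paralog fragments come out at
# the assay's fragment sizes: 7122 bp for the gamma-like and 8135 bp for the
# alpha-like amplicon.
ALPHA_UNIT_LEN = 4000
ALPHA_SPACER = 100
GAMMA_UNIT_LEN = 3400
GAMMA_SPACER = 272
DEFAULT_FLANK = 400
MOD_CONTIG_LEN = 3000


def build_mini_reference(
    seed: int,
    unit_len: int = ALPHA_UNIT_LEN,
    n_diagnostic: int = 40,
    flank_len: int = DEFAULT_FLANK,
    gamma_unit_len: int = GAMMA_UNIT_LEN,
) -> MiniReference:
    """Build the deterministic synthetic mini-reference.

    Three contigs: ``alpha`` (paralog pair of ``unit_len``-bp units, emulating
    HBA2/HBA1), ``gamma`` (paralog pair of ``gamma_unit_len``-bp units,
    emulating HBG2/HBG1) and ``mod`` (a plain modifier-gene-like contig).
    Each paralog pair differs at exactly ``n_diagnostic`` positions.
    """
    if unit_len < 1000 or gamma_unit_len < 1000:
        raise ValueError("unit_len must be >= 1000")
    if not (0 <= n_diagnostic < min(unit_len, gamma_unit_len)):
        raise ValueError("n_diagnostic must satisfy 0 <= n_diagnostic < unit_len")
    rng = np.random.default_rng(seed)
    alpha_seq, alpha_pair = _make_paralog_contig(
        rng, "alpha", unit_len, n_diagnostic, flank_len, ALPHA_SPACER
    )
    gamma_seq, gamma_pair = _make_paralog_contig(
        rng, "gamma", gamma_unit_len, n_diagnostic, flank_len, GAMMA_SPACER
    )
    mod_seq = _random_dna(rng, MOD_CONTIG_LEN)
    return MiniReference(
        contigs={"alpha": alpha_seq, "gamma": gamma_seq, "mod": mod_seq},
        paralog_pairs=[alpha_pair, gamma_pair],
    )


PRIMER_LEN = 25


def _amplicon_from_interval(
    mini: MiniReference, aid: str, contig: str, start: int, end: int, genes: list[GeneInterval]
) -> Amplicon:
    seq = mini.contigs[contig]
    pp = PrimerPair(
        name=aid,
        fwd_seq=seq[start : start + PRIMER_LEN],
        rev_seq=revcomp(seq[end - PRIMER_LEN : end]),
    )
    return Amplicon(id=aid, primer_pair=pp, contig=contig, start=start, end=end, genes=genes)


def default_panel(mini: MiniReference, flank_len: int = DEFAULT_FLANK) -> Panel:
    """The default 4-amplicon panel over the mini-reference.

    HBG (7122 bp) and HBA (8135 bp) each span a whole paralog pair; HBA_SPAN
    is a wider gap-PCR-style amplicon whose primers survive the largest
    catalogued alpha-cluster deletion; MOD covers the modifier contig.
    """
    ap = mini.pair_for("alpha")
    gp = mini.pair_for("gamma")
    assert ap is not None and gp is not None
    g_start = flank_len - PRIMER_LEN
    g_end = g_start + (2 * PRIMER_LEN + (gp.unit_a[1] - gp.unit_a[0]) * 2 + (gp.unit_b[0] - gp.unit_a[1]))
    a_start = flank_len - PRIMER_LEN
    a_end = ap.unit_b[1] + 10
    amplicons = [
        _amplicon_from_interval(
            mini,
            "HBG",
            "gamma",
            g_start,
            g_end,
            [GeneInterval("HBG2", *gp.unit_a), GeneInterval("HBG1", *gp.unit_b)],
        ),
        _amplicon_from_interval(
            mini,
            "HBA",
            "alpha",
            a_start,
            a_end,
            [GeneInterval("HBA2", *ap.unit_a), GeneInterval("HBA1", *ap.unit_b)],
        ),
        _amplicon_from_interval(mini, "HBA_SPAN", "alpha", 50, len(mini.contigs["alpha"]) - 50, []),
        _amplicon_from_interval(mini, "MOD", "mod", 100, 2600, [GeneInterval("MODG", 300, 2300)]),
    ]
    sv_catalog = [
        SVCatalogEntry("a3.7_del", "HBA", -3700, "deletion"),
        SVCatalogEntry("a3.7_del", "HBA_SPAN", -3700, "deletion"),
        SVCatalogEntry("a4.2_del", "HBA", -4200, "deletion"),
        SVCatalogEntry("a4.2_del", "HBA_SPAN", -4200, "deletion"),
        SVCatalogEntry("anti3.7_dup", "HBA", 3700, "duplication"),
        SVCatalogEntry("anti3.7_dup", "HBA_SPAN", 3700, "duplication"),
        SVCatalogEntry("SEA_del", "HBA_SPAN", -8300, "deletion", linked_dropout=("HBA",)),
        SVCatalogEntry("HK_crossover", "HBA", 500, "crossover"),
        SVCatalogEntry("HK_crossover", "HBA_SPAN", 500, "crossover"),
        SVCatalogEntry("g4.9_del", "HBG", -4900, "deletion"),
    ]
    return Panel(amplicons=amplicons, sv_catalog=sv_catalog)
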
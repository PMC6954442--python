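"""Sequence model shared by every design module.

Coordinates are 0-based, half-open, on the plus strand internally; residue
numbering is 1-based in user-facing reports. Circular sequences wrap modulo
their length.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DesignError, SwapError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, what: str = "sequence") -> str:
    """Uppercase and validate a DNA string; ambiguity codes are rejected."""
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise DesignError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


def circular_slice(seq: str, start: int, end: int) -> str:
    """Slice [start, end) with wrap-around; start may be negative, end > len."""
    n = len(seq)
    length = end - start
    if length < 0 or length > n:
        raise DesignError("invalid circular slice span")
    start %= n
    return (seq + seq)[start : start + length]


def translate(cds: str) -> str:
    """Standard-table translation; stop codons render as '*'.

    Raises on non-ACGT characters or length not divisible by 3.
    """
    cds = check_dna(cds, "CDS")
    if len(cds) % 3:
        raise DesignError(f"CDS length {len(cds)} not divisible by 3")
    if not cds:
        return ""
    return str(Seq(cds).translate())


# --- codon usage ----------------------------------------------------------

def _load_codon_usage() -> dict[str, list[str]]:
    """aa -> synonymous codons, best-ranked first.

    Ranking: descending usage fraction (human table shipped as data), ties
    broken by GC content (higher first) then alphabetically.
    """
    path = resources.files("dipdesign.data") / "codon_usage_human.tsv"
    by_aa: dict[str, list[tuple[float, int, str]]] = {}
    with path.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            codon, aa, frac = row["codon"], row["aa"], float(row["fraction"])
            gc = codon.count("G") + codon.count("C")
            by_aa.setdefault(aa, []).append((-frac, -gc, codon))
    return {aa: [c for *_, c in sorted(entries)] for aa, entries in by_aa.items()}


CODON_RANKING: dict[str, list[str]] = _load_codon_usage()


def synonymous_codons(residue: str) -> list[str]:
    """Codons for one amino acid (or '*'), preferred first."""
    try:
        return list(CODON_RANKING[residue])
    except KeyError:
        raise DesignError(f"unknown residue {residue!r}") from None


# --- restriction enzymes --------------------------------------------------

@dataclass(frozen=True)
class TypeIIS:
    """A type-IIS enzyme cutting downstream of its recognition sequence."""

    name: str
    recognition: str
    spacer: int       # nt between recognition end and the top-strand cut
    overhang: int     # length of the 5' overhang left by the staggered cut

    @property
    def recognition_rc(self) -> str:
        return revcomp(self.recognition)


ENZYMES: dict[str, TypeIIS] = {
    "BsaI": TypeIIS("BsaI", "GGTCTC", spacer=1, overhang=4),
    "BsmBI": TypeIIS("BsmBI", "CGTCTC", spacer=1, overhang=4),
}


def get_enzyme(name: str) -> TypeIIS:
    try:
        return ENZYMES[name]
    except KeyError:
        raise DesignError(f"unknown enzyme {name!r}; registry has {sorted(ENZYMES)}") from None


def enzymes_as_json() -> str:
    """Registry export for interoperability with other tooling."""
    return json.dumps(
        {e.name: {"recognition": e.recognition, "spacer": e.spacer, "overhang": e.overhang}
         for e in ENZYMES.values()},
        indent=2,
    )


@dataclass(frozen=True)
class RestrictionSite:
    enzyme: str
    position: int          # 0-based start of the recognition motif on the plus strand
    strand: str            # "plus" | "minus"

    def __post_init__(self):
        if self.strand not in ("plus", "minus"):
            raise DesignError(f"bad strand {self.strand!r}")


def find_restriction_sites(seq: str, enzyme: str, circular: bool = False) -> list[RestrictionSite]:
    """All recognition-site occurrences on both strands.

    On a circle, motifs spanning the origin are reported at their (mod-length)
    start position.
    """
    enz = get_enzyme(enzyme)
    seq = check_dna(seq)
    n = len(seq)
    m = len(enz.recognition)
    search = seq + seq[: m - 1] if circular and n >= m else seq
    sites = []
    for motif, strand in ((enz.recognition, "plus"), (enz.recognition_rc, "minus")):
        start = search.find(motif)
        while start != -1:
            if start < n:
                sites.append(RestrictionSite(enz.name, start % n, strand))
            start = search.find(motif, start + 1)
    return sorted(sites, key=lambda s: (s.position, s.strand))


def count_sites(seq: str, circular: bool = False) -> int:
    """Total BsaI + BsmBI sites, both strands."""
    return sum(len(find_restriction_sites(seq, e, circular)) for e in ENZYMES)


# --- silent codon swapping ------------------------------------------------

def _motif_hits_overlapping(window: str, banned_motifs: Sequence[str], span: tuple[int, int]) -> bool:
    lo, hi = span
    for motif in banned_motifs:
        for m in (motif, revcomp(motif)):
            start = window.find(m)
            while start != -1:
                if start < hi and start + len(m) > lo:
                    return True
                start = window.find(m, start + 1)
    return False


def silent_codon_swap(
    codon: str,
    residue: str,
    banned_motifs: Sequence[str],
    context: tuple[str, str] = ("", ""),
) -> str:
    """Replace ``codon`` with a synonymous codon that breaks every banned motif
    overlapping it in ``upstream + codon + downstream`` (both strands).

    Candidates are tried in the shipped codon-usage ranking. Raises
    :class:`SwapError` when no synonymous codon clears the motifs (single-codon
    residues Met/Trp are typically unresolvable).
    """
    codon = check_dna(codon, "codon")
    if len(codon) != 3:
        raise DesignError("codon must be a 3-mer")
    if translate(codon) != residue:
        raise DesignError(f"codon {codon} does not encode {residue}")
    upstream, downstream = (check_dna(c, "context") for c in context)
    span = (len(upstream), len(upstream) + 3)
    for candidate in synonymous_codons(residue):
        if candidate == codon:
            continue
        window = upstream + candidate + downstream
        if not _motif_hits_overlapping(window, banned_motifs, span):
            return candidate
    raise SwapError(
        f"no synonymous codon for {residue} ({codon}) removes the banned motifs"
    )


# --- plasmid model --------------------------------------------------------

@dataclass
class Plasmid:
    """Circular (or linear) DNA with one annotated target ORF.

    ``orf_start``/``orf_end`` are 0-based half-open nucleotide coordinates on
    the plus strand; on a circle ``orf_end`` may exceed the sequence length,
    meaning the ORF wraps the origin.
    """

    sequence: str
    orf_start: int
    orf_end: int
    circular: bool = True
    name: str = "plasmid"

    def __post_init__(self):
        self.sequence = check_dna(self.sequence, "plasmid")
        n = len(self.sequence)
        if not n:
            raise DesignError("empty plasmid")
        orf_len = self.orf_end - self.orf_start
        if orf_len <= 0 or orf_len % 3:
            raise DesignError("ORF length must be positive and divisible by 3")
        if not self.circular and self.orf_end > n:
            raise DesignError("ORF exceeds a linear plasmid")
        protein = translate(self.orf_nt)
        if "*" in protein[:-1]:
            raise DesignError("ORF contains an internal stop codon")

    # -- views ------------------------------------------------------------
    @property
    def orf_nt(self) -> str:
        return circular_slice(self.sequence, self.orf_start, self.orf_end)

    @property
    def n_codons(self) -> int:
        return (self.orf_end - self.orf_start) // 3

    @property
    def protein(self) -> str:
        return translate(self.orf_nt)

    def codon(self, index: int) -> str:
        """Codon by 1-based index."""
        if not 1 <= index <= self.n_codons:
            raise DesignError(f"codon index {index} out of 1..{self.n_codons}")
        a = self.orf_start + 3 * (index - 1)
        return circular_slice(self.sequence, a, a + 3)

    def codon_nt_start(self, index: int) -> int:
        """Plus-strand coordinate of a codon's first base (may exceed len-1 conceptually)."""
        return self.orf_start + 3 * (index - 1)

    def slice(self, start: int, end: int) -> str:
        return circular_slice(self.sequence, start, end)


# --- FASTA I/O ------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Multi-record FASTA as (id, uppercased sequence) pairs."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, check_dna(str(rec.seq), rec.id)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write (id, seq) pairs wrapped at ``width`` columns."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)
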
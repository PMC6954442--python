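"""Seeded generators for every input class the package consumes.

All generators are pure functions of a :class:`SimulationConfig`; each
operation derives its own independent random stream from the master seed, so
adding one generator call never perturbs another. Emitted objects use the
same types and file formats the analysis modules read (Plasmid/FASTA,
insertion count and call tables, SAM alignments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .errors import DesignError
from .library_stats import SIX_CLASSES, InsertionCountTable
from .sequence_core import ENZYMES, Plasmid, find_restriction_sites

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimulationConfig:
    seed: int = 0
    gene_length_codons: int = 300         # includes the start and stop codons
    plasmid_length: int = 3600
    orf_start: int = 100
    bias_model: str = "uniform"           # uniform | hotspot | trinucleotide
    bias_weight: float = 10.0
    bias_motif: str = "CGG"
    hotspot_fraction: float = 0.1
    total_reads: int = 100_000
    reads_per_position: int = 250
    permissibility: np.ndarray | None = None   # per-position values in [0, 1]
    deletion_rate: float = 0.0
    n_reads: int = 10_000
    read_length: int = 100
    forbid_sites: bool = True
    salt_sites: int = 0                   # BsmBI sites embedded in the backbone

    def __post_init__(self):
        if not 0 <= self.deletion_rate <= 1:
            raise DesignError("deletion_rate outside [0, 1]")
        if self.gene_length_codons < 4 or self.plasmid_length < 3 * self.gene_length_codons + 200:
            raise DesignError("lengths too small for a plasmid with this ORF")
        if self.permissibility is not None:
            q = np.asarray(self.permissibility, float)
            if ((q < 0) | (q > 1)).any():
                raise DesignError("permissibility outside [0, 1]")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


# --------------------------------------------------------------------------
# plasmid
# --------------------------------------------------------------------------

def make_synthetic_plasmid(cfg: SimulationConfig) -> Plasmid:
    """Random circular plasmid with an embedded ORF (ATG ... stop), scrubbed of
    BsaI/BsmBI sites unless ``salt_sites`` asks for embedded BsmBI sites."""
    rng = _rng(cfg, 1)
    n_codons = cfg.gene_length_codons
    orf = "ATG" + "".join(rng.choice(SENSE_CODONS, size=n_codons - 2)) + "TAA"
    backbone_len = cfg.plasmid_length - len(orf)
    bases = np.array(list("ACGT"))
    backbone = "".join(rng.choice(bases, size=backbone_len))
    start = cfg.orf_start
    seq = backbone[:start] + orf + backbone[start:]

    def all_sites(s):
        return [
            site
            for enz in ENZYMES
            for site in find_restriction_sites(s, enz, circular=True)
        ]

    orf_lo, orf_hi = start, start + len(orf)
    for _ in range(500):
        sites = all_sites(seq)
        if not sites:
            break
        site = sites[0]
        lo, hi = site.position, site.position + 6
        if lo >= orf_lo + 3 and hi <= orf_hi - 3:
            # resample a whole codon inside the ORF interior
            c = (lo - orf_lo) // 3
            a = orf_lo + 3 * c
            seq = seq[:a] + str(rng.choice(SENSE_CODONS)) + seq[a + 3 :]
        else:
            # resample the offending bases outside (or at the edge of) the ORF
            pos = lo if not (orf_lo <= lo < orf_hi) else hi - 1
            pos %= len(seq)
            seq = seq[:pos] + str(rng.choice(bases)) + seq[pos + 1 :]
    else:
        raise DesignError("site scrub did not converge")

    if cfg.salt_sites:
        motif = ENZYMES["BsmBI"].recognition
        slots = np.linspace(orf_hi + 50, len(seq) - 50, cfg.salt_sites, dtype=int)
        for p in slots:
            seq = seq[:p] + motif + seq[p + len(motif) :]
        got = len(find_restriction_sites(seq, "BsmBI", circular=True))
        if got != cfg.salt_sites:
            raise DesignError(f"salted {cfg.salt_sites} sites but scan finds {got}")

    return Plasmid(seq, orf_start=start, orf_end=start + len(orf),
                   circular=True, name=f"synth{cfg.seed}")


# --------------------------------------------------------------------------
# insertion counts
# --------------------------------------------------------------------------

def _position_weights(cfg: SimulationConfig, gene: Plasmid | None) -> np.ndarray:
    n = cfg.gene_length_codons
    w = np.ones(n)
    if cfg.bias_model == "uniform":
        return w
    if cfg.bias_model == "hotspot":
        rng = _rng(cfg, 2)
        k = max(1, int(round(cfg.hotspot_fraction * n)))
        hot = rng.choice(n, size=k, replace=False)
        w[hot] *= cfg.bias_weight
        return w
    if cfg.bias_model == "trinucleotide":
        if gene is None:
            raise DesignError("trinucleotide bias needs the gene sequence")
        orf = gene.orf_nt
        for i in range(n):
            ctx = orf[3 * i : 3 * i + 3]
            if ctx == cfg.bias_motif:
                w[i] *= cfg.bias_weight
        return w
    raise DesignError(f"unknown bias model {cfg.bias_model!r}")


def simulate_insertion_counts(
    cfg: SimulationConfig, gene: Plasmid | None = None
) -> tuple[InsertionCountTable, pd.DataFrame]:
    """Draw per-position insertion read counts under the configured bias model,
    plus a call table assigning frame/direction uniformly over the six classes
    (the behaviour of an unbiased random-insertion machine)."""
    w = _position_weights(cfg, gene)
    rng = _rng(cfg, 3)
    counts = rng.multinomial(cfg.total_reads, w / w.sum()).astype(float)
    table = InsertionCountTable(gene="synthetic", counts=counts, sample=cfg.bias_model)
    rows = []
    for i, c in enumerate(counts):
        if c == 0:
            continue
        split = rng.multinomial(int(c), np.full(6, 1 / 6))
        for (frame, direction), k in zip(SIX_CLASSES, split):
            if k:
                rows.append(
                    {"position": 3 * i, "frame": frame, "direction": direction, "count": int(k)}
                )
    calls = pd.DataFrame(rows, columns=["position", "frame", "direction", "count"])
    return table, calls


def simulate_sort_counts(
    cfg: SimulationConfig,
) -> tuple[InsertionCountTable, InsertionCountTable, np.ndarray]:
    """Split each position's reads between surface-expressed (SE) and
    non-surface-expressed (NSE) pools by its true permissibility with binomial
    sampling noise. Returns (SE, NSE, ground truth)."""
    n = cfg.gene_length_codons
    if cfg.permissibility is None:
        raise DesignError("simulate_sort_counts needs a true permissibility vector")
    q = np.asarray(cfg.permissibility, float)
    if len(q) != n:
        raise DesignError("permissibility length != gene length")
    rng = _rng(cfg, 4)
    per_pos = rng.multinomial(cfg.reads_per_position * n, np.full(n, 1 / n))
    se = rng.binomial(per_pos, q).astype(float)
    nse = (per_pos - se).astype(float)
    return (
        InsertionCountTable("synthetic", se, sample="SE"),
        InsertionCountTable("synthetic", nse, sample="NSE"),
        q,
    )


# --------------------------------------------------------------------------
# alignments with 1-bp deletions
# --------------------------------------------------------------------------

def simulate_deletion_alignments(cfg: SimulationConfig, path) -> str:
    """Write a SAM file of reads aligned to a synthetic reference in which a
    ``deletion_rate`` fraction carries exactly one 1-nt deletion; byte-identical
    for a fixed seed."""
    rng = _rng(cfg, 5)
    ref_len = max(3 * cfg.gene_length_codons, cfg.read_length + 10)
    ref = "".join(rng.choice(np.array(list("ACGT")), size=ref_len))
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": "synthetic_gene", "LN": ref_len}]}
    rl = cfg.read_length
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(cfg.n_reads):
            start = int(rng.integers(0, ref_len - rl - 1))
            a = pysam.AlignedSegment()
            a.query_name = f"read{i:06d}"
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.flag = 0
            if rng.random() < cfg.deletion_rate:
                k = int(rng.integers(10, rl - 10))
                a.query_sequence = ref[start : start + k] + ref[start + k + 1 : start + rl + 1]
                a.cigarstring = f"{k}M1D{rl - k}M"
            else:
                a.query_sequence = ref[start : start + rl]
                a.cigarstring = f"{rl}M"
            out.write(a)
    return str(path)
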
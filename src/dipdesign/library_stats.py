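"""Library-quality statistics for domain-insertion libraries.

Covers per-gene read-count normalization, ECDF/Kolmogorov-Smirnov bias
comparison, coverage-depth curves, reading-frame/direction class frequencies
and enrichments, 1-bp-deletion frequencies from alignments, insertion-site
sequence-context count matrices (two-sample logo input), and replicate
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .errors import DesignError

FRAMES = (0, 1, 2)
DIRECTIONS = ("plus", "minus")
SIX_CLASSES = [(f, d) for f in FRAMES for d in DIRECTIONS]


@dataclass
class InsertionCountTable:
    """Per-residue insertion read counts for one gene in one sample."""

    gene: str
    counts: np.ndarray        # length = number of residues, index 0 = residue 1
    sample: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise DesignError("counts must be a nonempty 1-D array")
        if (self.counts < 0).any():
            raise DesignError("negative read counts")

    @property
    def n_positions(self) -> int:
        return len(self.counts)

    @property
    def total_reads(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.gene, "position": np.arange(1, self.n_positions + 1),
             "count": self.counts, "sample": self.sample}
        )

    @classmethod
    def from_tsv(cls, path, gene: str | None = None, sample: str = "") -> "InsertionCountTable":
        df = pd.read_csv(path, sep="\t")
        if gene is not None:
            df = df[df["gene"] == gene]
        df = df.sort_values("position")
        n = int(df["position"].max())
        counts = np.zeros(n)
        counts[df["position"].to_numpy() - 1] = df["count"].to_numpy()
        return cls(gene=gene or str(df["gene"].iloc[0]), counts=counts, sample=sample)


def normalized_insertions_per_residue(table: InsertionCountTable) -> np.ndarray:
    """v_i = (r_i / t) * N: each count over the gene total, scaled by gene
    length, so a perfectly even library sits at 1 everywhere (mean is exactly
    1 for any table)."""
    t = table.total_reads
    if t <= 0:
        raise DesignError("zero total reads")
    return table.counts / t * table.n_positions


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_a - ECDF_b| with the
    asymptotic p-value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise DesignError("empty sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def coverage_curve(
    table: InsertionCountTable,
    thresholds: Sequence[float],
    normalize_to: int = 300,
    seed: int = 0,
) -> np.ndarray:
    """Fraction of positions at or above each read-depth threshold, after
    seeded multinomial resampling of the gene to ``normalize_to`` reads per
    position (so genes of different depth are comparable)."""
    t = table.total_reads
    if t <= 0:
        raise DesignError("zero total reads")
    target = int(normalize_to * table.n_positions)
    if t == target:
        resampled = table.counts
    else:
        rng = np.random.default_rng(seed)
        resampled = rng.multinomial(target, table.counts / t)
    return np.array([(resampled >= th).mean() for th in thresholds])


# --------------------------------------------------------------------------
# frame / direction classes
# --------------------------------------------------------------------------

def _class_counts(calls: pd.DataFrame) -> pd.Series:
    required = {"frame", "direction", "count"}
    if not required <= set(calls.columns):
        raise DesignError(f"call table needs columns {sorted(required)}")
    grouped = calls.groupby(["frame", "direction"])["count"].sum()
    idx = pd.MultiIndex.from_tuples(SIX_CLASSES, names=["frame", "direction"])
    return grouped.reindex(idx, fill_value=0).astype(float)


def frame_direction_enrichment(
    sorted_calls: pd.DataFrame, control_calls: pd.DataFrame
) -> pd.DataFrame:
    """Six-class (frame 0/+1/+2 x direction plus/minus) frequencies for the
    sorted sample and the pre-sort control, and their ratio.

    Zero-frequency control classes give a missing (NaN) enrichment, never an
    infinity."""
    s, c = _class_counts(sorted_calls), _class_counts(control_calls)
    if s.sum() == 0 or c.sum() == 0:
        raise DesignError("empty call table")
    fs, fc = s / s.sum(), c / c.sum()
    enr = fs / fc.replace(0, np.nan)
    return pd.DataFrame(
        {"freq_sorted": fs, "freq_control": fc, "enrichment": enr}
    ).reset_index()


# --------------------------------------------------------------------------
# 1-bp deletions from alignments
# --------------------------------------------------------------------------

def deletion_frequency(sam_path) -> tuple[float, int, int]:
    """Fraction of aligned reads whose CIGAR contains a length-1 deletion.

    Reads with several 1-nt deletions count once; unmapped reads are not
    aligned reads."""
    n_reads = 0
    n_del = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.cigartuples is None:
                continue
            n_reads += 1
            if any(op == 2 and ln == 1 for op, ln in read.cigartuples):
                n_del += 1
    if n_reads == 0:
        raise DesignError(f"no aligned reads in {sam_path}")
    return n_del / n_reads, n_del, n_reads


def deletion_enrichment(samples: Mapping[str, object], control: str) -> pd.DataFrame:
    """Per-sample 1-bp-deletion frequency and its ratio to the control sample.

    ``samples`` maps sample name to a SAM path."""
    if control not in samples:
        raise DesignError(f"control sample {control!r} missing")
    rows = []
    freqs = {}
    for name, path in samples.items():
        f, n_del, n_reads = deletion_frequency(path)
        freqs[name] = f
        rows.append({"sample": name, "frequency": f, "n_deletion_reads": n_del,
                     "n_aligned_reads": n_reads})
    if freqs[control] == 0:
        raise DesignError("control deletion frequency is zero")
    df = pd.DataFrame(rows)
    df["enrichment"] = df["frequency"] / freqs[control]
    return df


# --------------------------------------------------------------------------
# insertion-site sequence context (two-sample logo input)
# --------------------------------------------------------------------------

def insertion_context_matrices(
    sites: Sequence[int],
    sequence: str,
    window: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Position-by-base count matrices around insertion points.

    ``sites`` are 0-based nucleotide insertion points (the base immediately
    after the junction); the foreground counts bases at offsets -window..+window-1
    around each site, the background counts every possible junction of the
    sequence. Returns (foreground, background, frequency difference); the
    difference is the two-sample logo input with the compositional background
    removed. Windows are clipped at the sequence ends.
    """
    if len(sites) == 0:
        raise DesignError("empty site list")
    n = len(sequence)
    offsets = list(range(-window, window))
    bases = list("ACGT")

    def count(site_list):
        mat = pd.DataFrame(0.0, index=offsets, columns=bases)
        for s in site_list:
            for off in offsets:
                j = s + off
                if 0 <= j < n and sequence[j] in mat.columns:
                    mat.at[off, sequence[j]] += 1
        return mat

    fg = count(sites)
    bg = count(range(n))
    fg_freq = fg.div(fg.sum(axis=1).replace(0, np.nan), axis=0)
    bg_freq = bg.div(bg.sum(axis=1).replace(0, np.nan), axis=0)
    return fg, bg, (fg_freq - bg_freq).fillna(0.0)


# --------------------------------------------------------------------------
# replicate agreement
# --------------------------------------------------------------------------

def replicate_spearman(values: Sequence[np.ndarray], na_as_zero: bool = True) -> float:
    """Mean pairwise Spearman rank correlation across replicate per-position
    vectors; NaN entries become 0 when ``na_as_zero`` (dropping them entirely
    would discard the sparser replicate's information).

    Returns NaN when a vector is constant (undefined correlation)."""
    if len(values) < 2:
        raise DesignError("need >= 2 replicates")
    arrays = [np.asarray(v, float) for v in values]
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise DesignError("replicate length mismatch")
    if na_as_zero:
        arrays = [np.nan_to_num(a, nan=0.0) for a in arrays]
    rhos = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            if np.all(arrays[i] == arrays[i][0]) or np.all(arrays[j] == arrays[j][0]):
                rhos.append(np.nan)
                continue
            rho, _ = stats.spearmanr(arrays[i], arrays[j])
            rhos.append(rho)
    return float(np.nanmean(rhos)) if not all(np.isnan(r) for r in rhos) else float("nan")
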
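"""Domain-insertion permissibility scoring.

Permissibility of a position is the differential read enrichment between
surface-expressed (SE) and non-surface-expressed (NSE) sorted populations:

    F(i) = r_SE(i) / t_SE  -  r_NSE(i) / t_NSE

with read counts r and sample totals t. Only positions with reads in *both*
populations get a value; all other positions are NA and excluded downstream
(except where correlations explicitly zero-fill). Per-sample profiles are
z-scored, z_i = (x_i - mu) / sigma with the sample (n-1) standard deviation,
and replicates are averaged on the z scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .library_stats import InsertionCountTable


@dataclass
class PermissibilityProfile:
    gene: str
    F: np.ndarray                 # NaN where NA
    z: np.ndarray | None = None   # NaN where NA; set by zscore_profile
    sample: str = ""
    n_replicates: int = 1

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)

    @property
    def na_mask(self) -> np.ndarray:
        return np.isnan(self.F) if self.z is None else np.isnan(self.z)

    @property
    def n_positions(self) -> int:
        return len(self.F)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.n_positions + 1),
                "F": self.F,
                "z": self.z if self.z is not None else np.full(self.n_positions, np.nan),
                "n_replicates": self.n_replicates,
                "na": self.na_mask,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def enrichment_profile(
    counts_se: InsertionCountTable, counts_nse: InsertionCountTable
) -> PermissibilityProfile:
    """Per-position F values; NA wherever either population has zero reads.

    When no position is NA the F values sum to zero exactly (both terms are
    probability vectors)."""
    if counts_se.n_positions != counts_nse.n_positions:
        raise DesignError("SE/NSE length mismatch")
    t_se, t_nse = counts_se.total_reads, counts_nse.total_reads
    if t_se <= 0 or t_nse <= 0:
        raise DesignError("zero total reads in a sorted population")
    F = counts_se.counts / t_se - counts_nse.counts / t_nse
    covered = (counts_se.counts > 0) & (counts_nse.counts > 0)
    F = np.where(covered, F, np.nan)
    return PermissibilityProfile(gene=counts_se.gene, F=F, sample=counts_se.sample)


def zscore_profile(profile: PermissibilityProfile) -> PermissibilityProfile:
    """Standardize F over the non-NA positions (sample mean, n-1 sd); NA
    propagates."""
    x = profile.F
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise DesignError("need >= 2 non-NA positions to z-score")
    mu = x[ok].mean()
    sigma = x[ok].std(ddof=1)
    if sigma == 0:
        raise DesignError("constant profile: sigma = 0")
    z = (x - mu) / sigma
    return PermissibilityProfile(
        gene=profile.gene, F=profile.F, z=z, sample=profile.sample,
        n_replicates=profile.n_replicates,
    )


def aggregate_replicates(profiles: list[PermissibilityProfile]) -> PermissibilityProfile:
    """Position-wise mean of replicate z-scores; a position is NA only where
    every replicate is NA."""
    if len(profiles) < 2:
        raise DesignError("need >= 2 replicates")
    lengths = {p.n_positions for p in profiles}
    if len(lengths) != 1:
        raise DesignError("replicate length mismatch")
    zs = []
    for p in profiles:
        if p.z is None:
            p = zscore_profile(p)
        zs.append(p.z)
    zmat = np.vstack(zs)
    fmat = np.vstack([p.F for p in profiles])
    with np.errstate(invalid="ignore"):
        zbar = np.nanmean(zmat, axis=0)
        fbar = np.nanmean(fmat, axis=0)
    return PermissibilityProfile(
        gene=profiles[0].gene, F=fbar, z=zbar, sample="aggregate",
        n_replicates=len(profiles),
    )


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided normal p-value.

    z = (p1 - p2) / sqrt( p(1-p) (1/n1 + 1/n2) ) with p the pooled proportion.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 == 0 or n2 == 0:
        raise DesignError("counts out of range")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DesignError("degenerate pooled proportion")
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return z, float(p)
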
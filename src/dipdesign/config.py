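"""Design configuration: one dataclass, loadable from a YAML/key-value file."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .errors import DesignError


@dataclass
class DesignConfig:
    """Tunable parameters of the oligo-library design.

    Lengths in nt, temperatures in degrees C. Defaults follow the published
    synthesis and cloning constraints: 230-nt oligos, 12-nt subpool barcodes,
    a 24-nt genetic handle, primer Tm window 55-61, off-target cutoff 35.
    """

    oligo_max: int = 230
    barcode_length: int = 12
    barcode_min_distance: int = 4
    linker5_aa: str = "SG"
    linker3_aa: str = "GS"
    tm_low: float = 55.0
    tm_high: float = 61.0
    offtarget_threshold: float = 35.0
    primer_min: int = 12
    primer_max: int = 35
    frame_base: str = "A"       # N1 spacer between BsmBI site and cut window
    frame_base_alt: str = "T"   # fallback when the spacer creates a banned motif
    seed: int = 0

    def __post_init__(self):
        if self.frame_base == self.frame_base_alt:
            raise DesignError("frame_base and frame_base_alt must differ")
        if self.tm_low >= self.tm_high:
            raise DesignError("empty Tm window")
        if not 0 < self.primer_min <= self.primer_max:
            raise DesignError("bad primer length range")

    @property
    def fixed_costs(self) -> dict[str, int]:
        """Per-oligo overhead: barcodes 2x12, BsmBI sites + frame bases 2x7, handle 24."""
        return {
            "barcodes": 2 * self.barcode_length,
            "sites": 2 * 7,
            "handle": 24,
        }

    @property
    def max_payload(self) -> int:
        """Gene-sequence budget per oligo (nt)."""
        return self.oligo_max - sum(self.fixed_costs.values())

    @classmethod
    def from_file(cls, path) -> "DesignConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise DesignError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
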
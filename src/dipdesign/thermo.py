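"""Nearest-neighbor duplex melting temperatures and primer specificity.

Two published parameter sets are shipped as TSV data files and evaluated side
by side; accept/reject decisions use the mean of the two estimates (both are
always reported). Default solution conditions are 500 nM oligo and 50 mM
monovalent salt, with the entropic salt correction applied to both models.

Off-target annealing is modeled on what drives spurious PCR extension: the
longest contiguous exact match anchored at the primer's 3' end (minimum 6 nt)
at every register on both template strands, scored as the melting temperature
of that matched stretch.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

from .errors import DesignError
from .sequence_core import Plasmid, check_dna, revcomp

R_GAS = 1.9872  # cal/(mol*K)

OFFTARGET_THRESHOLD_C = 35.0  # flag as non-specific when exceeded
MIN_ANCHOR = 6                # shortest 3'-anchored match considered


def _load_nn(name: str) -> dict[str, tuple[float, float]]:
    path = resources.files("dipdesign.data") / name
    table = {}
    with path.open() as fh:
        rows = (line for line in fh if not line.startswith("#"))
        for row in csv.DictReader(rows, delimiter="\t"):
            table[row["key"]] = (float(row["dH"]), float(row["dS"]))
    return table


NN_TABLES: dict[str, dict[str, tuple[float, float]]] = {
    "santalucia": _load_nn("nn_santalucia_hicks.tsv"),
    "sugimoto": _load_nn("nn_sugimoto.tsv"),
}


@dataclass(frozen=True)
class ModelParams:
    """Solution conditions for the duplex model."""

    oligo_molar: float = 500e-9
    monovalent_molar: float = 0.05


DEFAULT_PARAMS = ModelParams()


@dataclass(frozen=True)
class TmEstimate:
    tm_sugimoto: float
    tm_santalucia: float
    model_params: ModelParams = DEFAULT_PARAMS

    @property
    def combined(self) -> float:
        """Mean of the two model estimates — the accept/reject statistic."""
        return 0.5 * (self.tm_sugimoto + self.tm_santalucia)


def _stack_params(table: Mapping[str, tuple[float, float]], dinuc: str) -> tuple[float, float]:
    return table[dinuc] if dinuc in table else table[revcomp(dinuc)]


def _nn_tm(seq: str, table: Mapping[str, tuple[float, float]], params: ModelParams) -> float:
    """Tm (degrees C) of a perfectly matched duplex; no length guard."""
    dh, ds = table["init"]
    for terminal in (seq[0], seq[-1]):
        key = "init_AT" if terminal in "AT" else "init_GC"
        dh += table[key][0]
        ds += table[key][1]
    self_comp = seq == revcomp(seq)
    if self_comp:
        dh += table["sym"][0]
        ds += table["sym"][1]
    for i in range(len(seq) - 1):
        h, s = _stack_params(table, seq[i : i + 2])
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(params.monovalent_molar)
    x = 1.0 if self_comp else 4.0
    return dh * 1000.0 / (ds + R_GAS * math.log(params.oligo_molar / x)) - 273.15


def melting_temperature(seq: str, params: ModelParams = DEFAULT_PARAMS) -> TmEstimate:
    """Duplex Tm under both nearest-neighbor parameter sets.

    Requires length >= 8 and unambiguous bases; deterministic.
    """
    seq = check_dna(seq, "oligo")
    if len(seq) < 8:
        raise DesignError(f"sequence of length {len(seq)} too short for a Tm estimate (need >= 8)")
    return TmEstimate(
        tm_sugimoto=_nn_tm(seq, NN_TABLES["sugimoto"], params),
        tm_santalucia=_nn_tm(seq, NN_TABLES["santalucia"], params),
        model_params=params,
    )


def _stretch_tm(seq: str, params: ModelParams) -> float:
    """Combined-model Tm of an arbitrary-length matched stretch (internal)."""
    if len(seq) < 2:
        return float("-inf")
    return 0.5 * (
        _nn_tm(seq, NN_TABLES["sugimoto"], params)
        + _nn_tm(seq, NN_TABLES["santalucia"], params)
    )


# --- off-target scanning --------------------------------------------------

@dataclass(frozen=True)
class AnnealHit:
    seq_id: str
    strand: str          # template strand the primer pairs with presented as
                         # "plus" (primer reads like the plus strand) / "minus"
    start: int           # plus-strand coords of the matched span, half-open
    end: int
    length: int
    tm: float


def _normalize_template(template) -> list[tuple[str, str, bool]]:
    """Accept a Plasmid, a raw string, (id, seq) pairs, or a mapping."""
    if isinstance(template, Plasmid):
        return [(template.name, template.sequence, template.circular)]
    if isinstance(template, str):
        return [("template", check_dna(template), False)]
    if isinstance(template, Mapping):
        return [(k, check_dna(v, k), False) for k, v in template.items()]
    out = []
    for item in template:
        if isinstance(item, Plasmid):
            out.append((item.name, item.sequence, item.circular))
        else:
            name, seq = item
            out.append((name, check_dna(seq, name), False))
    if not out:
        raise DesignError("empty template")
    return out


def _overlaps(lo: int, hi: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(lo < b and hi > a for a, b in intervals)


def max_offtarget_annealing(
    primer: str,
    template,
    exclude: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    params: ModelParams = DEFAULT_PARAMS,
    min_anchor: int = MIN_ANCHOR,
) -> tuple[float, list[AnnealHit]]:
    """Best spurious annealing of ``primer`` anywhere on ``template``.

    Every register on both strands (circularly for circular templates) is
    scored by the Tm of the longest exact match anchored at the primer 3' end;
    matches shorter than ``min_anchor`` are ignored. ``exclude`` maps sequence
    id to plus-strand intervals (the intended footprint); hits overlapping an
    excluded interval are skipped. Returns (max Tm, all hits); the max is
    ``-inf`` when nothing anneals.
    """
    primer = check_dna(primer, "primer")
    if len(primer) < 8:
        raise DesignError("primer shorter than 8 nt")
    exclude = exclude or {}
    anchor = primer[-min_anchor:]
    hits: list[AnnealHit] = []
    for seq_id, seq, circular in _normalize_template(template):
        n = len(seq)
        excl = list(exclude.get(seq_id, ()))
        for strand in ("plus", "minus"):
            strand_seq = seq if strand == "plus" else revcomp(seq)
            search = strand_seq + strand_seq[: len(primer) - 1] if circular else strand_seq
            pos = search.find(anchor)
            while pos != -1:
                # extend the anchored match toward the primer 5' end
                length = min_anchor
                while (
                    length < len(primer)
                    and pos - (length - min_anchor) - 1 >= 0
                    and search[pos - (length - min_anchor) - 1] == primer[-(length + 1)]
                ):
                    length += 1
                m_start = pos - (length - min_anchor)
                m_end = pos + min_anchor
                # map the match span to plus-strand coordinates
                if strand == "plus":
                    lo = m_start
                else:
                    lo = n - m_end
                span = m_end - m_start
                lo %= n
                excluded = _overlaps(lo, lo + span, excl) or (
                    circular and _overlaps(lo - n, lo - n + span, excl)
                )
                if not excluded:
                    hits.append(
                        AnnealHit(seq_id, strand, lo, lo + span, length,
                                  _stretch_tm(primer[-length:], params))
                    )
                pos = search.find(anchor, pos + 1)
    best = max((h.tm for h in hits), default=float("-inf"))
    return best, sorted(hits, key=lambda h: -h.tm)


def is_specific(
    primer: str,
    template,
    exclude: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    threshold: float = OFFTARGET_THRESHOLD_C,
    params: ModelParams = DEFAULT_PARAMS,
) -> bool:
    """True iff no off-target annealing exceeds ``threshold`` (strictly)."""
    best, _ = max_offtarget_annealing(primer, template, exclude, params)
    return best <= threshold
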
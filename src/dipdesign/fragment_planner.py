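"""Divide a target ORF into codon-aligned fragments with unique Golden Gate
overhangs.

Consecutive fragments share exactly one codon; each boundary's 4-nt overhang
is the boundary codon plus the following wildtype base, so every overhang is a
wildtype subsequence and the shared codon appears both in the neighbor
fragment and in the backbone cut site. Because the one extension base rides in
the gene-payload region of each oligo, the fragment codon cap is
floor((max_payload - 1) / 3).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .errors import DesignError, InfeasibleError
from .sequence_core import Plasmid, revcomp

MIN_FRAGMENT_CODONS = 3
MAX_BOUNDARY_SHIFT = 10  # codons searched outward when de-clashing overhangs


@dataclass
class Fragment:
    index: int               # 1-based
    start_codon: int         # 1-based inclusive
    end_codon: int           # 1-based inclusive
    left_overhang: str = ""
    right_overhang: str = ""

    @property
    def n_codons(self) -> int:
        return self.end_codon - self.start_codon + 1

    @property
    def nt_span(self) -> int:
        return 3 * self.n_codons


@dataclass
class FragmentPlan:
    fragments: list[Fragment]
    max_payload: int

    @property
    def boundaries(self) -> list[int]:
        """Boundary codons: start of fragment 1, each shared codon, end of last."""
        return [self.fragments[0].start_codon] + [f.end_codon for f in self.fragments]

    def to_tsv(self) -> str:
        lines = ["fragment\tstart_codon\tend_codon\tnt_span\tleft_overhang\tright_overhang"]
        for f in self.fragments:
            lines.append(
                f"{f.index}\t{f.start_codon}\t{f.end_codon}\t{f.nt_span}"
                f"\t{f.left_overhang}\t{f.right_overhang}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "max_payload": self.max_payload,
                "fragments": [vars(f) for f in self.fragments],
            },
            indent=2,
        )


def codon_cap(max_payload: int) -> int:
    """Largest fragment size (codons) whose payload plus the one extension base
    fits the budget."""
    return (max_payload - 1) // 3


def boundary_overhang(gene: Plasmid, boundary_codon: int) -> str:
    """4-nt overhang at a boundary: the boundary codon + the next wildtype base.

    For the last codon of the ORF the extension base comes from the plasmid
    context just downstream.
    """
    a = gene.codon_nt_start(boundary_codon)
    return gene.slice(a, a + 4)


def _overhang_key(oh: str) -> frozenset:
    return frozenset((oh, revcomp(oh)))


def _assign_overhangs(plan: FragmentPlan, gene: Plasmid) -> None:
    for frag in plan.fragments:
        frag.left_overhang = boundary_overhang(gene, frag.start_codon)
        frag.right_overhang = boundary_overhang(gene, frag.end_codon)


def overhang_clashes(plan: FragmentPlan) -> list[str]:
    """Human-readable list of overhang invariant violations (empty = valid)."""
    issues = []
    bounds = plan.boundaries
    ohs = [plan.fragments[0].left_overhang] + [f.right_overhang for f in plan.fragments]
    seen: dict[frozenset, int] = {}
    for codon, oh in zip(bounds, ohs):
        if oh == revcomp(oh):
            issues.append(f"palindromic overhang {oh} at codon {codon}")
        key = _overhang_key(oh)
        if key in seen:
            issues.append(
                f"overhang {oh} at codon {codon} collides with boundary at codon {seen[key]}"
            )
        else:
            seen[key] = codon
    return issues


def plan_fragments(gene: Plasmid, oligo_max: int = 230,
                   fixed_costs: int = 62, n_fragments: int | None = None) -> FragmentPlan:
    """Evenly split the ORF to the nearest codon under the oligo length budget.

    ``fixed_costs`` is the non-gene overhead (barcodes 24 + sites 14 + handle
    24 = 62 nt); the remaining payload additionally carries one extension base.
    Fragment lengths differ by at most one codon before any overhang
    adjustment. ``n_fragments`` forces a larger-than-minimal fragment count
    (extra slack for boundary adjustment).
    """
    max_payload = oligo_max - fixed_costs
    cap = codon_cap(max_payload)
    n = gene.n_codons
    if n < 2:
        raise DesignError("gene shorter than 2 codons")
    if cap < MIN_FRAGMENT_CODONS:
        raise InfeasibleError(
            f"oligo budget {oligo_max} leaves a {max_payload}-nt payload; infeasible"
        )
    # K fragments with one shared codon per junction cover n + K - 1 codons
    k = n_fragments or max(1, math.ceil((n - 1) / (cap - 1)))
    if k > 1 and (n + k - 1) / k < MIN_FRAGMENT_CODONS:
        raise InfeasibleError(f"{k} fragments would make fragments too small")
    total = n + k - 1
    base, extra = divmod(total, k)
    fragments = []
    start = 1
    for i in range(k):
        length = base + (1 if i < extra else 0)
        end = start + length - 1
        fragments.append(Fragment(index=i + 1, start_codon=start, end_codon=end))
        start = end  # one-codon overlap
    assert fragments[-1].end_codon == n
    plan = FragmentPlan(fragments=fragments, max_payload=max_payload)
    _assign_overhangs(plan, gene)
    return plan


def _move_boundary(plan: FragmentPlan, gene: Plasmid, boundary_idx: int, delta: int) -> bool:
    """Shift one internal boundary by ``delta`` codons if caps allow."""
    frags = plan.fragments
    if boundary_idx == 0 or boundary_idx == len(frags):
        return False  # gene ends are immovable
    left, right = frags[boundary_idx - 1], frags[boundary_idx]
    new_codon = left.end_codon + delta
    cap = codon_cap(plan.max_payload)
    new_left_len = new_codon - left.start_codon + 1
    new_right_len = right.end_codon - new_codon + 1
    if not (MIN_FRAGMENT_CODONS <= new_left_len <= cap):
        return False
    if not (MIN_FRAGMENT_CODONS <= new_right_len <= cap):
        return False
    left.end_codon = new_codon
    right.start_codon = new_codon
    left.right_overhang = boundary_overhang(gene, new_codon)
    right.left_overhang = left.right_overhang
    return True


def shift_boundary(plan: FragmentPlan, gene: Plasmid, boundary_idx: int, delta: int) -> FragmentPlan:
    """Public boundary adjustment used e.g. when primer design fails; validates
    overhang uniqueness afterwards."""
    if not _move_boundary(plan, gene, boundary_idx, delta):
        raise InfeasibleError(
            f"cannot move boundary {boundary_idx} by {delta} codons within the length caps"
        )
    issues = overhang_clashes(plan)
    if issues:
        raise InfeasibleError("; ".join(issues))
    return plan


def ensure_unique_overhangs(plan: FragmentPlan, gene: Plasmid) -> FragmentPlan:
    """Adjust boundaries (whole codons, greedy outward search, leftmost first)
    until all overhangs are pairwise distinct, reverse-complement distinct and
    non-palindromic.

    Raises :class:`InfeasibleError` naming the clashing boundaries when no
    assignment exists within the +/-10-codon search budget.
    """
    frags = plan.fragments
    n_bounds = len(frags) + 1

    def boundary_codon(i: int) -> int:
        return frags[0].start_codon if i == 0 else frags[i - 1].end_codon

    accepted: dict[frozenset, int] = {}

    def ok(oh: str) -> bool:
        return oh != revcomp(oh) and _overhang_key(oh) not in accepted

    # gene ends first: they cannot move
    for i in (0, n_bounds - 1):
        oh = boundary_overhang(gene, boundary_codon(i))
        if not ok(oh):
            raise InfeasibleError(
                f"overhang {oh} at immovable gene end (boundary {i}) clashes; "
                "shift the ORF or extend the search manually"
            )
        accepted[_overhang_key(oh)] = i

    for i in range(1, n_bounds - 1):
        oh = boundary_overhang(gene, boundary_codon(i))
        if ok(oh):
            accepted[_overhang_key(oh)] = i
            continue
        moved = False
        for step in range(1, MAX_BOUNDARY_SHIFT + 1):
            for delta in (step, -step):
                probe = boundary_codon(i) + delta
                if not 1 < probe < gene.n_codons:
                    continue
                candidate = boundary_overhang(gene, probe)
                if ok(candidate) and _move_boundary(plan, gene, i, delta):
                    accepted[_overhang_key(candidate)] = i
                    moved = True
                    break
            if moved:
                break
        if not moved:
            raise InfeasibleError(
                f"no unique overhang for boundary {i} (codon {boundary_codon(i)}) "
                f"within +/-{MAX_BOUNDARY_SHIFT} codons"
            )
    _assign_overhangs_from_boundaries(plan, gene)
    return plan


def _assign_overhangs_from_boundaries(plan: FragmentPlan, gene: Plasmid) -> None:
    _assign_overhangs(plan, gene)


def plan_unique_fragments(gene: Plasmid, oligo_max: int = 230,
                          fixed_costs: int = 62) -> FragmentPlan:
    """Plan fragments and de-clash overhangs, adding a fragment (more slack
    for boundary moves) when the minimal split leaves no room to adjust."""
    base_k = len(plan_fragments(gene, oligo_max, fixed_costs).fragments)
    last_err: InfeasibleError | None = None
    for k in range(base_k, base_k + 4):
        plan = plan_fragments(gene, oligo_max, fixed_costs, n_fragments=k)
        try:
            return ensure_unique_overhangs(plan, gene)
        except InfeasibleError as err:
            last_err = err
    raise InfeasibleError(f"no unique overhang assignment found: {last_err}")


def reconstruct_orf(plan: FragmentPlan, gene: Plasmid) -> str:
    """Concatenate fragment sequences with their one-codon overlaps removed;
    equals the ORF exactly for any valid plan."""
    parts = []
    for i, f in enumerate(plan.fragments):
        a = gene.codon_nt_start(f.start_codon + (1 if i else 0))
        b = gene.codon_nt_start(f.end_codon) + 3
        parts.append(gene.slice(a, b))
    return "".join(parts)
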
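"""Build the genetic handle, per-position oligos, barcodes and primers.

Oligo layout (5'->3'):

    [fwd barcode 12] [CGTCTC] [frame base] [payload] [frame base] [GAGACG] [rev barcode 12]

where the payload is the fragment sequence (first..last codon plus one
extension base) with the 24-nt handle inserted between two codons. The two
BsmBI sites face inward; digestion releases the payload with the fragment
plan's 4-nt overhangs. The handle carries two outward-facing BsaI sites whose
cut windows fall wholly inside the Ser-Gly / Gly-Ser linker codons, so the
handle can later be replaced by any in-frame domain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .config import DesignConfig
from .errors import DesignError, InfeasibleError
from .fragment_planner import Fragment
from .sequence_core import (
    ENZYMES,
    Plasmid,
    RestrictionSite,
    find_restriction_sites,
    revcomp,
    synonymous_codons,
)
from .thermo import TmEstimate, max_offtarget_annealing, melting_temperature

BSAI = ENZYMES["BsaI"].recognition       # GGTCTC
BSMBI = ENZYMES["BsmBI"].recognition     # CGTCTC
BANNED_MOTIFS = (BSAI, BSMBI)

BARCODE_FLANK_FWD = BSMBI                # fwd barcode is followed by this
BARCODE_FLANK_REV = revcomp(BSMBI)       # rev barcode is preceded by this


# --------------------------------------------------------------------------
# genetic handle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticHandle:
    """The replaceable insert: linker5 | BsaI< | >BsaI | linker3.

    ``left_window``/``right_window`` are the 4-nt BsaI cut windows (inside the
    linker codons) through which a domain later replaces the handle.
    """

    sequence: str
    linker5: str            # codons encoding linker5_aa
    linker3: str
    linker5_aa: str
    linker3_aa: str

    @property
    def bsai_sites(self) -> list[RestrictionSite]:
        return find_restriction_sites(self.sequence, "BsaI")

    @property
    def left_window(self) -> str:
        n5 = len(self.linker5)
        return self.sequence[n5 - 5 : n5 - 1]

    @property
    def right_window(self) -> str:
        n5 = len(self.linker5)
        return self.sequence[n5 + 13 : n5 + 17]

    def domain_amplicon(self, domain: str, frame_base: str = "A") -> str:
        """PCR amplicon that, after BsaI digestion, replaces the handle with
        ``domain`` flanked by the full linkers, in frame."""
        if len(domain) % 3:
            raise DesignError("domain length must be a multiple of 3")
        n5 = len(self.linker5)
        core = self.sequence[n5 - 1] + domain + self.sequence[n5 + 12]
        return (
            BSAI + frame_base + self.left_window + core + self.right_window
            + frame_base + revcomp(BSAI)
        )

    def final_insert(self, domain: str) -> str:
        """DNA placed between two gene codons after the domain swap."""
        return self.linker5 + domain + self.linker3


def build_handle(linker5_aa: str = "SG", linker3_aa: str = "GS") -> GeneticHandle:
    """Choose linker codons so the handle has exactly two outward-facing BsaI
    sites, no BsmBI site, and distinct non-palindromic cut windows.

    With the default 2+2 linkers the handle is exactly 24 nt.
    """
    if len(linker5_aa) < 2 or len(linker3_aa) < 2:
        raise DesignError("each linker needs >= 2 residues to host a 4-nt cut window")

    def codon_choices(aa_seq):
        return itertools.product(*(synonymous_codons(aa) for aa in aa_seq))

    for codons5 in codon_choices(linker5_aa):
        l5 = "".join(codons5)
        for codons3 in codon_choices(linker3_aa):
            l3 = "".join(codons3)
            seq = l5 + revcomp(BSAI) + BSAI + l3
            bsai = find_restriction_sites(seq, "BsaI")
            if len(bsai) != 2 or find_restriction_sites(seq, "BsmBI"):
                continue
            handle = GeneticHandle(seq, l5, l3, linker5_aa, linker3_aa)
            w1, w2 = handle.left_window, handle.right_window
            if w1 == revcomp(w1) or w2 == revcomp(w2):
                continue
            if w1 == w2 or w1 == revcomp(w2):
                continue
            return handle
    raise InfeasibleError(
        f"no codon assignment for linkers {linker5_aa}/{linker3_aa} avoids stray sites"
    )


# --------------------------------------------------------------------------
# barcodes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Barcode:
    sequence: str
    pool_role: str = ""      # "fwd" | "rev" once assigned
    subpool_id: str = ""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _motif_overlapping(ctx: str, lo: int, hi: int) -> bool:
    """A BsaI/BsmBI motif (either strand) overlapping span [lo, hi) of ctx."""
    for motif in BANNED_MOTIFS:
        for m in (motif, revcomp(motif)):
            start = ctx.find(m)
            while start != -1:
                if start < hi and start + len(m) > lo:
                    return True
                start = ctx.find(m, start + 1)
    return False


def _barcode_clean(bc: str) -> bool:
    """No BsaI/BsmBI motif within the barcode or spanning the junction to its
    constant oligo flanks (either role); the flanks' own designed sites do not
    count."""
    if _motif_overlapping(bc, 0, len(bc)):
        return False
    if _motif_overlapping(bc + BARCODE_FLANK_FWD, 0, len(bc)):
        return False
    if _motif_overlapping(BARCODE_FLANK_REV + bc, len(BARCODE_FLANK_REV), len(BARCODE_FLANK_REV) + len(bc)):
        return False
    return True


def generate_barcodes(
    n: int,
    length: int = 12,
    min_distance: int = 4,
    banned_motifs: tuple[str, ...] = BANNED_MOTIFS,
    seed: int = 0,
    max_tries: int = 200_000,
) -> list[str]:
    """Seeded rejection sampling of GC-balanced barcodes with pairwise Hamming
    distance >= ``min_distance`` and no banned motif in oligo context.

    A user-supplied list may be used instead (see :func:`validate_barcodes`).
    """
    if min_distance > length:
        raise InfeasibleError("min_distance exceeds barcode length")
    if n > 4 ** max(0, length - min_distance + 1):
        raise InfeasibleError(f"{n} barcodes of length {length} at distance {min_distance}: infeasible")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    picked: list[str] = []
    lo, hi = length // 2 - 1, length // 2 + 1
    for _ in range(max_tries):
        if len(picked) == n:
            break
        bc = "".join(rng.choice(bases, size=length))
        gc = bc.count("G") + bc.count("C")
        if not lo <= gc <= hi:
            continue
        if not _barcode_clean(bc):
            continue
        if any(_hamming(bc, p) < min_distance for p in picked):
            continue
        picked.append(bc)
    if len(picked) < n:
        raise InfeasibleError(
            f"only {len(picked)}/{n} barcodes found (length {length}, distance {min_distance})"
        )
    return picked


def validate_barcodes(barcodes: list[str], length: int = 12, min_distance: int = 4) -> list[str]:
    """Check a user-supplied barcode list against the same invariants."""
    out = []
    for bc in barcodes:
        bc = bc.strip().upper()
        if len(bc) != length:
            raise DesignError(f"barcode {bc} is not {length} nt")
        if not _barcode_clean(bc):
            raise DesignError(f"barcode {bc} contains or creates a BsaI/BsmBI site")
        out.append(bc)
    for i, a in enumerate(out):
        for b in out[i + 1 :]:
            if _hamming(a, b) < min_distance:
                raise DesignError(f"barcodes {a}/{b} closer than Hamming {min_distance}")
    return out


# --------------------------------------------------------------------------
# oligos
# --------------------------------------------------------------------------

@dataclass
class Oligo:
    gene: str
    subpool_id: str
    insertion_position: int      # 1-based residue after which the handle sits
    full_sequence: str
    barcode_fwd: str
    barcode_rev: str
    payload_start: int = 19      # offset of the payload in full_sequence
    handle_offset: int = 0       # offset of the handle within the payload

    @property
    def name(self) -> str:
        return f"{self.gene}|{self.subpool_id}|{self.insertion_position}"

    @property
    def payload(self) -> str:
        return self.full_sequence[self.payload_start : -self.payload_start]


def fragment_payload(gene: Plasmid, fragment: Fragment, handle: GeneticHandle,
                     position: int) -> tuple[str, int]:
    """Fragment sequence (+1 extension base) with the handle inserted after
    residue ``position``; returns (payload, handle offset)."""
    s, e = fragment.start_codon, fragment.end_codon
    if not s < position < e:
        raise DesignError(
            f"insertion after residue {position} outside the open interval ({s}, {e})"
        )
    a = gene.codon_nt_start(s)
    mid = gene.codon_nt_start(position) + 3
    b = gene.codon_nt_start(e) + 3 + 1  # +1 extension base for the right overhang
    left = gene.slice(a, mid)
    right = gene.slice(mid, b)
    return left + handle.sequence + right, len(left)


def design_subpool_oligos(
    gene: Plasmid,
    fragment: Fragment,
    handle: GeneticHandle,
    barcode_pair: tuple[str, str],
    config: DesignConfig = DesignConfig(),
    gene_name: str = "gene",
) -> list[Oligo]:
    """One oligo per insertion position strictly inside the fragment.

    Positions run from after the fragment's second codon boundary... precisely:
    the handle may sit after any residue p with start_codon < p < end_codon;
    the first and last codons are reserved for the cloning cut sites.
    """
    bc_f, bc_r = barcode_pair
    subpool_id = f"F{fragment.index:02d}"
    oligos = []
    for p in range(fragment.start_codon + 1, fragment.end_codon):
        payload, h_off = fragment_payload(gene, fragment, handle, p)
        full = (
            bc_f + BSMBI + config.frame_base + payload
            + config.frame_base + revcomp(BSMBI) + bc_r
        )
        if len(full) > config.oligo_max:
            raise DesignError(
                f"oligo for position {p} is {len(full)} nt > {config.oligo_max}; "
                "fragment plan violates the payload budget"
            )
        oligos.append(
            Oligo(
                gene=gene_name,
                subpool_id=subpool_id,
                insertion_position=p,
                full_sequence=full,
                barcode_fwd=bc_f,
                barcode_rev=bc_r,
                payload_start=len(bc_f) + len(BSMBI) + 1,
                handle_offset=h_off,
            )
        )
    return oligos


# --------------------------------------------------------------------------
# primers
# --------------------------------------------------------------------------

@dataclass
class Primer:
    name: str
    sequence: str            # full sequence incl. any non-annealing 5' tail
    tail: str                # 5' addition (BsmBI tail for backbone primers)
    anneal: str              # 3' annealing portion
    anneal_span: tuple[int, int]   # plus-strand template coords of the footprint
    strand: str              # template strand amplified: "plus" | "minus"
    tm: TmEstimate
    specific: bool
    role: str                # backbone_fwd | backbone_rev | subpool_fwd | subpool_rev
    subpool_id: str = ""


def _tm_in_window(tm: TmEstimate, config: DesignConfig) -> bool:
    return config.tm_low <= tm.combined <= config.tm_high


def _wrap_interval(lo: int, hi: int, n: int) -> list[tuple[int, int]]:
    """Normalize a possibly origin-spanning interval to in-range pieces."""
    lo %= n
    hi = lo + (hi - lo)
    if hi <= n:
        return [(lo, hi)]
    return [(lo, n), (0, hi - n)]


def design_backbone_primers(
    plasmid: Plasmid,
    fragment: Fragment,
    config: DesignConfig = DesignConfig(),
) -> tuple[Primer, Primer]:
    """Inverse-PCR primer pair amplifying the whole plasmid minus the fragment
    interior, with BsmBI tails whose cut windows equal the plan overhangs.

    The 5' end of each annealing region is pinned to its overhang, so only the
    3' length is tunable; raises :class:`DesignError` when no length in
    [primer_min, primer_max] meets both the Tm window and specificity (the
    caller may then shift the fragment boundary).
    """
    n = len(plasmid.sequence)
    specs = []
    for role in ("backbone_fwd", "backbone_rev"):
        if role == "backbone_fwd":
            start = plasmid.codon_nt_start(fragment.end_codon) % n
            footprint = lambda ln: (start, start + ln)
            anneal_of = lambda ln: plasmid.slice(start, start + ln)
        else:
            end = (plasmid.codon_nt_start(fragment.start_codon) + 4) % n
            footprint = lambda ln: (end - ln, end)
            anneal_of = lambda ln: revcomp(plasmid.slice(end - ln, end))
        reasons = []
        chosen = None
        for ln in range(config.primer_min, config.primer_max + 1):
            anneal = anneal_of(ln)
            tm = melting_temperature(anneal)
            if tm.combined < config.tm_low:
                continue
            if tm.combined > config.tm_high:
                reasons.append(f"{role}: Tm window skipped at length {ln} ({tm.combined:.1f} C)")
                break
            lo, hi = footprint(ln)
            excl = {plasmid.name: _wrap_interval(lo, hi, n)}
            best, _ = max_offtarget_annealing(anneal, plasmid, exclude=excl)
            if best > config.offtarget_threshold:
                reasons.append(f"{role}: off-target {best:.1f} C at length {ln}")
                continue
            lo_n = lo % n
            chosen = Primer(
                name=f"{plasmid.name}_{role}_F{fragment.index:02d}",
                sequence=BSMBI + config.frame_base + anneal,
                tail=BSMBI + config.frame_base,
                anneal=anneal,
                anneal_span=(lo_n, lo_n + ln),
                strand="plus" if role == "backbone_fwd" else "minus",
                tm=tm,
                specific=True,
                role=role,
                subpool_id=f"F{fragment.index:02d}",
            )
            break
        if chosen is None:
            raise DesignError(
                f"no {role} primer for fragment {fragment.index} in "
                f"[{config.primer_min}, {config.primer_max}] nt: "
                + ("; ".join(reasons) if reasons else "Tm never reached the window")
            )
        specs.append(chosen)
    return specs[0], specs[1]


def backbone_amplicon(plasmid: Plasmid, fragment: Fragment, fwd: Primer, rev: Primer) -> str:
    """Top strand of the inverse-PCR product (linear, tails included)."""
    n = len(plasmid.sequence)
    start = fwd.anneal_span[0]
    end = rev.anneal_span[1] % n
    span_len = (end - start) % n
    if span_len == 0:
        span_len = n
    body = plasmid.slice(start, start + span_len)
    return fwd.tail + body + revcomp(rev.tail)


def design_subpool_primers(
    oligos: list[Oligo],
    barcode_pair: tuple[str, str],
    config: DesignConfig = DesignConfig(),
) -> tuple[Primer, Primer]:
    """Subpool amplification primers annealing across barcode + BsmBI + cut
    window; the 3' end is pinned at the cut window, the 5' end is tuned.

    Raises :class:`InfeasibleError` when no length fits the Tm window — the
    caller should swap the barcode and retry.
    """
    if not oligos:
        raise DesignError("empty subpool")
    ref = oligos[0]
    bc_f, bc_r = barcode_pair
    left_const = ref.full_sequence[: ref.payload_start + 4]         # bc + site + frame + left window
    right_const = ref.full_sequence[-(ref.payload_start + 4):]      # right window + frame + site + bc
    out = []
    for role, const in (("subpool_fwd", left_const), ("subpool_rev", revcomp(right_const))):
        chosen = None
        reasons = []
        max_len = len(const)
        for ln in range(config.primer_min, max_len + 1):
            cand = const[-ln:]
            tm = melting_temperature(cand)
            if tm.combined < config.tm_low:
                continue
            if tm.combined > config.tm_high:
                reasons.append(f"{role}: Tm overshoots window at length {ln} ({tm.combined:.1f} C)")
                break
            chosen = Primer(
                name=f"{ref.gene}_{role}_{ref.subpool_id}",
                sequence=cand,
                tail="",
                anneal=cand,
                anneal_span=(0, ln) if role == "subpool_fwd" else (len(ref.full_sequence) - ln, len(ref.full_sequence)),
                strand="plus" if role == "subpool_fwd" else "minus",
                tm=tm,
                specific=True,
                role=role,
                subpool_id=ref.subpool_id,
            )
            break
        if chosen is None:
            raise InfeasibleError(
                f"{role} for subpool {ref.subpool_id}: no length in "
                f"[{config.primer_min}, {max_len}] fits the Tm window "
                f"({'; '.join(reasons) if reasons else 'Tm never reached the window'}); "
                "swap the barcode"
            )
        out.append(chosen)
    return out[0], out[1]
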
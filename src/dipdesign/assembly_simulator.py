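"""In silico type-IIS digestion and Golden Gate ligation.

Fragments are represented on the top strand with both terminal 4-mers
included: a staggered type-IIS cut (1-nt spacer, 4-nt 5' overhang) leaves the
overhang 4-mer on *both* product fragments' top-strand text, so ligation of
two compatible ends merges the shared 4-mer. Ligation requires exact 4/4
overhang complementarity (this is a design-verification oracle, not a
fidelity model); products retaining an intact recognition site are flagged
re-cuttable, as in a real one-pot reaction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DesignError
from .sequence_core import Plasmid, find_restriction_sites, get_enzyme, revcomp


@dataclass(frozen=True)
class DigestFragment:
    sequence: str
    left_overhang: str = ""     # "" = blunt; otherwise the first 4 nt of sequence
    right_overhang: str = ""    # "" = blunt; otherwise the last 4 nt of sequence

    def __post_init__(self):
        if self.left_overhang and not self.sequence.startswith(self.left_overhang):
            raise DesignError("left overhang inconsistent with sequence")
        if self.right_overhang and not self.sequence.endswith(self.right_overhang):
            raise DesignError("right overhang inconsistent with sequence")

    def reverse_complement(self) -> "DigestFragment":
        return DigestFragment(
            revcomp(self.sequence),
            left_overhang=revcomp(self.right_overhang) if self.right_overhang else "",
            right_overhang=revcomp(self.left_overhang) if self.left_overhang else "",
        )


def _cut_windows(seq: str, enzyme: str, circular: bool) -> list[int]:
    """Start coordinates of the 4-nt cut windows, sorted."""
    enz = get_enzyme(enzyme)
    n = len(seq)
    starts = []
    for site in find_restriction_sites(seq, enzyme, circular=circular):
        if site.strand == "plus":
            c = site.position + len(enz.recognition) + enz.spacer
        else:
            c = site.position - enz.spacer - enz.overhang
        if circular:
            starts.append(c % n)
        elif 0 <= c and c + enz.overhang <= n:
            starts.append(c)
    return sorted(set(starts))


def digest_type_iis(seq: str, enzyme: str, circular: bool = False) -> list[DigestFragment]:
    """Cut at every recognition site; recognition sequences stay on the
    fragment that carries them. A site-free input is returned intact."""
    enz = get_enzyme(enzyme)
    k = enz.overhang
    cuts = _cut_windows(seq, enzyme, circular)
    if not cuts:
        return [DigestFragment(seq)]
    n = len(seq)
    frags = []
    if circular:
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            length = (nxt - c) % n or n
            piece = (seq * 3)[c : c + length + k]  # may exceed one period by k
            frags.append(DigestFragment(piece, piece[:k], piece[-k:]))
    else:
        first = seq[: cuts[0] + k]
        frags.append(DigestFragment(first, "", first[-k:]))
        for c, nxt in zip(cuts, cuts[1:]):
            piece = seq[c : nxt + k]
            frags.append(DigestFragment(piece, piece[:k], piece[-k:]))
        last = seq[cuts[-1] :]
        frags.append(DigestFragment(last, last[:k], ""))
    return frags


# --------------------------------------------------------------------------
# ligation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyProduct:
    sequence: str            # top strand of the circular product (one rotation)
    n_parts: int
    recuttable: bool         # an intact recognition site survived


def _min_rotation(s: str) -> str:
    """Lexicographically least rotation (Booth's algorithm, O(n))."""
    ss = s + s
    n = len(s)
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + n]


def canonical_circle(s: str) -> str:
    """Strand- and rotation-independent representative of a circular DNA."""
    return min(_min_rotation(s), _min_rotation(revcomp(s)))


def circular_equal(a: str, b: str) -> bool:
    """Same circular molecule, allowing rotation and strand flip."""
    if len(a) != len(b):
        return False
    doubled = a + a
    return b in doubled or revcomp(b) in doubled


def _has_site(circle: str, enzyme: str) -> bool:
    return bool(find_restriction_sites(circle, enzyme, circular=True))


def assemble_golden_gate(
    parts: list[DigestFragment],
    enzyme: str,
    max_parts: int = 3,
) -> list[AssemblyProduct]:
    """Enumerate circular ligation products of up to ``max_parts`` distinct
    parts (each in either orientation), joining exact-complement overhangs.

    Returns a deterministic, duplicate-free list; an empty list when nothing
    circularizes.
    """
    if not parts:
        raise DesignError("no parts")
    oriented = []
    for idx, p in enumerate(parts):
        if not p.left_overhang or not p.right_overhang:
            continue  # blunt ends cannot join in this model
        oriented.append((idx, p))
        rc = p.reverse_complement()
        if rc.sequence != p.sequence:
            oriented.append((idx, rc))

    products: list[AssemblyProduct] = []

    def close_cycle(chain: list[DigestFragment]) -> None:
        seq = chain[0].sequence
        for nxt in chain[1:]:
            seq = seq + nxt.sequence[4:]
        # circular closure merges the duplicated closing 4-mer
        circle = seq[:-4]
        if any(circular_equal(circle, p.sequence) for p in products):
            return
        products.append(AssemblyProduct(circle, len(chain), _has_site(circle, enzyme)))

    def extend(chain_idx: list[int], chain: list[DigestFragment]) -> None:
        last = chain[-1]
        if last.right_overhang == chain[0].left_overhang:
            close_cycle(chain)
        if len(chain) >= max_parts:
            return
        for idx, cand in oriented:
            if idx in chain_idx:
                continue
            if last.right_overhang == cand.left_overhang:
                extend(chain_idx + [idx], chain + [cand])

    for idx, p in oriented:
        # self-circularization
        if p.left_overhang == p.right_overhang and len(p.sequence) > 8:
            close_cycle([p])
        extend([idx], [p])
    return sorted(products, key=lambda pr: (pr.n_parts, len(pr.sequence), pr.sequence))


# --------------------------------------------------------------------------
# pool verification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Verdict:
    oligo: str
    step1_ok: bool
    step2_ok: bool
    divergence: str = ""

    @property
    def ok(self) -> bool:
        return self.step1_ok and self.step2_ok


def insertion_product(plasmid: Plasmid, position: int, insert: str) -> str:
    """The plasmid with ``insert`` placed after ORF residue ``position``."""
    n = len(plasmid.sequence)
    at = (plasmid.orf_start + 3 * position) % n
    return plasmid.sequence[:at] + insert + plasmid.sequence[at:]


def _first_divergence(product: str, expected: str) -> str:
    if len(product) != len(expected):
        return f"length {len(product)} != expected {len(expected)}"
    anchor = expected[:40]
    at = (product + product).find(anchor)
    if at == -1:
        return "no alignment anchor"
    rotated = (product + product)[at : at + len(product)]
    for i, (a, b) in enumerate(zip(rotated, expected)):
        if a != b:
            return f"first divergent base at {(at + i) % len(product)} ({a}!={b})"
    return "rotationally identical but canonical forms differ"


def _sole_product(parts, enzyme):
    products = assemble_golden_gate(parts, enzyme)
    clean = [p for p in products if not p.recuttable]
    return clean[0] if len(clean) == 1 else None


def _expected_products(plasmid: Plasmid, oligo, fragment, handle, domain: str) -> tuple[str, str]:
    """Expected step-1 and step-2 circles: the wildtype backbone joined to the
    oligo's designed payload (so QC codon recoding is honored), then the
    handle replaced by linker5+domain+linker3."""
    n = len(plasmid.sequence)
    a = plasmid.codon_nt_start(fragment.start_codon) % n
    span = 3 * fragment.n_codons + 1  # fragment plus the extension base
    rotated = plasmid.sequence[a:] + plasmid.sequence[:a]
    payload = oligo.payload
    expected1 = payload + rotated[span:]
    h = oligo.handle_offset
    replaced = payload[:h] + handle.final_insert(domain) + payload[h + len(handle.sequence):]
    expected2 = replaced + rotated[span:]
    return expected1, expected2


def verify_oligo(plasmid: Plasmid, oligo, fragment, backbone: str, handle, domain: str,
                 frame_base: str = "A") -> Verdict:
    """Two-step check for one oligo: (1) BsmBI assembly reconstitutes the
    target plasmid with the handle after the oligo's residue; (2) BsaI
    replacement of the handle yields the in-frame domain insertion."""
    # step 1: subpool fragment + inverse-PCR backbone under BsmBI
    frags_o = digest_type_iis(oligo.full_sequence, "BsmBI")
    frags_b = digest_type_iis(backbone, "BsmBI")
    if len(frags_o) != 3 or len(frags_b) != 3:
        return Verdict(oligo.name, False, False,
                       f"unexpected BsmBI fragment counts {len(frags_o)}/{len(frags_b)}")
    product1 = _sole_product([frags_o[1], frags_b[1]], "BsmBI")
    if product1 is None:
        return Verdict(oligo.name, False, False, "no unique BsmBI assembly product")
    expected1, expected2 = _expected_products(plasmid, oligo, fragment, handle, domain)
    if not circular_equal(product1.sequence, expected1):
        return Verdict(oligo.name, False, False,
                       _first_divergence(product1.sequence, expected1))
    # step 2: replace the handle by the domain under BsaI
    frags_1 = digest_type_iis(product1.sequence, "BsaI", circular=True)
    receiving = [f for f in frags_1 if not find_restriction_sites(f.sequence, "BsaI")]
    frags_d = digest_type_iis(handle.domain_amplicon(domain, frame_base), "BsaI")
    if len(receiving) != 1 or len(frags_d) != 3:
        return Verdict(oligo.name, True, False, "unexpected BsaI digestion pattern")
    product2 = _sole_product([receiving[0], frags_d[1]], "BsaI")
    if product2 is None:
        return Verdict(oligo.name, True, False, "no unique BsaI assembly product")
    if not circular_equal(product2.sequence, expected2):
        return Verdict(oligo.name, True, False,
                       _first_divergence(product2.sequence, expected2))
    return Verdict(oligo.name, True, True)


def verify_pool(design, domain: str) -> list[Verdict]:
    """Run :func:`verify_oligo` for every oligo of a completed design."""
    from .oligo_designer import backbone_amplicon  # local import avoids a cycle

    verdicts = []
    for sp in design.subpools:
        backbone = backbone_amplicon(design.plasmid, sp.fragment,
                                     sp.backbone_fwd, sp.backbone_rev)
        for oligo in sp.oligos:
            verdicts.append(
                verify_oligo(design.plasmid, oligo, sp.fragment, backbone,
                             design.handle, domain, design.config.frame_base)
            )
    return verdicts


def verdicts_tsv(verdicts: list[Verdict]) -> str:
    lines = ["oligo\tstep1_ok\tstep2_ok\tdivergence"]
    for v in verdicts:
        lines.append(f"{v.oligo}\t{int(v.step1_ok)}\t{int(v.step2_ok)}\t{v.divergence}")
    return "\n".join(lines) + "\n"
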
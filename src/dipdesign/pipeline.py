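"""End-to-end library design: domestication, fragmentation, oligo and primer
design, and the final in silico quality-control loop.

The full design is a pure function of (plasmid, config, barcode list/seed):
reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .config import DesignConfig
from .errors import DesignError, InfeasibleError, SwapError
from .fragment_planner import (
    FragmentPlan,
    plan_unique_fragments,
    shift_boundary,
)
from .oligo_designer import (
    BANNED_MOTIFS,
    BSMBI,
    GeneticHandle,
    Oligo,
    Primer,
    build_handle,
    design_backbone_primers,
    design_subpool_oligos,
    design_subpool_primers,
    generate_barcodes,
    validate_barcodes,
)
from .sequence_core import (
    Plasmid,
    find_restriction_sites,
    revcomp,
    silent_codon_swap,
    translate,
)
from .thermo import max_offtarget_annealing

MAX_QC_ITERATIONS = 12
MAX_BARCODE_SWAPS = 24
MAX_BOUNDARY_RETRIES = 30


@dataclass
class QCReport:
    codon_swaps: list = field(default_factory=list)
    barcode_swaps: list = field(default_factory=list)
    frame_flips: list = field(default_factory=list)
    domestication: list = field(default_factory=list)
    boundary_shifts: list = field(default_factory=list)
    failures: list = field(default_factory=list)
    iterations: int = 0

    @property
    def clean(self) -> bool:
        return not self.failures

    def to_json(self) -> str:
        return json.dumps(vars(self), indent=2, default=str)


@dataclass
class Subpool:
    fragment: "Fragment"
    barcode_fwd: str
    barcode_rev: str
    oligos: list[Oligo]
    primer_fwd: Primer | None = None
    primer_rev: Primer | None = None
    backbone_fwd: Primer | None = None
    backbone_rev: Primer | None = None


@dataclass
class LibraryDesign:
    plasmid: Plasmid
    gene_name: str
    config: DesignConfig
    handle: GeneticHandle
    plan: FragmentPlan
    subpools: list[Subpool]
    barcode_pool: list[str]
    barcodes_used: int
    qc_report: QCReport

    @property
    def oligos(self) -> list[Oligo]:
        return [o for sp in self.subpools for o in sp.oligos]

    @property
    def primers(self) -> list[Primer]:
        out = []
        for sp in self.subpools:
            out += [sp.backbone_fwd, sp.backbone_rev, sp.primer_fwd, sp.primer_rev]
        return [p for p in out if p is not None]

    @property
    def insertion_positions(self) -> list[int]:
        return sorted(o.insertion_position for o in self.oligos)

    def next_barcode(self) -> str:
        if self.barcodes_used >= len(self.barcode_pool):
            raise InfeasibleError("barcode pool exhausted during QC")
        bc = self.barcode_pool[self.barcodes_used]
        self.barcodes_used += 1
        return bc

    # -- exports ----------------------------------------------------------
    def oligo_records(self) -> list[tuple[str, str]]:
        return [(o.name, o.full_sequence) for o in self.oligos]

    def primer_table(self) -> str:
        lines = ["name\trole\tsubpool\tsequence\ttm_sugimoto\ttm_santalucia\ttm_combined"]
        for p in self.primers:
            lines.append(
                f"{p.name}\t{p.role}\t{p.subpool_id}\t{p.sequence}"
                f"\t{p.tm.tm_sugimoto:.2f}\t{p.tm.tm_santalucia:.2f}\t{p.tm.combined:.2f}"
            )
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# domestication: remove pre-existing BsaI/BsmBI sites from the target
# --------------------------------------------------------------------------

def domesticate(plasmid: Plasmid, report: QCReport) -> Plasmid:
    """Silently recode ORF codons to remove every BsaI/BsmBI site; sites fully
    outside the ORF cannot be fixed silently and raise."""
    for _ in range(50):
        sites = [
            s
            for enz in ("BsaI", "BsmBI")
            for s in find_restriction_sites(plasmid.sequence, enz, circular=plasmid.circular)
        ]
        if not sites:
            return plasmid
        site = sites[0]
        lo, hi = site.position, site.position + 6
        fixed = False
        n = len(plasmid.sequence)
        for c in range(1, plasmid.n_codons + 1):
            a = plasmid.codon_nt_start(c) % n
            overlaps = any(a + sh < hi and a + sh + 3 > lo for sh in (0, -n, n))
            if not overlaps:
                continue
            codon = plasmid.codon(c)
            residue = translate(codon)
            up = plasmid.slice(plasmid.codon_nt_start(c) - 7, plasmid.codon_nt_start(c))
            down = plasmid.slice(plasmid.codon_nt_start(c) + 3, plasmid.codon_nt_start(c) + 10)
            try:
                new = silent_codon_swap(codon, residue, BANNED_MOTIFS, (up, down))
            except SwapError:
                continue
            a0 = plasmid.codon_nt_start(c) % n
            seq = plasmid.sequence
            if a0 + 3 <= n:
                seq = seq[:a0] + new + seq[a0 + 3 :]
            else:  # codon wraps the origin: bases [a0, n) then [0, a0+3-n)
                k = n - a0
                seq = new[k:] + seq[3 - k : a0] + new[:k]
            plasmid = Plasmid(seq, plasmid.orf_start, plasmid.orf_end,
                              plasmid.circular, plasmid.name)
            report.domestication.append(
                {"enzyme": site.enzyme, "position": site.position, "codon": c,
                 "old": codon, "new": new}
            )
            fixed = True
            break
        if not fixed:
            raise DesignError(
                f"{site.enzyme} site at {site.position} lies outside the ORF "
                "(or is unresolvable); domesticate the plasmid first"
            )
    raise InfeasibleError("domestication did not converge")


# --------------------------------------------------------------------------
# final in silico quality control
# --------------------------------------------------------------------------

def expected_sites(oligo: Oligo, handle: GeneticHandle) -> set[tuple[str, int, str]]:
    """(enzyme, position, strand) of the sites the layout intends."""
    n = len(oligo.full_sequence)
    n5 = len(handle.linker5)
    h = oligo.payload_start + oligo.handle_offset
    return {
        ("BsmBI", oligo.payload_start - 7, "plus"),
        ("BsmBI", n - oligo.payload_start + 1, "minus"),
        ("BsaI", h + n5, "minus"),          # outward-facing, cuts into linker5
        ("BsaI", h + n5 + 6, "plus"),       # outward-facing, cuts into linker3
    }


def unintended_sites(oligo: Oligo, handle: GeneticHandle):
    found = {
        (s.enzyme, s.position, s.strand)
        for enz in ("BsaI", "BsmBI")
        for s in find_restriction_sites(oligo.full_sequence, enz)
    }
    return sorted(found - expected_sites(oligo, handle))


def _rebuild_oligo(oligo: Oligo, payload: str | None = None,
                   bc_f: str | None = None, bc_r: str | None = None,
                   frame_l: str | None = None, frame_r: str | None = None) -> Oligo:
    old = oligo.full_sequence
    ps = oligo.payload_start
    cur_payload = old[ps:-ps]
    payload = payload if payload is not None else cur_payload
    bc_f = bc_f if bc_f is not None else oligo.barcode_fwd
    bc_r = bc_r if bc_r is not None else oligo.barcode_rev
    frame_l = frame_l if frame_l is not None else old[ps - 1]
    frame_r = frame_r if frame_r is not None else old[len(old) - ps]
    full = bc_f + BSMBI + frame_l + payload + frame_r + revcomp(BSMBI) + bc_r
    return Oligo(
        gene=oligo.gene, subpool_id=oligo.subpool_id,
        insertion_position=oligo.insertion_position, full_sequence=full,
        barcode_fwd=bc_f, barcode_rev=bc_r, payload_start=len(bc_f) + 7,
        handle_offset=oligo.handle_offset,
    )


def _payload_coding_codons(oligo: Oligo, handle: GeneticHandle):
    """(payload codon offset, is_gene_codon) pairs; the trailing extension base
    is not a codon."""
    payload_len = len(oligo.full_sequence) - 2 * oligo.payload_start
    h0, h1 = oligo.handle_offset, oligo.handle_offset + len(handle.sequence)
    out = []
    for off in range(0, payload_len - 1, 3):
        if off + 3 > payload_len - 1:
            break
        out.append((off, not (h0 <= off < h1)))
    return out


def _try_codon_fix(oligo: Oligo, handle: GeneticHandle, site, report: QCReport) -> Oligo | None:
    """Silently recode one gene codon overlapping the site; keeps the cut
    windows, the protein and the other designed sites intact."""
    _, pos, _ = site
    ps = oligo.payload_start
    payload = oligo.full_sequence[ps:-ps]
    lo, hi = pos - ps, pos - ps + 6        # site span in payload coordinates
    before = len(unintended_sites(oligo, handle))
    for off, is_gene in _payload_coding_codons(oligo, handle):
        if not is_gene or off + 3 <= lo or off >= hi:
            continue
        codon = payload[off : off + 3]
        residue = translate(codon)
        up = payload[max(0, off - 7) : off]
        down = payload[off + 3 : off + 10]
        try:
            new = silent_codon_swap(codon, residue, BANNED_MOTIFS, (up, down))
        except (SwapError, DesignError):
            continue
        new_payload = payload[:off] + new + payload[off + 3 :]
        if new_payload[:4] != payload[:4] or new_payload[-4:] != payload[-4:]:
            continue  # would corrupt a cloning overhang
        cand = _rebuild_oligo(oligo, payload=new_payload)
        if len(unintended_sites(cand, handle)) < before:
            report.codon_swaps.append(
                {"oligo": oligo.name, "payload_offset": off, "old": codon, "new": new}
            )
            return cand
    return None


def _qc_sites_pass(design: LibraryDesign) -> list[tuple[Subpool, str]]:
    """Remove unintended sites oligo by oligo; returns barcode-swap requests."""
    report = design.qc_report
    swap_requests: list[tuple[Subpool, str]] = []
    for sp in design.subpools:
        for i, oligo in enumerate(sp.oligos):
            guard = 0
            while guard < 8:
                guard += 1
                bad = unintended_sites(oligo, handle=design.handle)
                if not bad:
                    break
                site = bad[0]
                _, pos, _ = site
                n = len(oligo.full_sequence)
                fixed = _try_codon_fix(oligo, design.handle, site, report)
                if fixed is not None:
                    oligo = fixed
                    continue
                if pos < 12 + 6 and (sp, "fwd") not in swap_requests:
                    swap_requests.append((sp, "fwd"))
                    break
                if pos + 6 > n - 12 - 6 and (sp, "rev") not in swap_requests:
                    swap_requests.append((sp, "rev"))
                    break
                ps = oligo.payload_start
                if pos < ps <= pos + 6:      # overlaps the left frame base
                    alt = design.config.frame_base_alt
                    cand = _rebuild_oligo(oligo, frame_l=alt)
                elif pos < n - ps + 1 <= pos + 6:   # right frame base
                    alt = design.config.frame_base_alt
                    cand = _rebuild_oligo(oligo, frame_r=alt)
                else:
                    report.failures.append(
                        {"oligo": oligo.name, "site": site, "reason": "unresolvable site"}
                    )
                    break
                if len(unintended_sites(cand, design.handle)) < len(bad):
                    report.frame_flips.append({"oligo": oligo.name, "site": site})
                    oligo = cand
                else:
                    report.failures.append(
                        {"oligo": oligo.name, "site": site, "reason": "unresolvable site"}
                    )
                    break
            sp.oligos[i] = oligo
    return swap_requests


def _pool_templates(design: LibraryDesign):
    return [(o.name, o.full_sequence) for o in design.oligos] + [design.plasmid]


def _subpool_primer_exclusions(design: LibraryDesign, sp: Subpool, role: str):
    """The designed annealing loci on the primer's own subpool oligos."""
    excl = {}
    width = sp.oligos[0].payload_start + 4
    for o in sp.oligos:
        n = len(o.full_sequence)
        excl[o.name] = [(0, width)] if role == "fwd" else [(n - width, n)]
    return excl


def _swap_barcode(design: LibraryDesign, sp: Subpool, role: str, reason: str) -> None:
    new_bc = design.next_barcode()
    old = sp.barcode_fwd if role == "fwd" else sp.barcode_rev
    if role == "fwd":
        sp.barcode_fwd = new_bc
        sp.oligos = [_rebuild_oligo(o, bc_f=new_bc) for o in sp.oligos]
    else:
        sp.barcode_rev = new_bc
        sp.oligos = [_rebuild_oligo(o, bc_r=new_bc) for o in sp.oligos]
    sp.primer_fwd, sp.primer_rev = design_subpool_primers(
        sp.oligos, (sp.barcode_fwd, sp.barcode_rev), design.config
    )
    design.qc_report.barcode_swaps.append(
        {"subpool": sp.oligos[0].subpool_id, "role": role, "old": old,
         "new": new_bc, "reason": reason}
    )


def final_qc(design: LibraryDesign) -> LibraryDesign:
    """Iterate site removal and pool-wide subpool-primer specificity until the
    pool is clean; bounded, with every change recorded in the QC report."""
    report = design.qc_report
    for iteration in range(MAX_QC_ITERATIONS):
        report.iterations = iteration + 1
        swap_requests = _qc_sites_pass(design)
        for sp, role in swap_requests:
            _swap_barcode(design, sp, role, reason="unintended site at barcode junction")
        if swap_requests:
            continue
        # pool-wide subpool primer specificity
        templates = _pool_templates(design)
        dirty = False
        for sp in design.subpools:
            for role, primer in (("fwd", sp.primer_fwd), ("rev", sp.primer_rev)):
                excl = _subpool_primer_exclusions(design, sp, role)
                best, hits = max_offtarget_annealing(primer.sequence, templates, exclude=excl)
                if best > design.config.offtarget_threshold:
                    if len(report.barcode_swaps) >= MAX_BARCODE_SWAPS:
                        report.failures.append(
                            {"subpool": sp.oligos[0].subpool_id, "role": role,
                             "reason": f"non-specific primer ({best:.1f} C) and swap budget exhausted"}
                        )
                    else:
                        _swap_barcode(design, sp, role,
                                      reason=f"non-specific primer ({best:.1f} C)")
                        dirty = True
                else:
                    primer.specific = True
        if not dirty:
            break
    leftover = [o.name for o in design.oligos if unintended_sites(o, design.handle)]
    for name in leftover:
        if not any(f.get("oligo") == name for f in report.failures):
            report.failures.append({"oligo": name, "reason": "unintended site after QC"})
    return design


# --------------------------------------------------------------------------
# top-level design
# --------------------------------------------------------------------------

def _design_backbone_with_retries(design: LibraryDesign) -> None:
    """Backbone primer design with bounded boundary-shift fallback.

    When a primer cannot meet the Tm window or specificity at a boundary, the
    fragmented site itself is moved by whole codons; positions already tried
    for a boundary are never revisited."""
    cfg, gene, plan = design.config, design.plasmid, design.plan
    pending = set(range(len(plan.fragments)))
    tried: dict[int, set[int]] = {}
    retries = 0
    while pending:
        i = min(pending)
        sp = design.subpools[i]
        try:
            sp.backbone_fwd, sp.backbone_rev = design_backbone_primers(gene, sp.fragment, cfg)
            pending.discard(i)
            continue
        except DesignError as err:
            retries += 1
            if retries > MAX_BOUNDARY_RETRIES:
                raise DesignError(f"backbone primer design did not converge: {err}") from err
            fwd_failed = "backbone_fwd" in str(err)
            boundary_idx = (i + 1) if fwd_failed else i
            current = (
                plan.fragments[boundary_idx].start_codon
                if boundary_idx < len(plan.fragments)
                else plan.fragments[-1].end_codon
            )
            seen = tried.setdefault(boundary_idx, {current})
            moved = False
            for step in range(1, 7):
                for delta in (step, -step):
                    if current + delta in seen:
                        continue
                    try:
                        shift_boundary(plan, gene, boundary_idx, delta)
                    except InfeasibleError:
                        seen.add(current + delta)
                        continue
                    seen.add(current + delta)
                    design.qc_report.boundary_shifts.append(
                        {"boundary": boundary_idx, "delta": delta, "reason": str(err)}
                    )
                    moved = True
                    break
                if moved:
                    break
            if not moved:
                raise DesignError(
                    f"fragment {i + 1}: primer design failed and no boundary shift "
                    f"is available ({err})"
                ) from err
            # neighbors of the moved boundary must be redesigned
            for j in (boundary_idx - 1, boundary_idx):
                if 0 <= j < len(plan.fragments):
                    pending.add(j)


def design_library(
    plasmid: Plasmid,
    config: DesignConfig | None = None,
    gene_name: str = "gene",
    barcodes: list[str] | None = None,
) -> LibraryDesign:
    """Design the complete oligo pool and all primers for one target gene.

    Deterministic for fixed inputs; all QC interventions are recorded in the
    returned design's ``qc_report``.
    """
    config = config or DesignConfig()
    report = QCReport()
    plasmid = domesticate(plasmid, report)
    handle = build_handle(config.linker5_aa, config.linker3_aa)
    plan = plan_unique_fragments(plasmid, config.oligo_max, sum(config.fixed_costs.values()))
    k = len(plan.fragments)
    if barcodes is not None:
        pool = validate_barcodes(barcodes, config.barcode_length, config.barcode_min_distance)
        if len(pool) < 2 * k:
            raise DesignError(f"need at least {2 * k} barcodes, got {len(pool)}")
    else:
        pool = generate_barcodes(
            2 * k + max(8, k), config.barcode_length,
            config.barcode_min_distance, seed=config.seed,
        )
    design = LibraryDesign(
        plasmid=plasmid, gene_name=gene_name, config=config, handle=handle,
        plan=plan, subpools=[], barcode_pool=pool, barcodes_used=0,
        qc_report=report,
    )
    for frag in plan.fragments:
        design.subpools.append(
            Subpool(fragment=frag, barcode_fwd="", barcode_rev="", oligos=[])
        )
    _design_backbone_with_retries(design)
    for sp in design.subpools:
        for attempt in range(10):
            bc_f = sp.barcode_fwd or design.next_barcode()
            bc_r = sp.barcode_rev or design.next_barcode()
            sp.barcode_fwd, sp.barcode_rev = bc_f, bc_r
            sp.oligos = design_subpool_oligos(
                plasmid, sp.fragment, handle, (bc_f, bc_r), config, gene_name
            )
            try:
                sp.primer_fwd, sp.primer_rev = design_subpool_primers(
                    sp.oligos, (bc_f, bc_r), config
                )
                break
            except InfeasibleError as err:
                report.barcode_swaps.append(
                    {"subpool": f"F{sp.fragment.index:02d}", "role": "pair",
                     "old": f"{bc_f}/{bc_r}", "new": "regenerated",
                     "reason": f"Tm infeasible: {err}"}
                )
                sp.barcode_fwd = sp.barcode_rev = ""
        else:
            raise InfeasibleError(
                f"subpool F{sp.fragment.index:02d}: no barcode pair yields primers "
                "in the Tm window"
            )
    final_qc(design)
    return design


def offtarget_ceiling(design: LibraryDesign) -> float:
    """Worst off-target annealing over every accepted primer, each scanned
    against its amplification context: backbone primers against the plasmid
    (intended footprint excluded), subpool primers against the full oligo pool
    (designed loci excluded) and the plasmid."""
    from .oligo_designer import _wrap_interval

    worst = float("-inf")
    n = len(design.plasmid.sequence)
    pool = [(o.name, o.full_sequence) for o in design.oligos]
    for sp in design.subpools:
        for primer in (sp.backbone_fwd, sp.backbone_rev):
            lo, hi = primer.anneal_span
            excl = {design.plasmid.name: _wrap_interval(lo, hi, n)}
            best, _ = max_offtarget_annealing(primer.anneal, design.plasmid, excl)
            worst = max(worst, best)
        for role, primer in (("fwd", sp.primer_fwd), ("rev", sp.primer_rev)):
            excl = _subpool_primer_exclusions(design, sp, role)
            best, _ = max_offtarget_annealing(primer.sequence, pool + [design.plasmid],
                                              exclude=excl)
            worst = max(worst, best)
    return worst
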
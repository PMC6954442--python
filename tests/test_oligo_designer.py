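import pytest

from dipdesign.assembly_simulator import digest_type_iis
from dipdesign.config import DesignConfig
from dipdesign.errors import DesignError, InfeasibleError
from dipdesign.fragment_planner import Fragment
from dipdesign.oligo_designer import (
    build_handle,
    design_subpool_oligos,
    design_subpool_primers,
    generate_barcodes,
    validate_barcodes,
)
from dipdesign.sequence_core import find_restriction_sites, revcomp, translate
from dipdesign.thermo import max_offtarget_annealing, melting_temperature


class TestHandle:
    def test_default_handle_layout(self):
        h = build_handle()
        assert len(h.sequence) == 24
        bsai = h.bsai_sites
        assert len(bsai) == 2
        assert {s.strand for s in bsai} == {"plus", "minus"}
        assert find_restriction_sites(h.sequence, "BsmBI") == []
        # in-frame translation contributes the linkers at both ends
        aa = translate(h.sequence)
        assert aa.startswith("SG") and aa.endswith("GS")

    def test_cut_windows_inside_linker_codons(self):
        h = build_handle()
        n5 = len(h.linker5)
        digest = digest_type_iis("AAAACC" + h.sequence + "GGTTTT", "BsaI")
        assert len(digest) == 3
        left, middle, right = digest
        assert left.right_overhang == h.left_window
        assert right.left_overhang == h.right_window
        # windows fall wholly inside the linker codon spans
        assert h.sequence.index(h.left_window) + 4 <= n5
        assert h.sequence.rindex(h.right_window) >= n5 + 12

    def test_short_linker_rejected(self):
        with pytest.raises(DesignError):
            build_handle(linker5_aa="S", linker3_aa="GS")

    def test_domain_amplicon_recreates_full_linkers(self):
        h = build_handle()
        domain = "GACTTC" * 12
        amp = h.domain_amplicon(domain)
        frags = digest_type_iis(amp, "BsaI")
        assert len(frags) == 3
        insert = frags[1]
        assert insert.left_overhang == h.left_window
        assert insert.right_overhang == h.right_window


class TestSubpoolOligos:
    @pytest.fixture()
    def gene60(self):
        from tests.test_fragment_planner import _random_gene

        return _random_gene(60, seed=11)

    def test_56_codon_fragment_yields_54_oligos(self, gene60):
        """The loop runs from after the first codon to before the last codon:
        positions 2..55 for a fragment spanning codons 1..56 (budget relaxed
        by one base: 56 codons plus the extension base exceed 230 nt)."""
        handle = build_handle()
        frag = Fragment(1, 1, 56)
        oligos = design_subpool_oligos(gene60, frag, handle,
                                       ("ACGGATTGCAAC", "TGCCTAACGTTG"),
                                       DesignConfig(oligo_max=231))
        assert len(oligos) == 54
        assert [o.insertion_position for o in oligos] == list(range(2, 56))
        assert all(len(o.full_sequence) <= 231 for o in oligos)

    def test_cap_sized_fragment_within_budget(self, gene60):
        """At the planner's actual cap (55 codons) every oligo fits 230 nt."""
        handle = build_handle()
        oligos = design_subpool_oligos(gene60, Fragment(1, 1, 55), handle,
                                       ("ACGGATTGCAAC", "TGCCTAACGTTG"))
        assert [o.insertion_position for o in oligos] == list(range(2, 55))
        assert all(len(o.full_sequence) <= 230 for o in oligos)

    def test_payload_translation_is_wildtype_with_handle(self, gene60):
        handle = build_handle()
        frag = Fragment(1, 1, 56)
        oligos = design_subpool_oligos(gene60, frag, handle,
                                       ("ACGGATTGCAAC", "TGCCTAACGTTG"),
                                       DesignConfig(oligo_max=231))
        wt = translate(gene60.slice(gene60.codon_nt_start(1), gene60.codon_nt_start(56) + 3))
        handle_aa = translate(handle.sequence)
        for o in oligos[::7]:
            p = o.insertion_position
            aa = translate(o.payload[:-1])  # drop the extension base
            assert aa == wt[:p] + handle_aa + wt[p:]

    def test_no_position_duplicated_across_adjacent_subpools(self, design_300):
        positions = design_300.insertion_positions
        assert len(positions) == len(set(positions))
        # contiguous runs inside each fragment, single gap at each shared codon
        boundaries = design_300.plan.boundaries
        expected = set(range(2, design_300.plasmid.n_codons)) - set(boundaries[1:-1])
        assert set(positions) == expected


class TestBarcodes:
    def test_pairwise_distance_and_motif_freedom(self):
        bcs = generate_barcodes(20, min_distance=4, seed=5)
        assert len(bcs) == 20
        for i, a in enumerate(bcs):
            assert len(a) == 12
            for motif in ("GGTCTC", "CGTCTC"):
                assert motif not in a and revcomp(motif) not in a
            for b in bcs[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 4

    def test_single_barcode(self):
        assert len(generate_barcodes(1, seed=0)) == 1

    def test_pigeonhole_infeasible(self):
        with pytest.raises(InfeasibleError):
            generate_barcodes(100, length=2, min_distance=3)

    def test_deterministic_under_seed(self):
        assert generate_barcodes(8, seed=42) == generate_barcodes(8, seed=42)

    def test_user_list_validation(self):
        good = generate_barcodes(4, seed=3)
        assert validate_barcodes(good) == good
        with pytest.raises(DesignError):
            validate_barcodes(good + [good[0][:-1] + good[0][-1]])  # distance clash


class TestPrimers:
    def test_backbone_primers_meet_window_and_specificity(self, design_300):
        cfg = design_300.config
        for sp in design_300.subpools:
            for primer in (sp.backbone_fwd, sp.backbone_rev):
                tm = melting_temperature(primer.anneal)
                assert cfg.tm_low <= tm.combined <= cfg.tm_high
                lo, hi = primer.anneal_span
                n = len(design_300.plasmid.sequence)
                excl = {design_300.plasmid.name: [(lo % n, lo % n + (hi - lo))]}
                best, _ = max_offtarget_annealing(primer.anneal, design_300.plasmid, excl)
                assert best <= cfg.offtarget_threshold

    def test_backbone_tail_carries_inward_bsmbi(self, design_300):
        for sp in design_300.subpools:
            assert sp.backbone_fwd.sequence.startswith("CGTCTC")
            assert sp.backbone_rev.sequence.startswith("CGTCTC")

    def test_subpool_primers_anneal_only_their_subpool(self, design_300):
        """In silico PCR: above-threshold annealing only at the designed loci
        of the primer's own subpool."""
        cfg = design_300.config
        pool = [(o.name, o.full_sequence) for o in design_300.oligos]
        for sp in design_300.subpools:
            own = {o.name for o in sp.oligos}
            for role, primer in (("fwd", sp.primer_fwd), ("rev", sp.primer_rev)):
                width = sp.oligos[0].payload_start + 4
                excl = {}
                for o in sp.oligos:
                    n = len(o.full_sequence)
                    excl[o.name] = [(0, width)] if role == "fwd" else [(n - width, n)]
                best, hits = max_offtarget_annealing(primer.sequence, pool, exclude=excl)
                assert best <= cfg.offtarget_threshold
                # and it does anneal strongly at its own designed locus
                best_own, _ = max_offtarget_annealing(
                    primer.sequence, [(o.name, o.full_sequence) for o in sp.oligos]
                )
                assert best_own > cfg.offtarget_threshold

    def test_forced_shared_barcode_detected(self, design_300):
        """A second subpool carrying the same barcode and cut window (as can
        happen across genes in a multi-gene pool) is flagged non-specific."""
        sp0 = design_300.subpools[0]
        clones = [(f"othergene|F01|{o.insertion_position}", o.full_sequence)
                  for o in sp0.oligos]
        width = sp0.oligos[0].payload_start + 4
        excl = {o.name: [(0, width)] for o in sp0.oligos}  # own loci only
        best, hits = max_offtarget_annealing(
            sp0.primer_fwd.sequence,
            [(o.name, o.full_sequence) for o in sp0.oligos] + clones,
            exclude=excl,
        )
        assert best > design_300.config.offtarget_threshold  # planted collision

    def test_single_subpool_pool_trivially_specific(self, design_300):
        sp = design_300.subpools[0]
        width = sp.oligos[0].payload_start + 4
        excl = {o.name: [(0, width)] for o in sp.oligos}
        best, _ = max_offtarget_annealing(
            sp.primer_fwd.sequence, [(o.name, o.full_sequence) for o in sp.oligos],
            exclude=excl,
        )
        assert best <= design_300.config.offtarget_threshold
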
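from dipdesign.assembly_simulator import (
    DigestFragment,
    assemble_golden_gate,
    circular_equal,
    digest_type_iis,
    verify_oligo,
    verify_pool,
)
from dipdesign.oligo_designer import backbone_amplicon
from dipdesign.sequence_core import revcomp, translate

DOMAIN = "GATCTGGAAGCAAACCTGTTCGAA" * 4


class TestDigest:
    def test_single_plus_strand_cut(self):
        #              0123456789...
        seq = "AAAACCCGTCTCTGGGGTTTTAAAACCCC"  # CGTCTC at 7, spacer T, window GGGG
        frags = digest_type_iis(seq, "BsmBI")
        assert len(frags) == 2
        a, b = frags
        assert a.right_overhang == "GGGG" and b.left_overhang == "GGGG"
        assert a.sequence + b.sequence[4:] == seq

    def test_minus_strand_cut_mirrors_plus(self):
        seq = "AAAACCCGTCTCTGGGGTTTTAAAACCCC"
        frags_f = digest_type_iis(seq, "BsmBI")
        frags_r = digest_type_iis(revcomp(seq), "BsmBI")
        assert [f.sequence for f in frags_r] == [
            revcomp(f.sequence) for f in reversed(frags_f)
        ]

    def test_site_free_sequence_unchanged(self):
        seq = "ACGTACGTACGTAAAA"
        frags = digest_type_iis(seq, "BsaI")
        assert len(frags) == 1 and frags[0].sequence == seq

    def test_circular_single_site_yields_one_linearized_fragment(self):
        seq = "CCCGTCTCTGGGGTTTTAAAACCCC"
        circ = seq[10:] + seq[:10]
        frags = digest_type_iis(circ, "BsmBI", circular=True)
        assert len(frags) == 1
        assert frags[0].left_overhang == frags[0].right_overhang == "GGGG"
        assert len(frags[0].sequence) == len(seq) + 4  # shared 4-mer at both ends


class TestAssembly:
    def _two_parts(self):
        backbone = DigestFragment("TTACGGAAACCCTTTGGGATGC", "TTAC", "ATGC")
        insert = DigestFragment("ATGCAAAAAATTAC", "ATGC", "TTAC")
        return backbone, insert

    def test_two_part_join(self):
        backbone, insert = self._two_parts()
        products = assemble_golden_gate([backbone, insert], "BsmBI")
        assert len(products) == 1
        expected = backbone.sequence[:-4] + insert.sequence[:-4]
        assert circular_equal(products[0].sequence, expected)
        assert not products[0].recuttable

    def test_mismatched_overhang_no_product(self):
        backbone, _ = self._two_parts()
        insert = DigestFragment("AAAAAAAAAATTAC", "AAAA", "TTAC")
        assert assemble_golden_gate([backbone, insert], "BsmBI") == []

    def test_three_part_cycle(self):
        a = DigestFragment("AAGGCCCCCCTTCC", "AAGG", "TTCC")
        b = DigestFragment("TTCCGGGGGGACCA", "TTCC", "ACCA")
        c = DigestFragment("ACCATTTTTTAAGG", "ACCA", "AAGG")
        products = assemble_golden_gate([a, b, c], "BsaI")
        cycles = [p for p in products if p.n_parts == 3]
        assert len(cycles) == 1
        assert not cycles[0].recuttable
        expected = a.sequence[:-4] + b.sequence[:-4] + c.sequence[:-4]
        assert circular_equal(cycles[0].sequence, expected)

    def test_intact_site_flagged_recuttable(self):
        backbone = DigestFragment("TTACGGAAACGTCTCTTTGGGATGC", "TTAC", "ATGC")
        insert = DigestFragment("ATGCAAAAAATTAC", "ATGC", "TTAC")
        products = assemble_golden_gate([backbone, insert], "BsmBI")
        assert len(products) == 1 and products[0].recuttable

    def test_digest_then_ligate_roundtrip_identity(self, rng):
        """Digesting a circle at sites with unique overhangs and reassembling
        the pieces regenerates the molecule."""
        arms = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(2)]
        circ = arms[0] + "CGTCTCT" + "GGCA" + arms[1] + "CGTCTCT" + "ATCC"
        frags = digest_type_iis(circ, "BsmBI", circular=True)
        assert len(frags) == 2
        products = assemble_golden_gate(frags, "BsmBI")
        regenerated = [p for p in products if len(p.sequence) == len(circ)]
        assert any(circular_equal(p.sequence, circ) for p in regenerated)


class TestVerifyPool:
    def test_design_verifies_end_to_end(self, design_300):
        verdicts = verify_pool(design_300, DOMAIN)
        assert len(verdicts) == len(design_300.oligos)
        assert all(v.ok for v in verdicts)

    def test_final_products_translate_in_frame(self, design_300):
        """The step-2 product reads as the wildtype protein with SG + domain +
        GS inserted at the oligo's residue — the in-frame guarantee."""
        from dipdesign.assembly_simulator import _expected_products

        handle = design_300.handle
        wt = design_300.plasmid.protein
        domain_aa = translate(DOMAIN)
        sp = design_300.subpools[2]
        for oligo in sp.oligos[::10]:
            _, expected2 = _expected_products(design_300.plasmid, oligo, sp.fragment,
                                              handle, DOMAIN)
            # expected2 starts at the fragment's first codon
            s = sp.fragment.start_codon
            orf_len = 3 * design_300.plasmid.n_codons + len(handle.final_insert(DOMAIN))
            start = -3 * (s - 1) % len(expected2)
            orf = (expected2 + expected2)[start : start + orf_len]
            aa = translate(orf)
            p = oligo.insertion_position
            assert aa == wt[:p] + "SG" + domain_aa + "GS" + wt[p:]

    def test_corrupted_overhang_reported(self, design_300):
        sp = design_300.subpools[0]
        oligo = sp.oligos[5]
        backbone = backbone_amplicon(design_300.plasmid, sp.fragment,
                                     sp.backbone_fwd, sp.backbone_rev)
        import copy

        broken = copy.copy(oligo)
        seq = list(oligo.full_sequence)
        # mutate inside the left cut window
        i = oligo.payload_start + 1
        seq[i] = "A" if seq[i] != "A" else "G"
        broken.full_sequence = "".join(seq)
        verdict = verify_oligo(design_300.plasmid, broken, sp.fragment, backbone,
                               design_300.handle, DOMAIN)
        assert not verdict.ok and verdict.divergence

    def test_domain_with_internal_bsai_site_is_recuttable(self, design_300):
        bad_domain = "GACTTC" * 6 + "GGTCTCA" + "CA" + "GACTTC" * 6  # in-frame BsaI
        assert len(bad_domain) % 3 == 0
        sp = design_300.subpools[0]
        backbone = backbone_amplicon(design_300.plasmid, sp.fragment,
                                     sp.backbone_fwd, sp.backbone_rev)
        verdict = verify_oligo(design_300.plasmid, sp.oligos[0], sp.fragment, backbone,
                               design_300.handle, bad_domain)
        assert verdict.step1_ok and not verdict.step2_ok
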
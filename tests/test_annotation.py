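"""Dictionary-based annotation: matching, cascade, refinement, iteration."""

import pytest

import protacut as pc
from protacut import chem
from protacut.annotation import (
    AnnotatedProtac,
    AnnotationFailure,
    annotate_from_bonds,
    annotate_protac,
    infer_third,
    iterative_refinement,
    match_ligand,
    refine_attachment_points,
)
from protacut.dictionaries import Ligand, build_dictionary


def lig(smiles, role):
    return Ligand.from_smiles(smiles, role)


class TestMatchLigand:
    def test_methyl_warhead_matches_both_terminal_methyls(self):
        matches = match_ligand("CCOCC", lig("C[*:1]", "warhead"))
        assert len(matches) == 2
        assert all(len(m.atoms) == 1 for m in matches)

    def test_no_match_in_aromatic_ring(self):
        assert match_ligand("c1ccccc1", lig("C[*:1]", "warhead")) == []

    def test_attachment_atom_needs_exactly_one_external_bond(self):
        # ethyl warhead fits butane at both ends; in isobutane every
        # embedding leaves the central carbon with two external bonds
        assert len(match_ligand("CCCC", lig("CC[*:1]", "warhead"))) == 2
        assert match_ligand("CC(C)C", lig("CC[*:1]", "warhead")) == []

    def test_junction_bond_order_must_match_dummy_bond(self):
        # methyl warhead joins by a single bond: in propene only the sp3
        # terminal qualifies, the =CH2 end would need a double junction
        matches = match_ligand("C=CC", lig("C[*:1]", "warhead"))
        assert len(matches) == 1


class TestInferThird:
    def test_linker_by_subtraction(self):
        protac = "CCOCC"
        wh = lig("C[*:1]", "warhead")
        e3 = lig("C[*:2]", "e3")
        m_wh = match_ligand(protac, wh)
        m_e3 = match_ligand(protac, e3)
        # pick the two opposite terminals
        pair = next(
            (a, b) for a in m_wh for b in m_e3 if not (a.atoms & b.atoms)
        )
        linker = infer_third(protac, (wh, pair[0]), (e3, pair[1]))
        assert linker.smiles == chem.canonical_smiles("[*:1]COC[*:2]")

    def test_overlapping_matches_rejected(self):
        protac = "CC"
        wh = lig("C[*:1]", "warhead")
        e3 = lig("C[*:2]", "e3")
        m = match_ligand(protac, wh)[0]
        m2 = [x for x in match_ligand(protac, e3) if x.atoms == m.atoms][0]
        with pytest.raises(chem.ContractViolation):
            infer_third(protac, (wh, m), (e3, m2))

    def test_coincident_junctions_rejected(self):
        protac = "CC"
        wh = lig("C[*:1]", "warhead")
        e3 = lig("C[*:2]", "e3")
        m_wh = match_ligand(protac, wh)[0]
        m_e3 = [x for x in match_ligand(protac, e3) if not (x.atoms & m_wh.atoms)][0]
        with pytest.raises(chem.InvalidCutError):
            infer_third(protac, (wh, m_wh), (e3, m_e3))


class TestCascade:
    def test_stage1_recovers_library_recipes_exactly(self, toy_dicts, study_library):
        d_wh, d_link, d_e3 = toy_dicts
        for ann in study_library[:40]:
            res = annotate_protac(ann.parent, d_wh, d_link, d_e3)
            assert isinstance(res, AnnotatedProtac)
            assert res.provenance == "both-ligands-matched"
            assert [l.smiles for l in res.components] == [
                l.smiles for l in ann.components
            ]

    def test_unknown_warhead_recovered_via_later_stages(self, toy_dicts, study_library):
        d_wh, d_link, d_e3 = toy_dicts
        for ann in study_library[:8]:
            d_wh2 = build_dictionary(
                [l.smiles for l in d_wh if l.smiles != ann.warhead.smiles], "warhead"
            )
            res = annotate_protac(ann.parent, d_wh2, d_link, d_e3)
            assert isinstance(res, AnnotatedProtac)
            if res.provenance == "both-ligands-matched":
                # a different, smaller dictionary warhead took over
                assert res.warhead.smiles != ann.warhead.smiles
            back = chem.reassemble(res.warhead.smiles, res.linker.smiles, res.e3.smiles)
            assert back.smiles == ann.parent.smiles

    def test_no_shared_substructure_fails_at_deepest_stage(self, toy_dicts):
        d_wh, d_link, d_e3 = toy_dicts
        res = annotate_protac("c1ccc2ccccc2c1", d_wh, d_link, d_e3)
        assert isinstance(res, AnnotationFailure)
        assert res.stage_reached == 3

    def test_empty_dictionary_is_a_contract_violation(self, toy_dicts):
        d_wh, d_link, d_e3 = toy_dicts
        with pytest.raises(chem.ContractViolation):
            annotate_protac("CCOCC", d_wh, pc.LigandDictionary("linker"), d_e3)


class TestAttachmentRefinement:
    AMIDE_PARENT = "O=C(NCCCCC1CCCCC1)c1ccccc1"

    def test_cut_one_bond_past_amide_is_shifted_onto_cn_bond(self):
        # junction at N-CH2 (bond 2), one bond past the amide C-N (bond 1)
        ann = annotate_from_bonds(self.AMIDE_PARENT, 2, 6)
        refined = refine_attachment_points(ann)
        assert refined.warhead.smiles == chem.canonical_smiles("O=C([*:1])c1ccccc1")
        assert refined.linker.smiles == chem.canonical_smiles("[*:1]NCCCC[*:2]")
        back = chem.reassemble(
            refined.warhead.smiles, refined.linker.smiles, refined.e3.smiles
        )
        assert back.smiles == ann.parent.smiles

    def test_ester_adjacent_cut_relocated_to_co_single_bond(self):
        # junction at CH2-O (bond 3), sharing the ester oxygen (C-O = bond 4)
        parent = "CCCCOC(=O)CCCC1CCCCC1"
        ann = annotate_from_bonds(parent, 3, 9)
        refined = refine_attachment_points(ann)
        assert refined.warhead.smiles == chem.canonical_smiles("CCCCO[*:1]")
        back = chem.reassemble(
            refined.warhead.smiles, refined.linker.smiles, refined.e3.smiles
        )
        assert back.smiles == ann.parent.smiles

    def test_identity_when_no_acyl_group_near_junctions(self):
        ann = annotate_from_bonds("CCCCOCCCC1CCCCC1", 1, 6)
        assert refine_attachment_points(ann) is ann

    def test_idempotent(self):
        ann = annotate_from_bonds(self.AMIDE_PARENT, 2, 6)
        once = refine_attachment_points(ann)
        twice = refine_attachment_points(once)
        assert [l.smiles for l in twice.components] == [
            l.smiles for l in once.components
        ]


class TestIterativeRefinement:
    def _chain_setup(self):
        """toy_needing_round2 becomes annotatable only after toy_donor's
        warhead has been learned from round 1."""
        wh_a = "Cc1ccc(N2CCN([*:1])CC2)cc1"
        wh_other = "c1ccc([*:1])cc1"
        e3_a = "O=C(C)NC1CCC([*:2])CC1"
        e3_b = "CC(=O)N1CCC([*:2])CC1"
        link_long = "[*:1]CCOCCOCC[*:2]"
        link_short = "[*:1]CC[*:2]"
        toy_donor = chem.reassemble(wh_a, link_long, e3_a).smiles
        toy_round2 = chem.reassemble(wh_a, link_short, e3_b).smiles
        d_wh = build_dictionary([wh_other], "warhead")
        d_link = build_dictionary([link_long], "linker")
        d_e3 = build_dictionary([e3_a, e3_b], "e3")
        return [toy_round2, toy_donor], (d_wh, d_link, d_e3)

    def test_dependency_chain_resolved_in_round_two(self):
        corpus, dicts = self._chain_setup()
        result = iterative_refinement(corpus, *dicts)
        assert result.unannotated == []
        assert result.rounds[0]["annotated"] == 1
        assert result.rounds[1]["annotated"] == 1
        assert all(a is not None for a in result.annotations)

    def test_fully_annotatable_corpus_converges_after_one_productive_round(
        self, toy_dicts, study_library
    ):
        d_wh, d_link, d_e3 = toy_dicts
        corpus = [a.parent for a in study_library[:5]]
        result = iterative_refinement(corpus, d_wh, d_link, d_e3)
        assert result.rounds[0]["annotated"] == 5
        assert result.rounds[-1] == {"annotated": 0, "inserted": 0}
        assert len(result.rounds) <= len(corpus) + 1

    def test_empty_corpus(self, toy_dicts):
        result = iterative_refinement([], *toy_dicts)
        assert result.annotations == [] and result.unannotated == []


def test_every_annotation_passes_reassembly_validation(toy_dicts, study_library):
    d_wh, d_link, d_e3 = toy_dicts
    for ann in study_library[:60]:
        res = annotate_protac(ann.parent, d_wh, d_link, d_e3)
        assert isinstance(res, AnnotatedProtac)
        back = chem.reassemble(res.warhead.smiles, res.linker.smiles, res.e3.smiles)
        assert back.smiles == res.parent.smiles
        assert (
            res.warhead.heavy_atoms + res.linker.heavy_atoms + res.e3.heavy_atoms
            == res.parent.heavy_atoms
        )
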
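"""Bond featurization, imbalance-aware training, and cut prediction."""

import numpy as np
import pytest

import protacut as pc
from protacut import chem
from protacut.splitter import (
    Smote,
    SplitterConfig,
    UnsplittableError,
    build_e3_reference,
    featurize_bonds,
    predict_split,
    records_from_annotations,
    train_pipeline,
)


class TestFeaturizeBonds:
    def test_pentane_middle_bonds_have_maximal_line_graph_betweenness(self):
        # line graph of pentane is a 4-node path; hand-computed normalized
        # betweenness: ends 0, middle nodes 2/3
        records = featurize_bonds("CCCCC")
        assert len(records) == 4
        by_bond = {r.bond_idx: r.betweenness for r in records}
        assert by_bond[1] == pytest.approx(2 / 3)
        assert by_bond[2] == pytest.approx(2 / 3)
        assert by_bond[0] == 0.0 and by_bond[3] == 0.0

    def test_benzene_is_unsplittable(self):
        with pytest.raises(UnsplittableError):
            featurize_bonds("c1ccccc1")

    def test_butane_central_bond_first_order_degrees(self):
        records = featurize_bonds("CCCC")
        central = next(r for r in records if r.bond_idx == 1)
        # numeric layout: betweenness, then (max, min) first-order degrees
        assert tuple(central.numeric[1:3]) == (2, 2)

    def test_only_bridge_bonds_produce_records(self, study_library):
        ann = study_library[0]
        mol = chem.mol_from_smiles(ann.parent.smiles)
        records = featurize_bonds(mol)
        ring_bonds = {b.GetIdx() for b in mol.GetBonds() if b.IsInRing()}
        assert not ring_bonds & {r.bond_idx for r in records}

    def test_per_molecule_scaling_maps_betweenness_to_unit_range(self):
        records = featurize_bonds("CCCCC", SplitterConfig(per_molecule_scale=True))
        values = sorted(r.betweenness for r in records)
        assert values[0] == 0.0 and values[-1] == 1.0


class TestLabels:
    def test_exactly_two_positive_records_per_parent(self, study_library):
        records = records_from_annotations(study_library[:50])
        by_parent = {}
        for r in records:
            by_parent.setdefault(r.parent_id, []).append(r.label)
        assert len(by_parent) == 50
        assert all(sum(labels) == 2 for labels in by_parent.values())


class TestSmote:
    def test_balances_classes_and_keeps_originals(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(5, 1, (8, 3))])
        y = np.array([0] * 40 + [1] * 8)
        Xr, yr = Smote(k=3, seed=1).fit_resample(X, y)
        assert (yr == 1).sum() == (yr == 0).sum() == 40
        assert np.array_equal(Xr[:48], X)
        # synthetic points interpolate the minority cloud
        assert Xr[48:].mean() == pytest.approx(5, abs=1.0)

    def test_single_class_is_a_training_error(self):
        with pytest.raises(pc.splitter.TrainingError):
            Smote().fit_resample(np.zeros((5, 2)), np.zeros(5))


class TestTrainingAndPrediction:
    def test_training_is_reproducible_under_fixed_seed(self, train_library):
        config = SplitterConfig(seed=11)
        records = records_from_annotations(train_library[:120], config)
        m1 = train_pipeline(records, config)
        m2 = train_pipeline(records, config)
        probe = featurize_bonds(train_library[150].parent.smiles, config)
        assert np.allclose(m1.predict_scores(probe), m2.predict_scores(probe))

    def test_single_class_input_fails(self, train_library):
        records = [
            r for r in records_from_annotations(train_library[:5]) if r.label == 0
        ]
        with pytest.raises(pc.splitter.TrainingError):
            train_pipeline(records)

    def test_model_ranks_true_junctions_above_random_baseline(
        self, trained_splitter, heldout_library
    ):
        """Held-out top-2 bond accuracy must clearly beat picking two bridge
        bonds at random (sanity power check on learnable junction motifs)."""
        import random

        model, _ = trained_splitter
        rng = random.Random(0)
        hits = rand_hits = 0
        subset = heldout_library[:80]
        for ann in subset:
            mol = chem.mol_from_smiles(ann.parent.smiles)
            truth = {
                mol.GetBondBetweenAtoms(*pair).GetIdx()
                for pair in ann.junction_atoms
            }
            records = featurize_bonds(mol)
            scores = model.predict_scores(records)
            top2 = {
                records[i].bond_idx
                for i in sorted(
                    range(len(records)), key=lambda i: -scores[i]
                )[:2]
            }
            hits += top2 == truth
            rand2 = {r.bond_idx for r in rng.sample(records, 2)}
            rand_hits += rand2 == truth
        assert hits / len(subset) > rand_hits / len(subset) + 0.2

    def test_predictions_always_reassemble_with_zero_extra_atoms(
        self, trained_splitter, heldout_library
    ):
        model, e3_ref = trained_splitter
        for ann in heldout_library[:60]:
            pred = predict_split(model, ann.parent, e3_ref)
            back = chem.reassemble(
                pred.warhead.smiles, pred.linker.smiles, pred.e3.smiles
            )
            assert back.smiles == ann.parent.smiles
            assert (
                pred.warhead.heavy_atoms
                + pred.linker.heavy_atoms
                + pred.e3.heavy_atoms
                == ann.parent.heavy_atoms
            )

    def test_unsplittable_molecule_raises_not_malformed_output(self, trained_splitter):
        model, e3_ref = trained_splitter
        with pytest.raises(UnsplittableError):
            predict_split(model, "c1ccccc1", e3_ref)

    def test_end_fragment_identical_to_reference_member_is_labeled_e3(
        self, heldout_library
    ):
        from protacut.splitter import E3ReferenceSet, _split_at

        ann = heldout_library[0]
        mol = chem.mol_from_smiles(ann.parent.smiles)
        bonds = tuple(
            mol.GetBondBetweenAtoms(*pair).GetIdx() for pair in ann.junction_atoms
        )
        ref = E3ReferenceSet(members=[ann.e3.smiles])
        # feed the cut bonds in both orientations: role assignment must not
        # depend on the orientation of the bond pair
        for pair in (bonds, bonds[::-1]):
            pred = _split_at(
                ann.parent.smiles, pair, ref, source="graph_splitter",
                scores=None, refine=True,
            )
            assert pred.e3.smiles == ann.e3.smiles
            assert pred.warhead.smiles == ann.warhead.smiles


class TestE3Reference:
    def test_k_capped_at_population(self):
        ligs = ["O=C(C)NC1CCC([*:2])CC1", "CC(=O)N1CCC([*:2])CC1", "O=C(CC)C1CCN([*:2])CC1"]
        ref = build_e3_reference(ligs, k=50, seed=0)
        assert sorted(ref.members) == sorted(ligs)

    def test_duplicates_removed_before_clustering(self):
        ligs = ["O=C(C)NC1CCC([*:2])CC1"] * 4
        ref = build_e3_reference(ligs, k=50, seed=0)
        assert len(ref.members) == 1

    def test_two_tight_families_give_one_representative_each(self):
        family_a = [f"O=C({d})NC1CCC([*:2])CC1" for d in ("C", "CC", "CCC")]
        family_b = ["c1ccc(N2CCN([*:2])CC2)cc1", "Cc1ccc(N2CCN([*:2])CC2)cc1"]
        ref = build_e3_reference(family_a + family_b, k=2, seed=0)
        assert len(ref.members) == 2
        sim = chem.tanimoto(
            chem.strip_tags(ref.members[0]), chem.strip_tags(ref.members[1])
        )
        assert sim < 0.4  # one member per family, not two from the same
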
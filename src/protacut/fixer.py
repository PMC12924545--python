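"""Deterministic repair of predicted fragment triples.

Sequence models that emit fragment SMILES occasionally hallucinate or drop
atoms in one component.  Because the parent PROTAC is known and any two
correct components uniquely determine the third, such errors can be repaired:
find a pair of predicted components that embed disjointly in the parent as
attachment-consistent substructures, and replace the third by subtracting the
pair from the parent.  The repair is validated by reassembly.

The hybrid strategy accepts repaired (or already-valid) external predictions
and falls back to the graph splitter — whose outputs reassemble by
construction — whenever repair fails, so hybrid reassembly is 100% on any
input set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from . import chem
from .annotation import _annotation_from_bonds, _as_mol, _match_ligand_in_mol
from .chem import E3_TAG, WARHEAD_TAG, MoleculeRef
from .dictionaries import Ligand
from .splitter import E3ReferenceSet, SplitPrediction, SplitterModel, predict_split

logger = logging.getLogger(__name__)

ROLES = ("warhead", "linker", "e3")


@dataclass(frozen=True)
class FixOutcome:
    prediction: SplitPrediction
    status: str  # unchanged-valid | fixed | unfixable
    repaired_role: str | None = None


def _try_ligand(smiles, role: str) -> Ligand | None:
    try:
        return Ligand.from_smiles(smiles, role)
    except (chem.ParseError, chem.ContractViolation):
        return None


def _junction_pair_for(role_a: str, match_a, role_b: str, match_b):
    """Cut-bond pair (warhead-side, E3-side) implied by two matched roles.

    Returns None when the matches are inconsistent (shared junctions must
    coincide; the two cut bonds must differ).
    """
    by_role = {role_a: match_a, role_b: match_b}
    if "warhead" in by_role and "e3" in by_role:
        b1 = by_role["warhead"].junction_bond(WARHEAD_TAG)
        b2 = by_role["e3"].junction_bond(E3_TAG)
    elif "warhead" in by_role:  # warhead + linker
        wh, lm = by_role["warhead"], by_role["linker"]
        if lm.junction_bond(WARHEAD_TAG) != wh.junction_bond(WARHEAD_TAG):
            return None
        b1, b2 = wh.junction_bond(WARHEAD_TAG), lm.junction_bond(E3_TAG)
    else:  # linker + e3
        lm, e3 = by_role["linker"], by_role["e3"]
        if lm.junction_bond(E3_TAG) != e3.junction_bond(E3_TAG):
            return None
        b1, b2 = lm.junction_bond(WARHEAD_TAG), e3.junction_bond(E3_TAG)
    if b1 == b2:
        return None
    return b1, b2


def fix_triple(parent, predicted: tuple[str, str, str]) -> FixOutcome:
    """Repair a (warhead, linker, e3) SMILES triple against the known parent.

    If the triple already reassembles to the parent it is returned untouched
    (never degraded).  Otherwise every pair of parseable components is tested
    for disjoint attachment-consistent embeddings in the parent; the third
    component is replaced by subtraction and the repair validated by
    reassembly.  Ambiguous diagnoses prefer the pair with the largest joint
    heavy-atom count (repairing the smallest component).
    """
    mol, parent_ref = _as_mol(parent)
    ligands = {
        role: _try_ligand(smi, role) for role, smi in zip(ROLES, predicted)
    }

    if all(ligands.values()):
        try:
            assembled = chem.reassemble(
                ligands["warhead"].smiles, ligands["linker"].smiles, ligands["e3"].smiles
            )
            if assembled.smiles == parent_ref.smiles:
                return FixOutcome(
                    prediction=SplitPrediction(
                        warhead=ligands["warhead"],
                        linker=ligands["linker"],
                        e3=ligands["e3"],
                        source="external_model",
                    ),
                    status="unchanged-valid",
                )
        except (chem.JunctionError, chem.ContractViolation):
            pass

    # Pair preference: terminal-ligand pairs (warhead, e3) anchor both
    # junctions independently of the linker, whereas an erroneous chain
    # linker can still embed shifted by one atom and fabricate a plausible
    # pair; within a pair class, prefer the largest joint heavy-atom count
    # (repairing the smallest component).
    pair_priority = {("warhead", "e3"): 0, ("warhead", "linker"): 1, ("linker", "e3"): 2}
    candidates = []  # (sort_key, bond_pair, repaired_role)
    for role_a, role_b in combinations(ROLES, 2):
        lig_a, lig_b = ligands[role_a], ligands[role_b]
        if lig_a is None or lig_b is None:
            continue
        repaired = next(r for r in ROLES if r not in (role_a, role_b))
        for m_a in _match_ligand_in_mol(mol, lig_a):
            for m_b in _match_ligand_in_mol(mol, lig_b):
                if m_a.atoms & m_b.atoms:
                    continue
                pair = _junction_pair_for(role_a, m_a, role_b, m_b)
                if pair is None:
                    continue
                joint = lig_a.heavy_atoms + lig_b.heavy_atoms
                key = (pair_priority[(role_a, role_b)], -joint, pair)
                candidates.append((key, pair, repaired))
    for _key, pair, repaired in sorted(candidates, key=lambda c: c[0]):
        try:
            ann = _annotation_from_bonds(mol, parent_ref, pair[0], pair[1], "manual")
        except (chem.InvalidCutError, chem.JunctionError, chem.ContractViolation):
            continue
        return FixOutcome(
            prediction=SplitPrediction(
                warhead=ann.warhead, linker=ann.linker, e3=ann.e3, source="fixed"
            ),
            status="fixed",
            repaired_role=repaired,
        )
    original = SplitPrediction(
        warhead=ligands["warhead"] or _placeholder(predicted[0], "warhead"),
        linker=ligands["linker"] or _placeholder(predicted[1], "linker"),
        e3=ligands["e3"] or _placeholder(predicted[2], "e3"),
        source="external_model",
    )
    return FixOutcome(prediction=original, status="unfixable")


def _placeholder(raw: str, role: str) -> Ligand:
    """Carrier for an unparseable predicted string (kept verbatim)."""
    return Ligand(smiles=raw, role=role, heavy_atoms=0, stereo_free=True)


def hybrid_split(
    parent,
    external_prediction: tuple[str, str, str],
    fallback_model: SplitterModel,
    e3_ref: E3ReferenceSet,
) -> SplitPrediction:
    """Accept fixed/valid external predictions; otherwise fall back to the
    graph splitter, whose outputs always reassemble.  Unsplittable parents
    propagate :class:`splitter.UnsplittableError`."""
    outcome = fix_triple(parent, external_prediction)
    if outcome.status != "unfixable":
        return outcome.prediction
    parent_ref = parent if isinstance(parent, MoleculeRef) else chem.canonicalize(parent)
    pred = predict_split(fallback_model, parent_ref, e3_ref)
    return SplitPrediction(
        warhead=pred.warhead,
        linker=pred.linker,
        e3=pred.e3,
        source="hybrid",
        scores=pred.scores,
    )
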
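"""Evaluation metrics for predicted PROTAC splits.

Four metrics, each a different lens on a prediction set:

* **validity** — fraction of predictions whose three SMILES all parse;
* **exact-match** — fraction whose three components are string-equal to the
  labels after canonicalization, attachment tags included;
* **reassembly** — fraction whose components, joined at their tags and
  canonicalized, reproduce the parent exactly;
* **extra atoms** — mean heavy-atom difference ``heavy(parent) -
  heavy(reassembled)`` computed only over predictions failing reassembly
  (positive = missing atoms, negative = hallucinated atoms).

Per-component breakdowns report validity, exact-match, and extra atoms
independently per role.  An exact match always reassembles, so globally
``exact_match <= reassembly``; a valid triple need not reassemble.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from . import chem
from .annotation import AnnotatedProtac
from .splitter import E3ReferenceSet, SplitPrediction, UnsplittableError, featurize_bonds
from .dictionaries import Ligand

ROLES = ("warhead", "linker", "e3")


@dataclass
class RoleMetrics:
    validity: float
    exact_match: float
    extra_atoms_mean: float
    n_extra_atoms: int  # reassembly failures contributing to the mean


@dataclass
class EvalReport:
    n: int
    validity: float
    exact_match: float
    reassembly: float
    extra_atoms_mean: float
    n_reassembly_failures: int
    per_role: dict[str, RoleMetrics] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "validity": self.validity,
            "exact_match": self.exact_match,
            "reassembly": self.reassembly,
            "extra_atoms_mean": self.extra_atoms_mean,
            "n_reassembly_failures": self.n_reassembly_failures,
            "per_role": {
                role: {
                    "validity": m.validity,
                    "exact_match": m.exact_match,
                    "extra_atoms_mean": m.extra_atoms_mean,
                    "n_extra_atoms": m.n_extra_atoms,
                }
                for role, m in self.per_role.items()
            },
        }


def _triple(prediction) -> tuple[str, str, str]:
    if isinstance(prediction, SplitPrediction):
        return tuple(lig.smiles for lig in prediction.components)
    wh, link, e3 = prediction
    return (wh, link, e3)


def evaluate(predictions: Sequence, labels: Sequence[AnnotatedProtac]) -> EvalReport:
    """Score aligned prediction/label lists on all four metrics.

    Predictions may be :class:`SplitPrediction` objects or raw
    (warhead, linker, e3) SMILES triples; strings are canonicalized before
    comparison so metric values are invariant to input SMILES formatting.
    """
    if len(predictions) != len(labels):
        raise chem.ContractViolation(
            f"{len(predictions)} predictions vs {len(labels)} labels"
        )
    n = len(labels)
    n_valid = n_exact = n_reassembled = 0
    extra_sum = 0
    n_fail = 0
    role_valid = dict.fromkeys(ROLES, 0)
    role_exact = dict.fromkeys(ROLES, 0)
    role_extra: dict[str, list[int]] = {r: [] for r in ROLES}

    for pred, label in zip(predictions, labels):
        raw = _triple(pred)
        mols = [chem.try_mol_from_smiles(s) for s in raw]
        canon = [
            chem.Chem.MolToSmiles(m) if m is not None else None for m in mols
        ]
        label_smis = [lig.smiles for lig in label.components]

        valid = all(m is not None for m in mols)
        n_valid += valid
        exact_roles = [
            c is not None and c == l for c, l in zip(canon, label_smis)
        ]
        for role, v, e in zip(ROLES, mols, exact_roles):
            role_valid[role] += v is not None
            role_exact[role] += e
        exact = all(exact_roles)
        n_exact += exact

        reassembled = False
        if valid:
            try:
                assembled = chem.reassemble(*canon)
                reassembled = assembled.smiles == label.parent.smiles
            except (chem.JunctionError, chem.ContractViolation):
                reassembled = False
        n_reassembled += reassembled
        if not reassembled:
            n_fail += 1
            pred_heavy = sum(
                chem.heavy_atom_count(m) for m in mols if m is not None
            )
            extra_sum += label.parent.heavy_atoms - pred_heavy
            for role, m, lig in zip(ROLES, mols, label.components):
                if m is not None:
                    role_extra[role].append(lig.heavy_atoms - chem.heavy_atom_count(m))

    per_role = {
        role: RoleMetrics(
            validity=role_valid[role] / n if n else 0.0,
            exact_match=role_exact[role] / n if n else 0.0,
            extra_atoms_mean=(
                sum(role_extra[role]) / len(role_extra[role]) if role_extra[role] else 0.0
            ),
            n_extra_atoms=len(role_extra[role]),
        )
        for role in ROLES
    }
    return EvalReport(
        n=n,
        validity=n_valid / n if n else 0.0,
        exact_match=n_exact / n if n else 0.0,
        reassembly=n_reassembled / n if n else 0.0,
        extra_atoms_mean=extra_sum / n_fail if n_fail else 0.0,
        n_reassembly_failures=n_fail,
        per_role=per_role,
    )


def baseline_centrality_split(
    protac, e3_ref: E3ReferenceSet, *, min_end_atoms: int = 5, refine: bool = True
) -> SplitPrediction:
    """Learning-free baseline: cut the two most central bridge bonds.

    Bonds are ranked by line-graph betweenness; the highest-ranked pair whose
    cut leaves both end fragments with at least ``min_end_atoms`` heavy atoms
    is used (falling back to the top pair if none qualifies).  Role assignment
    follows the graph splitter.  This is a simple centrality heuristic native
    to this package, not a published algorithm.
    """
    from .splitter import _split_at  # shared cut/orient/refine plumbing

    smi = protac.smiles if isinstance(protac, chem.MoleculeRef) else protac
    parent = chem.canonicalize(smi)
    records = featurize_bonds(parent)  # raises UnsplittableError when < 2 bridges
    ranked = sorted(records, key=lambda r: (-r.betweenness, r.bond_idx))
    mol = chem.mol_from_smiles(parent.smiles)

    def end_sizes(b1: int, b2: int):
        cut = chem.cut_two_bonds(mol, (b1, b2))
        return (
            chem.canonicalize(cut.end1).heavy_atoms,
            chem.canonicalize(cut.end2).heavy_atoms,
        )

    best = None
    for r1, r2 in itertools.combinations(ranked, 2):
        if best is None:
            best = (r1.bond_idx, r2.bond_idx)
        try:
            s1, s2 = end_sizes(r1.bond_idx, r2.bond_idx)
        except chem.InvalidCutError:  # pragma: no cover
            continue
        if s1 >= min_end_atoms and s2 >= min_end_atoms:
            best = (r1.bond_idx, r2.bond_idx)
            break
    if best is None:  # pragma: no cover - featurize_bonds guarantees >= 2
        raise UnsplittableError(parent.smiles)
    pred = _split_at(
        parent.smiles, best, e3_ref, source="graph_splitter", scores=None, refine=refine
    )
    return pred
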
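"""Core SMILES handling, attachment-point conventions, fragmentation and reassembly.

PROTAC fragments are exchanged as attachment-tagged SMILES: a dummy atom with
atom-map number 1 (``[*:1]``) marks the warhead-facing junction and map number 2
(``[*:2]``) the E3-facing junction.  A warhead carries exactly one ``[*:1]``, an
E3 ligase ligand exactly one ``[*:2]``, and a linker one of each.  The bond
drawn between a dummy and its real neighbor records the junction bond order;
reassembly requires the orders to agree pairwise across each junction.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from rdkit import Chem, RDLogger
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

WARHEAD_TAG = 1
E3_TAG = 2

_BOND_ORDER_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_BOND_ORDER_TYPES = {v: k for k, v in _BOND_ORDER_NAMES.items()}


class ParseError(ValueError):
    """A SMILES string could not be parsed/sanitized."""


class ContractViolation(ValueError):
    """An input violates a documented precondition (e.g. wrong tag count)."""


class JunctionError(ValueError):
    """Junction bond orders disagree across a fragment junction."""


class InvalidCutError(ValueError):
    """A requested cut bond is not a distinct bridge (non-ring) bond."""


@dataclass(frozen=True)
class MoleculeRef:
    """A molecule pinned to its canonical SMILES form."""

    smiles: str
    heavy_atoms: int


@dataclass(frozen=True)
class JunctionBond:
    """Descriptor of a junction: bond order plus ordered element pair.

    Elements are ordered reading the PROTAC left to right: for the
    warhead-linker junction ``(warhead_atom, linker_atom)``, for the
    linker-E3 junction ``(linker_atom, e3_atom)``.
    """

    order: str
    elements: tuple[str, str]


class CutResult(NamedTuple):
    """Fragments from a two-bond cut; roles are assigned by the caller."""

    end1: str  # carries [*:1]
    linker: str  # carries [*:1] and [*:2]
    end2: str  # carries [*:2]


def mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str):
        raise ParseError(f"expected a SMILES string, got {type(smiles).__name__}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def try_mol_from_smiles(smiles) -> Chem.Mol | None:
    if not isinstance(smiles, str):
        return None
    return Chem.MolFromSmiles(smiles)


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Non-hydrogen, non-dummy atom count."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def canonicalize(smiles: str) -> MoleculeRef:
    """Canonicalize a SMILES string, preserving atom-map numbers on dummies.

    Raises :class:`ParseError` on syntactically or chemically invalid input
    (e.g. a pentavalent carbon).
    """
    mol = mol_from_smiles(smiles)
    return MoleculeRef(Chem.MolToSmiles(mol), heavy_atom_count(mol))


def canonical_smiles(smiles: str) -> str:
    return canonicalize(smiles).smiles


def strip_stereo(smiles: str) -> str:
    """Remove all chiral tags and double-bond stereo, then canonicalize."""
    mol = mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def dummy_atoms(mol: Chem.Mol) -> list[Chem.Atom]:
    return [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def tag_counts(mol: Chem.Mol) -> dict[int, int]:
    """Map of attachment tag -> number of dummies carrying it."""
    counts: dict[int, int] = {}
    for a in dummy_atoms(mol):
        counts[a.GetAtomMapNum()] = counts.get(a.GetAtomMapNum(), 0) + 1
    return counts


ROLE_TAGS = {
    "warhead": {WARHEAD_TAG: 1},
    "linker": {WARHEAD_TAG: 1, E3_TAG: 1},
    "e3": {E3_TAG: 1},
    "protac": {},
}


def validate_role_tags(mol: Chem.Mol, role: str) -> None:
    """Enforce the attachment-tag invariant for a fragment role."""
    if role not in ROLE_TAGS:
        raise ContractViolation(f"unknown role {role!r}")
    counts = tag_counts(mol)
    if counts != ROLE_TAGS[role]:
        raise ContractViolation(
            f"role {role!r} requires tags {ROLE_TAGS[role]}, got {counts}"
        )


def bond_order_name(bond: Chem.Bond) -> str:
    name = _BOND_ORDER_NAMES.get(bond.GetBondType())
    if name is None:
        raise ContractViolation(f"unsupported bond type {bond.GetBondType()}")
    return name


def _single_dummy(mol: Chem.Mol, tag: int) -> Chem.Atom:
    ds = [a for a in dummy_atoms(mol) if a.GetAtomMapNum() == tag]
    if len(ds) != 1:
        raise ContractViolation(f"expected exactly one [*:{tag}] dummy, found {len(ds)}")
    return ds[0]


def attachment_info(mol: Chem.Mol, tag: int) -> tuple[int, str, str]:
    """(neighbor atom index, neighbor element, dummy-bond order) for a tag."""
    d = _single_dummy(mol, tag)
    nbrs = d.GetNeighbors()
    if len(nbrs) != 1:
        raise ContractViolation(f"dummy [*:{tag}] must have exactly one neighbor")
    nbr = nbrs[0]
    bond = mol.GetBondBetweenAtoms(d.GetIdx(), nbr.GetIdx())
    return nbr.GetIdx(), nbr.GetSymbol(), bond_order_name(bond)


def canonical_order_map(mol: Chem.Mol) -> tuple[str, list[int]]:
    """Canonical SMILES plus mapping ``old_atom_index -> canonical_atom_index``.

    The canonical index is the atom's position in the mol obtained by
    re-parsing the returned SMILES.
    """
    smi = Chem.MolToSmiles(mol)
    order = ast.literal_eval(mol.GetProp("_smilesAtomOutputOrder"))
    mapping = [0] * mol.GetNumAtoms()
    for canon_idx, old_idx in enumerate(order):
        mapping[old_idx] = canon_idx
    return smi, mapping


def reassemble(
    warhead: str, linker: str, e3: str, *, return_junctions: bool = False
):
    """Join three attachment-tagged fragments into the parent molecule.

    The warhead's ``[*:1]`` neighbor is bonded to the linker's ``[*:1]``
    neighbor, the linker's ``[*:2]`` neighbor to the E3 ligand's ``[*:2]``
    neighbor; dummies are deleted and the result canonicalized.

    With ``return_junctions=True`` returns
    ``(MoleculeRef, junction_atoms, junction_bonds)`` where ``junction_atoms``
    are the two joined atom-index pairs in the canonical-order parent mol and
    ``junction_bonds`` the two :class:`JunctionBond` descriptors.
    """
    wm, lm, em = (mol_from_smiles(s) for s in (warhead, linker, e3))
    validate_role_tags(wm, "warhead")
    validate_role_tags(lm, "linker")
    validate_role_tags(em, "e3")

    combined = Chem.CombineMols(Chem.CombineMols(wm, lm), em)
    off_l = wm.GetNumAtoms()
    off_e = off_l + lm.GetNumAtoms()

    w_n, w_el, w_ord = attachment_info(wm, WARHEAD_TAG)
    l1_n, l1_el, l1_ord = attachment_info(lm, WARHEAD_TAG)
    l2_n, l2_el, l2_ord = attachment_info(lm, E3_TAG)
    e_n, e_el, e_ord = attachment_info(em, E3_TAG)
    if w_ord != l1_ord:
        raise JunctionError(f"warhead/linker junction orders differ: {w_ord} vs {l1_ord}")
    if l2_ord != e_ord:
        raise JunctionError(f"linker/E3 junction orders differ: {l2_ord} vs {e_ord}")

    rw = Chem.RWMol(combined)
    pairs = [
        (w_n, off_l + l1_n, _BOND_ORDER_TYPES[w_ord]),
        (off_l + l2_n, off_e + e_n, _BOND_ORDER_TYPES[l2_ord]),
    ]
    for a, b, bt in pairs:
        rw.AddBond(a, b, bt)
    doomed = sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    )
    for idx in doomed:
        rw.RemoveAtom(idx)

    # account for index shifts from dummy removal
    def shifted(i: int) -> int:
        return i - sum(1 for d in doomed if d < i)

    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - valence clash at a junction
        raise JunctionError(f"reassembled molecule failed sanitization: {exc}") from exc
    smi, order = canonical_order_map(mol)
    ref = MoleculeRef(smi, heavy_atom_count(mol))
    if not return_junctions:
        return ref
    junction_atoms = (
        (order[shifted(pairs[0][0])], order[shifted(pairs[0][1])]),
        (order[shifted(pairs[1][0])], order[shifted(pairs[1][1])]),
    )
    junction_bonds = (
        JunctionBond(w_ord, (w_el, l1_el)),
        JunctionBond(l2_ord, (l2_el, e_el)),
    )
    return ref, junction_atoms, junction_bonds


def bridge_bond_indices(mol: Chem.Mol) -> list[int]:
    """Indices of non-ring bonds between heavy atoms (SSSR membership test)."""
    out = []
    for b in mol.GetBonds():
        if b.IsInRing():
            continue
        if b.GetBeginAtom().GetAtomicNum() == 0 or b.GetEndAtom().GetAtomicNum() == 0:
            continue
        out.append(b.GetIdx())
    return out


def cut_two_bonds(protac, bonds: Sequence[int]) -> CutResult:
    """Cut two distinct bridge bonds, returning three attachment-tagged fragments.

    The unique fragment incident to both cuts is the linker (two tags); the
    fragment severed at ``bonds[0]`` receives ``[*:1]`` and the fragment
    severed at ``bonds[1]`` receives ``[*:2]``.  Role orientation is the
    caller's business.
    """
    mol = protac if isinstance(protac, Chem.Mol) else mol_from_smiles(
        protac.smiles if isinstance(protac, MoleculeRef) else protac
    )
    b1, b2 = bonds
    if b1 == b2:
        raise InvalidCutError("cut bonds must be distinct")
    for b in (b1, b2):
        bond = mol.GetBondWithIdx(int(b))
        if bond.IsInRing():
            raise InvalidCutError(f"bond {b} is a ring bond; only bridge bonds may be cut")
    frag = Chem.FragmentOnBonds(
        mol, [int(b1), int(b2)], addDummies=True, dummyLabels=[(1, 1), (2, 2)]
    )
    pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
    if len(pieces) != 3:  # pragma: no cover - bridge cuts always give 3
        raise InvalidCutError(f"cut produced {len(pieces)} fragments, expected 3")
    end1 = linker = end2 = None
    for piece in pieces:
        isotopes = sorted(
            a.GetIsotope() for a in piece.GetAtoms() if a.GetAtomicNum() == 0
        )
        for a in piece.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(a.GetIsotope())
                a.SetIsotope(0)
        Chem.SanitizeMol(piece)
        smi = Chem.MolToSmiles(piece)
        if isotopes == [1, 2]:
            linker = smi
        elif isotopes == [1]:
            end1 = smi
        elif isotopes == [2]:
            end2 = smi
        else:  # pragma: no cover
            raise InvalidCutError(f"unexpected dummy labels {isotopes} in fragment")
    if end1 is None or linker is None or end2 is None:
        raise InvalidCutError("the two cut bonds do not define an end-linker-end path")
    return CutResult(end1, linker, end2)


def junction_descriptors(mol: Chem.Mol, bond_pair: Sequence[int]) -> tuple[JunctionBond, JunctionBond]:
    """JunctionBond descriptors for the two cut bonds of an annotation.

    ``bond_pair`` holds the warhead-side and E3-side junction bond indices.
    Element order follows the warhead->linker->E3 reading direction: the
    linker-side atom is the one in the linker fragment.
    """
    cut = cut_two_bonds(mol, bond_pair)
    linker_mol = mol_from_smiles(cut.linker)
    out = []
    for bond_idx, tag in zip(bond_pair, (WARHEAD_TAG, E3_TAG)):
        bond = mol.GetBondWithIdx(int(bond_idx))
        order = bond_order_name(bond)
        _, link_el, _ = attachment_info(linker_mol, tag)
        a, b = bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()
        # orient: linker atom second for junction 1, first for junction 2
        other = b if a == link_el else a
        if tag == WARHEAD_TAG:
            # ambiguous when both elements equal; orientation is then irrelevant
            el_pair = (other, link_el)
        else:
            el_pair = (link_el, other)
        out.append(JunctionBond(order, el_pair))
    return out[0], out[1]


# --- fingerprints ---------------------------------------------------------


@dataclass(frozen=True)
class FingerprintSpec:
    """Morgan fingerprint parameters."""

    n_bits: int = 512
    radius: int = 2
    chirality: bool = False

    def generator(self):
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius,
            fpSize=self.n_bits,
            includeChirality=self.chirality,
        )


def strip_tags(smiles: str) -> str:
    """Remove attachment dummies, leaving the bare fragment."""
    mol = mol_from_smiles(smiles)
    rw = Chem.RWMol(mol)
    for idx in sorted((a.GetIdx() for a in dummy_atoms(rw)), reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def morgan_fingerprint(smiles_or_mol, spec: FingerprintSpec = FingerprintSpec()):
    mol = (
        smiles_or_mol
        if isinstance(smiles_or_mol, Chem.Mol)
        else mol_from_smiles(
            smiles_or_mol.smiles
            if isinstance(smiles_or_mol, MoleculeRef)
            else smiles_or_mol
        )
    )
    return spec.generator().GetFingerprint(mol)


def tanimoto(a, b, fp_spec: FingerprintSpec = FingerprintSpec()) -> float:
    """Tanimoto similarity of two molecules under a Morgan fingerprint."""
    return DataStructs.TanimotoSimilarity(
        morgan_fingerprint(a, fp_spec), morgan_fingerprint(b, fp_spec)
    )


def bulk_tanimoto(fp, fps) -> list[float]:
    return DataStructs.BulkTanimotoSimilarity(fp, list(fps))
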
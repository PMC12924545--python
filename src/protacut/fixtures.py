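"""Deterministic toy-ligand generator for self-contained testing.

Toy ligands are enumerated from hand-written SMILES templates with
combinatorial decorations (never random graph edits), guaranteeing chemical
validity.  The three roles are structurally separable by design — warheads
are decorated aromatics, linkers are alkyl/polyether chains, E3 ligands are
acyl-bearing saturated rings — so fingerprint-based role assignment is
learnable.  Carbonyl groups in the E3 templates sit at least two bonds from
the attachment point, keeping ground-truth junctions fixed under
attachment-point refinement.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from rdkit import Chem

from . import chem
from .annotation import AnnotatedProtac
from .chem import JunctionBond
from .dictionaries import LigandDictionary, build_dictionary
from .generator import ConnectionTypeDistribution


class FixtureError(ValueError):
    """A fixture request cannot be satisfied (pool too small, edit inapplicable)."""


@dataclass(frozen=True)
class ToyDictionarySpec:
    n_warheads: int = 12
    n_linkers: int = 12
    n_e3: int = 12
    seed: int = 0


_AROMATIC_DECOS = ["", "C", "CC", "CO", "N", "OC", "CC(C)", "CCO"]
_ACYL_DECOS = ["C", "CC", "CCC", "C(C)C", "CCCC", "CC(C)C", "CCCCC", "CC(C)CC", "CCC(C)C"]

# All attachment points sit on ring atoms: a ring-attached fragment cannot
# absorb acyclic linker atoms, so library recipes decompose uniquely and the
# annotation cascade recovers them exactly.
_WARHEAD_TEMPLATES = [
    "{d}c1ccc([*:1])cc1",
    "{d}c1ccc([*:1])cn1",
    "{d}c1ccc(N2CCN([*:1])CC2)cc1",
    "{d}c1ccc(C2CCN([*:1])CC2)cc1",
]

_E3_TEMPLATES = [
    "O=C({d})NC1CCC([*:2])CC1",
    "{d}C(=O)N1CCC([*:2])CC1",
    "O=C({d})C1CCN([*:2])CC1",
    "{d}NC(=O)C1CCN([*:2])CC1",
]


def _warhead_pool() -> list[str]:
    return [t.format(d=d) for t in _WARHEAD_TEMPLATES for d in _AROMATIC_DECOS]


def _e3_pool() -> list[str]:
    return [t.format(d=d) for t in _E3_TEMPLATES for d in _ACYL_DECOS]


def _linker_pool(max_n: int) -> list[str]:
    """Chains [*:1]C...C[*:2] over {C,O} middles without O-O contacts."""
    middles = [""]
    frontier = [""]
    while len(middles) < max_n + 8 and frontier:
        nxt = []
        for m in frontier:
            for unit in ("C", "O"):
                if unit == "O" and (m.endswith("O") or not m):
                    continue  # no O-O and no O next to the tag-1 carbon
                cand = m + unit
                if len(cand) <= 11:
                    nxt.append(cand)
        middles.extend(nxt)
        frontier = nxt
    # middles ending in O would put O adjacent to the tag-2 carbon: allowed
    return [f"[*:1]C{m}C[*:2]" for m in middles]


def _take(pool: list[str], role: str, n: int, rng: random.Random, lo: int, hi: int) -> LigandDictionary:
    canon = []
    seen = set()
    for smi in pool:
        ref = chem.canonicalize(smi)
        if ref.smiles in seen:
            continue
        seen.add(ref.smiles)
        if lo <= ref.heavy_atoms <= hi:
            canon.append(ref.smiles)
    if len(canon) < n:
        raise FixtureError(
            f"{role} pool has only {len(canon)} candidates, {n} requested"
        )
    rng.shuffle(canon)
    return build_dictionary(canon[:n], role)


def make_toy_dictionaries(
    spec: ToyDictionarySpec = ToyDictionarySpec(),
) -> tuple[LigandDictionary, LigandDictionary, LigandDictionary]:
    """Deterministic role-separable toy dictionaries (warheads, linkers, E3s).

    Warheads and E3 ligands span 6-20 heavy atoms, linkers 2-15.
    """
    if min(spec.n_warheads, spec.n_linkers, spec.n_e3) < 1:
        raise FixtureError("counts must be >= 1")
    rng = random.Random(spec.seed)
    d_wh = _take(_warhead_pool(), "warhead", spec.n_warheads, rng, 6, 20)
    d_link = _take(_linker_pool(4 * spec.n_linkers), "linker", spec.n_linkers, rng, 2, 15)
    d_e3 = _take(_e3_pool(), "e3", spec.n_e3, rng, 6, 20)
    return d_wh, d_link, d_e3


def toy_connection_distribution() -> ConnectionTypeDistribution:
    """Junction-type mix the toy library is generated under.

    Single C-C and C-N junctions dominate, echoing the amine/alkyl linkages
    through which degrader components are typically coupled.
    """
    return ConnectionTypeDistribution(
        wh_link={
            JunctionBond("single", ("C", "C")): 0.7,
            JunctionBond("single", ("N", "C")): 0.3,
        },
        link_e3={
            JunctionBond("single", ("C", "C")): 0.6,
            JunctionBond("single", ("C", "N")): 0.4,
        },
    )


def make_toy_protacs(
    n: int,
    seed: int,
    spec: ToyDictionarySpec | None = None,
) -> list[AnnotatedProtac]:
    """Convenience: toy dictionaries -> sampled annotated library."""
    from .generator import sample_and_assemble

    spec = spec or ToyDictionarySpec(n_warheads=24, n_linkers=32, n_e3=24, seed=7)
    d_wh, d_link, d_e3 = make_toy_dictionaries(spec)
    return sample_and_assemble(
        d_wh, d_link, d_e3, toy_connection_distribution(), n, seed
    )


# --- controlled corruption for fixer tests --------------------------------


def corrupt_component(
    annotation: AnnotatedProtac,
    role: str,
    edit: str,
    seed: int = 0,
) -> tuple[str, str, str]:
    """Mutate exactly one component of an annotation; the other two are untouched.

    ``edit`` is one of ``insert_atom`` (a methylene into an acyclic C-C bond),
    ``delete_atom`` (a chain atom removed, neighbors rejoined), or
    ``invalidate`` (an unparseable string).  Raises :class:`FixtureError` when
    the edit is inapplicable to the chosen component.
    """
    if role not in ("warhead", "linker", "e3"):
        raise FixtureError(f"unknown role {role!r}")
    triple = {r: getattr(annotation, r).smiles for r in ("warhead", "linker", "e3")}
    rng = random.Random(seed)
    mutated = _apply_edit(triple[role], edit, rng)
    triple[role] = mutated
    return (triple["warhead"], triple["linker"], triple["e3"])


def _apply_edit(smiles: str, edit: str, rng: random.Random) -> str:
    if edit == "invalidate":
        return smiles + "("
    mol = chem.mol_from_smiles(smiles)
    if edit == "insert_atom":
        cands = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBondType() == Chem.BondType.SINGLE
            and not b.IsInRing()
            and b.GetBeginAtom().GetAtomicNum() == 6
            and b.GetEndAtom().GetAtomicNum() == 6
        ]
        if not cands:
            raise FixtureError(f"no acyclic C-C single bond to stretch in {smiles!r}")
        bond = mol.GetBondWithIdx(rng.choice(sorted(cands)))
        rw = Chem.RWMol(mol)
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        rw.RemoveBond(a, b)
        new = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(a, new, Chem.BondType.SINGLE)
        rw.AddBond(new, b, Chem.BondType.SINGLE)
        out = rw.GetMol()
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out)
    if edit == "delete_atom":
        deg2 = []
        deg1 = []
        for a in mol.GetAtoms():
            if a.GetAtomicNum() == 0 or a.IsInRing():
                continue
            bonds = a.GetBonds()
            if len(bonds) == 2 and all(
                b.GetBondType() == Chem.BondType.SINGLE for b in bonds
            ):
                nbrs = [n for n in a.GetNeighbors()]
                if all(n.GetAtomicNum() == 0 for n in nbrs):
                    continue  # would bond two attachment dummies together
                deg2.append(a.GetIdx())
            elif (
                len(bonds) == 1
                and bonds[0].GetBondType() == Chem.BondType.SINGLE
                and a.GetNeighbors()[0].GetAtomicNum() != 0
            ):
                deg1.append(a.GetIdx())
        if deg2:
            idx = rng.choice(sorted(deg2))
            rw = Chem.RWMol(mol)
            nbrs = [n.GetIdx() for n in rw.GetAtomWithIdx(idx).GetNeighbors()]
            rw.RemoveAtom(idx)
            shifted = [i - (i > idx) for i in nbrs]
            if rw.GetMol().GetBondBetweenAtoms(*shifted) is None:
                rw.AddBond(shifted[0], shifted[1], Chem.BondType.SINGLE)
        elif deg1:
            idx = rng.choice(sorted(deg1))
            rw = Chem.RWMol(mol)
            rw.RemoveAtom(idx)
        else:
            raise FixtureError(f"no deletable chain atom in {smiles!r}")
        out = rw.GetMol()
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out)
    raise FixtureError(f"unknown edit {edit!r}")
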
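"""Dictionary-based PROTAC substructure annotation.

Given a PROTAC and curated warhead / linker / E3-ligand dictionaries, infer the
three components with attachment points via a three-stage cascade:

1. match a warhead and an E3 ligand as substructures; the linker is what is
   left between them;
2. if only one of the two ligands matches, search the linker dictionary
   (largest candidates first) for a match whose junction on the known-ligand
   side coincides with that ligand's junction; the remainder is the missing
   ligand;
3. fall back to matching linkers alone, assigning warhead vs E3 roles to the
   two leftover fragments by their maximum Tanimoto similarity to the
   respective dictionaries.

Every annotation is validated by reassembly: the three fragments, joined at
their attachment tags and canonicalized, must reproduce the parent SMILES
exactly.  A post-processing step shifts cut points onto amide C-N or ester C-O
bonds when such a group sits within one bond of the cut, reflecting how these
molecules are actually made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from rdkit import Chem

from . import chem
from .chem import (
    FingerprintSpec,
    JunctionBond,
    MoleculeRef,
    WARHEAD_TAG,
    E3_TAG,
)
from .dictionaries import Ligand, LigandDictionary

logger = logging.getLogger(__name__)

ROLE_FP = FingerprintSpec(n_bits=512, radius=2)

PROVENANCE_BOTH = "both-ligands-matched"
PROVENANCE_ONE = "one-ligand+linker"
PROVENANCE_LINKER = "linker-only"
PROVENANCE_MANUAL = "manual"


@dataclass(frozen=True)
class LigandMatch:
    """One attachment-consistent embedding of a ligand in a parent molecule."""

    atoms: frozenset[int]
    junctions: dict[int, int]  # tag -> parent bond index

    def junction_bond(self, tag: int) -> int:
        return self.junctions[tag]


@dataclass(frozen=True)
class AnnotatedProtac:
    """A PROTAC with its three components and junction descriptors.

    ``junction_atoms`` are the two cut-bond atom pairs, indexed in the mol
    obtained by parsing ``parent.smiles`` (the canonical frame); first the
    warhead-linker junction, then the linker-E3 junction.
    """

    parent: MoleculeRef
    warhead: Ligand
    linker: Ligand
    e3: Ligand
    junctions: tuple[JunctionBond, JunctionBond]
    junction_atoms: tuple[tuple[int, int], tuple[int, int]]
    provenance: str

    @property
    def components(self) -> tuple[Ligand, Ligand, Ligand]:
        return (self.warhead, self.linker, self.e3)


@dataclass(frozen=True)
class AnnotationFailure:
    parent: MoleculeRef
    stage_reached: int
    reason: str


def _as_mol(protac) -> tuple[Chem.Mol, MoleculeRef]:
    """Parse to the canonical frame: the mol of the canonical SMILES."""
    ref = (
        protac
        if isinstance(protac, MoleculeRef)
        else chem.canonicalize(protac if isinstance(protac, str) else Chem.MolToSmiles(protac))
    )
    # re-canonicalize defensively so atom indices match ref.smiles
    ref = chem.canonicalize(ref.smiles)
    return chem.mol_from_smiles(ref.smiles), ref


def _tag_stripped_core(ligand_smiles: str) -> tuple[Chem.Mol, list[tuple[int, int, str]]]:
    """Remove dummies; return core mol plus (tag, core_attach_idx, order) list."""
    mol = chem.mol_from_smiles(ligand_smiles)
    attach: list[tuple[int, int, str]] = []
    doomed = []
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 0:
            nbr = a.GetNeighbors()[0]
            bond = mol.GetBondBetweenAtoms(a.GetIdx(), nbr.GetIdx())
            attach.append((a.GetAtomMapNum(), nbr.GetIdx(), chem.bond_order_name(bond)))
            doomed.append(a.GetIdx())
    rw = Chem.RWMol(mol)
    for idx in sorted(doomed, reverse=True):
        rw.RemoveAtom(idx)

    def shifted(i: int) -> int:
        return i - sum(1 for d in doomed if d < i)

    attach = [(tag, shifted(i), order) for tag, i, order in attach]
    core = rw.GetMol()
    Chem.SanitizeMol(core)
    return core, attach


def match_ligand(protac, ligand: Ligand) -> list[LigandMatch]:
    """Attachment-consistent substructure matches of a tagged ligand.

    A match is kept only when every attachment atom has exactly one bond to an
    atom outside the match (the junction, whose order must equal the ligand's
    dummy-bond order) and no other matched atom has any external bond.
    """
    mol, _ = _as_mol(protac)
    return _match_ligand_in_mol(mol, ligand)


def _match_ligand_in_mol(mol: Chem.Mol, ligand: Ligand) -> list[LigandMatch]:
    core, attach = _tag_stripped_core(ligand.smiles)
    attach_by_atom: dict[int, list[tuple[int, str]]] = {}
    for tag, idx, order in attach:
        attach_by_atom.setdefault(idx, []).append((tag, order))

    out: list[LigandMatch] = []
    seen: set[tuple[frozenset[int], tuple[tuple[int, int], ...]]] = set()
    # uniquify=False: automorphic embeddings differ in which atom faces the
    # junction, and only some orientations pass the external-bond filter
    for match in mol.GetSubstructMatches(core, uniquify=False, maxMatches=4096):
        matched = set(match)
        junctions: dict[int, int] = {}
        ok = True
        for core_idx, parent_idx in enumerate(match):
            atom = mol.GetAtomWithIdx(parent_idx)
            external = [
                n.GetIdx() for n in atom.GetNeighbors() if n.GetIdx() not in matched
            ]
            tags_here = attach_by_atom.get(core_idx, [])
            if not tags_here:
                if external:
                    ok = False
                    break
                continue
            if len(external) != len(tags_here):
                ok = False
                break
            # assign tags to external bonds, orders must agree
            remaining = list(external)
            for tag, order in tags_here:
                hit = None
                for ext in remaining:
                    bond = mol.GetBondBetweenAtoms(parent_idx, ext)
                    if chem.bond_order_name(bond) == order:
                        hit = ext
                        break
                if hit is None:
                    ok = False
                    break
                remaining.remove(hit)
                junctions[tag] = mol.GetBondBetweenAtoms(parent_idx, hit).GetIdx()
            if not ok:
                break
        if not ok:
            continue
        key = (frozenset(matched), tuple(sorted(junctions.items())))
        if key in seen:
            continue
        seen.add(key)
        out.append(LigandMatch(atoms=frozenset(matched), junctions=junctions))
    return out


def _annotation_from_bonds(
    mol: Chem.Mol,
    parent: MoleculeRef,
    bond_wh: int,
    bond_e3: int,
    provenance: str,
) -> AnnotatedProtac:
    """Cut the parent at the two junction bonds and package the annotation."""
    cut = chem.cut_two_bonds(mol, (bond_wh, bond_e3))
    warhead = Ligand.from_smiles(cut.end1, "warhead")
    linker = Ligand.from_smiles(cut.linker, "linker")
    e3 = Ligand.from_smiles(cut.end2, "e3")
    assembled = chem.reassemble(warhead.smiles, linker.smiles, e3.smiles)
    if assembled.smiles != parent.smiles:
        raise chem.JunctionError(
            f"reassembly validation failed: {assembled.smiles} != {parent.smiles}"
        )
    junctions = chem.junction_descriptors(mol, (bond_wh, bond_e3))
    atom_pairs = []
    for b in (bond_wh, bond_e3):
        bond = mol.GetBondWithIdx(int(b))
        atom_pairs.append(tuple(sorted((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))))
    return AnnotatedProtac(
        parent=parent,
        warhead=warhead,
        linker=linker,
        e3=e3,
        junctions=junctions,
        junction_atoms=(atom_pairs[0], atom_pairs[1]),
        provenance=provenance,
    )


def annotate_from_bonds(
    protac, bond_wh: int, bond_e3: int, provenance: str = PROVENANCE_MANUAL
) -> AnnotatedProtac:
    """Build a reassembly-validated annotation from two explicit cut bonds.

    Bond indices refer to the mol parsed from the canonical parent SMILES.
    """
    mol, parent = _as_mol(protac)
    return _annotation_from_bonds(mol, parent, bond_wh, bond_e3, provenance)


def infer_third(protac, matched_a: tuple[Ligand, LigandMatch], matched_b: tuple[Ligand, LigandMatch]) -> Ligand:
    """Subtract a matched warhead and E3 ligand from the parent; return the linker.

    The two matches must be atom-disjoint with distinct junction bonds, and the
    remaining atoms must form a single connected fragment (guaranteed by the
    attachment-consistency of the matches).
    """
    mol, parent = _as_mol(protac)
    lig_a, m_a = matched_a
    lig_b, m_b = matched_b
    roles = {lig_a.role, lig_b.role}
    if roles != {"warhead", "e3"}:
        raise chem.ContractViolation("infer_third expects one warhead and one e3 match")
    if m_a.atoms & m_b.atoms:
        raise chem.ContractViolation("matches overlap; pair rejected")
    wh_m = m_a if lig_a.role == "warhead" else m_b
    e3_m = m_b if lig_b.role == "e3" else m_a
    b_wh = wh_m.junction_bond(WARHEAD_TAG)
    b_e3 = e3_m.junction_bond(E3_TAG)
    if b_wh == b_e3:
        raise chem.InvalidCutError("warhead and E3 junctions coincide; remainder empty")
    ann = _annotation_from_bonds(mol, parent, b_wh, b_e3, PROVENANCE_BOTH)
    return ann.linker


def _dict_fps(dictionary: LigandDictionary):
    fps = []
    for lig in dictionary:
        try:
            fps.append(chem.morgan_fingerprint(chem.strip_tags(lig.smiles), ROLE_FP))
        except chem.ParseError:  # pragma: no cover
            continue
    return fps


def max_similarity(fragment_smiles: str, dict_fps) -> float:
    if not dict_fps:
        return 0.0
    fp = chem.morgan_fingerprint(chem.strip_tags(fragment_smiles), ROLE_FP)
    return max(chem.bulk_tanimoto(fp, dict_fps))


def annotate_protac(
    protac,
    d_wh: LigandDictionary,
    d_link: LigandDictionary,
    d_e3: LigandDictionary,
    *,
    refine: bool = True,
):
    """Run the three-stage annotation cascade; returns an
    :class:`AnnotatedProtac` or an :class:`AnnotationFailure` carrying the
    deepest stage reached."""
    if not (len(d_wh) and len(d_link) and len(d_e3)):
        raise chem.ContractViolation("all three dictionaries must be non-empty")
    mol, parent = _as_mol(protac)

    wh_cands = [
        (lig, m)
        for lig in d_wh.iter_by_size_desc()
        for m in _match_ligand_in_mol(mol, lig)
    ]
    e3_cands = [
        (lig, m)
        for lig in d_e3.iter_by_size_desc()
        for m in _match_ligand_in_mol(mol, lig)
    ]

    def finish(ann: AnnotatedProtac) -> AnnotatedProtac:
        return refine_attachment_points(ann) if refine else ann

    # stage 1: both ligands matched
    for wh_lig, wh_m in wh_cands:
        for e3_lig, e3_m in e3_cands:
            if wh_m.atoms & e3_m.atoms:
                continue
            b1 = wh_m.junction_bond(WARHEAD_TAG)
            b2 = e3_m.junction_bond(E3_TAG)
            if b1 == b2:
                continue
            try:
                return finish(
                    _annotation_from_bonds(mol, parent, b1, b2, PROVENANCE_BOTH)
                )
            except (chem.InvalidCutError, chem.JunctionError, chem.ContractViolation):
                continue

    linker_cands = None

    def get_linker_cands():
        nonlocal linker_cands
        if linker_cands is None:
            linker_cands = [
                (lig, m)
                for lig in d_link.iter_by_size_desc()
                for m in _match_ligand_in_mol(mol, lig)
            ]
        return linker_cands

    # stage 2: one ligand matched; find a linker consistent with its junction
    if wh_cands or e3_cands:
        known = [(lig, m, "warhead") for lig, m in wh_cands] + [
            (lig, m, "e3") for lig, m in e3_cands
        ]
        for lig, m, role in known:
            for _link_lig, lm in get_linker_cands():
                if lm.atoms & m.atoms:
                    continue
                if role == "warhead":
                    if lm.junction_bond(WARHEAD_TAG) != m.junction_bond(WARHEAD_TAG):
                        continue
                    b1, b2 = m.junction_bond(WARHEAD_TAG), lm.junction_bond(E3_TAG)
                else:
                    if lm.junction_bond(E3_TAG) != m.junction_bond(E3_TAG):
                        continue
                    b1, b2 = lm.junction_bond(WARHEAD_TAG), m.junction_bond(E3_TAG)
                if b1 == b2:
                    continue
                try:
                    return finish(
                        _annotation_from_bonds(mol, parent, b1, b2, PROVENANCE_ONE)
                    )
                except (chem.InvalidCutError, chem.JunctionError, chem.ContractViolation):
                    continue

    # stage 3: linker-only; roles by Tanimoto similarity to the dictionaries
    wh_fps = _dict_fps(d_wh)
    e3_fps = _dict_fps(d_e3)
    for _link_lig, lm in get_linker_cands():
        b1, b2 = lm.junction_bond(WARHEAD_TAG), lm.junction_bond(E3_TAG)
        if b1 == b2:
            continue
        try:
            cut = chem.cut_two_bonds(mol, (b1, b2))
        except chem.InvalidCutError:
            continue
        frag1, frag2 = cut.end1, cut.end2
        margin1 = max_similarity(frag1, e3_fps) - max_similarity(frag1, wh_fps)
        margin2 = max_similarity(frag2, e3_fps) - max_similarity(frag2, wh_fps)
        if margin1 > margin2:
            e3_is_frag1 = True
        elif margin2 > margin1:
            e3_is_frag1 = False
        else:  # tie toward the tag-2 end carrying the higher E3 similarity
            e3_is_frag1 = max_similarity(frag1, e3_fps) > max_similarity(frag2, e3_fps)
        bonds = (b2, b1) if e3_is_frag1 else (b1, b2)
        try:
            return finish(
                _annotation_from_bonds(mol, parent, bonds[0], bonds[1], PROVENANCE_LINKER)
            )
        except (chem.InvalidCutError, chem.JunctionError, chem.ContractViolation):
            continue
    # every failure has fallen through the whole cascade
    return AnnotationFailure(
        parent=parent,
        stage_reached=3,
        reason="no stage of the cascade produced a reassembly-valid annotation",
    )


# --- attachment-point refinement -----------------------------------------

_AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])[NX3]")
_ESTER = Chem.MolFromSmarts("[CX3](=[OX1])[OX2]")


def _acyl_bonds(mol: Chem.Mol) -> list[tuple[int, int, frozenset[int]]]:
    """(bond_idx, carbonyl_atom, bond_atom_set) for amide C-N / ester C-O bonds."""
    out = []
    seen = set()
    for patt in (_AMIDE, _ESTER):
        for c_idx, _o_idx, x_idx in mol.GetSubstructMatches(patt):
            bond = mol.GetBondBetweenAtoms(c_idx, x_idx)
            if bond is None or bond.IsInRing() or bond.GetIdx() in seen:
                continue
            seen.add(bond.GetIdx())
            out.append((bond.GetIdx(), c_idx, frozenset((c_idx, x_idx))))
    return out


def _fragment_atom_sets(
    mol: Chem.Mol, bonds: tuple[int, int]
) -> tuple[set[int], set[int], set[int]]:
    """(end-at-bonds[0], middle, end-at-bonds[1]) atom sets of a two-bond cut."""
    frag = Chem.FragmentOnBonds(mol, [int(b) for b in bonds], addDummies=False)
    comps = Chem.GetMolFrags(frag, asMols=False, sanitizeFrags=False)
    b_atoms = [
        {mol.GetBondWithIdx(int(b)).GetBeginAtomIdx(), mol.GetBondWithIdx(int(b)).GetEndAtomIdx()}
        for b in bonds
    ]
    middle = end1 = end2 = None
    for comp in comps:
        cset = set(comp)
        touches = [bool(cset & ba) for ba in b_atoms]
        if all(touches):
            middle = cset
        elif touches[0]:
            end1 = cset
        elif touches[1]:
            end2 = cset
    if middle is None or end1 is None or end2 is None:
        raise chem.InvalidCutError("cut bonds do not define an end-linker-end path")
    return end1, middle, end2


def refine_attachment_points(annotated: AnnotatedProtac) -> AnnotatedProtac:
    """Shift junctions onto nearby amide C-N / ester C-O bonds.

    A junction within one bond of such a group (sharing an atom with the
    acyl C-X bond, or adjacent to the carbonyl carbon) is moved onto that
    bond; atoms between old and new cut change fragments.  Idempotent: a
    junction already on an acyl bond is left alone.  If the shifted cut
    cannot be validated, the unrefined annotation is returned with a warning.
    """
    mol = chem.mol_from_smiles(annotated.parent.smiles)
    old_bonds = []
    for pair in annotated.junction_atoms:
        bond = mol.GetBondBetweenAtoms(*pair)
        if bond is None:  # pragma: no cover - malformed annotation
            logger.warning("junction atoms %s not bonded; refinement skipped", pair)
            return annotated
        old_bonds.append(bond.GetIdx())

    acyl = _acyl_bonds(mol)
    acyl_bond_ids = {t[0] for t in acyl}
    new_bonds = list(old_bonds)
    for k in (0, 1):
        b = old_bonds[k]
        if b in acyl_bond_ids:
            continue
        bond = mol.GetBondWithIdx(b)
        b_atoms = {bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()}
        b_nbrs = set()
        for ai in b_atoms:
            b_nbrs.update(n.GetIdx() for n in mol.GetAtomWithIdx(ai).GetNeighbors())
        candidates = []
        for t_bond, carbonyl, t_atoms in acyl:
            if t_bond == old_bonds[1 - k] or t_bond == b:
                continue
            shares = bool(t_atoms & b_atoms)
            adjacent = carbonyl in b_nbrs
            if shares or adjacent:
                candidates.append((0 if shares else 1, t_bond))
        if candidates:
            new_bonds[k] = min(candidates)[1]
    if new_bonds == old_bonds:
        return annotated
    if new_bonds[0] == new_bonds[1]:
        logger.warning("refinement collapsed both junctions onto one bond; reverted")
        return annotated
    try:
        old_wh_atoms, _, _ = _fragment_atom_sets(mol, (old_bonds[0], old_bonds[1]))
        end_a, _, end_b = _fragment_atom_sets(mol, (new_bonds[0], new_bonds[1]))
        if len(end_a & old_wh_atoms) >= len(end_b & old_wh_atoms):
            pair = (new_bonds[0], new_bonds[1])
        else:
            pair = (new_bonds[1], new_bonds[0])
        return _annotation_from_bonds(
            mol, annotated.parent, pair[0], pair[1], annotated.provenance
        )
    except (chem.InvalidCutError, chem.JunctionError, chem.ContractViolation) as exc:
        logger.warning("attachment refinement reverted: %s", exc)
        return annotated


# --- iterative refinement over a corpus -----------------------------------


@dataclass
class RefinementResult:
    annotations: list  # AnnotatedProtac | None, aligned with the input corpus
    dictionaries: tuple[LigandDictionary, LigandDictionary, LigandDictionary]
    unannotated: list[MoleculeRef]
    rounds: list[dict]


def iterative_refinement(
    corpus: Sequence,
    d_wh: LigandDictionary,
    d_link: LigandDictionary,
    d_e3: LigandDictionary,
    *,
    refine: bool = True,
) -> RefinementResult:
    """Annotate a corpus, feeding newly inferred ligands back into the
    dictionaries, until a round annotates nothing new and inserts nothing new.

    Terminates in at most ``len(corpus) + 1`` rounds: every productive round
    annotates at least one molecule or grows a dictionary, and growth is
    bounded by the corpus's substructure content.
    """
    refs = [_as_mol(p)[1] for p in corpus]
    pending = list(range(len(refs)))
    annotations: dict[int, AnnotatedProtac] = {}
    rounds: list[dict] = []
    for _round in range(len(refs) + 1):
        annotated_n = 0
        inserted_n = 0
        for idx in list(pending):
            res = annotate_protac(refs[idx], d_wh, d_link, d_e3, refine=refine)
            if isinstance(res, AnnotatedProtac):
                annotations[idx] = res
                pending.remove(idx)
                annotated_n += 1
                inserted_n += int(d_wh.add(res.warhead))
                inserted_n += int(d_link.add(res.linker))
                inserted_n += int(d_e3.add(res.e3))
        rounds.append({"annotated": annotated_n, "inserted": inserted_n})
        if annotated_n == 0 and inserted_n == 0:
            break
    return RefinementResult(
        annotations=[annotations.get(i) for i in range(len(refs))],
        dictionaries=(d_wh, d_link, d_e3),
        unannotated=[refs[i] for i in pending],
        rounds=rounds,
    )
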
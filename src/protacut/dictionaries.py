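"""Curated SMILES dictionaries for warheads, linkers, E3 ligands and PROTACs.

Each dictionary deduplicates entries by exact canonical-SMILES string (tags
included), discards disconnected records (a ``.`` in the SMILES), and stores a
stereo-stripped copy alongside every stereo-bearing entry.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from . import chem
from .chem import ContractViolation

logger = logging.getLogger(__name__)

ROLES = ("warhead", "linker", "e3", "protac")


@dataclass(frozen=True)
class Ligand:
    """An attachment-tagged fragment with a role.

    ``stereo_free`` is True when the SMILES carries no stereochemistry (either
    natively or because it is the stripped copy of a stereo-bearing entry).
    """

    smiles: str
    role: str
    heavy_atoms: int
    stereo_free: bool

    @classmethod
    def from_smiles(cls, smiles: str, role: str) -> "Ligand":
        if role not in ROLES:
            raise ContractViolation(f"unknown role {role!r}")
        mol = chem.mol_from_smiles(smiles)
        canon = chem.canonical_smiles(smiles)
        if "." in canon:
            raise ContractViolation(f"disconnected SMILES not allowed: {smiles!r}")
        chem.validate_role_tags(mol, role)
        return cls(
            smiles=canon,
            role=role,
            heavy_atoms=chem.heavy_atom_count(mol),
            stereo_free=(chem.strip_stereo(canon) == canon),
        )


class LigandDictionary:
    """Ordered, deduplicated set of :class:`Ligand` keyed by canonical SMILES."""

    def __init__(self, role: str):
        if role not in ROLES:
            raise ContractViolation(f"unknown role {role!r}")
        self.role = role
        self._entries: dict[str, Ligand] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._entries

    def __iter__(self) -> Iterator[Ligand]:
        return iter(self._entries.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LigandDictionary)
            and self.role == other.role
            and set(self._entries) == set(other._entries)
        )

    def add(self, ligand: Ligand) -> bool:
        """Insert a ligand plus its stereo-stripped copy; True iff anything new.

        The insertion flag drives the convergence test of iterative
        dictionary refinement.
        """
        if ligand.role != self.role:
            raise ContractViolation(
                f"cannot add role {ligand.role!r} to a {self.role!r} dictionary"
            )
        inserted = False
        if ligand.smiles not in self._entries:
            self._entries[ligand.smiles] = ligand
            inserted = True
        stripped = chem.strip_stereo(ligand.smiles)
        if stripped != ligand.smiles and stripped not in self._entries:
            self._entries[stripped] = Ligand(
                smiles=stripped,
                role=self.role,
                heavy_atoms=ligand.heavy_atoms,
                stereo_free=True,
            )
            inserted = True
        return inserted

    def iter_by_size_desc(self) -> list[Ligand]:
        """Entries sorted by heavy-atom count descending, SMILES-lexicographic ties."""
        return sorted(self._entries.values(), key=lambda l: (-l.heavy_atoms, l.smiles))

    def entries(self) -> list[Ligand]:
        return list(self._entries.values())


def add_entry(dictionary: LigandDictionary, ligand: Ligand) -> bool:
    return dictionary.add(ligand)


def iter_by_size_desc(dictionary: LigandDictionary) -> list[Ligand]:
    return dictionary.iter_by_size_desc()


def build_dictionary(records: Iterable[str], role: str) -> LigandDictionary:
    """Canonicalize, dedupe and filter raw SMILES records into a dictionary.

    Invalid or disconnected records are logged and skipped; nothing is fatal.
    """
    d = LigandDictionary(role)
    for raw in records:
        try:
            ligand = Ligand.from_smiles(raw, role)
        except (chem.ParseError, ContractViolation) as exc:
            logger.warning("skipping record %r: %s", raw, exc)
            continue
        d.add(ligand)
    return d


# --- file I/O -------------------------------------------------------------


def read_smiles_records(path: str | Path) -> list[tuple[str, str | None]]:
    """Read (smiles, role) records from a CSV with a smiles column, or a plain
    one-SMILES-per-line file (role None)."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        return []
    first = text.splitlines()[0]
    if "," in first or first.lower().startswith("smiles"):
        out = []
        with path.open() as fh:
            for row in csv.DictReader(fh):
                smi = row.get("smiles") or row.get("parent_smiles")
                if smi is None:
                    raise KeyError(f"{path} has no smiles/parent_smiles column")
                out.append((smi, row.get("role")))
        return out
    return [(line.strip(), None) for line in text.splitlines() if line.strip()]


def write_dictionary(dictionary: LigandDictionary, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "role"])
        for lig in dictionary:
            writer.writerow([lig.smiles, lig.role])


def load_dictionary(path: str | Path, role: str) -> LigandDictionary:
    return build_dictionary([s for s, _ in read_smiles_records(path)], role)
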
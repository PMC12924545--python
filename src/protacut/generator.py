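"""Synthetic PROTAC library generation and leakage-free dataset splits.

Libraries are produced by recombining dictionary ligands under an empirical
distribution of junction connection types (bond order plus the element pair of
the joined atoms), estimated separately for the warhead-linker and linker-E3
junctions.  Sampling is category-first: a connection type is drawn for each
junction, then ligands are drawn uniformly among those whose attachment
chemistry is compatible, which enforces the requested junction-type marginals
directly.

Dataset splits hold out whole ligand clusters (Taylor-Butina sphere exclusion
over Morgan fingerprints) so that validation/test molecules can contain
ligands never seen in training.
"""

from __future__ import annotations

import json
import logging
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit.ML.Cluster import Butina

from . import chem
from .annotation import AnnotatedProtac
from .chem import FingerprintSpec, JunctionBond, WARHEAD_TAG, E3_TAG
from .dictionaries import Ligand, LigandDictionary

logger = logging.getLogger(__name__)

#: fingerprint used for ligand clustering; the high radius follows the
#: splitting protocol this package implements, see docs/methods.md
CLUSTER_FP = FingerprintSpec(n_bits=1024, radius=16, chirality=True)


class SplitError(ValueError):
    """Raised when a cluster-based split cannot be formed."""


@dataclass
class ConnectionTypeDistribution:
    """Per-junction categorical distribution over connection types."""

    wh_link: dict[JunctionBond, float]
    link_e3: dict[JunctionBond, float]

    def __post_init__(self):
        for name in ("wh_link", "link_e3"):
            probs = getattr(self, name)
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise chem.ContractViolation(
                    f"{name} probabilities sum to {total}, expected 1"
                )
            if any(p < 0 for p in probs.values()):
                raise chem.ContractViolation("negative probability")

    def to_json(self) -> str:
        def ser(probs):
            return [
                {"order": jb.order, "elements": list(jb.elements), "p": p}
                for jb, p in probs.items()
            ]

        return json.dumps({"wh_link": ser(self.wh_link), "link_e3": ser(self.link_e3)}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ConnectionTypeDistribution":
        raw = json.loads(text)

        def de(items):
            return {
                JunctionBond(d["order"], tuple(d["elements"])): d["p"] for d in items
            }

        return cls(wh_link=de(raw["wh_link"]), link_e3=de(raw["link_e3"]))


def estimate_connection_distribution(
    annotations: Sequence[AnnotatedProtac],
) -> ConnectionTypeDistribution:
    """Empirical junction-type frequencies of an annotated corpus."""
    if not annotations:
        raise chem.ContractViolation("cannot estimate a distribution from no annotations")
    counts1: dict[JunctionBond, int] = {}
    counts2: dict[JunctionBond, int] = {}
    for ann in annotations:
        j1, j2 = ann.junctions
        counts1[j1] = counts1.get(j1, 0) + 1
        counts2[j2] = counts2.get(j2, 0) + 1
    n = len(annotations)
    return ConnectionTypeDistribution(
        wh_link={k: v / n for k, v in counts1.items()},
        link_e3={k: v / n for k, v in counts2.items()},
    )


def _attachment_key(smiles: str, tag: int) -> tuple[str, str]:
    """(element, bond order) of a ligand's attachment for a tag."""
    mol = chem.mol_from_smiles(smiles)
    _, el, order = chem.attachment_info(mol, tag)
    return el, order


def _renormalize(probs: dict, supported: set) -> dict:
    kept = {k: v for k, v in probs.items() if k in supported and v > 0}
    dropped = [k for k in probs if k not in supported and probs[k] > 0]
    if dropped:
        logger.warning(
            "dropping %d connection categories with no compatible ligands: %s",
            len(dropped),
            dropped,
        )
    total = sum(kept.values())
    if total == 0:
        raise chem.ContractViolation("no connection category is compatible with the dictionaries")
    return {k: v / total for k, v in kept.items()}


def sample_and_assemble(
    d_wh: LigandDictionary,
    d_link: LigandDictionary,
    d_e3: LigandDictionary,
    p: ConnectionTypeDistribution,
    n: int,
    seed: int,
    *,
    max_attempts_factor: int = 60,
) -> list[AnnotatedProtac]:
    """Sample ``n`` unique PROTACs respecting the junction-type distribution.

    For each molecule a connection type is drawn independently per junction,
    then a warhead / linker / E3 triple is drawn uniformly among compatible
    ligands.  Duplicate parents are rejected and resampled.  When the retry
    budget is exhausted a partial library is returned with a warning.
    """
    if n < 1:
        raise chem.ContractViolation("n must be >= 1")
    if not (len(d_wh) and len(d_link) and len(d_e3)):
        raise chem.ContractViolation("all dictionaries must be non-empty")
    rng = random.Random(seed)

    wh_by_key: dict[tuple[str, str], list[Ligand]] = {}
    for lig in sorted(d_wh, key=lambda l: l.smiles):
        wh_by_key.setdefault(_attachment_key(lig.smiles, WARHEAD_TAG), []).append(lig)
    e3_by_key: dict[tuple[str, str], list[Ligand]] = {}
    for lig in sorted(d_e3, key=lambda l: l.smiles):
        e3_by_key.setdefault(_attachment_key(lig.smiles, E3_TAG), []).append(lig)
    link_by_keys: dict[tuple, list[Ligand]] = {}
    for lig in sorted(d_link, key=lambda l: l.smiles):
        k1 = _attachment_key(lig.smiles, WARHEAD_TAG)
        k2 = _attachment_key(lig.smiles, E3_TAG)
        link_by_keys.setdefault((k1, k2), []).append(lig)

    # category support: warhead-side needs a warhead and a linker tag-1 side
    link_k1 = {k[0] for k in link_by_keys}
    link_k2 = {k[1] for k in link_by_keys}
    supported1 = {
        jb
        for jb in p.wh_link
        if (jb.elements[0], jb.order) in wh_by_key
        and (jb.elements[1], jb.order) in link_k1
    }
    supported2 = {
        jb
        for jb in p.link_e3
        if (jb.elements[1], jb.order) in e3_by_key
        and (jb.elements[0], jb.order) in link_k2
    }
    p1 = _renormalize(p.wh_link, supported1)
    p2 = _renormalize(p.link_e3, supported2)
    cats1, w1 = zip(*sorted(p1.items(), key=lambda kv: (kv[0].order, kv[0].elements)))
    cats2, w2 = zip(*sorted(p2.items(), key=lambda kv: (kv[0].order, kv[0].elements)))

    # Per category cell, ligand triples are drawn uniformly WITHOUT
    # replacement (a lazily built, seed-shuffled deck).  Rejected duplicates
    # are retried within the same cell, so emitted junction-category counts
    # stay multinomial under P instead of drifting toward large cells.
    decks: dict[tuple, list] = {}

    def deck_for(c1: JunctionBond, c2: JunctionBond) -> list:
        key = (c1, c2)
        if key not in decks:
            k_wh = (c1.elements[0], c1.order)
            k_l1 = (c1.elements[1], c1.order)
            k_l2 = (c2.elements[0], c2.order)
            k_e3 = (c2.elements[1], c2.order)
            deck = [
                (wh, link, e3)
                for wh in wh_by_key.get(k_wh, [])
                for link in link_by_keys.get((k_l1, k_l2), [])
                for e3 in e3_by_key.get(k_e3, [])
            ]
            rng.shuffle(deck)
            decks[key] = deck
        return decks[key]

    out: list[AnnotatedProtac] = []
    seen: set[str] = set()
    attempts = 0
    budget = max_attempts_factor * n + 1000
    while len(out) < n and attempts < budget:
        attempts += 1
        c1 = rng.choices(cats1, weights=w1)[0]
        c2 = rng.choices(cats2, weights=w2)[0]
        deck = deck_for(c1, c2)
        built = None
        while deck and built is None:
            wh, link, e3 = deck.pop()
            try:
                parent, junction_atoms, junctions = chem.reassemble(
                    wh.smiles, link.smiles, e3.smiles, return_junctions=True
                )
            except (chem.JunctionError, chem.ContractViolation):
                continue
            if parent.smiles in seen:
                continue
            built = (wh, link, e3, parent, junction_atoms, junctions)
        if built is None:
            continue  # cell exhausted; redraw categories
        wh, link, e3, parent, junction_atoms, junctions = built
        seen.add(parent.smiles)
        out.append(
            AnnotatedProtac(
                parent=parent,
                warhead=wh,
                linker=link,
                e3=e3,
                junctions=junctions,
                junction_atoms=tuple(tuple(sorted(pair)) for pair in junction_atoms),
                provenance=PROVENANCE_SYNTHETIC,
            )
        )
    if len(out) < n:
        warnings.warn(
            f"retry budget exhausted: produced {len(out)} of {n} requested unique PROTACs",
            stacklevel=2,
        )
    return out


PROVENANCE_SYNTHETIC = "both-ligands-matched"  # recipe is the annotation


# --- Taylor-Butina cluster splits -----------------------------------------


@dataclass
class DatasetSplit:
    train: list[AnnotatedProtac]
    validation: list[AnnotatedProtac]
    test: list[AnnotatedProtac]
    unseen_report: dict[str, dict[int, int]] = field(default_factory=dict)
    reserved_ligands: dict[str, list[str]] = field(default_factory=dict)


def butina_clusters(fps, cutoff: float) -> list[tuple[int, ...]]:
    """Sphere-exclusion clustering on a fingerprint list (distance cutoff)."""
    n = len(fps)
    dists = []
    for i in range(1, n):
        sims = chem.bulk_tanimoto(fps[i], fps[:i])
        dists.extend(1.0 - s for s in sims)
    return list(Butina.ClusterData(dists, n, cutoff, isDistData=True))


def taylor_butina_split(
    protacs: Sequence[AnnotatedProtac],
    *,
    fp: FingerprintSpec = CLUSTER_FP,
    cutoff: float = 0.4,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> DatasetSplit:
    """Split a library so held-out sets contain whole unseen-ligand clusters.

    Ligands are clustered per role; randomly selected clusters are reserved,
    and every PROTAC containing a reserved ligand is excluded from train and
    assigned alternately to validation/test.  The unseen report counts, per
    held-out split, molecules with 1, 2, or 3 components absent from the
    train ligand pool.
    """
    rng = random.Random(seed)
    # unique ligands per role, stable order
    by_role: dict[str, list[str]] = {}
    for role in ("warhead", "linker", "e3"):
        seen = dict.fromkeys(getattr(ann, role).smiles for ann in protacs)
        by_role[role] = list(seen)

    reserved: dict[str, list[str]] = {}
    any_multi = False
    for role, smis in by_role.items():
        if len(smis) < 2:
            continue
        fps = [chem.morgan_fingerprint(chem.strip_tags(s), fp) for s in smis]
        clusters = butina_clusters(fps, cutoff)
        if len(clusters) < 2:
            continue
        any_multi = True
        order = sorted(range(len(clusters)), key=lambda i: (len(clusters[i]), i))
        rng.shuffle(order)
        target = holdout_fraction * len(smis)
        picked: list[str] = []
        for ci in order:
            if len(picked) >= target:
                break
            if len(picked) + len(clusters[ci]) >= len(smis):
                continue  # keep at least one cluster in train
            picked.extend(smis[j] for j in clusters[ci])
        reserved[role] = picked
    if not any_multi:
        raise SplitError(
            "ligands form a single cluster in every role; lower the Butina cutoff"
        )
    reserved_all = {s for smis in reserved.values() for s in smis}
    if not reserved_all:
        raise SplitError("no cluster could be reserved; adjust cutoff/holdout_fraction")

    train, holdout = [], []
    for ann in protacs:
        if any(lig.smiles in reserved_all for lig in ann.components):
            holdout.append(ann)
        else:
            train.append(ann)
    if not train or not holdout:
        raise SplitError("degenerate split (empty train or holdout); adjust parameters")
    idx = list(range(len(holdout)))
    rng.shuffle(idx)
    validation = [holdout[i] for i in idx[::2]]
    test = [holdout[i] for i in idx[1::2]]

    train_pool = {lig.smiles for ann in train for lig in ann.components}
    report: dict[str, dict[int, int]] = {}
    for name, subset in (("validation", validation), ("test", test)):
        hist = {0: 0, 1: 0, 2: 0, 3: 0}
        for ann in subset:
            k = sum(1 for lig in ann.components if lig.smiles not in train_pool)
            hist[k] += 1
        report[name] = hist
    return DatasetSplit(
        train=train,
        validation=validation,
        test=test,
        unseen_report=report,
        reserved_ligands=reserved,
    )


# --- CSV I/O --------------------------------------------------------------


def write_annotations_csv(annotations: Iterable[AnnotatedProtac], path: str | Path) -> None:
    import csv

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["parent_smiles", "warhead", "linker", "e3"])
        for ann in annotations:
            w.writerow([ann.parent.smiles, ann.warhead.smiles, ann.linker.smiles, ann.e3.smiles])


def read_annotations_csv(path: str | Path) -> list[AnnotatedProtac]:
    """Rebuild annotations from a (parent_smiles, warhead, linker, e3) CSV."""
    import csv

    out = []
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            parent, junction_atoms, junctions = chem.reassemble(
                row["warhead"], row["linker"], row["e3"], return_junctions=True
            )
            if parent.smiles != chem.canonical_smiles(row["parent_smiles"]):
                raise chem.JunctionError(
                    f"components do not reassemble to parent for {row['parent_smiles']}"
                )
            out.append(
                AnnotatedProtac(
                    parent=parent,
                    warhead=Ligand.from_smiles(row["warhead"], "warhead"),
                    linker=Ligand.from_smiles(row["linker"], "linker"),
                    e3=Ligand.from_smiles(row["e3"], "e3"),
                    junctions=junctions,
                    junction_atoms=tuple(tuple(sorted(p)) for p in junction_atoms),
                    provenance="both-ligands-matched",
                )
            )
    return out
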
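"""Bond-classification PROTAC splitter.

Every bridge (non-ring) bond of a PROTAC is featurized with graph descriptors
— normalized betweenness centrality of the bond's node in the molecular line
graph, first/second/third-order degree counts of its endpoint atoms in the
molecular graph and of the bond node in the line graph — plus the bond order,
the endpoint element symbols, and a 512-bit Morgan fingerprint (radius 6) of
the whole molecule as a global descriptor.  A gradient-boosted classifier
scores each bridge bond; the two highest-scoring bonds are cut, the middle
fragment is the linker, and the two end fragments are assigned warhead vs E3
roles by average Tanimoto similarity to a k-means-selected reference set of
training E3 ligands.

Because predictions are graph cuts of the input, every prediction reassembles
to the input exactly: validity and reassembly are 100% by construction and the
extra-atoms metric is identically zero.

Training data are wildly imbalanced (two positive bonds per molecule out of
tens of bridge bonds), so the pipeline reduces the fingerprint block with a
truncated SVD (50 components), one-hot encodes the categorical bond features,
and oversamples the minority class to 1:1 with SMOTE before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from rdkit import Chem
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import OneHotEncoder
from xgboost import XGBClassifier

from . import chem
from .annotation import AnnotatedProtac, refine_attachment_points
from .chem import FingerprintSpec, MoleculeRef
from .dictionaries import Ligand

logger = logging.getLogger(__name__)

GLOBAL_FP = FingerprintSpec(n_bits=512, radius=6)
ROLE_FP = FingerprintSpec(n_bits=512, radius=2)

NUMERIC_NAMES = (
    "betweenness",
    "deg1_hi", "deg1_lo", "deg2_hi", "deg2_lo", "deg3_hi", "deg3_lo",
    "ldeg1", "ldeg2", "ldeg3",
)


class UnsplittableError(ValueError):
    """Molecule has fewer than two bridge bonds and cannot be split."""


class TrainingError(ValueError):
    """Training data are unusable (e.g. a single class)."""


@dataclass
class SplitterConfig:
    """Featurization and training configuration.

    ``per_molecule_scale`` switches the betweenness feature from the standard
    combinatorial normalization to a per-molecule min-max rescale.
    """

    global_fp: FingerprintSpec = GLOBAL_FP
    per_molecule_scale: bool = False
    svd_components: int = 50
    smote_k: int = 5
    seed: int = 0


@dataclass
class BondRecord:
    """Feature vector of one bridge bond, with an optional cut label."""

    parent_id: str
    bond_idx: int
    numeric: np.ndarray  # aligned with NUMERIC_NAMES
    bond_type: str
    elements: tuple[str, str]  # lexicographically sorted endpoint symbols
    global_fp: np.ndarray  # uint8, shared across the parent's records
    label: int | None = None

    @property
    def betweenness(self) -> float:
        return float(self.numeric[0])


@dataclass
class SplitPrediction:
    warhead: Ligand
    linker: Ligand
    e3: Ligand
    source: str  # graph_splitter | external_model | fixed | hybrid
    scores: tuple[float, float] | None = None

    @property
    def components(self) -> tuple[Ligand, Ligand, Ligand]:
        return (self.warhead, self.linker, self.e3)


@dataclass
class E3ReferenceSet:
    """Representative training E3 ligands for role assignment."""

    members: list[str]  # attachment-tagged SMILES
    _fps: list = field(default_factory=list, repr=False)

    def fingerprints(self):
        if not self._fps:
            self._fps = [
                chem.morgan_fingerprint(chem.strip_tags(s), ROLE_FP) for s in self.members
            ]
        return self._fps

    def average_similarity(self, fragment_smiles: str) -> float:
        fp = chem.morgan_fingerprint(chem.strip_tags(fragment_smiles), ROLE_FP)
        sims = chem.bulk_tanimoto(fp, self.fingerprints())
        return float(np.mean(sims))


# --- featurization --------------------------------------------------------


def _k_order_degrees(graph: nx.Graph, node, max_k: int = 3) -> list[int]:
    """Counts of nodes at shortest-path distance exactly 1..max_k."""
    lengths = nx.single_source_shortest_path_length(graph, node, cutoff=max_k)
    counts = [0] * max_k
    for dist in lengths.values():
        if 1 <= dist <= max_k:
            counts[dist - 1] += 1
    return counts


def featurize_bonds(protac, config: SplitterConfig = SplitterConfig()) -> list[BondRecord]:
    """One :class:`BondRecord` per bridge bond of the molecule.

    Raises :class:`UnsplittableError` when fewer than two bridge bonds exist
    (e.g. a single ring).
    """
    if isinstance(protac, Chem.Mol):
        mol = protac
        parent_id = Chem.MolToSmiles(mol)
    else:
        smi = protac.smiles if isinstance(protac, MoleculeRef) else protac
        mol = chem.mol_from_smiles(smi)
        parent_id = Chem.MolToSmiles(mol)
    bridges = chem.bridge_bond_indices(mol)
    if len(bridges) < 2:
        raise UnsplittableError(
            f"{parent_id} has {len(bridges)} bridge bond(s); at least 2 required"
        )

    g = nx.Graph()
    g.add_nodes_from(a.GetIdx() for a in mol.GetAtoms())
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    lg = nx.line_graph(g)
    centrality = nx.betweenness_centrality(lg, normalized=True)

    def line_node(bond: Chem.Bond):
        key = (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
        return key if key in lg else (key[1], key[0])

    bet = {b: centrality[line_node(mol.GetBondWithIdx(b))] for b in bridges}
    if config.per_molecule_scale:
        lo, hi = min(bet.values()), max(bet.values())
        span = (hi - lo) or 1.0
        bet = {b: (v - lo) / span for b, v in bet.items()}

    fp_obj = chem.morgan_fingerprint(mol, config.global_fp)
    fp = np.frombuffer(bytes(fp_obj.ToBitString(), "ascii"), dtype=np.uint8) - ord("0")

    records = []
    for b in bridges:
        bond = mol.GetBondWithIdx(b)
        a1, a2 = bond.GetBeginAtom(), bond.GetEndAtom()
        d1 = _k_order_degrees(g, a1.GetIdx())
        d2 = _k_order_degrees(g, a2.GetIdx())
        ld = _k_order_degrees(lg, line_node(bond))
        numeric = np.array(
            [bet[b]]
            + [f(x, y) for x, y in zip(d1, d2) for f in (max, min)]
            + ld,
            dtype=float,
        )
        records.append(
            BondRecord(
                parent_id=parent_id,
                bond_idx=b,
                numeric=numeric,
                bond_type=chem.bond_order_name(bond),
                elements=tuple(sorted((a1.GetSymbol(), a2.GetSymbol()))),
                global_fp=fp,
            )
        )
    return records


def records_from_annotations(
    annotations: Sequence[AnnotatedProtac], config: SplitterConfig = SplitterConfig()
) -> list[BondRecord]:
    """Labeled bond records for training: the two junction bonds are positive.

    Every labeled parent contributes exactly two positive records.
    """
    out = []
    for ann in annotations:
        mol = chem.mol_from_smiles(ann.parent.smiles)
        positive = set()
        for pair in ann.junction_atoms:
            bond = mol.GetBondBetweenAtoms(*pair)
            if bond is None:
                raise chem.ContractViolation(
                    f"junction atoms {pair} not bonded in {ann.parent.smiles}"
                )
            positive.add(bond.GetIdx())
        if len(positive) != 2:
            raise chem.ContractViolation(
                f"annotation of {ann.parent.smiles} has {len(positive)} junction bonds"
            )
        records = featurize_bonds(mol, config)
        n_pos = 0
        for rec in records:
            rec.label = int(rec.bond_idx in positive)
            n_pos += rec.label
        if n_pos != 2:
            raise chem.ContractViolation(
                f"{ann.parent.smiles}: junction bonds not among bridge bonds"
            )
        out.extend(records)
    return out


# --- imbalance-aware pipeline ---------------------------------------------


class Smote:
    """Minimal SMOTE: interpolate minority samples toward minority k-NN."""

    def __init__(self, k: int = 5, seed: int = 0):
        self.k = k
        self.seed = seed

    def fit_resample(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise TrainingError(f"SMOTE needs two classes, got {list(classes)}")
        minority = classes[np.argmin(counts)]
        need = int(counts.max() - counts.min())
        if need == 0:
            return X, y
        Xm = X[y == minority]
        k = min(self.k, len(Xm) - 1)
        if k < 1:
            raise TrainingError("too few minority samples for SMOTE")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)
        rng = np.random.default_rng(self.seed)
        base = rng.integers(0, len(Xm), size=need)
        nbr = idx[base, rng.integers(1, k + 1, size=need)]
        lam = rng.random((need, 1))
        synth = Xm[base] + lam * (Xm[nbr] - Xm[base])
        Xr = np.vstack([X, synth])
        yr = np.concatenate([y, np.full(need, minority, dtype=y.dtype)])
        return Xr, yr


class SplitterModel:
    """SVD + one-hot + SMOTE + gradient-boosted bond classifier.

    SMOTE touches the training fold only: :meth:`predict_scores` never
    resamples.
    """

    def __init__(self, config: SplitterConfig = SplitterConfig()):
        self.config = config
        self.svd = TruncatedSVD(
            n_components=config.svd_components, random_state=config.seed
        )
        self.encoder = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
        self.smote = Smote(k=config.smote_k, seed=config.seed)
        self.classifier = XGBClassifier(random_state=config.seed, n_jobs=1)
        self.fitted = False

    @staticmethod
    def _blocks(records: Sequence[BondRecord]):
        numeric = np.array([r.numeric for r in records])
        cats = np.array([[r.bond_type, r.elements[0], r.elements[1]] for r in records])
        fps = np.array([r.global_fp for r in records], dtype=float)
        return numeric, cats, fps

    def _transform(self, records: Sequence[BondRecord], fit: bool) -> np.ndarray:
        numeric, cats, fps = self._blocks(records)
        if fit:
            fp_red = self.svd.fit_transform(fps)
            onehot = self.encoder.fit_transform(cats)
        else:
            fp_red = self.svd.transform(fps)
            onehot = self.encoder.transform(cats)
        return np.hstack([numeric, onehot, fp_red])

    def fit(self, records: Sequence[BondRecord]) -> "SplitterModel":
        labels = np.array([r.label for r in records])
        if None in labels or len(np.unique(labels)) < 2:
            raise TrainingError("both classes must be present in the training records")
        X = self._transform(records, fit=True)
        Xr, yr = self.smote.fit_resample(X, labels.astype(int))
        self.classifier.fit(Xr, yr)
        self.fitted = True
        return self

    def predict_scores(self, records: Sequence[BondRecord]) -> np.ndarray:
        if not self.fitted:
            raise TrainingError("model is not fitted")
        X = self._transform(records, fit=False)
        return self.classifier.predict_proba(X)[:, 1]


def train_pipeline(
    records: Sequence[BondRecord], config: SplitterConfig = SplitterConfig()
) -> SplitterModel:
    """Fit the imbalance-aware bond-classification pipeline."""
    return SplitterModel(config).fit(records)


# --- E3 reference set and prediction --------------------------------------


def build_e3_reference(
    train_e3: Sequence[Ligand | str], k: int = 50, seed: int = 0
) -> E3ReferenceSet:
    """k-means over fingerprints of the train E3 pool; the member nearest each
    centroid becomes a reference."""
    smis = list(
        dict.fromkeys(l.smiles if isinstance(l, Ligand) else l for l in train_e3)
    )
    if not smis:
        raise chem.ContractViolation("at least one E3 ligand is required")
    k = min(k, len(smis))
    if k == len(smis):
        return E3ReferenceSet(members=smis)
    fps = np.array(
        [
            np.frombuffer(
                bytes(
                    chem.morgan_fingerprint(chem.strip_tags(s), ROLE_FP).ToBitString(),
                    "ascii",
                ),
                dtype=np.uint8,
            )
            - ord("0")
            for s in smis
        ],
        dtype=float,
    )
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(fps)
    members = []
    for center in km.cluster_centers_:
        nearest = int(np.argmin(np.linalg.norm(fps - center, axis=1)))
        if smis[nearest] not in members:
            members.append(smis[nearest])
    return E3ReferenceSet(members=members)


def predict_split(
    model: SplitterModel,
    protac,
    e3_ref: E3ReferenceSet,
    config: SplitterConfig | None = None,
    *,
    refine: bool = True,
) -> SplitPrediction:
    """Score bridge bonds, cut the top two, and assign fragment roles.

    The middle fragment is the linker; of the end fragments, the one with the
    higher average Tanimoto similarity to the E3 reference set is the E3
    ligand.  The output reassembles to the input by construction.
    """
    config = config or model.config
    records = featurize_bonds(protac, config)  # raises UnsplittableError
    scores = model.predict_scores(records)
    order = sorted(
        range(len(records)),
        key=lambda i: (-scores[i], -records[i].betweenness, records[i].bond_idx),
    )
    top = [records[order[0]], records[order[1]]]
    top_scores = (float(scores[order[0]]), float(scores[order[1]]))
    smi = protac.smiles if isinstance(protac, MoleculeRef) else (
        Chem.MolToSmiles(protac) if isinstance(protac, Chem.Mol) else protac
    )
    return _split_at(
        smi,
        (top[0].bond_idx, top[1].bond_idx),
        e3_ref,
        source="graph_splitter",
        scores=top_scores,
        refine=refine,
    )


def _split_at(
    parent_smiles: str,
    bonds: tuple[int, int],
    e3_ref: E3ReferenceSet,
    *,
    source: str,
    scores: tuple[float, float] | None,
    refine: bool,
) -> SplitPrediction:
    """Cut, orient by E3-reference similarity, refine, and package."""
    parent = chem.canonicalize(parent_smiles)
    mol = chem.mol_from_smiles(parent.smiles)
    cut = chem.cut_two_bonds(mol, bonds)
    sim1 = e3_ref.average_similarity(cut.end1)
    sim2 = e3_ref.average_similarity(cut.end2)
    if sim1 > sim2:  # the tag-1 end is the E3 ligand: flip the cut orientation
        bonds = (bonds[1], bonds[0])
        cut = chem.cut_two_bonds(mol, bonds)
    ann = AnnotatedProtac(
        parent=parent,
        warhead=Ligand.from_smiles(cut.end1, "warhead"),
        linker=Ligand.from_smiles(cut.linker, "linker"),
        e3=Ligand.from_smiles(cut.end2, "e3"),
        junctions=chem.junction_descriptors(mol, bonds),
        junction_atoms=tuple(
            tuple(
                sorted(
                    (
                        mol.GetBondWithIdx(int(b)).GetBeginAtomIdx(),
                        mol.GetBondWithIdx(int(b)).GetEndAtomIdx(),
                    )
                )
            )
            for b in bonds
        ),
        provenance="manual",
    )
    if refine:
        ann = refine_attachment_points(ann)
    return SplitPrediction(
        warhead=ann.warhead, linker=ann.linker, e3=ann.e3, source=source, scores=scores
    )


# --- persistence ----------------------------------------------------------


def save_model(model: SplitterModel, e3_ref: E3ReferenceSet, path) -> None:
    import joblib

    joblib.dump({"model": model, "e3_ref": E3ReferenceSet(members=e3_ref.members)}, path)


def load_model(path) -> tuple[SplitterModel, E3ReferenceSet]:
    import joblib

    payload = joblib.load(path)
    return payload["model"], payload["e3_ref"]
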
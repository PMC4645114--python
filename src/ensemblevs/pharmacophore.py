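"""Receptor-ligand pharmacophore models and conformer fit values.

Feature perception uses a documented SMARTS rule set; models are subsets of
the ligand features that match receptor interactions under geometric
criteria; the fit value of a conformer against a model is a quadratic
displacement penalty summed over an optimal injective feature assignment
after least-squares rigid superposition.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

from ensemblevs.chemio import MoleculeRecord

logger = logging.getLogger(__name__)

FEATURE_KINDS = (
    "HB_donor",
    "HB_acceptor",
    "hydrophobe",
    "aromatic_ring",
    "pos_ionizable",
    "neg_ionizable",
)

# feature tolerance spheres (Angstrom); hydrophobes are fuzzier
DEFAULT_TOLERANCE = 1.6
HYDROPHOBE_TOLERANCE = 2.2
DEFAULT_WEIGHT = 1.0

# assignments are rejected outright when any feature lands beyond this
# multiple of its tolerance after superposition
REJECT_TOLERANCE_FACTOR = 2.0

MAX_ASSIGNMENTS = 100_000

# --- documented SMARTS rule set ------------------------------------------
# Ionizable groups are perceived first and claim their atoms: a protonatable
# amine or amidine nitrogen is an ionizable feature, not a donor/acceptor.
_POS_IONIZABLE_SMARTS = [
    "[NX3][CX3](=[NX2])[NX3]",  # guanidine
    "[NX3][CX3]=[NX2]",  # amidine
    "[NX3;+0;!$([NX3]a);!$([NX3][CX3]=[O,N,S]);!$([NX3][a,CX3]=[NX2])]",  # basic amine
    "[NX4+]",
    "[NX3+;!$([NX3+]=O)]",
]
_NEG_IONIZABLE_SMARTS = [
    "[CX3](=O)[OX2H1,OX1-]",  # carboxylic acid / carboxylate
    "[SX4](=O)(=O)[OX2H1,OX1-]",
    "[PX4](=O)[OX2H1,OX1-]",
    "c1nnn[nH]1",  # tetrazole
    "c1nnn[n-]1",
]
_DONOR_SMARTS = (
    "[$([N;!H0;v3]),$([N;!H0;+1;v4]),$([O;H1;+0]),$([S;H1;+0]),$([n;H1;+0])]"
)
_ACCEPTOR_SMARTS = (
    "[$([O;H1;v2]),$([O;H0;v2]),$([O;H0;v1]),$([O;-]),"
    "$([n;H0;+0;X2]),$([NX2;H0;+0;!$(N=O)]),"
    "$([NX3;+0;!$([NX3]C=[O,N,S]);!$([NX3]a)])]"
)


@dataclass
class PharmacophoreFeature:
    """A typed feature sphere: kind, center (A), tolerance (A), weight."""

    kind: str
    center: np.ndarray
    tolerance: float = DEFAULT_TOLERANCE
    weight: float = DEFAULT_WEIGHT
    atom_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")


@dataclass
class PharmacophoreModel:
    """A set of >= min_features feature spheres with a selectivity score."""

    model_id: str
    source_complex_id: str
    features: list[PharmacophoreFeature]
    selectivity: float = 0.0

    MIN_FEATURES = 3

    def __post_init__(self) -> None:
        if len(self.features) < self.MIN_FEATURES:
            raise ValueError(
                f"model needs >= {self.MIN_FEATURES} features, got {len(self.features)}"
            )
        if not math.isfinite(self.selectivity):
            raise ValueError("selectivity must be finite")

    @property
    def total_weight(self) -> float:
        return float(sum(f.weight for f in self.features))

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "model_id": self.model_id,
            "source_complex_id": self.source_complex_id,
            "selectivity": self.selectivity,
            "features": [
                {
                    "kind": f.kind,
                    "center": [float(x) for x in f.center],
                    "tolerance": f.tolerance,
                    "weight": f.weight,
                }
                for f in self.features
            ],
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PharmacophoreModel":
        path = Path(source) if isinstance(source, Path) else None
        if path is None:
            try:
                if Path(str(source)).is_file():
                    path = Path(str(source))
            except OSError:
                pass  # raw JSON text, not a path
        doc = json.loads(path.read_text() if path else str(source))
        features = [
            PharmacophoreFeature(
                kind=f["kind"],
                center=np.array(f["center"], dtype=float),
                tolerance=f["tolerance"],
                weight=f["weight"],
            )
            for f in doc["features"]
        ]
        return cls(
            model_id=doc["model_id"],
            source_complex_id=doc["source_complex_id"],
            features=features,
            selectivity=doc.get("selectivity", 0.0),
        )


@dataclass
class FitResult:
    molecule_id: str
    model_id: str
    fit_value: float
    best_conformer_index: int | None = None
    feature_assignment: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# feature perception
# ---------------------------------------------------------------------------


def _feature_atom_groups(mol: Chem.Mol) -> list[tuple[str, tuple[int, ...]]]:
    """Graph-level feature groups (kind, atom indices), coordinate-free."""
    groups: list[tuple[str, tuple[int, ...]]] = []
    claimed: set[int] = set()

    for kind, patterns in (
        ("pos_ionizable", _POS_IONIZABLE_SMARTS),
        ("neg_ionizable", _NEG_IONIZABLE_SMARTS),
    ):
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            for match in mol.GetSubstructMatches(patt):
                if set(match) & claimed:
                    continue
                claimed.update(match)
                groups.append((kind, tuple(sorted(match))))

    for kind, smarts in (("HB_donor", _DONOR_SMARTS), ("HB_acceptor", _ACCEPTOR_SMARTS)):
        patt = Chem.MolFromSmarts(smarts)
        for (idx,) in mol.GetSubstructMatches(patt):
            if idx in claimed:
                continue
            groups.append((kind, (idx,)))

    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            groups.append(("aromatic_ring", tuple(sorted(ring))))

    # hydrophobes: connected clusters (>= 3 atoms) of aliphatic carbons whose
    # neighbours are only carbon or hydrogen
    greasy = {
        atom.GetIdx()
        for atom in mol.GetAtoms()
        if atom.GetAtomicNum() == 6
        and not atom.GetIsAromatic()
        and all(n.GetAtomicNum() in (1, 6) for n in atom.GetNeighbors())
    }
    unvisited = set(greasy)
    while unvisited:
        seed = min(unvisited)
        component = {seed}
        frontier = [seed]
        while frontier:
            idx = frontier.pop()
            for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = nb.GetIdx()
                if j in greasy and j not in component:
                    component.add(j)
                    frontier.append(j)
        unvisited -= component
        if len(component) >= 3:
            groups.append(("hydrophobe", tuple(sorted(component))))

    groups.sort(key=lambda g: (FEATURE_KINDS.index(g[0]), g[1]))
    return groups


def perceive_features(
    record: MoleculeRecord, conformer_index: int = 0
) -> list[PharmacophoreFeature]:
    """Locate typed pharmacophore features on one conformer.

    Deterministic for a given structure: ionizable groups are perceived
    first and claim their atoms, then donors/acceptors on the remaining
    polar atoms, aromatic ring centroids, and hydrophobic aliphatic-carbon
    clusters.
    """
    if record.mol is None:
        raise ValueError(f"molecule {record.id!r} has no structure")
    if record.mol.GetNumConformers() <= conformer_index:
        raise ValueError(
            f"molecule {record.id!r} has no conformer {conformer_index}"
        )
    coords = record.mol.GetConformer(conformer_index).GetPositions()
    features = []
    for kind, atoms in _feature_atom_groups(record.mol):
        tolerance = HYDROPHOBE_TOLERANCE if kind == "hydrophobe" else DEFAULT_TOLERANCE
        features.append(
            PharmacophoreFeature(
                kind=kind,
                center=coords[list(atoms)].mean(axis=0),
                tolerance=tolerance,
                atom_indices=atoms,
            )
        )
    return features


def generate_conformers(
    record: MoleculeRecord, max_confs: int = 100, seed: int = 20150
) -> MoleculeRecord:
    """Embed up to ``max_confs`` conformers (ETKDG, pruned at 0.5 A RMSD).

    Rigid molecules (zero rotatable bonds) get a single conformer.  The
    same seed reproduces the same ensemble.
    """
    if record.mol is None:
        raise ValueError(f"molecule {record.id!r} has no structure")
    if max_confs < 1:
        raise ValueError("max_confs must be >= 1")
    n_rot = rdMolDescriptors.CalcNumRotatableBonds(record.mol)
    n_confs = 1 if n_rot == 0 else max_confs
    molh = Chem.AddHs(record.mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    params.pruneRmsThresh = 0.5
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_confs, params=params)
    if len(conf_ids) == 0:
        params.useRandomCoords = True
        conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_confs, params=params)
    if len(conf_ids) == 0:
        raise RuntimeError(f"conformer embedding failed for molecule {record.id!r}")
    mol = Chem.RemoveHs(molh)
    if mol.GetNumConformers() > max_confs:
        for conf_id in [c.GetId() for c in mol.GetConformers()][max_confs:]:
            mol.RemoveConformer(conf_id)
    return MoleculeRecord(
        id=record.id, mol=mol, properties=dict(record.properties), label=record.label
    )


# ---------------------------------------------------------------------------
# receptor matching and model derivation
# ---------------------------------------------------------------------------


@dataclass
class ReceptorEnvironment:
    """Binding-site interaction partners as bare coordinate sets (A)."""

    donor_xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    acceptor_xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    hydrophobe_xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    pos_xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    neg_xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        for name in ("donor_xyz", "acceptor_xyz", "hydrophobe_xyz", "pos_xyz", "neg_xyz"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1, 3)
            setattr(self, name, arr)

    @classmethod
    def from_atoms(
        cls, elements: Sequence[str], coords: np.ndarray
    ) -> "ReceptorEnvironment":
        """Coarse typing of bare receptor atoms: N -> donor, O -> acceptor,
        C/S -> hydrophobic.  Use explicit arrays for anything finer."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        elements = [e.capitalize() for e in elements]
        sel = lambda want: coords[[i for i, e in enumerate(elements) if e in want]]
        return cls(
            donor_xyz=sel({"N"}),
            acceptor_xyz=sel({"O"}),
            hydrophobe_xyz=sel({"C", "S"}),
        )


# geometric interaction windows (A): H-bond heavy-atom distance, hydrophobic
# contact, ionic contact
HBOND_MAX_DIST = 3.5
HYDROPHOBE_MAX_DIST = 4.5
IONIC_MAX_DIST = 4.0

_PARTNER_RULES = {
    "HB_donor": ("acceptor_xyz", HBOND_MAX_DIST),
    "HB_acceptor": ("donor_xyz", HBOND_MAX_DIST),
    "hydrophobe": ("hydrophobe_xyz", HYDROPHOBE_MAX_DIST),
    "aromatic_ring": ("hydrophobe_xyz", HYDROPHOBE_MAX_DIST),
    "pos_ionizable": ("neg_xyz", IONIC_MAX_DIST),
    "neg_ionizable": ("pos_xyz", IONIC_MAX_DIST),
}


def match_receptor_contacts(
    features: Sequence[PharmacophoreFeature], receptor: ReceptorEnvironment
) -> list[bool]:
    """Whether each ligand feature has a receptor partner within its window."""
    flags = []
    for feat in features:
        attr, max_dist = _PARTNER_RULES[feat.kind]
        partners = getattr(receptor, attr)
        if partners.shape[0] == 0:
            flags.append(False)
            continue
        dists = np.linalg.norm(partners - feat.center, axis=1)
        flags.append(bool(np.min(dists) <= max_dist))
    return flags


def derive_models(
    ligand_features: Sequence[PharmacophoreFeature],
    receptor_contacts: ReceptorEnvironment | Sequence[bool],
    min_features: int = 3,
    max_models: int = 10,
    source_complex_id: str = "complex",
    reference: Sequence[MoleculeRecord] | None = None,
    max_candidates: int = 512,
) -> list[PharmacophoreModel]:
    """Models are subsets (size min_features..all) of the interaction-matched
    ligand features, ranked by descending selectivity.

    Selectivity is estimated against ``reference`` when given (empirical
    rarity, see :func:`estimate_selectivity`); otherwise the feature count
    serves as an a-priori proxy (more constraints => rarer matches).
    """
    if isinstance(receptor_contacts, ReceptorEnvironment):
        flags = match_receptor_contacts(ligand_features, receptor_contacts)
    else:
        flags = list(receptor_contacts)
        if len(flags) != len(ligand_features):
            raise ValueError("contact flags must align with ligand features")
    matched = [f for f, ok in zip(ligand_features, flags) if ok]
    if len(matched) < min_features:
        logger.warning(
            "only %d interaction-matched features (< %d); no model derived",
            len(matched),
            min_features,
        )
        return []

    candidates: list[tuple[int, ...]] = []
    for size in range(len(matched), min_features - 1, -1):
        for combo in itertools.combinations(range(len(matched)), size):
            candidates.append(combo)
            if len(candidates) >= max_candidates:
                break
        if len(candidates) >= max_candidates:
            logger.warning("model enumeration capped at %d candidates", max_candidates)
            break

    scored = []
    for combo in candidates:
        features = [matched[i] for i in combo]
        model = PharmacophoreModel(
            model_id="tmp",
            source_complex_id=source_complex_id,
            features=features,
        )
        if reference is not None:
            selectivity = estimate_selectivity(model, reference)
        else:
            selectivity = float(len(combo))
        model.selectivity = selectivity
        scored.append((combo, model))

    scored.sort(key=lambda item: (-item[1].selectivity, item[0]))
    models = []
    for rank, (_, model) in enumerate(scored[:max_models], start=1):
        model.model_id = f"{source_complex_id}_m{rank:02d}"
        models.append(model)
    return models


def estimate_selectivity(
    model: PharmacophoreModel, reference: Sequence[MoleculeRecord]
) -> float:
    """Empirical rarity: -log10 of the fraction of reference molecules that
    map the model (fit > 0); matched by none is capped at -log10(0.5/N)."""
    if not reference:
        raise ValueError("reference library must be non-empty")
    n = len(reference)
    matched = sum(1 for rec in reference if map_fit(model, rec).fit_value > 0.0)
    if matched == 0:
        return -math.log10(0.5 / n)
    return -math.log10(matched / n)


# ---------------------------------------------------------------------------
# fit mapping
# ---------------------------------------------------------------------------


def kabsch_transform(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping points P onto Q
    (proper rotation; reflections are corrected away)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def _injective_assignments(
    candidates: list[list[int]], cap: int
) -> Iterator[tuple[int, ...]]:
    """Injective choices, one ligand feature per model feature, capped."""
    count = 0
    used: list[int] = []

    def rec(depth: int) -> Iterator[tuple[int, ...]]:
        nonlocal count
        if count >= cap:
            return
        if depth == len(candidates):
            count += 1
            yield tuple(used)
            return
        for choice in candidates[depth]:
            if choice in used:
                continue
            used.append(choice)
            yield from rec(depth + 1)
            used.pop()
            if count >= cap:
                return

    yield from rec(0)


def map_fit(
    model: PharmacophoreModel,
    record: MoleculeRecord,
    align: bool = True,
    max_assignments: int = MAX_ASSIGNMENTS,
) -> FitResult:
    """Best fit value of a molecule's conformer ensemble against a model.

    For every conformer and every injective kind-compatible assignment of
    ligand features to model features, the matched ligand-feature centroids
    are rigidly superposed onto the model centers (skipped with
    ``align=False`` for pre-posed conformers), and

        fit = sum_f weight_f * max(0, 1 - (d_f / tolerance_f)^2)

    with d_f the post-alignment displacement.  Assignments placing any
    feature beyond 2x its tolerance are rejected; fit is 0 when no valid
    assignment exists on any conformer.
    """
    if not model.features:
        raise ValueError("model has no features")
    if record.mol is None or record.mol.GetNumConformers() == 0:
        raise ValueError(f"molecule {record.id!r} has no conformers")

    groups = _feature_atom_groups(record.mol)
    kind_to_groups: dict[str, list[int]] = {}
    for gi, (kind, _) in enumerate(groups):
        kind_to_groups.setdefault(kind, []).append(gi)
    candidates = [kind_to_groups.get(f.kind, []) for f in model.features]
    if any(len(c) == 0 for c in candidates):
        return FitResult(record.id, model.model_id, 0.0)

    model_centers = np.array([f.center for f in model.features])
    tolerances = np.array([f.tolerance for f in model.features])
    weights = np.array([f.weight for f in model.features])

    best_fit = 0.0
    best_conf: int | None = None
    best_assignment: list[tuple[int, int]] = []
    n_assign_total = math.prod(len(c) for c in candidates)
    if n_assign_total > max_assignments:
        logger.warning(
            "assignment search truncated at %d of ~%d per conformer",
            max_assignments,
            n_assign_total,
        )

    for conf_idx, conf in enumerate(record.mol.GetConformers()):
        coords = conf.GetPositions()
        centers = np.array(
            [coords[list(atoms)].mean(axis=0) for _, atoms in groups]
        )
        for assignment in _injective_assignments(candidates, max_assignments):
            P = centers[list(assignment)]
            if align:
                R, t = kabsch_transform(P, model_centers)
                placed = P @ R.T + t
            else:
                placed = P
            d = np.linalg.norm(placed - model_centers, axis=1)
            if np.any(d > REJECT_TOLERANCE_FACTOR * tolerances):
                continue
            fit = float(np.sum(weights * np.clip(1.0 - (d / tolerances) ** 2, 0.0, None)))
            if fit > best_fit:
                best_fit = fit
                best_conf = conf_idx
                best_assignment = list(enumerate(assignment))

    return FitResult(
        molecule_id=record.id,
        model_id=model.model_id,
        fit_value=best_fit,
        best_conformer_index=best_conf,
        feature_assignment=best_assignment,
    )


def model_from_conformer(
    record: MoleculeRecord,
    conformer_index: int = 0,
    source_complex_id: str = "complex",
    model_id: str | None = None,
    feature_indices: Sequence[int] | None = None,
) -> PharmacophoreModel:
    """Convenience: turn (a subset of) a conformer's perceived features into
    a model; mapping that model back onto the same conformer attains the
    maximum fit of sum(weights)."""
    features = perceive_features(record, conformer_index)
    if feature_indices is not None:
        features = [features[i] for i in feature_indices]
    return PharmacophoreModel(
        model_id=model_id or f"{record.id}_self",
        source_complex_id=source_complex_id,
        features=features,
    )
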
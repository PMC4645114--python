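"""Chemical/tabular I/O and the deterministic fixture generator.

Readers accept SMILES (``SMILES<whitespace>id`` per line) and SDF V2000
libraries plus CSV docking-score tables.  The fixture generator produces a
synthetic active/decoy library with per-structure docking-score channels
(class-conditional Gaussians sharing one latent factor) and zero-inflated
fit-value channels, so every downstream module is testable offline.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

LABELS = ("active", "decoy", "unknown")


@dataclass
class MoleculeRecord:
    """A library compound: graph, optional conformers, properties, label."""

    id: str
    mol: Chem.Mol | None = None
    properties: dict[str, float] = field(default_factory=dict)
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        for key, value in self.properties.items():
            if not math.isfinite(float(value)):
                raise ValueError(f"property {key!r} of {self.id!r} is not finite")

    @property
    def conformers(self) -> list[np.ndarray]:
        """3D coordinate sets in Angstroms, one (n_atoms, 3) array each."""
        if self.mol is None:
            return []
        return [conf.GetPositions().copy() for conf in self.mol.GetConformers()]

    @property
    def num_heavy_atoms(self) -> int:
        if self.mol is None:
            return 0
        return self.mol.GetNumHeavyAtoms()

    @property
    def smiles(self) -> str | None:
        if self.mol is None:
            return None
        return Chem.MolToSmiles(self.mol)


@dataclass
class ScoreTable:
    """Per-structure channel values keyed by molecule id.

    Docking convention: more negative = better.  ``score_mode`` marks the
    provenance; ``"fit"`` tables hold pharmacophore fit values instead
    (larger = better, 0 = no mapping).
    """

    structure_id: str
    entries: dict[str, float]
    score_mode: str = "stand-in"

    VALID_MODES = ("SP", "XP", "stand-in", "fit")

    def __post_init__(self) -> None:
        if self.score_mode not in self.VALID_MODES:
            raise ValueError(f"score_mode must be one of {self.VALID_MODES}")
        for mid, score in self.entries.items():
            if not math.isfinite(score):
                raise ValueError(f"non-finite score for {mid!r}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic active/decoy screening fixture."""

    n_actives: int = 350
    decoy_ratio: int = 20
    n_structures: int = 8
    active_score_mean: float = -9.0
    decoy_score_mean: float = -6.5
    score_sd: float = 1.5
    cross_structure_correlation: float = 0.3
    fit_nonmapper_prob: float = 0.6
    active_fit_mean: float = 3.0
    decoy_fit_mean: float = 1.2
    fit_sd: float = 0.8
    n_failing_structures: int = 0
    with_structures: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actives < 1:
            raise ValueError("n_actives must be >= 1")
        if self.decoy_ratio < 1:
            raise ValueError("decoy_ratio must be >= 1")
        if self.score_sd <= 0 or self.fit_sd <= 0:
            raise ValueError("standard deviations must be > 0")
        if not 0.0 <= self.cross_structure_correlation <= 1.0:
            raise ValueError("cross_structure_correlation must be in [0, 1]")
        if not 0.0 <= self.fit_nonmapper_prob <= 1.0:
            raise ValueError("fit_nonmapper_prob must be in [0, 1]")
        if self.n_failing_structures < 0 or self.n_failing_structures > self.n_structures:
            raise ValueError("n_failing_structures must be in [0, n_structures]")

    @property
    def n_decoys(self) -> int:
        return self.n_actives * self.decoy_ratio


@dataclass
class FixtureBundle:
    """Everything :func:`generate_fixtures` emits."""

    molecules: list[MoleculeRecord]
    score_tables: list[ScoreTable]
    fit_tables: list[ScoreTable]
    redock_rmsd: dict[str, float]

    @property
    def actives(self) -> list[MoleculeRecord]:
        return [m for m in self.molecules if m.label == "active"]

    @property
    def decoys(self) -> list[MoleculeRecord]:
        return [m for m in self.molecules if m.label == "decoy"]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".smi", ".smiles", ".txt"):
        return "smiles"
    if suffix == ".sdf":
        return "sdf"
    raise ValueError(f"cannot infer library format from {path.name!r}; pass format=")


def read_library(path: str | Path, format: str | None = None) -> list[MoleculeRecord]:
    """Read a compound library from a SMILES or SDF V2000 file.

    Unparsable entries are logged with their line/record index and skipped;
    order of parsable entries is preserved.  Missing SMILES ids become
    ``mol_<line>``.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"library file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "smiles":
        records = _read_smiles(path)
    elif fmt == "sdf":
        records = _read_sdf(path)
    else:
        raise ValueError(f"unknown library format {fmt!r}")
    if not records:
        raise ValueError(f"no parsable records in {path}")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate molecule id {rec.id!r} in {path}")
        seen.add(rec.id)
    return records


def _read_smiles(path: Path) -> list[MoleculeRecord]:
    records = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol_{lineno}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                logger.warning("line %d: unparsable SMILES %r, skipped", lineno, smiles)
                continue
            records.append(MoleculeRecord(id=mol_id, mol=mol))
    return records


def _read_sdf(path: Path) -> list[MoleculeRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for index, mol in enumerate(supplier):
        if mol is None:
            logger.warning("SDF record %d unparsable, skipped", index)
            continue
        mol_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not mol_id:
            mol_id = f"mol_{index}"
        props: dict[str, float] = {}
        for key in mol.GetPropNames():
            try:
                value = float(mol.GetProp(key))
            except ValueError:
                continue
            if math.isfinite(value):
                props[key] = value
        records.append(MoleculeRecord(id=mol_id, mol=mol, properties=props))
    return records


def write_library(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records as SMILES (.smi) or SDF V2000 (.sdf) by extension."""
    path = Path(path)
    fmt = _infer_format(path)
    if fmt == "smiles":
        with path.open("w") as handle:
            for rec in records:
                if rec.mol is None:
                    raise ValueError(f"record {rec.id!r} has no structure")
                handle.write(f"{Chem.MolToSmiles(rec.mol)} {rec.id}\n")
    else:
        writer = Chem.SDWriter(str(path))
        writer.SetForceV3000(False)
        for rec in records:
            if rec.mol is None:
                raise ValueError(f"record {rec.id!r} has no structure")
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.id)
            writer.write(mol)
        writer.close()


def read_score_table(path: str | Path, structure_id: str | None = None) -> ScoreTable:
    """Read a ``molecule_id,score`` CSV docking table.

    Duplicate molecule ids keep the most negative (best) score with a
    warning; non-numeric scores reject the row with a warning.  The
    structure id defaults to the file stem.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"score table not found: {path}")
    sid = structure_id or path.stem
    entries: dict[str, float] = {}
    with path.open() as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"empty score table: {path}")
        cols = [c.strip().lower() for c in header]
        if cols[:2] != ["molecule_id", "score"]:
            raise ValueError(f"expected header 'molecule_id,score' in {path}, got {header}")
        for rowno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            mid = row[0].strip()
            try:
                score = float(row[1])
            except (IndexError, ValueError):
                logger.warning("%s row %d: non-numeric score, rejected", path.name, rowno)
                continue
            if not math.isfinite(score):
                logger.warning("%s row %d: non-finite score, rejected", path.name, rowno)
                continue
            if mid in entries:
                logger.warning("%s: duplicate id %r, keeping best score", path.name, mid)
                entries[mid] = min(entries[mid], score)
            else:
                entries[mid] = score
    if not entries:
        raise ValueError(f"no valid rows in score table: {path}")
    return ScoreTable(structure_id=sid, entries=entries)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["molecule_id", "score"])
        for mid, score in table.entries.items():
            writer.writerow([mid, repr(score)])


def load_assayed_hits() -> pd.DataFrame:
    """Bundled assay panel: the reference inhibitor plus the 11 screening hits
    with measured IC50 (uM) and predicted properties."""
    with resources.files("ensemblevs.data").joinpath("assayed_hits.csv").open() as handle:
        return pd.read_csv(handle)


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

# druglike cores with one substitution slot; combined with the groups below
# they span ~200-450 Da, mostly inside the REOS property windows
_CORES = [
    "c1ccc(-c2ccnc3[nH]ccc23)cc1{r}",
    "c1ccc2c(c1)nc(N{r})n2C",
    "c1ccc(S(=O)(=O)N{r})cc1",
    "c1ccc(C(=O)N{r})cc1",
    "c1ccc2[nH]c(C(=O)N{r})cc2c1",
    "c1ccc(-c2nc3ccccc3o2)cc1{r}",
    "c1ccc(-c2nc3ccccc3s2)cc1{r}",
    "c1ccnc(N{r})c1",
    "c1ccc(CN2CCN(C(=O)C{r})CC2)cc1",
    "c1ccc(OCC(=O)N{r})cc1",
    "c1ccc2c(c1)ccc1cc(C(=O)N{r})ccc12",
    "c1cnc2[nH]cc(-c3ccccc3{r})c2c1",
    "c1ccc(-n2cnc3ccccc32)cc1{r}",
    "c1ccc(NC(=O)Nc2ccccc2{r})cc1",
    "c1ccc(C2CCN(C{r})CC2)cc1",
    "c1ccc(-c2csc(N{r})n2)cc1",
    "c1ccc(CCNC(=O)c2ccco2)cc1{r}",
    "c1ccc(N2CCOCC2)c(NC(=O)C{r})c1",
    "c1ccc(-c2noc(C{r})n2)cc1",
    "c1cc2cccnc2c(N{r})c1",
]

_GROUPS = [
    "CC(=O)Nc1ccccc1",
    "Cc1ccc(F)cc1",
    "CCN1CCOCC1",
    "c1ccc(Cl)cc1",
    "CC(C)Cc1ccccc1",
    "CCOC(=O)c1ccccc1",
    "Cc1cccc(C)n1",
    "CCN(CC)CC",
    "c1ccc(OC)cc1",
    "CC1CCCCC1",
    "Cc1ccncc1",
    "CCc1ccc(O)cc1",
    "CC(=O)N1CCCC1",
    "Cc1ccc(S(C)(=O)=O)cc1",
    "CCCOc1ccccc1",
]

_FIXTURE_SMILES: list[str] | None = None


def _fixture_smiles_pool() -> list[str]:
    """Validated combinatorial SMILES pool (cores x substituents), cached."""
    global _FIXTURE_SMILES
    if _FIXTURE_SMILES is None:
        pool = []
        for core in _CORES:
            for group in _GROUPS:
                smiles = core.format(r=group)
                if Chem.MolFromSmiles(smiles) is not None:
                    pool.append(smiles)
        _FIXTURE_SMILES = pool
    return _FIXTURE_SMILES


def _draw_scores(
    rng: np.random.Generator,
    latent: np.ndarray,
    mean: float,
    sd: float,
    rho: float,
) -> np.ndarray:
    noise = rng.standard_normal(latent.shape[0])
    return mean + sd * (math.sqrt(rho) * latent + math.sqrt(1.0 - rho) * noise)


def generate_fixtures(spec: FixtureSpec) -> FixtureBundle:
    """Generate the synthetic screening campaign described by ``spec``.

    Per structure, docking scores are class-conditional Gaussians sharing a
    per-molecule latent factor with the requested equicorrelation; fit
    values are zero with probability ``fit_nonmapper_prob`` for decoys and
    Gaussian (clipped at 0) otherwise.  The last ``n_failing_structures``
    structures get a redock RMSD above 2 A and no class separation, so they
    fail both qualification criteria.  Identical seed, identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n_act, n_dec = spec.n_actives, spec.n_decoys
    n_total = n_act + n_dec

    width_a = len(str(n_act))
    width_d = len(str(n_dec))
    ids = [f"act_{i:0{width_a}d}" for i in range(n_act)] + [
        f"dec_{i:0{width_d}d}" for i in range(n_dec)
    ]
    labels = ["active"] * n_act + ["decoy"] * n_dec

    molecules = []
    if spec.with_structures:
        pool = _fixture_smiles_pool()
        choices = rng.integers(0, len(pool), size=n_total)
        for mid, label, idx in zip(ids, labels, choices):
            molecules.append(
                MoleculeRecord(id=mid, mol=Chem.MolFromSmiles(pool[idx]), label=label)
            )
    else:
        molecules = [MoleculeRecord(id=mid, label=label) for mid, label in zip(ids, labels)]

    is_active = np.array([label == "active" for label in labels])
    latent = rng.standard_normal(n_total)
    rho = spec.cross_structure_correlation

    n_fail = spec.n_failing_structures
    score_tables, fit_tables = [], []
    redock_rmsd: dict[str, float] = {}
    for s in range(spec.n_structures):
        sid = f"struct_{s + 1:02d}"
        failing = s >= spec.n_structures - n_fail
        act_mean = spec.decoy_score_mean if failing else spec.active_score_mean
        scores = _draw_scores(rng, latent, spec.decoy_score_mean, spec.score_sd, rho)
        scores_act = _draw_scores(rng, latent, act_mean, spec.score_sd, rho)
        scores = np.where(is_active, scores_act, scores)
        score_tables.append(
            ScoreTable(sid, dict(zip(ids, (float(v) for v in scores))), score_mode="stand-in")
        )

        act_fit_mean = spec.decoy_fit_mean if failing else spec.active_fit_mean
        fits = np.clip(rng.normal(spec.decoy_fit_mean, spec.fit_sd, n_total), 0.0, None)
        fits_act = np.clip(rng.normal(act_fit_mean, spec.fit_sd, n_total), 0.0, None)
        fits = np.where(is_active, fits_act, fits)
        nonmapper = rng.random(n_total) < spec.fit_nonmapper_prob
        fits = np.where(nonmapper & ~is_active, 0.0, fits)
        fit_tables.append(
            ScoreTable(sid, dict(zip(ids, (float(v) for v in fits))), score_mode="fit")
        )

        if failing:
            redock_rmsd[sid] = float(rng.uniform(2.5, 4.0))
        else:
            redock_rmsd[sid] = float(rng.uniform(0.3, 1.5))

    return FixtureBundle(
        molecules=molecules,
        score_tables=score_tables,
        fit_tables=fit_tables,
        redock_rmsd=redock_rmsd,
    )


def gaussian_channel_auc(delta_mu: float, sd: float) -> float:
    """Closed-form single-channel AUC for equal-variance Gaussian classes."""
    from scipy.stats import norm

    return float(norm.cdf(delta_mu / (sd * math.sqrt(2.0))))
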
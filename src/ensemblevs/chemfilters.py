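"""Drug-likeness filters, fingerprints, similarity, clustering, and scaffold
substructure search for post-processing ranked hits.

The structural-key fingerprint is the public 166-key MACCS definition as
shipped with RDKit; similarities are contract-stable within this toolkit
but not bit-compatible with vendor implementations.  The circular
fingerprint uses radius 3 (diameter 6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

from ensemblevs.chemio import MoleculeRecord

logger = logging.getLogger(__name__)

MACCS_BITS = 166
ECFP6_RADIUS = 3
ECFP6_BITS = 2048

CLUSTER_THRESHOLD = 0.85

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=ECFP6_RADIUS, fpSize=ECFP6_BITS
)


@dataclass
class Fingerprint:
    kind: str  # "maccs" or "ecfp6"
    bits: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("maccs", "ecfp6"):
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        self.bits = np.asarray(self.bits, dtype=bool)
        expected = MACCS_BITS if self.kind == "maccs" else ECFP6_BITS
        if self.bits.shape != (expected,):
            raise ValueError(f"{self.kind} fingerprint must have {expected} bits")

    @property
    def count(self) -> int:
        return int(self.bits.sum())


@dataclass
class FilterVerdict:
    molecule_id: str
    rule_set: str
    passed: bool
    violations: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def fingerprint(record: MoleculeRecord, kind: str = "maccs") -> Fingerprint:
    """Deterministic bit vector: 166 structural keys or 2048-bit circular
    radius-3 fingerprint."""
    if record.mol is None or record.mol.GetNumAtoms() == 0:
        raise ValueError(f"molecule {record.id!r} has no structure")
    if kind == "maccs":
        bv = MACCSkeys.GenMACCSKeys(record.mol)  # 167 bits, bit 0 unused
        bits = np.array([bv.GetBit(i) for i in range(1, 167)], dtype=bool)
    elif kind == "ecfp6":
        bv = _morgan_gen.GetFingerprint(record.mol)
        bits = np.zeros(ECFP6_BITS, dtype=bool)
        bits[list(bv.GetOnBits())] = True
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    return Fingerprint(kind=kind, bits=bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; two empty fingerprints give 0 by convention."""
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind} vs {b.kind}")
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        return 0.0
    return float(np.sum(a.bits & b.bits) / union)


def cluster_by_similarity(
    fps: Sequence[Fingerprint], threshold: float = CLUSTER_THRESHOLD
) -> list[int]:
    """Single-linkage connected components of the graph with edges where
    Tanimoto > threshold (strict); labels numbered by first-seen order."""
    if not fps:
        raise ValueError("need at least one fingerprint")
    n = len(fps)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if tanimoto(fps[i], fps[j]) > threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    labels: list[int] = []
    relabel: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        if root not in relabel:
            relabel[root] = len(relabel)
        labels.append(relabel[root])
    return labels


# ---------------------------------------------------------------------------
# property computation and rule sets
# ---------------------------------------------------------------------------


def compute_properties(record: MoleculeRecord) -> dict[str, float]:
    """2D descriptors needed by the filters (MW, logP, HBD, HBA, rotatable
    bonds, heavy atoms, formal charge)."""
    if record.mol is None:
        raise ValueError(f"molecule {record.id!r} has no structure")
    mol = record.mol
    return {
        "MW": float(Descriptors.MolWt(mol)),
        "logP": float(Crippen.MolLogP(mol)),
        "HBD": float(Lipinski.NumHDonors(mol)),
        "HBA": float(Lipinski.NumHAcceptors(mol)),
        "rotatable_bonds": float(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        "heavy_atoms": float(mol.GetNumHeavyAtoms()),
        "formal_charge": float(Chem.GetFormalCharge(mol)),
    }


_RO5_RULES = (
    ("MW", lambda v: v > 500, "MW > 500"),
    ("logP", lambda v: v > 5, "logP > 5"),
    ("HBD", lambda v: v > 5, "HBD > 5"),
    ("HBA", lambda v: v > 10, "HBA > 10"),
)


def lipinski_ro5(props: dict[str, float], molecule_id: str = "") -> FilterVerdict:
    """Rule-of-Five: pass with at most one violation among the four bounds.

    Rules whose property is absent are skipped and recorded.
    """
    violations, skipped = [], []
    for key, bad, reason in _RO5_RULES:
        if key not in props:
            skipped.append(key)
            continue
        if bad(props[key]):
            violations.append(reason)
    return FilterVerdict(
        molecule_id=molecule_id,
        rule_set="Ro5",
        passed=len(violations) <= 1,
        violations=violations,
        skipped=skipped,
    )


# property windows for the swill filter, plus structural alerts
_REOS_WINDOWS = (
    ("MW", 200.0, 500.0),
    ("logP", -5.0, 5.0),
    ("HBD", 0.0, 5.0),
    ("HBA", 0.0, 10.0),
    ("formal_charge", -2.0, 2.0),
    ("rotatable_bonds", 0.0, 8.0),
    ("heavy_atoms", 20.0, 70.0),
)

REOS_ALERTS = {
    "acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "sulfonyl_halide": "[SX4](=O)(=O)[F,Cl,Br,I]",
    "anhydride": "[CX3](=O)O[CX3](=O)",
    "aldehyde": "[CX3H1](=O)[#6]",
    "three_ring_heteroatom": "[O,N;r3]",
    "michael_acceptor": "[CX3]=[CX3][CX3]=[OX1]",
    "nitro": "[N+](=O)[O-]",
    "azo": "[NX2]=[NX2]",
    "peroxide": "[OX2][OX2]",
    "isocyanate": "[NX2]=[CX2]=[OX1]",
    "thiol": "[SX2H1]",
    "alkyl_halide": "[CH2X4][Cl,Br,I]",
}

_ALERT_PATTERNS = {name: Chem.MolFromSmarts(s) for name, s in REOS_ALERTS.items()}


def reos_filter(
    record: MoleculeRecord, props: dict[str, float] | None = None
) -> FilterVerdict:
    """Property windows plus structural alerts; pass requires zero
    violations.  Missing properties are computed from the structure."""
    if record.mol is None:
        raise ValueError(f"molecule {record.id!r} has no structure")
    computed = compute_properties(record)
    if props:
        computed.update(props)
    violations = []
    for key, lo, hi in _REOS_WINDOWS:
        value = computed[key]
        if not lo <= value <= hi:
            violations.append(f"{key}={value:g} outside [{lo:g}, {hi:g}]")
    for name, patt in _ALERT_PATTERNS.items():
        if record.mol.HasSubstructMatch(patt):
            violations.append(f"alert:{name}")
    return FilterVerdict(
        molecule_id=record.id,
        rule_set="REOS",
        passed=not violations,
        violations=violations,
    )


def substructure_search(
    pattern: str | Chem.Mol,
    library: Sequence[MoleculeRecord],
    is_smarts: bool = True,
) -> list[MoleculeRecord]:
    """Order-preserving subset of the library containing the scaffold
    (aromaticity-aware subgraph isomorphism)."""
    if isinstance(pattern, Chem.Mol):
        query = pattern
    elif is_smarts:
        query = Chem.MolFromSmarts(pattern)
    else:
        query = Chem.MolFromSmiles(pattern)
    if query is None:
        raise ValueError(f"invalid substructure pattern {pattern!r}")
    matches = []
    for rec in library:
        if rec.mol is not None and rec.mol.HasSubstructMatch(query):
            matches.append(rec)
    return matches


def max_similarity_to_known(
    record: MoleculeRecord,
    known: Sequence[MoleculeRecord],
    kind: str = "ecfp6",
) -> float:
    """Maximum pairwise Tanimoto of a molecule against a known-actives set
    (novelty assessment: low values mean a new chemotype)."""
    if not known:
        raise ValueError("known set must be non-empty")
    fp = fingerprint(record, kind)
    return max(tanimoto(fp, fingerprint(rec, kind)) for rec in known)
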
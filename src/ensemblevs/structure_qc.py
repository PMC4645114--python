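"""Receptor-structure qualification.

A candidate structure qualifies when its redocked ligand pose reproduces the
crystallographic pose (RMSD at or below a threshold, default 2.0 A) and its
docking scores separate actives from decoys (one-sided Mann-Whitney p-value
at or below a threshold, default 1e-20).  p-values far below float underflow
are handled on the log10 scale throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

# exact Mann-Whitney enumeration up to this many active x decoy pairs
EXACT_PAIR_LIMIT = 10_000


@dataclass
class StructureQCResult:
    structure_id: str
    redock_rmsd: float
    log10_p: float
    qualified: bool = False

    def __post_init__(self) -> None:
        if self.redock_rmsd < 0:
            raise ValueError("redock_rmsd must be >= 0")
        if self.log10_p > 0:
            raise ValueError("log10_p must be <= 0")

    @property
    def discrimination_p(self) -> float:
        """May underflow to 0.0 for very strong separation; log10_p is exact."""
        return 10.0 ** self.log10_p


def pose_rmsd(
    pose_a: np.ndarray,
    pose_b: np.ndarray,
    atom_map: Sequence[tuple[int, int]] | None = None,
    automorphisms: Sequence[Sequence[int]] | None = None,
) -> float:
    """RMSD between two poses in a common frame — no superposition applied.

    ``atom_map`` pairs indices of ``pose_a`` with indices of ``pose_b``
    (identity by default).  With ``automorphisms`` (index permutations of
    pose_b, e.g. from :func:`ligand_automorphisms`) the minimum RMSD over
    all symmetry-equivalent atom orderings is returned.
    """
    pose_a = np.asarray(pose_a, dtype=float)
    pose_b = np.asarray(pose_b, dtype=float)
    if atom_map is None:
        if pose_a.shape != pose_b.shape:
            raise ValueError(
                f"pose shapes differ: {pose_a.shape} vs {pose_b.shape}"
            )
        idx_a = np.arange(pose_a.shape[0])
        idx_b = idx_a
    else:
        idx_a = np.array([i for i, _ in atom_map])
        idx_b = np.array([j for _, j in atom_map])
        if len(idx_a) == 0:
            raise ValueError("empty atom map")

    a = pose_a[idx_a]
    if automorphisms is None:
        b = pose_b[idx_b]
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    best = math.inf
    for perm in automorphisms:
        b = pose_b[np.asarray(perm)[idx_b]]
        best = min(best, float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))))
    return best


def ligand_automorphisms(mol, max_matches: int = 10_000) -> list[tuple[int, ...]]:
    """Graph automorphisms of a molecule (heavy atoms), via self-matching."""
    from rdkit import Chem

    query = Chem.Mol(mol)
    return list(
        mol.GetSubstructMatches(query, uniquify=False, maxMatches=max_matches)
    )


def _mannwhitney_log10p(actives: np.ndarray, decoys: np.ndarray) -> float:
    """log10 of the one-sided (actives lower) MW p-value, tie-corrected
    normal approximation, computed in log space to survive underflow."""
    n1, n2 = len(actives), len(decoys)
    combined = np.concatenate([actives, decoys])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # number of (active > decoy) pairs, ties 1/2
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    z = (u1 + 0.5 - mu) / math.sqrt(var)  # continuity-corrected, lower tail
    return float(stats.norm.logcdf(z) / math.log(10.0))


def discrimination_power(
    active_scores: Sequence[float],
    decoy_scores: Sequence[float],
    exact_pair_limit: int = EXACT_PAIR_LIMIT,
) -> float:
    """One-sided Mann-Whitney p-value for actives scoring better (more
    negative) than decoys.

    Exact enumeration when n_actives * n_decoys <= ``exact_pair_limit``,
    tie-corrected normal approximation otherwise.  May underflow to 0.0 for
    extreme separation; use :func:`discrimination_log10p` in that regime.
    """
    return 10.0 ** discrimination_log10p(active_scores, decoy_scores, exact_pair_limit)


def discrimination_log10p(
    active_scores: Sequence[float],
    decoy_scores: Sequence[float],
    exact_pair_limit: int = EXACT_PAIR_LIMIT,
) -> float:
    """log10 of :func:`discrimination_power`, robust below float underflow."""
    actives = np.asarray(active_scores, dtype=float)
    decoys = np.asarray(decoy_scores, dtype=float)
    if actives.size == 0 or decoys.size == 0:
        raise ValueError("both score lists must be non-empty")
    if np.all(actives == actives[0]) and np.all(decoys == actives[0]):
        logger.warning("all scores identical across both groups; p = 1")
        return 0.0
    if actives.size * decoys.size <= exact_pair_limit:
        result = stats.mannwhitneyu(actives, decoys, alternative="less", method="exact")
        return float(math.log10(result.pvalue))
    return _mannwhitney_log10p(actives, decoys)


def qualify_structures(
    results: Sequence[StructureQCResult],
    rmsd_threshold: float = 2.0,
    p_threshold: float = 1e-20,
) -> list[StructureQCResult]:
    """Subset of structures passing both criteria, order preserved.

    Sets the ``qualified`` flag on every input result as a side effect.
    """
    if rmsd_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    log10_p_threshold = math.log10(p_threshold)
    qualified = []
    for res in results:
        res.qualified = (
            res.redock_rmsd <= rmsd_threshold and res.log10_p <= log10_p_threshold
        )
        if res.qualified:
            qualified.append(res)
    return qualified
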
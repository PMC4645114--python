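"""Multi-structure feature matrix and the Laplacian-corrected naive Bayes
score fusion.

Each qualified receptor structure contributes one docking-score channel and
one fit-value channel.  Channels are discretized into equal-frequency bins;
a bin with A actives among T molecules gets the log-weight

    W = log[(A + prior * K) / ((T + K) * prior)],    K = 1 / prior

so an empty bin is exactly neutral (W = 0).  A molecule's score is the sum
of bin weights over its non-missing channels.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ensemblevs.chemio import MoleculeRecord, ScoreTable

logger = logging.getLogger(__name__)

DEFAULT_BINS = 10
DEFAULT_DECOY_RATIO = 20


@dataclass
class FeatureMatrix:
    """Molecules x channels with a missing mask and optional 0/1 labels."""

    molecule_ids: list[str]
    channels: list[str]
    values: np.ndarray
    missing: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, c = len(self.molecule_ids), len(self.channels)
        if self.values.shape != (n, c) or self.missing.shape != (n, c):
            raise ValueError("values/missing must be (n_molecules, n_channels)")
        if not np.all(np.isfinite(self.values[~self.missing])):
            raise ValueError("non-missing values must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must be one per molecule")
            if not set(np.unique(self.labels)) <= {0, 1}:
                raise ValueError("labels must be 0/1")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    def subset_channels(self, channels: Sequence[str]) -> "FeatureMatrix":
        idx = [self.channels.index(c) for c in channels]
        return FeatureMatrix(
            molecule_ids=list(self.molecule_ids),
            channels=list(channels),
            values=self.values[:, idx].copy(),
            missing=self.missing[:, idx].copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )


@dataclass
class BinningScheme:
    """Per-channel strictly increasing interior edges; open outer bins.

    A value v falls into bin ``searchsorted(edges, v, side='left')``, i.e.
    bins are (-inf, e1], (e1, e2], ..., (e_{B-1}, +inf).
    """

    edges: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for channel, e in self.edges.items():
            e = np.asarray(e, dtype=float)
            if e.size and not np.all(np.diff(e) > 0):
                raise ValueError(f"edges for {channel!r} must be strictly increasing")
            self.edges[channel] = e

    def n_bins(self, channel: str) -> int:
        return len(self.edges[channel]) + 1

    def bin_index(self, channel: str, values: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.edges[channel], np.asarray(values), side="left")


@dataclass
class BayesModel:
    """Binning scheme plus per-channel-per-bin log-weights and class prior."""

    prior: float
    binning: BinningScheme
    weights: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must be in (0, 1)")
        for channel, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if not np.all(np.isfinite(w)):
                raise ValueError(f"non-finite weight in channel {channel!r}")
            if len(w) != self.binning.n_bins(channel):
                raise ValueError(f"weight/bin count mismatch in {channel!r}")
            self.weights[channel] = w

    @property
    def smoothing_k(self) -> float:
        return 1.0 / self.prior

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "prior": self.prior,
            "edges": {c: [float(x) for x in e] for c, e in self.binning.edges.items()},
            "weights": {c: [float(x) for x in w] for c, w in self.weights.items()},
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BayesModel":
        text = str(source)
        try:
            if Path(text).is_file():
                text = Path(text).read_text()
        except OSError:
            pass  # raw JSON text, not a path
        doc = json.loads(text)
        return cls(
            prior=doc["prior"],
            binning=BinningScheme(
                {c: np.array(e, dtype=float) for c, e in doc["edges"].items()}
            ),
            weights={c: np.array(w, dtype=float) for c, w in doc["weights"].items()},
        )


@dataclass
class ScreeningHit:
    """A ranked library entry; filter/cluster annotations are added by the
    post-processing stages."""

    molecule_id: str
    score: float
    rank: int
    passed_filters: bool | None = None
    filter_violations: list[str] = field(default_factory=list)
    cluster: int | None = None
    representative: bool | None = None


# ---------------------------------------------------------------------------
# training-set assembly
# ---------------------------------------------------------------------------


def _packed_fingerprints(records: Sequence[MoleculeRecord]) -> np.ndarray:
    from ensemblevs.chemfilters import fingerprint

    fps = [fingerprint(rec, kind="maccs").bits for rec in records]
    return np.array(fps, dtype=bool)


def _bulk_tanimoto(fp: np.ndarray, fps: np.ndarray) -> np.ndarray:
    inter = (fps & fp).sum(axis=1)
    union = (fps | fp).sum(axis=1)
    return np.where(union > 0, inter / np.maximum(union, 1), 0.0)


def build_training_set(
    actives: Sequence[MoleculeRecord],
    decoy_pool: Sequence[MoleculeRecord],
    ratio: int = DEFAULT_DECOY_RATIO,
    seed: int = 0,
) -> list[MoleculeRecord]:
    """All actives plus ``ratio * len(actives)`` decoys picked from the pool
    by greedy max-min MACCS-fingerprint diversity (deterministic per seed).

    When the pool holds exactly the required number, every decoy is taken.
    """
    n_needed = ratio * len(actives)
    if len(decoy_pool) < n_needed:
        raise ValueError(
            f"decoy pool too small: need {n_needed}, have {len(decoy_pool)}"
        )
    labeled_actives = [
        MoleculeRecord(r.id, r.mol, dict(r.properties), "active") for r in actives
    ]
    if len(decoy_pool) == n_needed:
        selected = list(decoy_pool)
    else:
        fps = _packed_fingerprints(decoy_pool)
        rng = np.random.default_rng(seed)
        first = int(rng.integers(0, len(decoy_pool)))
        chosen = [first]
        max_sim = _bulk_tanimoto(fps[first], fps)
        max_sim[first] = np.inf
        while len(chosen) < n_needed:
            nxt = int(np.argmin(max_sim))  # ties: lowest index, deterministic
            chosen.append(nxt)
            sims = _bulk_tanimoto(fps[nxt], fps)
            np.maximum(max_sim, sims, out=max_sim)
            max_sim[nxt] = np.inf
        selected = [decoy_pool[i] for i in sorted(chosen)]
    labeled_decoys = [
        MoleculeRecord(r.id, r.mol, dict(r.properties), "decoy") for r in selected
    ]
    return labeled_actives + labeled_decoys


# ---------------------------------------------------------------------------
# matrix assembly and binning
# ---------------------------------------------------------------------------


def assemble_features(
    molecules: Sequence[MoleculeRecord],
    score_tables: Sequence[ScoreTable],
    fit_tables: Sequence[ScoreTable] = (),
    labeled: bool = True,
) -> FeatureMatrix:
    """One docking channel (``dock:<sid>``) per score table and one fit
    channel (``fit:<sid>``) per fit table.

    A molecule absent from a docking table is masked missing (failed run);
    absence from a fit table is a real 0.0 observation (non-mapper).
    """
    ids = [m.id for m in molecules]
    channels, columns, masks = [], [], []
    for table in score_tables:
        channels.append(f"dock:{table.structure_id}")
        col = np.array([table.entries.get(i, np.nan) for i in ids])
        masks.append(np.isnan(col))
        columns.append(np.nan_to_num(col))
    for table in fit_tables:
        channels.append(f"fit:{table.structure_id}")
        columns.append(np.array([table.entries.get(i, 0.0) for i in ids]))
        masks.append(np.zeros(len(ids), dtype=bool))
    labels = None
    if labeled and all(m.label != "unknown" for m in molecules):
        labels = np.array([1 if m.label == "active" else 0 for m in molecules])
    return FeatureMatrix(
        molecule_ids=ids,
        channels=channels,
        values=np.column_stack(columns),
        missing=np.column_stack(masks),
        labels=labels,
    )


def fit_bins(matrix: FeatureMatrix, n_bins: int = DEFAULT_BINS) -> BinningScheme:
    """Equal-frequency interior edges per channel from the training values.

    Edge rule: with n sorted non-missing values, interior edge k (k=1..B-1)
    is the midpoint between v[ceil(k*n/B)-1] and v[ceil(k*n/B)]; duplicate
    edges from ties are dropped (fewer bins, with a warning).  Missing
    values never influence the edges; a constant channel gets one bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges: dict[str, np.ndarray] = {}
    for ci, channel in enumerate(matrix.channels):
        col = matrix.values[:, ci][~matrix.missing[:, ci]]
        if col.size == 0:
            logger.warning("channel %r is all-missing; dropped from binning", channel)
            continue
        v = np.sort(col)
        n = v.size
        n_distinct = np.unique(v).size
        b = min(n_bins, n_distinct)
        if b < n_bins:
            logger.warning(
                "channel %r has %d distinct values; using %d bins", channel, n_distinct, b
            )
        cut: list[float] = []
        for k in range(1, b):
            pos = math.ceil(k * n / b)
            if pos >= n:
                continue
            edge = 0.5 * (v[pos - 1] + v[pos])
            if v[pos - 1] == v[pos]:
                continue  # tie straddles the cut; merge into one bin
            cut.append(float(edge))
        e = np.unique(np.array(cut))
        if e.size < b - 1:
            logger.warning(
                "channel %r: ties reduced %d bins to %d", channel, b, e.size + 1
            )
        edges[channel] = e
    if not edges:
        raise ValueError("no channel with usable values")
    return BinningScheme(edges)


# ---------------------------------------------------------------------------
# training and scoring
# ---------------------------------------------------------------------------


def train_nbc(matrix: FeatureMatrix, bins: BinningScheme) -> BayesModel:
    """Laplacian-corrected naive Bayes weights from a labeled matrix."""
    if matrix.labels is None:
        raise ValueError("training matrix must carry labels")
    labels = matrix.labels
    n_active = int(labels.sum())
    n_total = labels.size
    if n_active == 0 or n_active == n_total:
        raise ValueError("training set must contain both classes")
    prior = n_active / n_total
    k = 1.0 / prior
    weights: dict[str, np.ndarray] = {}
    for ci, channel in enumerate(matrix.channels):
        if channel not in bins.edges:
            continue
        n_b = bins.n_bins(channel)
        present = ~matrix.missing[:, ci]
        idx = bins.bin_index(channel, matrix.values[present, ci])
        total = np.bincount(idx, minlength=n_b).astype(float)
        active = np.bincount(idx, weights=labels[present].astype(float), minlength=n_b)
        weights[channel] = np.log((active + prior * k) / ((total + k) * prior))
    return BayesModel(prior=prior, binning=bins, weights=weights)


def score_nbc(
    model: BayesModel,
    row: dict[str, float] | Sequence[float],
    channels: Sequence[str] | None = None,
) -> float:
    """Score one molecule: sum of bin log-weights over non-missing channels.

    ``row`` is either {channel: value} (absent/NaN channels contribute 0)
    or a value sequence aligned with ``channels``.
    """
    if isinstance(row, dict):
        items = row.items()
    else:
        if channels is None:
            raise ValueError("channels must accompany a value sequence")
        items = zip(channels, row)
    score = 0.0
    for channel, value in items:
        if channel not in model.weights:
            raise KeyError(f"unknown channel {channel!r}")
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        b = int(model.binning.bin_index(channel, np.array([value]))[0])
        score += float(model.weights[channel][b])
    return score


def score_matrix(model: BayesModel, matrix: FeatureMatrix) -> np.ndarray:
    """Vectorized :func:`score_nbc` over a feature matrix."""
    scores = np.zeros(matrix.n_molecules)
    for ci, channel in enumerate(matrix.channels):
        if channel not in model.weights:
            raise KeyError(f"unknown channel {channel!r}")
        present = ~matrix.missing[:, ci]
        idx = model.binning.bin_index(channel, matrix.values[present, ci])
        scores[present] += model.weights[channel][idx]
    return scores


def rank_library(
    model: BayesModel, matrix: FeatureMatrix, top_n: int
) -> list[ScreeningHit]:
    """Top-``top_n`` molecules by descending Bayes score, ties broken by
    lexicographic molecule id (stable and documented)."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    scores = score_matrix(model, matrix)
    order = sorted(
        range(matrix.n_molecules), key=lambda i: (-scores[i], matrix.molecule_ids[i])
    )
    return [
        ScreeningHit(molecule_id=matrix.molecule_ids[i], score=float(scores[i]), rank=r)
        for r, i in enumerate(order[:top_n], start=1)
    ]
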
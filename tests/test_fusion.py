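import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensemblevs.chemio import FixtureSpec, MoleculeRecord, ScoreTable, generate_fixtures
from ensemblevs.fusion import (
    BayesModel,
    BinningScheme,
    FeatureMatrix,
    assemble_features,
    build_training_set,
    fit_bins,
    rank_library,
    score_matrix,
    score_nbc,
    train_nbc,
)
from ensemblevs.screen_eval import roc_auc
from tests.conftest import make_record


def simple_matrix(values, labels=None, channels=None, missing=None):
    values = np.asarray(values, dtype=float)
    n, c = values.shape
    return FeatureMatrix(
        molecule_ids=[f"m{i:03d}" for i in range(n)],
        channels=channels or [f"ch{j}" for j in range(c)],
        values=values,
        missing=np.zeros((n, c), bool) if missing is None else np.asarray(missing, bool),
        labels=labels if labels is None else np.asarray(labels, int),
    )


class TestBuildTrainingSet:
    def _pool(self, n, seed=0):
        smiles = ["CCO", "CCN", "CCC", "c1ccccc1", "c1ccncc1", "CC(=O)N",
                  "CCOC", "CCS", "CC(C)C", "C1CCCCC1"]
        rng = np.random.default_rng(seed)
        return [
            make_record(f"d{i:04d}", smiles[int(rng.integers(0, len(smiles)))])
            for i in range(n)
        ]

    def test_exact_pool_selects_all(self):
        actives = self._pool(5)
        for rec in actives:
            rec.label = "active"
        training = build_training_set(actives, self._pool(100, seed=1), ratio=20)
        decoys = [m for m in training if m.label == "decoy"]
        assert len(decoys) == 100
        assert len([m for m in training if m.label == "active"]) == 5

    def test_oversized_pool_diversity_picks(self):
        actives = self._pool(2)
        training = build_training_set(actives, self._pool(60, seed=2), ratio=20, seed=3)
        assert sum(1 for m in training if m.label == "decoy") == 40

    def test_deterministic_per_seed(self):
        actives, pool = self._pool(2), self._pool(60, seed=2)
        one = build_training_set(actives, pool, ratio=20, seed=5)
        two = build_training_set(actives, pool, ratio=20, seed=5)
        assert [m.id for m in one] == [m.id for m in two]

    def test_pool_too_small_names_requirement(self):
        with pytest.raises(ValueError, match="100"):
            build_training_set(self._pool(5), self._pool(10, seed=4), ratio=20)


class TestFitBins:
    def test_equal_frequency_1_to_100(self):
        matrix = simple_matrix(np.arange(1, 101).reshape(-1, 1))
        scheme = fit_bins(matrix, 10)
        idx = scheme.bin_index("ch0", matrix.values[:, 0])
        counts = np.bincount(idx, minlength=10)
        assert list(counts) == [10] * 10

    def test_documented_tie_rule_1_to_10_four_bins(self):
        matrix = simple_matrix(np.arange(1, 11).reshape(-1, 1))
        scheme = fit_bins(matrix, 4)
        idx = scheme.bin_index("ch0", matrix.values[:, 0])
        occupancies = list(np.bincount(idx, minlength=4))
        assert occupancies in ([3, 2, 3, 2], [3, 3, 2, 2])

    def test_constant_channel_single_bin(self, caplog):
        matrix = simple_matrix(np.full((20, 1), 3.14))
        with caplog.at_level("WARNING"):
            scheme = fit_bins(matrix, 10)
        assert scheme.n_bins("ch0") == 1

    def test_missing_excluded_from_edges(self):
        values = np.arange(1, 21, dtype=float).reshape(-1, 1)
        missing = np.zeros((20, 1), bool)
        missing[10:] = True  # only 1..10 are observed
        values[10:] = 1e9
        matrix = simple_matrix(values, missing=missing)
        scheme = fit_bins(matrix, 2)
        assert scheme.edges["ch0"][0] == 5.5

    def test_all_missing_channel_dropped(self, caplog):
        values = np.column_stack([np.arange(10.0), np.zeros(10)])
        missing = np.column_stack([np.zeros(10, bool), np.ones(10, bool)])
        matrix = simple_matrix(values, missing=missing)
        with caplog.at_level("WARNING"):
            scheme = fit_bins(matrix, 3)
        assert "ch1" not in scheme.edges
        assert "ch0" in scheme.edges


class TestTrainNbc:
    def test_hand_computed_weight(self):
        # 3 actives in 30 molecules: prior 0.1, K 10.  One bin holds 2
        # molecules, both active: W = log((2+1)/((2+10)*0.1)) = log 2.5
        values = np.linspace(0, 1, 30).reshape(-1, 1)
        labels = np.zeros(30, int)
        labels[[28, 29]] = 1
        labels[0] = 1
        matrix = simple_matrix(values, labels=labels)
        bins = BinningScheme({"ch0": np.array([0.5, 0.94])})  # last bin = top 2
        model = train_nbc(matrix, bins)
        assert math.isclose(model.prior, 0.1)
        assert math.isclose(model.smoothing_k, 10.0)
        assert math.isclose(model.weights["ch0"][2], math.log(2.5), rel_tol=1e-12)

    def test_empty_bin_weight_zero(self):
        values = np.array([[0.0]] * 5 + [[10.0]] * 5)
        labels = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        matrix = simple_matrix(values, labels=labels)
        bins = BinningScheme({"ch0": np.array([2.0, 5.0])})  # middle bin empty
        model = train_nbc(matrix, bins)
        assert model.weights["ch0"][1] == 0.0

    def test_prior_consistent_bin_weight_vanishes(self):
        # A/T == prior in a large bin => W -> 0
        n = 20000
        labels = np.array([1] * (n // 10) + [0] * (n - n // 10))
        values = np.zeros((n, 1))
        matrix = simple_matrix(values, labels=labels)
        bins = BinningScheme({"ch0": np.array([])})
        model = train_nbc(matrix, bins)
        assert abs(model.weights["ch0"][0]) < 1e-3

    def test_single_class_fatal(self):
        matrix = simple_matrix(np.zeros((5, 1)), labels=[1] * 5)
        with pytest.raises(ValueError):
            train_nbc(matrix, BinningScheme({"ch0": np.array([])}))


def brute_force_nbc_scores(values, labels, edges_per_channel):
    """Independent pure-python oracle: bin counts -> Laplacian log-ratio."""
    n, n_channels = len(values), len(values[0])
    n_active = sum(labels)
    prior = n_active / n
    k = 1.0 / prior

    def bin_of(channel, v):
        edges = edges_per_channel[channel]
        b = 0
        for e in edges:
            if v > e:
                b += 1
        return b

    weights = []
    for c in range(n_channels):
        n_bins = len(edges_per_channel[c]) + 1
        w = []
        for b in range(n_bins):
            total = sum(1 for i in range(n) if bin_of(c, values[i][c]) == b)
            active = sum(
                1 for i in range(n) if labels[i] == 1 and bin_of(c, values[i][c]) == b
            )
            w.append(math.log((active + prior * k) / ((total + k) * prior)))
        weights.append(w)

    return [
        sum(weights[c][bin_of(c, values[i][c])] for c in range(n_channels))
        for i in range(n)
    ]


class TestScoreNbc:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_enumerable_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 31))
        n_channels = int(rng.integers(1, 5))
        values = rng.normal(size=(n, n_channels)).round(3)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        edges = {
            f"ch{c}": np.sort(rng.choice(values[:, c], size=int(rng.integers(1, 3)),
                                         replace=False))
            for c in range(n_channels)
        }
        edges = {k: np.unique(v) for k, v in edges.items()}
        matrix = simple_matrix(values, labels=labels)
        model = train_nbc(matrix, BinningScheme(edges))
        ours = score_matrix(model, matrix)
        oracle = brute_force_nbc_scores(
            values.tolist(), labels.tolist(),
            [edges[f"ch{c}"].tolist() for c in range(n_channels)],
        )
        assert np.allclose(ours, oracle, atol=1e-12)

    def test_all_channels_missing_scores_zero(self):
        matrix = simple_matrix(np.zeros((4, 2)), labels=[1, 0, 0, 1])
        model = train_nbc(matrix, BinningScheme({"ch0": np.array([]), "ch1": np.array([])}))
        assert score_nbc(model, {"ch0": float("nan"), "ch1": None}) == 0.0

    def test_single_channel_single_bin_weight(self):
        values = np.linspace(0, 1, 30).reshape(-1, 1)
        labels = np.zeros(30, int)
        labels[[0, 28, 29]] = 1
        matrix = simple_matrix(values, labels=labels)
        model = train_nbc(matrix, BinningScheme({"ch0": np.array([0.5, 0.94])}))
        assert math.isclose(
            score_nbc(model, {"ch0": 0.99}), math.log(2.5), rel_tol=1e-12
        )

    def test_additivity_over_channels(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(20, 2))
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        matrix = simple_matrix(values, labels=labels)
        model = train_nbc(
            matrix, BinningScheme({"ch0": np.array([0.0]), "ch1": np.array([0.3])})
        )
        row = {"ch0": 0.7, "ch1": -0.2}
        total = score_nbc(model, row)
        # single-channel scores via NaN-masking the other channel
        s0 = score_nbc(model, {"ch0": 0.7, "ch1": float("nan")})
        s1 = score_nbc(model, {"ch0": float("nan"), "ch1": -0.2})
        assert math.isclose(total, s0 + s1, rel_tol=1e-12)

    def test_unknown_channel_fatal(self):
        matrix = simple_matrix(np.zeros((4, 1)), labels=[1, 0, 0, 1])
        model = train_nbc(matrix, BinningScheme({"ch0": np.array([])}))
        with pytest.raises(KeyError):
            score_nbc(model, {"mystery": 1.0})

    def test_training_separation_shows_in_scores(self):
        rng = np.random.default_rng(2)
        n = 200
        labels = np.array([1] * 50 + [0] * 150)
        values = np.where(labels == 1, rng.normal(2, 1, n), rng.normal(0, 1, n))
        matrix = simple_matrix(values.reshape(-1, 1), labels=labels)
        model = train_nbc(matrix, fit_bins(matrix, 5))
        scores = score_matrix(model, matrix)
        assert scores[labels == 1].mean() > scores[labels == 0].mean()


class TestRankLibrary:
    def _model_and_matrix(self, n):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(n, 1))
        labels = (values[:, 0] > 0).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        matrix = simple_matrix(values, labels=labels)
        model = train_nbc(matrix, fit_bins(matrix, 4))
        return model, matrix

    def test_top_n_truncation_and_order(self):
        model, matrix = self._model_and_matrix(50)
        hits = rank_library(model, matrix, top_n=10)
        assert len(hits) == 10
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)
        assert [h.rank for h in hits] == list(range(1, 11))

    def test_top_n_larger_than_library(self):
        model, matrix = self._model_and_matrix(10)
        assert len(rank_library(model, matrix, top_n=99)) == 10

    def test_ties_broken_by_id(self):
        matrix = simple_matrix(np.zeros((6, 1)), labels=[1, 0, 1, 0, 1, 0])
        model = train_nbc(matrix, BinningScheme({"ch0": np.array([])}))
        hits = rank_library(model, matrix, top_n=6)
        assert [h.molecule_id for h in hits] == sorted(matrix.molecule_ids)

    def test_row_permutation_invariance(self):
        model, matrix = self._model_and_matrix(30)
        hits = rank_library(model, matrix, top_n=30)
        perm = np.random.default_rng(1).permutation(30)
        shuffled = FeatureMatrix(
            molecule_ids=[matrix.molecule_ids[i] for i in perm],
            channels=matrix.channels,
            values=matrix.values[perm],
            missing=matrix.missing[perm],
        )
        hits2 = rank_library(model, shuffled, top_n=30)
        assert [(h.molecule_id, h.score) for h in hits] == [
            (h.molecule_id, h.score) for h in hits2
        ]


class TestAssembleFeatures:
    def test_channel_layout_and_missing_semantics(self):
        molecules = [
            MoleculeRecord("a", label="active"),
            MoleculeRecord("b", label="decoy"),
        ]
        dock = ScoreTable("s1", {"a": -9.0})  # b failed docking -> missing
        fit = ScoreTable("s1", {"a": 2.5}, score_mode="fit")  # b non-mapper -> 0.0
        matrix = assemble_features(molecules, [dock], [fit])
        assert matrix.channels == ["dock:s1", "fit:s1"]
        assert matrix.missing[1, 0]  # docking miss is masked
        assert not matrix.missing[1, 1]
        assert matrix.values[1, 1] == 0.0
        assert list(matrix.labels) == [1, 0]

    def test_channel_count_two_per_structure(self, small_fixture_bundle):
        b = small_fixture_bundle
        matrix = assemble_features(b.molecules, b.score_tables, b.fit_tables)
        assert len(matrix.channels) == 2 * len(b.score_tables)


class TestFusedAucProperty:
    def test_fused_auc_at_least_best_single_channel(self):
        # averaged over 10 seeds, fused NBC AUC >= best single channel - 0.01
        fused, best_single = [], []
        for seed in range(10):
            spec = FixtureSpec(
                n_actives=100, decoy_ratio=10, n_structures=4,
                cross_structure_correlation=0.3, seed=seed,
            )
            bundle = generate_fixtures(spec)
            matrix = assemble_features(bundle.molecules, bundle.score_tables,
                                       bundle.fit_tables)
            dock_mask = [c.startswith("dock:") for c in matrix.channels]
            matrix.values[:, dock_mask] *= -1.0
            model = train_nbc(matrix, fit_bins(matrix, 10))
            scores = score_matrix(model, matrix)
            fused.append(roc_auc(scores, matrix.labels))
            singles = [
                roc_auc(matrix.values[~matrix.missing[:, c], c],
                        matrix.labels[~matrix.missing[:, c]])
                for c in range(len(matrix.channels))
            ]
            best_single.append(max(singles))
        assert np.mean(fused) >= np.mean(best_single) - 0.01


class TestBayesModelSerialization:
    def test_json_round_trip(self):
        matrix = simple_matrix(
            np.random.default_rng(0).normal(size=(40, 2)),
            labels=[1] * 10 + [0] * 30,
        )
        model = train_nbc(matrix, fit_bins(matrix, 5))
        back = BayesModel.from_json(model.to_json())
        assert math.isclose(back.prior, model.prior)
        for channel in model.weights:
            assert np.allclose(back.weights[channel], model.weights[channel])
            assert np.allclose(back.binning.edges[channel], model.binning.edges[channel])
        row = {"ch0": 0.2, "ch1": -1.0}
        assert math.isclose(score_nbc(back, row), score_nbc(model, row), rel_tol=1e-12)
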
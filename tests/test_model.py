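import numpy as np
import pytest

from plantdbp.datasets import DNA_BP, NON_DNA_BP, LabeledDataset
from plantdbp.features import composition_matrix
from plantdbp.model import (
    GridSearchConfig,
    TrainedModel,
    grid_search_train,
    load_model,
    predict,
    save_model,
)
from plantdbp.sequences import CANONICAL_RESIDUES

from conftest import random_protein


@pytest.fixture(scope="module")
def trained(separable_dataset_module):
    dataset = separable_dataset_module
    model, report = grid_search_train(dataset, GridSearchConfig.small(seed=3))
    return dataset, model, report


@pytest.fixture(scope="module")
def separable_dataset_module():
    from plantdbp.simulate import SyntheticSpec, generate

    spec = SyntheticSpec(n_pos=100, n_neg=100, effect_delta=0.12, seed=3)
    dataset, _ = generate(spec)
    return dataset


def nearest_centroid_accuracy(dataset: LabeledDataset) -> float:
    """Separability oracle independent of the SVM."""
    X = composition_matrix(dataset.records).to_numpy()
    y = np.array([1 if l == DNA_BP else 0 for l in dataset.labels])
    c1, c0 = X[y == 1].mean(axis=0), X[y == 0].mean(axis=0)
    pred = (np.linalg.norm(X - c1, axis=1) < np.linalg.norm(X - c0, axis=1)).astype(int)
    return float((pred == y).mean())


class TestGridSearchTrain:
    def test_separable_data_reaches_high_inner_cv_accuracy(self, trained):
        dataset, model, report = trained
        assert nearest_centroid_accuracy(dataset) >= 0.95  # oracle: classes separable
        assert report["cv_accuracy"].max() >= 0.95
        assert model.cost in report["cost"].values
        assert model.gamma in report["gamma"].values

    def test_selected_pair_maximises_grid_metric(self, trained):
        _, model, report = trained
        best = report["cv_accuracy"].max()
        row = report[(report["cost"] == model.cost) & (report["gamma"] == model.gamma)]
        assert row["cv_accuracy"].iloc[0] == best

    def test_tie_break_prefers_smaller_cost_then_gamma(self, trained):
        _, model, report = trained
        best = report["cv_accuracy"].max()
        winners = report[report["cv_accuracy"] == best].sort_values(["cost", "gamma"])
        assert model.cost == winners["cost"].iloc[0]
        assert model.gamma == winners["gamma"].iloc[0]

    def test_single_class_dataset_rejected(self, rng):
        records = [random_protein(rng, 50, "p", i) for i in range(10)]
        dataset = LabeledDataset([(r, DNA_BP) for r in records])
        with pytest.raises(ValueError, match="both classes"):
            grid_search_train(dataset, GridSearchConfig.small())

    def test_deterministic_selection(self, separable_dataset_module):
        cfg = GridSearchConfig.small(seed=3)
        m1, _ = grid_search_train(separable_dataset_module, cfg)
        m2, _ = grid_search_train(separable_dataset_module, cfg)
        assert (m1.cost, m1.gamma) == (m2.cost, m2.gamma)


class TestPredict:
    def test_probability_score_definitional_bounds(self, trained, rng):
        _, model, _ = trained
        records = [random_protein(rng, 80, "q", i) for i in range(30)]
        preds = predict(model, records)
        assert [p.protein_id for p in preds] == [r.id for r in records]
        for p in preds:
            assert 0.5 <= p.probability_score <= 1.0
            assert p.probability_score == pytest.approx(max(p.p_dna_bp, 1 - p.p_dna_bp))
            expected_label = DNA_BP if p.p_dna_bp >= 0.5 else NON_DNA_BP
            assert p.predicted_label == expected_label

    def test_positive_centroid_predicted_confidently(self, trained):
        dataset, model, _ = trained
        pos_records = [r for r, l in dataset.entries if l == DNA_BP]
        preds = predict(model, pos_records)
        mean_p = np.mean([p.p_dna_bp for p in preds])
        assert mean_p > 0.9

    def test_empty_input(self, trained):
        _, model, _ = trained
        assert predict(model, []) == []


class TestPersistence:
    def test_round_trip_preserves_predictions(self, trained, tmp_path, rng):
        _, model, _ = trained
        records = [random_protein(rng, 80, "z", i) for i in range(50)]
        path = tmp_path / "model.pkl"
        save_model(model, path)
        reloaded = load_model(path)
        assert predict(reloaded, records) == predict(model, records)
        assert (reloaded.cost, reloaded.gamma) == (model.cost, model.gamma)

    def test_permuted_feature_order_rejected(self, trained, tmp_path):
        import pickle

        _, model, _ = trained
        path = tmp_path / "model.pkl"
        save_model(model, path)
        payload = pickle.loads(path.read_bytes())
        payload["feature_order"] = payload["feature_order"][::-1]
        path.write_bytes(pickle.dumps(payload))
        with pytest.raises(ValueError, match="feature order"):
            load_model(path)

    def test_truncated_file_rejected(self, trained, tmp_path):
        _, model, _ = trained
        path = tmp_path / "model.pkl"
        save_model(model, path)
        path.write_bytes(path.read_bytes()[: path.stat().st_size // 2])
        with pytest.raises(ValueError, match="truncated|corrupt|not a plantdbp"):
            load_model(path)

    def test_foreign_pickle_rejected(self, tmp_path):
        import pickle

        path = tmp_path / "other.pkl"
        path.write_bytes(pickle.dumps({"hello": "world"}))
        with pytest.raises(ValueError, match="not a plantdbp model"):
            load_model(path)


def test_label_swap_antisymmetry(rng):
    """Swapping training labels flips the posterior within calibration noise."""
    from plantdbp.simulate import SyntheticSpec, generate

    dataset, _ = generate(SyntheticSpec(n_pos=60, n_neg=60, effect_delta=0.12, seed=9))
    swapped = LabeledDataset(
        [(r, NON_DNA_BP if l == DNA_BP else DNA_BP) for r, l in dataset.entries],
        provenance="swapped",
    )
    cfg = GridSearchConfig.small(seed=9)
    m1, _ = grid_search_train(dataset, cfg)
    m2, _ = grid_search_train(swapped, cfg)
    held_out, _ = generate(SyntheticSpec(n_pos=25, n_neg=25, effect_delta=0.12, seed=10))
    p1 = np.array([p.p_dna_bp for p in predict(m1, held_out.records)])
    p2 = np.array([p.p_dna_bp for p in predict(m2, held_out.records)])
    assert np.abs(p1 - (1 - p2)).mean() <= 0.05


def test_grid_config_validation():
    with pytest.raises(ValueError):
        GridSearchConfig(cost_grid=(), gamma_grid=(1.0,))
    with pytest.raises(ValueError):
        GridSearchConfig(inner_folds=1)
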
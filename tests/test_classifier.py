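import itertools

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st
from sklearn.model_selection import cross_val_score
from sklearn.svm import SVC

from dsite import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    Dataset,
    EnsembleModel,
    RnaWindow,
    SvmConfig,
    grid_search_svm,
    load_model,
    majority_vote,
    predict_ensemble,
    predict_probability,
    save_model,
    train_base,
    train_ensemble,
)
from dsite.classifier import ClassifierError
from dsite.io import NEGATIVE, POSITIVE


@pytest.fixture(scope="module")
def toy_features():
    """Linearly separable toy matrix: class mean +/- 2 in 5 dims."""
    rng = np.random.default_rng(11)
    X = np.vstack(
        [rng.normal(2, 0.5, size=(20, 5)), rng.normal(-2, 0.5, size=(20, 5))]
    )
    y = np.array([1] * 20 + [0] * 20)
    return X, y


class TestGridSearch:
    def test_default_grid_shapes(self):
        assert len(DEFAULT_C_GRID) == 11
        assert len(DEFAULT_GAMMA_GRID) == 11
        assert DEFAULT_C_GRID[0] == 2.0**-5 and DEFAULT_C_GRID[-1] == 2.0**15
        assert DEFAULT_GAMMA_GRID[0] == 2.0**-15 and DEFAULT_GAMMA_GRID[-1] == 2.0**-5

    def test_selected_config_in_grid_and_separates(self, toy_features):
        X, y = toy_features
        cfg = grid_search_svm(X, y, seed=0)
        assert cfg.C in DEFAULT_C_GRID and cfg.gamma in DEFAULT_GAMMA_GRID
        acc = cross_val_score(SVC(C=cfg.C, gamma=cfg.gamma), X, y, cv=5).mean()
        assert acc > 0.9

    def test_row_order_invariance(self, toy_features):
        X, y = toy_features
        rng = np.random.default_rng(12)
        perm = rng.permutation(len(y))
        assert grid_search_svm(X, y, seed=0) == grid_search_svm(
            X[perm], y[perm], seed=0
        )

    def test_single_class_rejected(self, toy_features):
        X, _ = toy_features
        with pytest.raises(ClassifierError, match="both classes"):
            grid_search_svm(X, np.ones(len(X)), seed=0)


@pytest.fixture(scope="module")
def trained(separable_dataset, ctx):
    cfg = SvmConfig(C=2.0, gamma=2.0**-7)
    return {
        kind: train_base(separable_dataset, kind, ctx, cfg, seed=0)
        for kind in ("NPCP", "PseDNC", "SSC")
    }


class TestTrainBase:
    def test_determinism(self, separable_dataset, ctx, random_windows, trained):
        again = train_base(
            separable_dataset, "NPCP", ctx, SvmConfig(C=2.0, gamma=2.0**-7), seed=0
        )
        probe = random_windows[:5]
        for w in probe:
            assert predict_probability(again, w) == predict_probability(
                trained["NPCP"], w
            )
        assert again.training_fingerprint == trained["NPCP"].training_fingerprint

    def test_training_accuracy_on_separable_data(self, separable_dataset, trained):
        correct = 0
        for w in separable_dataset:
            p = predict_probability(trained["NPCP"], w)
            correct += (p > 0.5) == (w.label == POSITIVE)
        assert correct / len(separable_dataset) > 0.9

    def test_single_class_rejected(self, separable_dataset, ctx):
        ds = Dataset([w for w in separable_dataset if w.label == POSITIVE])
        with pytest.raises(ClassifierError):
            train_base(ds, "NPCP", ctx, SvmConfig(C=1.0, gamma=0.01), seed=0)

    def test_unlabeled_rejected(self, random_windows, ctx):
        ds = Dataset(random_windows[:6])
        with pytest.raises(ClassifierError, match="unlabeled"):
            train_base(ds, "NPCP", ctx, SvmConfig(C=1.0, gamma=0.01), seed=0)

    def test_probabilities_in_unit_interval_and_pure(
        self, trained, random_windows
    ):
        for w in random_windows[:10]:
            p = predict_probability(trained["PseDNC"], w)
            assert 0.0 <= p <= 1.0
            assert predict_probability(trained["PseDNC"], w) == p


def eq_vote_oracle(votes):
    """Literal voting-score evaluation: V_i counts predictors calling class i."""
    v = {POSITIVE: 0, NEGATIVE: 0}
    for call in votes:
        v[POSITIVE if call else NEGATIVE] += 1
    return max(v, key=v.get)


class TestMajorityVote:
    @pytest.mark.parametrize("votes", list(itertools.product([False, True], repeat=3)))
    def test_all_patterns_match_voting_score_oracle(self, votes):
        assert majority_vote(votes) == eq_vote_oracle(votes)

    def test_two_of_three(self):
        assert majority_vote([True, True, False]) == POSITIVE
        assert majority_vote([False, False, False]) == NEGATIVE

    def test_wrong_count_rejected(self):
        with pytest.raises(ClassifierError):
            majority_vote([True, False])

    @given(votes=st.tuples(st.booleans(), st.booleans(), st.booleans()),
           flip=st.integers(min_value=0, max_value=2))
    @seed(8)
    @settings(max_examples=50, deadline=None)
    def test_single_vote_flip_cannot_change_unanimous_call(self, votes, flip):
        flipped = list(votes)
        flipped[flip] = not flipped[flip]
        if majority_vote(votes) != majority_vote(flipped):
            # the final label changed: the flipped vote must have been pivotal,
            # which requires the original vote split to be 2-1
            assert sum(votes) in (1, 2)


@pytest.fixture(scope="module")
def ensemble(trained):
    return EnsembleModel(predictors=dict(trained))


class TestEnsemble:
    def test_empty_input(self, ensemble):
        assert predict_ensemble(ensemble, []) == []

    def test_internal_consistency(self, ensemble, random_windows):
        for r in predict_ensemble(ensemble, random_windows[:10]):
            assert r.votes == tuple(p > 0.5 for p in r.probabilities)
            assert r.final_label == majority_vote(r.votes)

    def test_invalid_window_named(self, ensemble):
        bad = RnaWindow("oops", "A" * 41)  # bypasses validation; center not U
        with pytest.raises(ClassifierError, match="oops"):
            predict_ensemble(ensemble, [bad])

    def test_incomplete_ensemble_rejected(self, trained):
        with pytest.raises(ClassifierError):
            EnsembleModel(predictors={"NPCP": trained["NPCP"]})

    def test_ensemble_jackknife_tracks_second_best_base(
        self, separable_dataset, ctx
    ):
        """Voting robustness: a 2-of-3 majority errs only when at least two
        base predictors err, so the ensemble cannot fall far below the
        second-best base predictor (it may trail a single dominant one)."""
        from dsite import compute_metrics, run_jackknife
        from dsite.evaluation import counts_from_predictions

        results, counts, metrics, _ = run_jackknife(
            separable_dataset, ctx, mode="paper-parity", seed=0
        )
        true = [w.label for w in separable_dataset]
        base_mccs = []
        for k in range(3):
            calls = [
                POSITIVE if r.votes[k] else NEGATIVE for r in results
            ]
            m = compute_metrics(counts_from_predictions(true, calls))
            if m.mcc is not None:
                base_mccs.append(m.mcc)
        assert metrics.mcc is not None
        second_best = sorted(base_mccs)[-2]
        assert metrics.mcc >= second_best - 0.05


class TestPersistence:
    def test_round_trip(self, ensemble, random_windows, tmp_path):
        before = predict_ensemble(ensemble, random_windows[:5])
        path = tmp_path / "model.joblib"
        save_model(ensemble, path)
        after = predict_ensemble(load_model(path), random_windows[:5])
        assert before == after

    def test_truncated_file(self, ensemble, tmp_path):
        path = tmp_path / "model.joblib"
        save_model(ensemble, path)
        path.write_bytes(path.read_bytes()[:100])
        with pytest.raises(ClassifierError, match="cannot read|not a dsite"):
            load_model(path)

    def test_not_an_archive(self, tmp_path):
        import joblib

        path = tmp_path / "other.joblib"
        joblib.dump([1, 2, 3], path)
        with pytest.raises(ClassifierError, match="not a dsite model"):
            load_model(path)

    def test_provenance_recorded(self, separable_dataset, ctx, tmp_path):
        model = train_ensemble(
            separable_dataset, ctx,
            configs={k: SvmConfig(C=2.0, gamma=0.01) for k in ("NPCP", "PseDNC", "SSC")},
            seed=0,
        )
        assert "property_table_hash" in model.provenance
        assert model.provenance["engine"] == "nussinov"
        path = tmp_path / "model.joblib"
        save_model(model, path)
        assert load_model(path).provenance == model.provenance
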
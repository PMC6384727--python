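"""RBF-SVM base predictors and the majority-vote ensemble.

Three base predictors — one per feature encoding (NPCP, PseDNC, SSC) — are
RBF-kernel SVMs with probability estimates.  A window is called positive by
a base predictor when its probability score exceeds 0.5 (an exact 0.5 tie is
negative).  The ensemble counts the three binary votes and returns the class
with the larger voting score; with three voters and two classes a tie cannot
occur, so the final call is simply the class supported by at least two base
predictors.

Hyperparameters (C, gamma) are selected by grid search over
C in {2^-5, 2^-3, ..., 2^15} and gamma in {2^-15, 2^-14, ..., 2^-5},
maximizing internal k-fold cross-validated accuracy with deterministic
tie-breaking (smaller C, then smaller gamma).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoders import FEATURE_KINDS, EncoderContext, encode_window, feature_matrix
from .io import NEGATIVE, POSITIVE, Dataset, RnaWindow

#: C exponents -5..15 in steps of 2 (11 values)
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 16, 2))
#: gamma exponents -15..-5 in steps of 1 (11 values)
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-15, -4))

PROBABILITY_THRESHOLD = 0.5

MODEL_FORMAT_VERSION = 1

# libsvm's built-in Platt/pairwise-coupling calibration is exactly the
# probability machinery this predictor is defined around; keep using it.
warnings.filterwarnings(
    "ignore",
    message="The `probability` parameter was deprecated",
    category=FutureWarning,
)


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyperparameters; kernel and probability mode are fixed."""

    C: float
    gamma: float
    kernel: str = "rbf"
    probability: bool = True
    threshold: float = PROBABILITY_THRESHOLD

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ClassifierError("C and gamma must be positive")


@dataclass
class BasePredictor:
    """One trained feature-specific SVM."""

    feature_kind: str
    config: SvmConfig
    model: SVC
    training_fingerprint: str
    context: EncoderContext

    def predict_probability(self, window: Union[RnaWindow, str]) -> float:
        return predict_probability(self, window)


@dataclass
class PredictionResult:
    """Per-window ensemble output; internally consistent by construction."""

    id: str
    probabilities: tuple[float, float, float]
    votes: tuple[bool, bool, bool]
    final_label: str

    def __post_init__(self) -> None:
        expected = tuple(p > PROBABILITY_THRESHOLD for p in self.probabilities)
        if self.votes != expected:
            raise ClassifierError("votes inconsistent with probabilities")
        if self.final_label != majority_vote(self.votes):
            raise ClassifierError("final label inconsistent with majority vote")


@dataclass
class EnsembleModel:
    """Three base predictors (one per feature kind) plus the voting rule."""

    predictors: dict[str, BasePredictor]
    vote_rule: str = "majority"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(sorted(self.predictors)) != tuple(sorted(FEATURE_KINDS)):
            raise ClassifierError(
                f"need exactly one predictor per kind {FEATURE_KINDS}, "
                f"got {sorted(self.predictors)}"
            )

    def predict(self, windows: Sequence[RnaWindow]) -> list[PredictionResult]:
        return predict_ensemble(self, windows)


def _labels_to_int(windows: Sequence[RnaWindow]) -> np.ndarray:
    y = []
    for w in windows:
        if w.label not in (POSITIVE, NEGATIVE):
            raise ClassifierError(f"window {w.id!r} is unlabeled")
        y.append(1 if w.label == POSITIVE else 0)
    return np.array(y)


def grid_search_svm(
    features: np.ndarray,
    labels: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> SvmConfig:
    """Pick (C, gamma) maximizing internal cross-validated accuracy.

    Samples are put in a canonical order (label, then feature bytes) before
    the seeded stratified shuffle-split, so the selection is deterministic
    and invariant to the row order of the training matrix.  Ties break
    toward smaller C, then smaller gamma.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ClassifierError("grid search needs samples from both classes")
    if counts.min() < 2:
        raise ClassifierError("grid search needs >= 2 samples per class")
    order = sorted(range(len(y)), key=lambda i: (int(y[i]), X[i].tobytes()))
    X, y = X[order], y[order]
    n_splits = min(folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    best: Optional[tuple[float, float, float]] = None  # (acc, C, gamma)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            correct = 0
            for train_idx, test_idx in splits:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(X[train_idx], y[train_idx])
                correct += int((clf.predict(X[test_idx]) == y[test_idx]).sum())
            acc = correct / len(y)
            if best is None or acc > best[0]:
                best = (acc, C, gamma)
    assert best is not None
    return SvmConfig(C=best[1], gamma=best[2])


def train_base(
    dataset: Dataset,
    feature_kind: str,
    ctx: EncoderContext,
    config: SvmConfig,
    seed: int = 0,
) -> BasePredictor:
    """Train one probability-emitting base SVM on the labeled dataset."""
    X = feature_matrix(list(dataset), feature_kind, ctx)
    y = _labels_to_int(list(dataset))
    if len(np.unique(y)) < 2:
        raise ClassifierError("training requires both classes")
    clf = SVC(
        C=config.C,
        gamma=config.gamma,
        kernel=config.kernel,
        probability=True,
        random_state=seed,
    )
    clf.fit(X, y)
    fp = hashlib.sha256(
        X.tobytes() + y.tobytes() + str(seed).encode() + feature_kind.encode()
    ).hexdigest()
    return BasePredictor(
        feature_kind=feature_kind,
        config=config,
        model=clf,
        training_fingerprint=fp,
        context=ctx,
    )


def predict_probability(
    predictor: BasePredictor, window: Union[RnaWindow, str]
) -> float:
    """Probability that the centered uridine is a D site."""
    x = encode_window(window, predictor.feature_kind, predictor.context)
    if x.shape[0] != predictor.model.n_features_in_:
        raise ClassifierError(
            f"feature dimension {x.shape[0]} != model's "
            f"{predictor.model.n_features_in_}"
        )
    pos_col = int(np.nonzero(predictor.model.classes_ == 1)[0][0])
    return float(predictor.model.predict_proba(x[None, :])[0, pos_col])


def majority_vote(votes: Sequence[Union[bool, str]]) -> str:
    """Final class from three binary votes: argmax of the voting scores.

    The voting score of a class is the number of base predictors calling it;
    with 3 voters and 2 classes the argmax is unique.
    """
    if len(votes) != 3:
        raise ClassifierError(f"need exactly 3 votes, got {len(votes)}")
    v_pos = 0
    for v in votes:
        if isinstance(v, str):
            if v not in (POSITIVE, NEGATIVE):
                raise ClassifierError(f"unknown vote {v!r}")
            v_pos += v == POSITIVE
        else:
            v_pos += bool(v)
    v_neg = 3 - v_pos
    return POSITIVE if v_pos > v_neg else NEGATIVE


def predict_ensemble(
    model: EnsembleModel, windows: Sequence[RnaWindow]
) -> list[PredictionResult]:
    """One :class:`PredictionResult` per window, in input order."""
    from .io import validate_window

    results = []
    for w in windows:
        try:
            validate_window(w.id, w.sequence)
        except Exception as exc:
            raise ClassifierError(f"invalid window {w.id!r}: {exc}") from exc
        probs = tuple(
            predict_probability(model.predictors[k], w) for k in FEATURE_KINDS
        )
        votes = tuple(p > PROBABILITY_THRESHOLD for p in probs)
        results.append(
            PredictionResult(
                id=w.id,
                probabilities=probs,  # type: ignore[arg-type]
                votes=votes,  # type: ignore[arg-type]
                final_label=majority_vote(votes),
            )
        )
    return results


def train_ensemble(
    dataset: Dataset,
    ctx: EncoderContext,
    configs: Optional[dict[str, SvmConfig]] = None,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> EnsembleModel:
    """Train the three base predictors (grid-searching unless configs given)."""
    windows = list(dataset)
    y = _labels_to_int(windows)
    predictors = {}
    for kind in FEATURE_KINDS:
        if configs is not None and kind in configs:
            cfg = configs[kind]
        else:
            X = feature_matrix(windows, kind, ctx)
            cfg = grid_search_svm(X, y, C_grid, gamma_grid, folds=folds, seed=seed)
        predictors[kind] = train_base(dataset, kind, ctx, cfg, seed=seed)
    provenance = dict(ctx.provenance())
    provenance.update(
        {
            "seed": seed,
            "configs": {
                k: {"C": p.config.C, "gamma": p.config.gamma}
                for k, p in predictors.items()
            },
            "n_windows": len(windows),
        }
    )
    return EnsembleModel(predictors=predictors, provenance=provenance)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Single-file model archive with format version and provenance."""
    joblib.dump(
        {"format_version": MODEL_FORMAT_VERSION, "model": model},
        path,
        compress=3,
    )


def load_model(path: str | Path) -> EnsembleModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ClassifierError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ClassifierError(f"{path} is not a dsite model archive")
    version = payload["format_version"]
    if version != MODEL_FORMAT_VERSION:
        raise ClassifierError(
            f"model format version {version} != supported {MODEL_FORMAT_VERSION}"
        )
    return payload["model"]
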
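"""Jackknife cross-validation and performance metrics.

Metrics follow the intuitive confusion-count formulation common in the
site-prediction literature.  With N+ total positives, N- total negatives,
FN positives called negative and FP negatives called positive:

    Sn  = 1 - FN/N+
    Sp  = 1 - FP/N-
    Acc = 1 - (FN + FP)/(N+ + N-)
    MCC = (1 - (FN/N+ + FP/N-))
          / sqrt((1 + (FP - FN)/N+) * (1 + (FN - FP)/N-))

This MCC is algebraically identical to the textbook Matthews correlation
coefficient wherever both are defined; it is undefined (reported as None,
never coerced to 0) when nothing is predicted positive or nothing negative.

Jackknife (leave-one-out) evaluation trains on n-1 windows and predicts the
held-out one, for every window in turn; metrics are computed from the pooled
predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Optional, Protocol, Sequence

from .classifier import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    EnsembleModel,
    PredictionResult,
    SvmConfig,
    grid_search_svm,
    train_ensemble,
    _labels_to_int,
)
from .encoders import FEATURE_KINDS, EncoderContext, feature_matrix
from .io import NEGATIVE, POSITIVE, Dataset


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """Totals and errors: n_pos/n_neg are class sizes, fn/fp the mistakes."""

    n_pos: int
    n_neg: int
    fn: int  # positives predicted negative
    fp: int  # negatives predicted positive

    def __post_init__(self) -> None:
        if not 0 <= self.fn <= self.n_pos:
            raise EvaluationError(f"fn={self.fn} outside [0, n_pos={self.n_pos}]")
        if not 0 <= self.fp <= self.n_neg:
            raise EvaluationError(f"fp={self.fp} outside [0, n_neg={self.n_neg}]")

    @property
    def tp(self) -> int:
        return self.n_pos - self.fn

    @property
    def tn(self) -> int:
        return self.n_neg - self.fp


@dataclass(frozen=True)
class Metrics:
    """Sn/Sp/Acc as fractions in [0,1]; MCC in [-1,1] or None if undefined."""

    sn: float
    sp: float
    acc: float
    mcc: Optional[float]

    def as_percent(self) -> dict[str, str]:
        """Two-decimal percentage formatting (report style)."""
        out = {
            "Sn": f"{100 * self.sn:.2f}",
            "Sp": f"{100 * self.sp:.2f}",
            "Acc": f"{100 * self.acc:.2f}",
            "MCC": "undefined" if self.mcc is None else f"{self.mcc:.2f}",
        }
        return out


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, accuracy and MCC from confusion counts."""
    n_pos, n_neg, fn, fp = counts.n_pos, counts.n_neg, counts.fn, counts.fp
    if n_pos <= 0 or n_neg <= 0:
        raise EvaluationError("both classes must be present")
    sn = 1 - fn / n_pos
    sp = 1 - fp / n_neg
    acc = 1 - (fn + fp) / (n_pos + n_neg)
    # denominator factors vanish iff no predicted positives / negatives
    left = 1 + (fp - fn) / n_pos
    right = 1 + (fn - fp) / n_neg
    if left <= 0 or right <= 0 or math.isclose(left * right, 0.0):
        mcc: Optional[float] = None
    else:
        mcc = (1 - (fn / n_pos + fp / n_neg)) / math.sqrt(left * right)
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


def counts_from_predictions(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> ConfusionCounts:
    if len(true_labels) != len(predicted_labels):
        raise EvaluationError("label sequences differ in length")
    n_pos = sum(t == POSITIVE for t in true_labels)
    n_neg = sum(t == NEGATIVE for t in true_labels)
    fn = sum(t == POSITIVE and p == NEGATIVE for t, p in zip(true_labels, predicted_labels))
    fp = sum(t == NEGATIVE and p == POSITIVE for t, p in zip(true_labels, predicted_labels))
    return ConfusionCounts(n_pos=n_pos, n_neg=n_neg, fn=fn, fp=fp)


class _Predictor(Protocol):
    def predict(self, windows) -> list[PredictionResult]: ...


Trainer = Callable[[Dataset, int], _Predictor]


def jackknife_evaluate(
    dataset: Dataset, trainer: Trainer, seed: int = 0
) -> tuple[list[PredictionResult], ConfusionCounts, Metrics]:
    """Leave-one-out evaluation of an arbitrary training procedure.

    ``trainer(train_dataset, seed)`` must return an object whose
    ``predict(windows)`` yields one :class:`PredictionResult` per window.
    Each window is predicted exactly once by a model trained without it;
    metrics are pooled over all n rounds.
    """
    windows = list(dataset)
    if len(windows) < 2:
        raise EvaluationError("jackknife needs at least 2 windows")
    labels = [w.label for w in windows]
    if POSITIVE not in labels or NEGATIVE not in labels:
        raise EvaluationError("jackknife needs both classes present")
    results: list[PredictionResult] = []
    for i, held_out in enumerate(windows):
        train = Dataset(
            windows[:i] + windows[i + 1 :], metadata=dict(dataset.metadata)
        )
        model = trainer(train, seed)
        (result,) = model.predict([held_out])
        results.append(result)
    counts = counts_from_predictions(labels, [r.final_label for r in results])
    return results, counts, compute_metrics(counts)


def run_jackknife(
    dataset: Dataset,
    ctx: Optional[EncoderContext] = None,
    mode: str = "paper-parity",
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> tuple[list[PredictionResult], ConfusionCounts, Metrics, dict]:
    """Jackknife the full three-predictor ensemble.

    ``mode="paper-parity"`` selects (C, gamma) once per feature kind by
    internal cross-validation on the full dataset, then jackknifes with the
    hyperparameters fixed.  ``mode="nested"`` re-runs the grid search inside
    every leave-one-out round, giving leakage-free (and slower) estimates.
    """
    if ctx is None:
        ctx = EncoderContext()
    if mode not in ("paper-parity", "nested"):
        raise EvaluationError(f"unknown evaluation mode {mode!r}")

    configs: Optional[dict[str, SvmConfig]] = None
    if mode == "paper-parity":
        windows = list(dataset)
        y = _labels_to_int(windows)
        configs = {}
        for kind in FEATURE_KINDS:
            X = feature_matrix(windows, kind, ctx)
            configs[kind] = grid_search_svm(
                X, y, C_grid, gamma_grid, folds=folds, seed=seed
            )

    def trainer(train: Dataset, s: int) -> EnsembleModel:
        return train_ensemble(
            train, ctx, configs=configs, C_grid=C_grid,
            gamma_grid=gamma_grid, folds=folds, seed=s,
        )

    results, counts, metrics = jackknife_evaluate(dataset, trainer, seed=seed)
    meta = {
        "mode": mode,
        "seed": seed,
        "n_windows": len(dataset),
        "configs": None
        if configs is None
        else {k: {"C": c.C, "gamma": c.gamma} for k, c in configs.items()},
        **ctx.provenance(),
    }
    return results, counts, metrics, meta


def write_report(
    path: str | Path,
    results: Sequence[PredictionResult],
    true_labels: Sequence[Optional[str]],
    counts: ConfusionCounts,
    metrics: Metrics,
    metadata: Optional[dict] = None,
) -> None:
    """Per-window TSV plus a summary block of counts and metrics."""
    with open(path, "w") as fh:
        fh.write("id\ttrue\tp_NPCP\tp_PseDNC\tp_SSC\tvotes\tfinal\n")
        for r, t in zip(results, true_labels):
            votes = "".join("+" if v else "-" for v in r.votes)
            probs = "\t".join(f"{p:.4f}" for p in r.probabilities)
            fh.write(f"{r.id}\t{t or 'NA'}\t{probs}\t{votes}\t{r.final_label}\n")
        fh.write("\n# summary\n")
        fh.write(f"# N+ = {counts.n_pos}\tN- = {counts.n_neg}\t"
                 f"FN = {counts.fn}\tFP = {counts.fp}\n")
        pct = metrics.as_percent()
        fh.write(f"# Sn = {pct['Sn']}%\n# Sp = {pct['Sp']}%\n")
        fh.write(f"# Acc = {pct['Acc']}%\n# MCC = {pct['MCC']}\n")
        if metadata:
            for k in sorted(metadata):
                fh.write(f"# {k} = {metadata[k]}\n")
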
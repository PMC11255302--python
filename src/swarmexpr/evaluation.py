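"""Cross-validation, confusion-matrix metrics, feature statistics, benchmarks.

Headline metrics follow the *pooled* K-fold convention: out-of-fold
predictions for every sample are collected first and the confusion matrix is
computed once over all of them, so metric denominators equal the full sample
count.  Cancer is the positive class throughout.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_data import CANCER, NORMAL, ExpressionDataset, ValidationError
from .feature_extraction import (
    EHOFeatureConfig,
    FeatureMatrix,
    LassoConfig,
    STFTConfig,
    eho_features,
    lasso_features,
    stft_features,
)
from . import classifiers as clf
from .classifiers import TargetScheme
from .metaheuristics import FireflyParams, FPOParams, PSOParams

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "CVPlan",
    "ClassStatistics",
    "BenchmarkResult",
    "confusion_matrix",
    "compute_metrics",
    "kappa_band",
    "stratified_folds",
    "cross_validate",
    "feature_statistics",
    "canonical_correlation",
    "benchmark",
    "make_classifier",
    "make_extractor",
    "CLASSIFIER_NAMES",
    "EXTRACTOR_NAMES",
]


# ---------------------------------------------------------------------------
# Confusion matrix and metric suite
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with cancer as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_matrix(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionMatrix:
    t = np.asarray(y_true, dtype=object)
    p = np.asarray(y_pred, dtype=object)
    if t.size != p.size:
        raise ValidationError(f"length mismatch: {t.size} vs {p.size}")
    for arr, name in ((t, "y_true"), (p, "y_pred")):
        bad = sorted(set(arr.tolist()) - {CANCER, NORMAL})
        if bad:
            raise ValidationError(f"{name} contains unknown labels {bad}")
    return ConfusionMatrix(
        tp=int(np.sum((t == CANCER) & (p == CANCER))),
        tn=int(np.sum((t == NORMAL) & (p == NORMAL))),
        fp=int(np.sum((t == NORMAL) & (p == CANCER))),
        fn=int(np.sum((t == CANCER) & (p == NORMAL))),
    )


@dataclass
class MetricsReport:
    """The seven-metric suite: proportions plus chance-corrected agreement.

    All quantities are stored as proportions (0–1); ``percent()`` renders
    the 0–100 scale.  ``flags`` records degenerate denominators (the metric
    is then reported as 0 rather than NaN).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    error_rate: float
    mcc: float
    po: float
    pe: float
    kappa: float
    kappa_band: str
    flags: list[str] = field(default_factory=list)

    def percent(self) -> dict[str, float]:
        return {
            "accuracy": 100.0 * self.accuracy,
            "f1": 100.0 * self.f1,
            "error_rate": 100.0 * self.error_rate,
            "precision": 100.0 * self.precision,
            "recall": 100.0 * self.recall,
        }

    def to_dict(self) -> dict:
        return asdict(self)


def kappa_band(kappa: float) -> str:
    """Agreement band for a kappa value; boundaries go to the upper band."""
    if kappa >= 0.8:
        return "very good"
    if kappa >= 0.6:
        return "good"
    if kappa >= 0.4:
        return "moderate"
    if kappa >= 0.2:
        return "fair"
    return "poor"


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision/recall/F1, error rate, MCC and Cohen's kappa.

    Degenerate denominators (empty predicted-positive set, MCC with a zero
    margin product, chance agreement of 1) yield 0 with an entry in
    ``flags`` instead of NaN.
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    n = cm.total
    if n < 1:
        raise ValidationError("empty confusion matrix")
    flags: list[str] = []

    accuracy = (tp + tn) / n
    error_rate = (fp + fn) / n

    if tp + fp == 0:
        precision, = (0.0,); flags.append("precision_undefined")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0; flags.append("recall_undefined")
    else:
        recall = tp / (tp + fn)
    f1 = (2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) > 0 else 0.0
    if 2 * tp + fp + fn == 0:
        flags.append("f1_undefined")

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0; flags.append("mcc_undefined")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)

    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fp + tn) * (fn + tn)) / n**2
    if pe >= 1.0:
        kappa = 0.0; flags.append("kappa_undefined")
    else:
        kappa = (po - pe) / (1.0 - pe)

    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        error_rate=error_rate, mcc=mcc, po=po, pe=pe, kappa=kappa,
        kappa_band=kappa_band(kappa), flags=flags,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    k: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("K must be >= 2")
        if not (5 <= self.k <= 20):
            raise ValidationError("K folds must lie in the supported range 5-20")


def stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator, stratified: bool = True
) -> list[np.ndarray]:
    """Partition indices into K folds, each sample in exactly one fold.

    Stratified mode shuffles within each class and deals round-robin; if a
    class has fewer members than folds a warning is emitted and some folds
    simply lack that class.
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratified:
        for label in (CANCER, NORMAL):
            idx = np.flatnonzero(labels == label)
            if 0 < idx.size < k:
                warnings.warn(
                    f"class '{label}' has {idx.size} samples for {k} folds; "
                    "some folds will lack this class"
                )
            for pos, i in enumerate(rng.permutation(idx)):
                folds[pos % k].append(int(i))
    else:
        for pos, i in enumerate(rng.permutation(n)):
            folds[pos % k].append(int(i))
    return [np.asarray(sorted(f), dtype=int) for f in folds if f]


FitPredictFn = Callable[[np.ndarray, np.ndarray, np.ndarray, int], np.ndarray]


def cross_validate(
    features: FeatureMatrix,
    fit_predict: FitPredictFn,
    plan: CVPlan = CVPlan(),
) -> tuple[np.ndarray, MetricsReport, ConfusionMatrix]:
    """Pooled K-fold cross-validation of a fit/predict pipeline.

    Each fold is held out once, the pipeline is fit on the remaining folds
    and predicts the held-out samples; the pooled predictions (one per
    sample) give a single confusion matrix whose denominators equal the
    full sample count.
    """
    X = features.values
    labels = features.label_array()
    rng = np.random.default_rng(plan.seed)
    folds = stratified_folds(labels, plan.k, rng, plan.stratified)
    pooled = np.empty(X.shape[0], dtype=object)
    for f, val_idx in enumerate(folds):
        tr_idx = np.setdiff1d(np.arange(X.shape[0]), val_idx)
        preds = fit_predict(X[tr_idx], labels[tr_idx], X[val_idx], plan.seed + f)
        pooled[val_idx] = np.asarray(preds, dtype=object)
    cm = confusion_matrix(labels, pooled)
    return pooled, compute_metrics(cm), cm


# ---------------------------------------------------------------------------
# Feature statistics
# ---------------------------------------------------------------------------

@dataclass
class ClassStatistics:
    """Per-class pooled moments, mean pairwise PCC and the cross-class CCA."""

    per_class: dict  # label -> {mean, variance, skewness, kurtosis, mean_pcc, flags}
    cca: float


def _pooled_moments(values: np.ndarray) -> dict:
    flags = []
    if values.size < 3:
        raise ValidationError("need at least 3 pooled values per class")
    mean = float(values.mean())
    variance = float(values.var(ddof=1))
    if variance <= 0:
        skewness = None
        kurtosis = None
        flags.append("moments_undefined_constant")
    else:
        skewness = float(sps.skew(values, bias=False))
        kurtosis = float(sps.kurtosis(values, fisher=False, bias=False))
    return {
        "mean": mean, "variance": variance,
        "skewness": skewness, "kurtosis": kurtosis, "flags": flags,
    }


def _mean_offdiag_pcc(X: np.ndarray) -> float | None:
    # X: samples × features; correlations across features
    keep = X.std(axis=0) > 0
    if keep.sum() < 2:
        return None
    R = np.corrcoef(X[:, keep], rowvar=False)
    off = R[~np.eye(R.shape[0], dtype=bool)]
    return float(off.mean())


def canonical_correlation(A: np.ndarray, B: np.ndarray, ridge: float = 1e-8) -> float:
    """First canonical correlation between two observation × variable blocks.

    Largest singular value of the ridge-whitened cross-covariance,
    clipped into [0, 1].
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValidationError("A and B must have equal observation counts")
    if A.shape[0] < 3:
        raise ValidationError("need at least 3 paired observations")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    n = A.shape[0] - 1
    Caa = Ac.T @ Ac / n + ridge * np.eye(A.shape[1])
    Cbb = Bc.T @ Bc / n + ridge * np.eye(B.shape[1])
    Cab = Ac.T @ Bc / n

    def inv_sqrt(M: np.ndarray) -> np.ndarray:
        w, V = np.linalg.eigh(M)
        w = np.maximum(w, ridge)
        return V @ np.diag(w**-0.5) @ V.T

    M = inv_sqrt(Caa) @ Cab @ inv_sqrt(Cbb)
    s = np.linalg.svd(M, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def feature_statistics(features: FeatureMatrix) -> ClassStatistics:
    """Per-class statistics of the pooled feature values plus cross-class CCA.

    Pooled moments flatten every (sample, feature) cell of a class.  The
    cross-class canonical correlation pairs the two classes by truncating to
    the smaller class size, ordering each class's samples by their mean
    feature value and pairing by rank (a deterministic pairing rule; the two
    classes have no natural sample correspondence).
    """
    labels = features.label_array()
    per_class = {}
    blocks = {}
    for label in (CANCER, NORMAL):
        idx = np.flatnonzero(labels == label)
        if idx.size == 0:
            raise ValidationError(f"class '{label}' absent")
        X = features.values[idx]
        stats_ = _pooled_moments(X.ravel())
        stats_["mean_pcc"] = _mean_offdiag_pcc(X)
        per_class[label] = stats_
        blocks[label] = X
    m = min(b.shape[0] for b in blocks.values())
    paired = {}
    for label, X in blocks.items():
        order = np.argsort(X.mean(axis=1), kind="stable")
        paired[label] = X[order][:m]
    cca = canonical_correlation(paired[CANCER], paired[NORMAL])
    return ClassStatistics(per_class=per_class, cca=cca)


# ---------------------------------------------------------------------------
# Benchmark orchestration
# ---------------------------------------------------------------------------

CLASSIFIER_NAMES = (
    "gmm", "pso-gmm", "dfa", "nbc", "firefly-gmm", "svm-rbf", "fpo-gmm",
)
EXTRACTOR_NAMES = ("stft", "lasso", "eho")

#: Scaled-down swarm budgets used when a hybrid classifier runs inside a
#: cross-validated benchmark cell (one fit per fold); full Table-style search
#: budgets remain the dataclass defaults for standalone use.
_BENCH_BUDGET = {"population": 20, "max_iter": 30}


def _standardize_train_test(train_X, test_X):
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train_X - mu) / sd, (test_X - mu) / sd


def _median_sigma(X: np.ndarray) -> float:
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(X**2, axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    d = np.sqrt(np.maximum(d2[np.triu_indices(X.shape[0], k=1)], 0.0))
    med = float(np.median(d))
    return med if med > 0 else 1.0


def make_classifier(
    name: str,
    targets: TargetScheme = TargetScheme(),
    standardize: bool = True,
    svm_sigma: float | str = "median",
    svm_C: float = 1.0,
    n_components: int = 2,
    hybrid_budget: dict | None = None,
) -> FitPredictFn:
    """Build a fit/predict callable for :func:`cross_validate`.

    Features are z-scored with training-fold statistics before every
    classifier (``standardize=False`` disables this).  The SVM kernel width
    defaults to the median pairwise-distance heuristic on the training fold;
    pass a float to fix it.  Hybrid GMM classifiers use scaled-down swarm
    budgets inside benchmark cells (see ``_BENCH_BUDGET``).
    """
    if name not in CLASSIFIER_NAMES:
        raise ValidationError(
            f"unknown classifier '{name}'; choose from {CLASSIFIER_NAMES}"
        )
    budget = dict(_BENCH_BUDGET, **(hybrid_budget or {}))
    hybrid_params = {
        "pso-gmm": PSOParams(**budget),
        "firefly-gmm": FireflyParams(**budget),
        "fpo-gmm": FPOParams(**budget),
    }

    def fit_predict(train_X, train_labels, test_X, seed):
        if name == "dfa":
            # DFA reads each sample's feature vector as a series; per-column
            # z-scoring would strip the within-series structure it relies on
            return clf.dfa_classify(train_X, train_labels, test_X)
        if standardize:
            train_X, test_X = _standardize_train_test(train_X, test_X)
        feats = FeatureMatrix(
            values=train_X,
            feature_names=[f"f{i}" for i in range(train_X.shape[1])],
            method="cv-fold", params={}, labels=list(train_labels),
        )
        if name == "gmm":
            G = _fit_components(train_labels, n_components)
            model = clf.gmm_fit(feats, G, seed=seed, covariance_type=_auto_cov(
                train_X, train_labels))
            return clf.gmm_predict(model, test_X, targets)[0]
        if name in hybrid_params:
            G = _fit_components(train_labels, n_components)
            hybrid = clf.hybrid_gmm_fit(
                feats, optimizer=name.split("-")[0],
                params=hybrid_params[name], targets=targets,
                seed=seed, n_components=G,
            )
            return clf.gmm_predict(hybrid.model, test_X, targets)[0]
        if name == "nbc":
            return clf.nbc_fit_predict(train_X, train_labels, test_X)[0]
        # svm-rbf
        sigma = (
            _median_sigma(train_X) if svm_sigma == "median" else float(svm_sigma)
        )
        return clf.svm_fit_predict(
            train_X, train_labels, test_X, sigma=sigma, C=svm_C, seed=seed
        )[0]

    return fit_predict


def _auto_cov(train_X, train_labels) -> str:
    """Full covariance only when every class has more samples than features;
    otherwise diagonal (a full covariance would be rank deficient)."""
    counts = [int(np.sum(np.asarray(train_labels, dtype=object) == c))
              for c in (CANCER, NORMAL)]
    return "full" if min(counts) > train_X.shape[1] else "diag"


def _fit_components(train_labels, requested: int) -> int:
    counts = [int(np.sum(np.asarray(train_labels, dtype=object) == c))
              for c in (CANCER, NORMAL)]
    return max(1, min(requested, min(counts) // 2))


def make_extractor(name: str, seed: int = 0, **kwargs):
    """Build an ``ExpressionDataset -> FeatureMatrix`` callable by name."""
    if name == "stft":
        config = kwargs.get("config", STFTConfig())
        return lambda ds: stft_features(ds, config)
    if name == "lasso":
        config = kwargs.get("config", LassoConfig())
        return lambda ds: lasso_features(ds, config)
    if name == "eho":
        config = kwargs.get("config", EHOFeatureConfig())
        return lambda ds: eho_features(ds, config, seed=seed)
    raise ValidationError(f"unknown extractor '{name}'; choose from {EXTRACTOR_NAMES}")


@dataclass
class BenchmarkResult:
    table: pd.DataFrame
    errors: dict
    config: dict

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.table.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        payload = {
            "config": self.config,
            "errors": {k: str(v) for k, v in self.errors.items()},
            "results": self.table.to_dict(orient="records"),
        }
        prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def benchmark(
    dataset: ExpressionDataset,
    extractors: Sequence[str] = EXTRACTOR_NAMES,
    classifier_names: Sequence[str] = CLASSIFIER_NAMES,
    plan: CVPlan = CVPlan(),
    seed: int = 0,
    targets: TargetScheme = TargetScheme(),
    extractor_kwargs: dict | None = None,
    classifier_kwargs: dict | None = None,
) -> BenchmarkResult:
    """Pooled-CV metrics for the Cartesian product extractors × classifiers.

    Features are extracted once per extractor on the full dataset (the
    study's pipeline ordering), then each classifier is cross-validated on
    them.  Failures are recorded per cell and the run continues.
    """
    rows = []
    errors: dict[str, Exception] = {}
    ek = extractor_kwargs or {}
    ck = classifier_kwargs or {}
    for ex_name in extractors:
        try:
            feats = make_extractor(ex_name, seed=seed, **ek.get(ex_name, {}))(dataset)
        except Exception as exc:  # noqa: BLE001 - per-cell error payload
            for c_name in classifier_names:
                errors[f"{ex_name}/{c_name}"] = exc
            continue
        for c_name in classifier_names:
            try:
                fp = make_classifier(c_name, targets=targets, **ck.get(c_name, {}))
                _, report, _ = cross_validate(feats, fp, plan)
                rows.append(
                    {
                        "method": ex_name,
                        "classifier": c_name,
                        "accuracy": report.accuracy,
                        "f1": report.f1,
                        "mcc": report.mcc,
                        "error_rate": report.error_rate,
                        "kappa": report.kappa,
                        "seed": seed,
                    }
                )
            except Exception as exc:  # noqa: BLE001
                errors[f"{ex_name}/{c_name}"] = exc
    table = pd.DataFrame(
        rows,
        columns=["method", "classifier", "accuracy", "f1", "mcc",
                 "error_rate", "kappa", "seed"],
    )
    config = {
        "extractors": list(extractors),
        "classifiers": list(classifier_names),
        "k": plan.k,
        "seed": seed,
        "targets": {"t_normal": targets.t_normal, "t_cancer": targets.t_cancer},
    }
    return BenchmarkResult(table=table, errors=errors, config=config)
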
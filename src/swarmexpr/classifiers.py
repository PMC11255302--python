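"""The seven classifiers and the shared class-target / MSE training contract.

All classifiers share one orientation: *cancer is the positive class*.
Probabilistic classifiers additionally expose a continuous score on the
class-target axis — each sample's posterior-weighted combination of the two
scalar regression targets (0.85 for normal, 0.1 for cancer) — and the
metaheuristic-tuned Gaussian-mixture hybrids minimize the mean squared error
between that score and each training sample's own class target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_triangular

from .core_data import CANCER, NORMAL, ValidationError
from .feature_extraction import FeatureMatrix
from .metaheuristics import (
    Bounds,
    FireflyParams,
    FPOParams,
    PSOParams,
    firefly_optimize,
    fpo_optimize,
    pso_optimize,
)

__all__ = [
    "TargetScheme",
    "GMMClassModel",
    "HybridGMMModel",
    "DFAConfig",
    "DFAResult",
    "NumericalError",
    "ConfigurationError",
    "check_targets",
    "mse",
    "gmm_fit",
    "gmm_predict",
    "hybrid_gmm_fit",
    "dfa_exponent",
    "dfa_classify",
    "nbc_fit_predict",
    "svm_rbf_kernel",
    "svm_fit_predict",
]

CLASS_ORDER = (CANCER, NORMAL)


class NumericalError(RuntimeError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TargetScheme:
    """Scalar regression targets for the two classes.

    Scores live on [0, 1]; the two targets must be at least
    ``min_separation`` apart so that the nearest-target label rule is
    well conditioned.
    """

    t_normal: float = 0.85
    t_cancer: float = 0.1
    min_separation: float = 0.5

    def target_for(self, labels: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(labels, dtype=object) == CANCER,
                        self.t_cancer, self.t_normal)


def check_targets(scheme: TargetScheme) -> TargetScheme:
    """Validate a target scheme: both targets in [0,1], separated by >= 0.5."""
    if not (0.0 <= scheme.t_normal <= 1.0 and 0.0 <= scheme.t_cancer <= 1.0):
        raise ConfigurationError(
            f"class targets must lie in [0, 1]; got "
            f"T_N={scheme.t_normal}, T_C={scheme.t_cancer}"
        )
    sep = abs(scheme.t_normal - scheme.t_cancer)
    if sep < scheme.min_separation:
        raise ConfigurationError(
            f"class-target separation |T_N - T_C| = {sep:.3g} is below the "
            f"required minimum {scheme.min_separation}"
        )
    return scheme


def mse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared error (1/N)·Σ (A_j − P_j)²."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size or a.size == 0:
        raise ValidationError(f"length mismatch: {a.size} vs {p.size}")
    return float(np.mean((a - p) ** 2))


# ---------------------------------------------------------------------------
# Gaussian mixture classifier
# ---------------------------------------------------------------------------

@dataclass
class GMMClassModel:
    """Per-class Gaussian mixture: weights, means, covariances, priors."""

    classes: tuple[str, str]
    weights: dict[str, np.ndarray]        # label -> (G,)
    means: dict[str, np.ndarray]          # label -> (G, D)
    covariances: dict[str, np.ndarray]    # label -> (G, D, D)
    priors: dict[str, float]
    n_components: int
    n_features: int
    loglik_trace: dict[str, np.ndarray] = field(default_factory=dict)
    covariance_type: str = "full"


def _mvn_logpdf(X: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    D = mu.size
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"covariance not positive definite: {exc}") from exc
    diff = X - mu
    sol = solve_triangular(chol, diff.T, lower=True)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (D * math.log(2 * math.pi) + logdet + maha)


def _kmeanspp_centers(X: np.ndarray, G: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, G):
        d2 = np.min(
            np.stack([np.sum((X - c) ** 2, axis=1) for c in centers]), axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)].copy())
            continue
        centers.append(X[rng.choice(n, p=d2 / total)].copy())
    return np.stack(centers)


def _regularize(cov: np.ndarray, ridge_frac: float = 1e-6) -> np.ndarray:
    D = cov.shape[0]
    tr = max(np.trace(cov), 1e-12)
    return cov + np.eye(D) * max(ridge_frac * tr / D, 1e-10)


def _fit_class_em(
    X: np.ndarray,
    G: int,
    rng: np.random.Generator,
    cov_type: str,
    label: str,
    max_iter: int = 200,
    tol: float = 1e-6,
):
    n, D = X.shape
    means = _kmeanspp_centers(X, G, rng)
    base_cov = np.cov(X, rowvar=False).reshape(D, D) if n > 1 else np.eye(D)
    if cov_type == "diag":
        base_cov = np.diag(np.diag(base_cov))
    base_cov = _regularize(base_cov)
    covs = np.stack([base_cov.copy() for _ in range(G)])
    weights = np.full(G, 1.0 / G)

    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        # E-step
        log_comp = np.stack(
            [
                math.log(max(weights[g], 1e-300)) + _component_logpdf(X, means[g], covs[g], label, g)
                for g in range(G)
            ],
            axis=1,
        )
        mx = log_comp.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.sum(np.exp(log_comp - mx), axis=1))
        loglik = float(np.sum(lse))
        trace.append(loglik)
        resp = np.exp(log_comp - lse[:, None])
        if loglik - prev < tol * max(1.0, abs(loglik)) and len(trace) > 1:
            break
        prev = loglik
        # M-step
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for g in range(G):
            diff = X - means[g]
            cov = (resp[:, g, None] * diff).T @ diff / nk[g]
            if cov_type == "diag":
                cov = np.diag(np.diag(cov))
            covs[g] = _regularize(cov)
    return weights, means, covs, np.asarray(trace)


def _component_logpdf(X, mu, cov, label, g):
    for bump in (0.0, 1e-6, 1e-4, 1e-2):
        try:
            c = cov if bump == 0.0 else cov + np.eye(cov.shape[0]) * bump * max(
                np.trace(cov) / cov.shape[0], 1e-12
            )
            return _mvn_logpdf(X, mu, c)
        except NumericalError:
            continue
    raise NumericalError(
        f"singular covariance for class '{label}', component {g} "
        "after regularization"
    )


def gmm_fit(
    features: FeatureMatrix,
    n_components: int = 2,
    seed: int = 0,
    covariance_type: str = "full",
) -> GMMClassModel:
    """Fit one Gaussian mixture per class by EM (seeded k-means++ init).

    Covariances are ridge-regularized (1e-6 · trace/D on the diagonal);
    class priors are the class frequencies.  The per-class log-likelihood
    trace is stored and is non-decreasing (EM guarantee).
    """
    X = features.values
    labels = features.label_array()
    rng = np.random.default_rng(seed)
    weights, means, covs, priors, traces = {}, {}, {}, {}, {}
    n = X.shape[0]
    for label in CLASS_ORDER:
        idx = np.flatnonzero(labels == label)
        if idx.size < n_components:
            raise ValidationError(
                f"class '{label}' has {idx.size} samples, fewer than "
                f"{n_components} mixture components"
            )
        w, m, c, t = _fit_class_em(
            X[idx], n_components, rng, covariance_type, label
        )
        weights[label], means[label], covs[label] = w, m, c
        priors[label] = idx.size / n
        traces[label] = t
    return GMMClassModel(
        classes=CLASS_ORDER,
        weights=weights,
        means=means,
        covariances=covs,
        priors=priors,
        n_components=n_components,
        n_features=X.shape[1],
        loglik_trace=traces,
        covariance_type=covariance_type,
    )


def gmm_predict(
    model: GMMClassModel,
    X: np.ndarray,
    targets: TargetScheme = TargetScheme(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior classification under the per-class mixtures.

    Returns ``(labels, posteriors, scores)`` where posterior columns follow
    ``model.classes`` (cancer first), labels are the argmax class (ties to
    cancer), and the score is the posterior-weighted combination of the class
    targets — ``p(normal)·T_N + p(cancer)·T_C``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature dimensionality {X.shape[1]} != model D {model.n_features}"
        )
    log_post = np.zeros((X.shape[0], 2))
    for c, label in enumerate(model.classes):
        comp = np.stack(
            [
                math.log(max(model.weights[label][g], 1e-300))
                + _component_logpdf(
                    X, model.means[label][g], model.covariances[label][g], label, g
                )
                for g in range(model.n_components)
            ],
            axis=1,
        )
        mx = comp.max(axis=1, keepdims=True)
        log_post[:, c] = math.log(model.priors[label]) + mx[:, 0] + np.log(
            np.sum(np.exp(comp - mx), axis=1)
        )
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    # ties resolve toward cancer (sensitivity-first): cancer is column 0
    labels = np.where(post[:, 0] >= post[:, 1], CANCER, NORMAL).astype(object)
    scores = post[:, 0] * targets.t_cancer + post[:, 1] * targets.t_normal
    return labels, post, scores


# ---------------------------------------------------------------------------
# Metaheuristic-tuned GMM hybrids
# ---------------------------------------------------------------------------

_OPTIMIZERS = {
    "pso": (pso_optimize, PSOParams),
    "firefly": (firefly_optimize, FireflyParams),
    "fpo": (fpo_optimize, FPOParams),
}


@dataclass
class HybridGMMModel:
    """A diagonal-covariance GMM whose parameters were tuned by a swarm
    optimizer against the class-target MSE, starting from the EM solution."""

    base: GMMClassModel
    model: GMMClassModel
    optimizer: str
    params: object
    theta: np.ndarray
    trace: np.ndarray
    train_mse: float
    em_mse: float


def _encode(model: GMMClassModel) -> np.ndarray:
    parts = []
    for label in model.classes:
        parts.append(model.means[label].ravel())
        logvar = np.log(
            np.stack([np.diag(model.covariances[label][g])
                      for g in range(model.n_components)])
        )
        parts.append(logvar.ravel())
        parts.append(np.log(np.maximum(model.weights[label], 1e-12)))
    return np.concatenate(parts)


def _decode(theta: np.ndarray, template: GMMClassModel) -> GMMClassModel:
    G, D = template.n_components, template.n_features
    block = G * D
    weights, means, covs = {}, {}, {}
    pos = 0
    for label in template.classes:
        m = theta[pos : pos + block].reshape(G, D); pos += block
        lv = theta[pos : pos + block].reshape(G, D); pos += block
        logits = theta[pos : pos + G]; pos += G
        w = np.exp(logits - logits.max())
        weights[label] = w / w.sum()
        means[label] = m
        covs[label] = np.stack([np.diag(np.exp(np.clip(lv[g], -30, 30)))
                                for g in range(G)])
    return replace(
        template, weights=weights, means=means, covariances=covs,
        loglik_trace={}, covariance_type="diag",
    )


def hybrid_gmm_fit(
    features: FeatureMatrix,
    optimizer: str = "fpo",
    params: object | None = None,
    targets: TargetScheme = TargetScheme(),
    seed: int = 0,
    n_components: int = 2,
    perturb: float = 0.1,
) -> HybridGMMModel:
    """Tune a diagonal-covariance GMM with PSO, firefly or FPO.

    The decision vector flattens, per class, the component means, the log of
    the diagonal covariances and the mixture-weight logits.  The fitness is
    the MSE between the model's continuous scores on the training samples
    and the per-sample class targets.  The optimizer population is seeded
    around the EM solution (which is itself one individual), and the elitist
    archive guarantees the returned model's training MSE never exceeds the
    EM initialization's.
    """
    check_targets(targets)
    if optimizer not in _OPTIMIZERS:
        raise ConfigurationError(
            f"unknown optimizer '{optimizer}'; choose from {sorted(_OPTIMIZERS)}"
        )
    opt_fn, params_cls = _OPTIMIZERS[optimizer]
    if params is None:
        params = params_cls()

    base = gmm_fit(features, n_components, seed=seed, covariance_type="diag")
    theta0 = _encode(base)
    X = features.values
    sample_targets = targets.target_for(features.label_array())

    def fitness(theta: np.ndarray) -> float:
        model = _decode(theta, base)
        _, _, scores = gmm_predict(model, X, targets)
        return float(np.mean((scores - sample_targets) ** 2))

    em_mse = fitness(theta0)
    if getattr(params, "max_iter") == 0:
        return HybridGMMModel(
            base=base, model=base, optimizer=optimizer, params=params,
            theta=theta0, trace=np.array([em_mse]),
            train_mse=em_mse, em_mse=em_mse,
        )

    # per-coordinate scales: feature spread for means, fixed for log-terms
    G, D = n_components, features.n_features
    feat_scale = np.maximum(X.std(axis=0), 1e-3)
    scale_parts = []
    for _label in base.classes:
        scale_parts.append(np.tile(feat_scale, G))       # means
        scale_parts.append(np.full(G * D, 2.0))          # log variances
        scale_parts.append(np.full(G, 2.0))              # weight logits
    scale = np.concatenate(scale_parts)
    bounds = Bounds(theta0 - 3.0 * scale, theta0 + 3.0 * scale)

    rng = np.random.default_rng(seed)
    n_pop = getattr(params, "population")
    init = theta0 + perturb * scale * rng.standard_normal((n_pop, theta0.size))
    init[0] = theta0
    init = np.clip(init, bounds.lower, bounds.upper)

    result = opt_fn(fitness, bounds, params, seed=seed, init_positions=init)
    best_model = _decode(result.best_position, base)
    return HybridGMMModel(
        base=base, model=best_model, optimizer=optimizer, params=params,
        theta=result.best_position, trace=result.trace,
        train_mse=float(result.best_fitness), em_mse=em_mse,
    )


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DFAConfig:
    """Scale ladder: integer windows from ``min_window`` up to length/4 in
    geometric steps of ``scale_ratio``; linear detrending; 50% overlap."""

    scale_ratio: float = 1.6
    poly_order: int = 1
    overlap: float = 0.5
    min_window: int = 4


@dataclass
class DFAResult:
    exponent: float
    degenerate: bool
    scales: np.ndarray
    fluctuations: np.ndarray


def _scale_ladder(n_points: int, config: DFAConfig) -> np.ndarray:
    top = n_points // 4
    scales = []
    n = config.min_window
    while n <= top:
        scales.append(n)
        n = max(n + 1, int(round(n * config.scale_ratio)))
    return np.asarray(scales, dtype=int)


def dfa_exponent(series: np.ndarray, config: DFAConfig = DFAConfig()) -> DFAResult:
    """Detrended fluctuation analysis scaling exponent.

    Integrates the mean-removed series into a profile, computes the RMS of
    linearly detrended profile fluctuations in overlapping windows at each
    ladder scale, and fits the log–log slope.  White noise gives ≈ 0.5,
    integrated white noise (a random walk) ≈ 1.5.  An all-constant series has
    a zero profile; the result is exponent 0 with the ``degenerate`` flag set.
    """
    x = np.asarray(series, dtype=float).ravel()
    scales = _scale_ladder(x.size, config)
    if x.size < 4 * config.min_window or scales.size < 2:
        raise ValidationError(
            f"series of length {x.size} is too short for DFA "
            f"(need >= {4 * config.min_window} points and >= 2 ladder scales)"
        )
    profile = np.cumsum(x - x.mean())
    flucts = np.zeros(scales.size)
    for s_i, n in enumerate(scales):
        step = max(1, int(round(n * (1.0 - config.overlap))))
        starts = np.arange(0, x.size - n + 1, step)
        W = np.stack([profile[s : s + n] for s in starts])
        t = np.arange(n, dtype=float)
        A = np.vander(t, config.poly_order + 1)
        # residual-maker matrix: projects out the polynomial trend
        Q = np.eye(n) - A @ np.linalg.solve(A.T @ A, A.T)
        resid = W @ Q.T
        flucts[s_i] = math.sqrt(float(np.mean(resid**2)))
    valid = flucts > 0
    if valid.sum() < 2:
        return DFAResult(0.0, True, scales, flucts)
    slope = np.polyfit(np.log(scales[valid]), np.log(flucts[valid]), 1)[0]
    return DFAResult(float(slope), False, scales, flucts)


def dfa_classify(
    train_X: np.ndarray,
    train_labels: np.ndarray,
    test_X: np.ndarray,
    config: DFAConfig = DFAConfig(),
) -> np.ndarray:
    """Nearest-class-mean rule on per-sample DFA exponents.

    Each sample's feature vector is treated as a series; the per-class mean
    exponent is learned from training samples and a test sample takes the
    class whose mean exponent is nearer.  Exact midpoints and equal class
    means resolve toward cancer (sensitivity-first).
    """
    train_labels = np.asarray(train_labels, dtype=object)
    exps = np.array([dfa_exponent(row, config).exponent for row in np.atleast_2d(train_X)])
    mean_c = exps[train_labels == CANCER].mean()
    mean_n = exps[train_labels == NORMAL].mean()
    if mean_c == mean_n:
        warnings.warn(
            "class mean DFA exponents are equal; all samples assigned to cancer"
        )
        return np.full(np.atleast_2d(test_X).shape[0], CANCER, dtype=object)
    out = []
    for row in np.atleast_2d(test_X):
        e = dfa_exponent(row, config).exponent
        d_c, d_n = abs(e - mean_c), abs(e - mean_n)
        out.append(CANCER if d_c <= d_n else NORMAL)
    return np.asarray(out, dtype=object)


# ---------------------------------------------------------------------------
# Gaussian naive Bayes
# ---------------------------------------------------------------------------

def nbc_fit_predict(
    train_X: np.ndarray,
    train_labels: np.ndarray,
    test_X: np.ndarray,
    alpha: float = 0.06,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian naive Bayes with a variance floor.

    Per-feature class-conditional Gaussians; every variance is floored at
    ``alpha`` times the largest per-feature variance in the training data
    (the smoothing that keeps zero-variance features finite).  Posteriors
    are computed in log space; returns ``(labels, posteriors)`` with
    posterior columns ordered (cancer, normal) and ties toward cancer.
    """
    if alpha < 0:
        raise ValidationError("smoothing alpha must be >= 0")
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    labels = np.asarray(train_labels, dtype=object)
    floor = alpha * float(np.max(train_X.var(axis=0))) if train_X.size else 0.0
    log_post = np.zeros((test_X.shape[0], 2))
    for c, label in enumerate(CLASS_ORDER):
        Xc = train_X[labels == label]
        if Xc.shape[0] == 0:
            raise ValidationError(f"no training samples of class '{label}'")
        mu = Xc.mean(axis=0)
        var = np.maximum(Xc.var(axis=0), floor)
        if np.any(var <= 0):
            raise NumericalError(
                "zero-variance feature encountered with alpha=0; "
                "use a smoothing alpha > 0"
            )
        log_post[:, c] = math.log(Xc.shape[0] / train_X.shape[0]) - 0.5 * np.sum(
            (test_X - mu) ** 2 / var + np.log(2 * np.pi * var), axis=1
        )
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    pred = np.where(post[:, 0] >= post[:, 1], CANCER, NORMAL).astype(object)
    return pred, post


# ---------------------------------------------------------------------------
# SVM with RBF kernel (SMO)
# ---------------------------------------------------------------------------

def svm_rbf_kernel(x: np.ndarray, z: np.ndarray, sigma: float) -> float:
    """Gaussian RBF similarity exp(−‖x−z‖² / (2σ²)), always in (0, 1]."""
    if sigma <= 0:
        raise ValidationError("kernel width sigma must be > 0")
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.size != z.size:
        raise ValidationError("kernel arguments must have equal dimensionality")
    return float(np.exp(-np.sum((x - z) ** 2) / (2.0 * sigma**2)))


def _rbf_gram(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * sigma**2))


@dataclass
class SVMModel:
    alphas: np.ndarray
    y: np.ndarray           # ±1, cancer = +1
    X: np.ndarray
    b: float
    sigma: float
    C: float

    def decision(self, test_X: np.ndarray) -> np.ndarray:
        K = _rbf_gram(self.X, np.atleast_2d(test_X), self.sigma)
        return (self.alphas * self.y) @ K + self.b


class SVMConvergenceError(RuntimeError):
    def __init__(self, message: str, n_iterations: int):
        super().__init__(message)
        self.n_iterations = n_iterations


def svm_fit(
    train_X: np.ndarray,
    y: np.ndarray,
    sigma: float = 0.1,
    C: float = 1.0,
    tol: float = 1e-5,
    max_passes: int = 20,
    max_iterations: int = 20_000,
    seed: int = 0,
) -> SVMModel:
    """Soft-margin RBF SVM trained by SMO-style pairwise optimization.

    Iterates over KKT-violating multipliers (violation tolerance ``tol``),
    pairing each with a random partner; stops after ``max_passes`` sweeps
    without any update.  The updates keep ``0 <= alpha_i <= C`` and
    ``sum alpha_i y_i = 0`` exactly.
    """
    if sigma <= 0:
        raise ValidationError("kernel width sigma must be > 0")
    X = np.atleast_2d(np.asarray(train_X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValidationError("labels must contain both classes (encoded ±1)")
    rng = np.random.default_rng(seed)
    K = _rbf_gram(X, X, sigma)
    alphas = np.zeros(n)
    b = 0.0
    passes = 0
    iters = 0
    while passes < max_passes:
        iters += 1
        if iters > max_iterations:
            raise SVMConvergenceError(
                f"SMO did not converge within {max_iterations} sweeps "
                f"(tol={tol}, C={C}, sigma={sigma})",
                n_iterations=iters,
            )
        changed = 0
        f = (alphas * y) @ K + b
        for i in range(n):
            Ei = f[i] - y[i]
            if (y[i] * Ei < -tol and alphas[i] < C) or (
                y[i] * Ei > tol and alphas[i] > 0
            ):
                j = int(rng.integers(n - 1))
                if j >= i:
                    j += 1
                Ej = f[j] - y[j]
                ai_old, aj_old = alphas[i], alphas[j]
                if y[i] != y[j]:
                    L, H = max(0.0, aj_old - ai_old), min(C, C + aj_old - ai_old)
                else:
                    L, H = max(0.0, ai_old + aj_old - C), min(C, ai_old + aj_old)
                if L >= H:
                    continue
                eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
                if eta >= 0:
                    continue
                aj = np.clip(aj_old - y[j] * (Ei - Ej) / eta, L, H)
                if abs(aj - aj_old) < 1e-7:
                    continue
                ai = ai_old + y[i] * y[j] * (aj_old - aj)
                alphas[i], alphas[j] = ai, aj
                b1 = b - Ei - y[i] * (ai - ai_old) * K[i, i] - y[j] * (
                    aj - aj_old
                ) * K[i, j]
                b2 = b - Ej - y[i] * (ai - ai_old) * K[i, j] - y[j] * (
                    aj - aj_old
                ) * K[j, j]
                if 0 < ai < C:
                    b = b1
                elif 0 < aj < C:
                    b = b2
                else:
                    b = (b1 + b2) / 2.0
                f = (alphas * y) @ K + b
                changed += 1
        passes = passes + 1 if changed == 0 else 0
    return SVMModel(alphas=alphas, y=y, X=X, b=b, sigma=sigma, C=C)


def svm_fit_predict(
    train_X: np.ndarray,
    train_labels: np.ndarray,
    test_X: np.ndarray,
    sigma: float = 0.1,
    C: float = 1.0,
    tol: float = 1e-5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SVMModel]:
    """Train an RBF SVM (cancer = +1) and predict test labels.

    Returns ``(labels, decision_values, model)``; the label is the sign of
    the decision value with zero resolving toward cancer.
    """
    labels = np.asarray(train_labels, dtype=object)
    y = np.where(labels == CANCER, 1.0, -1.0)
    model = svm_fit(train_X, y, sigma=sigma, C=C, tol=tol, seed=seed)
    dec = model.decision(test_X)
    pred = np.where(dec >= 0, CANCER, NORMAL).astype(object)
    return pred, dec, model
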
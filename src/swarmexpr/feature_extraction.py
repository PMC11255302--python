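"""Dimensionality reduction of expression matrices: STFT, LASSO and EHO.

Three routes from a 2000-gene intensity vector per sample down to a handful
of features:

* **STFT** — treat each sample's gene-intensity vector (in input gene order)
  as a sequence, slide a Blackman-windowed discrete Fourier transform along
  it, and summarise each frame's magnitude spectrum with a small statistic
  set.  A spectral, unsupervised reduction.
* **LASSO** — L1-penalized least squares of the ±1 class label on the
  standardized gene intensities, solved by cyclic coordinate descent; genes
  with nonzero coefficients are retained (embedded selection).
* **EHO** — wrapper selection: elephant-herding optimization searches
  continuous gene scores in [0,1]^p; the top-scoring subset is evaluated by
  the training MSE of a one-Gaussian-per-class scorer against the class
  targets, and the best subset wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .core_data import CANCER, NORMAL, ExpressionDataset, ValidationError
from .metaheuristics import Bounds, EHOParams, eho_optimize

__all__ = [
    "STFTConfig",
    "LassoConfig",
    "EHOFeatureConfig",
    "FeatureMatrix",
    "blackman_window",
    "stft",
    "stft_features",
    "lasso_fit",
    "lasso_path",
    "lasso_features",
    "eho_features",
]

STAT_NAMES = ("mean_abs", "max_abs", "energy")


@dataclass
class FeatureMatrix:
    """samples × features output of an extractor, with provenance."""

    values: np.ndarray
    feature_names: list[str]
    method: str
    params: dict
    labels: list[str]
    selected_gene_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature values must be 2-D (samples × features)")
        if self.values.shape[0] != len(self.labels):
            raise ValidationError("feature rows must align with sample labels")
        if self.values.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names must match the feature count")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


@dataclass(frozen=True)
class STFTConfig:
    window_length: int = 256
    hop: int | None = None  # defaults to window_length // 2
    aggregation: tuple[str, ...] = STAT_NAMES
    window: str = "blackman"  # or "rectangular"
    zero_pad: bool = True

    def resolved_hop(self) -> int:
        return self.window_length // 2 if self.hop is None else self.hop

    def validate(self) -> None:
        if self.window_length < 1:
            raise ValidationError("window_length must be >= 1")
        hop = self.resolved_hop()
        if not (0 < hop <= self.window_length):
            raise ValidationError("hop must satisfy 0 < hop <= window_length")
        unknown = set(self.aggregation) - set(STAT_NAMES)
        if unknown:
            raise ValidationError(f"unknown aggregation statistics {sorted(unknown)}")
        if self.window not in ("blackman", "rectangular"):
            raise ValidationError(f"unknown window '{self.window}'")


@dataclass(frozen=True)
class LassoConfig:
    lambda_grid: tuple[float, ...] | None = None  # default: 50-pt log grid
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 10
    tol: float = 1e-6
    max_iter: int = 10_000
    target_n_features: int | None = None


@dataclass(frozen=True)
class EHOFeatureConfig:
    n_select: int = 30
    eho_params: EHOParams = field(default_factory=EHOParams)


# ---------------------------------------------------------------------------
# STFT
# ---------------------------------------------------------------------------

def blackman_window(M: int) -> np.ndarray:
    """Blackman taper w[n] = 0.42 − 0.5·cos(2πn/M) + 0.08·cos(4πn/M)."""
    if M < 1:
        raise ValidationError("window length M must be >= 1")
    n = np.arange(M)
    return 0.42 - 0.5 * np.cos(2 * np.pi * n / M) + 0.08 * np.cos(4 * np.pi * n / M)


def _frame_starts(length: int, M: int, hop: int, zero_pad: bool) -> np.ndarray:
    if length <= M:
        return np.array([0])
    if zero_pad:
        n_frames = math.ceil((length - M) / hop) + 1
    else:
        n_frames = (length - M) // hop + 1
    return np.arange(n_frames) * hop


def stft(signal: np.ndarray, config: STFTConfig = STFTConfig()) -> np.ndarray:
    """Short-time Fourier transform: rows are frame spectra (full DFT of the
    windowed slice), frame t starting at ``t · hop``.  With ``zero_pad`` the
    tail is padded with zeros so the final partial frame is included."""
    config.validate()
    x = np.asarray(signal, dtype=float).ravel()
    if x.size == 0:
        raise ValidationError("empty signal")
    M, hop = config.window_length, config.resolved_hop()
    if x.size < M and not config.zero_pad:
        raise ValidationError(
            f"signal length {x.size} < window {M} and zero padding is disabled"
        )
    starts = _frame_starts(x.size, M, hop, config.zero_pad)
    needed = int(starts[-1]) + M
    if needed > x.size:
        x = np.concatenate([x, np.zeros(needed - x.size)])
    w = blackman_window(M) if config.window == "blackman" else np.ones(M)
    frames = np.stack([x[s : s + M] for s in starts]) * w
    return np.fft.fft(frames, axis=1)


def stft_features(
    dataset: ExpressionDataset, config: STFTConfig = STFTConfig()
) -> FeatureMatrix:
    """Per sample: STFT of its gene-intensity vector, then per-frame
    aggregation statistics of |X| (mean, max, spectral energy by default)."""
    config.validate()
    if dataset.n_genes < config.window_length and not config.zero_pad:
        raise ValidationError(
            f"window {config.window_length} exceeds gene count {dataset.n_genes} "
            "and zero padding is disabled"
        )
    stats = config.aggregation
    rows = []
    n_frames = None
    for s in range(dataset.n_samples):
        spec = np.abs(stft(dataset.values[:, s], config))
        n_frames = spec.shape[0]
        parts = []
        for t in range(n_frames):
            frame = spec[t]
            for stat in stats:
                if stat == "mean_abs":
                    parts.append(frame.mean())
                elif stat == "max_abs":
                    parts.append(frame.max())
                else:  # energy
                    parts.append(float(np.sum(frame**2)))
        rows.append(parts)
    names = [
        f"frame{t:02d}_{stat}" for t in range(n_frames) for stat in stats
    ]
    return FeatureMatrix(
        values=np.asarray(rows),
        feature_names=names,
        method="stft",
        params={
            "window_length": config.window_length,
            "hop": config.resolved_hop(),
            "aggregation": list(stats),
            "window": config.window,
            "zero_pad": config.zero_pad,
        },
        labels=dataset.labels,
    )


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_sweep_py(X, r, beta, col_sq, lam, indices):
    """One cyclic coordinate-descent sweep; updates beta and the residual r
    in place and returns the largest coefficient change."""
    n = X.shape[0]
    max_delta = 0.0
    for j in indices:
        cj = col_sq[j]
        if cj <= 0.0:
            continue
        rho = X[:, j] @ r / n + cj * beta[j]
        if rho > lam:
            new = (rho - lam) / cj
        elif rho < -lam:
            new = (rho + lam) / cj
        else:
            new = 0.0
        delta = new - beta[j]
        if delta != 0.0:
            r -= X[:, j] * delta
            beta[j] = new
            if abs(delta) > max_delta:
                max_delta = abs(delta)
    return max_delta


try:  # jit-compiled sweep: the path over a 50-point grid × CV folds is hot
    import numba as _numba

    _cd_sweep = _numba.njit(cache=False, fastmath=False)(_cd_sweep_py)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _cd_sweep = _cd_sweep_py


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    config: LassoConfig = LassoConfig(),
    beta0: np.ndarray | None = None,
) -> np.ndarray:
    """Cyclic coordinate descent for (1/(2n))‖y − Xβ‖² + λ‖β‖₁.

    Columns of X must be centered (mean within 1e-8 of 0); each coordinate
    update is the closed-form soft threshold, and convergence is declared
    when the largest coefficient change in a sweep drops below ``tol``.
    After the first full sweep, descent cycles over the active (nonzero) set
    with periodic full sweeps to admit new coordinates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValidationError("X and y have incompatible shapes")
    col_means = X.mean(axis=0)
    if np.max(np.abs(col_means)) > 1e-8:
        raise ValidationError(
            "X columns must be centered to mean 0 (max |mean| = "
            f"{np.max(np.abs(col_means)):.3g})"
        )
    if lam < 0:
        raise ValidationError("lambda must be >= 0")

    Xc = np.asfortranarray(X, dtype=float)  # column slices contiguous for the sweep
    col_sq = np.einsum("ij,ij->j", Xc, Xc) / n  # (1/n)·x_jᵀx_j
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    r = np.ascontiguousarray(y - Xc @ beta)

    def sweep(indices: np.ndarray) -> float:
        return _cd_sweep(Xc, r, beta, col_sq, float(lam), indices)

    all_idx = np.arange(p)
    for it in range(config.max_iter):
        full = it == 0 or it % 10 == 9
        idx = all_idx if full else np.flatnonzero(beta)
        if idx.size == 0:
            idx = all_idx
            full = True
        max_delta = sweep(idx)
        if max_delta < config.tol and full:
            break
        if max_delta < config.tol and not full:
            # converged on the active set; confirm with a full sweep
            if sweep(all_idx) < config.tol:
                break
    return beta


def lasso_path(
    X: np.ndarray, y: np.ndarray, grid: np.ndarray, config: LassoConfig
) -> np.ndarray:
    """Warm-started coefficient path over a descending λ grid (len(grid) × p)."""
    betas = np.zeros((grid.size, X.shape[1]))
    beta = None
    for i, lam in enumerate(grid):
        beta = lasso_fit(X, y, lam, config, beta0=beta)
        betas[i] = beta
    return betas


def _default_grid(X: np.ndarray, y: np.ndarray, config: LassoConfig) -> np.ndarray:
    if config.lambda_grid is not None:
        grid = np.asarray(config.lambda_grid, dtype=float)
        if np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
            raise ValidationError("lambda_grid must be strictly positive and descending")
        return grid
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ y)) / n
    if lam_max <= 0:
        raise ValidationError("degenerate response: max |Xᵀy| is zero")
    return np.geomspace(lam_max, config.lambda_min_ratio * lam_max, config.n_lambda)


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


def lasso_features(
    dataset: ExpressionDataset, config: LassoConfig = LassoConfig()
) -> FeatureMatrix:
    """Select genes with nonzero LASSO coefficients for the ±1 class label.

    λ is chosen by ``cv_folds``-fold cross-validated squared error over the
    grid (deterministic stratified folds), or — when ``target_n_features``
    is set — as the smallest grid λ whose refit keeps at most that many
    genes.  The returned features are the raw intensities of the selected
    genes in ascending gene order.
    """
    labels = dataset.label_array()
    y_raw = np.where(labels == CANCER, 1.0, -1.0)
    if np.unique(y_raw).size < 2:
        raise ValidationError("degenerate response: labels are constant")
    X = _standardize_columns(dataset.values.T)  # samples × genes
    y = y_raw - y_raw.mean()
    grid = _default_grid(X, y, config)

    if config.target_n_features is not None:
        betas = lasso_path(X, y, grid, config)
        nnz = (betas != 0).sum(axis=1)
        ok = np.flatnonzero(nnz <= config.target_n_features)
        if ok.size == 0 or nnz[ok].max() == 0:
            raise ValidationError(
                "no grid point selects a nonzero set of at most "
                f"{config.target_n_features} features"
            )
        # smallest λ (grid is descending, so the last qualifying index)
        nonzero_ok = ok[nnz[ok] > 0]
        best_beta = betas[nonzero_ok[-1]]
    else:
        # deterministic stratified K folds by index order within each class
        folds = _stratified_folds(labels, config.cv_folds)
        cv_err = np.zeros(grid.size)
        for val_idx in folds:
            tr_idx = np.setdiff1d(np.arange(X.shape[0]), val_idx)
            Xtr = X[tr_idx] - X[tr_idx].mean(axis=0)
            ytr = y[tr_idx] - y[tr_idx].mean()
            Xva = X[val_idx] - X[tr_idx].mean(axis=0)
            yva = y[val_idx] - y[tr_idx].mean()
            betas = lasso_path(Xtr, ytr, grid, config)
            pred = betas @ Xva.T  # grid × n_val
            cv_err += np.mean((pred - yva) ** 2, axis=1)
        best_beta = lasso_path(X, y, grid, config)[int(np.argmin(cv_err))]

    selected = np.flatnonzero(best_beta)
    if selected.size == 0:
        raise ValidationError(
            "all coefficients are zero over the whole grid; "
            "lower lambda_min_ratio or supply a smaller lambda_grid floor"
        )
    return FeatureMatrix(
        values=dataset.values[selected].T,
        feature_names=[dataset.gene_ids[i] for i in selected],
        method="lasso",
        params={
            "cv_folds": config.cv_folds,
            "n_lambda": grid.size,
            "target_n_features": config.target_n_features,
        },
        labels=dataset.labels,
        selected_gene_indices=selected,
    )


def _stratified_folds(labels: np.ndarray, k: int) -> list[np.ndarray]:
    """Deterministic stratified folds: per class, deal indices round-robin."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in (CANCER, NORMAL):
        idx = np.flatnonzero(labels == label)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.asarray(sorted(f), dtype=int) for f in folds if f]


# ---------------------------------------------------------------------------
# EHO wrapper selection
# ---------------------------------------------------------------------------

def _gaussian_scorer_mse(
    Z: np.ndarray, is_cancer: np.ndarray, t_cancer: float = 0.1, t_normal: float = 0.85
) -> float:
    """Training MSE of a one-diagonal-Gaussian-per-class scorer.

    Fits a diagonal Gaussian per class on the candidate feature block Z
    (samples × features, standardized), scores each sample by the
    posterior-weighted combination of the class targets, and returns the MSE
    against each sample's own class target.  Cheap enough to serve as a
    wrapper fitness evaluated thousands of times.
    """
    eps = 1e-6
    out_log = np.zeros((Z.shape[0], 2))
    for c, mask in enumerate((is_cancer, ~is_cancer)):
        mu = Z[mask].mean(axis=0)
        var = Z[mask].var(axis=0) + eps
        out_log[:, c] = (
            -0.5 * np.sum((Z - mu) ** 2 / var + np.log(2 * np.pi * var), axis=1)
            + math.log(mask.mean())
        )
    out_log -= out_log.max(axis=1, keepdims=True)
    post = np.exp(out_log)
    post /= post.sum(axis=1, keepdims=True)
    score = post[:, 0] * t_cancer + post[:, 1] * t_normal
    target = np.where(is_cancer, t_cancer, t_normal)
    return float(np.mean((score - target) ** 2))


def eho_features(
    dataset: ExpressionDataset,
    config: EHOFeatureConfig = EHOFeatureConfig(),
    seed: int = 0,
) -> FeatureMatrix:
    """Wrapper gene selection by elephant-herding optimization.

    Each optimizer position is a vector of continuous scores in
    [0,1]^n_genes; the candidate subset is the ``n_select`` highest-scoring
    genes (ties broken by lower gene index) and the fitness is the training
    MSE of the inner one-Gaussian-per-class scorer on that subset.  The
    returned features are raw intensities of the best subset found.
    """
    p = dataset.n_genes
    if not (1 <= config.n_select <= p):
        raise ValidationError(f"n_select must lie in [1, {p}]")
    Z = _standardize_columns(dataset.values.T)
    is_cancer = dataset.label_array() == CANCER

    def top_k(scores: np.ndarray) -> np.ndarray:
        # stable: higher score wins, lower index breaks ties
        order = np.lexsort((np.arange(p), -scores))
        return np.sort(order[: config.n_select])

    if config.n_select == p:
        selected = np.arange(p)
    else:
        def fitness(position: np.ndarray) -> float:
            return _gaussian_scorer_mse(Z[:, top_k(position)], is_cancer)

        bounds = Bounds(np.zeros(p), np.ones(p))
        result = eho_optimize(fitness, bounds, config.eho_params, seed=seed)
        selected = top_k(result.best_position)

    return FeatureMatrix(
        values=dataset.values[selected].T,
        feature_names=[dataset.gene_ids[i] for i in selected],
        method="eho",
        params={
            "n_select": config.n_select,
            "population": config.eho_params.population,
            "max_iter": config.eho_params.max_iter,
        },
        labels=dataset.labels,
        selected_gene_indices=selected,
    )
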
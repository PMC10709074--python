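"""Relief feature weighting, per-period top-k union, table PCA, image-cube PCA.

The feature-selection stage ranks simple-ratio indices with a deterministic
full-pass ReliefF: every instance in turn contributes, for each feature, the
mean normalized difference to its k nearest different-class neighbours
("misses") minus that to its k nearest same-class neighbours ("hits"):

    w_f += sum_miss diff(f, x, miss) / (m k)  -  sum_hit diff(f, x, hit) / (m k)

on min-max normalized features with Euclidean neighbourhoods.  Features that
separate the classes locally accumulate positive weight; pure-noise features
hover near zero.

Dimensionality reduction uses PCA twice: on the scalar feature table, and on
the image cube — every fused stack is unfolded to (masked pixels x 30
channels), pixels from all training samples are pooled, channels are z-scored
and a single global PCA is fitted.  Score vectors of the retained components
fold back into per-sample score images; the explained-variance ratios of those
components are the "contributions" that later apportion stem kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .errors import SaltSpecError, ShapeMismatchError
from .imaging_io import FeatureTable
from .spectral_features import FusedStack

# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

@dataclass
class ReliefResult:
    """Feature weights from one ReliefF pass."""

    weights: dict[str, float]
    k_neighbors: int
    n_iterations: int
    seed: int = 0

    def top_k(self, k: int) -> list[str]:
        """Feature names of the k highest weights (ties by name order)."""
        if k > len(self.weights):
            raise SaltSpecError(f"k={k} exceeds feature count {len(self.weights)}")
        ranked = sorted(self.weights.items(), key=lambda kv: (-kv[1], kv[0]))
        return [name for name, _ in ranked[:k]]


def relief_weights(table: FeatureTable, k: int = 10, seed: int = 0,
                   columns=None) -> ReliefResult:
    """Deterministic full-pass ReliefF weights for binary-class tables.

    All m instances are visited once (no sampling; ``seed`` is recorded for
    provenance only).  Features are min-max normalized internally, so the
    per-feature difference is |x1 - x2| on the normalized scale.
    """
    names = list(columns) if columns is not None else table.feature_names
    X = table.df[names].to_numpy(dtype=np.float64)
    y = table.class_labels
    classes = np.unique(y)
    if len(classes) != 2:
        raise SaltSpecError(f"ReliefF requires exactly 2 classes, got {len(classes)}")
    for c in classes:
        if (y == c).sum() < 2:
            raise SaltSpecError(f"class {c!r} has fewer than 2 samples")
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    span[span == 0] = 1.0       # constant features contribute 0 everywhere
    Xn = (X - lo) / span
    m, n_feat = Xn.shape
    dist = cdist(Xn, Xn, metric="euclidean")
    np.fill_diagonal(dist, np.inf)
    weights = np.zeros(n_feat)
    for i in range(m):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        other = np.flatnonzero(y != y[i])
        k_hit = min(k, len(same))
        k_miss = min(k, len(other))
        hits = same[np.argsort(dist[i, same], kind="stable")[:k_hit]]
        misses = other[np.argsort(dist[i, other], kind="stable")[:k_miss]]
        weights += np.abs(Xn[misses] - Xn[i]).sum(axis=0) / (m * k_miss)
        weights -= np.abs(Xn[hits] - Xn[i]).sum(axis=0) / (m * k_hit)
    return ReliefResult(
        weights=dict(zip(names, weights.tolist())),
        k_neighbors=k,
        n_iterations=m,
        seed=seed,
    )


def select_union_top_k(per_period_weights: list[ReliefResult], k: int = 5) -> list[str]:
    """Union of per-period top-k features, sorted by name.

    With the three treatment periods and k=5 this reproduces the 11-parameter
    SR subset used downstream.
    """
    if not per_period_weights:
        raise SaltSpecError("need at least one ReliefResult")
    feature_sets = [set(r.weights) for r in per_period_weights]
    if any(fs != feature_sets[0] for fs in feature_sets[1:]):
        raise SaltSpecError("all ReliefResults must cover the same feature set")
    selected: set[str] = set()
    for result in per_period_weights:
        selected.update(result.top_k(k))
    return sorted(selected)


# ---------------------------------------------------------------------------
# PCA (feature tables and image cubes)
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Standardization statistics + loadings + explained-variance ratios.

    ``loadings`` is (channels x components) with orthonormal columns; signs
    are fixed so each column's largest-magnitude entry is positive.
    """

    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    evr: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.scales = np.asarray(self.scales, dtype=np.float64)
        self.loadings = np.asarray(self.loadings, dtype=np.float64)
        self.evr = np.asarray(self.evr, dtype=np.float64)
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise SaltSpecError("loadings columns are not orthonormal")
        if np.any(np.diff(self.evr) > 1e-12) or np.any(self.evr < -1e-12):
            raise SaltSpecError("explained-variance ratios must be non-increasing, >= 0")
        if self.evr.sum() > 1 + 1e-9:
            raise SaltSpecError("explained-variance ratios sum above 1")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) / self.scales

    def transform(self, X: np.ndarray, retain: int | None = None) -> np.ndarray:
        r = self.n_components if retain is None else retain
        return self.standardize(X) @ self.loadings[:, :r]

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        r = scores.shape[1]
        return scores @ self.loadings[:, :r].T * self.scales + self.means


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude loading entry positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


def _fit_standardized_pca(X: np.ndarray, channel_names: list[str],
                          standardize: bool) -> PCAModel:
    means = X.mean(axis=0)
    if standardize:
        scales = X.std(axis=0, ddof=0)
    else:
        scales = np.ones(X.shape[1])
    Z = (X - means) / scales
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(Z)
    loadings = _fix_signs(pca.components_.T)
    return PCAModel(
        means=means,
        scales=scales,
        loadings=loadings,
        evr=pca.explained_variance_ratio_,
        channel_names=channel_names,
    )


def fit_table_pca(table: FeatureTable, standardize: bool = True,
                  columns=None) -> PCAModel:
    """Z-score + PCA on the scalar feature table (zero-variance columns dropped)."""
    names = list(columns) if columns is not None else table.feature_names
    X = table.df[names].to_numpy(dtype=np.float64)
    if X.shape[0] < 2:
        raise SaltSpecError("table PCA requires at least 2 rows")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance columns before PCA: {dropped}")
        names = [n for n, k in zip(names, keep) if k]
        X = X[:, keep]
    return _fit_standardized_pca(X, names, standardize)


def fit_cube_pca(stacks) -> PCAModel:
    """Global PCA on masked pixels pooled from all training fused stacks.

    Pixels are pooled into one (n_pixels x n_channels) matrix, z-scored per
    channel, and decomposed once, so the explained-variance contributions are
    dataset-level quantities (as required by the stem-kernel allocation).
    ``stacks`` may be any iterable of :class:`FusedStack`; pooled first and
    second moments are accumulated in a streaming pass, so arbitrarily many
    stacks fit in constant memory.  The decomposition equals the
    eigendecomposition of the pooled correlation matrix.
    """
    names: list[str] | None = None
    n_px = 0
    s1 = s2 = None
    for stack in stacks:
        if names is None:
            names = stack.channel_names
            c = len(names)
            s1 = np.zeros(c)
            s2 = np.zeros((c, c))
        elif stack.channel_names != names:
            raise SaltSpecError("all stacks must share channel order")
        px = stack.masked_pixels()
        n_px += px.shape[0]
        s1 += px.sum(axis=0)
        s2 += px.T @ px
    if names is None:
        raise SaltSpecError("fit_cube_pca requires at least one stack")
    if n_px == 0:
        raise SaltSpecError("no masked pixels to fit cube PCA")
    means = s1 / n_px
    cov = s2 / n_px - np.outer(means, means)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    keep = sd > 0
    if not keep.all():
        dead = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance channels before cube PCA: {dead}")
        names = [n for n, k in zip(names, keep) if k]
        cov = cov[np.ix_(keep, keep)]
        means, sd = means[keep], sd[keep]
    corr = cov / np.outer(sd, sd)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = _fix_signs(eigvecs[:, order])
    return PCAModel(
        means=means,
        scales=sd,
        loadings=loadings,
        evr=eigvals / eigvals.sum(),
        channel_names=list(names),
    )


@dataclass
class ScoreImageStack:
    """Retained principal-component score images for one sample."""

    images: np.ndarray            # (retain, H, W)
    contributions: np.ndarray     # evr of the retained components
    mask: "np.ndarray | None" = None
    pot_id: str = ""
    view_index: int = 0
    period_days: int = 5
    class_label: str = "control"

    @property
    def n_components(self) -> int:
        return self.images.shape[0]


def unfold(stack: np.ndarray) -> np.ndarray:
    """(C, H, W) image cube -> (H*W, C) pixel matrix (row-major)."""
    c = stack.shape[0]
    return stack.reshape(c, -1).T


def fold(matrix: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """(H*W, C) pixel matrix -> (C, H, W) cube; inverse of :func:`unfold`."""
    return matrix.T.reshape(-1, *shape)


def transform_to_score_images(stack: FusedStack, model: PCAModel,
                              retain: int) -> ScoreImageStack:
    """Project each masked pixel onto the first ``retain`` loadings and fold back."""
    if stack.channel_names != model.channel_names:
        raise SaltSpecError("stack channels do not match the fitted PCA model")
    if retain > model.n_components:
        raise SaltSpecError("retain exceeds the number of fitted components")
    h, w = stack.mask.shape
    out = np.zeros((retain, h, w))
    m = stack.mask.pixels
    scores = model.transform(stack.channels[:, m].T, retain=retain)
    out[:, m] = scores.T
    return ScoreImageStack(
        images=out,
        contributions=model.evr[:retain].copy(),
        mask=m,
        pot_id=stack.pot_id,
        view_index=stack.view_index,
        period_days=stack.period_days,
        class_label=stack.class_label,
    )


def choose_retained(model: PCAModel, threshold: float = 0.95) -> int:
    """Smallest r with cumulative explained variance >= threshold."""
    if not 0 < threshold <= 1:
        raise SaltSpecError("threshold must be in (0, 1]")
    cum = np.cumsum(model.evr)
    idx = np.searchsorted(cum, threshold - 1e-12)
    return int(min(idx + 1, model.n_components))
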
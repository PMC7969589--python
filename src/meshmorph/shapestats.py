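"""Statistics on shape representations (momenta or Procrustes tangent coords).

Kernel PCA for dimension reduction, a stratified k-fold permutation test for
group classification, the scrambled-group overfitting diagnostic, allometry
(common allometric component and size-explained variance) and Bland-Altman
method agreement.

All stochastic operations take explicit seeds and are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from scipy.spatial.distance import pdist

from .errors import ConsistencyError, DegenerateInputError, ParameterError

__all__ = [
    "ShapeScores",
    "PermTestResult",
    "ScrambleResult",
    "AllometryResult",
    "kernel_pca",
    "classify_permutation_test",
    "scrambled_group_test",
    "allometry",
    "bland_altman",
]


# ---------------------------------------------------------------------------
# kernel PCA
# ---------------------------------------------------------------------------


@dataclass
class ShapeScores:
    """Per-subject coordinates in a reduced shape space.

    Columns are ordered by decreasing variance; scores are centred.
    ``explained_variance_ratio`` is each component's share of the total
    kernel variance.
    """

    scores: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    kernel: str = "linear"

    @property
    def n_subjects(self) -> int:
        return len(self.scores)

    @property
    def dim(self) -> int:
        return self.scores.shape[1]


def kernel_pca(
    features: np.ndarray,
    dim: int = 5,
    kernel: str = "linear",
    bandwidth: float | None = None,
) -> ShapeScores:
    """Kernel principal component analysis of per-subject feature vectors.

    The kernel matrix is double-centred and eigendecomposed; scores are
    ``eigenvector * sqrt(eigenvalue)`` for the top ``dim`` components.  With
    the linear kernel this reproduces ordinary PCA scores (up to per-
    component sign).  The Gaussian bandwidth defaults to the median pairwise
    feature distance.
    """
    X = np.asarray(features, float)
    if X.ndim != 2:
        raise ParameterError("features must be a 2-D (subjects x features) array")
    n, p = X.shape
    if n < 3 or p < 1:
        raise ParameterError("need at least 3 subjects and 1 feature")
    if kernel not in ("linear", "gaussian"):
        raise ParameterError("kernel must be 'linear' or 'gaussian'")
    if dim > n - 1:
        warnings.warn(
            f"dim={dim} exceeds n-1={n - 1}; truncating", RuntimeWarning, stacklevel=2
        )
        dim = n - 1
    if kernel == "linear":
        K = X @ X.T
    else:
        if bandwidth is None:
            d = pdist(X)
            bandwidth = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
        D2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        K = np.exp(-D2 / (2.0 * bandwidth**2))
    one = np.full((n, n), 1.0 / n)
    Kc = K - one @ K - K @ one + one @ K @ one
    Kc = (Kc + Kc.T) / 2.0
    vals, vecs = np.linalg.eigh(Kc)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    scores = vecs[:, :dim] * np.sqrt(vals[:dim])
    total = vals.sum()
    ratio = vals[:dim] / total if total > 0 else np.zeros(dim)
    return ShapeScores(scores, vals[:dim], ratio, kernel=kernel)


# ---------------------------------------------------------------------------
# stratified k-fold LDA permutation test
# ---------------------------------------------------------------------------


def _as_binary_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ParameterError(f"exactly two groups required, got {len(classes)}")
    return (y == classes[1]).astype(int), classes


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per sample, preserving class proportions."""
    fold = np.empty(len(y), int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = np.arange(len(idx)) % k
    return fold


def _lda_cv_accuracy(X: np.ndarray, y: np.ndarray, fold: np.ndarray, k: int) -> float:
    """Mean accuracy of a pooled-covariance linear discriminant across folds."""
    correct = 0
    d = X.shape[1]
    ridge = 1e-8
    for f in range(k):
        tr = fold != f
        te = ~tr
        Xtr, ytr = X[tr], y[tr]
        m0 = Xtr[ytr == 0].mean(axis=0)
        m1 = Xtr[ytr == 1].mean(axis=0)
        R0 = Xtr[ytr == 0] - m0
        R1 = Xtr[ytr == 1] - m1
        n_tr = len(Xtr)
        S = (R0.T @ R0 + R1.T @ R1) / max(n_tr - 2, 1)
        S = S + ridge * (np.trace(S) / d + 1.0) * np.eye(d)
        w = np.linalg.solve(S, m1 - m0)
        c = w @ (m0 + m1) / 2.0 - np.log(max((ytr == 1).sum(), 1) / max((ytr == 0).sum(), 1))
        pred = (X[te] @ w > c).astype(int)
        correct += int((pred == y[te]).sum())
    return correct / len(y)


@dataclass
class PermTestResult:
    """Cross-validated accuracy and its permutation null."""

    observed_score: float
    permuted_scores: np.ndarray
    p_value: float


def classify_permutation_test(
    scores: ShapeScores | np.ndarray,
    labels,
    k_folds: int = 5,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermTestResult:
    """Stratified k-fold cross-validated linear-discriminant accuracy with a
    label-permutation null.

    ``p = (#{permuted accuracy >= observed} + 1) / (n_perm + 1)``.  The fold
    structure is redrawn per permutation so the null reflects the full
    procedure.  ``k_folds`` is reduced to the smallest group size if needed.
    """
    X = scores.scores if isinstance(scores, ShapeScores) else np.asarray(scores, float)
    y, _ = _as_binary_labels(labels)
    if len(y) != len(X):
        raise ConsistencyError("labels length must match score rows")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    smallest = min((y == 0).sum(), (y == 1).sum())
    k = int(min(k_folds, smallest))
    if k < 2:
        raise ParameterError("each group needs at least 2 members for k-fold CV")
    rng = np.random.default_rng(seed)
    observed = _lda_cv_accuracy(X, y, _stratified_folds(y, k, rng), k)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        yp = y[rng.permutation(len(y))]
        permuted[i] = _lda_cv_accuracy(X, yp, _stratified_folds(yp, k, rng), k)
    p = (int((permuted >= observed).sum()) + 1) / (n_perm + 1)
    return PermTestResult(float(observed), permuted, float(p))


# ---------------------------------------------------------------------------
# scrambled-group overfitting diagnostic
# ---------------------------------------------------------------------------


@dataclass
class ScrambleResult:
    """Group-difference vector magnitude against randomly scrambled groups.

    ``z_score`` is how many scramble standard deviations the true between-
    group vector magnitude lies from the scramble mean; ``shapiro_p`` checks
    the scramble magnitudes for normality (so the z-score is interpretable).
    """

    true_vector_magnitude: float
    scramble_magnitudes: np.ndarray
    z_score: float
    shapiro_p: float


def scrambled_group_test(
    scores: ShapeScores | np.ndarray,
    labels,
    n_scrambles: int = 1000,
    seed: int | None = None,
) -> ScrambleResult:
    """Compare the observed between-group mean-score vector magnitude with
    group-size-preserving random scrambles of the labels."""
    X = scores.scores if isinstance(scores, ShapeScores) else np.asarray(scores, float)
    y, _ = _as_binary_labels(labels)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ParameterError("each group needs at least 2 members")
    if n_scrambles < 20:
        warnings.warn(
            "fewer than 20 scrambles makes the Shapiro-Wilk check unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    true_mag = float(np.linalg.norm(X[y == 0].mean(axis=0) - X[y == 1].mean(axis=0)))
    n1 = int((y == 1).sum())
    mags = np.empty(n_scrambles)
    for i in range(n_scrambles):
        perm = rng.permutation(len(y))
        g1 = perm[:n1]
        g0 = perm[n1:]
        mags[i] = np.linalg.norm(X[g0].mean(axis=0) - X[g1].mean(axis=0))
    sd = mags.std(ddof=1)
    z = (true_mag - mags.mean()) / sd if sd > 0 else np.inf
    shapiro_p = float(_sps.shapiro(mags).pvalue) if len(mags) >= 3 else np.nan
    return ScrambleResult(true_mag, mags, float(z), shapiro_p)


# ---------------------------------------------------------------------------
# allometry — common allometric component and size-explained variance
# ---------------------------------------------------------------------------


@dataclass
class AllometryResult:
    """Common allometric component (CAC) of a shape sample.

    ``cac_vector`` is the unit shape direction of maximal covariance with
    (log) centroid size; ``cac_scores`` are the per-subject projections on
    it; ``r2_size`` is the proportion of total shape variance explained by
    the multivariate regression of shape on (log) size.
    """

    cac_vector: np.ndarray
    cac_scores: np.ndarray
    r2_size: float
    log_size: bool = True


def allometry(
    shapes: np.ndarray,
    sizes: np.ndarray,
    groups=None,
    log_size: bool = True,
) -> AllometryResult:
    """Allometric shape variation: CAC direction, scores, and size R².

    With ``groups`` the covariance of shape with size is pooled within
    groups (the classical common allometric component); without, it is the
    total-sample covariance.  Size enters as ``log`` centroid size by
    default (``log_size=False`` keeps raw size).
    """
    X = np.asarray(shapes, float)
    s = np.asarray(sizes, float).ravel()
    if X.ndim != 2 or len(s) != len(X):
        raise ConsistencyError("shapes must be (n, p) with one size per row")
    if len(X) < 3:
        raise ParameterError("need at least 3 subjects")
    if np.any(s <= 0):
        raise ParameterError("centroid sizes must be positive")
    x = np.log(s) if log_size else s.copy()

    if groups is not None:
        g = np.asarray(groups)
        Xc = X.copy().astype(float)
        xc = x.copy()
        for lab in np.unique(g):
            m = g == lab
            Xc[m] -= X[m].mean(axis=0)
            xc[m] -= x[m].mean()
    else:
        Xc = X - X.mean(axis=0)
        xc = x - x.mean()

    if not np.any(Xc != 0):
        raise DegenerateInputError("zero shape variance")
    cov = Xc.T @ xc / max(len(X) - 1, 1)
    norm = np.linalg.norm(cov)
    if norm == 0:
        raise DegenerateInputError("shape does not covary with size at all (zero vector)")
    cac = cov / norm
    cac_scores = Xc @ cac

    # multivariate regression of (group-centred) shape on (group-centred) size
    denom = float(xc @ xc)
    if denom == 0:
        raise DegenerateInputError("size has zero variance")
    beta = Xc.T @ xc / denom  # (p,) per-coordinate slope
    fitted = np.outer(xc, beta)
    ss_model = float((fitted**2).sum())
    ss_total = float((Xc**2).sum())
    r2 = ss_model / ss_total if ss_total > 0 else 0.0
    return AllometryResult(cac, cac_scores, float(np.clip(r2, 0.0, 1.0)), log_size)


# ---------------------------------------------------------------------------
# Bland-Altman method agreement
# ---------------------------------------------------------------------------


def bland_altman(
    reference: np.ndarray, other: np.ndarray
) -> tuple[float, float, float, np.ndarray]:
    """Bland-Altman agreement of two per-subject measurements.

    Returns ``(mean_diff, loa_low, loa_high, outliers)`` where the limits of
    agreement are ``mean ± 1.96 sd`` of the differences ``other - reference``
    and ``outliers`` are the indices outside those limits.
    """
    ref = np.asarray(reference, float).ravel()
    oth = np.asarray(other, float).ravel()
    if len(ref) != len(oth):
        raise ParameterError("reference and other must have equal length")
    if len(ref) < 3:
        raise ParameterError("need at least 3 paired measurements")
    diffs = oth - ref
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    outliers = np.flatnonzero((diffs < lo) | (diffs > hi))
    return mean, lo, hi, outliers
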
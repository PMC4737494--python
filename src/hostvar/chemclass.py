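"""Ordination and discriminant analysis of phytochemical profiles.

Two pieces of machinery live here:

* Non-metric multidimensional scaling (NMDS) minimizing Kruskal stress-1 by
  alternating monotone (isotonic) regression of configuration distances on
  observed dissimilarity ranks with SMACOF/Guttman majorization updates,
  best-of-restarts. Stress is reported on the conventional 0-100 scale.

* Multi-class linear discriminant analysis (LDA) via the generalized
  eigen-solution of the between/within scatter problem, with
  proportion-of-trace separation fractions, repeated train/validate
  classification of colonization status, and two Monte-Carlo null models
  (whole-chemotype label permutation and per-compound value permutation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .types import DistanceMatrix, HostvarError

__all__ = [
    "nmds",
    "LdaModel",
    "lda_fit",
    "ValidationResult",
    "resampled_validation",
    "null_validation",
    "discriminant_scores_vs_performance",
]


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = np.sum(d ** 2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _classical_mds(D: np.ndarray, n_dims: int) -> np.ndarray:
    """Principal-coordinates configuration used as a warm start."""
    n = D.shape[0]
    J = np.eye(n) - 1.0 / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:n_dims]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)[None, :]


def _nmds_single(D: np.ndarray, n_dims: int, X0, max_iter: int, tol: float):
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    delta = D[iu]
    order = np.argsort(delta, kind="stable")
    X = X0
    stress_prev = np.inf
    for _ in range(max_iter):
        d = pdist(X)
        # monotone regression of configuration distances on dissimilarity rank;
        # the isotonic fit itself minimizes sum (d - dhat)^2, so no rescaling
        dhat = np.empty_like(d)
        dhat[order] = isotonic_regression(d[order], increasing=True).x
        stress = _stress1(d, dhat)
        if stress_prev - stress < tol:
            stress_prev = min(stress, stress_prev)
            break
        stress_prev = stress
        # Guttman transform with weights 1
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = squareform(-ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B @ X / n
    return X, stress_prev


def nmds(
    dist: DistanceMatrix,
    n_dims: int,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
):
    """Best-of-restarts non-metric MDS.

    Returns ``(coordinates, stress)`` with Kruskal stress-1 on the 0-100
    scale (e.g. 10.5 means stress-1 = 0.105).
    """
    if n_dims < 1:
        raise HostvarError("n_dims must be >= 1")
    if n_dims >= dist.n:
        raise HostvarError(f"n_dims={n_dims} must be < number of points ({dist.n})")
    rng = np.random.default_rng(seed)
    best = (None, np.inf)
    for start in range(n_starts):
        if start == 0:
            X0 = _classical_mds(dist.values, n_dims)  # PCoA warm start
            if not np.isfinite(X0).all() or np.allclose(X0, 0):
                X0 = rng.normal(size=(dist.n, n_dims))
        else:
            X0 = rng.normal(size=(dist.n, n_dims))
        X, s = _nmds_single(dist.values, n_dims, X0, max_iter, tol)
        if s < best[1]:
            best = (X, s)
    return best[0], best[1] * 100.0


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    """Fitted linear discriminant model.

    ``discriminant_axes`` (features x axes) are scaled to unit pooled
    within-class variance; ``proportion_of_trace`` gives each axis's share
    of the between-group separation.
    """

    classes: list
    class_means: np.ndarray            # classes x features
    pooled_within_cov: np.ndarray      # features x features
    discriminant_axes: np.ndarray      # features x axes
    proportion_of_trace: np.ndarray    # per retained axis
    ridge_used: float = 0.0
    priors: np.ndarray = field(default=None)

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, float) @ self.discriminant_axes

    def predict(self, X) -> np.ndarray:
        """Assign by largest class posterior (equal priors by default)."""
        Z = self.transform(X)
        M = self.class_means @ self.discriminant_axes
        # within-class covariance is spherical in discriminant space
        d2 = ((Z[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
        logpost = -0.5 * d2
        if self.priors is not None:
            logpost = logpost + np.log(self.priors)[None, :]
        return np.asarray(self.classes, dtype=object)[np.argmax(logpost, axis=1)]


def lda_fit(X, labels, ridge: float | None = None, priors: str = "equal") -> LdaModel:
    """Fit multi-class LDA by generalized eigendecomposition.

    Solves S_B v = lambda S_W v for the between-/within-class scatter
    matrices; retains min(classes-1, features) axes. A ridge of
    ``ridge * trace(S_W)/p`` is added to S_W when it is singular (default
    factor 1e-6, logged via a warning whenever triggered).
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise HostvarError("features must be finite")
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise HostvarError("LDA needs >= 2 classes")
    n, p = X.shape
    counts = np.bincount(y)
    for c, cnt in zip(classes, counts):
        if cnt < 2:
            raise HostvarError(f"class {c!r} has < 2 samples")
    means = np.vstack([X[y == k].mean(axis=0) for k in range(len(classes))])
    grand = X.mean(axis=0)
    Xc = X - means[y]
    S_W = Xc.T @ Xc
    Mc = (means - grand) * np.sqrt(counts)[:, None]
    S_B = Mc.T @ Mc

    ridge_used = 0.0
    base = ridge if ridge is not None else 1e-6
    eigw = scipy.linalg.eigvalsh(S_W)
    if eigw[0] <= 1e-10 * max(eigw[-1], 1.0):
        ridge_used = base * np.trace(S_W) / p
        if ridge_used <= 0:
            ridge_used = base
        S_W = S_W + ridge_used * np.eye(p)
        warnings.warn(
            f"within-class scatter singular; ridge {ridge_used:.3g} added",
            stacklevel=2,
        )
    evals, evecs = scipy.linalg.eigh(S_B, S_W)
    order = np.argsort(evals)[::-1]
    n_axes = min(len(classes) - 1, p)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    A = evecs[:, order][:, :n_axes]
    pooled_cov = S_W / (n - len(classes))
    # scale each axis to unit pooled within-class variance
    scale = np.sqrt(np.einsum("fa,fg,ga->a", A, pooled_cov, A))
    scale[scale == 0] = 1.0
    A = A / scale
    tot = evals.sum()
    pot = evals / tot if tot > 0 else np.full(n_axes, 1.0 / n_axes)
    prior_vec = None
    if priors == "empirical":
        prior_vec = counts / n
    return LdaModel(
        classes=list(classes),
        class_means=means,
        pooled_within_cov=pooled_cov,
        discriminant_axes=A,
        proportion_of_trace=pot,
        ridge_used=ridge_used,
        priors=prior_vec,
    )


@dataclass
class ValidationResult:
    """Accuracy distribution over repeated train/validate splits."""

    n_iterations: int
    accuracy_per_iteration: np.ndarray
    mean_accuracy: float
    ci95: tuple
    n_redraws: int = 0

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracy_per_iteration, float)
        if ((acc < 0) | (acc > 1)).any():
            raise HostvarError("accuracies must lie in [0, 1]")
        self.accuracy_per_iteration = acc


def resampled_validation(
    X,
    status_labels,
    n_train: int = 90,
    n_valid: int = 45,
    n_iter: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ValidationResult:
    """Repeated random train/validate LDA classification.

    Each iteration draws ``n_train`` samples to fit the model and
    ``n_valid`` disjoint samples to score; splits where any training class
    has < 2 members are redrawn (counted). The 95% CI is the 2.5/97.5
    percentile range of the per-iteration accuracy distribution.
    """
    X = np.asarray(X, float)
    labels = np.asarray(status_labels)
    n = X.shape[0]
    if n_train + n_valid > n:
        raise HostvarError(
            f"n_train + n_valid = {n_train + n_valid} exceeds n_samples = {n}"
        )
    if n_train < 4 or n_valid < 1:
        raise HostvarError("split sizes too small")
    if rng is None:
        rng = np.random.default_rng(seed)
    acc = np.empty(n_iter)
    redraws = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-split ridge warnings counted once
        for it in range(n_iter):
            for _attempt in range(200):
                perm = rng.permutation(n)
                tr, va = perm[:n_train], perm[n_train:n_train + n_valid]
                _, cnt = np.unique(labels[tr], return_counts=True)
                if len(cnt) >= 2 and cnt.min() >= 2:
                    break
                redraws += 1
            else:
                raise HostvarError("could not draw a two-class training split")
            model = lda_fit(X[tr], labels[tr])
            acc[it] = np.mean(model.predict(X[va]) == labels[va])
    lo, hi = np.percentile(acc, [2.5, 97.5])
    return ValidationResult(n_iter, acc, float(acc.mean()), (float(lo), float(hi)),
                            n_redraws=redraws)


def null_validation(
    X,
    labels,
    null_type: str,
    n_perm: int = 1000,
    inner_iter: int = 100,
    n_train: int = 90,
    n_valid: int = 45,
    seed: int | None = None,
):
    """Monte-Carlo null distribution for the validation accuracy.

    ``permute_plants`` reassigns whole chemotypes to status labels (label
    shuffle); ``permute_within_compound`` shuffles each compound's values
    independently across plants, destroying among-compound covariance while
    preserving marginals. p = (1 + #{null mean >= observed}) / (n_perm + 1).

    Returns ``(observed_mean, null_means, p_value)``.
    """
    if null_type not in ("permute_plants", "permute_within_compound"):
        raise HostvarError(f"unknown null_type {null_type!r}")
    if n_perm < 1:
        raise HostvarError("n_perm must be >= 1")
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = resampled_validation(
        X, labels, n_train, n_valid, inner_iter, rng=rng
    ).mean_accuracy
    null_means = np.empty(n_perm)
    for b in range(n_perm):
        if null_type == "permute_plants":
            Xb, lb = X, labels[rng.permutation(len(labels))]
        else:
            Xb = np.column_stack(
                [X[rng.permutation(X.shape[0]), j] for j in range(X.shape[1])]
            )
            lb = labels
        null_means[b] = resampled_validation(
            Xb, lb, n_train, n_valid, inner_iter, rng=rng
        ).mean_accuracy
    p = (1 + int(np.sum(null_means >= observed))) / (n_perm + 1)
    return observed, null_means, p


def discriminant_scores_vs_performance(
    model: LdaModel,
    X,
    populations,
    performance: dict,
):
    """Spearman correlation of per-population mean discriminant scores with
    a per-population performance value (survival or mass), per axis.

    Returns a list of ``(rho, p)`` per axis; ``(nan, nan)`` with a warning
    when scores are constant across populations.
    """
    populations = np.asarray(populations)
    pops = sorted(performance)
    if len(pops) < 4:
        raise HostvarError("need >= 4 populations for a rank correlation")
    Z = model.transform(np.asarray(X, float))
    perf = np.array([performance[p] for p in pops], float)
    out = []
    for a in range(Z.shape[1]):
        means = np.array([Z[populations == p, a].mean() for p in pops])
        if np.allclose(means, means[0]):
            warnings.warn(f"axis {a}: constant scores, correlation undefined",
                          stacklevel=2)
            out.append((np.nan, np.nan))
            continue
        rho, pval = spearmanr(means, perf)
        out.append((float(rho), float(pval)))
    return out
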
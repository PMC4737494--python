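"""Cross-axis association tests: Mantel matrix correlations and thin
standard univariate tests.

The Mantel test correlates the off-diagonal entries of two distance
matrices and assesses significance by jointly permuting the rows and
columns of one matrix (entity relabeling). Both Pearson and Spearman
variants are provided. Permutation p-values use the (1 + exceedances) /
(n_perm + 1) convention, which includes the observed statistic and so is
never smaller than 1/(n_perm + 1).

Univariate tests (Kruskal-Wallis, Wilcoxon rank sum, Spearman) delegate to
scipy; they are deliberately contract-level wrappers. Post-hoc pairwise
comparisons after Kruskal-Wallis use Dunn's z statistics with a Holm
correction and compact-letter display.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .prefmodel import compact_letter_display
from .types import DistanceMatrix, HostvarError

__all__ = [
    "standardize_absorbance",
    "euclidean_matrix",
    "mantel",
    "univariate_tests",
    "post_hoc_kw",
]


def standardize_absorbance(table: pd.DataFrame) -> pd.Series:
    """Absorbance (AU) divided by sample mass (mg), per plant.

    Expects columns ``absorbance`` and ``sample_mass_mg``; the index
    identifies plants.
    """
    for col in ("absorbance", "sample_mass_mg"):
        if col not in table.columns:
            raise HostvarError(f"protein table missing column {col!r}")
    mass = table["sample_mass_mg"]
    if mass.isna().any() or (mass <= 0).any():
        bad = table.index[mass.isna() | (mass <= 0)][0]
        raise HostvarError(f"missing or non-positive sample mass for {bad!r}")
    absorb = table["absorbance"]
    if (absorb < 0).any():
        raise HostvarError("negative absorbance")
    return absorb / mass


def euclidean_matrix(values, labels=None) -> DistanceMatrix:
    """Euclidean distances between entities given scalar or vector values."""
    if isinstance(values, pd.Series):
        labels = list(values.index) if labels is None else list(labels)
        X = values.to_numpy(dtype=float)[:, None]
    elif isinstance(values, pd.DataFrame):
        labels = list(values.index) if labels is None else list(labels)
        X = values.to_numpy(dtype=float)
    else:
        X = np.asarray(values, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        labels = list(labels) if labels is not None else list(range(X.shape[0]))
    if not np.isfinite(X).all():
        raise HostvarError("missing values in input to euclidean_matrix")
    return DistanceMatrix(labels, squareform(pdist(X, metric="euclidean")))


def _upper(v: np.ndarray, n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    return v[iu]


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 1000,
    alternative: str = "two-sided",
    seed: int | None = None,
):
    """Mantel correlation between two labelled distance matrices.

    ``b`` is reindexed to ``a``'s labels; its rows and columns are permuted
    jointly for the null. Returns ``(r, p)``; ``r`` is NaN (with a warning)
    when either matrix is constant off-diagonal.
    """
    if method not in ("pearson", "spearman"):
        raise HostvarError(f"unknown method {method!r}")
    if alternative not in ("two-sided", "greater", "less"):
        raise HostvarError(f"unknown alternative {alternative!r}")
    if set(a.labels) != set(b.labels):
        raise HostvarError("distance matrices have different labels")
    if a.n < 4:
        raise HostvarError("need >= 4 entities for a Mantel test")
    b = b.reindex(a.labels)
    n = a.n
    A, B = a.values, b.values
    va = _upper(A, n)

    def corr(vb):
        return float(np.corrcoef(va_t, _rank(vb))[0, 1])

    if method == "spearman":
        _rank = lambda v: scipy.stats.rankdata(v)  # noqa: E731
    else:
        _rank = lambda v: v  # noqa: E731
    va_t = _rank(va)
    vb = _upper(B, n)
    if np.allclose(va, va[0]) or np.allclose(vb, vb[0]):
        warnings.warn("constant distance matrix; Mantel r undefined", stacklevel=2)
        return float("nan"), float("nan")
    r_obs = corr(vb)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(_upper(B[np.ix_(perm, perm)], n))
        if alternative == "two-sided":
            exceed += abs(r_p) >= abs(r_obs) - 1e-12
        elif alternative == "greater":
            exceed += r_p >= r_obs - 1e-12
        else:
            exceed += r_p <= r_obs + 1e-12
    p = (1 + exceed) / (n_perm + 1)
    return r_obs, float(p)


def univariate_tests(values, groups=None, test: str = "kruskal_wallis", paired_with=None):
    """Thin wrappers over standard rank-based tests.

    * ``kruskal_wallis``: values + group labels -> (H, p, df)
    * ``wilcoxon_rank_sum``: values + two-level groups -> (U-normal z-based
      statistic, p) via the two-sided rank-sum test
    * ``spearman``: values + paired_with -> (rho, p)

    All use mid-rank tie handling (scipy defaults). Degenerate, all-tied
    data yield a warning and a NaN p-value.
    """
    values = np.asarray(values, float)
    if test == "kruskal_wallis":
        labels = np.unique(np.asarray(groups))
        if len(labels) < 2:
            raise HostvarError("Kruskal-Wallis needs >= 2 groups")
        samples = [values[np.asarray(groups) == g] for g in labels]
        if np.allclose(values, values[0]):
            warnings.warn("all values tied; Kruskal-Wallis degenerate", stacklevel=2)
            return 0.0, float("nan"), len(labels) - 1
        stat, p = scipy.stats.kruskal(*samples)
        return float(stat), float(p), len(labels) - 1
    if test == "wilcoxon_rank_sum":
        labels = np.unique(np.asarray(groups))
        if len(labels) != 2:
            raise HostvarError("Wilcoxon rank sum needs exactly 2 groups")
        x = values[np.asarray(groups) == labels[0]]
        y = values[np.asarray(groups) == labels[1]]
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "spearman":
        if paired_with is None:
            raise HostvarError("spearman needs paired_with")
        rho, p = scipy.stats.spearmanr(values, np.asarray(paired_with, float))
        return float(rho), float(p)
    raise HostvarError(f"unknown test {test!r}")


def post_hoc_kw(values, groups, alpha: float = 0.05):
    """Dunn's pairwise rank comparisons after Kruskal-Wallis, Holm-corrected.

    Returns ``(pairs, letters)``: a tidy DataFrame of pairwise z statistics
    with raw and Holm-adjusted p-values, and a compact letter display in
    which groups sharing a letter are not significantly different at
    ``alpha``.
    """
    values = np.asarray(values, float)
    g = np.asarray(groups)
    labels = sorted(set(g.tolist()))
    if len(labels) < 2:
        raise HostvarError("post-hoc needs >= 2 groups")
    N = len(values)
    ranks = scipy.stats.rankdata(values)
    mean_rank = {k: ranks[g == k].mean() for k in labels}
    n = {k: int((g == k).sum()) for k in labels}
    # tie correction
    _, t = np.unique(values, return_counts=True)
    tie = np.sum(t ** 3 - t) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    pairs = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(pairs["p_raw"], alpha=alpha, method="holm")
    pairs["p_holm"] = p_adj
    pairs["significant"] = reject
    # letters: groups ordered by mean rank; 'same' = not significant
    order = sorted(labels, key=lambda k: mean_rank[k])
    idx = {k: i for i, k in enumerate(order)}
    same = [[True] * len(order) for _ in order]
    for row, rej in zip(rows, reject):
        i, j = idx[row["group_a"]], idx[row["group_b"]]
        same[i][j] = same[j][i] = not rej
    letters = compact_letter_display(order, same)
    return pairs, letters
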
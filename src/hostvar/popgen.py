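"""Tetraploid population genetics from genotype likelihoods.

The pipeline consumes per-individual, per-locus genotype likelihoods
L(g), g = 0..4 non-reference allele copies (ploidy 4), as produced by an
upstream variant caller. Posteriors combine the likelihoods with a
Hardy-Weinberg prior Binomial(4, p) at the global non-reference allele
frequency p; the posterior-mean dosage (a continuous value in [0, 4]) is
the genotype estimate used downstream.

Downstream summaries: individual-by-individual genetic covariance and its
PCA, within-population genetic variance 1 - [p^2 + (1-p)^2], genome-average
global and pairwise Fst (Nei-style G_ST as a ratio of sums over loci, with
bootstrap-over-loci CIs), and an isolation-by-distance Mantel test.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import assoc
from .types import DistanceMatrix, FstResult, GenotypeLikelihoods, HostvarError

__all__ = [
    "genotype_posterior",
    "genetic_covariance",
    "pca",
    "genetic_variance",
    "allele_freqs_from_dosage",
    "fst",
    "pairwise_fst",
    "isolation_by_distance",
]

_G = np.arange(5.0)


def genotype_posterior(gl: GenotypeLikelihoods):
    """Posterior genotype distribution and posterior-mean dosages.

    posterior(g) propto L(g) * C(4,g) p^g (1-p)^(4-g), normalized over
    g = 0..4. Returns ``(dosage, posterior)`` where dosage is an
    individuals x loci array in [0, 4]; entries whose likelihood row is
    all zero are NaN (flagged with a warning).
    """
    prior = binom.pmf(_G[None, :], 4, gl.global_freq[:, None])  # loci x 5
    post = gl.lik * prior[None, :, :]
    norm = post.sum(axis=2)
    bad = norm == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} (individual, locus) cells have all-zero "
            "likelihood; dosage set to missing",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        post = post / norm[:, :, None]
    dosage = (post * _G[None, None, :]).sum(axis=2)
    dosage[bad] = np.nan
    post[bad] = np.nan
    return dosage, post


def genetic_covariance(dosage: np.ndarray) -> np.ndarray:
    """Individual x individual covariance of mean-centered dosages.

    Dosages are centered per locus (mean over observed individuals);
    missing entries are excluded pairwise, so C(i, j) averages the product
    of centered dosages over loci observed in both i and j.
    """
    D = np.asarray(dosage, float)
    if D.ndim != 2 or D.shape[0] < 2 or D.shape[1] < 2:
        raise HostvarError("need >= 2 individuals and >= 2 loci")
    obs = np.isfinite(D)
    none = ~obs.any(axis=1)
    if none.any():
        raise HostvarError(
            f"individual(s) with no observed loci: {np.flatnonzero(none).tolist()}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        centered = D - np.nanmean(D, axis=0)[None, :]
    Z = np.where(obs, centered, 0.0)
    num = Z @ Z.T
    cnt = obs.astype(float) @ obs.astype(float).T
    if (cnt == 0).any():
        raise HostvarError("some individual pairs share no observed loci")
    return num / cnt


def pca(cov: np.ndarray):
    """Eigendecomposition of a genetic covariance matrix.

    Returns ``(scores, percent_variance)``: scores are eigenvectors scaled
    by sqrt(eigenvalue) (descending), percent variance uses eigenvalues
    floored at zero (a warning is issued when negatives are floored).
    """
    C = np.asarray(cov, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise HostvarError("covariance matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise HostvarError("covariance matrix is not symmetric")
    evals, evecs = np.linalg.eigh((C + C.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if (evals < -1e-10 * max(abs(evals[0]), 1.0)).any():
        warnings.warn("negative eigenvalues floored at 0 for percent variance",
                      stacklevel=2)
    lam = np.clip(evals, 0.0, None)
    scores = evecs * np.sqrt(lam)[None, :]
    tot = lam.sum()
    pct = 100.0 * lam / tot if tot > 0 else np.zeros_like(lam)
    return scores, pct


def genetic_variance(freqs) -> float:
    """Average genetic variance 1 - [p^2 + (1-p)^2] over loci."""
    p = np.asarray(freqs, float)
    if p.size == 0:
        raise HostvarError("empty locus set")
    if ((p < 0) | (p > 1)).any():
        raise HostvarError("frequencies must lie in [0, 1]")
    return float(np.mean(1.0 - (p ** 2 + (1.0 - p) ** 2)))


def allele_freqs_from_dosage(dosage: np.ndarray, populations) -> pd.DataFrame:
    """Per-population sample allele frequencies from posterior-mean dosages.

    p_kl = (mean dosage of population k at locus l) / 4; missing dosages
    are excluded from the mean.
    """
    D = np.asarray(dosage, float)
    pops = np.asarray(populations)
    if len(pops) != D.shape[0]:
        raise HostvarError("population labels must match dosage rows")
    labels = sorted(set(pops.tolist()))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k in labels:
            rows.append(np.nanmean(D[pops == k], axis=0) / 4.0)
    return pd.DataFrame(rows, index=labels)


def _fst_components(P: np.ndarray):
    """Per-locus H_T and H_S for a populations x loci frequency matrix."""
    pbar = P.mean(axis=0)
    h_t = 2.0 * pbar * (1.0 - pbar)
    h_s = np.mean(2.0 * P * (1.0 - P), axis=0)
    return h_t, h_s


def fst(
    freqs,
    scope: str | tuple = "global",
    n_boot: int = 1000,
    seed: int | None = None,
    labels=None,
) -> FstResult:
    """Genome-average Fst as a ratio of sums over loci.

    ``freqs`` is a populations x loci matrix (DataFrame rows are population
    labels); ``scope`` is "global" or a pair of population labels/indices.
    Fst = sum_l (H_T,l - H_S,l) / sum_l H_T,l with H_T from the unweighted
    mean frequency and H_S the mean within-population heterozygosity. The
    95% CI comes from a percentile bootstrap over loci. Loci with a missing
    frequency in any scoped population are dropped (counted in a warning);
    a scope where every locus is monomorphic yields Fst = NaN.
    """
    if isinstance(freqs, pd.DataFrame):
        labels = list(freqs.index)
        P = freqs.to_numpy(dtype=float)
    else:
        P = np.asarray(freqs, float)
        labels = list(labels) if labels is not None else list(range(P.shape[0]))
    if scope == "global":
        scoped = P
        scope_t = ("global",)
    else:
        a, b = scope
        ia = labels.index(a) if a in labels else int(a)
        ib = labels.index(b) if b in labels else int(b)
        scoped = P[[ia, ib]]
        scope_t = (labels[ia], labels[ib])
    if scoped.shape[0] < 2:
        raise HostvarError("Fst scope needs >= 2 populations")
    keep = np.isfinite(scoped).all(axis=0)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} loci with missing frequency in scope",
            stacklevel=2,
        )
    scoped = scoped[:, keep]
    h_t, h_s = _fst_components(scoped)
    denom = h_t.sum()
    if denom == 0:
        warnings.warn("all loci monomorphic in scope; Fst undefined", stacklevel=2)
        return FstResult(scope_t, float("nan"), (float("nan"), float("nan")),
                         int(scoped.shape[1]))
    est = float((h_t - h_s).sum() / denom)
    rng = np.random.default_rng(seed)
    L = scoped.shape[1]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, L, size=L)
        bt = h_t[take].sum()
        boots[b] = (h_t[take] - h_s[take]).sum() / bt if bt > 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return FstResult(scope_t, est, (float(lo), float(hi)), L)


def pairwise_fst(freqs, n_boot: int = 1000, seed: int | None = None):
    """All pairwise Fst values plus a DistanceMatrix for Mantel tests.

    Negative point estimates (possible for an unbiased-style estimator
    under near-panmixia) are floored at zero in the distance matrix only.
    """
    if not isinstance(freqs, pd.DataFrame):
        freqs = pd.DataFrame(np.asarray(freqs, float))
    labels = list(freqs.index)
    rng = np.random.default_rng(seed)
    results = []
    D = np.zeros((len(labels), len(labels)))
    for a, b in combinations(range(len(labels)), 2):
        r = fst(freqs, scope=(labels[a], labels[b]), n_boot=n_boot,
                seed=int(rng.integers(2**31 - 1)))
        results.append(r)
        D[a, b] = D[b, a] = max(r.fst, 0.0) if np.isfinite(r.fst) else 0.0
    return results, DistanceMatrix(labels, D)


def isolation_by_distance(
    pairwise_fst_dm: DistanceMatrix,
    geo_km: DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
):
    """One-sided Mantel test for Fst increasing with geographic distance.

    Returns ``(mantel_r, one_sided_p, significant)``.
    """
    if set(pairwise_fst_dm.labels) != set(geo_km.labels):
        raise HostvarError("population labels of Fst and geographic matrices differ")
    if pairwise_fst_dm.n < 4:
        raise HostvarError("need >= 4 populations for a Mantel test")
    geo = geo_km.reindex(pairwise_fst_dm.labels)
    r, p = assoc.mantel(
        pairwise_fst_dm, geo, method="pearson", n_perm=n_perm,
        alternative="greater", seed=seed,
    )
    return r, p, bool(p <= alpha)
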
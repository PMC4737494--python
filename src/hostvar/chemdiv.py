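"""Phytochemical matrix preprocessing and Hill-number diversity profiling.

The peak table (plants x anonymous HPLC compounds) is standardized by plant
dry weight, optionally Hellinger-transformed for ordination, and summarized
with Hill numbers (diversity equivalents):

    qD = (sum_i p_i^q)^(1/(1-q))        for q != 1
    1D = exp(-sum_i p_i ln p_i)          (continuity limit at q = 1)

qD is the effective number of equally abundant compounds in a profile; q
tunes sensitivity to rare compounds (q=0: richness; q=2: inverse Simpson).
Hierarchical partitioning splits pooled (gamma) diversity into mean
within-unit (alpha) diversity and among-unit turnover (beta = gamma/alpha),
with equal unit weights so that beta ranges from 1 (all units share one
chemotype) to N (complete turnover among N units).

Diversity is computed on dry-weight-standardized intensities, not the
Hellinger-transformed ones: the square-root transform distorts relative
abundances and is applied here only before ordination/distances.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .types import DistanceMatrix, HostvarError, PeakTable

__all__ = [
    "standardize_by_dry_weight",
    "hellinger",
    "manhattan_distance",
    "hill_diversity",
    "hierarchical_partition",
    "diversity_profile_bootstrap",
    "shared_compounds",
    "population_profiles",
]


def standardize_by_dry_weight(table: PeakTable) -> PeakTable:
    """Divide each plant's intensity row by that plant's dry mass (mg)."""
    missing = table.dry_mass.index[~np.isfinite(table.dry_mass)]
    if len(missing):
        raise HostvarError(f"missing dry mass for plant {missing[0]!r}")
    X = table.intensities.div(table.dry_mass, axis=0)
    return table.with_intensities(X)


def hellinger(table: PeakTable) -> PeakTable:
    """Hellinger transform: y_ij = sqrt(x_ij / sum_k x_ik), per row.

    Rows with all-zero intensity are mapped to all-zero rows with a warning;
    every nonzero output row has unit sum of squares.
    """
    X = table.intensities.to_numpy(dtype=float)
    if (X < 0).any():
        raise HostvarError("Hellinger transform requires non-negative intensities")
    rowsum = X.sum(axis=1)
    zero = rowsum == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero plant row(s) left as zeros in "
            f"Hellinger transform: {list(table.plants[zero])}",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, rowsum)
    Y = np.sqrt(X / safe[:, None])
    return table.with_intensities(
        pd.DataFrame(Y, index=table.plants, columns=table.compounds)
    )


def manhattan_distance(table: PeakTable) -> DistanceMatrix:
    """Pairwise Manhattan (city-block) distances between plant rows."""
    X = table.intensities.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise HostvarError("intensity matrix contains missing values")
    d = squareform(pdist(X, metric="cityblock"))
    return DistanceMatrix(list(table.plants), d)


def _as_simplex(p, tol: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0 or (p < 0).any():
        raise HostvarError("relative abundances must be a non-empty, non-negative vector")
    s = p.sum()
    if s <= 0:
        raise HostvarError("all-zero abundance vector has no defined diversity")
    if abs(s - 1.0) > tol:
        raise HostvarError(f"abundance vector sums to {s}, not 1 (tol {tol})")
    return p / s


def hill_diversity(p, q: float) -> float:
    """Hill number qD of a relative-abundance vector.

    ``p`` must sum to 1 within 1e-9 (it is renormalized exactly); zero
    entries contribute nothing at any q.
    """
    if q < 0:
        raise HostvarError("diversity order q must be >= 0")
    p = _as_simplex(p)
    nz = p[p > 0]
    if q == 0:
        return float(nz.size)
    if q == 1:
        return float(np.exp(-np.sum(nz * np.log(nz))))
    return float(np.sum(nz ** q) ** (1.0 / (1.0 - q)))


def _unit_relative_abundances(X: np.ndarray, labels) -> np.ndarray:
    """Row-normalize; drop all-zero rows with a warning."""
    rowsum = X.sum(axis=1)
    zero = rowsum == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} all-zero unit(s) from diversity: "
            f"{[labels[i] for i in np.flatnonzero(zero)]}",
            stacklevel=3,
        )
        X = X[~zero]
        rowsum = rowsum[~zero]
    if X.shape[0] == 0:
        raise HostvarError("no non-empty units for diversity partition")
    return X / rowsum[:, None]


def _partition_units(P: np.ndarray, q_grid) -> dict:
    """Equal-weight alpha/beta/gamma over units with relative abundances P."""
    N = P.shape[0]
    pooled = P.mean(axis=0)
    alpha, beta, gamma = [], [], []
    for q in q_grid:
        g = hill_diversity(pooled, q)
        if q == 1:
            with np.errstate(divide="ignore", invalid="ignore"):
                ent = -np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0)
            a = float(np.exp(ent.sum(axis=1).mean()))
        else:
            s = np.sum(np.where(P > 0, P, 0.0) ** q, axis=1).mean() if q != 0 else \
                (P > 0).sum(axis=1).mean()
            a = float(s ** (1.0 / (1.0 - q))) if q != 0 else float(s)
        alpha.append(a)
        gamma.append(g)
        beta.append(g / a)
    return {
        "alpha": np.array(alpha),
        "beta": np.array(beta),
        "gamma": np.array(gamma),
        "n_units": N,
    }


def hierarchical_partition(
    table: PeakTable,
    grouping: Mapping | pd.Series | None,
    q_grid: Iterable[float],
) -> dict:
    """Alpha/beta/gamma diversity profiles per group of plants.

    ``grouping`` maps plant id -> group label (default: the table's
    population labels). Units are plants; per-unit relative abundances come
    from the (dry-weight standardized) intensity rows. Groups with a single
    usable unit get ``None`` (beta undefined) with a warning.

    For the among-population scale, pool plants into population profiles
    first (:func:`population_profiles`) and pass a single global group.
    """
    q_grid = [float(q) for q in q_grid]
    if grouping is None:
        grouping = table.population
    groups = pd.Series(
        [grouping[p] for p in table.plants], index=table.plants, name="group"
    )
    out = {}
    for g, idx in groups.groupby(groups).groups.items():
        X = table.intensities.loc[idx].to_numpy(dtype=float)
        P = _unit_relative_abundances(X, list(idx))
        if P.shape[0] < 2:
            warnings.warn(
                f"group {g!r} has a single unit; beta diversity undefined",
                stacklevel=2,
            )
            out[g] = None
            continue
        res = _partition_units(P, q_grid)
        res["q_grid"] = np.array(q_grid)
        out[g] = res
    return out


def population_profiles(table: PeakTable) -> PeakTable:
    """Pool plants into equally weighted population abundance profiles.

    Each population's profile is the mean of its plants' relative-abundance
    vectors, so every plant contributes equally regardless of total signal.
    All-zero plants are excluded with a warning. The result is a PeakTable
    whose "plants" are populations (dry mass 1, status = modal status).
    """
    rows, pops, statuses = [], [], []
    for pop, idx in table.population.groupby(table.population).groups.items():
        X = table.intensities.loc[idx].to_numpy(dtype=float)
        P = _unit_relative_abundances(X, list(idx))
        rows.append(P.mean(axis=0))
        pops.append(pop)
        statuses.append(table.status.loc[idx].mode().iloc[0])
    X = pd.DataFrame(rows, index=pops, columns=table.compounds)
    ones = pd.Series(1.0, index=X.index)
    return PeakTable(X, ones, pd.Series(pops, index=X.index),
                     pd.Series(statuses, index=X.index))


def diversity_profile_bootstrap(
    table: PeakTable,
    grouping: Mapping | pd.Series | None,
    q_grid: Iterable[float],
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Bootstrap SEs for the hierarchical partition.

    Plants (units) are resampled with replacement within their group;
    compounds are never resampled. Returns the point partition with an
    ``se`` entry per level, plus the seed used.
    """
    if n_boot < 1:
        raise HostvarError("n_boot must be >= 1")
    if n_boot == 1:
        warnings.warn("n_boot=1 gives a degenerate SE of 0", stacklevel=2)
    q_grid = [float(q) for q in q_grid]
    rng = np.random.default_rng(seed)
    point = hierarchical_partition(table, grouping, q_grid)
    if grouping is None:
        grouping = table.population
    groups = pd.Series([grouping[p] for p in table.plants], index=table.plants)
    out = {}
    for g, res in point.items():
        if res is None:
            out[g] = None
            continue
        idx = list(groups.index[groups == g])
        X = table.intensities.loc[idx].to_numpy(dtype=float)
        keep = X.sum(axis=1) > 0
        X = X[keep]
        n = X.shape[0]
        boots = {lvl: np.empty((n_boot, len(q_grid))) for lvl in ("alpha", "beta", "gamma")}
        for b in range(n_boot):
            take = rng.integers(0, n, size=n)
            P = X[take]
            P = P / P.sum(axis=1)[:, None]
            part = _partition_units(P, q_grid)
            for lvl in boots:
                boots[lvl][b] = part[lvl]
        res = dict(res)
        res["se"] = {lvl: boots[lvl].std(axis=0, ddof=1) if n_boot > 1
                     else np.zeros(len(q_grid)) for lvl in boots}
        res["seed"] = seed
        res["n_boot"] = n_boot
        out[g] = res
    return out


def shared_compounds(table: PeakTable) -> list:
    """Compounds detected (nonzero in >= 1 plant) in every population."""
    pres = table.intensities.gt(0).groupby(table.population).any()
    return list(table.compounds[pres.all(axis=0)])
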
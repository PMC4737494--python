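"""Core data containers shared across the pipeline.

All containers are thin, validated wrappers around pandas/numpy objects.
They carry aligned labels so that downstream matrix operations (distances,
Mantel tests, Fst) can refuse silently mismatched inputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VALID_STATUS = ("colonized", "uncolonized", "uncertain")


class HostvarError(ValueError):
    """Base class for input/contract violations."""


@dataclass
class PeakTable:
    """Plants x compounds intensity matrix with per-plant metadata.

    Parameters
    ----------
    intensities
        Non-negative matrix, index = plant ids, columns = compound ids.
    dry_mass
        Per-plant dry mass in mg (index aligned with ``intensities``).
    population
        Per-plant population label.
    status
        Per-plant colonization status: colonized / uncolonized / uncertain.
    """

    intensities: pd.DataFrame
    dry_mass: pd.Series
    population: pd.Series
    status: pd.Series

    def __post_init__(self) -> None:
        X = self.intensities
        if not X.index.is_unique or not X.columns.is_unique:
            raise HostvarError("plant and compound labels must be unique")
        if (X.to_numpy() < 0).any():
            bad = np.argwhere(X.to_numpy() < 0)[0]
            raise HostvarError(
                f"negative intensity at plant {X.index[bad[0]]!r}, "
                f"compound {X.columns[bad[1]]!r}"
            )
        for name, s in (("dry_mass", self.dry_mass),
                        ("population", self.population),
                        ("status", self.status)):
            if not s.index.equals(X.index):
                raise HostvarError(f"{name} index does not match intensity rows")
        if (self.dry_mass <= 0).any():
            plant = self.dry_mass.index[self.dry_mass <= 0][0]
            raise HostvarError(f"non-positive dry mass for plant {plant!r}")
        bad_status = set(self.status) - set(VALID_STATUS)
        if bad_status:
            raise HostvarError(f"unknown colonization status: {sorted(bad_status)}")

    @property
    def plants(self) -> pd.Index:
        return self.intensities.index

    @property
    def compounds(self) -> pd.Index:
        return self.intensities.columns

    def with_intensities(self, X: pd.DataFrame) -> "PeakTable":
        """Return a copy sharing metadata but with a new intensity matrix."""
        return PeakTable(X, self.dry_mass, self.population, self.status)


@dataclass
class DistanceMatrix:
    """Symmetric, labelled, non-negative distance matrix with zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        self.labels = list(self.labels)
        n = len(self.labels)
        if d.shape != (n, n):
            raise HostvarError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if len(set(self.labels)) != n:
            raise HostvarError("duplicate labels in distance matrix")
        if not np.allclose(d, d.T, atol=1e-12, rtol=0):
            raise HostvarError("distance matrix is not symmetric (tol 1e-12)")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise HostvarError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise HostvarError("negative distances")
        self.values = d

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order (scipy squareform order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reindex(self, labels: Sequence) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


@dataclass
class PreferenceCounts:
    """Per-female egg counts over the substrates offered in each arena."""

    female_id: list
    source_population: list
    counts: np.ndarray  # females x substrates, non-negative integers
    substrate_labels: list

    def __post_init__(self) -> None:
        Y = np.asarray(self.counts)
        if Y.ndim != 2 or Y.shape[1] < 2:
            raise HostvarError("counts must be females x substrates with >= 2 substrates")
        if Y.shape[0] != len(self.female_id):
            raise HostvarError("female_id length does not match counts")
        if Y.shape[1] != len(self.substrate_labels):
            raise HostvarError("substrate_labels length does not match counts")
        if len(self.source_population) != len(self.female_id):
            raise HostvarError("source_population length does not match female_id")
        if (Y < 0).any() or not np.issubdtype(Y.dtype, np.integer):
            if not np.allclose(Y, np.round(Y)) or (Y < 0).any():
                raise HostvarError("counts must be non-negative integers")
            Y = np.round(Y).astype(int)
        self.counts = Y.astype(int)

    @property
    def n_females(self) -> int:
        return self.counts.shape[0]

    @property
    def n_substrates(self) -> int:
        return self.counts.shape[1]


@dataclass
class GenotypeLikelihoods:
    """Genotype likelihoods for tetraploid individuals at biallelic loci.

    ``lik[i, l, g]`` is the likelihood of observing individual *i*'s reads at
    locus *l* given genotype *g* non-reference allele copies (g = 0..4).
    ``global_freq`` holds the per-locus non-reference allele frequency used
    as the Hardy-Weinberg prior.
    """

    individuals: list
    populations: list
    loci: list
    lik: np.ndarray  # (n_ind, n_loci, 5)
    global_freq: np.ndarray  # (n_loci,)

    def __post_init__(self) -> None:
        L = np.asarray(self.lik, dtype=float)
        if L.ndim != 3 or L.shape[2] != 5:
            raise HostvarError("lik must have shape (individuals, loci, 5)")
        if L.shape[0] != len(self.individuals):
            raise HostvarError("individuals length does not match lik")
        if L.shape[1] != len(self.loci):
            raise HostvarError("loci length does not match lik")
        if len(self.populations) != len(self.individuals):
            raise HostvarError("populations length does not match individuals")
        if (L < 0).any():
            raise HostvarError("negative genotype likelihoods")
        p = np.asarray(self.global_freq, dtype=float)
        if p.shape != (L.shape[1],):
            raise HostvarError("global_freq length does not match loci")
        if ((p < 0) | (p > 1)).any():
            raise HostvarError("allele frequencies must lie in [0, 1]")
        self.lik = L
        self.global_freq = p

    @property
    def n_individuals(self) -> int:
        return self.lik.shape[0]

    @property
    def n_loci(self) -> int:
        return self.lik.shape[1]


@dataclass
class McmcSamples:
    """Labelled posterior draws with chain structure.

    ``draws[name]`` has shape (chains, iterations, *param_shape) and holds the
    raw (unthinned) chain including burn-in; accessors apply burn-in/thinning.
    """

    draws: dict
    burn_in: int
    thin: int = 1
    meta: dict = field(default_factory=dict)

    def parameters(self) -> list:
        return list(self.draws)

    def get(self, name: str):
        """Post burn-in, thinned draws pooled over chains.

        Returns an array of shape (n_kept_total, *param_shape).
        """
        if name not in self.draws:
            raise HostvarError(
                f"parameter {name!r} not found; have {sorted(self.draws)}"
            )
        arr = np.asarray(self.draws[name])
        kept = arr[:, self.burn_in::self.thin]
        return kept.reshape(-1, *arr.shape[2:])


@dataclass
class EtpiSummary:
    """Posterior mean with a 95% equal-tail probability interval."""

    parameter: str
    point_estimate: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.point_estimate <= self.upper):
            # tiny numerical excursions from percentile interpolation are fine
            if not (self.lower - 1e-9 <= self.point_estimate <= self.upper + 1e-9):
                raise HostvarError(
                    f"ETPI out of order for {self.parameter}: "
                    f"{self.lower} <= {self.point_estimate} <= {self.upper} fails"
                )

    def overlaps(self, other: "EtpiSummary") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper


@dataclass
class FstResult:
    """Genome-average Fst with a bootstrap-over-loci confidence interval."""

    scope: tuple
    fst: float
    ci95: tuple
    n_loci: int

    def as_dict(self) -> dict:
        return {
            "scope": "-".join(map(str, self.scope)),
            "fst": self.fst,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "n_loci": self.n_loci,
        }


def asdict(obj) -> dict:
    return dataclasses.asdict(obj)
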
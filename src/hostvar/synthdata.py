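"""Synthetic datasets with the statistical structure of the field study.

The study design emulated here: 7 host-plant populations (3 colonized by
the herbivore, 3 uncolonized, 1 uncertain) with ~20 plants each profiled
for 49 anonymous HPLC compounds of which 28 occur in every population and
a few are restricted to one colonization status; two-host-plus-control
oviposition arenas scored after 48 h; ~60 larvae reared per host source;
and 71 tetraploid individuals from 5 populations genotyped at thousands of
biallelic SNVs via genotype likelihoods.

Every generator takes a frozen scenario dataclass with an explicit seed and
returns ground-truth parameters alongside the data, so downstream modules
can be tested for parameter recovery. Identical scenario + seed gives
bit-identical output.

Modeling choices (these are stand-ins, not claims about the real data):
compound intensities are lognormal with population- and status-level mean
shifts and Bernoulli presence/absence; population divergence follows the
Balding-Nichols model (population frequencies Beta-distributed around an
ancestral frequency with divergence parameter F), which has an analytic
Fst expectation; sequencing reads are binomial with a symmetric per-read
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeLikelihoods, HostvarError, PeakTable, PreferenceCounts

__all__ = [
    "SyntheticScenario",
    "PopGenScenario",
    "PreferenceScenario",
    "generate_peak_table",
    "generate_genotype_data",
    "generate_preference_counts",
    "generate_survival_and_mass",
    "generate_protein_table",
    "default_status_map",
    "default_coordinates",
]

# study-like layout: 3 colonized, 3 uncolonized (prefix A), 1 uncertain
_DEFAULT_STATUS = {
    "BWP": "colonized",
    "VUH": "colonized",
    "GVL": "colonized",
    "AWFS": "uncolonized",
    "AFAL": "uncolonized",
    "APLL": "uncolonized",
    "SCC": "uncertain",
}

# rough site coordinates (deg) for isolation-by-distance plumbing
_DEFAULT_COORDS = {
    "BWP": (39.78, -120.07),
    "VUH": (39.52, -119.99),
    "GVL": (38.94, -119.75),
    "AWFS": (39.51, -119.91),
    "AFAL": (39.47, -118.78),
    "APLL": (38.71, -121.75),
    "SCC": (39.87, -119.70),
}


def default_status_map() -> dict:
    return dict(_DEFAULT_STATUS)


def default_coordinates() -> dict:
    return dict(_DEFAULT_COORDS)


@dataclass(frozen=True)
class SyntheticScenario:
    """Layout and effect sizes for a synthetic phytochemical peak table."""

    n_populations: int = 7
    plants_per_population: int = 20
    n_compounds: int = 49
    n_shared_compounds: int = 28
    n_colonized_only: int = 5
    n_uncolonized_only: int = 2
    status_map: dict = field(default_factory=default_status_map)
    effect_size: float = 0.8   # status-group mean separation, within-SD units
    dry_mass_range: tuple = (100.0, 200.0)  # mg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared_compounds > self.n_compounds:
            raise HostvarError("n_shared_compounds must be <= n_compounds")
        restricted = self.n_colonized_only + self.n_uncolonized_only
        if self.n_shared_compounds + restricted > self.n_compounds:
            raise HostvarError("shared + status-restricted compounds exceed total")
        if self.plants_per_population < 2:
            raise HostvarError("every population needs >= 2 plants")
        if len(self.status_map) != self.n_populations:
            raise HostvarError("status_map must name every population")
        if self.dry_mass_range[0] <= 0 or self.dry_mass_range[0] > self.dry_mass_range[1]:
            raise HostvarError("invalid dry_mass_range")


@dataclass(frozen=True)
class PopGenScenario:
    """Balding-Nichols divergence + binomial read model for tetraploids."""

    n_populations: int = 5
    individuals_per_population: tuple = (15, 14, 14, 14, 14)  # 71 total
    n_loci: int = 16920
    ancestral_freq_beta: tuple = (0.8, 0.8)
    drift_param: float = 0.025  # Balding-Nichols F; weak structure, Fst ~ 0.02
    mean_depth: float = 8.0
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.drift_param < 1.0):
            raise HostvarError("drift_param must lie in (0, 1)")
        if not (0.0 <= self.error_rate < 0.5):
            raise HostvarError("error_rate must lie in [0, 0.5)")
        if len(self.individuals_per_population) != self.n_populations:
            raise HostvarError("individuals_per_population must match n_populations")
        if self.n_loci < 1 or min(self.individuals_per_population) < 1:
            raise HostvarError("need >= 1 locus and >= 1 individual per population")
        if self.mean_depth < 0:
            raise HostvarError("mean_depth must be >= 0")


@dataclass(frozen=True)
class PreferenceScenario:
    """Dirichlet-multinomial arena: H substrates, one 48-h bout per female."""

    n_females: int = 40
    substrates: tuple = ("host_a", "host_b", "control")
    population_preference: tuple = (0.5, 0.35, 0.15)
    concentration: float = 20.0
    eggs_per_female_mean: float = 30.0  # Poisson mean, truncated at >= 1
    seed: int = 0

    def __post_init__(self) -> None:
        H = len(self.substrates)
        if H < 2:
            raise HostvarError("need >= 2 substrates")
        Pi = np.asarray(self.population_preference, float)
        if Pi.shape != (H,) or (Pi < 0).any() or abs(Pi.sum() - 1.0) > 1e-9:
            raise HostvarError("population_preference must be a simplex vector of length H")
        if self.concentration <= 0:
            raise HostvarError("concentration must be > 0")
        if self.n_females < 1:
            raise HostvarError("need >= 1 female")


def generate_peak_table(scenario: SyntheticScenario):
    """Synthetic plants x compounds peak table with known group structure.

    Returns ``(PeakTable, truth)`` where ``truth`` holds the log-scale
    compound means per status group, compound categories, and presence
    probabilities. Shared compounds are guaranteed nonzero in at least one
    plant of every population; status-restricted compounds are zero outside
    their status group (and in uncertain populations).
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    pops = list(sc.status_map)
    plants, plant_pop, plant_status = [], [], []
    for pop in pops:
        for i in range(sc.plants_per_population):
            plants.append(f"{pop}-{i + 1:02d}")
            plant_pop.append(pop)
            plant_status.append(sc.status_map[pop])
    n_plants = len(plants)
    compounds = [f"c{j + 1:02d}" for j in range(sc.n_compounds)]

    n_shared = sc.n_shared_compounds
    cat = np.array(
        ["shared"] * n_shared
        + ["colonized_only"] * sc.n_colonized_only
        + ["uncolonized_only"] * sc.n_uncolonized_only
        + ["sporadic"] * (sc.n_compounds - n_shared - sc.n_colonized_only
                          - sc.n_uncolonized_only)
    )

    status = np.asarray(plant_status)
    pop_arr = np.asarray(plant_pop)

    # log-scale structure: per-compound baseline, population shift, status effect
    log_sd = 0.5  # within-group SD on the log scale
    base = rng.normal(2.0, 0.8, size=sc.n_compounds)
    pop_shift = rng.normal(0.0, 0.3, size=(len(pops), sc.n_compounds))
    informative = np.zeros(sc.n_compounds, dtype=bool)
    informative[rng.choice(n_shared, size=max(n_shared // 2, 1), replace=False)] = True
    # effect_size in units of within-group SD, applied on the log scale
    status_effect = np.where(informative, sc.effect_size * log_sd, 0.0)

    mu = np.tile(base, (n_plants, 1))
    pop_idx = np.array([pops.index(p) for p in pop_arr])
    mu += pop_shift[pop_idx]
    mu += np.where(status[:, None] == "colonized", 0.5, -0.5) * status_effect[None, :] \
        * (status[:, None] != "uncertain")

    X = np.exp(rng.normal(mu, log_sd))

    # presence/absence
    present = np.ones((n_plants, sc.n_compounds), dtype=bool)
    presence_p = {"shared": 0.9, "restricted": 0.7, "sporadic": 0.35}
    for j in range(sc.n_compounds):
        if cat[j] == "shared":
            present[:, j] = rng.random(n_plants) < presence_p["shared"]
            # guarantee occupancy in every population
            for k, pop in enumerate(pops):
                rows = np.flatnonzero(pop_idx == k)
                if not present[rows, j].any():
                    present[rng.choice(rows), j] = True
        elif cat[j] == "colonized_only":
            present[:, j] = (status == "colonized") & (rng.random(n_plants)
                                                       < presence_p["restricted"])
        elif cat[j] == "uncolonized_only":
            present[:, j] = (status == "uncolonized") & (rng.random(n_plants)
                                                         < presence_p["restricted"])
        else:
            # sporadic: present in a random subset of populations only
            n_pop_in = int(rng.integers(1, max(len(pops) - 1, 2)))
            pops_in = rng.choice(len(pops), size=n_pop_in, replace=False)
            present[:, j] = np.isin(pop_idx, pops_in) & (rng.random(n_plants)
                                                         < presence_p["sporadic"])
    X = X * present

    dry_mass = rng.uniform(*sc.dry_mass_range, size=n_plants)
    idx = pd.Index(plants, name="plant")
    table = PeakTable(
        intensities=pd.DataFrame(X, index=idx, columns=compounds),
        dry_mass=pd.Series(dry_mass, index=idx, name="dry_mass_mg"),
        population=pd.Series(plant_pop, index=idx, name="pop"),
        status=pd.Series(plant_status, index=idx, name="status"),
    )
    truth = {
        "compound_category": dict(zip(compounds, cat)),
        "informative": dict(zip(compounds, informative.tolist())),
        "log_mean_colonized": dict(zip(compounds, (base + 0.5 * status_effect).tolist())),
        "log_mean_uncolonized": dict(zip(compounds, (base - 0.5 * status_effect).tolist())),
        "log_sd": log_sd,
        "effect_size": sc.effect_size,
    }
    return table, truth


def generate_genotype_data(scenario: PopGenScenario):
    """Tetraploid genotype likelihoods under Balding-Nichols divergence.

    Population frequencies p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around an
    ancestral frequency p; genotypes g ~ Binomial(4, p_k); per-locus read
    depth ~ Poisson(mean_depth); non-reference read counts binomial with
    per-read error; likelihoods are the binomial read likelihood for each
    g in 0..4 (a zero-depth cell has flat likelihoods). Returns
    ``(GenotypeLikelihoods, true_dosages, true_pop_freqs)``.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    K = sc.n_populations
    L = sc.n_loci
    n_per = sc.individuals_per_population
    N = int(sum(n_per))

    anc = rng.beta(*sc.ancestral_freq_beta, size=L)
    anc = np.clip(anc, 1e-4, 1 - 1e-4)
    F = sc.drift_param
    a = anc * (1 - F) / F
    b = (1 - anc) * (1 - F) / F
    pop_freq = rng.beta(a[None, :], b[None, :], size=(K, L))

    pop_of = np.repeat(np.arange(K), n_per)
    G = rng.binomial(4, pop_freq[pop_of])  # N x L true dosages

    depth = rng.poisson(sc.mean_depth, size=(N, L))
    if (depth.sum(axis=1) == 0).any():
        raise HostvarError(
            "degenerate data: an individual has zero depth at every locus; "
            "increase mean_depth"
        )
    e = sc.error_rate
    p_read = G / 4.0 * (1 - e) + (1 - G / 4.0) * e
    nonref_reads = rng.binomial(depth, p_read)

    # likelihood of the read counts under each candidate genotype
    g_grid = np.arange(5)[None, None, :]
    pg = g_grid / 4.0 * (1 - e) + (1 - g_grid / 4.0) * e
    from scipy.stats import binom as _binom
    lik = _binom.pmf(nonref_reads[:, :, None], depth[:, :, None], pg)
    flat = depth == 0
    lik[flat] = 1.0  # no reads: flat likelihood

    # dataset-wide ML frequency under HWE from the pooled true genotypes'
    # read data is external upstream; the generator reports the pooled
    # sample frequency as the "global" estimate
    global_freq = G.mean(axis=0) / 4.0

    individuals = []
    populations = []
    for k in range(K):
        for i in range(n_per[k]):
            individuals.append(f"pop{k + 1}-{i + 1:02d}")
            populations.append(f"pop{k + 1}")
    gl = GenotypeLikelihoods(
        individuals=individuals,
        populations=populations,
        loci=[f"snv{l + 1:05d}" for l in range(L)],
        lik=lik,
        global_freq=global_freq,
    )
    return gl, G, pd.DataFrame(pop_freq, index=[f"pop{k + 1}" for k in range(K)],
                               columns=gl.loci)


def generate_preference_counts(scenario: PreferenceScenario):
    """Dirichlet-multinomial egg counts with known (Pi, kappa, pi_i).

    Returns ``(PreferenceCounts, truth)``.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    H = len(sc.substrates)
    Pi = np.asarray(sc.population_preference, float)
    alpha = sc.concentration * Pi
    # Dirichlet via gammas; zero-alpha components get exact zeros
    gam = np.where(alpha[None, :] > 0,
                   rng.gamma(np.clip(alpha, 1e-12, None), size=(sc.n_females, H)),
                   0.0)
    pi = gam / gam.sum(axis=1, keepdims=True)
    n_eggs = np.maximum(rng.poisson(sc.eggs_per_female_mean, size=sc.n_females), 1)
    counts = np.vstack([rng.multinomial(n_eggs[i], pi[i]) for i in range(sc.n_females)])
    data = PreferenceCounts(
        female_id=[f"F{i + 1:03d}" for i in range(sc.n_females)],
        source_population=["synthetic"] * sc.n_females,
        counts=counts,
        substrate_labels=list(sc.substrates),
    )
    truth = {"Pi": Pi, "kappa": sc.concentration, "pi": pi, "n_eggs": n_eggs}
    return data, truth


def generate_survival_and_mass(
    survival_probs,
    mass_means,
    mass_sds,
    sources=None,
    n_started: int = 60,
    seed: int | None = None,
):
    """Binomial survival and lognormal masses per host source.

    ``mass_means``/``mass_sds`` are on the natural (mg) scale; masses are
    drawn lognormal with matching mean and SD, survivors only. Returns
    ``(survival_df, mass_df)``.
    """
    p = np.asarray(survival_probs, float)
    if ((p < 0) | (p > 1)).any():
        raise HostvarError("survival probabilities must lie in [0, 1]")
    mm = np.asarray(mass_means, float)
    ms = np.asarray(mass_sds, float)
    if not (len(p) == len(mm) == len(ms)):
        raise HostvarError("per-source parameter lengths differ")
    if sources is None:
        sources = [f"src{i + 1}" for i in range(len(p))]
    rng = np.random.default_rng(seed)
    rows, mass_rows = [], []
    for k, src in enumerate(sources):
        surv = int(rng.binomial(n_started, p[k]))
        rows.append({"source": src, "n_started": n_started, "n_survived": surv,
                     "true_p": p[k]})
        if surv > 0:
            # lognormal with mean mm, sd ms on the natural scale
            sigma2 = np.log1p((ms[k] / mm[k]) ** 2)
            mu = np.log(mm[k]) - sigma2 / 2.0
            masses = rng.lognormal(mu, np.sqrt(sigma2), size=surv)
            for j, m in enumerate(masses):
                mass_rows.append({"source": src, "larva": f"{src}-{j + 1:02d}",
                                  "mass_mg": m})
    return pd.DataFrame(rows), pd.DataFrame(mass_rows)


def generate_protein_table(
    populations,
    plants_per_population: int = 20,
    pop_mean_absorbance=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic Bradford-style absorbance table (AU) with sample masses.

    Per-population mean absorbance defaults to a lognormal spread around
    0.5 AU; per-plant noise is lognormal. Returns a tidy DataFrame with
    columns plant, pop, absorbance, sample_mass_mg.
    """
    rng = np.random.default_rng(seed)
    pops = list(populations)
    if pop_mean_absorbance is None:
        pop_mean_absorbance = 0.5 * np.exp(rng.normal(0, 0.25, size=len(pops)))
    rows = []
    for k, pop in enumerate(pops):
        for i in range(plants_per_population):
            rows.append({
                "plant": f"{pop}-{i + 1:02d}",
                "pop": pop,
                "absorbance": pop_mean_absorbance[k] * np.exp(rng.normal(0, 0.3)),
                "sample_mass_mg": rng.uniform(8.0, 12.0),
            })
    return pd.DataFrame(rows).set_index("plant")
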
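"""Hierarchical Bayesian models of oviposition preference and larval
performance.

Preference model (Dirichlet-multinomial hierarchy)
--------------------------------------------------
Each female i lays ``n_i`` eggs over H substrates:

    y_i | pi_i          ~ Multinomial(n_i, pi_i)
    pi_i | Pi, kappa    ~ Dirichlet(kappa * Pi)
    Pi                  ~ Dirichlet(1, ..., 1)
    kappa               ~ half-Cauchy(scale 25)   [or Gamma(1, 0.001)]

``Pi`` is the population-level preference (a point on the simplex) and
``kappa`` the concentration: large kappa means females agree with the
population preference, small kappa means idiosyncratic females. The
individual preferences are conjugate given (Pi, kappa) —
pi_i | y_i, Pi, kappa ~ Dirichlet(kappa*Pi + y_i) — so the sampler is Gibbs
on pi_i with adaptive Metropolis-within-Gibbs updates of Pi (Dirichlet
proposal) and log kappa (random walk). Adaptation runs during burn-in only.

The same machinery, applied to the vector of survivor counts across host
sources, yields relative survival support per source; a per-source
Beta-binomial variant (flat prior on each survival fraction) is also
provided because per-source survival fractions are the quantity usually
plotted.

Bayesian ANOVA (group means with heterogeneous variances)
---------------------------------------------------------
Larval masses y_gk by host source g:

    y_gk ~ Normal(mu + delta_g, precision tau_g)
    mu       ~ Normal(0, precision 0.001)
    delta_g  ~ Normal(0, precision psi_g)
    psi_g    ~ folded-t(mu=0, precision 0.001, df=2)
    tau_g    ~ Gamma(shape 1, rate 1)

mu, delta_g and tau_g have conjugate conditionals (Gibbs); psi_g is updated
by adaptive Metropolis on the log scale. Group means mu + delta_g are the
identified quantities and are stored directly.

Point estimates are posterior means; intervals are 95% equal-tail
probability intervals (ETPIs, 2.5/97.5 percentiles with linear
interpolation). Non-overlap of ETPIs is displayed with compact letters.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln

from .types import EtpiSummary, HostvarError, McmcSamples, PreferenceCounts

__all__ = [
    "fit_preference",
    "fit_survival",
    "fit_banova",
    "etpi",
    "letter_groups",
    "compact_letter_display",
]

_EPS = 1e-12


def _log_dirichlet(x: np.ndarray, alpha: np.ndarray) -> float:
    """Sum of Dirichlet log densities over rows of x (alpha shared)."""
    x = np.clip(x, _EPS, None)
    return float(
        x.shape[0] * (gammaln(alpha.sum()) - gammaln(alpha).sum())
        + ((alpha - 1.0) * np.log(x)).sum()
    )


def _log_kappa_prior(kappa: float, prior) -> float:
    kind = prior[0]
    if kind == "half_cauchy":
        scale = prior[1]
        return -np.log1p((kappa / scale) ** 2)
    if kind == "gamma":
        shape, rate = prior[1], prior[2]
        return (shape - 1.0) * np.log(kappa) - rate * kappa
    raise HostvarError(f"unknown kappa prior {prior!r}")


def _sample_dirichlet_rows(rng, alpha: np.ndarray) -> np.ndarray:
    g = rng.gamma(np.clip(alpha, 1e-8, None))
    g = np.clip(g, _EPS, None)
    return g / g.sum(axis=-1, keepdims=True)


def _run_dm_chain(Y, n_iter, burn_in, rng, kappa_prior, store_individual):
    I, H = Y.shape
    n_i = Y.sum(axis=1)
    # init: pooled fractions, moderate concentration
    Pi = (Y.sum(axis=0) + 1.0) / (Y.sum() + H)
    kappa = 10.0
    pi = (Y + 1.0) / (n_i + H)[:, None]

    Pi_draws = np.empty((n_iter, H))
    kappa_draws = np.empty(n_iter)
    pi_draws = np.empty((n_iter, I, H)) if store_individual else None

    prop_conc = 200.0   # Dirichlet proposal concentration for Pi
    log_step = 0.5      # RW step for log kappa
    acc = {"Pi": 0, "kappa": 0}
    win = {"Pi": 0, "kappa": 0}

    for t in range(n_iter):
        # Gibbs: pi_i | y_i, Pi, kappa ~ Dirichlet(kappa*Pi + y_i)
        pi = _sample_dirichlet_rows(rng, kappa * Pi[None, :] + Y)

        log_pi = np.log(np.clip(pi, _EPS, None))
        sum_log_pi = log_pi.sum(axis=0)

        def loglik(Pi_, kappa_):
            a = kappa_ * Pi_
            return float(
                I * (gammaln(kappa_) - gammaln(a).sum()) + ((a - 1.0) * sum_log_pi).sum()
            )

        # MH on Pi with a Dirichlet proposal centred at the current value
        prop = _sample_dirichlet_rows(rng, (prop_conc * Pi)[None, :])[0]
        logr = (
            loglik(prop, kappa) - loglik(Pi, kappa)
            + _log_dirichlet(Pi[None, :], prop_conc * prop)
            - _log_dirichlet(prop[None, :], prop_conc * Pi)
        )
        win["Pi"] += 1
        if np.log(rng.uniform()) < logr:
            Pi = prop
            acc["Pi"] += 1

        # MH on log kappa
        prop_k = float(np.exp(np.log(kappa) + log_step * rng.normal()))
        logr = (
            loglik(Pi, prop_k) - loglik(Pi, kappa)
            + _log_kappa_prior(prop_k, kappa_prior)
            - _log_kappa_prior(kappa, kappa_prior)
            + np.log(prop_k) - np.log(kappa)  # Jacobian of the log transform
        )
        win["kappa"] += 1
        if np.log(rng.uniform()) < logr:
            kappa = prop_k
            acc["kappa"] += 1

        # adapt proposals during burn-in only, targeting 0.2-0.5 acceptance
        if t < burn_in and (t + 1) % 50 == 0:
            for key in ("Pi", "kappa"):
                rate = acc[key] / win[key]
                if key == "Pi":
                    if rate < 0.2:
                        prop_conc *= 1.5
                    elif rate > 0.5:
                        prop_conc /= 1.5
                else:
                    if rate < 0.2:
                        log_step /= 1.5
                    elif rate > 0.5:
                        log_step *= 1.5
                acc[key] = win[key] = 0

        Pi_draws[t] = Pi
        kappa_draws[t] = kappa
        if store_individual:
            pi_draws[t] = pi

    diag = {
        "accept_Pi": acc["Pi"] / max(win["Pi"], 1),
        "accept_kappa": acc["kappa"] / max(win["kappa"], 1),
        "final_prop_conc": prop_conc,
        "final_log_step": log_step,
    }
    return Pi_draws, kappa_draws, pi_draws, diag


def fit_preference(
    data: PreferenceCounts,
    n_iter: int = 20000,
    burn_in: int = 5000,
    seed: int | None = None,
    kappa_prior=("half_cauchy", 25.0),
    store_individual: bool = True,
) -> McmcSamples:
    """Sample the Dirichlet-multinomial preference hierarchy.

    Defaults are 20,000 iterations with a 5,000-iteration burn-in. Females
    with zero total eggs carry no information and are dropped with a
    warning. Returns draws for ``Pi`` (population preference), ``kappa``
    (concentration) and, optionally, ``pi`` (per-female preferences).
    """
    Y = np.asarray(data.counts, float)
    n_i = Y.sum(axis=1)
    if (n_i == 0).any():
        dropped = [data.female_id[i] for i in np.flatnonzero(n_i == 0)]
        warnings.warn(f"dropping females with zero eggs: {dropped}", stacklevel=2)
        Y = Y[n_i > 0]
    if Y.shape[0] == 0:
        raise HostvarError("no females with nonzero egg counts")
    if burn_in >= n_iter:
        raise HostvarError("burn_in must be < n_iter")
    rng = np.random.default_rng(seed)
    Pi_d, k_d, pi_d, diag = _run_dm_chain(
        Y, n_iter, burn_in, rng, kappa_prior, store_individual
    )
    draws = {"Pi": Pi_d[None], "kappa": k_d[None]}
    if store_individual:
        draws["pi"] = pi_d[None]
    meta = {
        "substrates": list(data.substrate_labels),
        "diagnostics": diag,
        "kappa_prior": kappa_prior,
        "seed": seed,
    }
    return McmcSamples(draws=draws, burn_in=burn_in, thin=1, meta=meta)


def fit_survival(
    survivors,
    sources,
    n_started=None,
    n_iter: int = 5000,
    burn_in: int = 1000,
    seed: int | None = None,
) -> McmcSamples:
    """Bayesian analysis of survivor counts across host sources.

    Two complementary parameterizations are returned in one set of draws:

    * ``support`` — the multinomial machinery of :func:`fit_preference`
      applied to the single vector of survivor counts, giving relative
      support per source (sums to 1 across sources).
    * ``survival_rate`` (only when ``n_started`` is given) — per-source
      Beta-binomial survival fraction with a flat Beta(1, 1) prior, i.e.
      draws from Beta(1 + s_g, 1 + n_g - s_g).

    The two answer different questions (share of surviving larvae vs
    probability of surviving) and are both reported.
    """
    s = np.asarray(survivors, float)
    if len(sources) < 2:
        raise HostvarError("need >= 2 host sources")
    if s.sum() == 0:
        raise HostvarError("zero total survivors: nothing to model")
    if (s < 0).any():
        raise HostvarError("negative survivor counts")
    rng = np.random.default_rng(seed)
    counts = PreferenceCounts(
        female_id=["pooled"],
        source_population=["pooled"],
        counts=s[None, :].astype(int),
        substrate_labels=list(sources),
    )
    fit = fit_preference(
        counts, n_iter=n_iter, burn_in=burn_in,
        seed=int(rng.integers(2**31 - 1)), store_individual=True,
    )
    draws = {"support": fit.draws["pi"][:, :, 0, :]}
    meta = {"sources": list(sources), "diagnostics": fit.meta["diagnostics"]}
    if n_started is not None:
        n = np.asarray(n_started, float)
        if n.shape != s.shape or (s > n).any():
            raise HostvarError("n_started must match sources with survivors <= started")
        rates = rng.beta(1.0 + s, 1.0 + (n - s), size=(n_iter, len(sources)))
        draws["survival_rate"] = rates[None]
        meta["n_started"] = list(map(int, n))
    return McmcSamples(draws=draws, burn_in=burn_in, thin=1, meta=meta)


# ---------------------------------------------------------------------------
# Bayesian ANOVA
# ---------------------------------------------------------------------------

def _log_folded_t(psi, precision=0.001, df=2.0):
    return -0.5 * (df + 1.0) * np.log1p(precision * psi ** 2 / df)


def fit_banova(
    masses,
    groups,
    n_iter: int = 1_000_000,
    chains: int = 3,
    burn_in: int = 5000,
    thin: int = 100,
    seed: int | None = None,
    folded_t_df: float = 2.0,
) -> McmcSamples:
    """Bayesian ANOVA of (larval) masses by host source.

    Groups with a single observation are excluded with a warning (a single
    mass cannot inform a group variance). Total iterations are divided
    between ``chains``. Stored parameters: ``mu``, ``delta`` (per-group
    deflection), ``tau`` (per-group data precision), ``group_mean``
    (mu + delta_g, the identified quantity).
    """
    y = np.asarray(masses, float)
    g = np.asarray(groups)
    if (y <= 0).any():
        raise HostvarError("masses must be positive")
    if y.shape != g.shape:
        raise HostvarError("masses and groups must align")
    labels, counts = np.unique(g, return_counts=True)
    singletons = labels[counts < 2]
    if len(singletons):
        warnings.warn(
            f"excluding groups with a single observation: {list(singletons)}",
            stacklevel=2,
        )
        keep = ~np.isin(g, singletons)
        y, g = y[keep], g[keep]
        labels = labels[~np.isin(labels, singletons)]
    if len(labels) < 1:
        raise HostvarError("need >= 1 group with >= 2 observations")
    if len(labels) == 1:
        warnings.warn(
            "single group: model reduces to a Bayesian mean estimate",
            stacklevel=2,
        )
    G = len(labels)
    gi = np.searchsorted(labels, g)
    n_g = np.bincount(gi, minlength=G).astype(float)
    S_g = np.bincount(gi, weights=y, minlength=G)       # group sums
    SS_g = np.bincount(gi, weights=y * y, minlength=G)  # group sums of squares

    per_chain = max(n_iter // chains, burn_in + thin)
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)

    kept = (per_chain - burn_in + thin - 1) // thin
    mu_out = np.empty((chains, kept))
    delta_out = np.empty((chains, kept, G))
    tau_out = np.empty((chains, kept, G))
    gm_out = np.empty((chains, kept, G))

    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        mu = float(y.mean())
        delta = S_g / n_g - mu
        tau = np.full(G, 1.0 / max(y.var(), 1e-6))
        psi = np.full(G, 1.0)
        step = np.full(G, 0.5)
        acc = np.zeros(G)
        win = 0
        k = 0
        for t in range(per_chain):
            # mu | rest  (prior precision 0.001)
            prec = 0.001 + np.sum(tau * n_g)
            mean = np.sum(tau * (S_g - n_g * delta)) / prec
            mu = mean + rng.normal() / np.sqrt(prec)
            # delta_g | rest
            prec_d = psi + tau * n_g
            mean_d = tau * (S_g - n_g * mu) / prec_d
            delta = mean_d + rng.normal(size=G) / np.sqrt(prec_d)
            # tau_g | rest ~ Gamma(1 + n_g/2, 1 + RSS_g/2)
            m = mu + delta
            rss = SS_g - 2.0 * m * S_g + n_g * m * m
            tau = rng.gamma(1.0 + n_g / 2.0, 1.0 / (1.0 + rss / 2.0))
            # psi_g | delta_g: folded-t prior, adaptive MH on log psi
            prop = psi * np.exp(step * rng.normal(size=G))
            logr = (
                _log_folded_t(prop, df=folded_t_df)
                - _log_folded_t(psi, df=folded_t_df)
                + 0.5 * (np.log(prop) - np.log(psi))
                - 0.5 * delta ** 2 * (prop - psi)
                + np.log(prop) - np.log(psi)  # Jacobian
            )
            take = np.log(rng.uniform(size=G)) < logr
            psi = np.where(take, prop, psi)
            acc += take
            win += 1
            if t < burn_in and (t + 1) % 50 == 0:
                rate = acc / win
                step = np.where(rate < 0.2, step / 1.5,
                                np.where(rate > 0.5, step * 1.5, step))
                acc[:] = 0
                win = 0
            if t >= burn_in and (t - burn_in) % thin == 0:
                mu_out[c, k] = mu
                delta_out[c, k] = delta
                tau_out[c, k] = tau
                gm_out[c, k] = mu + delta
                k += 1

    samples = McmcSamples(
        draws={"mu": mu_out, "delta": delta_out, "tau": tau_out,
               "group_mean": gm_out},
        burn_in=0,  # burn-in/thinning already applied during sampling
        thin=1,
        meta={"groups": list(labels), "chains": chains,
              "iterations_per_chain": per_chain, "thin": thin, "seed": seed},
    )
    return samples


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def etpi(samples: McmcSamples, parameter: str, index=None) -> EtpiSummary:
    """Posterior mean and 95% equal-tail probability interval.

    ``index`` selects a component of a vector parameter. Percentiles use
    linear interpolation (numpy's default, type-7), which fixes the exact
    endpoint convention.
    """
    draws = samples.get(parameter)
    if index is not None:
        draws = draws[(slice(None), *np.atleast_1d(index))]
    draws = np.asarray(draws, float).ravel()
    if draws.size < 100:
        raise HostvarError(
            f"only {draws.size} post-burn-in draws for {parameter!r}; need >= 100"
        )
    lo, hi = np.percentile(draws, [2.5, 97.5])
    name = parameter if index is None else f"{parameter}[{index}]"
    return EtpiSummary(name, float(draws.mean()), float(lo), float(hi))


def compact_letter_display(names, same) -> dict:
    """Compact letter display from a 'not separated' relation.

    ``same[i][j]`` is True when items i and j must be allowed to share a
    letter (e.g. overlapping intervals, or a non-significant pairwise
    test). Insert-and-absorb: start from one letter covering everything,
    split on each separated pair, drop absorbed (subset) letters.
    """
    n = len(names)
    sets = [set(range(n))]
    for i in range(n):
        for j in range(i + 1, n):
            if same[i][j]:
                continue
            new_sets = []
            for s in sets:
                if i in s and j in s:
                    new_sets.append(s - {i})
                    new_sets.append(s - {j})
                else:
                    new_sets.append(s)
            # absorb subsets
            new_sets.sort(key=len, reverse=True)
            kept = []
            for s in new_sets:
                if not any(s < k or s == k for k in kept):
                    kept.append(s)
            sets = kept
    # order letters by the smallest member index for a stable display
    sets.sort(key=lambda s: min(s) if s else n)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = {name: "" for name in names}
    for letter, s in zip(alphabet, sets):
        for i in sorted(s):
            labels[names[i]] += letter
    return labels


def letter_groups(summaries) -> dict:
    """Letters for a set of ETPI summaries: overlapping intervals share a
    letter, non-overlapping intervals share none.

    Summaries are ordered by point estimate before letter assignment, so
    'a' belongs to the smallest group.
    """
    if len(summaries) < 2:
        raise HostvarError("need >= 2 summaries to compare")
    ordered = sorted(summaries, key=lambda s: s.point_estimate)
    names = [s.parameter for s in ordered]
    same = [[ordered[i].overlaps(ordered[j]) for j in range(len(ordered))]
            for i in range(len(ordered))]
    return compact_letter_display(names, same)
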
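"""End-to-end orchestration of the synthetic-data pipeline.

A :class:`RunConfig` names the stages to run and their problem sizes; a
master seed deterministically derives a child seed per stage (so toggling
one stage never shifts another stage's random stream). ``run_pipeline``
executes the requested stages in dependency order, writes per-stage CSV
outputs, collects every warning raised anywhere in the run, and emits a
machine-readable JSON summary plus a human-readable report.

The bundled default configuration runs every stage at demonstration scale
(reduced MCMC chain lengths, permutation counts, and locus numbers) so a
full run finishes in about a minute; the statistical defaults of the
library functions themselves are the full-scale ones.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assoc, chemclass, chemdiv, io, popgen, prefmodel, synthdata
from ._rng import child_seed
from .types import HostvarError

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Configuration for a seeded end-to-end run."""

    seed: int = 1
    output_dir: str = "hostvar_run"
    # stage toggles
    run_chem: bool = True
    run_pref: bool = True
    run_popgen: bool = True
    run_assoc: bool = True
    # chemistry scenario + analysis sizes
    plants_per_population: int = 20
    effect_size: float = 0.8
    q_grid: tuple = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)
    nmds_dims: tuple = (2, 3)
    nmds_starts: int = 4
    # 6 certain-status populations x 20 plants = 120 usable plants, so the
    # demo split keeps the study's 2:1 train:validate ratio at 80/40
    lda_n_train: int = 80
    lda_n_valid: int = 40
    lda_n_iter: int = 200
    null_n_perm: int = 19
    null_inner_iter: int = 20
    diversity_n_boot: int = 100
    # preference / performance MCMC sizes
    pref_n_females: int = 40
    pref_n_iter: int = 2000
    pref_burn_in: int = 500
    banova_n_iter: int = 9000
    banova_chains: int = 3
    banova_burn_in: int = 500
    banova_thin: int = 5
    # population genetics sizes
    popgen_n_loci: int = 2000
    fst_n_boot: int = 200
    # association sizes
    mantel_n_perm: int = 999

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise HostvarError(f"unknown config keys: {sorted(unknown)}")
        for key in ("q_grid", "nmds_dims"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return float(round(obj, ndigits))
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages on synthetic data; return the summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    captured: list = []

    def run_stage(name, fn):
        with warnings.catch_warnings(record=True) as ws:
            warnings.simplefilter("always")
            result = fn()
        for w in ws:
            captured.append(f"[{name}] {w.message}")
        summary["stages"][name] = result

    master = config.seed

    # ---- chemistry -------------------------------------------------------
    chem_table = None
    if config.run_chem or config.run_assoc:
        scenario = synthdata.SyntheticScenario(
            plants_per_population=config.plants_per_population,
            effect_size=config.effect_size,
            seed=child_seed(master, "synth_chem"),
        )
        chem_table, _truth = synthdata.generate_peak_table(scenario)
        io.write_peak_table(chem_table, out / "peak_table.csv")

    if config.run_chem:
        def chem_stage():
            std = chemdiv.standardize_by_dry_weight(chem_table)
            hel = chemdiv.hellinger(std)
            dist = chemdiv.manhattan_distance(hel)
            io.write_distance_matrix(dist, out / "manhattan_distance.csv")

            part = chemdiv.diversity_profile_bootstrap(
                std, None, config.q_grid, n_boot=config.diversity_n_boot,
                seed=child_seed(master, "diversity_bootstrap"),
            )
            prof_rows = []
            for g, res in part.items():
                if res is None:
                    continue
                for lvl in ("alpha", "beta", "gamma"):
                    for qi, q in enumerate(config.q_grid):
                        prof_rows.append({
                            "group": g, "level": lvl, "q": q,
                            "value": res[lvl][qi], "se": res["se"][lvl][qi],
                        })
            import pandas as pd
            pd.DataFrame(prof_rows).to_csv(out / "diversity_profiles.csv",
                                           index=False)

            pooled = chemdiv.population_profiles(std)
            among = chemdiv.hierarchical_partition(
                pooled, {p: "global" for p in pooled.plants}, config.q_grid
            )["global"]

            stress = {}
            nm_seed = child_seed(master, "nmds")
            for k in config.nmds_dims:
                _, s = chemclass.nmds(dist, k, n_starts=config.nmds_starts,
                                      seed=nm_seed)
                stress[str(k)] = s

            shared = chemdiv.shared_compounds(chem_table)
            certain = chem_table.status != "uncertain"
            X = std.intensities.loc[certain, shared].to_numpy()
            labels = chem_table.status[certain].to_numpy()
            val = chemclass.resampled_validation(
                X, labels, config.lda_n_train, config.lda_n_valid,
                config.lda_n_iter, seed=child_seed(master, "lda_validation"),
            )
            obs, null_means, pval = chemclass.null_validation(
                X, labels, "permute_plants", config.null_n_perm,
                config.null_inner_iter, config.lda_n_train,
                config.lda_n_valid, seed=child_seed(master, "lda_null"),
            )
            model = chemclass.lda_fit(X, labels)
            return {
                "n_plants": int(chem_table.intensities.shape[0]),
                "n_compounds": int(chem_table.intensities.shape[1]),
                "n_shared_compounds": len(shared),
                "beta_among_populations": {
                    str(q): among["beta"][qi]
                    for qi, q in enumerate(config.q_grid)
                },
                "nmds_stress": stress,
                "lda_mean_accuracy": val.mean_accuracy,
                "lda_ci95": list(val.ci95),
                "lda_null_p": pval,
                "lda_proportion_of_trace": model.proportion_of_trace.tolist(),
            }
        run_stage("chem", chem_stage)

    # ---- preference and performance --------------------------------------
    if config.run_pref:
        def pref_stage():
            psc = synthdata.PreferenceScenario(
                n_females=config.pref_n_females,
                seed=child_seed(master, "synth_pref"),
            )
            counts, truth = synthdata.generate_preference_counts(psc)
            io.write_preference_counts(counts, out / "preference_counts.csv")
            fit = prefmodel.fit_preference(
                counts, n_iter=config.pref_n_iter, burn_in=config.pref_burn_in,
                seed=child_seed(master, "pref_mcmc"), store_individual=False,
            )
            pis = [prefmodel.etpi(fit, "Pi", index=h)
                   for h in range(counts.n_substrates)]
            letters = prefmodel.letter_groups(
                [dataclasses.replace(s, parameter=lab)
                 for s, lab in zip(pis, counts.substrate_labels)]
            )

            surv_p = (0.65, 0.8, 0.45, 0.85, 0.6, 0.5, 0.7)
            mass_mu = (12.0, 18.0, 25.0, 8.0, 15.0, 22.0, 10.0)
            surv, masses = synthdata.generate_survival_and_mass(
                surv_p, mass_mu, tuple(m * 0.3 for m in mass_mu),
                sources=list(synthdata.default_status_map()),
                seed=child_seed(master, "synth_survival"),
            )
            surv.to_csv(out / "survival_counts.csv", index=False)
            masses.to_csv(out / "larval_masses.csv", index=False)
            sfit = prefmodel.fit_survival(
                surv["n_survived"].to_numpy(), list(surv["source"]),
                n_started=surv["n_started"].to_numpy(),
                n_iter=config.pref_n_iter, burn_in=config.pref_burn_in,
                seed=child_seed(master, "survival_mcmc"),
            )
            bfit = prefmodel.fit_banova(
                masses["mass_mg"].to_numpy(), masses["source"].to_numpy(),
                n_iter=config.banova_n_iter, chains=config.banova_chains,
                burn_in=config.banova_burn_in, thin=config.banova_thin,
                seed=child_seed(master, "banova_mcmc"),
            )
            groups = bfit.meta["groups"]
            gm = [prefmodel.etpi(bfit, "group_mean", index=i)
                  for i in range(len(groups))]
            return {
                "preference_point": {
                    lab: s.point_estimate
                    for lab, s in zip(counts.substrate_labels, pis)
                },
                "preference_etpi": {
                    lab: [s.lower, s.upper]
                    for lab, s in zip(counts.substrate_labels, pis)
                },
                "preference_letters": letters,
                "preference_truth_Pi": list(map(float, truth["Pi"])),
                "survival_rate_point": {
                    src: prefmodel.etpi(sfit, "survival_rate", index=k).point_estimate
                    for k, src in enumerate(surv["source"])
                },
                "banova_group_mean": {
                    g: s.point_estimate for g, s in zip(groups, gm)
                },
                "banova_letters": prefmodel.letter_groups(
                    [dataclasses.replace(s, parameter=g)
                     for s, g in zip(gm, groups)]
                ),
            }
        run_stage("pref", pref_stage)

    # ---- population genetics ----------------------------------------------
    fst_dm = None
    dosage = None
    gl = None
    if config.run_popgen or config.run_assoc:
        gsc = synthdata.PopGenScenario(
            n_loci=config.popgen_n_loci,
            seed=child_seed(master, "synth_popgen"),
        )
        gl, true_G, true_freqs = synthdata.generate_genotype_data(gsc)
        dosage, _post = popgen.genotype_posterior(gl)

    if config.run_popgen:
        def popgen_stage():
            import pandas as pd
            cov = popgen.genetic_covariance(dosage)
            scores, pct = popgen.pca(cov)
            freqs = popgen.allele_freqs_from_dosage(dosage, gl.populations)
            gv = {k: popgen.genetic_variance(freqs.loc[k].to_numpy())
                  for k in freqs.index}
            fst_global = popgen.fst(freqs, "global", n_boot=config.fst_n_boot,
                                    seed=child_seed(master, "fst_bootstrap"))
            pairs, dm = popgen.pairwise_fst(freqs, n_boot=config.fst_n_boot,
                                            seed=child_seed(master, "fst_bootstrap"))
            nonlocal_fst_dm[0] = dm
            pd.DataFrame([r.as_dict() for r in pairs]).to_csv(
                out / "pairwise_fst.csv", index=False
            )
            pd.DataFrame(
                dosage, index=gl.individuals, columns=gl.loci
            ).round(4).to_csv(out / "dosage.csv")
            coords = {p: synthdata.default_coordinates().get(p, None)
                      for p in dm.labels}
            # synthetic populations have no real coordinates; lay them on a
            # deterministic grid for the IBD demonstration
            grid = {p: (39.0 + 0.3 * i, -120.0 + 0.4 * i)
                    for i, p in enumerate(dm.labels)}
            geo = io.geographic_distance_matrix(
                {p: coords[p] or grid[p] for p in dm.labels}
            )
            r, pval, sig = popgen.isolation_by_distance(
                dm, geo, n_perm=config.mantel_n_perm,
                seed=child_seed(master, "ibd"),
            )
            pair_vals = [r_.fst for r_ in pairs]
            return {
                "n_individuals": gl.n_individuals,
                "n_loci": gl.n_loci,
                "pc1_percent": pct[0],
                "pc2_percent": pct[1],
                "genetic_variance": gv,
                "global_fst": fst_global.fst,
                "global_fst_ci": list(fst_global.ci95),
                "pairwise_fst_mean": float(np.mean(pair_vals)),
                "pairwise_fst_min": float(np.min(pair_vals)),
                "pairwise_fst_max": float(np.max(pair_vals)),
                "ibd_mantel_r": r,
                "ibd_p": pval,
                "ibd_significant": sig,
            }
        nonlocal_fst_dm = [None]
        run_stage("popgen", popgen_stage)
        fst_dm = nonlocal_fst_dm[0]

    # ---- cross-axis associations ------------------------------------------
    if config.run_assoc:
        def assoc_stage():
            prot = synthdata.generate_protein_table(
                list(synthdata.default_status_map()),
                plants_per_population=config.plants_per_population,
                seed=child_seed(master, "synth_protein"),
            )
            prot.to_csv(out / "protein.csv")
            std_abs = assoc.standardize_absorbance(prot)
            stat, pval, df = assoc.univariate_tests(
                std_abs.to_numpy(), prot["pop"].to_numpy(), "kruskal_wallis"
            )
            pairs, letters = assoc.post_hoc_kw(
                std_abs.to_numpy(), prot["pop"].to_numpy()
            )
            pairs.to_csv(out / "protein_posthoc.csv", index=False)

            # per-population Mantel: protein vs phytochemistry (plants shared)
            std = chemdiv.standardize_by_dry_weight(chem_table)
            results = []
            m_seed = child_seed(master, "mantel")
            for k, pop in enumerate(sorted(set(chem_table.population))):
                plants = [p for p in chem_table.plants
                          if chem_table.population[p] == pop and p in prot.index]
                if len(plants) < 4:
                    continue
                chem_dm = assoc.euclidean_matrix(std.intensities.loc[plants])
                prot_dm = assoc.euclidean_matrix(std_abs.loc[plants])
                for method in ("pearson", "spearman"):
                    r, p = assoc.mantel(chem_dm, prot_dm, method=method,
                                        n_perm=config.mantel_n_perm,
                                        seed=m_seed + k)
                    results.append({"pop": pop, "pair": "protein~chem",
                                    "method": method, "r": r, "p": p})
            import pandas as pd
            pd.DataFrame(results).to_csv(out / "mantel_results.csv", index=False)
            return {
                "kruskal_wallis_chi2": stat,
                "kruskal_wallis_df": df,
                "kruskal_wallis_p": pval,
                "protein_letters": letters,
                "n_mantel_tests": len(results),
                "mantel_significant": int(sum(r["p"] <= 0.05 for r in results)),
            }
        run_stage("assoc", assoc_stage)

    summary["warnings"] = captured
    summary = _round_floats(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_report(summary, out / "report.txt")
    return summary


def _write_report(summary: dict, path) -> None:
    lines = [f"hostvar run (seed {summary['seed']})", "=" * 40]
    for stage, res in summary["stages"].items():
        lines.append(f"\n[{stage}]")
        for k, v in res.items():
            lines.append(f"  {k}: {v}")
    if summary["warnings"]:
        lines.append("\nwarnings:")
        lines.extend(f"  - {w}" for w in summary["warnings"])
    Path(path).write_text("\n".join(lines) + "\n")


def validate_inputs(paths: dict) -> list:
    """Structural validation of input files; returns a list of error strings.

    ``paths`` maps kind -> path for any of: peak_table, preference_counts,
    genotype_likelihoods (pair of (lik, freq)), distance_matrix,
    coordinates. Report-only: never raises on bad content.
    """
    errors = []
    readers = {
        "peak_table": io.read_peak_table,
        "preference_counts": io.read_preference_counts,
        "distance_matrix": io.read_distance_matrix,
        "coordinates": io.read_coordinates,
    }
    loaded = {}
    for kind, path in paths.items():
        try:
            if kind == "genotype_likelihoods":
                loaded[kind] = io.read_genotype_likelihoods(*path)
            elif kind in readers:
                loaded[kind] = readers[kind](path)
            else:
                errors.append(f"{kind}: unknown input kind")
        except FileNotFoundError:
            errors.append(f"{kind}: file not found: {path}")
        except Exception as exc:  # report-only contract
            errors.append(f"{kind}: {exc}")
    # cross-file checks
    if "peak_table" in loaded and "coordinates" in loaded:
        pops = set(loaded["peak_table"].population)
        missing = pops - set(loaded["coordinates"].index)
        if missing:
            errors.append(
                f"coordinates missing for populations: {sorted(missing)}"
            )
    return errors
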
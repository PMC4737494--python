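"""CSV dialects and readers for the pipeline's input formats.

Everything is plain text:

* peak table — first column plant id, then ``pop``, ``status``,
  ``dry_mass_mg``, then one column per compound (ids preserved verbatim);
* distance matrix — labelled square CSV;
* preference counts — long format (female_id, source_pop, substrate, eggs);
* genotype likelihoods — long CSV (individual, pop, locus, L0..L4) with a
  sidecar frequency CSV (locus, global_freq), or a minimal VCF with
  tetraploid GL/PL fields restricted to biallelic records;
* coordinates — (pop, lat, lon) in decimal degrees, converted to great-
  circle km.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from .types import (
    DistanceMatrix,
    GenotypeLikelihoods,
    HostvarError,
    PeakTable,
    PreferenceCounts,
)

_META_COLS = ["pop", "status", "dry_mass_mg"]


def write_peak_table(table: PeakTable, path) -> None:
    df = pd.concat(
        [table.population.rename("pop"), table.status.rename("status"),
         table.dry_mass.rename("dry_mass_mg"), table.intensities],
        axis=1,
    )
    df.to_csv(path, index_label="plant")


def read_peak_table(path) -> PeakTable:
    df = pd.read_csv(path, index_col=0)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise HostvarError(f"peak table missing metadata columns: {missing}")
    compounds = [c for c in df.columns if c not in _META_COLS]
    return PeakTable(
        intensities=df[compounds].astype(float),
        dry_mass=df["dry_mass_mg"].astype(float),
        population=df["pop"].astype(str),
        status=df["status"].astype(str),
    )


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, index_label="id")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise HostvarError("distance matrix row and column labels differ")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))


def write_preference_counts(counts: PreferenceCounts, path) -> None:
    rows = []
    for i, fid in enumerate(counts.female_id):
        for h, sub in enumerate(counts.substrate_labels):
            rows.append({
                "female_id": fid,
                "source_pop": counts.source_population[i],
                "substrate": sub,
                "eggs": int(counts.counts[i, h]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_preference_counts(path) -> PreferenceCounts:
    df = pd.read_csv(path)
    need = {"female_id", "source_pop", "substrate", "eggs"}
    if not need.issubset(df.columns):
        raise HostvarError(f"preference counts need columns {sorted(need)}")
    wide = df.pivot_table(index="female_id", columns="substrate", values="eggs",
                          aggfunc="sum", fill_value=0)
    src = df.drop_duplicates("female_id").set_index("female_id")["source_pop"]
    src = src.loc[wide.index]
    return PreferenceCounts(
        female_id=list(wide.index),
        source_population=list(src),
        counts=wide.to_numpy(),
        substrate_labels=list(wide.columns),
    )


def write_genotype_likelihoods(gl: GenotypeLikelihoods, lik_path, freq_path) -> None:
    n, L, _ = gl.lik.shape
    rec = {
        "individual": np.repeat(gl.individuals, L),
        "pop": np.repeat(gl.populations, L),
        "locus": np.tile(gl.loci, n),
    }
    flat = gl.lik.reshape(n * L, 5)
    for g in range(5):
        rec[f"L{g}"] = flat[:, g]
    pd.DataFrame(rec).to_csv(lik_path, index=False)
    pd.DataFrame({"locus": gl.loci, "global_freq": gl.global_freq}).to_csv(
        freq_path, index=False
    )


def read_genotype_likelihoods(lik_path, freq_path) -> GenotypeLikelihoods:
    df = pd.read_csv(lik_path)
    need = {"individual", "pop", "locus", "L0", "L1", "L2", "L3", "L4"}
    if not need.issubset(df.columns):
        raise HostvarError(f"genotype likelihood CSV needs columns {sorted(need)}")
    freq = pd.read_csv(freq_path).set_index("locus")["global_freq"]
    inds = list(dict.fromkeys(df["individual"]))
    loci = list(dict.fromkeys(df["locus"]))
    pop_of = df.drop_duplicates("individual").set_index("individual")["pop"]
    wide = df.set_index(["individual", "locus"])[["L0", "L1", "L2", "L3", "L4"]]
    try:
        lik = wide.to_numpy(dtype=float).reshape(len(inds), len(loci), 5)
    except ValueError as exc:
        raise HostvarError("genotype likelihood CSV is not a full grid") from exc
    return GenotypeLikelihoods(
        individuals=inds,
        populations=[pop_of[i] for i in inds],
        loci=loci,
        lik=lik,
        global_freq=freq.loc[loci].to_numpy(dtype=float),
    )


def read_vcf_likelihoods(path, population_map=None) -> GenotypeLikelihoods:
    """Minimal VCF reader for tetraploid genotype likelihoods.

    Accepts biallelic records carrying a 5-entry ``GL`` (log10) or ``PL``
    (phred) FORMAT field. The per-locus global frequency comes from the
    INFO ``AF`` field when present, otherwise from a per-locus maximum-
    likelihood estimate under Hardy-Weinberg (EM over the likelihoods).
    ``population_map`` maps sample name -> population (default: one
    population "all").
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    liks, loci, freqs = [], [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        row = np.ones((len(samples), 5))
        ok = True
        for i, s in enumerate(samples):
            fmt = rec.samples[s]
            if "GL" in fmt and fmt["GL"] is not None and fmt["GL"][0] is not None:
                vals = np.array(fmt["GL"], dtype=float)
                if vals.size != 5:
                    ok = False
                    break
                row[i] = 10.0 ** (vals - vals.max())
            elif "PL" in fmt and fmt["PL"] is not None and fmt["PL"][0] is not None:
                vals = np.array(fmt["PL"], dtype=float)
                if vals.size != 5:
                    ok = False
                    break
                row[i] = 10.0 ** (-(vals - vals.min()) / 10.0)
            else:
                row[i] = 1.0  # missing: flat
        if not ok:
            continue
        loci.append(f"{rec.chrom}:{rec.pos}")
        liks.append(row)
        af = rec.info.get("AF")
        if af is not None:
            freqs.append(float(af[0] if isinstance(af, tuple) else af))
        else:
            freqs.append(_ml_freq(row))
    if not loci:
        raise HostvarError("no usable biallelic tetraploid records in VCF")
    lik = np.stack(liks, axis=1)  # individuals x loci x 5
    if population_map is None:
        pops = ["all"] * len(samples)
    else:
        pops = [population_map.get(s, "all") for s in samples]
    return GenotypeLikelihoods(samples, pops, loci, lik, np.array(freqs))


def _ml_freq(lik_row: np.ndarray, n_iter: int = 50) -> float:
    """Per-locus ML allele frequency under HWE via EM over likelihoods."""
    from scipy.stats import binom

    g = np.arange(5)
    p = 0.5
    for _ in range(n_iter):
        prior = binom.pmf(g, 4, p)
        post = lik_row * prior[None, :]
        norm = post.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        post = post / norm
        p_new = float((post * g).sum() / (4 * post.shape[0]))
        p_new = min(max(p_new, 1e-6), 1 - 1e-6)
        if abs(p_new - p) < 1e-10:
            p = p_new
            break
        p = p_new
    return p


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    R = 6371.0
    la1, lo1, la2, lo2 = map(math.radians, (lat1, lon1, lat2, lon2))
    a = (math.sin((la2 - la1) / 2) ** 2
         + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2)
    return 2 * R * math.asin(math.sqrt(a))


def read_coordinates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"pop", "lat", "lon"}
    if not need.issubset(df.columns):
        raise HostvarError(f"coordinates file needs columns {sorted(need)}")
    return df.set_index("pop")


def geographic_distance_matrix(coords) -> DistanceMatrix:
    """Population-pair great-circle distances (km) from a coords mapping or
    DataFrame with lat/lon."""
    if isinstance(coords, dict):
        coords = pd.DataFrame(
            [(k, v[0], v[1]) for k, v in coords.items()],
            columns=["pop", "lat", "lon"],
        ).set_index("pop")
    labels = list(coords.index)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = coords.iloc[i], coords.iloc[j]
        d[i, j] = d[j, i] = haversine_km(a["lat"], a["lon"], b["lat"], b["lon"])
    return DistanceMatrix(labels, d)
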
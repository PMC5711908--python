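"""Synthetic datasets with the statistical structure the analyses assume.

Three generators stand in for field data so that every pipeline stage is
testable end to end with known truth:

* sequence datasets — per-group coalescent samples on a shared ancestral
  plastid backbone, with two gene pools separated by a configurable number
  of fixed differences and group-specific demographies (constant size or
  sudden expansion);
* AFLP matrices — two-pool dominant-marker fingerprints under the
  recessive-allele convention (band presence probability 1-(1-p)^2), with
  replicate pairs carrying a per-locus flip error and herbarium-style
  year-dependent fragment loss;
* landscapes — multivariate response axes built from orthogonalized
  condition / spatial-surface / climate / noise components whose variance
  fractions are planted exactly, for validating the partial-RDA partition.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import coalescent_genotypes
from .seqio import Alignment, InputError, SampleRecord

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SequenceGroupSpec:
    """One sampling group: a demography within one of the two gene pools."""

    name: str
    n: int
    pool: str  # 'A' or 'B'
    theta0: float = 0.5
    theta1: float = 1000.0
    tau: float = 0.0
    status: str = "native"
    center: tuple[float, float] = (45.0, 42.0)  # lon, lat cluster center


@dataclass(frozen=True)
class SequenceSpec:
    """Defaults emulate the study conditions: a diverse native pool with an
    old expansion, a younger expanding pool, and a 1512-site alignment with
    the pools fixed apart."""

    L: int = 1512
    fixed_differences: int = 10
    groups: tuple[SequenceGroupSpec, ...] = (
        SequenceGroupSpec(
            name="Caucasus-Irano-Turanian", n=25, pool="A",
            theta0=0.5, theta1=1000.0, tau=11.34,
            status="native", center=(44.0, 41.5),
        ),
        SequenceGroupSpec(
            name="Europe", n=52, pool="B",
            theta0=0.5, theta1=1000.0, tau=2.84,
            status="invasive", center=(10.0, 50.0),
        ),
    )


@dataclass(frozen=True)
class AFLPSpec:
    """Defaults emulate the large herbarium fingerprint survey: 134
    genotypes over 404 loci, ~1-2% replicate error, fragment loss for
    pre-2003 collections."""

    n_per_pool: tuple[int, int] = (67, 67)
    loci: int = 404
    allele_freq_beta: tuple[float, float] = (0.4, 1.6)
    private_band_rate: tuple[float, float] = (0.10, 0.03)  # per pool
    n_replicate_pairs: int = 25
    error_rate: float = 0.011
    year_range: tuple[int, int] = (1960, 2015)
    recent_fraction: float = 0.55
    cutoff_year: int = 2003
    degradation_slope: float = 0.006  # band-loss probability per year before cutoff
    n_extreme_degraded: int = 3
    extreme_loss: float = 0.6


@dataclass(frozen=True)
class LandscapeSpec:
    """Planted variance partition for the partial-RDA recovery experiment."""

    n: int = 400
    n_axes: int = 3
    fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.0, 0.50)
    # (condition, spatial, climate, noise); must sum to <= 1
    n_climate: int = 4
    spatial_terms: tuple[str, ...] = ("x", "y", "y2", "xy")  # degree <= 2


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    sequences: SequenceSpec = field(default_factory=SequenceSpec)
    aflp: AFLPSpec = field(default_factory=AFLPSpec)
    landscape: LandscapeSpec = field(default_factory=LandscapeSpec)


# ---------------------------------------------------------------- sequences


def make_sequence_dataset(
    spec: SequenceSpec, seed: int
) -> tuple[Alignment, dict]:
    """Aligned multi-group sample with embedded truth labels.

    A shared random ancestral sequence carries ``fixed_differences`` sites
    at which pool B is fixed for an alternative base; each group's
    within-pool variation comes from an independent coalescent sample whose
    infinite-sites mutations are mapped to distinct spare columns.
    """
    rng = np.random.default_rng(seed)
    L = spec.L
    ancestral = rng.choice(BASES, size=L)
    fixed_pos = rng.choice(L, size=spec.fixed_differences, replace=False)
    taken = set(int(p) for p in fixed_pos)
    pool_b_bases = {}
    for p in fixed_pos:
        pool_b_bases[int(p)] = rng.choice([b for b in BASES if b != ancestral[p]])

    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    truth_pool: dict[str, str] = {}
    counter = 0
    for g in spec.groups:
        G = coalescent_genotypes(g.n, g.theta0, g.theta1, g.tau, rng)
        S = G.shape[1]
        free = [c for c in range(L) if c not in taken]
        if S > len(free):
            raise InputError(f"group {g.name}: {S} mutations exceed free sites")
        pos = rng.choice(len(free), size=S, replace=False)
        positions = [free[int(i)] for i in pos]
        taken.update(positions)
        derived = {
            c: rng.choice([b for b in BASES if b != ancestral[c]]) for c in positions
        }
        for i in range(g.n):
            counter += 1
            sid = f"{g.name[:3].upper()}{counter:03d}"
            seq = ancestral.copy()
            if g.pool == "B":
                for c, b in pool_b_bases.items():
                    seq[c] = b
            for s_idx, c in enumerate(positions):
                if G[i, s_idx]:
                    seq[c] = derived[c]
            lon = g.center[0] + rng.normal(0, 3.0)
            lat = g.center[1] + rng.normal(0, 2.0)
            samples.append(
                SampleRecord(
                    sample_id=sid, region=g.name, status=g.status,
                    year=int(rng.integers(1995, 2016)),
                    lon=float(np.clip(lon, -180, 180)),
                    lat=float(np.clip(lat, -90, 90)),
                )
            )
            rows.append(seq)
            truth_pool[sid] = g.pool
    aln = Alignment(samples=samples, sites=np.array(rows, dtype="U1"))
    truth = {
        "pool": truth_pool,
        "ancestral": "".join(ancestral),
        "fixed_positions": sorted(int(p) for p in fixed_pos),
        "groups": {g.name: {"tau": g.tau, "theta0": g.theta0, "theta1": g.theta1,
                            "n": g.n, "pool": g.pool} for g in spec.groups},
    }
    return aln, truth


def write_sequence_dataset(aln: Alignment, out_dir, truth: dict | None = None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "alignment.fasta"
    with open(fasta, "w") as fh:
        for s, row in zip(aln.samples, aln.sites):
            fh.write(f">{s.sample_id}\n{''.join(row)}\n")
    meta = out / "metadata.tsv"
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id, "region": s.region, "status": s.status,
                "year": s.year, "lon": s.lon, "lat": s.lat,
            }
            for s in aln.samples
        ]
    )
    df.to_csv(meta, sep="\t", index=False)
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return fasta, meta


# --------------------------------------------------------------------- AFLP


def make_aflp_dataset(spec: AFLPSpec, seed: int):
    """Two-pool dominant-marker matrix with replicates and degradation.

    Returns (AFLPMatrix, truth dict).  Null-allele frequencies are drawn per
    pool from a Beta distribution; band presence probability follows the
    recessive-allele convention 1-(1-p)^2 with p the dominant-allele
    frequency.  Collections before the cutoff year lose each present band
    with probability slope x (cutoff - year); a few planted samples lose an
    extreme fraction outright.
    """
    from .aflp import AFLPMatrix

    rng = np.random.default_rng(seed)
    a, b = spec.allele_freq_beta
    pools = ("A", "B")
    p_freq = {}
    for k, pool in enumerate(pools):
        p = rng.beta(a, b, size=spec.loci)
        private_other = rng.random(spec.loci) < spec.private_band_rate[1 - k]
        p[private_other] = 0.0  # band private to the other pool
        p_freq[pool] = p

    n_total = sum(spec.n_per_pool)
    years = np.where(
        rng.random(n_total) < spec.recent_fraction,
        rng.integers(spec.cutoff_year, spec.year_range[1] + 1, size=n_total),
        rng.integers(spec.year_range[0], spec.cutoff_year, size=n_total),
    )
    samples = []
    data_rows = []
    pool_of = {}
    idx = 0
    for k, pool in enumerate(pools):
        region = "Caucasus-Irano-Turanian" if pool == "A" else "Europe"
        for _ in range(spec.n_per_pool[k]):
            idx += 1
            sid = f"AF{idx:03d}"
            band_p = 1.0 - (1.0 - p_freq[pool]) ** 2
            row = (rng.random(spec.loci) < band_p).astype(float)
            samples.append(
                SampleRecord(sample_id=sid, region=region,
                             status="native" if pool == "A" else "invasive",
                             year=int(years[idx - 1]))
            )
            data_rows.append(row)
            pool_of[sid] = pool
    data = np.array(data_rows)

    # replicate pairs: duplicates of recent samples with per-locus flip error
    recent = [i for i, s in enumerate(samples) if s.year >= spec.cutoff_year]
    rep_src = rng.choice(recent, size=min(spec.n_replicate_pairs, len(recent)),
                         replace=False)
    replicate_pairs = []
    for i in rep_src:
        sid = samples[i].sample_id
        rid = f"{sid}r"
        flip = rng.random(spec.loci) < spec.error_rate
        row = data[i].copy()
        row[flip] = 1.0 - row[flip]
        samples.append(
            SampleRecord(sample_id=rid, region=samples[i].region,
                         status=samples[i].status, year=samples[i].year)
        )
        data = np.vstack([data, row[None, :]])
        replicate_pairs.append((sid, rid))

    # herbarium degradation: year-dependent band loss for pre-cutoff samples
    degraded = []
    for i, s in enumerate(samples):
        if s.year is not None and s.year < spec.cutoff_year:
            loss = spec.degradation_slope * (spec.cutoff_year - s.year)
            drop = (rng.random(spec.loci) < loss) & (data[i] == 1.0)
            data[i, drop] = 0.0
            degraded.append(s.sample_id)
    # planted extreme-degradation samples (oldest collections)
    old_idx = [i for i, s in enumerate(samples)
               if s.year is not None and s.year < spec.cutoff_year]
    old_idx.sort(key=lambda i: samples[i].year)
    extreme = []
    for i in old_idx[: spec.n_extreme_degraded]:
        drop = (rng.random(spec.loci) < spec.extreme_loss) & (data[i] == 1.0)
        data[i, drop] = 0.0
        extreme.append(samples[i].sample_id)

    m = AFLPMatrix(samples=samples, loci=[f"L{j + 1:03d}" for j in range(spec.loci)],
                   data=data, replicate_pairs=replicate_pairs)
    truth = {
        "pool": pool_of,
        "error_rate": spec.error_rate,
        "degraded": degraded,
        "extreme_degraded": extreme,
        "cutoff_year": spec.cutoff_year,
    }
    return m, truth


def write_aflp_dataset(m, out_dir, truth: dict | None = None):
    from .aflp import write_aflp

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = out / "aflp_matrix.csv"
    write_aflp(m, matrix)
    meta = out / "aflp_metadata.tsv"
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "region": s.region, "status": s.status,
             "year": s.year, "lon": s.lon, "lat": s.lat}
            for s in m.samples
        ]
    ).to_csv(meta, sep="\t", index=False)
    reps = out / "replicates.tsv"
    pd.DataFrame(m.replicate_pairs, columns=["sample_a", "sample_b"]).to_csv(
        reps, sep="\t", index=False
    )
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return matrix, meta, reps


# ---------------------------------------------------------------- landscape


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_landscape(spec: LandscapeSpec, seed: int):
    """Response axes with an exactly planted variance partition.

    Components are built per axis and orthogonalized sequentially
    (condition, spatial surface, climate, noise) so that the planted
    fractions are exact sums of squares of the generated response.  The
    spatial surface is a degree-2 polynomial field, leaving the degree-3
    candidates of forward selection as true negatives.

    Returns (Y DataFrame, coords DataFrame, climate DataFrame,
    condition Series, truth dict).
    """
    f_cond, f_spat, f_clim, f_noise = spec.fractions
    if min(spec.fractions) < 0 or sum(spec.fractions) > 1.0 + 1e-9:
        raise InputError("fractions must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    n = spec.n
    lon = rng.uniform(-20, 60, size=n)
    lat = rng.uniform(35, 65, size=n)
    x = (lon - lon.mean()) / lon.std(ddof=0)
    y = (lat - lat.mean()) / lat.std(ddof=0)
    condition = (x + 0.5 * rng.standard_normal(n) > 0).astype(float)
    climate = pd.DataFrame(
        {f"bio{j + 1}": 0.5 * x + rng.standard_normal(n)
         for j in range(spec.n_climate)}
    )
    term_funcs = {
        "x": x, "y": y, "x2": x**2, "xy": x * y, "y2": y**2,
    }
    ones = np.ones(n)
    Y = np.empty((n, spec.n_axes))
    for jax in range(spec.n_axes):
        C = condition - condition.mean()
        w = rng.standard_normal(len(spec.spatial_terms))
        S = sum(wi * term_funcs[t] for wi, t in zip(w, spec.spatial_terms))
        K = climate.to_numpy() @ rng.standard_normal(spec.n_climate)
        E = rng.standard_normal(n)
        comps = []
        basis = [ones / np.linalg.norm(ones)]
        for v in (C, S, K, E):
            for b in basis:
                v = v - (v @ b) * b
            v = _unit(v)
            basis.append(v)
            comps.append(v)
        Chat, Shat, Khat, Ehat = comps
        Y[:, jax] = (
            np.sqrt(f_cond) * Chat + np.sqrt(f_spat) * Shat
            + np.sqrt(f_clim) * Khat + np.sqrt(f_noise) * Ehat
        )
    Ydf = pd.DataFrame(Y, columns=[f"axis{j + 1}" for j in range(spec.n_axes)])
    coords = pd.DataFrame({"lon": lon, "lat": lat})
    truth = {
        "fractions": {
            "condition": f_cond, "spatial": f_spat,
            "climate": f_clim, "noise": f_noise,
        },
        "spatial_terms": list(spec.spatial_terms),
        "n": n,
    }
    return Ydf, coords, climate, pd.Series(condition, name="condition"), truth


def write_landscape(Y, coords, climate, condition, out_dir, truth=None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Y.to_csv(out / "response.tsv", sep="\t", index=False)
    coords.to_csv(out / "coords.tsv", sep="\t", index=False)
    climate.to_csv(out / "climate.tsv", sep="\t", index=False)
    condition.to_frame().to_csv(out / "condition.tsv", sep="\t", index=False)
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out
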
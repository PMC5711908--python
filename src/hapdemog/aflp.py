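"""Dominant-marker (AFLP) quality control, ordination and structure post-processing.

AFLP fingerprints are binary presence/absence profiles over anonymous loci.
Herbarium-derived DNA loses fragments with specimen age, so the module
screens fragment counts for degradation (Brown-Forsythe homogeneity of
variance, ANOVA) and filters samples whose fragment count falls outside the
mu +/- 2 sigma band of a recent reference cohort, before distance-based
ordination (PCoA with broken-stick assessment), AMOVA, band statistics and
Evanno delta-K post-processing of external clustering log-likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import InputError, SampleRecord, read_metadata


@dataclass
class AFLPMatrix:
    """Binary samples x loci matrix with replicate map and batch labels.

    ``data`` is float with entries 0.0 / 1.0 / NaN (missing).
    """

    samples: list[SampleRecord]
    loci: list[str]
    data: np.ndarray
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    batch: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.samples), len(self.loci)):
            raise InputError(
                f"data shape {self.data.shape} != "
                f"({len(self.samples)}, {len(self.loci)})"
            )
        finite = self.data[np.isfinite(self.data)]
        if not np.all(np.isin(finite, (0.0, 1.0))):
            bad = sorted(set(finite) - {0.0, 1.0})
            raise InputError(f"non-binary AFLP entries: {bad}")
        ids = set(self.sample_ids)
        for a, b in self.replicate_pairs:
            if a not in ids or b not in ids:
                raise InputError(f"replicate pair ({a}, {b}) references unknown sample")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset(self, sample_ids) -> "AFLPMatrix":
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        rows = [index[sid] for sid in sample_ids]
        keep = set(sample_ids)
        return AFLPMatrix(
            samples=[self.samples[i] for i in rows],
            loci=list(self.loci),
            data=self.data[rows],
            replicate_pairs=[
                (a, b) for a, b in self.replicate_pairs if a in keep and b in keep
            ],
            batch=[self.batch[i] for i in rows] if self.batch else None,
        )


def read_aflp(matrix_path, metadata_path, replicates_path=None) -> AFLPMatrix:
    """Load a 0/1/NA matrix (rows = samples), metadata and replicate pairs."""
    df = pd.read_csv(matrix_path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    data = df.to_numpy(dtype=float)
    meta = read_metadata(metadata_path).set_index("sample_id")
    absent = [sid for sid in df.index if sid not in meta.index]
    if absent:
        raise InputError(f"samples missing from metadata: {absent}")
    samples = []
    for sid in df.index:
        row = meta.loc[sid]
        samples.append(
            SampleRecord(
                sample_id=sid,
                region=None if pd.isna(row.get("region")) else str(row.get("region")),
                status=None if pd.isna(row.get("status")) else str(row.get("status")),
                year=None if pd.isna(row.get("year")) else int(row.get("year")),
                lon=None if pd.isna(row.get("lon")) else float(row.get("lon")),
                lat=None if pd.isna(row.get("lat")) else float(row.get("lat")),
            )
        )
    pairs = []
    if replicates_path is not None:
        rep = pd.read_csv(replicates_path, sep="\t", dtype=str)
        pairs = list(zip(rep.iloc[:, 0], rep.iloc[:, 1]))
    batch = (
        meta.loc[df.index, "batch"].astype(str).tolist()
        if "batch" in meta.columns
        else None
    )
    return AFLPMatrix(
        samples=samples, loci=list(df.columns), data=data,
        replicate_pairs=pairs, batch=batch,
    )


def write_aflp(m: AFLPMatrix, matrix_path) -> None:
    pd.DataFrame(m.data, index=m.sample_ids, columns=m.loci).to_csv(matrix_path)


def replicate_error_rate(m: AFLPMatrix) -> float:
    """Mismatch rate over all replicate pairs: sum(mismatches)/sum(scored loci)."""
    if not m.replicate_pairs:
        raise InputError("no replicate pairs")
    index = {sid: i for i, sid in enumerate(m.sample_ids)}
    mismatch = 0
    scored = 0
    for a, b in m.replicate_pairs:
        x, y = m.data[index[a]], m.data[index[b]]
        both = np.isfinite(x) & np.isfinite(y)
        mismatch += int(np.sum(x[both] != y[both]))
        scored += int(both.sum())
    if scored == 0:
        raise InputError("replicate pairs share no scored loci")
    return mismatch / scored


def fragment_counts(m: AFLPMatrix) -> np.ndarray:
    """Per-sample number of present fragments (missing loci ignored)."""
    return np.nansum(m.data, axis=1).astype(int)


def brown_forsythe(groups) -> tuple[float, tuple[int, int], float]:
    """Brown-Forsythe HOV test: ANOVA F on |x - group median|.

    Returns (F, (df1, df2), p).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InputError("need >= 2 groups with >= 2 values each")
    F, p = stats.levene(*groups, center="median")
    k = len(groups)
    N = sum(len(g) for g in groups)
    return float(F), (k - 1, N - k), float(p)


def anova_oneway(groups) -> tuple[float, tuple[int, int], float]:
    """Plain one-way ANOVA on the raw values (mean differences)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    F, p = stats.f_oneway(*groups)
    k = len(groups)
    N = sum(len(g) for g in groups)
    return float(F), (k - 1, N - k), float(p)


@dataclass
class FilterReport:
    mu: float
    sigma: float
    lower: float
    upper: float
    reference_ids: list[str]
    removed_ids: list[str]


def fragment_filter(
    m: AFLPMatrix, reference_year: int = 2003, k_sigma: float = 2.0
) -> tuple[AFLPMatrix, FilterReport]:
    """Drop samples whose fragment count leaves the reference mu +/- k sigma band.

    The band is estimated from samples collected in ``reference_year`` or
    later (recent, presumably undegraded material) and applied two-sided to
    every sample.  Because removing a recent outlier shrinks the reference
    spread, the band is re-estimated after each removal pass until no
    further sample falls outside it (a trimmed estimate); this makes the
    filter idempotent on its own output.  The reported band is the final one.
    """
    counts = fragment_counts(m)
    keep = np.ones(m.n, dtype=bool)
    ref_mask = np.array(
        [s.year is not None and s.year >= reference_year for s in m.samples]
    )
    if not ref_mask.any():
        raise InputError(f"no reference samples collected in {reference_year} or later")
    while True:
        ref = ref_mask & keep
        if not ref.any():
            raise InputError("fragment filter removed every reference sample")
        mu = float(np.mean(counts[ref]))
        sigma = float(np.std(counts[ref], ddof=1))
        lower, upper = mu - k_sigma * sigma, mu + k_sigma * sigma
        new_keep = keep & (counts >= lower) & (counts <= upper)
        if new_keep.sum() == keep.sum():
            break
        keep = new_keep
    report = FilterReport(
        mu=mu, sigma=sigma, lower=lower, upper=upper,
        reference_ids=[s.sample_id for s, r in zip(m.samples, ref_mask & keep)
                       if r],
        removed_ids=[s.sample_id for s, k in zip(m.samples, keep) if not k],
    )
    return m.subset([sid for sid, k in zip(m.sample_ids, keep) if k]), report


def euclidean_distance(m: AFLPMatrix) -> np.ndarray:
    """Pairwise Euclidean distance over mutually scored loci."""
    X = m.data
    n = m.n
    d = np.zeros((n, n))
    finite = np.isfinite(X)
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            d[i, j] = d[j, i] = float(
                np.sqrt(np.sum((X[i, both] - X[j, both]) ** 2))
            )
    return d


def jaccard_distance(m: AFLPMatrix) -> np.ndarray:
    """sqrt(1 - Jaccard similarity), a dissimilarity with Euclidean properties."""
    X = m.data
    n = m.n
    d = np.zeros((n, n))
    finite = np.isfinite(X)
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            a = np.sum((X[i, both] == 1) & (X[j, both] == 1))
            u = np.sum((X[i, both] == 1) | (X[j, both] == 1))
            sim = a / u if u else 1.0
            d[i, j] = d[j, i] = float(np.sqrt(1.0 - sim))
    return d


@dataclass
class PCoAResult:
    eigenvalues: np.ndarray  # all, descending (may include negatives)
    coordinates: np.ndarray  # samples x positive axes
    explained: np.ndarray  # % of positive-eigenvalue variation per axis
    broken_stick: np.ndarray  # expected proportions over positive axes

    @property
    def n_positive(self) -> int:
        return self.coordinates.shape[1]

    def significant_axes(self) -> np.ndarray:
        """Axes whose relative eigenvalue exceeds the broken-stick expectation."""
        rel = self.explained / 100.0
        return np.flatnonzero(rel > self.broken_stick)


def broken_stick(p: int) -> np.ndarray:
    """Expected eigenvalue proportions b_k = (1/p) sum_{i=k}^p 1/i."""
    if p < 1:
        raise InputError("p must be >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def pcoa(d: np.ndarray, positive_tol: float = 1e-8) -> PCoAResult:
    """Principal coordinates: eigendecomposition of the Gower-centered matrix.

    Negative eigenvalues (possible for non-Euclidean dissimilarities) are
    reported but excluded from the coordinate axes and from the
    explained-variance denominator; positivity threshold is
    ``positive_tol`` x the largest eigenvalue.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise InputError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    A = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > positive_tol * max(vals[0], 0.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    explained = 100.0 * vals[pos] / vals[pos].sum()
    return PCoAResult(
        eigenvalues=vals,
        coordinates=coords,
        explained=explained,
        broken_stick=broken_stick(int(pos.sum())),
    )


def band_statistics(m: AFLPMatrix, group_by: str = "region") -> pd.DataFrame:
    """Per-group fragment totals, unique (private) fragments, % polymorphic
    loci and mean Nei gene diversity under the dominant-marker convention.

    Band (null-allele) frequency per locus: q = sqrt(1 - f) with f the band
    presence frequency, allele frequency p = 1 - q assuming Hardy-Weinberg;
    gene diversity H = 2 p q averaged over scored loci.
    """
    labels = sorted({getattr(s, group_by) for s in m.samples if getattr(s, group_by)})
    present_by_group = {}
    rows = []
    for lab in labels:
        rows_idx = [i for i, s in enumerate(m.samples) if getattr(s, group_by) == lab]
        X = m.data[rows_idx]
        present = np.nansum(X, axis=0) > 0
        present_by_group[lab] = present
    for lab in labels:
        rows_idx = [i for i, s in enumerate(m.samples) if getattr(s, group_by) == lab]
        X = m.data[rows_idx]
        scored = np.isfinite(X)
        n_per_locus = scored.sum(axis=0)
        ok = n_per_locus > 0
        f = np.zeros(len(m.loci))
        f[ok] = np.nansum(X[:, ok], axis=0) / n_per_locus[ok]
        present = present_by_group[lab]
        others = [present_by_group[o] for o in labels if o != lab]
        unique = present & ~np.logical_or.reduce(others) if others else present
        poly = ok & (f > 0) & (f < 1)
        q = np.sqrt(np.clip(1.0 - f[ok], 0.0, 1.0))
        h = 2.0 * (1.0 - q) * q
        rows.append(
            {
                group_by: lab,
                "n": len(rows_idx),
                "fragments": int(present.sum()),
                "unique_fragments": int(unique.sum()),
                "pct_polymorphic": 100.0 * poly.sum() / ok.sum(),
                "gene_diversity": float(np.mean(h)),
            }
        )
    return pd.DataFrame(rows)


def _amova_ss(d2: np.ndarray, groups: np.ndarray):
    """Total / within sums of squares from squared distances."""
    N = d2.shape[0]
    iu = np.triu_indices(N, k=1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 1:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


@dataclass
class AmovaResult:
    phi_st: float
    sigma2_among: float
    sigma2_within: float
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    p: float | None


def amova(
    d: np.ndarray, groups, permutations: int = 999, seed: int = 0
) -> AmovaResult:
    """One-level AMOVA from a distance matrix: Phi_ST and permutation p-value."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise InputError("AMOVA needs >= 2 groups")
    d2 = np.asarray(d, dtype=float) ** 2
    N = d2.shape[0]
    k = len(labels)
    sizes = np.array([np.sum(groups == g) for g in labels], dtype=float)
    ss_total, ss_within = _amova_ss(d2, groups)
    ss_among = ss_total - ss_within
    df_a, df_w = k - 1, N - k
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    n0 = (N - np.sum(sizes**2) / N) / (k - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n0
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom > 0 else 0.0
    p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(groups)
            sst, ssw = _amova_ss(d2, perm)
            ssa = sst - ssw
            msa, msw = ssa / df_a, ssw / df_w
            sa = (msa - msw) / n0
            ph = sa / (sa + msw) if (sa + msw) > 0 else 0.0
            if ph >= phi:
                count += 1
        p = (count + 1) / (permutations + 1)
    return AmovaResult(
        phi_st=float(phi), sigma2_among=float(sigma_a), sigma2_within=float(sigma_w),
        ss_among=float(ss_among), ss_within=float(ss_within),
        df_among=df_a, df_within=df_w, p=p,
    )


def evanno_delta_k(lnp: pd.DataFrame) -> pd.DataFrame:
    """Evanno's mean Delta-K from a (K, replicate log-probability) table.

    Input columns: ``K``, ``lnP`` (one row per replicate run).  Returns per
    interior K: mean lnP, sd, and delta_K = |mean L(K+1) - 2 mean L(K) +
    mean L(K-1)| / sd(K); NaN with a warning where sd is zero, and NaN at
    the boundary K values.
    """
    if not {"K", "lnP"} <= set(lnp.columns):
        raise InputError("lnP table needs columns 'K' and 'lnP'")
    g = lnp.groupby("K")["lnP"]
    mean = g.mean()
    sd = g.std(ddof=1)
    counts = g.size()
    ks = sorted(mean.index)
    if len(ks) < 3:
        raise InputError("need >= 3 consecutive K values")
    if (counts < 2).any():
        raise InputError("need >= 2 replicates per K")
    rows = []
    for i, K in enumerate(ks):
        if i == 0 or i == len(ks) - 1:
            dk = np.nan
        else:
            second = abs(mean[ks[i + 1]] - 2 * mean[K] + mean[ks[i - 1]])
            if sd[K] == 0:
                warnings.warn(f"sd of lnP is zero at K={K}; delta-K undefined",
                              stacklevel=2)
                dk = np.nan
            else:
                dk = second / sd[K]
        rows.append({"K": K, "mean_lnP": mean[K], "sd_lnP": sd[K], "delta_K": dk})
    return pd.DataFrame(rows)
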
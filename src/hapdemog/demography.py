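"""Mismatch-distribution demography under the sudden-expansion model.

The observed distribution of pairwise nucleotide differences is compared
with the transient expectation of a stepwise (sudden) expansion: a
population at mutation-scaled size theta0 grows instantaneously to theta1
at tau/2 mutational time units in the past (tau = 2*u*t with u the
per-haplotype per-generation mutation rate and t the time in generations).

For a pair of lineages with coalescence followed in pair-mutational time
(rate 1/theta of coalescing per unit, Poisson(t) differences given
coalescence at t), the expected frequency of j differences is

    F_j = Fhat_j(theta1) * P[Gamma(j+1) <= tau*(1+theta1)/theta1]
        + exp(-tau/theta1) * sum_{i<=j} Pois(i; tau) * Fhat_{j-i}(theta0)

with Fhat_j(theta) = theta^j / (1+theta)^(j+1) the constant-size
(geometric) equilibrium.  The first term covers pairs coalescing since the
expansion, the second pairs whose ancestry predates it.

Goodness of fit uses the sum of squared deviations (SSD) between observed
and expected frequencies and Harpending's raggedness index; significance
and confidence intervals come from a parametric bootstrap in which
coalescent datasets are simulated at the fitted parameters and re-fitted.
The per-generation haplotype mutation rate is u = mu*k*g (substitution
rate x sequence length x generation time), and tau converts to calendar
time via T = tau / (2u).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .seqio import Alignment, InputError, SampleRecord
from .popgen import pairwise_differences

THETA1_MAX = 99999.0  # conventional bound for effectively infinite post-expansion size


@dataclass
class MismatchHistogram:
    """Counts of pairwise difference values over all unordered pairs."""

    counts: np.ndarray  # index = difference class 0..d
    n: int  # sample size

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        expected_pairs = self.n * (self.n - 1) // 2
        if int(round(self.counts.sum())) != expected_pairs:
            raise InputError(
                f"histogram mass {self.counts.sum():.0f} != n(n-1)/2 = {expected_pairs}"
            )

    @property
    def d(self) -> int:
        return len(self.counts) - 1

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass(frozen=True)
class RateModel:
    """Calibrated mutation-rate inputs for the tau -> time conversion."""

    mu: float  # substitutions / site / year
    k: int  # sequence length (sites)
    g: float  # generation time (years)

    def __post_init__(self):
        if self.mu <= 0 or self.k <= 0 or self.g <= 0:
            raise InputError("rate model fields must all be positive")

    @property
    def u(self) -> float:
        """Per-haplotype per-generation neutral mutation rate, u = mu*k*g."""
        return self.mu * self.k * self.g


@dataclass
class MismatchResult:
    tau: float
    theta0: float
    theta1: float
    expected: np.ndarray
    SSD: float
    HRag: float
    p_SSD: float | None = None
    p_HRag: float | None = None
    tau_CI: tuple[float, float] | None = None
    T_years: float | None = None
    T_years_CI: tuple[float, float] | None = None
    degenerate: bool = False
    boot_tau: np.ndarray | None = field(default=None, repr=False)


def mismatch_histogram(aln: Alignment) -> MismatchHistogram:
    if aln.n < 3:
        raise InputError("mismatch analysis requires n >= 3")
    diffs, _ = pairwise_differences(aln)
    iu = np.triu_indices(aln.n, k=1)
    return _histogram_from_pairs(diffs[iu], aln.n)


def _histogram_from_pairs(pair_diffs: np.ndarray, n: int) -> MismatchHistogram:
    d = int(pair_diffs.max()) if len(pair_diffs) else 0
    counts = np.bincount(pair_diffs.astype(int), minlength=d + 1).astype(float)
    return MismatchHistogram(counts=counts, n=n)


def _geometric_equilibrium(theta: float, d: int) -> np.ndarray:
    """Fhat_j(theta) = theta^j/(1+theta)^(j+1) for j = 0..d."""
    j = np.arange(d + 1)
    if theta <= 0:
        out = np.zeros(d + 1)
        out[0] = 1.0
        return out
    return np.exp(j * np.log(theta) - (j + 1) * np.log1p(theta))


def expected_mismatch(
    tau: float,
    theta0: float,
    theta1: float,
    d: int,
    tail: str = "fold",
) -> np.ndarray:
    """Model frequencies over difference classes 0..d.

    The transient distribution has support on all non-negative integers;
    mass beyond class d is folded into class d (``tail='fold'``) or the
    truncated vector is renormalized (``tail='renorm'``).
    """
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise InputError("mismatch model parameters must be non-negative")
    if tail not in ("fold", "renorm"):
        raise InputError(f"tail must be 'fold' or 'renorm', got {tail!r}")
    j = np.arange(d + 1)
    eq1 = _geometric_equilibrium(theta1, d)
    eq0 = _geometric_equilibrium(theta0, d)
    if tau == 0:
        F = eq0.copy()
    else:
        if theta1 > 0:
            recent = eq1 * special.gammainc(j + 1, tau * (1.0 + theta1) / theta1)
            survive = np.exp(-tau / theta1)
        else:
            # theta1 = 0: every pair coalesces instantly after the expansion
            recent = _geometric_equilibrium(0.0, d)
            survive = 0.0
        pois = stats.poisson.pmf(j, tau)
        ancient = survive * np.convolve(pois, eq0)[: d + 1]
        F = recent + ancient
    if tail == "fold":
        # the exact distribution sums to 1, so the folded last class is the
        # complement of the classes below it
        out = F.copy()
        out[d] = 1.0 - F[:d].sum()
    else:
        out = F / F.sum()
    return out


def raggedness(h: MismatchHistogram) -> float:
    """Harpending's raggedness r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2, x_{d+1} = 0."""
    x = np.append(h.frequencies, 0.0)
    return float(np.sum(np.diff(x) ** 2))


def fit_sudden_expansion(
    h: MismatchHistogram,
    starts: list[tuple[float, float, float]] | None = None,
) -> MismatchResult:
    """Least-squares point fit of (tau, theta0, theta1) to the histogram.

    Deterministic multistart: a 3x3x3 grid scaled to the histogram mean
    (or caller-supplied warm starts), each polished with bounded
    trust-region least squares; ties broken by lowest SSD then lowest tau.
    """
    obs = h.frequencies
    d = h.d
    if d == 0:  # all pairs identical
        expected = expected_mismatch(0.0, 0.0, 0.0, d=0)
        return MismatchResult(
            tau=0.0, theta0=0.0, theta1=0.0, expected=expected,
            SSD=float(np.sum((obs - expected) ** 2)), HRag=raggedness(h),
            degenerate=True,
        )
    m = float(np.sum(np.arange(d + 1) * obs))  # mean pairwise differences
    m = max(m, 0.1)
    if starts is None:
        starts = []
        for ft in (0.5, 1.0, 1.5):
            for f0 in (0.02, 0.3, 1.0):
                for f1 in (5.0, 50.0, THETA1_MAX / m):
                    starts.append((ft * m, f0 * m, f1 * m))

    def residuals(p):
        t, a, b = np.maximum(p, 0.0)
        return obs - expected_mismatch(t, a, min(b, THETA1_MAX), d=d)

    hi = 10.0 * (d + 1)
    best = None
    for s in starts:
        x0 = np.clip(np.asarray(s, dtype=float), 0.0, [hi, hi, THETA1_MAX])
        res = optimize.least_squares(
            residuals, x0, bounds=([0.0, 0.0, 0.0], [hi, hi, THETA1_MAX]),
            xtol=1e-12, ftol=1e-14, gtol=1e-12,
        )
        ssd = float(np.sum(res.fun**2))
        key = (ssd, res.x[0])
        if best is None or key < best[0]:
            best = (key, res.x)
    tau, theta0, theta1 = (float(v) for v in best[1])
    expected = expected_mismatch(tau, theta0, theta1, d=d)
    return MismatchResult(
        tau=tau, theta0=theta0, theta1=theta1, expected=expected,
        SSD=float(np.sum((obs - expected) ** 2)), HRag=raggedness(h),
    )


def _msprime_demography(theta0: float, theta1: float, tau: float):
    import msprime

    # time unit: generations with per-haplotype mutation rate u = 1/2, so
    # N = theta and the size change sits tau generations (= tau/2 units of
    # 1/u) in the past; pairwise coalescence rate for ploidy 1 is 1/N.
    dem = msprime.Demography()
    dem.add_population(name="pop", initial_size=max(theta1, 1e-10))
    dem.add_population_parameters_change(
        time=tau, initial_size=max(theta0, 1e-10), population="pop"
    )
    return dem


def _coalescent_tree(
    n: int, theta0: float, theta1: float, tau: float, rng: np.random.Generator
):
    """Kingman genealogy under the two-epoch (sudden expansion) model.

    Time runs backwards in generations with N = theta (pairwise coalescence
    rate 1/theta), switching from theta1 to theta0 at time tau.  Returns
    (parent, time) arrays over 2n-1 nodes, leaves first.
    """
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=int)
    time = np.zeros(total)
    active = list(range(n))
    t = 0.0
    next_node = n
    th1 = max(theta1, 1e-12)
    th0 = max(theta0, 1e-12)
    while len(active) > 1:
        k = len(active)
        rate_pairs = k * (k - 1) / 2.0
        if t < tau:
            dt = rng.exponential(th1 / rate_pairs)
            if t + dt > tau:
                t = tau  # memoryless: redraw in the ancient epoch
                continue
        else:
            dt = rng.exponential(th0 / rate_pairs)
        t += dt
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for x in sorted((i, j), reverse=True):
            active.pop(x)
        parent[a] = parent[b] = next_node
        time[next_node] = t
        active.append(next_node)
        next_node += 1
    return parent, time


def simulate_pair_differences(
    n: int,
    theta0: float,
    theta1: float,
    tau: float,
    seed: int,
    engine: str = "internal",
) -> np.ndarray:
    """Pairwise difference counts for one coalescent dataset (no alignment).

    ``engine='internal'`` uses the package's own genealogy sampler with
    Poisson(u * branch length) infinite-sites mutations (u = 1/2 per lineage
    per generation, matching the msprime parameterization);
    ``engine='msprime'`` runs the identical model through msprime and is
    kept as an independent cross-check.
    """
    if engine == "msprime":
        import msprime

        ts = msprime.sim_ancestry(
            samples=n, ploidy=1,
            demography=_msprime_demography(theta0, theta1, tau),
            random_seed=seed,
        )
        mts = msprime.sim_mutations(
            ts, rate=0.5, model=msprime.BinaryMutationModel(),
            discrete_genome=False, random_seed=seed,
        )
        G = (mts.genotype_matrix() > 0).astype(np.int64)  # sites x samples
        diffs = np.zeros((n, n), dtype=int)
        if G.shape[0]:
            cross = G.T @ (1 - G)
            diffs = cross + cross.T
        iu = np.triu_indices(n, k=1)
        return diffs[iu]
    if engine != "internal":
        raise InputError(f"unknown engine {engine!r}")
    rng = np.random.default_rng(seed)
    parent, time = _coalescent_tree(n, theta0, theta1, tau, rng)
    total = 2 * n - 1
    # leaves below each node
    below = np.zeros((total, n), dtype=bool)
    below[np.arange(n), np.arange(n)] = True
    for v in range(total - 1):  # children appear before parents
        if parent[v] >= 0:
            below[parent[v]] |= below[v]
    diffs = np.zeros((n, n), dtype=int)
    for v in range(total - 1):
        if parent[v] < 0:
            continue
        branch = time[parent[v]] - time[v]
        m = rng.poisson(0.5 * branch)
        if m:
            mask = below[v]
            diffs += m * np.outer(mask, ~mask)
    diffs = diffs + diffs.T
    iu = np.triu_indices(n, k=1)
    return diffs[iu]


def coalescent_genotypes(
    n: int, theta0: float, theta1: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, S) binary infinite-sites genotype matrix from the internal sampler."""
    parent, time = _coalescent_tree(n, theta0, theta1, tau, rng)
    total = 2 * n - 1
    below = np.zeros((total, n), dtype=bool)
    below[np.arange(n), np.arange(n)] = True
    for v in range(total - 1):
        if parent[v] >= 0:
            below[parent[v]] |= below[v]
    cols = []
    for v in range(total - 1):
        if parent[v] < 0:
            continue
        m = rng.poisson(0.5 * (time[parent[v]] - time[v]))
        cols.extend([below[v]] * m)
    if not cols:
        return np.zeros((n, 0), dtype=bool)
    return np.array(cols, dtype=bool).T


def coalescent_simulate(
    n: int, theta0: float, theta1: float, tau: float, L: int, seed: int
) -> Alignment:
    """Simulate an aligned sample under the sudden-expansion coalescent.

    Infinite-sites mutations are mapped to distinct columns of an L-site
    alignment (collisions redrawn); the ancestral sequence is random over
    A/C/G/T and each mutation introduces a distinct derived base.
    """
    import msprime

    if n < 2:
        raise InputError("coalescent_simulate requires n >= 2")
    ts = msprime.sim_ancestry(
        samples=n, ploidy=1,
        demography=_msprime_demography(theta0, theta1, tau),
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=0.5, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=seed,
    )
    rng = np.random.default_rng(seed)
    ancestral = rng.choice(list("ACGT"), size=L)
    sites = np.tile(ancestral, (n, 1)).astype("U1")
    G = (mts.genotype_matrix() > 0).astype(bool)  # S x n
    S = G.shape[0]
    if S > L:
        raise InputError(f"{S} mutations exceed alignment length {L}")
    positions = rng.choice(L, size=S, replace=False)
    bases = "ACGT"
    for s_idx, col in enumerate(positions):
        derived = rng.choice([b for b in bases if b != ancestral[col]])
        sites[G[s_idx], col] = derived
    samples = [SampleRecord(sample_id=f"sim{i + 1}") for i in range(n)]
    return Alignment(samples=samples, sites=sites)


def parametric_bootstrap(
    h: MismatchHistogram,
    fit: MismatchResult,
    B: int = 1000,
    seed: int = 0,
    rate: RateModel | None = None,
    ci_level: float = 0.95,
) -> MismatchResult:
    """Goodness-of-fit p-values and percentile CI for tau by simulation.

    B coalescent datasets of the observed sample size are simulated at the
    fitted (tau, theta0, theta1) and re-fitted; p_SSD is the proportion of
    simulated SSDs at least as large as the observed one (analogously for
    the raggedness index), and the tau CI is the percentile interval of the
    re-fitted taus.
    """
    if B < 100:
        warnings.warn(f"B = {B} < 100: p-values will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    ssd_sim = np.empty(B)
    rag_sim = np.empty(B)
    tau_sim = np.empty(B)
    warm = [(fit.tau, fit.theta0, fit.theta1)]
    for b in range(B):
        s = int(rng.integers(1, 2**31 - 1))
        pair_diffs = simulate_pair_differences(
            h.n, fit.theta0, fit.theta1, fit.tau, seed=s
        )
        hb = _histogram_from_pairs(pair_diffs, h.n)
        fb = fit_sudden_expansion(
            hb,
            starts=warm + [(max(hb.frequencies @ np.arange(hb.d + 1), 0.1),
                            0.3, 50.0)],
        )
        ssd_sim[b] = fb.SSD
        rag_sim[b] = fb.HRag
        tau_sim[b] = fb.tau
    p_ssd = float(np.mean(ssd_sim >= fit.SSD))
    p_rag = float(np.mean(rag_sim >= fit.HRag))
    lo, hi = np.quantile(tau_sim, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    result = MismatchResult(
        tau=fit.tau, theta0=fit.theta0, theta1=fit.theta1,
        expected=fit.expected, SSD=fit.SSD, HRag=fit.HRag,
        p_SSD=p_ssd, p_HRag=p_rag, tau_CI=(float(lo), float(hi)),
        degenerate=fit.degenerate, boot_tau=tau_sim,
    )
    if rate is not None:
        result.T_years = expansion_time(fit.tau, rate)
        result.T_years_CI = (
            expansion_time(float(lo), rate),
            expansion_time(float(hi), rate),
        )
    return result


def expansion_time(
    tau: float, rate: RateModel, convention: str = "per-year"
) -> float:
    """Convert tau to calendar years since the start of expansion.

    ``convention='per-year'`` (default): T_years = tau / (2 u) with
    u = mu*k*g — the reading of T = tau/(2u) in which u plays the role of a
    per-year haplotype rate.  ``convention='per-generation'``: T = tau/(2u)
    generations, multiplied by g to give years (i.e. tau/(2*mu*k)); the
    dimensionally strict alternative, g times larger.
    """
    if tau < 0:
        raise InputError("tau must be non-negative")
    if convention == "per-year":
        return tau / (2.0 * rate.u)
    if convention == "per-generation":
        return tau * rate.g / (2.0 * rate.u)
    raise InputError(f"unknown convention {convention!r}")


def rate_from_calibration(divergence_per_site: float, split_age_years: float) -> float:
    """Generic d/2t substitution-rate estimate from a dated split."""
    if split_age_years <= 0:
        raise InputError("split age must be positive")
    if divergence_per_site < 0:
        raise InputError("divergence must be non-negative")
    if divergence_per_site == 0:
        warnings.warn("zero divergence: rate estimate is 0", stacklevel=2)
    return divergence_per_site / (2.0 * split_age_years)
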
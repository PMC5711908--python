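"""Per-group molecular diversity statistics.

Reproduces the standard summary row for a plastid sample: sample size n,
segregating sites S, haplotype count h, haplotype diversity Hd, nucleotide
diversity pi (per site; printed as percent in tabular output), mean pairwise
differences k-bar, and Tajima's D.  Missing data (N) and masked columns are
handled by pairwise deletion: each pair of sequences is compared over the
sites at which both are scored, and per-site quantities are normalised by
the per-pair comparable length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import Alignment, HaplotypeSet, InputError, collapse_haplotypes

MISSING = ("N", "-")


@dataclass(frozen=True)
class TajimaConstants:
    """The n-dependent coefficients of Tajima's neutrality statistic."""

    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise InputError(f"Tajima constants require n >= 2, got {n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class DiversityStats:
    """One summary row (one group)."""

    group: str
    n: int
    S: int
    h: int
    Hd: float
    pi_site: float
    k_bar: float
    D: float | None  # None when undefined (S == 0 or n < 4)

    @property
    def pi_percent(self) -> float:
        return 100.0 * self.pi_site


def _scored(sites: np.ndarray) -> np.ndarray:
    """Boolean matrix of positions carrying a real base (not N, not gap)."""
    return (sites != "N") & (sites != "-")


def segregating_sites(aln: Alignment) -> int:
    """Unmasked columns with >= 2 distinct non-missing states."""
    if aln.n < 2:
        raise InputError("segregating_sites requires n >= 2")
    count = 0
    for c in np.flatnonzero(~aln.masked):
        col = aln.sites[:, c]
        states = set(col) - set(MISSING)
        if len(states) >= 2:
            count += 1
    return count


def haplotype_diversity(counts) -> float:
    """Nei's unbiased haplotype (gene) diversity: Hd = n/(n-1) (1 - sum p_i^2)."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0 or np.any(counts <= 0):
        raise InputError("counts must be a nonempty list of positive integers")
    n = counts.sum()
    if n < 2:
        raise InputError("haplotype diversity undefined for n < 2")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def pairwise_differences(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair difference counts and comparable lengths (pairwise deletion).

    Returns two (n, n) symmetric integer matrices: diffs[i, j] = number of
    unmasked sites where i and j are both scored and differ; comp[i, j] =
    number of sites where both are scored.
    """
    keep = ~aln.masked
    sites = aln.sites[:, keep]
    scored = _scored(sites)
    n = aln.n
    diffs = np.zeros((n, n), dtype=int)
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = scored[i] & scored[j]
            d = int(np.sum(sites[i, both] != sites[j, both]))
            diffs[i, j] = diffs[j, i] = d
            comp[i, j] = comp[j, i] = int(both.sum())
    return diffs, comp


def nucleotide_diversity(aln: Alignment) -> tuple[float, float]:
    """(pi per site, mean pairwise differences k-bar) over all unordered pairs.

    pi is the mean of per-pair (differences / comparable sites); k-bar is the
    plain mean of per-pair difference counts.
    """
    if aln.n < 2:
        raise InputError("nucleotide_diversity requires n >= 2")
    diffs, comp = pairwise_differences(aln)
    iu = np.triu_indices(aln.n, k=1)
    d = diffs[iu].astype(float)
    m = comp[iu].astype(float)
    if np.any(m == 0):
        raise InputError("a pair of sequences shares no scored sites")
    return float(np.mean(d / m)), float(np.mean(d))


def tajimas_D(n: int, S: int, k_bar: float) -> float | None:
    """Tajima's D = (k_bar - S/a1) / sqrt(e1 S + e2 S(S-1)); None when S = 0."""
    if n < 4:
        raise InputError(f"Tajima's D requires n >= 4, got {n}")
    if S < 0:
        raise InputError("S must be non-negative")
    if S == 0:
        return None
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return float((k_bar - S / c.a1) / math.sqrt(var))


def diversity_stats(aln: Alignment, group: str = "all") -> DiversityStats:
    """All summary statistics for one alignment subset."""
    S = segregating_sites(aln)
    hset = collapse_haplotypes(aln)
    counts = [len(m) for _, _, m in hset.haplotypes]
    Hd = 0.0 if len(counts) == 1 else haplotype_diversity(counts)
    pi, k_bar = nucleotide_diversity(aln)
    D = tajimas_D(aln.n, S, k_bar) if aln.n >= 4 and S > 0 else None
    return DiversityStats(
        group=group, n=aln.n, S=S, h=hset.n_haplotypes, Hd=Hd,
        pi_site=pi, k_bar=k_bar, D=D,
    )


def group_summary(
    aln: Alignment,
    hset: HaplotypeSet,
    grouping: str = "region",
    exclude_haplotypes: dict[str, list[str]] | None = None,
) -> list[DiversityStats]:
    """One DiversityStats per group of the metadata field ``grouping``.

    ``exclude_haplotypes`` maps group label -> haplotype ids to drop from
    that group before computing statistics (e.g. excluding a genetically
    intermediate accession from a refugium group).
    """
    if grouping not in ("region", "status"):
        raise InputError(f"grouping must be 'region' or 'status', got {grouping!r}")
    exclude_haplotypes = exclude_haplotypes or {}
    assign = hset.assignment()
    out = []
    labels = []
    for s in aln.samples:
        lab = getattr(s, grouping)
        if lab is not None and lab not in labels:
            labels.append(lab)
    for lab in labels:
        drop = set(exclude_haplotypes.get(lab, ()))
        ids = [
            s.sample_id
            for s in aln.samples
            if getattr(s, grouping) == lab and assign[s.sample_id] not in drop
        ]
        if len(ids) < 2:
            continue
        out.append(diversity_stats(aln.subset(ids), group=lab))
    return out


def summary_frame(stats: list[DiversityStats]) -> pd.DataFrame:
    """Serialize rows in the conventional table layout (pi as percent, D as em-dash when undefined)."""
    return pd.DataFrame(
        {
            "group": [s.group for s in stats],
            "n": [s.n for s in stats],
            "S": [s.S for s in stats],
            "h": [s.h for s in stats],
            "Hd": [round(s.Hd, 3) for s in stats],
            "pi_percent": [round(s.pi_percent, 3) for s in stats],
            "D": ["—" if s.D is None else round(s.D, 4) for s in stats],
        }
    )
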
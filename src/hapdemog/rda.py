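"""Partial redundancy analysis of genotype ordination axes.

Multivariate genotype axes (typically the significant PCoA coordinates of
an AFLP distance matrix) are regressed on trend-surface spatial predictors
(third-degree orthogonal polynomials of Z-standardized longitude/latitude)
and bioclimatic covariates, after partialling out a binary gene-pool
indicator as a conditioning term.  Significance of terms, axes and the
whole model is assessed by permutation of residuals under the reduced
model; forward selection adds the candidate with the strongest marginal
pseudo-F whose permutation p-value clears alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import InputError

MONOMIALS = (
    (1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)
)
MONOMIAL_NAMES = ("x", "y", "x2", "xy", "y2", "x3", "x2y", "xy2", "y3")


def standardize_and_polynomials(
    lon, lat
) -> pd.DataFrame:
    """Nine orthogonalized degree-<=3 polynomial terms of standardized coordinates.

    Longitude/latitude are Z-standardized; the monomial basis
    {x, y, x2, xy, y2, x3, x2y, xy2, y3} is orthogonalized sequentially
    (Gram-Schmidt against the intercept and all prior terms) and unit-scaled.
    Degenerate (numerically zero after projection) columns are dropped with
    a warning.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(lon)
    if n < 10:
        raise InputError("need >= 10 samples for trend-surface terms")
    if np.std(lon) == 0 or np.std(lat) == 0:
        raise InputError("degenerate coordinates: zero variance in lon or lat")
    x = (lon - lon.mean()) / lon.std(ddof=0)
    y = (lat - lat.mean()) / lat.std(ddof=0)
    basis = [np.ones(n)]
    cols = {}
    import warnings as _w

    for (i, j), name in zip(MONOMIALS, MONOMIAL_NAMES):
        v = x**i * y**j
        for b in basis:
            v = v - (v @ b) / (b @ b) * b
        norm = np.linalg.norm(v)
        if norm < 1e-10 * n:
            _w.warn(f"spatial term {name} is degenerate and was dropped",
                    stacklevel=2)
            continue
        basis.append(v)
        cols[name] = v / (norm / np.sqrt(n))  # unit variance scale
    out = pd.DataFrame(cols)
    # mean 0 by construction (orthogonal to intercept); scale to sd 1
    return out / out.std(ddof=0)


def zscore(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=0)


def correlation_screen(
    climate: pd.DataFrame, threshold: float = 0.5
) -> tuple[list[str], pd.DataFrame]:
    """Pairwise Pearson correlations with |r| >= threshold flagged.

    Columns are reported, not auto-dropped; the caller decides retention.
    Returns (retained column names, report of flagged pairs).
    """
    corr = climate.corr()
    flags = []
    cols = list(climate.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                flags.append({"var1": a, "var2": b, "r": float(r)})
    return cols, pd.DataFrame(flags, columns=["var1", "var2", "r"])


def _as_matrix(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def _residualize(A: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of A on [intercept, covariates]."""
    n = A.shape[0]
    X = np.ones((n, 1))
    if covariates is not None and covariates.size:
        X = np.hstack([X, _as_matrix(covariates)])
    Q, _ = np.linalg.qr(X)
    return A - Q @ (Q.T @ A)


@dataclass
class RDAResult:
    total_variance: float
    conditional_pct: float
    constrained_pct: float
    residual_pct: float
    axis_variance_pct: np.ndarray  # % of constrained variance per axis
    F_whole: float
    df_model: int
    df_resid: int
    p_whole: float | None = None
    term_table: pd.DataFrame | None = None
    vif: pd.Series | None = None
    axis_p: np.ndarray | None = None
    site_scores: np.ndarray | None = field(default=None, repr=False)


def partial_rda(Y, X, Z=None) -> RDAResult:
    """Variance partition of Y into conditional (Z), constrained (X) and residual.

    Y is centered; Y and X are residualized on [intercept, Z]; the
    constrained component is the variance of the fitted values of the
    residualized regression.  Percentages refer to the total variance of
    centered Y; the decomposition is exact.
    """
    Y = _as_matrix(Y)
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    total = float(np.sum(Yc**2))
    if total == 0:
        raise InputError("response has zero variance")
    Z_ = _as_matrix(Z) if Z is not None else None
    Yres = _residualize(Yc, Z_)
    conditional = total - float(np.sum(Yres**2))
    q_z = Z_.shape[1] if Z_ is not None else 0
    if X is None or np.size(X) == 0:
        constrained = 0.0
        fitted = np.zeros_like(Yres)
        df_model = 0
        rank = 0
    else:
        X_ = _as_matrix(X)
        Xres = _residualize(X_, Z_)
        Q, R = np.linalg.qr(Xres)
        keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
        Q = Q[:, keep]
        rank = Q.shape[1]
        fitted = Q @ (Q.T @ Yres)
        constrained = float(np.sum(fitted**2))
        df_model = rank
    residual = total - conditional - constrained
    df_resid = n - 1 - q_z - df_model
    # canonical axes: SVD of the fitted matrix
    if df_model > 0:
        u, s, vt = np.linalg.svd(fitted, full_matrices=False)
        axis_var = s**2
        axis_var = axis_var[axis_var > 1e-12 * max(axis_var[0], 1e-300)]
        axis_pct = 100.0 * axis_var / axis_var.sum()
        scores = u[:, : len(axis_var)] * s[: len(axis_var)]
    else:
        axis_pct = np.array([])
        scores = np.zeros((n, 0))
    F = np.inf
    if residual > 1e-12 * total:
        if df_model > 0:
            F = (constrained / df_model) / (residual / df_resid)
        else:
            F = 0.0
    return RDAResult(
        total_variance=total,
        conditional_pct=100.0 * conditional / total,
        constrained_pct=100.0 * constrained / total,
        residual_pct=100.0 * residual / total,
        axis_variance_pct=axis_pct,
        F_whole=float(F),
        df_model=df_model,
        df_resid=df_resid,
        site_scores=scores,
    )


def pseudo_F(
    constrained: float, residual: float, df_model: int, df_resid: int
) -> float:
    """F = (constrained/df_model) / (residual/df_resid)."""
    if residual <= 0:
        return np.inf
    return (constrained / df_model) / (residual / df_resid)


def _perm_F_stats(
    Y: np.ndarray, X: np.ndarray, Z: np.ndarray | None,
    n_perm: int, rng: np.random.Generator,
) -> tuple[float, np.ndarray, int, int]:
    """Observed and permuted pseudo-F for adding X given [intercept, Z].

    Permutation of residuals under the reduced model: the response residuals
    E (Y residualized on the reduced model) are row-permuted; the total sum
    of squares of E is permutation-invariant, so only the constrained part
    needs recomputation.
    """
    Y = _as_matrix(Y)
    n = Y.shape[0]
    Z_ = _as_matrix(Z) if Z is not None else None
    q_z = Z_.shape[1] if Z_ is not None else 0
    E = _residualize(Y - Y.mean(axis=0), Z_)
    Xres = _residualize(_as_matrix(X), Z_)
    Q, R = np.linalg.qr(Xres)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    df_model = Q.shape[1]
    df_resid = n - 1 - q_z - df_model
    total = float(np.sum(E**2))

    def f_stat(Em):
        con = float(np.sum((Q.T @ Em) ** 2))
        res = total - con
        if res <= 0:
            return np.inf
        return (con / df_model) / (res / df_resid)

    F_obs = f_stat(E)
    F_perm = np.empty(n_perm)
    for b in range(n_perm):
        F_perm[b] = f_stat(E[rng.permutation(n)])
    return F_obs, F_perm, df_model, df_resid


def permutation_test(
    Y, X, Z=None, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """(pseudo-F, p) for the whole constrained model given the condition.

    p = (#{F' > F} + 1)/(n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    F_obs, F_perm, _, _ = _perm_F_stats(
        _as_matrix(Y), _as_matrix(X), Z, n_perm, rng
    )
    p = (np.sum(F_perm > F_obs) + 1) / (n_perm + 1)
    return float(F_obs), float(p)


def forward_select(
    Y,
    candidates: pd.DataFrame,
    Z=None,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy forward selection by marginal permutation pseudo-F.

    A global permutation test of the full candidate set acts as the gate:
    when it is not significant at ``alpha`` nothing is selected (protecting
    the family-wise error of the many marginal tests).  At each subsequent
    step every remaining candidate is tested conditional on the
    already-selected terms plus the condition; the candidate with the
    largest observed pseudo-F is admitted if its permutation p <= alpha.
    Returns (selected names in order, log of every evaluation).
    """
    rng = np.random.default_rng(seed)
    Y = _as_matrix(Y)
    Z_ = _as_matrix(Z) if Z is not None else None
    selected: list[str] = []
    log_rows = []
    F_g, F_g_perm, _, _ = _perm_F_stats(
        Y, candidates.to_numpy(), Z_, n_perm, rng
    )
    p_global = (np.sum(F_g_perm > F_g) + 1) / (n_perm + 1)
    log_rows.append(
        {"step": 0, "term": "<global>", "F": F_g, "p": p_global,
         "selected": False}
    )
    if p_global > alpha:
        return [], pd.DataFrame(log_rows)
    remaining = list(candidates.columns)
    step = 0
    while remaining:
        step += 1
        covar = Z_
        if selected:
            sel = candidates[selected].to_numpy()
            covar = sel if covar is None else np.hstack([covar, sel])
        best = None
        for name in remaining:
            F_obs, F_perm, _, _ = _perm_F_stats(
                Y, candidates[[name]].to_numpy(), covar, n_perm, rng
            )
            p = (np.sum(F_perm > F_obs) + 1) / (n_perm + 1)
            log_rows.append(
                {"step": step, "term": name, "F": F_obs, "p": p, "selected": False}
            )
            if best is None or F_obs > best[1]:
                best = (name, F_obs, p)
        name, F_obs, p = best
        if p <= alpha:
            selected.append(name)
            remaining.remove(name)
            for row in log_rows:
                if row["step"] == step and row["term"] == name:
                    row["selected"] = True
        else:
            break
    return selected, pd.DataFrame(log_rows)


def vif(X: pd.DataFrame, condition=None) -> pd.Series:
    """Variance inflation factor per column: 1/(1 - R^2_j).

    Each term is regressed on the remaining terms (plus the condition as a
    covariate when given); VIF of a duplicated column is reported as inf.
    """
    names = list(X.columns)
    M = X.to_numpy(dtype=float)
    Z_ = _as_matrix(condition) if condition is not None else None
    out = {}
    for j, name in enumerate(names):
        others = np.delete(M, j, axis=1)
        if Z_ is not None:
            others = np.hstack([others, Z_])
        yj = M[:, j]
        res = _residualize(yj[:, None], others if others.size else None)
        ss_res = float(np.sum(res**2))
        yc = yj - yj.mean()
        ss_tot = float(np.sum(yc**2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[name] = np.inf if r2 > 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def term_table(
    Y, X: pd.DataFrame, Z=None, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Sequential per-term variance and permutation p (terms in given order)."""
    Y = _as_matrix(Y)
    Yc = Y - Y.mean(axis=0)
    total = float(np.sum(Yc**2))
    Z_ = _as_matrix(Z) if Z is not None else None
    rng = np.random.default_rng(seed)
    rows = []
    prior: list[str] = []
    for name in X.columns:
        covar = Z_
        if prior:
            prev = X[prior].to_numpy()
            covar = prev if covar is None else np.hstack([covar, prev])
        F_obs, F_perm, dfm, _ = _perm_F_stats(
            Y, X[[name]].to_numpy(), covar, n_perm, rng
        )
        # variance attributed to this term, sequentially
        E = _residualize(Yc, covar)
        Xres = _residualize(X[[name]].to_numpy(), covar)
        Q, _ = np.linalg.qr(Xres)
        var = float(np.sum((Q.T @ E) ** 2))
        p = (np.sum(F_perm > F_obs) + 1) / (n_perm + 1)
        rows.append(
            {
                "term": name, "df": dfm, "variance": var / (Y.shape[0] - 1),
                "pct_of_total": 100.0 * var / total, "F": F_obs, "p": p,
            }
        )
        prior.append(name)
    return pd.DataFrame(rows)


def axis_tests(
    Y, X, Z=None, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Marginal permutation test per constrained axis, prior axes as covariates."""
    rng = np.random.default_rng(seed)
    result = partial_rda(Y, X, Z)
    scores = result.site_scores
    Y = _as_matrix(Y)
    Z_ = _as_matrix(Z) if Z is not None else None
    rows = []
    for a in range(scores.shape[1]):
        covar = Z_
        if a > 0:
            prev = scores[:, :a]
            covar = prev if covar is None else np.hstack([covar, prev])
        F_obs, F_perm, _, _ = _perm_F_stats(
            Y, scores[:, [a]], covar, n_perm, rng
        )
        p = (np.sum(F_perm > F_obs) + 1) / (n_perm + 1)
        rows.append(
            {
                "axis": a + 1,
                "pct_constrained": result.axis_variance_pct[a],
                "F": F_obs,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def interaction_terms(
    spatial: pd.DataFrame, climate: pd.DataFrame
) -> pd.DataFrame:
    """All pairwise spatial x climate products, Z-standardized."""
    cols = {}
    for s in spatial.columns:
        for c in climate.columns:
            cols[f"{s}:{c}"] = spatial[s].to_numpy() * climate[c].to_numpy()
    out = pd.DataFrame(cols, index=spatial.index)
    return zscore(out)


def candidate_set(spatial: pd.DataFrame, climate: pd.DataFrame) -> pd.DataFrame:
    """Forward-selection candidates: spatial + climate mains + interactions."""
    return pd.concat(
        [spatial.reset_index(drop=True),
         zscore(climate).reset_index(drop=True),
         interaction_terms(spatial.reset_index(drop=True),
                           zscore(climate).reset_index(drop=True))],
        axis=1,
    )
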
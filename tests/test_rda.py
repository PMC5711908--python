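import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from hapdemog import rda, synthetic
from hapdemog.rda import (
    candidate_set,
    correlation_screen,
    forward_select,
    partial_rda,
    permutation_test,
    pseudo_F,
    standardize_and_polynomials,
    term_table,
    vif,
)
from hapdemog.seqio import InputError


@pytest.fixture
def landscape():
    return synthetic.make_landscape(
        synthetic.LandscapeSpec(n=200, fractions=(0.25, 0.25, 0.0, 0.50)),
        seed=21,
    )


class TestSpatialTerms:
    def test_orthogonality_and_scaling(self):
        rng = np.random.default_rng(1)
        sp = standardize_and_polynomials(
            rng.uniform(-10, 40, 80), rng.uniform(35, 60, 80)
        )
        M = sp.to_numpy()
        assert np.allclose(M.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(M.std(axis=0), 1.0, atol=1e-10)
        corr = np.corrcoef(M.T)
        assert np.allclose(corr - np.eye(9), 0.0, atol=1e-8)

    def test_cubic_orthogonal_to_linear_on_symmetric_grid(self):
        x = np.tile(np.linspace(-2, 2, 9), 9)
        y = np.repeat(np.linspace(-2, 2, 9), 9)
        # raw x and x^3 are strongly correlated on this grid
        assert abs(np.corrcoef(x, x**3)[0, 1]) > 0.9
        sp = standardize_and_polynomials(x, y)
        assert abs(sp["x"] @ sp["x3"]) < 1e-8

    def test_rank_preserved_round_trip(self):
        rng = np.random.default_rng(2)
        lon, lat = rng.uniform(0, 30, 60), rng.uniform(40, 60, 60)
        sp = standardize_and_polynomials(lon, lat)
        x = (lon - lon.mean()) / lon.std()
        y = (lat - lat.mean()) / lat.std()
        basis = np.column_stack([np.ones(60), sp.to_numpy()])
        for raw in (x, y, x * y, x**2 * y, y**3):
            coef, res, *_ = np.linalg.lstsq(basis, raw, rcond=None)
            assert np.allclose(basis @ coef, raw, atol=1e-8)

    def test_degenerate_coordinate_rejected(self):
        with pytest.raises(InputError, match="degenerate"):
            standardize_and_polynomials(np.ones(20), np.linspace(0, 1, 20))


class TestCorrelationScreen:
    def test_duplicate_column_flagged(self):
        x = np.random.default_rng(0).normal(size=50)
        clim = pd.DataFrame({"a": x, "b": x, "c": np.random.default_rng(1)
                             .normal(size=50)})
        retained, report = correlation_screen(clim)
        assert retained == ["a", "b", "c"]  # reported, not dropped
        assert {"a", "b"} == set(report.iloc[0][["var1", "var2"]])
        assert report.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_noise_unflagged(self):
        rng = np.random.default_rng(3)
        clim = pd.DataFrame(rng.normal(size=(400, 4)),
                            columns=list("abcd"))
        _, report = correlation_screen(clim)
        assert report.empty

    def test_threshold_one_retains_everything(self):
        clim = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        retained, report = correlation_screen(clim, threshold=1.1)
        assert retained == ["a", "b"] and report.empty


class TestPartialRDA:
    def test_decomposition_exact(self, landscape):
        Y, coords, clim, cond, _ = landscape
        sp = standardize_and_polynomials(coords["lon"], coords["lat"])
        res = partial_rda(Y.to_numpy(), sp.to_numpy(), Z=cond.to_numpy())
        assert res.conditional_pct + res.constrained_pct + res.residual_pct == (
            pytest.approx(100.0, abs=1e-8)
        )
        assert res.axis_variance_pct.sum() == pytest.approx(100.0)

    def test_orthogonal_predictors_explain_nothing(self):
        rng = np.random.default_rng(5)
        n = 100
        X = rng.normal(size=(n, 3))
        # response orthogonal to X by construction
        Y = rng.normal(size=(n, 2))
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), X]))
        Y = Y - Q @ (Q.T @ Y)
        res = partial_rda(Y, X)
        assert res.constrained_pct == pytest.approx(0.0, abs=1e-8)

    def test_exact_linear_map_fully_explained(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        Y = X @ rng.normal(size=(3, 2))
        res = partial_rda(Y, X)
        assert res.constrained_pct == pytest.approx(100.0, abs=1e-6)
        assert res.residual_pct == pytest.approx(0.0, abs=1e-6)

    def test_empty_condition_equals_plain_rda(self, landscape):
        Y, coords, _, _, _ = landscape
        sp = standardize_and_polynomials(coords["lon"], coords["lat"])
        res = partial_rda(Y.to_numpy(), sp.to_numpy(), Z=None)
        assert res.conditional_pct == pytest.approx(0.0, abs=1e-10)

    def test_empty_predictors_constrain_nothing(self, landscape):
        Y, _, _, cond, _ = landscape
        res = partial_rda(Y.to_numpy(), None, Z=cond.to_numpy())
        assert res.constrained_pct == 0.0

    def test_planted_partition_recovered(self, landscape):
        Y, coords, clim, cond, truth = landscape
        sp = standardize_and_polynomials(coords["lon"], coords["lat"])
        res = partial_rda(Y.to_numpy(), sp.to_numpy(), Z=cond.to_numpy())
        f = truth["fractions"]
        assert res.conditional_pct == pytest.approx(100 * f["condition"], abs=5)
        assert res.constrained_pct == pytest.approx(100 * f["spatial"], abs=5)
        assert res.residual_pct == pytest.approx(100 * f["noise"], abs=5)

    def test_matches_vegan_reference(self, tmp_path, landscape):
        Y, coords, clim, cond, _ = landscape
        sp = standardize_and_polynomials(coords["lon"], coords["lat"])
        ours = partial_rda(Y.to_numpy(), sp.to_numpy(), Z=cond.to_numpy())
        pd.concat(
            [Y, sp.add_prefix("S_"), cond.rename("cond")], axis=1
        ).to_csv(tmp_path / "d.csv", index=False)
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            d <- read.csv(commandArgs(TRUE)[1])
            Y <- d[, grep("^axis", names(d))]
            X <- d[, grep("^S_", names(d))]
            m <- rda(Y ~ . + Condition(cond), data = cbind(X, cond = d$cond))
            v <- c(m$pCCA$tot.chi, m$CCA$tot.chi, m$CA$tot.chi) / m$tot.chi
            cat(sprintf("%.8f %.8f %.8f", v[1], v[2], v[3]))
            """
        )
        (tmp_path / "check.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "check.R"), str(tmp_path / "d.csv")],
            capture_output=True, text=True, timeout=240,
        )
        if out.returncode != 0:
            pytest.skip(f"vegan unavailable: {out.stderr[:200]}")
        ref = [100 * float(x) for x in out.stdout.split()]
        assert ours.conditional_pct == pytest.approx(ref[0], abs=1e-4)
        assert ours.constrained_pct == pytest.approx(ref[1], abs=1e-4)
        assert ours.residual_pct == pytest.approx(ref[2], abs=1e-4)


class TestPseudoFAndPermutation:
    def test_f_identities(self):
        assert pseudo_F(10.0, 10.0, 2, 2) == pytest.approx(1.0)
        assert pseudo_F(5.0, 0.0, 1, 10) == np.inf

    def test_f_recomputed_from_variance_table(self, landscape):
        Y, coords, _, cond, _ = landscape
        sp = standardize_and_polynomials(coords["lon"], coords["lat"])
        res = partial_rda(Y.to_numpy(), sp.to_numpy(), Z=cond.to_numpy())
        total = res.total_variance
        F = pseudo_F(
            res.constrained_pct * total / 100,
            res.residual_pct * total / 100,
            res.df_model, res.df_resid,
        )
        assert F == pytest.approx(res.F_whole, rel=1e-9)

    def test_perfect_fit_minimal_p(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 2))
        Y = X @ rng.normal(size=(2, 2))
        _, p = permutation_test(Y, X, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_seeded_reproducibility(self, landscape):
        Y, coords, _, cond, _ = landscape
        sp = standardize_and_polynomials(coords["lon"], coords["lat"])
        a = permutation_test(Y.to_numpy(), sp.to_numpy(), cond.to_numpy(),
                             n_perm=99, seed=3)
        b = permutation_test(Y.to_numpy(), sp.to_numpy(), cond.to_numpy(),
                             n_perm=99, seed=3)
        assert a == b


class TestForwardSelectionAndVIF:
    def test_planted_term_selected_first(self):
        hits = 0
        for s in range(20):
            spec = synthetic.LandscapeSpec(
                n=150, fractions=(0.0, 0.4, 0.0, 0.6), spatial_terms=("y",)
            )
            Y, coords, clim, cond, _ = synthetic.make_landscape(spec, 800 + s)
            sp = standardize_and_polynomials(coords["lon"], coords["lat"])
            sel, _ = forward_select(Y.to_numpy(), sp, alpha=0.01,
                                    n_perm=199, seed=s)
            hits += bool(sel) and sel[0] == "y"
        assert hits >= 19

    def test_alpha_one_selects_everything(self):
        rng = np.random.default_rng(9)
        cand = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        Y = rng.normal(size=(60, 2))
        sel, _ = forward_select(Y, cand, alpha=1.0, n_perm=49, seed=0)
        assert sorted(sel) == list("abcd")

    def test_vif_orthogonal_design_is_one(self):
        rng = np.random.default_rng(10)
        # columns mutually orthogonal and orthogonal to the intercept
        M = np.column_stack([np.ones(50), rng.normal(size=(50, 4))])
        Q, _ = np.linalg.qr(M)
        X = pd.DataFrame(Q[:, 1:], columns=list("abcd"))
        assert np.allclose(vif(X).to_numpy(), 1.0, atol=1e-10)

    def test_vif_duplicated_column_flagged_infinite(self):
        x = np.random.default_rng(11).normal(size=30)
        X = pd.DataFrame({"a": x, "b": x, "c": np.random.default_rng(12)
                          .normal(size=30)})
        v = vif(X)
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_vif_hand_computed_three_columns(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        c = 0.8 * a + 0.6 * rng.normal(size=100)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        v = vif(X)
        import statsmodels.api as sm

        for j, name in enumerate(X.columns):
            others = sm.add_constant(X.drop(columns=name))
            r2 = sm.OLS(X[name], others).fit().rsquared
            assert v[name] == pytest.approx(1 / (1 - r2), rel=1e-6)

    def test_candidate_set_size(self):
        rng = np.random.default_rng(14)
        sp = standardize_and_polynomials(
            rng.uniform(0, 30, 60), rng.uniform(40, 60, 60)
        )
        clim = pd.DataFrame(rng.normal(size=(60, 4)),
                            columns=[f"bio{i}" for i in range(4)])
        cand = candidate_set(sp, clim)
        assert cand.shape[1] == 9 + 4 + 36


class TestAxisTests:
    def test_one_dimensional_signal_on_first_axis(self):
        rng = np.random.default_rng(15)
        n = 80
        x = rng.normal(size=n)
        Y = np.column_stack([x, 2 * x]) + 0.01 * rng.normal(size=(n, 2))
        res = rda.axis_tests(Y, x[:, None], n_perm=99, seed=0)
        assert res.loc[0, "pct_constrained"] > 99.9

    def test_two_signals_two_significant_axes(self):
        rng = np.random.default_rng(16)
        n = 150
        X = rng.normal(size=(n, 2))
        Y = np.column_stack(
            [X[:, 0], X[:, 1], 0.3 * X[:, 0] - X[:, 1]]
        ) + 0.2 * rng.normal(size=(n, 3))
        res = rda.axis_tests(Y, X, n_perm=199, seed=1)
        assert (res["p"] <= 0.05).sum() >= 2
        assert res["pct_constrained"].sum() == pytest.approx(100.0)
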
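import numpy as np
import pandas as pd
import pytest

from hapdemog import aflp, synthetic
from hapdemog.aflp import (
    AFLPMatrix,
    amova,
    band_statistics,
    broken_stick,
    brown_forsythe,
    euclidean_distance,
    evanno_delta_k,
    fragment_counts,
    fragment_filter,
    pcoa,
    read_aflp,
    replicate_error_rate,
    write_aflp,
)
from hapdemog.seqio import InputError, SampleRecord


def make_matrix(data, years=None, pairs=None, regions=None):
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    samples = [
        SampleRecord(
            sample_id=f"a{i + 1}",
            region=(regions[i] if regions else "R"),
            year=(years[i] if years else 2010),
        )
        for i in range(n)
    ]
    return AFLPMatrix(
        samples=samples,
        loci=[f"L{j + 1}" for j in range(data.shape[1])],
        data=data,
        replicate_pairs=pairs or [],
    )


class TestIO:
    def test_roundtrip(self, tmp_path):
        m = make_matrix(np.eye(4)[:, :3])
        path = tmp_path / "m.csv"
        write_aflp(m, path)
        meta = tmp_path / "meta.tsv"
        meta.write_text(
            "sample_id\tregion\tyear\n"
            + "".join(f"a{i + 1}\tR\t2010\n" for i in range(4))
        )
        back = read_aflp(path, meta)
        assert np.array_equal(back.data, m.data)
        assert back.loci == m.loci

    def test_non_binary_entry_rejected(self):
        with pytest.raises(InputError, match="non-binary"):
            make_matrix([[0, 2], [1, 0]])

    def test_orphan_replicate_rejected(self):
        with pytest.raises(InputError, match="unknown sample"):
            make_matrix([[0, 1]], pairs=[("a1", "zz")])

    def test_synthetic_dataset_loads_with_invariants(self, tmp_path):
        m, _ = synthetic.make_aflp_dataset(
            synthetic.AFLPSpec(n_per_pool=(20, 20), loci=60,
                               n_replicate_pairs=5), seed=2
        )
        paths = synthetic.write_aflp_dataset(m, tmp_path)
        back = read_aflp(*paths)
        assert back.n == m.n and len(back.loci) == 60
        assert len(back.replicate_pairs) == 5


class TestReplicateError:
    def test_identical_replicates(self):
        m = make_matrix([[1, 0, 1], [1, 0, 1]], pairs=[("a1", "a2")])
        assert replicate_error_rate(m) == 0.0

    def test_direct_count(self):
        data = np.zeros((4, 10))
        data[1, 0] = 1  # 1 mismatch in pair 1
        data[3, :3] = 1  # 3 mismatches in pair 2
        m = make_matrix(data, pairs=[("a1", "a2"), ("a3", "a4")])
        assert replicate_error_rate(m) == pytest.approx(4 / 20)

    def test_estimator_unbiased_on_flip_simulation(self):
        rng = np.random.default_rng(8)
        flip_rate, loci, pairs = 0.011, 400, 500
        base = (rng.random((pairs, loci)) < 0.4).astype(float)
        flips = rng.random((pairs, loci)) < flip_rate
        rep = np.abs(base - flips)
        data = np.vstack([base, rep])
        pair_ids = [(f"a{i + 1}", f"a{pairs + i + 1}") for i in range(pairs)]
        m = make_matrix(data, pairs=pair_ids)
        assert replicate_error_rate(m) == pytest.approx(flip_rate, abs=0.003)


class TestFragmentScreen:
    def test_counts(self):
        m = make_matrix([[1, 1, 0], [0, 0, 0], [1, np.nan, 1]])
        assert fragment_counts(m).tolist() == [2, 0, 2]

    def test_brown_forsythe_matches_anova_on_deviations_oracle(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, s, size=30) for s in (1.0, 2.5, 0.7)]
        F, df, p = brown_forsythe(groups)
        from scipy.stats import f_oneway

        devs = [np.abs(g - np.median(g)) for g in groups]
        F_o, p_o = f_oneway(*devs)
        assert F == pytest.approx(F_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-12)
        assert df == (2, 87)

    def test_equal_spread_gives_small_F(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        F, _, p = brown_forsythe([g, g + 10])
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_degradation_detected_by_hov(self):
        hits = 0
        for s in range(20):
            m, _ = synthetic.make_aflp_dataset(
                synthetic.AFLPSpec(n_per_pool=(40, 40), loci=404,
                                   n_replicate_pairs=0), seed=100 + s
            )
            counts = fragment_counts(m)
            old = [c for c, smp in zip(counts, m.samples) if smp.year < 2003]
            new = [c for c, smp in zip(counts, m.samples) if smp.year >= 2003]
            _, _, p = brown_forsythe([old, new])
            _, _, p_anova = aflp.anova_oneway([old, new])
            hits += (p_anova < 0.001)
        assert hits >= 18

    def test_filter_keeps_in_band_samples(self):
        data = np.ones((5, 10))
        m = make_matrix(data, years=[2005] * 5)
        filtered, report = fragment_filter(m)
        assert filtered.n == 5 and report.removed_ids == []

    def test_filter_removes_extreme_sample(self):
        rng = np.random.default_rng(1)
        data = (rng.random((30, 100)) < 0.5).astype(float)
        data[0] = 0.0
        data[0, :2] = 1.0  # far below the reference band
        m = make_matrix(data, years=[1990] + [2010] * 29)
        filtered, report = fragment_filter(m)
        assert "a1" in report.removed_ids

    def test_filter_idempotent(self):
        m, _ = synthetic.make_aflp_dataset(
            synthetic.AFLPSpec(n_per_pool=(30, 30), loci=120), seed=5
        )
        once, _ = fragment_filter(m)
        twice, rep2 = fragment_filter(once)
        assert twice.sample_ids == once.sample_ids

    def test_removal_covers_planted_extremes(self):
        m, truth = synthetic.make_aflp_dataset(synthetic.AFLPSpec(), seed=3)
        _, report = fragment_filter(m)
        assert set(truth["extreme_degraded"]) <= set(report.removed_ids)


class TestDistancesAndPCoA:
    def test_distance_identities(self):
        m = make_matrix([[1, 1, 0, 0, 1], [1, 1, 0, 0, 1]])
        assert euclidean_distance(m)[0, 1] == 0.0
        m2 = make_matrix([[1, 1, 1, 1, 0], [0, 0, 0, 0, 0]])
        assert euclidean_distance(m2)[0, 1] == pytest.approx(2.0)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(0)
        m = make_matrix((rng.random((6, 40)) < 0.5).astype(float))
        d = euclidean_distance(m)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_two_points_closed_form(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        res = pcoa(d)
        assert res.n_positive == 1
        assert res.eigenvalues[0] == pytest.approx(4.5)  # delta^2/2
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-1.5, 1.5])

    def test_euclidean_distances_recovered_exactly(self):
        rng = np.random.default_rng(4)
        m = make_matrix((rng.random((12, 50)) < 0.4).astype(float))
        d = euclidean_distance(m)
        res = pcoa(d)
        from scipy.spatial.distance import pdist, squareform

        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, d, atol=1e-8)

    def test_explained_sums_to_100(self):
        rng = np.random.default_rng(9)
        m = make_matrix((rng.random((15, 30)) < 0.5).astype(float))
        res = pcoa(euclidean_distance(m))
        assert res.explained.sum() == pytest.approx(100.0)

    def test_matches_skbio_ordination(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(6)
        m = make_matrix((rng.random((10, 25)) < 0.5).astype(float))
        d = euclidean_distance(m)
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        k = ours.n_positive
        assert np.allclose(
            np.sort(theirs.eigvals.to_numpy())[::-1][:k],
            ours.eigenvalues[:k], atol=1e-8,
        )

    def test_broken_stick_values(self):
        assert broken_stick(1) == pytest.approx([1.0])
        assert broken_stick(3) == pytest.approx([0.6111, 0.2778, 0.1111],
                                                abs=1e-4)
        assert broken_stick(50).sum() == pytest.approx(1.0)


class TestBandStatisticsAndAmova:
    def test_one_region_all_present_unique(self):
        m = make_matrix([[1, 0, 1], [1, 1, 0]])
        tab = band_statistics(m)
        assert tab.loc[0, "fragments"] == 3
        assert tab.loc[0, "unique_fragments"] == 3

    def test_two_region_hand_example(self):
        m = make_matrix(
            [[1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]],
            regions=["A", "A", "B", "B"],
        )
        tab = band_statistics(m).set_index("region")
        assert tab.loc["A", "unique_fragments"] == 1  # locus 2
        assert tab.loc["B", "unique_fragments"] == 2  # loci 3, 4

    def test_private_band_pool_has_more_unique(self):
        m, truth = synthetic.make_aflp_dataset(
            synthetic.AFLPSpec(private_band_rate=(0.25, 0.02),
                               n_replicate_pairs=0), seed=12
        )
        tab = band_statistics(m).set_index("region")
        assert (tab.loc["Caucasus-Irano-Turanian", "unique_fragments"]
                > tab.loc["Europe", "unique_fragments"])

    def test_amova_perfectly_structured(self):
        data = np.zeros((6, 10))
        data[3:, :] = 1.0
        m = make_matrix(data, regions=["A"] * 3 + ["B"] * 3)
        res = amova(euclidean_distance(m), ["A"] * 3 + ["B"] * 3,
                    permutations=0)
        assert res.phi_st == pytest.approx(1.0)

    def test_amova_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(2)
        X = (rng.random((8, 20)) < 0.5).astype(float)
        m = make_matrix(X, regions=["A"] * 4 + ["B"] * 4)
        d = euclidean_distance(m)
        res = amova(d, ["A"] * 4 + ["B"] * 4, permutations=0)
        d2 = d**2
        ss_total = sum(d2[i, j] for i in range(8) for j in range(i + 1, 8)) / 8
        ssw = 0.0
        for idx in ([0, 1, 2, 3], [4, 5, 6, 7]):
            ssw += sum(
                d2[a, b] for a in idx for b in idx if a < b
            ) / len(idx)
        assert res.ss_within == pytest.approx(ssw, abs=1e-9)
        assert res.ss_among == pytest.approx(ss_total - ssw, abs=1e-9)

    def test_amova_null_phi_near_zero_and_p_reproducible(self):
        rng = np.random.default_rng(11)
        X = (rng.random((20, 60)) < 0.5).astype(float)
        labels = ["A"] * 10 + ["B"] * 10
        m = make_matrix(X, regions=labels)
        d = euclidean_distance(m)
        r1 = amova(d, labels, permutations=199, seed=7)
        r2 = amova(d, labels, permutations=199, seed=7)
        assert abs(r1.phi_st) < 0.1
        assert r1.p == r2.p
        assert r1.p > 0.05


class TestEvanno:
    def _table(self, means, sd=1.0, reps=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for K, mu in means.items():
            for _ in range(reps):
                rows.append({"K": K, "lnP": mu + rng.normal(0, sd)})
        return pd.DataFrame(rows)

    def test_linear_means_give_zero_delta_k(self):
        table = pd.DataFrame(
            [
                {"K": K, "lnP": -100.0 + 10.0 * K + eps}
                for K in (1, 2, 3, 4)
                for eps in (-0.5, 0.5)
            ]
        )
        res = evanno_delta_k(table).set_index("K")
        assert res.loc[2, "delta_K"] == pytest.approx(0.0, abs=1e-9)
        assert res.loc[3, "delta_K"] == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(res.loc[1, "delta_K"])

    def test_kink_detected(self):
        means = {1: -500.0, 2: -300.0, 3: -290.0, 4: -285.0}
        res = evanno_delta_k(self._table(means, sd=2.0)).set_index("K")
        interior = res["delta_K"].dropna()
        assert interior.idxmax() == 2

    def test_zero_variance_warns_and_is_nan(self):
        table = pd.DataFrame(
            [{"K": K, "lnP": float(-K**2)} for K in (1, 2, 3) for _ in range(3)]
        )
        with pytest.warns(UserWarning, match="sd of lnP is zero"):
            res = evanno_delta_k(table).set_index("K")
        assert np.isnan(res.loc[2, "delta_K"])
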
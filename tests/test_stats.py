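"""Stepwise yield regression, Mantel tests, Kruskal-Wallis, PCA."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ricepheno import (
    CohortSpec,
    euclidean_distance_matrix,
    kruskal_wallis,
    mantel_test,
    pairwise_wilcoxon,
    partial_mantel,
    pca_traits,
    simulate_cohort,
    stepwise_regression,
    variance_explained_by_group,
)


def random_X(rng, n=100, p=10):
    return pd.DataFrame(rng.normal(size=(n, p)), columns=[f"T{i}" for i in range(p)])


class TestStepwise:
    def test_noiseless_planted_model_recovered_exactly(self, rng):
        X = random_X(rng)
        y = 3.0 * X["T1"] - 2.0 * X["T2"]
        res = stepwise_regression(X, y)
        assert sorted(res.selected) == ["T1", "T2"]
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.coefficients["T1"] == pytest.approx(3.0)
        assert res.coefficients["T2"] == pytest.approx(-2.0)

    def test_entry_p_zero_selects_nothing(self, rng):
        X = random_X(rng)
        y = 3.0 * X["T1"] + rng.normal(size=len(X))
        res = stepwise_regression(X, y, entry_p=0.0)
        assert res.selected == []
        assert res.r2 == 0.0

    def test_null_selection_rate_matches_multiple_testing_oracle(self):
        # Under the null, P(no candidate enters) ~= (1 - alpha)^p for p
        # independent candidates; check the Monte-Carlo rate against it.
        rng = np.random.default_rng(2024)
        p = 10
        empty = 0
        n_rep = 100
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_rep):
                X = random_X(rng, n=200, p=p)
                y = rng.normal(size=200)
                empty += stepwise_regression(X, y).selected == []
        expect = (1 - 0.05) ** p
        se = np.sqrt(expect * (1 - expect) / n_rep)
        assert abs(empty / n_rep - expect) < 4 * se

    def test_trace_replay_reproduces_selection(self, rng):
        X = random_X(rng)
        y = 2 * X["T0"] + X["T5"] + 0.5 * rng.normal(size=len(X))
        res = stepwise_regression(X, y)
        replay: list[str] = []
        for step, trait, _p in res.trace:
            if step == "add":
                replay.append(trait)
            else:
                replay.remove(trait)
        assert replay == res.selected

    def test_constant_y_rejected(self, rng):
        X = random_X(rng, n=10)
        with pytest.raises(ValueError, match="constant"):
            stepwise_regression(X, np.ones(10))

    def test_cohort_planted_yield_recovery(self):
        spec = CohortSpec(n_plants=93, seed=2, yield_noise_sd=0.0,
                          yield_beta={"PanicleTPA": 0.002, "AveGL": 4.0})
        table, y, _, _ = simulate_cohort(spec)
        candidates = table.drop(columns=["W", "GN", "SF", "TFN"])  # yield-derived columns
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stepwise_regression(candidates, y)
        assert sorted(res.selected) == ["AveGL", "PanicleTPA"]
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_group_with_planted_signal_beats_others(self):
        spec = CohortSpec(n_plants=93, seed=4, yield_noise_sd=0.5,
                          yield_beta={"PanicleTPAG": 0.5, "PanicleYpar_a": 3e5})
        table, y, _, _ = simulate_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = variance_explained_by_group(table, y)
        r2 = res["r2"]
        assert r2["panicle_growth"] == r2.drop("pooled").max()
        assert r2["pooled"] >= r2.drop("pooled").max() - 1e-9


class TestMantel:
    def test_identity_matrices(self, rng):
        D = euclidean_distance_matrix(rng.normal(size=(20, 4)))
        res = mantel_test(D, D, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0 / 1000.0)

    def test_p_value_bounds_and_determinism(self, rng):
        D1 = euclidean_distance_matrix(rng.normal(size=(15, 3)))
        D2 = euclidean_distance_matrix(rng.normal(size=(15, 3)))
        a = mantel_test(D1, D2, n_perm=499, seed=7)
        b = mantel_test(D1, D2, n_perm=499, seed=7)
        assert a.p == b.p and a.r == b.r
        assert 1.0 / 500.0 <= a.p <= 1.0

    def test_r_statistic_matches_scikit_bio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        X = rng.normal(size=(18, 5))
        Y = X + rng.normal(0, 0.5, size=(18, 5))
        D1 = euclidean_distance_matrix(X)
        D2 = euclidean_distance_matrix(Y)
        ours = mantel_test(D1, D2, n_perm=99, seed=0)
        r_ref, _, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(D1), skbio_stats.DistanceMatrix(D2),
            method="pearson", permutations=0,
        )
        assert ours.r == pytest.approx(float(r_ref), abs=1e-10)

    def test_partial_mantel_removes_shared_structure(self, rng):
        D1 = euclidean_distance_matrix(rng.normal(size=(20, 4)))
        D2 = euclidean_distance_matrix(rng.normal(size=(20, 4)))
        res = partial_mantel(D1, D2, D2, n_perm=99, seed=0)
        assert abs(res.r) < 0.05

    def test_invalid_matrices_rejected(self):
        bad = np.arange(9.0).reshape(3, 3)
        good = np.zeros((3, 3))
        with pytest.raises(ValueError, match="symmetric"):
            mantel_test(bad, good)
        with pytest.raises(ValueError, match="diagonal"):
            mantel_test(np.ones((3, 3)), np.ones((3, 3)))


class TestKruskalWallis:
    def test_identical_constant_groups(self):
        with pytest.warns(UserWarning, match="tied"):
            H, p = kruskal_wallis([1.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert H == 0.0 and p == 1.0

    def test_planted_shift_detected_with_high_power(self):
        # 3-SD location shift, n=30/group: power >= 0.95 over 200 replicates
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            v = np.r_[rng.normal(0, 1, 30), rng.normal(3, 1, 30)]
            g = np.r_[["a"] * 30, ["b"] * 30]
            _, p = kruskal_wallis(v, g)
            hits += p < 0.05
        assert hits / n_rep >= 0.95

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            kruskal_wallis([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_pairwise_gated_on_omnibus(self, rng):
        # identical groups: empty pairwise table in the typical case
        v = rng.normal(size=60)
        g = np.r_[["a"] * 20, ["b"] * 20, ["c"] * 20]
        _, p = kruskal_wallis(v, g)
        pw = pairwise_wilcoxon(v, g)
        if p >= 0.05:
            assert len(pw) == 0
        else:  # pragma: no cover - unlucky draw
            assert len(pw) == 3

    def test_pairwise_table_structure_and_holm(self):
        rng = np.random.default_rng(5)
        v = np.r_[rng.normal(0, 1, 25), rng.normal(2, 1, 25), rng.normal(4, 1, 25)]
        g = np.r_[["a"] * 25, ["b"] * 25, ["c"] * 25]
        pw = pairwise_wilcoxon(v, g)
        assert len(pw) == 3
        assert (pw["p_adjusted"] >= pw["p"] - 1e-15).all()

    def test_cohort_group_shift_detected(self):
        # default cohort plants a PlantYpar offset between subpopulations
        table, _, groups, _ = simulate_cohort(CohortSpec(n_plants=60, seed=11))
        _, p = kruskal_wallis(table["PlantYpar"].to_numpy(), groups.to_numpy())
        assert p < 0.05


class TestPCA:
    def test_rank_one_data(self, rng):
        base = rng.normal(size=50)
        df = pd.DataFrame({"A": base, "B": 2 * base, "C": -base})
        res = pca_traits(df, "Organ_PC", columns=["A", "B", "C"])
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("ABCDEF"))
        res = pca_traits(df, "Time_PC", columns=list("ABCDEF"))
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_two_variable_closed_form(self, rng):
        # PC1 fraction of a correlated pair is (1 + |rho|) / 2
        x = rng.normal(size=500)
        y = 0.6 * x + np.sqrt(1 - 0.6**2) * rng.normal(size=500)
        df = pd.DataFrame({"X": x, "Y": y})
        rho = np.corrcoef(x, y)[0, 1]
        res = pca_traits(df, "Organ_PC", columns=["X", "Y"])
        assert res.variance_fraction[0] == pytest.approx((1 + abs(rho)) / 2, abs=1e-10)

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("ABCDE"))
        res = pca_traits(df, "Organ_PC", columns=list("ABCDE"))
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-8)
        X = df.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(res.scores.to_numpy() @ L.T, Z, atol=1e-8)

    def test_sign_convention(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("ABCD"))
        res = pca_traits(df, "Organ_PC", columns=list("ABCD"))
        L = res.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_constant_column_named_in_error(self, rng):
        df = pd.DataFrame({"A": rng.normal(size=10), "B": np.ones(10)})
        with pytest.raises(ValueError, match="B"):
            pca_traits(df, "Organ_PC", columns=["A", "B"])

    def test_missing_values_rejected(self, rng):
        df = pd.DataFrame({"A": rng.normal(size=10), "B": rng.normal(size=10)})
        df.loc[3, "B"] = np.nan
        with pytest.raises(ValueError, match="complete-case"):
            pca_traits(df, "Organ_PC", columns=["A", "B"])
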
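"""Standardization, fuzzy c-means behavior and the three-layer overlay."""

import numpy as np
import pandas as pd
import pytest

from caspkit import cluster, synthetic


def naive_fcm(X, c, m, rng, max_iter=2000, tol=1e-12):
    """Loop-based reference implementation of the alternating updates."""
    n, T = X.shape
    U = rng.dirichlet(np.ones(c), size=n)
    J_prev = np.inf
    for _ in range(max_iter):
        centers = np.zeros((c, T))
        for i in range(c):
            num = np.zeros(T)
            den = 0.0
            for j in range(n):
                w = U[j, i] ** m
                num += w * X[j]
                den += w
            centers[i] = num / den
        J = 0.0
        d2 = np.zeros((n, c))
        for j in range(n):
            for i in range(c):
                d2[j, i] = ((X[j] - centers[i]) ** 2).sum()
                J += (U[j, i] ** m) * d2[j, i]
        for j in range(n):
            if (d2[j] < 1e-300).any():
                U[j] = 0.0
                U[j, int(np.argmin(d2[j]))] = 1.0
            else:
                inv = d2[j] ** (-1.0 / (m - 1.0))
                U[j] = inv / inv.sum()
        if abs(J_prev - J) < tol:
            break
        J_prev = J
    return J


class TestStandardize:
    def test_linear_row_becomes_zero_mean_unit_sd(self):
        X = pd.DataFrame([[1, 2, 3, 4, 5, 6]])
        Z = cluster.standardize(X)
        assert Z.to_numpy().mean() == pytest.approx(0, abs=1e-12)
        assert Z.to_numpy().std() == pytest.approx(1, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 6)))
        once = cluster.standardize(X)
        twice = cluster.standardize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_matches_rowwise_formula(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(2, 3, size=(30, 6)))
        Z = cluster.standardize(X).to_numpy()
        raw = X.to_numpy()
        expected = (raw - raw.mean(1, keepdims=True)) / raw.std(1, keepdims=True)
        assert np.allclose(Z, expected, atol=1e-12)

    def test_constant_row_dropped_with_warning(self):
        X = pd.DataFrame([[1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6]], index=["flat", "ramp"])
        with pytest.warns(UserWarning, match="constant"):
            Z = cluster.standardize(X)
        assert list(Z.index) == ["ramp"]


class TestFuzzyCMeans:
    def test_equidistant_point_splits_membership(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 0.0]])
        # cluster the two endpoints; midpoint is equidistant
        fc = cluster.fuzzy_cmeans(X, c=2, m=2.0, seed=0, n_starts=5)
        mid = fc.membership[2]
        assert np.allclose(mid, [0.5, 0.5], atol=1e-3)

    def test_point_at_center_gets_full_membership(self):
        X = np.array([[0.0, 0.0]] * 5 + [[10.0, 10.0]] * 5)
        fc = cluster.fuzzy_cmeans(X, c=2, m=1.5, seed=1, n_starts=3)
        for row in fc.membership:
            assert row.max() > 0.999

    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        fc = cluster.fuzzy_cmeans(X, c=4, m=1.5, seed=2, n_starts=3)
        assert np.allclose(fc.membership.sum(axis=1), 1.0, atol=1e-9)
        assert (fc.membership >= 0).all() and (fc.membership <= 1).all()

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 6))
        fc = cluster.fuzzy_cmeans(X, c=3, m=1.5, seed=3, n_starts=2)
        diffs = np.diff(fc.objective_history)
        assert (diffs <= 1e-9).all()

    def test_tiny_instance_matches_dense_restart_reference(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 2)) * 2
        fc = cluster.fuzzy_cmeans(X, c=2, m=1.5, seed=4, n_starts=10)
        ref = min(
            naive_fcm(X, 2, 1.5, np.random.default_rng(1000 + k)) for k in range(60)
        )
        assert fc.objective == pytest.approx(ref, abs=1e-6)

    def test_partition_invariant_across_seeds(self):
        X, _ = synthetic.gen_trajectories(80, noise_sd=0.2, seed=5)
        Xs = cluster.standardize(X).to_numpy()
        la, _ = cluster.assign_clusters(cluster.fuzzy_cmeans(Xs, 5, seed=10).membership)
        lb, _ = cluster.assign_clusters(cluster.fuzzy_cmeans(Xs, 5, seed=20).membership)
        # co-membership structure identical although labels may permute
        coa = la[:, None] == la[None, :]
        cob = lb[:, None] == lb[None, :]
        assert (coa == cob).mean() > 0.99

    def test_parameter_validation(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            cluster.fuzzy_cmeans(X, c=1)
        with pytest.raises(ValueError):
            cluster.fuzzy_cmeans(X, c=2, m=1.0)
        with pytest.raises(ValueError):
            cluster.fuzzy_cmeans(X, c=5)


class TestAssignClusters:
    def test_argmax_and_tie_break(self):
        U = np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
        labels, memb = cluster.assign_clusters(U)
        assert list(labels) == [0, 0, 1]  # tie goes to the lowest index
        assert np.allclose(memb, [0.9, 0.5, 0.8])

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(6)
        U = rng.dirichlet(np.ones(5), size=50)
        labels, _ = cluster.assign_clusters(U)
        assert np.array_equal(labels, np.array([int(np.argmax(r)) for r in U]))


class TestRecovery:
    def test_planted_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        X, truth = synthetic.gen_trajectories(600, noise_sd=0.3, seed=7)
        Xs = cluster.standardize(X)
        fc = cluster.fuzzy_cmeans(Xs, c=5, m=1.5, seed=7, n_starts=10)
        labels, _ = cluster.assign_clusters(fc.membership)
        assert adjusted_rand_score(truth.loc[Xs.index], labels) >= 0.9


def _toy_layers():
    time_cols = [f"t{j}" for j in range(6)]
    csp = pd.DataFrame([[0, 1, 2, 3, 4, 5], [5, 4, 3, 2, 1, 0]],
                       index=["pepA", "pepB"], columns=time_cols, dtype=float)
    gpp = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["ACC1"], columns=time_cols, dtype=float)
    rna = pd.DataFrame([[6, 5, 4, 3, 2, 1]], index=["ACC1"], columns=time_cols, dtype=float)
    csp_labels = pd.Series([1, 2], index=["pepA", "pepB"])
    gpp_labels = pd.Series([5], index=["ACC1"])
    id_map = pd.DataFrame(
        {"peptide": ["pepA", "pepB"], "accession": ["ACC1", "ACC2"], "gene": ["ACC1", "ACC2"]}
    )
    return csp, gpp, rna, csp_labels, gpp_labels, id_map


class TestOverlay:
    def test_complete_triad_joined(self):
        csp, gpp, rna, cl, gl, id_map = _toy_layers()
        ov = cluster.overlay(csp, gpp, rna, cl, gl, id_map)
        a = ov[ov["peptide"] == "pepA"]
        assert len(a) == 6
        assert a["complete"].all()
        assert np.allclose(a["protein"], gpp.loc["ACC1"])

    def test_unmapped_feature_retained_with_missing_layers(self):
        csp, gpp, rna, cl, gl, id_map = _toy_layers()
        ov = cluster.overlay(csp, gpp, rna, cl, gl, id_map)
        b = ov[ov["peptide"] == "pepB"]
        assert len(b) == 6
        assert not b["complete"].any()
        assert b["protein"].isna().all()

    def test_restriction_to_down_clusters_excludes_others(self):
        csp, gpp, rna, cl, gl, id_map = _toy_layers()
        ov = cluster.overlay(csp, gpp, rna, cl, gl, id_map, restrict_gpp_clusters=[6])
        assert ov.empty
        ov5 = cluster.overlay(csp, gpp, rna, cl, gl, id_map, restrict_gpp_clusters=[5])
        assert set(ov5["peptide"]) == {"pepA"}

    def test_row_count_matches_brute_force_join(self):
        rng = np.random.default_rng(8)
        time_cols = [f"t{j}" for j in range(6)]
        peps = [f"p{i}" for i in range(30)]
        accs = [f"A{i}" for i in range(12)]
        csp = pd.DataFrame(rng.normal(size=(30, 6)), index=peps, columns=time_cols)
        gpp = pd.DataFrame(rng.normal(size=(8, 6)), index=accs[:8], columns=time_cols)
        rna = pd.DataFrame(rng.normal(size=(10, 6)), index=accs[:10], columns=time_cols)
        id_map = pd.DataFrame({
            "peptide": peps,
            "accession": rng.choice(accs, size=30),
        })
        id_map["gene"] = id_map["accession"]
        cl = pd.Series(rng.integers(1, 6, size=30), index=peps)
        gl = pd.Series(rng.integers(1, 7, size=8), index=accs[:8])
        ov = cluster.overlay(csp, gpp, rna, cl, gl, id_map)
        assert len(ov) == 30 * 6
        restricted = cluster.overlay(csp, gpp, rna, cl, gl, id_map,
                                     restrict_gpp_clusters=[5, 6])
        expected = sum(
            1 for _, r in id_map.iterrows()
            if r["accession"] in gl.index and gl[r["accession"]] in (5, 6)
        )
        assert len(restricted) == expected * 6
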
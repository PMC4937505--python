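"""RPKM, precision weights, moderated statistics and sample clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from caspkit import synthetic, transcriptome
from caspkit.design import DEFAULT_DESIGN


def _null_counts(n_genes=2000, seed=0):
    genes = [f"g{i}" for i in range(n_genes)]
    counts, _, _, _ = synthetic.gen_counts(
        genes, DEFAULT_DESIGN, time_points=(72.0,), treatments=("TM", "TMZ"),
        replicates=3, dispersion=0.02, seed=seed,
    )
    X = np.zeros((6, 2))
    X[:, 0] = 1.0
    X[3:, 1] = 1.0
    return counts, X, np.array([0.0, 1.0])


class TestRpkm:
    def test_closed_form_example(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        lengths = pd.Series([2000], index=["g1"])
        lib = pd.Series([1e6], index=["s1"])
        out = transcriptome.rpkm(counts, lengths, lib)
        assert out.loc["g1", "s1"] == pytest.approx(5.0)

    def test_zero_reads_give_zero(self):
        counts = pd.DataFrame({"s1": [0, 100]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 1000], index=["g1", "g2"])
        out = transcriptome.rpkm(counts, lengths)
        assert out.loc["g1", "s1"] == 0.0

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 500, size=(30, 4)),
                              index=[f"g{i}" for i in range(30)],
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(200, 5000, size=30), index=counts.index)
        out = transcriptome.rpkm(counts, lengths)
        lib = counts.sum(axis=0)
        for g in counts.index[:5]:
            for s in counts.columns:
                expected = counts.loc[g, s] / (lengths[g] / 1e3) / (lib[s] / 1e6)
                assert out.loc[g, s] == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            transcriptome.rpkm(counts, pd.Series([0], index=["g1"]))
        with pytest.raises(ValueError):
            transcriptome.rpkm(counts, pd.Series([100], index=["g1"]),
                               pd.Series([0.0], index=["s1"]))


class TestPrecisionWeights:
    def test_all_zero_genes_excluded(self):
        counts, X, _ = _null_counts(50, seed=2)
        counts.iloc[5] = 0
        we = transcriptome.precision_weights(counts, X)
        assert counts.index[5] not in we.logexpr.index

    def test_homoskedastic_input_gives_near_constant_weights(self):
        rng = np.random.default_rng(3)
        # Gaussian-log counts: constant log-scale variance at every mean,
        # so the mean-variance trend is flat and weights near-constant
        genes = [f"g{i}" for i in range(2000)]
        mu = rng.uniform(8, 12, size=2000)  # log2 means, high-count regime
        counts = pd.DataFrame(
            {f"s{j}": np.round(2.0 ** (mu + rng.normal(0, 0.3, 2000))).astype(int)
             for j in range(6)},
            index=genes,
        )
        X = np.zeros((6, 2)); X[:, 0] = 1; X[3:, 1] = 1
        we = transcriptome.precision_weights(counts, X)
        cv = we.weights.std() / we.weights.mean()
        assert cv < 0.10

    def test_insufficient_residual_df_rejected(self):
        counts = pd.DataFrame({"a": [10], "b": [12]}, index=["g1"])
        with pytest.raises(ValueError):
            transcriptome.precision_weights(counts, np.eye(2))


class TestModeratedFit:
    def test_infinite_prior_pools_variances(self):
        counts, X, con = _null_counts(300, seed=4)
        we = transcriptome.precision_weights(counts, X)
        de = transcriptome.moderated_fit(we, X, con, d0_override=np.inf)
        # every gene shares the pooled variance: |t| proportional to |b|/sqrt(u)
        assert de.attrs["d0"] == np.inf

    def test_zero_prior_recovers_ordinary_t(self):
        counts, X, con = _null_counts(300, seed=5)
        we = transcriptome.precision_weights(counts, X)
        de = transcriptome.moderated_fit(we, X, con, d0_override=0)
        # reproduce one gene's ordinary weighted t by hand
        g = we.logexpr.index[7]
        y = we.logexpr.loc[g].to_numpy()
        w = we.weights[list(we.logexpr.index).index(g)]
        sw = np.sqrt(w)
        Xw, yw = X * sw[:, None], y * sw
        beta, res, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        s2 = (resid**2).sum() / (len(y) - 2)
        u = (con @ np.linalg.inv(Xw.T @ Xw) @ con)
        t_hand = (con @ beta) / np.sqrt(s2 * u)
        assert de.loc[g, "t"] == pytest.approx(t_hand, rel=1e-10)

    def test_null_type_one_error_calibrated(self):
        counts, X, con = _null_counts(2000, seed=6)
        we = transcriptome.precision_weights(counts, X)
        de = transcriptome.moderated_fit(we, X, con)
        p = de["p"].to_numpy()
        assert 0.04 <= (p < 0.05).mean() <= 0.06
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_rank_deficient_design_rejected(self):
        counts, X, con = _null_counts(50, seed=7)
        Xbad = np.c_[X, X[:, 0]]
        with pytest.raises(ValueError):
            transcriptome.moderated_fit(
                transcriptome.precision_weights(counts, X), Xbad,
                np.array([0.0, 1.0, 0.0])
            )


class TestBhAdjust:
    def test_hand_traced_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(transcriptome.bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_unit_pvalues(self):
        assert transcriptome.bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
        assert (transcriptome.bh_adjust(np.ones(5)) == 1.0).all()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        adj = transcriptome.bh_adjust(p)
        adj_perm = transcriptome.bh_adjust(p[perm])
        assert np.allclose(adj[perm], adj_perm)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        assert (transcriptome.bh_adjust(p) >= p - 1e-12).all()


class TestSignificantGenes:
    def _de(self):
        return pd.DataFrame(
            {"log2_fc": [1.1, 1.1, 0.9, -1.5], "t": [5, 5, 5, -6],
             "p": [0.001, 0.01, 0.001, 0.0001],
             "adj_p": [0.049, 0.05, 0.01, 0.002]},
            index=["a", "b", "c", "d"],
        )

    def test_strict_thresholds(self):
        sig = transcriptome.significant_genes(self._de())
        # a: p 0.049 FC 2.14 kept; b: p exactly 0.05 excluded;
        # c: FC 1.87 < 2 excluded; d: down 2.8-fold kept
        assert list(sig.index) == ["a", "d"]
        assert sig.attrs["n_up"] == 1 and sig.attrs["n_down"] == 1

    def test_monotone_in_both_cutoffs(self):
        de = self._de()
        base = set(transcriptome.significant_genes(de, 0.05, 2.0).index)
        looser = set(transcriptome.significant_genes(de, 0.10, 1.5).index)
        tighter = set(transcriptome.significant_genes(de, 0.01, 4.0).index)
        assert tighter <= base <= looser


class TestSampleCluster:
    def test_identical_samples_merge_first_at_zero_height(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.integers(10, 1000, size=(600, 3)),
                              columns=["a", "b", "c"])
        counts["d"] = counts["a"]
        Z, labels, newick = transcriptome.sample_cluster(counts, top_n=500)
        first = Z[0]
        merged = {labels[int(first[0])], labels[int(first[1])]}
        assert merged == {"a", "d"}
        assert first[2] == pytest.approx(0.0, abs=1e-9)
        assert newick.endswith(";")

    def test_replicates_cluster_before_conditions(self):
        from caspkit.design import RNA_ARCHETYPES

        # mixed up/down kinetic shapes so time changes composition, not
        # merely sequencing depth
        genes = [f"g{i}" for i in range(800)]
        counts, _, samples, _ = synthetic.gen_counts(
            genes, DEFAULT_DESIGN, time_points=(0.0, 72.0),
            treatments=("TM", "TMZ"), replicates=3,
            planted_sets={"S": genes[:200]}, dual_tf_sets=["S"],
            dispersion=0.02, seed=10,
            time_archetypes=RNA_ARCHETYPES, time_amplitude=1.0,
        )
        from scipy.cluster.hierarchy import fcluster

        Z, labels, _ = transcriptome.sample_cluster(counts, top_n=500)
        # three real conditions: t0 (arms identical before the inhibitor
        # acts), stress-only 72 h and inhibitor 72 h
        flat = fcluster(Z, t=3, criterion="maxclust")
        groups: dict = {}
        for lab, cl in zip(labels, flat):
            cond = lab.rsplit("_r", 1)[0]
            groups.setdefault(cond, set()).add(cl)
        # each replicate triple lands in a single flat cluster...
        assert all(len(v) == 1 for v in groups.values())
        # ...and the 72 h arms separate while the two t0 arms co-cluster
        assert groups["TM_t72"] != groups["TMZ_t72"]
        assert groups["TM_t0"] == groups["TMZ_t0"]

    def test_toy_matrix_matches_naive_ward_agglomeration(self):
        """Merge heights equal a loop-based Lance-Williams Ward reference."""
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            rng.integers(50, 500, size=(10, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        Z, labels, _ = transcriptome.sample_cluster(counts, top_n=10, vst="anscombe")
        # reference: naive agglomeration on the same VST points
        pts = transcriptome.variance_stabilize(counts, "anscombe").to_numpy().T
        n = len(pts)
        d2 = {(i, j): ((pts[i] - pts[j]) ** 2).sum()
              for i in range(n) for j in range(i + 1, n)}
        sizes = {i: 1 for i in range(n)}
        active = set(range(n))
        heights = []
        next_id = n
        while len(active) > 1:
            (a, b), dij = min(
                ((k, v) for k, v in d2.items()
                 if k[0] in active and k[1] in active),
                key=lambda kv: kv[1],
            )
            heights.append(np.sqrt(dij))
            na, nb = sizes[a], sizes[b]
            for k in active - {a, b}:
                nk = sizes[k]
                dak = d2[tuple(sorted((a, k)))]
                dbk = d2[tuple(sorted((b, k)))]
                dnew = ((na + nk) * dak + (nb + nk) * dbk - nk * dij) / (na + nb + nk)
                d2[tuple(sorted((next_id, k)))] = dnew
            sizes[next_id] = na + nb
            active -= {a, b}
            active.add(next_id)
            next_id += 1
        assert np.allclose(sorted(Z[:, 2]), sorted(heights), atol=1e-8)

    def test_top_n_capped_with_warning(self):
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(rng.integers(1, 100, size=(20, 4)))
        with pytest.warns(UserWarning):
            transcriptome.sample_cluster(counts, top_n=500)

    def test_too_few_samples_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2]})
        with pytest.raises(ValueError):
            transcriptome.sample_cluster(counts)
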
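"""Phylogenetic PCA and phylogenetic MANOVA."""

import numpy as np
import pandas as pd
import pytest

from caudalmorph.morphodata import GroupFactor
from caudalmorph.multivar import (phylo_manova, phylo_pca, pillai_trace,
                                  select_components)
from caudalmorph.phylo import read_newick, simulate_bm, tree_vcv
from caudalmorph.synth import (_SyntheticGroups, assign_convergent_groups,
                               simulate_group_traits, simulate_yule_tree)


def _star(n):
    return read_newick("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")


class TestPhyloPCA:
    def test_star_tree_equals_ordinary_pca(self):
        t = _star(20)
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 4)), index=list(t.tips))
        r = phylo_pca(X, t)
        w = np.linalg.eigvalsh(np.cov(X.to_numpy().T))[::-1]
        assert np.allclose(r.eigenvalues, w, atol=1e-8)

    def test_three_taxon_hand_oracle(self, three_taxon_tree):
        X = pd.DataFrame({"x": [1.0, 2.0, 4.0], "y": [0.5, -0.5, 1.0]},
                         index=["A", "B", "C"])
        C = tree_vcv(three_taxon_tree).reorder(["A", "B", "C"]).C
        Ci = np.linalg.inv(C)
        ones = np.ones(3)
        Xv = X.to_numpy()
        a = (ones @ Ci @ Xv) / (ones @ Ci @ ones)
        D = Xv - a
        R = D.T @ Ci @ D / 2
        w = np.sort(np.linalg.eigvalsh(R))[::-1]
        r = phylo_pca(X, three_taxon_tree)
        assert np.allclose(r.phylo_mean, a, atol=1e-12)
        assert np.allclose(r.evolutionary_cov, R, atol=1e-12)
        assert np.allclose(r.eigenvalues, w, atol=1e-12)

    def test_eigenvalue_sum_equals_trace(self, yule16):
        X = simulate_bm(yule16, np.eye(5), 1.0, seed=1)
        r = phylo_pca(X, yule16)
        assert r.eigenvalues.sum() == pytest.approx(
            np.trace(r.evolutionary_cov), abs=1e-8)

    def test_loadings_orthonormal(self, yule16):
        X = simulate_bm(yule16, np.eye(4), 1.0, seed=2)
        r = phylo_pca(X, yule16)
        assert np.allclose(r.loadings.T @ r.loadings, np.eye(4), atol=1e-8)

    def test_duplicated_column_gives_zero_eigenvalue(self, yule16):
        X = simulate_bm(yule16, np.eye(2), 1.0, seed=3)
        X["dup"] = X[0]
        r = phylo_pca(X, yule16)
        assert abs(r.eigenvalues[-1]) < 1e-10

    def test_scores_reconstruct_centered_data(self, yule16):
        X = simulate_bm(yule16, np.eye(3), 1.0, seed=4)
        r = phylo_pca(X, yule16)
        back = r.scores.to_numpy() @ r.loadings.T + r.phylo_mean
        assert np.allclose(back, X.to_numpy(), atol=1e-8)

    def test_select_components_threshold(self, yule16):
        X = simulate_bm(yule16, np.diag([10.0, 3.0, 0.1, 0.1]), 1.0, seed=5)
        r = phylo_pca(X, yule16)
        keep = select_components(r, 5.0)
        assert keep == [i for i, p in enumerate(r.percent_variance) if p >= 5.0]
        assert select_components(r, 0.0) == [0, 1, 2, 3]


class TestPillai:
    def test_univariate_equals_anova_r2(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        Y = pd.get_dummies(pd.Series(labels)).to_numpy(float)
        V = pillai_trace(y[:, None], Y)
        gm = [y[labels == g].mean() for g in ("a", "b", "c")]
        ssb = sum(10 * (m - y.mean()) ** 2 for m in gm)
        sst = ((y - y.mean()) ** 2).sum()
        assert V == pytest.approx(ssb / sst, abs=1e-10)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.multivariate.manova")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(24, 3))
        labels = np.repeat(["a", "b", "c", "d"], 6)
        df = pd.DataFrame(X, columns=["v1", "v2", "v3"])
        df["g"] = labels
        Y = pd.get_dummies(pd.Series(labels)).to_numpy(float)
        ours = pillai_trace(X, Y)
        tab = sm.MANOVA.from_formula("v1 + v2 + v3 ~ g", data=df) \
            .mv_test().results["g"]["stat"]
        assert ours == pytest.approx(tab.loc["Pillai's trace", "Value"], abs=1e-10)


class TestPhyloManova:
    def _setup(self, seed, n=32, effect=0.0):
        t = simulate_yule_tree(n, seed=seed)
        g = assign_convergent_groups(t, 3, {"a": 1, "b": 2, "c": 1}, seed + 1)
        X = simulate_group_traits(t, g, effect, 1.0, 3, seed + 2)
        return t, g, X

    def test_strong_separation_detected(self):
        t = _star(30)
        rng = np.random.default_rng(5)
        labels = pd.Series(np.repeat(["a", "b", "c"], 10), index=list(t.tips))
        g = _SyntheticGroups(labels)
        means = {"a": 0.0, "b": 5.0, "c": 10.0}
        X = pd.DataFrame(rng.normal(size=(30, 2)), index=list(t.tips))
        X[0] += labels.map(means)
        r = phylo_manova(X, g, t, n_sim=999, seed=0)
        assert r.p_ahistorical < 1e-4
        assert r.p_phylogenetic <= 0.01

    def test_deterministic_per_seed(self):
        t, g, X = self._setup(10, effect=1.0)
        a = phylo_manova(X, g, t, n_sim=199, seed=3)
        b = phylo_manova(X, g, t, n_sim=199, seed=3)
        assert a.p_phylogenetic == b.p_phylogenetic

    def test_type_one_error_calibrated(self):
        rej = 0
        n_runs = 120
        for s in range(n_runs):
            t, g, X = self._setup(5000 + 10 * s, n=24, effect=0.0)
            r = phylo_manova(X, g, t, n_sim=199, seed=s)
            rej += r.p_phylogenetic <= 0.05
        assert 0.01 <= rej / n_runs <= 0.09

    def test_lambda_zero_null_matches_ahistorical(self):
        # with the covariance collapsed to a star, the simulation null and
        # the F-based p-value should agree in distribution
        diffs = []
        for s in range(60):
            t = simulate_yule_tree(24, seed=7000 + s)
            g = assign_convergent_groups(t, 3, {"a": 1, "b": 1, "c": 1}, 100 + s)
            rng = np.random.default_rng(7500 + s)
            X = pd.DataFrame(rng.normal(size=(24, 2)), index=list(t.tips))
            r = phylo_manova(X, g, t, n_sim=199, seed=s, lam=0.0)
            diffs.append(r.p_phylogenetic - r.p_ahistorical)
        # paired p-values track each other closely under the null
        assert abs(np.mean(diffs)) < 0.1

    def test_single_group_rejected(self, yule16):
        g = _SyntheticGroups(pd.Series("a", index=list(yule16.tips)))
        X = simulate_bm(yule16, np.eye(2), 1.0, seed=1)
        with pytest.raises(ValueError):
            phylo_manova(X, g, yule16, n_sim=99, seed=0)

    def test_phylo_p_more_conservative_for_clustered_groups(self):
        # groups that are clades inflate the ahistorical test; the
        # simulation null should reject less often
        wins = 0
        for s in range(40):
            t = simulate_yule_tree(24, seed=8000 + s)
            g = assign_convergent_groups(t, 3, {"a": 1, "b": 1, "c": 1}, 200 + s)
            X = simulate_bm(t, np.eye(2), 1.0, seed=8500 + s)
            r = phylo_manova(X, g, t, n_sim=199, seed=s)
            wins += r.p_phylogenetic >= r.p_ahistorical
        assert wins >= 24  # on average the phylogenetic p is larger
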
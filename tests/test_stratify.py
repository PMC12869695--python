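"""Patient stratification, survival separation, LPS, LCC test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from combosyn.stratify import (LPSClassifier, classify_lps,
                               lcc_permutation_test, logrank_compare,
                               rank_partners, stratify_patients)
from combosyn.synth import make_survival


def planted_matrix(rng, n_hi=6, n_lo=6, n_cols=8):
    hi = np.clip(rng.normal(0.8, 0.05, (n_hi, n_cols)), 0, 1)
    lo = np.clip(rng.normal(0.2, 0.05, (n_lo, n_cols)), 0, 1)
    idx = [f"hi{i}" for i in range(n_hi)] + [f"lo{i}" for i in range(n_lo)]
    return pd.DataFrame(np.vstack([hi, lo]), index=idx,
                        columns=[f"A+p{j}" for j in range(n_cols)])


class TestStratifyPatients:
    def test_planted_groups_recovered(self, rng):
        mat = planted_matrix(rng)
        groups = stratify_patients(mat)
        assert (groups[[i for i in mat.index if i.startswith("hi")]]
                == "responsive").all()
        assert (groups[[i for i in mat.index if i.startswith("lo")]]
                == "non_responsive").all()

    def test_identical_rows_rejected(self):
        mat = pd.DataFrame(np.full((4, 3), 0.5))
        with pytest.raises(ValueError):
            stratify_patients(mat)

    def test_column_permutation_invariance(self, rng):
        mat = planted_matrix(rng)
        perm = list(rng.permutation(mat.columns))
        g1 = stratify_patients(mat)
        g2 = stratify_patients(mat[perm])
        pd.testing.assert_series_equal(g1, g2)

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            stratify_patients(planted_matrix(np.random.default_rng(0),
                                             n_hi=1, n_lo=0))

    def test_rank_partners_by_column_mean(self, rng):
        mat = planted_matrix(rng)
        ranked = rank_partners(mat)
        assert list(ranked.index) == list(
            mat.mean(0).sort_values(ascending=False).index)


class TestLogrank:
    def test_identical_groups_nonsignificant(self):
        t = np.array([5.0, 8, 12, 3, 9, 7])
        surv = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(12)],
            "time": np.concatenate([t, t]),
            "event": [1] * 12})
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=surv["sample_id"])
        stat, p = logrank_compare(groups, surv)
        assert stat < 1e-9 and p > 0.99

    def test_hand_computed_two_by_two(self):
        """Two samples per group, single event each at distinct times.

        Group a events at t=1 (4 at risk: O-E = 1 - 2/4), group b at t=2
        (2 at risk, one per group: O-E = -1/2 + ... ) — the classic
        log-rank tables give chi2 = (sum(O-E))^2 / Var.
        """
        surv = pd.DataFrame({
            "sample_id": ["a1", "a2", "b1", "b2"],
            "time": [1.0, 3.0, 2.0, 4.0],
            "event": [1, 1, 1, 1]})
        groups = pd.Series(["a", "a", "b", "b"],
                           index=["a1", "a2", "b1", "b2"])
        # hand computation over event times 1,2,3,4 for group a:
        # t=1: O=1 E=2/4  V=(2*2*1*3)/(16*3)=0.25
        # t=2: O=0 E=1/3  V=(1*2*1*2)/(9*2) =2/9
        # t=3: O=1 E=1/2  V=(1*1*1*1)/(4*1)=0.25
        # t=4: O=0 E=0    V=0
        U = (1 - 0.5) + (0 - 1 / 3) + (1 - 0.5)
        V = 0.25 + 2 / 9 + 0.25
        chi2 = U ** 2 / V
        stat, _ = logrank_compare(groups, surv)
        assert abs(stat - chi2) < 1e-9

    def test_hazard_ratio_three_usually_significant(self):
        groups = {f"s{i}": ("a" if i < 200 else "b") for i in range(400)}
        g = pd.Series(groups)
        hits = 0
        for seed in range(100):
            surv = make_survival(groups, hazard_ratio=3.0, seed=seed)
            _, p = logrank_compare(g, surv)
            hits += p < 0.05
        assert hits >= 95

    def test_empty_group_rejected(self):
        surv = pd.DataFrame({"sample_id": ["s1", "s2"], "time": [1.0, 2.0],
                             "event": [1, 1]})
        groups = pd.Series(["a", "a"], index=["s1", "s2"])
        with pytest.raises(ValueError):
            logrank_compare(groups, surv)


class TestLPS:
    def _separable(self, rng, shift=3.0, n=40, g=80):
        X = pd.DataFrame(rng.normal(0, 1, (n, g)),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"g{j}" for j in range(g)])
        y = pd.Series(["A"] * (n // 2) + ["B"] * (n // 2), index=X.index)
        X.iloc[: n // 2, :10] += shift
        return X, y

    def test_separable_high_validation_accuracy(self, rng):
        X, y = self._separable(rng)
        res = LPSClassifier(X, y, n_genes=50).fit(seed=0)
        assert res.val_accuracy >= 0.95

    def test_null_labels_chance_accuracy(self, rng):
        accs = []
        for seed in range(5):
            X, y = self._separable(rng, shift=0.0)
            res = LPSClassifier(X, y, n_genes=50).fit(seed=seed)
            accs.append(res.val_accuracy)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_weights_equal_t_statistics(self, rng):
        """Oracle: recompute pooled-variance t by hand, tol 1e-9."""
        X, y = self._separable(rng)
        res = LPSClassifier(X, y, n_genes=50).fit(train_frac=1.0, seed=0)
        xa = X[y == "B"]
        xb = X[y == "A"]
        na, nb = len(xa), len(xb)
        sp = np.sqrt(((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1))
                     / (na + nb - 2))
        t_hand = (xa.mean() - xb.mean()) / (sp * np.sqrt(1 / na + 1 / nb))
        for g in res.genes:
            assert abs(res.weights[g] - t_hand[g]) < 1e-9

    def test_posterior_tail_and_tie(self, rng):
        X, y = self._separable(rng)
        res = LPSClassifier(X, y).fit(seed=0)
        g0, g1 = res.labels
        mid = (res.group_means[g0] + res.group_means[g1]) / 2
        if abs(res.group_sds[g0] - res.group_sds[g1]) < 1e-9 \
                and abs(res.priors[g0] - res.priors[g1]) < 1e-9:
            assert abs(res.posterior(mid) - 0.5) < 1e-9
        # 5 sd into group1 territory
        deep = res.group_means[g1] + 5 * res.group_sds[g1] * np.sign(
            res.group_means[g1] - res.group_means[g0])
        assert res.posterior(deep) > 0.99

    def test_zero_weights_posterior_equals_prior(self):
        from combosyn.stratify import LPSResults
        res = LPSResults(genes=["g1"], weights=pd.Series({"g1": 0.0}),
                         group_means={"A": 0.0, "B": 0.0},
                         group_sds={"A": 1.0, "B": 1.0},
                         priors={"A": 0.7, "B": 0.3}, labels=("A", "B"),
                         train_accuracy=np.nan, val_accuracy=None)
        assert abs(res.posterior(res.score(pd.Series({"g1": 5.0}))) - 0.3) \
            < 1e-12

    def test_missing_genes_schema_error(self, rng):
        X, y = self._separable(rng)
        res = LPSClassifier(X, y).fit(seed=0)
        with pytest.raises(ValueError, match="missing"):
            classify_lps(res, pd.Series({"gX": 1.0}))

    def test_round_trip_train_accuracy(self, rng):
        X, y = self._separable(rng)
        model = LPSClassifier(X, y)
        res = model.fit(train_frac=1.0, seed=0)
        acc = np.mean([res.classify(X.loc[s])[0] == y.loc[s]
                       for s in X.index])
        assert abs(acc - res.train_accuracy) < 1e-12

    def test_json_round_trip_and_confidence_band(self, rng):
        from combosyn.stratify import LPSResults
        X, y = self._separable(rng)
        res = LPSClassifier(X, y).fit(seed=0)
        back = LPSResults.from_dict(res.to_dict())
        s = X.index[0]
        assert back.classify(X.loc[s]) == res.classify(X.loc[s])
        # borderline posterior falls inside a strict confidence band
        g0, g1 = res.labels
        mid = (res.group_means[g0] + res.group_means[g1]) / 2
        weights = res.weights.to_numpy()
        profile = pd.Series(np.zeros(len(res.genes)), index=res.genes)
        profile.iloc[0] = mid / weights[0]
        group, post = res.classify(profile, confidence_band=0.99)
        if max(post, 1 - post) < 0.99:
            assert group == "unclassified"

    def test_small_class_rejected(self, rng):
        X, _ = self._separable(rng, n=10)
        y = pd.Series(["A"] * 8 + ["B"] * 2, index=X.index)
        with pytest.raises(ValueError):
            LPSClassifier(X, y)


def path3_ppi():
    return pd.DataFrame({"protein_a": ["a", "b"], "protein_b": ["b", "c"],
                         "weight": [1.0, 1.0]})


class TestLcc:
    def test_exhaustive_path_graph(self):
        """Oracle: all 2-subsets of a-b-c give LCC sizes {2,2,1};
        p for observed 2 is 2/3 exactly (with the +1 correction
        approached in the Monte-Carlo limit)."""
        sizes = []
        for pair in itertools.combinations(["a", "b", "c"], 2):
            import networkx as nx
            g = nx.Graph([("a", "b"), ("b", "c")]).subgraph(pair)
            sizes.append(max(len(c) for c in nx.connected_components(g)))
        assert sorted(sizes) == [1, 2, 2]
        res = lcc_permutation_test(["a", "b"], path3_ppi(), n_perm=6000,
                                   seed=0)
        assert res.observed_lcc == 2
        assert abs(res.p_value - 2 / 3) < 2 / np.sqrt(6000)

    def test_single_node_p_one(self):
        res = lcc_permutation_test(["a"], path3_ppi(), n_perm=500, seed=0)
        assert res.observed_lcc == 1
        assert res.p_value == 1.0

    def test_planted_module_significant(self, default_world):
        """Targets inside one pathway (dense block) form a larger LCC
        than random gene sets."""
        w = default_world
        genes = [g for g in w.genes if w.pathway_of_gene[g] == "P00"][:12]
        res = lcc_permutation_test(genes, w.ppi_edges, n_perm=2000, seed=0)
        assert res.p_value < 0.05

    def test_super_uniform_under_null(self, default_world):
        rng = np.random.default_rng(0)
        nodes = sorted(set(default_world.ppi_edges["protein_a"])
                       | set(default_world.ppi_edges["protein_b"]))
        hits = 0
        for i in range(200):
            targets = [nodes[j] for j in
                       rng.choice(len(nodes), size=10, replace=False)]
            res = lcc_permutation_test(targets, default_world.ppi_edges,
                                       n_perm=200, seed=i)
            hits += res.p_value <= 0.05
        assert hits / 200 <= 0.08

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            lcc_permutation_test(["zz"], path3_ppi(), n_perm=10)

    def test_determinism(self):
        r1 = lcc_permutation_test(["a", "c"], path3_ppi(), n_perm=100, seed=4)
        r2 = lcc_permutation_test(["a", "c"], path3_ppi(), n_perm=100, seed=4)
        np.testing.assert_array_equal(r1.null_sizes, r2.null_sizes)
        assert r1.p_value == r2.p_value
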
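"""Feature engineering: graphs, propagation, marker genes, autoencoder."""

import numpy as np
import pandas as pd
import pytest

from combosyn.features import (AutoencoderConfig, build_dti_matrix,
                               encode_sample, mutation_profile,
                               pretrain_autoencoder, propagate,
                               select_marker_genes, smiles_to_graph)


class TestSmilesToGraph:
    @pytest.mark.parametrize("smiles,n_atoms,n_bonds", [
        ("CC", 2, 1),          # ethane
        ("C1CC1", 3, 3),       # cyclopropane: ring closure adds a bond
        ("c1ccccc1", 6, 6),    # benzene
    ])
    def test_atom_and_bond_counts(self, smiles, n_atoms, n_bonds):
        g = smiles_to_graph(smiles)
        assert g.n_atoms == n_atoms
        assert g.n_bonds == n_bonds
        assert np.array_equal(g.adjacency, g.adjacency.T)
        assert np.all(np.diag(g.adjacency) == 0)

    def test_benzene_aromatic_flags(self):
        g = smiles_to_graph("c1ccccc1")
        assert g.aromatic.all()
        assert g.atom_features[:, -1].all()

    def test_parse_failure(self):
        with pytest.raises(ValueError):
            smiles_to_graph("xyz((")


class TestDtiMatrix:
    def test_basic_matrix(self):
        mat, n_ign = build_dti_matrix([("d1", "g1"), ("d2", "g3")],
                                      ["g1", "g2", "g3"])
        assert mat.shape == (2, 3)
        assert mat.loc["d1", "g1"] == 1 and mat.loc["d2", "g3"] == 1
        assert mat.to_numpy().sum() == 2 and n_ign == 0

    def test_unknown_gene_warns(self):
        with pytest.warns(UserWarning):
            mat, n_ign = build_dti_matrix([("d1", "gX"), ("d1", "g1")],
                                          ["g1"])
        assert n_ign == 1 and mat.to_numpy().sum() == 1

    def test_duplicate_annotations_idempotent(self):
        mat, _ = build_dti_matrix([("d1", "g1"), ("d1", "g1")], ["g1"])
        assert mat.loc["d1", "g1"] == 1


def path_graph_ppi():
    return pd.DataFrame({"protein_a": ["g1", "g2"],
                         "protein_b": ["g2", "g3"],
                         "weight": [1.0, 1.0]})


class TestPropagate:
    def test_alpha_one_returns_input(self):
        dti = pd.DataFrame([[1.0, 0.0, 1.0]], index=["d"],
                           columns=["g1", "g2", "g3"])
        out = propagate(dti, path_graph_ppi(), alpha=1.0)
        pd.testing.assert_frame_equal(out, dti)

    def test_edgeless_network_identity(self):
        dti = pd.DataFrame([[1.0, 0.0]], index=["d"], columns=["g1", "g2"])
        empty = pd.DataFrame(columns=["protein_a", "protein_b", "weight"])
        out = propagate(dti, empty, alpha=0.3)
        np.testing.assert_allclose(out.to_numpy(), dti.to_numpy())

    def test_path_graph_matches_direct_solve(self):
        """Oracle: fixed point of (I - (1-a)S)F = a F0 by linear solve."""
        dti = pd.DataFrame([[1.0, 0.0, 0.0]], index=["d"],
                           columns=["g1", "g2", "g3"])
        out = propagate(dti, path_graph_ppi(), alpha=0.5, tol=1e-10)
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        d = A.sum(1)
        S = A / np.sqrt(np.outer(d, d))
        F = np.linalg.solve(np.eye(3) - 0.5 * S, 0.5 * np.array([1, 0, 0.]))
        np.testing.assert_allclose(out.to_numpy()[0], F, atol=1e-6)

    def test_random_graphs_match_solve(self, rng):
        """Linear-solve oracle on random graphs up to 50 nodes."""
        for trial in range(5):
            n = int(rng.integers(10, 51))
            genes = [f"g{i}" for i in range(n)]
            rows = [(genes[i], genes[j], float(rng.uniform(0.2, 1.0)))
                    for i in range(n) for j in range(i + 1, n)
                    if rng.random() < 0.15]
            ppi = pd.DataFrame(rows, columns=["protein_a", "protein_b",
                                              "weight"])
            dti = pd.DataFrame(
                (rng.random((3, n)) < 0.1).astype(float),
                index=["d1", "d2", "d3"], columns=genes)
            alpha = float(rng.uniform(0.2, 0.9))
            out = propagate(dti, ppi, alpha=alpha, tol=1e-10)
            A = np.zeros((n, n))
            for a, b, w in rows:
                i, j = genes.index(a), genes.index(b)
                A[i, j] = A[j, i] = w
            deg = A.sum(1)
            with np.errstate(divide="ignore"):
                dinv = 1 / np.sqrt(deg)
            dinv[~np.isfinite(dinv)] = 0
            S = A * dinv[:, None] * dinv[None, :]
            S[deg == 0, deg == 0] = 1.0   # isolated nodes self-loop
            F = np.linalg.solve(np.eye(n) - (1 - alpha) * S,
                                alpha * dti.to_numpy().T)
            np.testing.assert_allclose(out.to_numpy(), F.T, atol=1e-6)

    def test_alpha_near_one_approaches_input(self):
        dti = pd.DataFrame([[1.0, 0.0, 0.0]], index=["d"],
                           columns=["g1", "g2", "g3"])
        out = propagate(dti, path_graph_ppi(), alpha=0.999)
        assert np.max(np.abs(out.to_numpy() - dti.to_numpy())) < 1e-2

    def test_hub_removed_exact_top_fraction(self, default_world,
                                            default_features):
        """hub_removed deletes exactly the top-ceil(5%) degree nodes."""
        w = default_world
        dti = default_features.dti_binary
        full = propagate(dti, w.ppi_edges, variant="full")
        hub = propagate(dti, w.ppi_edges, variant="hub_removed")
        # recompute the expected removal set independently
        deg = pd.Series(0, index=dti.columns, dtype=int)
        for r in w.ppi_edges.itertuples(index=False):
            deg[r.protein_a] += 1
            deg[r.protein_b] += 1
        n_remove = int(np.ceil(0.05 * len(dti.columns)))
        expected = set(sorted(deg.index, key=lambda g: (-deg[g], g))
                       [:n_remove])
        # removed hubs receive no diffused mass (only their own restart)
        diff = (full - hub).abs().sum(axis=0)
        affected = set(diff[diff > 1e-12].index)
        for g in expected:
            untargeted = dti[g].sum() == 0
            if not untargeted:
                continue
            assert hub[g].abs().sum() < 1e-12

    def test_invalid_alpha(self):
        dti = pd.DataFrame([[1.0]], index=["d"], columns=["g1"])
        with pytest.raises(ValueError):
            propagate(dti, path_graph_ppi(), alpha=0.0)

    def test_output_nonnegative_finite(self, default_features):
        out = default_features.dti_propagated.to_numpy()
        assert np.all(np.isfinite(out)) and np.all(out >= 0)


class TestMarkerGenes:
    def _expr(self, rng, n=20, g=30):
        X = pd.DataFrame(rng.normal(0, 1, (n, g)),
                         columns=[f"g{j}" for j in range(g)])
        return X

    def test_union_with_all_tags(self, rng):
        X = self._expr(rng)
        genes = list(X.columns[:5])
        ppi = pd.DataFrame({"protein_a": genes[:4], "protein_b": genes[1:5],
                            "weight": [0.9] * 4})
        ms = select_marker_genes(X[genes], genes, ppi, genes,
                                 variable_frac=1.0, hub_n=5)
        assert sorted(ms.genes) == sorted(genes)
        for g in ms.genes:
            assert ms.provenance[g] == {"landmark", "variable", "hub",
                                        "target"}

    def test_variance_rank_oracle(self, default_world):
        """High-variance selection prefers pathway genes; cross-check
        against a direct variance sort."""
        w = default_world
        ms = select_marker_genes(w.expression, [], w.ppi_edges.iloc[:0],
                                 [], variable_frac=0.15,
                                 hub_n=0)
        var = w.expression.var(axis=0, ddof=1)
        k = int(round(0.15 * len(var)))
        expected = set(var.sort_values(ascending=False).index[:k])
        assert set(ms.genes) == expected

    def test_hub_rule_star_graph(self, rng):
        X = self._expr(rng, g=5)
        star = pd.DataFrame({"protein_a": ["g0"] * 4,
                             "protein_b": ["g1", "g2", "g3", "g4"],
                             "weight": [0.9] * 4})
        ms = select_marker_genes(X, [], star, [], variable_frac=1 / 30,
                                 hub_n=1)
        assert "g0" in ms.genes and "hub" in ms.provenance["g0"]

    def test_monotone_in_sources(self, rng):
        X = self._expr(rng)
        ppi = pd.DataFrame(columns=["protein_a", "protein_b", "weight"])
        small = select_marker_genes(X, ["g0"], ppi, [], variable_frac=0.1,
                                    hub_n=0)
        big = select_marker_genes(X, ["g0", "g1", "g2"], ppi, ["g5"],
                                  variable_frac=0.1, hub_n=0)
        assert set(small.genes) <= set(big.genes)


class TestAutoencoder:
    def test_low_rank_reconstruction(self, rng):
        """Rank-3 data with bottleneck >= 3: holdout MSE < 1% of input
        variance (standardized units: variance 1 per gene)."""
        n, g, k = 60, 40, 3
        U = rng.normal(0, 1, (n, k))
        V = rng.normal(0, 1, (k, g))
        X = pd.DataFrame(U @ V)
        cfg = AutoencoderConfig(hidden=32, bottleneck=8, dropout=0.0,
                                epochs=800, lr=3e-3, seed=0)
        enc = pretrain_autoencoder(X, cfg)
        assert enc.loss_log["holdout_mse"].min() < 0.01

    def test_determinism(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (20, 10)))
        c = AutoencoderConfig(epochs=20, seed=5)
        e1 = pretrain_autoencoder(X, c)
        e2 = pretrain_autoencoder(X, c)
        pd.testing.assert_frame_equal(e1.loss_log, e2.loss_log)
        for w1, w2 in zip(e1.weights, e2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_too_few_samples(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (5, 10)))
        with pytest.raises(ValueError):
            pretrain_autoencoder(X)

    def test_encode_sample_contract(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (20, 10)),
                         columns=[f"g{j}" for j in range(10)])
        enc = pretrain_autoencoder(X, AutoencoderConfig(
            epochs=5, bottleneck=4, hidden=8, seed=0))
        z1 = encode_sample(enc, X.iloc[0])
        z2 = encode_sample(enc, X.iloc[0])
        np.testing.assert_array_equal(z1, z2)
        assert z1.shape == (4,)
        assert np.all(np.isfinite(encode_sample(enc, np.zeros(10))))
        with pytest.raises(ValueError):
            encode_sample(enc, np.zeros(7))

    def test_group_structure_beats_random_projection(self, default_world):
        """Pathway-activity groups are tighter in autoencoder space than
        under a random projection of matched dimension."""
        w = default_world
        X = w.expression
        enc = pretrain_autoencoder(X, AutoencoderConfig(
            hidden=64, bottleneck=16, epochs=300, seed=0))
        Z = enc.encode(X.to_numpy())
        rng = np.random.default_rng(0)
        mu = X.to_numpy().mean(0)
        sd = X.to_numpy().std(0)
        R = ((X.to_numpy() - mu) / sd) @ rng.normal(
            0, 1, (X.shape[1], 16)) / np.sqrt(X.shape[1])
        groups = w.sample_activity[w.pathways[0]].to_numpy()

        def ratio(E):
            d = ((E[:, None, :] - E[None, :, :]) ** 2).sum(-1) ** 0.5
            same = groups[:, None] == groups[None, :]
            np.fill_diagonal(same, False)
            within = d[same].mean()
            between = d[~same & ~np.eye(len(E), dtype=bool)].mean()
            return within / between
        assert ratio(Z) < ratio(R)


class TestMutationProfile:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene",
                                           "variant_class"])

    def test_single_missense(self):
        mat = mutation_profile(self._calls([("s1", "g1", "missense")]),
                               ["g1", "g2"])
        assert mat.loc["s1", "g1"] == 1 and mat.loc["s1", "g2"] == 0

    def test_synonymous_filtered(self):
        mat = mutation_profile(self._calls([("s1", "g1", "synonymous")]),
                               ["g1"])
        assert mat.loc["s1", "g1"] == 0

    def test_binarized_and_unknown_class_warns(self):
        calls = self._calls([("s1", "g1", "missense"),
                             ("s1", "g1", "nonsense"),
                             ("s1", "g1", "weird_class")])
        with pytest.warns(UserWarning):
            mat = mutation_profile(calls, ["g1"])
        assert mat.loc["s1", "g1"] == 1
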
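"""Synergy scores, coarse-grained attribution, interaction regression, DE selection."""

import numpy as np
import pytest

from cfot.downstream import (
    attribution_ratios,
    attribution_regression,
    cell_synergy_score,
    coarse_grain_matching,
    gene_synergy_score,
    select_de_genes,
    synergy_matrix,
)
from cfot.pipeline import ITEMatrix


def _ite(values, **kw):
    return ITEMatrix(values=np.asarray(values, float), **kw)


class TestSynergy:
    def test_additive_inputs_give_zero(self):
        rng = np.random.default_rng(0)
        A = _ite(rng.normal(size=(5, 4)))
        B = _ite(rng.normal(size=(5, 4)))
        AB = _ite(A.values + B.values)
        np.testing.assert_allclose(synergy_matrix(A, B, AB).psi, 0.0, atol=1e-12)

    def test_single_entry_arithmetic(self):
        psi = synergy_matrix(_ite([[1.0]]), _ite([[2.0]]), _ite([[5.0]])).psi
        np.testing.assert_allclose(psi, [[2.0]])

    def test_linearity_exact(self):
        # synergy(A, B, A + B + E) == E for any interaction matrix E
        rng = np.random.default_rng(1)
        A = _ite(rng.normal(size=(7, 3)))
        B = _ite(rng.normal(size=(7, 3)))
        E = rng.normal(size=(7, 3))
        psi = synergy_matrix(A, B, _ite(A.values + B.values + E)).psi
        np.testing.assert_allclose(psi, E, atol=1e-12)

    def test_mode_bookkeeping(self):
        a = _ite(np.zeros((2, 2)), log_transformed=True)
        assert synergy_matrix(a, a, a).mode == "multiplicative"
        b = _ite(np.zeros((2, 2)), log_transformed=False)
        assert synergy_matrix(b, a, a).mode == "additive"

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            synergy_matrix(_ite(np.zeros((2, 2))), _ite(np.zeros((3, 2))),
                           _ite(np.zeros((2, 2))))
        t = _ite(np.zeros((2, 2)), direction="counterfactual_for_treated")
        with pytest.raises(ValueError):
            synergy_matrix(t, t, t)
        a = _ite(np.zeros((2, 2)), cell_indices=np.array([0, 1]))
        b = _ite(np.zeros((2, 2)), cell_indices=np.array([0, 2]))
        with pytest.raises(ValueError, match="control populations"):
            synergy_matrix(a, b, a)

    def test_gene_score_sign_cancellation(self):
        psi = np.array([[1.0, 0.2, 0.0], [-1.0, 0.2, 0.0], [0.0, 0.2, 0.0]])
        np.testing.assert_allclose(gene_synergy_score(psi), [0.0, 0.2, 0.0])

    def test_cell_score_euclidean_norm(self):
        # two passing genes with row values (3, 4) -> norm 5
        psi = np.zeros((2, 3))
        psi[:, 0] = [3.0, 3.0]
        psi[:, 1] = [4.0, 4.0]
        scores = cell_synergy_score(psi, gene_threshold=1.0)
        np.testing.assert_allclose(scores, [5.0, 5.0])

    def test_cell_score_no_passing_gene_errors(self):
        with pytest.raises(ValueError, match="max score"):
            cell_synergy_score(np.full((3, 2), 0.01), gene_threshold=0.15)


class TestCoarseMatching:
    def test_block_diagonal_gives_identity(self):
        M = np.kron(np.eye(2), np.full((2, 2), 0.125))
        ctrl = np.array([0, 0, 1, 1])
        resp = np.array([0, 0, 1, 1])
        cm = coarse_grain_matching(M, resp, ctrl)
        np.testing.assert_allclose(cm.matrix, np.eye(2), atol=1e-12)

    def test_uniform_plan_proportional_to_cluster_sizes(self):
        n0, n1 = 6, 4
        M = np.full((n0, n1), 1.0 / (n0 * n1))
        ctrl = np.array([0, 0, 0, 1, 1, 1])
        resp = np.array([0, 0, 0, 1])
        cm = coarse_grain_matching(M, resp, ctrl)
        # each row splits mass across control clusters by their sizes (3, 3)
        np.testing.assert_allclose(cm.matrix, 0.5, atol=1e-12)

    def test_rows_sum_to_one_and_mass_conserved(self):
        rng = np.random.default_rng(2)
        M = rng.random((8, 10))
        M /= M.sum()
        resp = rng.integers(0, 3, size=10)
        ctrl = rng.integers(0, 2, size=8)
        cm = coarse_grain_matching(M, resp, ctrl)
        np.testing.assert_allclose(cm.matrix.sum(axis=1), 1.0, atol=1e-12)
        assert cm.mass.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(cm.column_view.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_mass_response_cluster_dropped(self):
        M = np.array([[0.5, 0.0], [0.5, 0.0]])
        resp = np.array([0, 1])
        ctrl = np.array([0, 1])
        with pytest.warns(UserWarning, match="dropped"):
            cm = coarse_grain_matching(M, resp, ctrl)
        assert cm.matrix.shape[0] == 1


class TestAttribution:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(3)
        n = 200
        z = rng.integers(0, 2, size=n).astype(float)
        c = rng.normal(size=n)
        y = 2.0 * z + 1.0 * c + 3.0 * c * z + 0.7
        fit = attribution_regression(y, z, c)
        assert fit.alpha == pytest.approx(2.0, abs=1e-8)
        assert fit.beta[0] == pytest.approx(1.0, abs=1e-8)
        assert fit.gamma[0] == pytest.approx(3.0, abs=1e-8)
        assert fit.intercept == pytest.approx(0.7, abs=1e-8)
        assert fit.ratio_infinite and np.isinf(fit.ratio)

    def test_null_interaction_small_ratio(self):
        rng = np.random.default_rng(4)
        n = 2000
        hits = 0
        for _ in range(50):
            z = rng.integers(0, 2, size=n).astype(float)
            c = rng.normal(size=n)
            y = 1.0 * z + 0.5 * c + rng.normal(size=n)
            if attribution_regression(y, z, c).ratio < 0.1:
                hits += 1
        assert hits >= 48  # >= 95% of seeds

    def test_pure_noise_coefficients_within_sampling_error(self):
        rng = np.random.default_rng(5)
        n = 2000
        z = rng.integers(0, 2, size=n).astype(float)
        c = rng.normal(size=n)
        y = rng.normal(size=n)
        fit = attribution_regression(y, z, c)
        # crude standard errors: sigma=1 over sqrt of regressor variation,
        # with a conservative factor for design correlation
        se_alpha = 1.0 / np.sqrt(((z - z.mean()) ** 2).sum())
        se_beta = 1.0 / np.sqrt(((c - c.mean()) ** 2).sum())
        cz = c * z
        se_gamma = 1.0 / np.sqrt(((cz - cz.mean()) ** 2).sum())
        assert abs(fit.alpha) < 6 * se_alpha
        assert abs(fit.beta[0]) < 6 * se_beta
        assert abs(fit.gamma[0]) < 6 * se_gamma

    def test_rank_deficient_design_errors(self):
        z = np.array([0.0, 1.0, 0.0, 1.0])
        c = z.copy()  # c == z -> interaction column collinear
        with pytest.raises(ValueError, match="rank"):
            attribution_regression(np.ones(4), z, c)

    def test_vectorized_matches_single_gene(self):
        rng = np.random.default_rng(6)
        n = 300
        z = rng.integers(0, 2, size=n).astype(float)
        C = rng.normal(size=(n, 2))
        Y = rng.normal(size=(n, 5))
        Y[:, 0] += 2.0 * C[:, 0] * z
        ratios = attribution_ratios(Y, z, C)
        for j in range(5):
            assert ratios[j] == pytest.approx(
                attribution_regression(Y[:, j], z, C).ratio, rel=1e-10)
        assert ratios[0] == ratios.max()

    def test_interaction_genes_rank_top_decile(self):
        """Genes whose treatment response depends on the cell state must rank
        in the top decile of the interaction-to-residual ratio, across seeds."""
        from cfot.data import log_normalize
        from cfot.simulate import SimulationConfig, simulate_dataset

        wins = 0
        for seed in range(5):
            # deterministic state -> response cluster mapping: state-specific
            # treatment effects by construction
            P = np.eye(3)[np.array([0, 1, 2])]
            cfg = SimulationConfig(n_cells=1000, n_confounder_genes=300,
                                   n_response_genes=150, n_states=3,
                                   n_response_clusters=3,
                                   response_distributions=P, seed=seed)
            sim = simulate_dataset(cfg)
            data = log_normalize(sim.dataset)
            C = (sim.true_state[:, None] == np.arange(3)[None, :])[:, 1:].astype(float)
            ratios = attribution_ratios(data.values, data.treatment, C)
            # truth: response genes with cluster-dependent signatures
            resp = data.values[:, sim.response_genes]
            treated = data.treatment == 1
            var_across = np.zeros(resp.shape[1])
            for k in range(3):
                m = treated & (sim.true_response_cluster == k)
                var_across += (resp[m].mean(axis=0) - resp[treated].mean(axis=0)) ** 2
            target = sim.response_genes[np.argsort(var_across)[-10:]]
            cutoff = np.quantile(ratios, 0.9)
            if np.median(ratios[target]) >= cutoff:
                wins += 1
        assert wins >= 4


class TestDESelection:
    def test_strong_concordant_gene_passes(self):
        V = np.zeros((100, 2))
        V[:, 0] = 1.0
        rng = np.random.default_rng(0)
        V[:, 1] = rng.normal(0, 0.1, size=100)
        table = select_de_genes(V, gene_ids=["hit", "null"])
        row = table.set_index("gene").loc["hit"]
        assert row["pass"] and row["p"] < 1e-5 and row["effect"] == pytest.approx(1.0)
        assert not table.set_index("gene").loc["null"]["pass"]

    def test_five_cells_p_floor_fails(self):
        # exact two-sided signed-rank floor at n=5 is 2/2^5 = 0.0625
        V = np.ones((5, 1))
        with pytest.warns(UserWarning, match="fewer than 6"):
            table = select_de_genes(V)
        assert table["p"].iloc[0] == pytest.approx(0.0625, abs=1e-12)
        assert not table["pass"].iloc[0]

    def test_small_effect_fails_delta_threshold(self):
        rng = np.random.default_rng(1)
        V = 0.3 + rng.normal(0, 0.01, size=(100, 1))
        table = select_de_genes(V)
        assert table["p"].iloc[0] < 1e-5  # significant ...
        assert not table["pass"].iloc[0]  # ... but below the effect threshold

    def test_all_zero_gene_fails_with_nan_p(self):
        V = np.zeros((20, 1))
        table = select_de_genes(V)
        assert np.isnan(table["p"].iloc[0]) and not table["pass"].iloc[0]

    def test_sorted_by_significance(self):
        rng = np.random.default_rng(2)
        V = np.column_stack([rng.normal(0, 1, 50), 2.0 + rng.normal(0, 0.1, 50)])
        table = select_de_genes(V, gene_ids=["weak", "strong"])
        assert table["gene"].iloc[0] == "strong"
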
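"""Moments smoothing, kinetic fitting, velocity and Markov-chain stages."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from pachydyn import (
    KineticGene,
    cluster_graph,
    compute_moments,
    compute_velocity,
    fit_all_genes,
    fit_gene_kinetics,
    inferred_cell_time,
    kinetics_expected,
    select_driver_genes,
    terminal_states,
    velocity_graph,
)
from pachydyn.kinetics import Moments, TransitionMatrix, VelocityField


class TestMoments:
    def test_self_only_smoothing_is_identity(self, noisy_pair):
        wt = noisy_pair.sample("WT")
        mom = compute_moments(wt, n_neighbors=1)
        totals = wt.spliced.sum(axis=1).astype(float)
        target = np.median(totals[totals > 0])
        expected = wt.spliced * (target / totals)[:, None]
        np.testing.assert_allclose(mom.Ms, expected, rtol=1e-9)

    def test_identical_cells_smooth_to_identical_rows(self, small_panel):
        from pachydyn import CellMatrixPair

        S = np.tile(np.arange(1, 21), (40, 1))
        meta = pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(40)], "sample": "WT"}
        )
        genes = pd.DataFrame({"gene_id": [f"g{j}" for j in range(20)]})
        pair = CellMatrixPair(S, S.copy(), meta, genes)
        mom = compute_moments(pair, n_neighbors=5, n_pcs=5)
        assert np.allclose(mom.Ms, mom.Ms[0])

    def test_matches_brute_force_knn_mean(self):
        from pachydyn import CellMatrixPair
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(7)
        S = rng.poisson(20.0, size=(50, 20))
        U = rng.poisson(5.0, size=(50, 20))
        meta = pd.DataFrame({"cell_id": [f"c{i}" for i in range(50)], "sample": "WT"})
        genes = pd.DataFrame({"gene_id": [f"g{j}" for j in range(20)]})
        pair = CellMatrixPair(S, U, meta, genes)
        mom = compute_moments(pair, n_neighbors=5, n_pcs=10)

        tot = S.sum(1).astype(float)
        Sn = S * (np.median(tot) / tot)[:, None]
        X = PCA(n_components=10, random_state=0).fit_transform(np.log1p(Sn))
        for i in range(50):
            d = np.linalg.norm(X - X[i], axis=1)
            nn = np.argsort(d, kind="stable")[:5]
            np.testing.assert_allclose(mom.Ms[i], Sn[nn].mean(0), rtol=1e-6)

    def test_too_many_neighbors_rejected(self, noisy_pair):
        with pytest.raises(ValueError, match="n_neighbors"):
            compute_moments(noisy_pair.sample("WT"), n_neighbors=10_000)


class TestFitGeneKinetics:
    def test_noiseless_recovery_and_latent_time(self):
        rng = np.random.default_rng(3)
        gene = KineticGene("g", 2.0, 1.0, 0.5, 0.4, "repression")
        t = np.sort(rng.uniform(0, 1, 300))
        u, s = kinetics_expected(gene, t)
        fit = fit_gene_kinetics(u, s, gene_id="g")
        assert fit.valid
        assert abs(fit.gamma / fit.beta - 0.5) / 0.5 <= 0.05
        assert spearmanr(fit.latent_time, t).statistic >= 0.95

    def test_all_zero_gene_invalid(self):
        fit = fit_gene_kinetics(np.zeros(100), np.zeros(100))
        assert not fit.valid and fit.fit_likelihood == 0.0

    def test_shuffled_gene_scores_lower(self):
        rng = np.random.default_rng(4)
        gene = KineticGene("g", 3.0, 1.0, 0.4, 0.4, "repression")
        t = np.sort(rng.uniform(0, 1, 200))
        u, s = kinetics_expected(gene, t)
        clean = fit_gene_kinetics(u, s)
        perm = rng.permutation(200)
        # shuffle u against s: destroys the phase-plane relation
        noisy = fit_gene_kinetics(u[perm], s)
        assert noisy.fit_likelihood < clean.fit_likelihood

    def test_objective_trace_monotone_nonincreasing(self):
        rng = np.random.default_rng(5)
        gene = KineticGene("g", 2.5, 1.0, 0.7, 0.4, "repression")
        t = np.sort(rng.uniform(0, 1, 150))
        u, s = kinetics_expected(gene, t)
        u = rng.poisson(np.maximum(u, 0) * 10) / 10.0
        s = rng.poisson(np.maximum(s, 0) * 10) / 10.0
        fit = fit_gene_kinetics(u, s)
        trace = np.array(fit.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1e-12))

    def test_likelihood_in_unit_interval(self, noisy_pair):
        wt = noisy_pair.sample("WT")
        mom = compute_moments(wt, n_neighbors=10)
        for fit in fit_all_genes(mom):
            assert 0.0 <= fit.fit_likelihood <= 1.0


class TestDriverSelection:
    @pytest.fixture(scope="class")
    def wt_fitted(self, noisy_pair):
        wt = noisy_pair.sample("WT")
        mom = compute_moments(wt, n_neighbors=30)
        return wt, mom, fit_all_genes(mom)

    def test_threshold_zero_keeps_all_valid_fits(self, wt_fitted):
        _, mom, fits = wt_fitted
        drivers = select_driver_genes(fits, mom, threshold=0.0)
        valid_ids = {f.gene_id for f in fits if f.valid and f.fit_likelihood > 0}
        assert set(drivers["gene_id"]) == valid_ids

    def test_threshold_above_one_empty(self, wt_fitted):
        _, mom, fits = wt_fitted
        assert select_driver_genes(fits, mom, threshold=1.1).empty

    def test_direction_matches_gene_class(self, wt_fitted):
        wt, mom, fits = wt_fitted
        consensus = inferred_cell_time(fits)
        drivers = select_driver_genes(fits, mom, threshold=0.3, cell_time=consensus)
        classes = wt.gene_meta.set_index("gene_id")["gene_class"]
        nonsteady = [r for r in drivers.itertuples()
                     if classes[r.gene_id] != "steady"]
        match = [classes[r.gene_id] == r.direction for r in nonsteady]
        assert len(nonsteady) >= 0.9 * (classes != "steady").sum()
        assert np.mean(match) >= 0.9


class TestVelocity:
    def test_zero_on_steady_state_line(self):
        mom = Moments(
            Ms=np.array([[2.0], [4.0]]),
            Mu=np.array([[1.0], [2.0]]),  # Mu = (gamma/beta) Ms with ratio .5
            knn_indices=np.array([[0], [1]]),
            n_neighbors=1, n_pcs=1, gene_ids=["g"],
        )
        from pachydyn.kinetics import GeneFit

        fit = GeneFit("g", alpha=1.0, beta=1.0, gamma=0.5, valid=True)
        v = compute_velocity([fit], mom)
        np.testing.assert_allclose(v.velocity, 0.0, atol=1e-12)

    def test_sign_convention(self):
        mom = Moments(
            Ms=np.array([[2.0], [2.0]]),
            Mu=np.array([[2.0], [0.5]]),  # above / below the steady line
            knn_indices=np.array([[0], [1]]),
            n_neighbors=1, n_pcs=1, gene_ids=["g"],
        )
        from pachydyn.kinetics import GeneFit

        fit = GeneFit("g", alpha=1.0, beta=1.0, gamma=0.5, valid=True)
        v = compute_velocity([fit], mom).velocity
        assert v[0, 0] > 0 > v[1, 0]

    def test_repression_phase_velocity_negative(self):
        rng = np.random.default_rng(6)
        gene = KineticGene("g", 3.0, 1.0, 0.5, 0.2, "repression")
        t = np.sort(rng.uniform(0.3, 1.0, 100))  # decay phase only
        u, s = kinetics_expected(gene, t)
        fit = fit_gene_kinetics(u, s, gene_id="g")
        mom = Moments(Ms=s[:, None], Mu=u[:, None],
                      knn_indices=np.arange(100)[:, None],
                      n_neighbors=1, n_pcs=1, gene_ids=["g"])
        v = compute_velocity([fit], mom).velocity
        assert np.median(v) < 0


class TestVelocityGraph:
    def _chain_moments(self):
        # 3 cells on a line in expression space
        Ms = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        Mu = np.ones_like(Ms)
        knn = np.array([[0, 1], [1, 0], [2, 1]])
        return Moments(Ms=Ms, Mu=Mu, knn_indices=knn,
                       n_neighbors=2, n_pcs=2, gene_ids=["a", "b"])

    def test_rows_stochastic(self, noisy_pair):
        wt = noisy_pair.sample("WT")
        mom = compute_moments(wt, n_neighbors=10)
        fits = fit_all_genes(mom)
        T = velocity_graph(mom, compute_velocity(fits, mom))
        np.testing.assert_allclose(T.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert (T.matrix >= 0).all()

    def test_aligned_neighbor_preferred(self):
        mom = self._chain_moments()
        mom.knn_indices = np.array([[1, 0, 2]] * 3)  # cell 1 sees 0 and 2
        vel = VelocityField(velocity=np.array([[1.0, 0.0]] * 3), gene_ids=["a", "b"])
        T = velocity_graph(mom, vel)
        assert T.matrix[1, 2] > T.matrix[1, 0]

    def test_forward_chain_transition_mass(self):
        # every cell sees the whole chain; velocity points forward
        mom = self._chain_moments()
        mom.knn_indices = np.array([[0, 1, 2], [1, 0, 2], [2, 1, 0]])
        vel = VelocityField(velocity=np.array([[1.0, 0.0]] * 3), gene_ids=["a", "b"])
        T = velocity_graph(mom, vel).matrix
        assert T[0, 1] + T[0, 2] > T[0, 0]  # all mass forward at the start
        assert T[1, 2] > T[1, 0]  # interior cell prefers the forward hop

    def test_zero_velocity_uniform(self):
        mom = self._chain_moments()
        mom.knn_indices = np.array([[0, 1, 2]] * 3)
        vel = VelocityField(velocity=np.zeros((3, 2)), gene_ids=["a", "b"])
        T = velocity_graph(mom, vel)
        np.testing.assert_allclose(T.matrix[0], 1 / 3)

    def test_dead_end_cell_holds_mass(self):
        # interior cell with an aligned neighbor passes mass on; the chain
        # end, whose velocity points into empty space, keeps most of its own
        mom = self._chain_moments()
        mom.knn_indices = np.array([[0, 1, 2], [1, 0, 2], [2, 1, 0]])
        vel = VelocityField(velocity=np.array([[1.0, 0.0]] * 3), gene_ids=["a", "b"])
        T = velocity_graph(mom, vel).matrix
        assert T[1, 1] < 0.01  # aligned forward neighbor dominates
        assert T[2, 2] > 0.9  # no forward neighbor: quasi-absorbing


class TestTerminalStates:
    def test_absorbing_state_takes_all_mass(self):
        T = TransitionMatrix(
            matrix=np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, 1.0]]),
            kernel_scale=0.1,
        )
        res = terminal_states(T, np.array(["a", "b", "c"], dtype=object))
        assert res.cell_probability[2] == pytest.approx(1.0, abs=1e-8)
        assert res.cluster_score.idxmax() == "c"

    def test_doubly_stochastic_uniform(self):
        M = np.full((4, 4), 0.25)
        res = terminal_states(
            TransitionMatrix(matrix=M, kernel_scale=0.1),
            np.array(["a", "a", "b", "b"], dtype=object),
        )
        np.testing.assert_allclose(res.cell_probability, 0.25, atol=1e-9)

    def test_probabilities_sum_to_one(self, noisy_pair):
        wt = noisy_pair.sample("WT")
        mom = compute_moments(wt, n_neighbors=10)
        fits = fit_all_genes(mom)
        T = velocity_graph(mom, compute_velocity(fits, mom))
        res = terminal_states(T, wt.cell_meta["cluster"].to_numpy())
        assert res.cell_probability.sum() == pytest.approx(1.0, abs=1e-6)
        assert (res.cell_probability >= 0).all()


class TestClusterGraph:
    def test_separated_blobs_zero_connectivity(self):
        # two blobs whose kNN sets never cross
        knn = np.vstack([
            np.tile([0, 1, 2], (3, 1)),
            np.tile([3, 4, 5], (3, 1)),
        ])
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        cg = cluster_graph(knn, labels)
        assert cg.connectivity.loc["a", "b"] == 0.0
        assert cg.connectivity.loc["a", "a"] == 0.0

    def test_arbitrary_split_high_connectivity(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))
        from sklearn.neighbors import NearestNeighbors

        _, knn = NearestNeighbors(n_neighbors=6).fit(X).kneighbors(X)
        labels = np.array(["a"] * 20 + ["b"] * 20, dtype=object)[rng.permutation(40)]
        cg = cluster_graph(knn, labels)
        # expected-count oracle: obs/exp ~ 1 for a random split of one blob
        assert cg.connectivity.loc["a", "b"] > 0.5

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            cluster_graph(np.array([[0, 1], [1, 0]]), np.array(["a", "a"], dtype=object))

    def test_flux_antisymmetric(self):
        M = np.array([[0.0, 0.8, 0.2], [0.1, 0.0, 0.9], [0.3, 0.7, 0.0]])
        T = TransitionMatrix(matrix=M, kernel_scale=0.1)
        knn = np.array([[0, 1, 2]] * 3)
        labels = np.array(["a", "b", "c"], dtype=object)
        cg = cluster_graph(knn, labels, T)
        F = cg.flux.to_numpy()
        np.testing.assert_allclose(F, -F.T, atol=1e-12)


class TestInferredCellTime:
    def test_single_gene_equals_rescaled_latent_time(self):
        rng = np.random.default_rng(9)
        gene = KineticGene("g", 2.0, 1.0, 0.5, 0.4, "repression")
        t = np.sort(rng.uniform(0, 1, 100))
        u, s = kinetics_expected(gene, t)
        fit = fit_gene_kinetics(u, s, gene_id="g")
        ct = inferred_cell_time([fit], min_genes=1)
        np.testing.assert_allclose(ct, fit.latent_time / fit.latent_time.max())

    def test_gene_order_irrelevant(self, noiseless_pair):
        wt = noiseless_pair.sample("WT")
        fits = [
            fit_gene_kinetics(wt.unspliced[:, j], wt.spliced[:, j], gene_id=g)
            for j, g in enumerate(wt.gene_meta["gene_id"][:12])
        ]
        a = inferred_cell_time(fits, min_genes=3)
        b = inferred_cell_time(fits[::-1], min_genes=3)
        np.testing.assert_array_equal(a, b)

    def test_too_few_genes_errors_with_cutoff(self):
        rng = np.random.default_rng(10)
        gene = KineticGene("g", 2.0, 1.0, 0.5, 0.4, "repression")
        t = np.sort(rng.uniform(0, 1, 60))
        u, s = kinetics_expected(gene, t)
        fit = fit_gene_kinetics(u, s, gene_id="g")
        with pytest.raises(ValueError, match="cutoff"):
            inferred_cell_time([fit], min_genes=10)
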
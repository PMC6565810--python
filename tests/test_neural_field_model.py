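"""Mode-superposition simulation and the two-moment grid fit."""

import numpy as np
import pytest

from neomode import connectivity as conn
from neomode import neural_field_model as nfm

FS = 100.0


class TestSimulation:
    def test_pure_noise_field_is_uncorrelated(self, basis):
        p = nfm.ModelParams(a=(0, 0, 0, 0), sigma=1.0, duration=30.0, seed=0)
        field = nfm.simulate_field(p, basis)
        sub = field.activity[::50]          # subset of vertices
        C = np.corrcoef(sub)
        off = np.abs(C[np.triu_indices(len(sub), 1)])
        assert off.mean() < 0.02

    def test_noiseless_spectrum_is_a_beat(self, basis):
        # amplitude-modulated carrier = two pure lines at omega -/+ nu
        p = nfm.ModelParams(a=(0.5, 0, 0, 0), sigma=0.0, duration=60.0)
        field = nfm.simulate_field(p, basis)
        y = field.activity[0]
        spec = np.abs(np.fft.rfft(y)) / len(y)
        freqs = np.fft.rfftfreq(len(y), 1 / FS)
        lines = spec > 1e-6
        assert set(np.round(freqs[lines], 6)) == {9.9, 10.1}

    def test_noiseless_field_is_rank_one_in_space(self, basis):
        p = nfm.ModelParams(a=(0.4, 0, 0, 0), sigma=0.0, duration=5.0)
        Y = nfm.simulate_field(p, basis).activity
        # every vertex signal is a scalar multiple of the first one
        ref = Y[0]
        ratios = Y @ ref / (ref @ ref)
        assert np.allclose(Y, np.outer(ratios, ref), atol=1e-12)

    def test_carrier_aliasing_rejected(self):
        with pytest.raises(ValueError):
            nfm.ModelParams(a=(0.1, 0, 0, 0), fs=15.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            nfm.ModelParams(a=(-0.1, 0, 0, 0))

    def test_parcel_shortcut_matches_field_projection_statistics(
            self, basis, parcellation, parcel_modes):
        # deterministic part of the parcel-level shortcut equals the
        # projected vertex-level field exactly
        from neomode.eigenmodes import parcel_weight_matrix
        p = nfm.ModelParams(a=(0.3, 0, 0.1, 0.05), sigma=0.0, duration=5.0)
        field = nfm.simulate_field(p, basis)
        W = parcel_weight_matrix(parcellation, basis.vertex_areas)
        projected = np.asarray(W @ field.activity)
        shortcut = nfm.simulate_parcel_timeseries(p, parcel_modes)
        assert np.allclose(projected, shortcut, atol=1e-9)

    def test_scale_invariance_of_connectivity(self, basis, parcellation):
        # (a, sigma) and (c a, c sigma) share connectivity exactly at a
        # shared noise seed
        p1 = nfm.ModelParams(a=(0.3, 0, 0.1, 0.05), sigma=1.0, duration=20.0)
        p2 = nfm.ModelParams(a=(0.9, 0, 0.3, 0.15), sigma=3.0, duration=20.0)
        C1 = nfm.model_connectivity(p1, basis, parcellation,
                                    rng=np.random.default_rng(1))
        C2 = nfm.model_connectivity(p2, basis, parcellation,
                                    rng=np.random.default_rng(1))
        assert np.allclose(C1.weights, C2.weights, atol=1e-9)


class TestModelConnectivity:
    def test_null_weights_give_weak_network(self, basis, parcellation):
        p = nfm.ModelParams(a=(0, 0, 0, 0), sigma=1.0, duration=300.0)
        C = nfm.model_connectivity(p, basis, parcellation, normalize=False,
                                   rng=np.random.default_rng(2))
        assert np.abs(C.edge_vector()).mean() < 0.02

    def test_mean_weight_increases_with_uniform_mode(self, basis,
                                                     parcellation):
        means = []
        for a1 in (0.05, 0.2, 0.4):
            p = nfm.ModelParams(a=(a1, 0, 0, 0), sigma=1.0, duration=60.0)
            C = nfm.model_connectivity(p, basis, parcellation,
                                       normalize=False,
                                       rng=np.random.default_rng(3))
            means.append(C.edge_vector().mean())
        assert means[0] < means[1] < means[2]

    def test_mode3_coupling_follows_its_magnitude_profile(self, basis,
                                                          parcellation,
                                                          parcel_modes):
        # amplitude coupling is polarity-blind; with only the third mode
        # active, edges between strongly expressing parcels (large |m3|)
        # outweigh edges between weakly expressing parcels
        p = nfm.ModelParams(a=(0, 0, 0.5, 0), sigma=1.0, duration=120.0)
        C = nfm.model_connectivity(p, basis, parcellation, normalize=False,
                                   rng=np.random.default_rng(4))
        m3 = np.abs(parcel_modes[:, 2])
        strong = np.argsort(m3)[-10:]
        weak = np.argsort(m3)[:10]
        w_strong = np.nanmean(C.weights[np.ix_(strong, strong)])
        w_weak = np.nanmean(C.weights[np.ix_(weak, weak)])
        assert w_strong > w_weak + 0.05


class TestResponseTable:
    @pytest.fixture(scope="class")
    def table(self):
        return nfm.build_pair_response_table(u_max=2.0, duration=30.0,
                                             n_u=9, n_reps=8, seed=0)

    def test_coupling_increases_with_snr(self, table):
        diag = np.diag(table.mean)
        assert diag[-1] > diag[4] > diag[0]
        assert diag[-1] > 0.3

    def test_surface_is_symmetric(self, table):
        assert np.allclose(table.mean, table.mean.T, atol=1e-12)

    def test_interpolation_matches_nodes(self, table):
        u = table.u_grid
        m, s = table(u[3], u[5])
        assert m == pytest.approx(table.mean[3, 5], abs=1e-12)
        assert s == pytest.approx(table.sd[3, 5], abs=1e-12)

    def test_evaluator_agrees_with_direct_simulation(
            self, response_table_300, basis, parcellation, parcel_modes):
        """Dual route: F-table expectation vs per-node simulated moments."""
        ev = nfm.ModelMomentEvaluator(response_table_300, parcel_modes,
                                      np.ones(58))
        A = np.array([[0.3, 0.1, 0.05]])
        mu_t, s_t = ev.moments(A)
        mus, ss = [], []
        for seed in range(4):
            p = nfm.ModelParams(a=(0.3, 0, 0.1, 0.05), sigma=1.0,
                                duration=300.0)
            C = nfm.model_connectivity(p, basis, parcellation,
                                       rng=np.random.default_rng(50 + seed))
            summ = nfm.connectivity_moments(C)
            mus.append(summ.mu)
            ss.append(summ.s)
        assert mu_t[0] == pytest.approx(np.mean(mus), rel=0.15)
        assert s_t[0] == pytest.approx(np.mean(ss), rel=0.15)


class TestFitGrid:
    def test_surface_smooth_and_null_at_origin(self, fit_grid):
        # expectation-based summaries vary smoothly between adjacent coarse
        # nodes, and the all-zero-weight node is indistinguishable from the
        # null coupling floor
        for arr in (fit_grid.mu, fit_grid.s):
            step = np.abs(np.diff(arr, axis=0)).max()
            assert step < 0.15 * (arr.max() - arr.min())
        null_mu = fit_grid.mu[0, 0, 0]
        assert abs(null_mu) < 0.1 * np.abs(fit_grid.mu).max()

    def test_single_node_grid_matches_evaluator(self, fit_grid):
        ev = fit_grid.evaluator
        from neomode.neural_field_model import precompute_fit_grid
        axes = (np.array([0.3]), np.array([0.1]), np.array([0.05]))
        g1 = precompute_fit_grid(ev, axes)
        mu, s = ev.moments(np.array([[0.3, 0.1, 0.05]]))
        assert g1.mu.ravel()[0] == mu[0] and g1.s.ravel()[0] == s[0]

    def test_empty_grid_rejected(self, fit_grid):
        from neomode.neural_field_model import precompute_fit_grid
        with pytest.raises(ValueError):
            precompute_fit_grid(fit_grid.evaluator,
                                (np.array([]), np.array([0.1]),
                                 np.array([0.1])))

    def test_hdf5_export(self, fit_grid, tmp_path):
        import h5py
        path = str(tmp_path / "grid.h5")
        fit_grid.save(path)
        with h5py.File(path) as fh:
            assert fh["mu"].shape == fit_grid.mu.shape


class TestFit:
    def test_exact_match_of_node_moments_reaches_zero_cost(self, fit_grid):
        # a data summary equal to a node's tabulated moments drives J to
        # zero; the minimizer reproduces those moments exactly (distinct
        # weight triples can share moments, so the *moments*, not the
        # node coordinates, are the recoverable quantity)
        idx = (10, 3, 2)
        mu_t, s_t = fit_grid.mu[idx], fit_grid.s[idx]
        # three-edge matrix with exactly that mean and (population) SD
        c = s_t * np.sqrt(1.5)
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = mu_t + c
        w[0, 2] = w[2, 0] = mu_t - c
        w[1, 2] = w[2, 1] = mu_t
        fit = nfm.fit_subject(conn.ConnectivityMatrix(w), fit_grid,
                              refine=False)
        assert fit.cost == pytest.approx(0.0, abs=1e-16)
        k = tuple(int(np.flatnonzero(np.isclose(ax, v))[0])
                  for ax, v in zip(fit_grid.axes, fit.a_prime))
        assert fit_grid.mu[k] == pytest.approx(mu_t, abs=1e-10)
        assert fit_grid.s[k] == pytest.approx(s_t, abs=1e-10)

    def test_ties_break_lexicographically(self, response_table_300,
                                          parcel_modes):
        ev = nfm.ModelMomentEvaluator(response_table_300, parcel_modes,
                                      np.ones(58))
        axes = (np.array([0.1, 0.2]), np.array([0.0]), np.array([0.0]))
        grid = nfm.precompute_fit_grid(ev, axes)
        grid.mu[:] = 0.5
        grid.s[:] = 0.1                     # all nodes tie exactly
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.6
        w[0, 2] = w[2, 0] = 0.4
        w[1, 2] = w[2, 1] = 0.5
        fit = nfm.fit_subject(conn.ConnectivityMatrix(w), grid, refine=False)
        assert fit.a_prime == (0.1, 0.0, 0.0)
        assert fit.boundary                 # a'_3 = a'_4 = 0 sit on the edge

    def test_recovery_of_planted_subject(self, basis, parcellation, fit_grid):
        true = (0.30, 0.10, 0.05)
        hits = 0
        for rep in range(5):
            p = nfm.ModelParams(a=(true[0], 0, true[1], true[2]), sigma=1.0,
                                duration=300.0)
            C = nfm.model_connectivity(p, basis, parcellation,
                                       rng=np.random.default_rng(80 + rep))
            fit = nfm.fit_subject(C, fit_grid)
            err = np.abs(np.array(fit.a_prime) - true)
            hits += err[0] <= 0.05
            assert not fit.boundary
        assert hits >= 4                    # uniform-mode weight recovered

    def test_rank_correlation_between_true_and_fitted_a1(
            self, basis, parcellation, fit_grid):
        from scipy.stats import spearmanr
        trues, fits = [], []
        k = 0
        for a1 in (0.15, 0.25, 0.35):
            for a3 in (0.03, 0.06, 0.09):
                p = nfm.ModelParams(a=(a1, 0, a3, 0.04), sigma=1.0,
                                    duration=300.0)
                C = nfm.model_connectivity(p, basis, parcellation,
                                           rng=np.random.default_rng(200 + k))
                fits.append(nfm.fit_subject(C, fit_grid).a_prime[0])
                trues.append(a1)
                k += 1
        rho = spearmanr(trues, fits).statistic
        assert rho >= 0.8


class TestSigma:
    def test_fixed_point_at_matching_scale(self, parcel_modes):
        p = nfm.ModelParams(a=(0.3, 0, 0.1, 0.05), sigma=1.0, duration=60.0)
        ts = nfm.simulate_parcel_timeseries(p, parcel_modes,
                                            rng=np.random.default_rng(0))
        fit = nfm.FitResult((0.3, 0.1, 0.05), 0.0, 0.0, 0.0)
        out = nfm.estimate_sigma(fit, ts, parcel_modes, params=p)
        assert out.sigma == pytest.approx(1.0, rel=0.03)
        assert out.a == pytest.approx(tuple(out.sigma * np.array(fit.a_prime)))

    def test_doubling_the_data_doubles_sigma_and_weights(self, parcel_modes):
        p = nfm.ModelParams(a=(0.3, 0, 0.1, 0.05), sigma=1.0, duration=30.0)
        ts = nfm.simulate_parcel_timeseries(p, parcel_modes,
                                            rng=np.random.default_rng(1))
        fit = nfm.FitResult((0.3, 0.1, 0.05), 0.0, 0.0, 0.0)
        out1 = nfm.estimate_sigma(fit, ts, parcel_modes, params=p)
        out2 = nfm.estimate_sigma(fit, 2.0 * ts, parcel_modes, params=p)
        assert out2.sigma == pytest.approx(2.0 * out1.sigma, rel=1e-12)
        assert np.allclose(out2.a, 2.0 * np.asarray(out1.a))

    def test_known_noise_scale_recovered(self, parcel_modes):
        errs = []
        for rep in range(10):
            p = nfm.ModelParams(a=(0.75, 0, 0.25, 0.125), sigma=2.5,
                                duration=60.0)
            ts = nfm.simulate_parcel_timeseries(
                p, parcel_modes, rng=np.random.default_rng(300 + rep))
            fit = nfm.FitResult((0.3, 0.1, 0.05), 0.0, 0.0, 0.0)
            out = nfm.estimate_sigma(fit, ts, parcel_modes, params=p)
            errs.append(abs(out.sigma - 2.5) / 2.5)
        assert np.mean(errs) < 0.10

    def test_zero_variance_input_rejected(self, parcel_modes):
        fit = nfm.FitResult((0.3, 0.1, 0.05), 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            nfm.estimate_sigma(fit, np.zeros((58, 100)), parcel_modes)
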
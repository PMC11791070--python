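import numpy as np
import pytest
from scipy import integrate

from signalcap import (
    ConfigurationError,
    FeatureSpec,
    SimConfig,
    bootstrap_diagnostics,
    build_response_matrix,
    channel_capacity,
    fit_decoder,
    mutual_information,
    simulate_trajectories,
)

from conftest import make_trajectory_set, three_class_trajectories


def gaussian_binary_samples(n, mu0=0.0, mu1=1.0, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    z = np.concatenate(
        [rng.normal(mu0, sd, n // 2), rng.normal(mu1, sd, n // 2)]
    )[:, None]
    s = np.array(["s0"] * (n // 2) + ["s1"] * (n // 2))
    return z, s


def exact_binary_gaussian_mi(mu0=0.0, mu1=1.0, sd=1.0):
    """1-D quadrature of I(Z;S) for a two-Gaussian channel, uniform input."""

    def pdf(x, m):
        return np.exp(-((x - m) ** 2) / (2 * sd**2)) / (sd * np.sqrt(2 * np.pi))

    def integrand(x):
        p0, p1 = pdf(x, mu0), pdf(x, mu1)
        pz = 0.5 * (p0 + p1)
        total = 0.0
        for ps in (p0, p1):
            if ps > 0:
                total += 0.5 * ps * np.log2(ps / pz)
        return total

    lo = min(mu0, mu1) - 10 * sd
    hi = max(mu0, mu1) + 10 * sd
    value, _ = integrate.quad(integrand, lo, hi, limit=200)
    return value


class TestResponseMatrix:
    def test_trajectory_mode_shape(self):
        ts = simulate_trajectories(SimConfig(n_cells=60, seed=1))
        Z, S = build_response_matrix(ts)
        assert Z.shape == (60, 52)
        assert S.shape == (60,)

    def test_snapshot_mode_single_column(self):
        ts = simulate_trajectories(SimConfig(n_cells=60, seed=1))
        Z, _ = build_response_matrix(ts, FeatureSpec(mode="snapshot", time=10.0))
        assert Z.shape == (60, 1)

    def test_cell_with_missing_value_dropped(self, caplog):
        ts = simulate_trajectories(SimConfig(n_cells=60, seed=1))
        ts.values[7, 30] = np.nan
        with caplog.at_level("WARNING"):
            Z, S = build_response_matrix(ts)
        assert Z.shape == (59, 52)
        assert "dropped 1/60" in caplog.text

    def test_label_by_selects_metadata_columns(self):
        ts = simulate_trajectories(SimConfig(n_cells=20, seed=1))
        _, S = build_response_matrix(ts, label_by=("genotype",))
        assert set(S) == {"WT"}


class TestDecoder:
    def test_indistinguishable_inputs_give_uniform_posterior(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(0, 1, size=(400, 3))
        S = np.array(["a", "b"] * 200)
        dec = fit_decoder(Z, S, seed=0)
        probs = dec.predict_proba(Z)
        assert np.abs(probs - 0.5).mean() < 0.1

    def test_separable_classes_learned_confidently(self):
        ts = three_class_trajectories(n_cells=50, seed=1)
        Z, S = build_response_matrix(ts)
        dec = fit_decoder(Z, S, seed=0)
        correct = dec.predict_proba(Z)[np.arange(len(S)), np.searchsorted(dec.classes, S)]
        assert correct.mean() > 0.99

    def test_refit_reproduces_coefficients(self):
        Z, S = gaussian_binary_samples(200, seed=3)
        a = fit_decoder(Z, S, seed=5)
        b = fit_decoder(Z, S, seed=5)
        np.testing.assert_array_equal(a.model.coef_, b.model.coef_)

    def test_degenerate_class_named_in_error(self):
        Z = np.random.default_rng(0).normal(size=(25, 2))
        S = np.array(["big"] * 20 + ["tiny"] * 5)
        with pytest.raises(ConfigurationError, match="tiny"):
            fit_decoder(Z, S)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_decoder(np.ones((30, 2)), np.array(["a"] * 30))


class TestMutualInformation:
    def test_identical_class_conditionals_give_zero(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(0, 1, size=(600, 2))
        S = np.array(["a", "b", "c"] * 200)
        dec = fit_decoder(Z, S, seed=0)
        est = mutual_information(dec, Z, S, seed=0)
        assert est.bits == pytest.approx(0.0, abs=0.05)

    def test_deterministic_binary_channel_reaches_one_bit(self):
        Z, S = gaussian_binary_samples(400, mu1=20.0, sd=0.1, seed=2)
        dec = fit_decoder(Z, S, seed=0)
        est = mutual_information(dec, Z, S, seed=0)
        assert est.bits == pytest.approx(1.0, abs=0.02)
        assert est.h_s == pytest.approx(1.0)

    def test_matches_quadrature_oracle_on_gaussian_channel(self):
        Z, S = gaussian_binary_samples(5000, seed=4)
        dec = fit_decoder(Z, S, seed=0)
        est = mutual_information(dec, Z, S, seed=0)
        assert est.bits == pytest.approx(exact_binary_gaussian_mi(), abs=0.03)

    def test_matches_plugin_oracle_on_discrete_support(self):
        # monotone-likelihood-ratio channel on 4 support points
        p_z_given_a = np.array([0.4, 0.3, 0.2, 0.1])
        p_z_given_b = np.array([0.1, 0.2, 0.3, 0.4])
        rng = np.random.default_rng(6)
        n = 5000
        za = rng.choice(4, size=n // 2, p=p_z_given_a)
        zb = rng.choice(4, size=n // 2, p=p_z_given_b)
        Z = np.concatenate([za, zb]).astype(float)[:, None]
        S = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        # exact plug-in MI from the empirical joint table
        joint = np.zeros((2, 4))
        for k, zs in enumerate((za, zb)):
            counts = np.bincount(zs, minlength=4)
            joint[k] = 0.5 * counts / counts.sum()
        pz = joint.sum(axis=0)
        ps = joint.sum(axis=1)
        mask = joint > 0
        plugin = float(
            (joint[mask] * np.log2(joint[mask] / np.outer(ps, pz)[mask])).sum()
        )
        dec = fit_decoder(Z, S, seed=0)
        est = mutual_information(dec, Z, S, seed=0)
        assert est.bits == pytest.approx(plugin, abs=0.05)

    def test_bounded_by_input_entropy(self):
        ts = three_class_trajectories(n_cells=60, noise_sd=0.3, seed=2)
        Z, S = build_response_matrix(ts)
        dec = fit_decoder(Z, S, regularization=1.0, seed=0)
        est = mutual_information(dec, Z, S, seed=0)
        assert -0.02 <= est.bits <= np.log2(3) + 0.02

    def test_zero_weight_on_observed_class_rejected(self):
        Z, S = gaussian_binary_samples(100, seed=7)
        dec = fit_decoder(Z, S, seed=0)
        with pytest.raises(ConfigurationError):
            mutual_information(dec, Z, S, p_s=np.array([1.0, 0.0]))

    def test_in_sample_mode_available(self):
        Z, S = gaussian_binary_samples(300, seed=8)
        dec = fit_decoder(Z, S, seed=0)
        est = mutual_information(dec, Z, S, cv=0, seed=0)
        assert 0 <= est.bits <= 1.0


class TestChannelCapacity:
    def test_three_separable_inputs_reach_log2_three(self):
        ts = three_class_trajectories(n_cells=150, seed=3)
        Z, S = build_response_matrix(ts)
        dec = fit_decoder(Z, S, seed=0)
        est = channel_capacity(dec, Z, S, seed=0)
        assert est.bits == pytest.approx(np.log2(3), abs=0.03)
        np.testing.assert_allclose(est.optimal_p, 1 / 3, atol=0.05)

    def test_two_clone_inputs_merge_to_one_bit(self):
        # classes a and b share a response distribution; c is separated
        rng = np.random.default_rng(9)
        n = 300
        Z = np.concatenate(
            [rng.normal(0, 0.05, n), rng.normal(0, 0.05, n), rng.normal(5, 0.05, n)]
        )[:, None]
        S = np.array(["a"] * n + ["b"] * n + ["c"] * n)
        dec = fit_decoder(Z, S, seed=0)
        est = channel_capacity(dec, Z, S, seed=0)
        # brute-force oracle: plug-in MI on a grid over the 3-simplex with the
        # (effectively deterministic) two-state channel a,b -> z0, c -> z1
        best = 0.0
        grid = np.linspace(0, 1, 101)
        for pa in grid:
            for pb in grid[grid <= 1 - pa + 1e-12]:
                pc = 1 - pa - pb
                p_low = pa + pb  # mass on the shared response state
                h = 0.0
                for p in (p_low, pc):
                    if p > 0:
                        h -= p * np.log2(p)
                best = max(best, h)
        assert best == pytest.approx(1.0, abs=1e-6)
        assert est.bits == pytest.approx(best, abs=0.05)
        # the optimum splits mass evenly between the merged clones and c
        assert est.optimal_p[2] == pytest.approx(0.5, abs=0.05)

    def test_single_input_level_carries_no_information(self):
        Z = np.random.default_rng(0).normal(size=(50, 2))
        S = np.array(["only"] * 50)
        est = channel_capacity(None, Z, S)
        assert est.bits == 0.0

    def test_capacity_at_least_uniform_mi(self):
        ts = three_class_trajectories(
            amplitudes=(0.3, 0.5, 0.6), n_cells=80, noise_sd=0.15,
            heterogeneity_cv=0.2, seed=4,
        )
        Z, S = build_response_matrix(ts)
        dec = fit_decoder(Z, S, regularization=1.0, seed=0)
        mi = mutual_information(dec, Z, S, seed=0)
        cap = channel_capacity(dec, Z, S, seed=0)
        assert cap.bits >= mi.bits - 1e-6

    def test_noise_degrades_median_mi_monotonically(self):
        rng = np.random.default_rng(10)
        base_z, S = gaussian_binary_samples(400, mu1=2.0, sd=0.3, seed=11)
        medians = []
        for extra_sd in (0.0, 1.0, 4.0):
            Z = base_z + rng.normal(0, extra_sd, size=base_z.shape)
            est = bootstrap_diagnostics(
                Z, S, estimator="mi", n_boot=10, seed=12, regularization=1.0
            )
            medians.append((est.boot_median, est.boot_iqr))
        # non-increasing within the bootstrap IQR
        for (m_hi, iqr_hi), (m_lo, _) in zip(medians, medians[1:]):
            assert m_lo <= m_hi + (iqr_hi[1] - iqr_hi[0])
        assert medians[-1][0] < medians[0][0]


class TestBootstrapDiagnostics:
    def test_separable_data_has_tight_replicates(self):
        ts = three_class_trajectories(n_cells=60, seed=5)
        Z, S = build_response_matrix(ts)
        est = bootstrap_diagnostics(
            Z, S, estimator="capacity", n_boot=8, seed=0, regularization=100.0
        )
        q1, q3 = est.boot_iqr
        assert q3 - q1 < 0.05
        assert est.boot_median == pytest.approx(est.bits, abs=0.05)
        assert q1 <= est.boot_median <= q3

    def test_seed_reproducibility(self):
        Z, S = gaussian_binary_samples(200, mu1=3.0, seed=13)
        a = bootstrap_diagnostics(Z, S, "mi", n_boot=6, seed=3, regularization=1.0)
        b = bootstrap_diagnostics(Z, S, "mi", n_boot=6, seed=3, regularization=1.0)
        assert a.boot_median == b.boot_median and a.boot_iqr == b.boot_iqr

    def test_unknown_estimator_rejected(self):
        Z, S = gaussian_binary_samples(100, seed=14)
        with pytest.raises(ConfigurationError):
            bootstrap_diagnostics(Z, S, estimator="banana")
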
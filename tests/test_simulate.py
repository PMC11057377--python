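"""Synthetic generator: stability, distributional checks, ground-truth recovery."""

import numpy as np
import pytest

from dyadcausal import (
    TapGenConfig,
    VARSpec,
    make_dyad_spec,
    simulate_taps,
    simulate_var,
)
from dyadcausal.exceptions import StabilityError

from conftest import ar1_spec, white_noise_spec


def lag1_autocorr(x):
    return np.corrcoef(x[:-1], x[1:])[0, 1]


class TestSimulateVar:
    def test_white_noise_has_no_lag1_autocorrelation(self):
        series = simulate_var(white_noise_spec(3), 5000, seed=0)
        for k in range(3):
            assert abs(lag1_autocorr(series.values[:, k])) < 0.05

    def test_ar1_lag1_autocorrelation_matches_theory(self):
        # analytic AR(1) autocorrelation rho(1) = phi = 0.9
        series = simulate_var(ar1_spec(0.9), 10_000, seed=1)
        assert lag1_autocorr(series.values[:, 0]) == pytest.approx(0.9, abs=0.03)

    def test_unit_root_spec_refused(self):
        spec = white_noise_spec(2)
        spec.coeffs[0] = np.eye(2)  # spectral radius exactly 1
        with pytest.raises(StabilityError):
            simulate_var(spec, 1000, seed=0)

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            simulate_var(white_noise_spec(2), -5, seed=0)
        with pytest.raises(ValueError):
            simulate_var(white_noise_spec(2), 1000, seed=0, burn_in=10)

    def test_seed_determinism_and_variation(self):
        spec = ar1_spec(0.5, n_vars=2)
        a = simulate_var(spec, 500, seed=7)
        b = simulate_var(spec, 500, seed=7)
        c = simulate_var(spec, 500, seed=8)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_long_run_means_are_zero(self, planted_dyad_spec):
        series = simulate_var(planted_dyad_spec, 50_000, seed=11)
        X = series.values
        # AR-adjusted standard error of the mean; all channel means within 4 SE
        phi = 0.4
        se = X.std(axis=0) * np.sqrt((1 + phi) / (1 - phi)) / np.sqrt(X.shape[0])
        assert (np.abs(X.mean(axis=0)) < 4 * se).all()

    def test_planted_coefficients_recoverable_by_ols(self, planted_dyad_spec, planted_dyad_series):
        """Planted couplings equal the partial regression coefficients on the true parents."""
        spec, X = planted_dyad_spec, planted_dyad_series.values
        L = spec.max_lag
        T = X.shape[0]
        for j in range(spec.n_vars):
            parents = [(l, i) for l in range(L) for i in range(spec.n_vars)
                       if spec.coeffs[l, j, i] != 0.0]
            y = X[L:]
            D = np.column_stack([np.ones(T - L)] + [X[L - l - 1 : T - l - 1, i] for l, i in parents])
            beta, *_ = np.linalg.lstsq(D, y[:, j], rcond=None)
            for (l, i), b in zip(parents, beta[1:]):
                assert b == pytest.approx(spec.coeffs[l, j, i], abs=0.05)


class TestDyadSpec:
    def test_no_links_gives_white_noise_spec(self):
        spec = make_dyad_spec(autocorr=0.0)
        assert spec.n_vars == 6
        assert np.all(spec.coeffs == 0.0)
        assert spec.labels == ["L_F3", "L_Fz", "L_F4", "F_F3", "F_Fz", "F_F4"]

    def test_single_inter_link_lands_in_right_cell(self):
        spec = make_dyad_spec(
            inter_links=[("leader", "Fz", "follower", "Fz", 2, 0.3)], autocorr=0.4
        )
        fz_l, fz_f = spec.labels.index("L_Fz"), spec.labels.index("F_Fz")
        assert spec.coeffs[1, fz_f, fz_l] == 0.3
        assert np.allclose(np.diag(spec.coeffs[0]), 0.4)
        mask = spec.coeffs.copy()
        mask[1, fz_f, fz_l] = 0.0
        mask[0][np.diag_indices(6)] = 0.0
        assert np.all(mask == 0.0)

    def test_near_unit_autocorr_with_couplings_is_unstable(self):
        # oracle: companion-matrix eigenvalues exceed 1 for this configuration
        with pytest.raises(StabilityError) as err:
            make_dyad_spec(
                inter_links=[
                    ("leader", "Fz", "follower", "Fz", 1, 0.5),
                    ("follower", "Fz", "leader", "Fz", 1, 0.5),
                ],
                autocorr=0.999,
            )
        assert err.value.spectral_radius >= 1.0

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            make_dyad_spec(intra_links=[("leader", "F3", "Fz", 9, 0.1)])
        with pytest.raises(ValueError):
            make_dyad_spec(intra_links=[("leader", "F99", "Fz", 1, 0.1)])
        with pytest.raises(ValueError):
            make_dyad_spec(inter_links=[("boss", "F3", "follower", "F3", 1, 0.1)])

    def test_yaml_round_trip(self, tmp_path, planted_dyad_spec):
        path = tmp_path / "spec.yaml"
        planted_dyad_spec.to_yaml(path)
        loaded = VARSpec.from_yaml(path)
        np.testing.assert_allclose(loaded.coeffs, planted_dyad_spec.coeffs)
        assert loaded.labels == planted_dyad_spec.labels


class TestSimulateTaps:
    def test_pure_delay_gives_constant_difference(self):
        cfg = TapGenConfig(reaction_delay=0.16, jitter_sd=0.0, seed=0)
        sim = simulate_taps(cfg)
        diffs = [sim.follower.times[fi] - sim.leader.times[li] for li, fi in sim.matches]
        np.testing.assert_allclose(diffs, 0.16)
        assert len(sim.matches) == len(sim.leader.times)

    def test_certain_double_taps_follow_every_genuine_tap(self):
        cfg = TapGenConfig(double_tap_prob=1.0, double_tap_gap=0.1, jitter_sd=0.0, seed=0)
        sim = simulate_taps(cfg)
        genuine = {fi for _, fi in sim.matches}
        ft = sim.follower.times
        for fi in genuine:
            assert fi + 1 < len(ft) and ft[fi + 1] == pytest.approx(ft[fi] + 0.1)
        assert sim.n_doubles_planted == len(genuine)

    def test_reproducible_under_seed(self):
        cfg = TapGenConfig(jitter_sd=0.03, double_tap_prob=0.2, outlier_prob=0.2, seed=42)
        a, b = simulate_taps(cfg), simulate_taps(cfg)
        np.testing.assert_array_equal(a.follower.times, b.follower.times)
        assert a.matches == b.matches

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TapGenConfig(double_tap_gap=0.3)
        with pytest.raises(ValueError):
            TapGenConfig(outlier_gap=1.0)
        with pytest.raises(ValueError):
            TapGenConfig(rhythm=(0.0, 7.0), cycle_len=6.0)
        with pytest.raises(ValueError):
            TapGenConfig(double_tap_prob=1.5)
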
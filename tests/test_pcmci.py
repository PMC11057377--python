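"""PC condition selection, MCI testing, FDR correction, and graph invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from dyadcausal import (
    PCMCI,
    PCMCIConfig,
    VARSpec,
    bh_fdr,
    make_dyad_spec,
    mci_link_test,
    parcorr_test,
    pc_select,
    run_pcmci,
    select_alpha_by_aic,
    simulate_var,
)
from dyadcausal.pcmci import ParentSet, _aic_of_parents, _standardize_system

from conftest import ar1_spec, white_noise_spec


def planted_link_spec(coeff=0.5, lag=2, autocorr=0.4, n_vars=3):
    """X0 -> X1 at the given lag, everything else only autocorrelated."""
    coeffs = np.zeros((lag, n_vars, n_vars))
    coeffs[0][np.diag_indices(n_vars)] = autocorr
    coeffs[lag - 1, 1, 0] = coeff
    return VARSpec(coeffs=coeffs, noise_sd=np.ones(n_vars))


class TestBHFDR:
    def test_textbook_vector(self):
        # direct step-up: p*(m/rank) then suffix minimum -> all 0.04
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.05] * 7), [0.05] * 7)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=100, derandomize=True)
    def test_matches_statsmodels(self, ps, _seed):
        q = bh_fdr(ps)
        expected = multipletests(ps, method="fdr_bh")[1]
        np.testing.assert_allclose(q, expected, atol=1e-12)
        assert ((q >= 0) & (q <= 1)).all()


class TestPCSelect:
    def test_null_retention_matches_nominal_alpha(self):
        """Under the full null the PC screen retains spurious parents at its
        nominal rate: conditioning on unrelated variables barely moves an
        already-selected statistic, so retention stays near alpha times the 30
        candidates per target rather than shrinking further (downstream
        false-positive control is the MCI + FDR stage's job)."""
        counts = []
        for seed in range(20):
            series = simulate_var(white_noise_spec(6, max_lag=5), 2000, seed=seed)
            parents = pc_select(series, PCMCIConfig(tau_max=5, pc_alpha=0.05))
            counts.append(np.mean([len(p) for p in parents.parents.values()]))
        retention = np.mean(counts) / 30  # 6 vars x 5 lags candidates per target
        assert 0.03 <= retention <= 0.07

    def test_planted_link_and_autocorrelation_recovered(self):
        hits = 0
        for seed in range(20):
            series = simulate_var(planted_link_spec(), 2000, seed=seed)
            parents = pc_select(series, PCMCIConfig(tau_max=5, pc_alpha=0.05))
            if (0, 2) in parents.parents[1] and (1, 1) in parents.parents[1]:
                hits += 1
        assert hits >= 19

    def test_single_ar1_variable_keeps_only_self_lag(self):
        series = simulate_var(ar1_spec(0.8), 2000, seed=0)
        parents = pc_select(series, PCMCIConfig(tau_max=1, pc_alpha=0.05))
        assert parents.parents[0] == [(0, 1)]

    def test_parents_ordered_by_strength(self, planted_dyad_series):
        parents = pc_select(planted_dyad_series, PCMCIConfig(tau_max=5, pc_alpha=0.05))
        for j, pset in parents.parents.items():
            strengths = [abs(parents.stats[j][p]) for p in pset]
            assert strengths == sorted(strengths, reverse=True)


class TestAlphaSelection:
    def test_singleton_list_returned_as_is(self):
        series = simulate_var(white_noise_spec(3), 1500, seed=0)
        alpha, _ = select_alpha_by_aic(series, PCMCIConfig(tau_max=3, pc_alpha=[0.05]))
        assert alpha == 0.05

    def test_chosen_alpha_minimizes_summed_aic(self):
        grid = [0.01, 0.05, 0.2, 0.5]
        series = simulate_var(planted_link_spec(), 3000, seed=1)
        cfg = PCMCIConfig(tau_max=5, pc_alpha=grid)
        chosen, chosen_parents = select_alpha_by_aic(series, cfg)
        X = _standardize_system(series.values, series.labels)
        chosen_aic = _aic_of_parents(X, chosen_parents.parents, 5)
        for a in grid:
            other = pc_select(series, cfg, alpha=a)
            assert chosen_aic <= _aic_of_parents(X, other.parents, 5) + 1e-9

    def test_white_noise_prefers_the_stricter_alpha(self):
        wins = 0
        for seed in range(20):
            series = simulate_var(white_noise_spec(4, max_lag=3), 1200, seed=100 + seed)
            alpha, _ = select_alpha_by_aic(series, PCMCIConfig(tau_max=3, pc_alpha=[0.05, 0.5]))
            wins += alpha == 0.05
        assert wins > 10

    def test_empty_alpha_list_rejected(self):
        with pytest.raises(ValueError):
            PCMCIConfig(pc_alpha=[])


class TestMCI:
    def test_reduces_to_plain_lagged_test_without_parents(self):
        series = simulate_var(white_noise_spec(2), 2000, seed=3)
        empty = ParentSet(parents={0: [], 1: []}, stats={0: {}, 1: {}})
        cfg = PCMCIConfig(tau_max=5)
        res = mci_link_test(series, empty, (0, 2), 1, cfg)
        X = _standardize_system(series.values, series.labels)
        t0 = 2 * cfg.tau_max
        plain = parcorr_test(X[t0 - 2 : -2, 0], X[t0:, 1], n_eff=X.shape[0] - t0)
        assert res.stat == pytest.approx(plain.stat, abs=1e-12)
        assert res.pvalue == pytest.approx(plain.pvalue, abs=1e-12)

    def test_planted_link_mci_matches_large_sample_oracle(self):
        # oracle: empirical partial correlation of the link at T=100,000
        spec = planted_link_spec(coeff=0.3, lag=2)
        big = simulate_var(spec, 100_000, seed=4)
        cfg = PCMCIConfig(tau_max=5, pc_alpha=0.05)
        parents_big = pc_select(big, cfg)
        oracle = mci_link_test(big, parents_big, (0, 2), 1, cfg).stat

        series = simulate_var(spec, 4000, seed=5)
        parents = pc_select(series, cfg)
        res = mci_link_test(series, parents, (0, 2), 1, cfg)
        assert res.stat > 0
        assert abs(res.stat) == pytest.approx(abs(oracle), abs=0.1)


class TestRunPCMCI:
    def test_no_contemporaneous_or_excess_lags(self, planted_dyad_series):
        graph = run_pcmci(planted_dyad_series, tau_max=5, pc_alpha=0.05)
        lags = {l.lag for l in graph.links}
        assert lags == {1, 2, 3, 4, 5}
        assert len(graph.links) == 6 * 6 * 5

    def test_planted_dyad_links_significant(self, planted_dyad_spec, planted_dyad_series):
        graph = run_pcmci(planted_dyad_series, tau_max=5, pc_alpha=0.05)
        sig = {(l.source, l.lag, l.target) for l in graph.significant_links()}
        for src, lag, tgt, coeff in planted_dyad_spec.links():
            assert (src, lag, tgt) in sig

    def test_deterministic_given_data(self, planted_dyad_series):
        g1 = run_pcmci(planted_dyad_series, tau_max=5, pc_alpha=0.05)
        g2 = run_pcmci(planted_dyad_series, tau_max=5, pc_alpha=0.05)
        assert g1.to_frame().equals(g2.to_frame())

    def test_tightening_fdr_never_adds_links(self, planted_dyad_series):
        loose = run_pcmci(planted_dyad_series, tau_max=5, pc_alpha=0.05, fdr_alpha=0.05)
        strict = run_pcmci(planted_dyad_series, tau_max=5, pc_alpha=0.05, fdr_alpha=0.01)
        sig_loose = {(l.source, l.lag, l.target) for l in loose.significant_links()}
        sig_strict = {(l.source, l.lag, l.target) for l in strict.significant_links()}
        assert sig_strict <= sig_loose

    def test_variable_permutation_only_relabels(self):
        series = simulate_var(planted_link_spec(), 3000, seed=6)
        graph = run_pcmci(series, tau_max=3, pc_alpha=0.05)
        perm = [2, 0, 1]
        permuted = series.with_values(series.values[:, perm],
                                      labels=[series.labels[i] for i in perm])
        graph_p = run_pcmci(permuted, tau_max=3, pc_alpha=0.05)
        by_key = {(l.source, l.lag, l.target): l for l in graph.links}
        by_key_p = {(l.source, l.lag, l.target): l for l in graph_p.links}
        assert by_key.keys() == by_key_p.keys()
        for key, link in by_key.items():
            assert link.mci == pytest.approx(by_key_p[key].mci, abs=1e-8)
            assert link.significant == by_key_p[key].significant

    def test_mci_signs_match_planted_coefficients(self, planted_dyad_spec, planted_dyad_series):
        graph = run_pcmci(planted_dyad_series, tau_max=5, pc_alpha=0.05)
        by_key = {(l.source, l.lag, l.target): l for l in graph.links}
        for src, lag, tgt, coeff in planted_dyad_spec.links():
            assert np.sign(by_key[(src, lag, tgt)].mci) == np.sign(coeff)

    def test_nonstationary_input_warns_not_errors(self):
        series = simulate_var(white_noise_spec(2), 2000, seed=7)
        drift = series.values + np.linspace(0, 5, 2000)[:, None]
        with pytest.warns(UserWarning, match="nonstationary"):
            run_pcmci(series.with_values(drift), tau_max=2, pc_alpha=0.05)

    def test_estimator_protocol(self):
        est = PCMCI(tau_max=3, pc_alpha=0.05)
        assert est.get_params()["tau_max"] == 3
        est.set_params(fdr_alpha=0.01)
        series = simulate_var(white_noise_spec(2), 1500, seed=8)
        est.fit(series)
        assert est.links_.shape[0] == 2 * 2 * 3
        assert est.graph_.fdr_alpha == 0.01
        assert est.pc_alpha_ == 0.05
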
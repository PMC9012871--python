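import itertools

import numpy as np
import pytest

from shallowcn.hmm import (
    HMMConfig,
    N_STATES,
    STATES,
    _state_means,
    _t_logpdf,
    estimate_tumor_fraction,
    expected_log2,
    forward_backward_posteriors,
    run_hmm,
    viterbi_path,
)
from shallowcn.normalize import NormalizedProfile
from tests.conftest import make_flat_scheme


class TestExpectedLog2:
    def test_no_tumor_no_shift(self):
        for c in (0, 1, 2, 3):
            assert expected_log2(0.0, c) == 0.0

    def test_hand_values(self):
        assert expected_log2(0.5, 1, 2) == pytest.approx(np.log2(0.75))
        assert expected_log2(0.5, 1, 2) == pytest.approx(-0.415, abs=5e-4)
        assert expected_log2(0.2, 3, 2) == pytest.approx(np.log2(1.1))
        assert expected_log2(0.2, 3, 2) == pytest.approx(0.1375, abs=5e-4)

    def test_undefined_at_tf1_c0(self):
        with pytest.raises(ValueError):
            expected_log2(1.0, 0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            expected_log2(1.5, 2)
        with pytest.raises(ValueError):
            expected_log2(0.5, -1)


def _profile_from_values(x, scheme):
    return NormalizedProfile("s", np.asarray(x, dtype=float), np.ones(len(x), dtype=bool))


class TestForwardBackward:
    def test_posteriors_normalize(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.1, 300)
        cfg = HMMConfig()
        gamma, ll = forward_backward_posteriors(x, 0.2, 0.5, 0.06, cfg)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)
        assert np.isfinite(ll)

    def test_loglik_matches_direct_sum_on_tiny_chain(self):
        # brute-force marginal likelihood by summing over all state paths
        x = np.array([0.0, 0.3, 0.3])
        cfg = HMMConfig()
        tf, sp, sigma = 0.25, 0.5, 0.05
        gamma, ll = forward_backward_posteriors(x, tf, sp, sigma, cfg)
        means = _state_means(tf, sp)
        logB = _t_logpdf(x[:, None], means[None, :], sigma, cfg.emission_df)
        logB[:, [0, 1, 3, 4, 5]] -= cfg.alteration_penalty  # match the model
        logB[:, 4:] -= cfg.subclone_penalty
        p_self = cfg.self_transition
        p_off = (1 - p_self) / (N_STATES - 1)
        total = 0.0
        for path in itertools.product(range(N_STATES), repeat=3):
            lp = -np.log(N_STATES) + logB[0, path[0]]
            for t in (1, 2):
                lp += np.log(p_self if path[t] == path[t - 1] else p_off) + logB[t, path[t]]
            total += np.exp(lp)
        assert ll == pytest.approx(np.log(total), abs=1e-10)


class TestViterbi:
    def brute_force_path(self, x, tf, sp, sigma, cfg):
        means = _state_means(tf, sp)
        logB = _t_logpdf(x[:, None], means[None, :], sigma, cfg.emission_df)
        logB[:, [0, 1, 3, 4, 5]] -= cfg.alteration_penalty  # match the model
        logB[:, 4:] -= cfg.subclone_penalty
        p_self = cfg.self_transition
        p_off = (1 - p_self) / (N_STATES - 1)
        best_lp, best_path = -np.inf, None
        for path in itertools.product(range(N_STATES), repeat=len(x)):
            lp = -np.log(N_STATES) + logB[0, path[0]]
            for t in range(1, len(x)):
                lp += np.log(p_self if path[t] == path[t - 1] else p_off) + logB[t, path[t]]
            if lp > best_lp:
                best_lp, best_path = lp, path
        return np.array(best_path)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 7  # 6^7 = 280k paths: exhaustive oracle stays tractable
        tf = 0.3
        x = rng.normal(0, 0.08, n)
        x[3:5] += expected_log2(tf, 3)
        cfg = HMMConfig()
        path = viterbi_path(x, tf, 0.5, 0.08, cfg)
        oracle = self.brute_force_path(x, tf, 0.5, 0.08, cfg)
        np.testing.assert_array_equal(path, oracle)


class TestRunHMM:
    def test_noise_free_recovery(self):
        scheme = make_flat_scheme(n_bins_per_chrom=150, n_chrom=2)
        tf = 0.30
        x = np.zeros(300)
        x[30:80] = expected_log2(tf, 3)  # clonal gain
        x[200:240] = expected_log2(tf, 1)  # clonal loss
        prof = _profile_from_values(x, scheme)
        segset, est = run_hmm(prof, scheme, HMMConfig(), init_n=0.7)
        assert est.tumor_fraction == pytest.approx(0.30, abs=0.01)
        states = np.concatenate(
            [[s.copy_state] * s.n_bins for s in segset.segments]
        )
        expected = np.full(300, 2)
        expected[30:80] = 3
        expected[200:240] = 1
        np.testing.assert_array_equal(states, expected)

    def test_all_zero_profile(self):
        scheme = make_flat_scheme(n_bins_per_chrom=150, n_chrom=2)
        prof = _profile_from_values(np.zeros(300), scheme)
        segset, est = run_hmm(prof, scheme, HMMConfig(), init_n=0.7)
        assert est.tumor_fraction <= 0.01
        assert len(segset.segments) == 2  # one neutral segment per chromosome
        assert all(s.copy_state == 2 for s in segset.segments)
        assert est.fraction_genome_altered == 0.0

    def test_loglikelihood_nondecreasing(self, monkeypatch):
        """EM log-likelihood trace is non-decreasing every iteration."""
        import shallowcn.hmm as hmm_mod

        scheme = make_flat_scheme(n_bins_per_chrom=200, n_chrom=2)
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.06, 400)
        x[50:150] += expected_log2(0.2, 3)
        prof = _profile_from_values(x, scheme)

        lls = []
        orig = hmm_mod._forward_backward

        def spy(logB, self_p):
            g, ll = orig(logB, self_p)
            lls.append(ll)
            return g, ll

        monkeypatch.setattr(hmm_mod, "_forward_backward", spy)
        run_hmm(prof, scheme, HMMConfig(), init_n=0.8)
        # sum per-iteration chain logliks (2 chains per E-step)
        per_iter = [lls[i] + lls[i + 1] for i in range(0, len(lls) - 1, 2)]
        diffs = np.diff(per_iter)
        assert np.all(diffs >= -1e-6 * np.maximum(1.0, np.abs(per_iter[:-1])))

    def test_invalid_init(self):
        scheme = make_flat_scheme(n_bins_per_chrom=150, n_chrom=1)
        prof = _profile_from_values(np.zeros(150), scheme)
        with pytest.raises(ValueError):
            run_hmm(prof, scheme, HMMConfig(), init_n=1.5)


class TestEstimateTumorFraction:
    def test_default_grid(self):
        assert HMMConfig().normal_grid == (0.7, 0.8, 0.9, 0.95, 0.99)

    def test_tie_break_toward_lower_tf(self):
        # symmetric all-zero data: every init converges to the same solution,
        # and the reported tf is the lowest among the tied ones
        scheme = make_flat_scheme(n_bins_per_chrom=150, n_chrom=1)
        prof = _profile_from_values(np.zeros(150), scheme)
        _, est = estimate_tumor_fraction(prof, scheme, HMMConfig())
        lls = [t["log_likelihood"] for t in est.grid_trace]
        tied_tfs = [
            t["tumor_fraction"] for t in est.grid_trace if t["log_likelihood"] >= max(lls) - 1e-6
        ]
        assert est.tumor_fraction == pytest.approx(min(tied_tfs))
        assert len(est.grid_trace) == 5

    def test_parameter_recovery_with_noise(self, small_sim, small_panel):
        from shallowcn.normalize import normalize_profile
        from shallowcn.simulate import random_cna_truth, simulate_depth

        cfg, layout, _, _, scheme = small_sim
        controls, pon = small_panel
        rng = np.random.default_rng(77)
        truth = random_cna_truth(cfg, layout, rng)
        case = simulate_depth(cfg, scheme, 0.2, truth, rng, "case")
        norm = normalize_profile(case, pon, scheme)
        _, est = estimate_tumor_fraction(norm, scheme, HMMConfig())
        assert est.tumor_fraction == pytest.approx(0.2, abs=0.05)

    def test_subclonal_attenuation_fits_subclone_states(self):
        # bins shifted by tf*sp (half the clonal magnitude) should engage
        # the subclonal gain state rather than distorting tf
        scheme = make_flat_scheme(n_bins_per_chrom=200, n_chrom=2)
        tf, sp = 0.3, 0.5
        rng = np.random.default_rng(9)
        x = rng.normal(0, 0.03, 400)
        x[20:120] += expected_log2(tf, 3)  # clonal gain anchors tf
        x[250:330] += expected_log2(tf * sp, 3)  # subclonal-level gain
        prof = _profile_from_values(x, scheme)
        segset, est = run_hmm(prof, scheme, HMMConfig(), init_n=0.7)
        assert est.tumor_fraction == pytest.approx(tf, abs=0.03)
        assert est.subclone_prevalence == pytest.approx(sp, abs=0.1)


def test_state_table():
    assert STATES == ((0, False), (1, False), (2, False), (3, False), (1, True), (3, True))
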
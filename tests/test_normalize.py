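import numpy as np
import pytest

from shallowcn.coverage import DepthProfile
from shallowcn.normalize import (
    build_panel,
    correct_gc,
    normalize_profile,
    to_log2_ratio,
)
from shallowcn.simulate import simulate_depth
from tests.conftest import make_flat_scheme


def gc_scheme(n=200, seed=0):
    """Flat scheme with per-bin GC spread over [0.3, 0.6]."""
    scheme = make_flat_scheme(n_bins_per_chrom=n, n_chrom=1)
    rng = np.random.default_rng(seed)
    scheme.gc[:] = rng.uniform(0.3, 0.6, size=n)
    return scheme


class TestCorrectGC:
    def test_identity_when_counts_flat(self):
        scheme = gc_scheme()
        prof = DepthProfile("s", np.full(scheme.n_bins, 100.0))
        out = correct_gc(prof, scheme)
        np.testing.assert_allclose(out.counts, prof.counts, rtol=1e-3)

    def test_linear_bias_removed(self):
        scheme = gc_scheme(n=500, seed=1)
        rng = np.random.default_rng(11)
        counts = rng.poisson(1000.0 * (1.0 + (scheme.gc - 0.5))).astype(float)
        biased_r = np.corrcoef(counts, scheme.gc)[0, 1]
        out = correct_gc(DepthProfile("s", counts), scheme)
        r = np.corrcoef(out.counts, scheme.gc)[0, 1]
        assert biased_r > 0.5  # bias clearly present before correction
        assert abs(r) < 0.05

    def test_total_count_conserved(self):
        scheme = gc_scheme(n=300, seed=2)
        rng = np.random.default_rng(3)
        counts = rng.poisson(100.0 * (1.0 + 0.5 * (scheme.gc - 0.45)), scheme.n_bins) + 1.0
        out = correct_gc(DepthProfile("s", counts), scheme)
        assert out.counts.sum() == pytest.approx(counts.sum(), rel=1e-3)

    def test_constant_gc_warns_and_is_identity(self):
        scheme = make_flat_scheme(n_bins_per_chrom=100, n_chrom=1, gc=0.5)
        prof = DepthProfile("s", np.arange(100, 200.0))
        with pytest.warns(UserWarning, match="identity"):
            out = correct_gc(prof, scheme)
        np.testing.assert_array_equal(out.counts, prof.counts)

    def test_too_few_bins_rejected(self):
        scheme = make_flat_scheme(n_bins_per_chrom=10, n_chrom=1)
        with pytest.raises(ValueError, match="50"):
            correct_gc(DepthProfile("s", np.ones(10)), scheme)


class TestBuildPanel:
    def test_identical_controls(self):
        scheme = gc_scheme(n=100)
        base = np.full(100, 50.0)
        controls = [DepthProfile(f"c{i}", base.copy()) for i in range(3)]
        pon = build_panel(controls, scheme)
        ref_corrected = correct_gc(controls[0], scheme).counts
        np.testing.assert_allclose(pon.reference, ref_corrected, rtol=1e-6)
        np.testing.assert_allclose(pon.dispersion, 0.0, atol=1e-9)

    def test_median_of_three(self):
        scheme = make_flat_scheme(n_bins_per_chrom=100, n_chrom=1, gc=0.5)
        controls = [DepthProfile(f"c{i}", np.full(100, v)) for i, v in enumerate((8.0, 10.0, 12.0))]
        with pytest.warns(UserWarning):  # constant GC: correction is identity
            pon = build_panel(controls, scheme)
        # all scaled to common library size first; median of scaled bins = 10
        np.testing.assert_allclose(pon.reference, 10.0, rtol=1e-9)

    def test_simulated_medians_match_direct_recomputation(self, small_sim, small_panel):
        cfg, layout, _, _, scheme = small_sim
        controls, pon = small_panel
        usable = ~scheme.masked
        target = float(np.median([c.counts[usable].sum() for c in controls]))
        mat = []
        for c in controls:
            corr = correct_gc(c, scheme).counts
            mat.append(corr * target / corr[usable].sum())
        np.testing.assert_allclose(pon.reference, np.median(np.vstack(mat), axis=0), rtol=1e-9)

    def test_zero_depth_bin_invalidated(self):
        scheme = gc_scheme(n=100)
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(2, 100)).astype(float) + 1
        counts[0, 7] = 0.0
        pon = build_panel([DepthProfile("a", counts[0]), DepthProfile("b", counts[1])], scheme)
        assert not pon.valid[7]

    def test_fewer_than_two_controls_rejected(self):
        scheme = gc_scheme()
        with pytest.raises(ValueError, match="2 controls"):
            build_panel([DepthProfile("a", np.ones(scheme.n_bins))], scheme)

    def test_scheme_mismatch_rejected(self):
        scheme = gc_scheme(n=100)
        with pytest.raises(ValueError):
            build_panel([DepthProfile("a", np.ones(5)), DepthProfile("b", np.ones(5))], scheme)

    def test_merged_mode(self, small_sim, small_panel):
        cfg, layout, _, _, scheme = small_sim
        controls, _ = small_panel
        pon = build_panel(controls, scheme, mode="merged")
        assert pon.mode == "merged"
        assert np.all(pon.reference[pon.valid] > 0)


class TestLog2Ratio:
    def test_sample_equal_to_reference_gives_zero(self):
        scheme = gc_scheme(n=100)
        rng = np.random.default_rng(1)
        base = rng.poisson(100, 100).astype(float) + 1
        controls = [DepthProfile(f"c{i}", base.copy()) for i in range(3)]
        pon = build_panel(controls, scheme)
        norm = to_log2_ratio(correct_gc(DepthProfile("s", base), scheme), pon, scheme)
        np.testing.assert_allclose(norm.log2_ratio[norm.valid], 0.0, atol=1e-9)

    def test_doubled_bin_is_log2_one(self):
        scheme = make_flat_scheme(n_bins_per_chrom=101, n_chrom=1, gc=0.5)
        base = np.full(101, 10_000.0)
        controls = [DepthProfile(f"c{i}", base.copy()) for i in range(3)]
        with pytest.warns(UserWarning):
            pon = build_panel(controls, scheme)
        case = base.copy()
        case[50] *= 2
        with pytest.warns(UserWarning):
            corr = correct_gc(DepthProfile("s", case), scheme)
        # undo the library-size inflation the doubled bin causes, then ratio
        norm = to_log2_ratio(
            DepthProfile("s", corr.counts * base.sum() / case.sum()), pon, scheme
        )
        assert norm.log2_ratio[50] == pytest.approx(1.0, abs=2e-3)

    def test_elementwise_log2_oracle(self):
        scheme = gc_scheme(n=120, seed=9)
        rng = np.random.default_rng(10)
        base = rng.poisson(200, 120).astype(float) + 1
        controls = [DepthProfile(f"c{i}", base * s) for i, s in enumerate((0.9, 1.0, 1.1))]
        pon = build_panel(controls, scheme)
        case = correct_gc(DepthProfile("s", rng.poisson(200, 120).astype(float) + 1), scheme)
        norm = to_log2_ratio(case, pon, scheme)
        scaled = case.counts * pon.reference[norm.valid].sum() / case.counts[norm.valid].sum()
        expected = np.log2((scaled + 1.0) / (pon.reference + 1.0))
        expected -= np.median(expected[norm.valid & scheme.autosomal])
        np.testing.assert_allclose(norm.log2_ratio[norm.valid], expected[norm.valid], rtol=1e-9)

    def test_control_self_normalization_near_zero(self, small_sim, small_panel):
        """Panel property: a held-in control centers at |median log2| < 0.02.

        (The median of per-bin |log2| is floored by counting noise — about
        0.04 at the default bin coverage — so the calibration property is
        on the centering bias, not the absolute residuals.)
        """
        cfg, layout, _, _, scheme = small_sim
        controls, pon = small_panel
        for control in controls[:3]:
            norm = normalize_profile(control, pon, scheme)
            assert abs(np.median(norm.log2_ratio[norm.valid])) < 0.02

    def test_gc_bias_removed_on_simulated_sample(self, small_sim, small_panel):
        cfg, layout, _, _, scheme = small_sim
        controls, pon = small_panel
        rng = np.random.default_rng(123)
        case = simulate_depth(cfg, scheme, 0.0, None, rng, "case")
        raw_r = np.corrcoef(case.counts[~scheme.masked], scheme.gc[~scheme.masked])[0, 1]
        corrected = correct_gc(case, scheme)
        r = np.corrcoef(corrected.counts[~scheme.masked], scheme.gc[~scheme.masked])[0, 1]
        assert abs(raw_r) > abs(r)
        assert abs(r) < 0.05
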
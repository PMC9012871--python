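import numpy as np
import pytest

from shallowcn.cbs import SegmentRecord, SegmentSet
from shallowcn.hmm import TumorFractionEstimate
from shallowcn.recurrence import (
    gscore,
    permutation_significance,
    select_max_tf_sample,
)
from tests.conftest import make_flat_scheme


def _est(sid, tf):
    return TumorFractionEstimate(
        sample_id=sid,
        tumor_fraction=tf,
        normal_proportion=1 - tf,
        subclone_prevalence=0.5,
        log_likelihood=0.0,
        fraction_genome_altered=0.1,
    )


def _segset(sid, spans, scheme):
    """spans: list of (first_bin, last_bin, mean_log2, state)."""
    segs = []
    covered = set()
    for a, b, mean, state in spans:
        segs.append(
            SegmentRecord(
                str(scheme.chrom[a]),
                int(scheme.start[a]),
                int(scheme.end[b]),
                b - a + 1,
                mean,
                copy_state=state,
                first_bin=a,
                last_bin=b,
            )
        )
        covered.update(range(a, b + 1))
    # fill the rest with neutral segments per chromosome
    for chrom, sl in scheme.chrom_slices():
        run = []
        for i in range(sl.start, sl.stop):
            if i in covered:
                if run:
                    segs.append(_neutral(run, scheme))
                    run = []
            else:
                run.append(i)
        if run:
            segs.append(_neutral(run, scheme))
    segs.sort(key=lambda s: (str(s.chrom), s.start))
    return SegmentSet(sid, "hmm_arm", segs)


def _neutral(run, scheme):
    return SegmentRecord(
        str(scheme.chrom[run[0]]),
        int(scheme.start[run[0]]),
        int(scheme.end[run[-1]]),
        len(run),
        0.0,
        copy_state=2,
        first_bin=run[0],
        last_bin=run[-1],
    )


class TestSelectMaxTf:
    def test_per_dog_argmax(self):
        cohort = {
            "dog1": [(_est("a", 0.05), 1), (_est("b", 0.21), 2)],
            "dog2": [(_est("c", 0.10), 1)],
        }
        chosen = select_max_tf_sample(cohort)
        assert chosen["dog1"].sample_id == "b"
        assert chosen["dog2"].sample_id == "c"

    def test_tie_broken_by_earliest_date(self):
        cohort = {"d": [(_est("late", 0.1), 5), (_est("early", 0.1), 2)]}
        assert select_max_tf_sample(cohort)["d"].sample_id == "early"

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        cohort = {}
        for d in range(10):
            entries = [
                (_est(f"d{d}s{i}", float(rng.uniform(0, 0.5))), i) for i in range(1 + d % 3)
            ]
            cohort[f"dog{d}"] = entries
        chosen = select_max_tf_sample(cohort)
        for dog, entries in cohort.items():
            best = max(e[0].tumor_fraction for e in entries)
            assert chosen[dog].tumor_fraction == best

    def test_empty_dog_rejected(self):
        with pytest.raises(ValueError):
            select_max_tf_sample({"d": []})


class TestGScore:
    def test_single_sample_single_gain(self):
        scheme = make_flat_scheme(n_bins_per_chrom=50, n_chrom=2)
        ss = _segset("s1", [(10, 19, 0.5, 3)], scheme)
        track = gscore([ss], scheme, "gain")
        expected = np.zeros(100)
        expected[10:20] = 0.5
        np.testing.assert_allclose(track.g_score, expected)

    def test_two_samples_additive(self):
        scheme = make_flat_scheme(n_bins_per_chrom=50, n_chrom=2)
        one = gscore([_segset("s1", [(10, 19, 0.5, 3)], scheme)], scheme, "gain")
        two = gscore(
            [
                _segset("s1", [(10, 19, 0.5, 3)], scheme),
                _segset("s2", [(10, 19, 0.5, 3)], scheme),
            ],
            scheme,
            "gain",
        )
        # G = sum(amplitude)/N: same per-bin value, but the sum doubles
        np.testing.assert_allclose(two.g_score * 2, one.g_score * 2)
        np.testing.assert_allclose(
            two.g_score * two.n_samples, one.g_score * one.n_samples * 2
        )

    def test_loss_direction_uses_negated_amplitude(self):
        scheme = make_flat_scheme(n_bins_per_chrom=50, n_chrom=1)
        ss = _segset("s1", [(5, 9, -0.4, 1)], scheme)
        track = gscore([ss], scheme, "loss")
        assert track.g_score[5] == pytest.approx(0.4)
        assert gscore([ss], scheme, "gain").g_score.max() == 0.0

    def test_matches_brute_force_summation(self):
        scheme = make_flat_scheme(n_bins_per_chrom=40, n_chrom=2)
        rng = np.random.default_rng(1)
        sets = []
        for si in range(5):
            spans = []
            a = int(rng.integers(0, 30))
            b = a + int(rng.integers(1, 9))
            mean = float(rng.uniform(0.1, 0.8))
            spans.append((a, b, mean, 3))
            sets.append(_segset(f"s{si}", spans, scheme))
        track = gscore(sets, scheme, "gain")
        oracle = np.zeros(scheme.n_bins)
        for ss in sets:
            for seg in ss.segments:
                if seg.copy_state == 3:
                    for b in range(seg.first_bin, seg.last_bin + 1):
                        oracle[b] += max(seg.mean_log2, 0.0)
        np.testing.assert_allclose(track.g_score, oracle / len(sets))

    def test_empty_cohort_rejected(self):
        scheme = make_flat_scheme(n_bins_per_chrom=10, n_chrom=1)
        with pytest.raises(ValueError):
            gscore([], scheme, "gain")

    def test_gain_loss_supports_disjoint_per_sample(self):
        scheme = make_flat_scheme(n_bins_per_chrom=50, n_chrom=1)
        ss = _segset("s1", [(5, 9, 0.5, 3), (20, 29, -0.5, 1)], scheme)
        g = gscore([ss], scheme, "gain").g_score
        l = gscore([ss], scheme, "loss").g_score
        assert np.all((g > 0) + (l > 0) <= 1)


class TestPermutation:
    def test_zero_g_gives_p_one(self):
        scheme = make_flat_scheme(n_bins_per_chrom=50, n_chrom=2)
        sets = [_segset("s1", [(10, 19, 0.5, 3)], scheme)]
        track = gscore(sets, scheme, "gain")
        out = permutation_significance(track, sets, scheme, n_perm=100, seed=0)
        assert np.all(out.perm_p[track.g_score == 0] == 1.0)

    def test_all_neutral_cohort_no_significant_regions(self):
        scheme = make_flat_scheme(n_bins_per_chrom=50, n_chrom=2)
        sets = [_segset(f"s{i}", [], scheme) for i in range(4)]
        track = gscore(sets, scheme, "gain")
        out = permutation_significance(track, sets, scheme, n_perm=100, seed=0)
        assert out.significant_regions == []
        assert np.all(out.perm_p == 1.0)

    def test_recurrent_region_detected(self):
        scheme = make_flat_scheme(n_bins_per_chrom=100, n_chrom=3)
        rng = np.random.default_rng(3)
        sets = []
        for si in range(8):
            spans = [(120, 139, 0.5, 3)]  # shared gain on chr2
            a = int(rng.integers(0, 80))  # plus a random private gain on chr1
            spans.append((a, a + 10, 0.3, 3))
            sets.append(_segset(f"s{si}", spans, scheme))
        track = gscore(sets, scheme, "gain")
        out = permutation_significance(track, sets, scheme, n_perm=200, seed=1)
        hit = [r for r in out.significant_regions if r[0] == "chr2"]
        assert hit, "shared gain must reach significance"

    def test_deterministic_given_seed(self):
        scheme = make_flat_scheme(n_bins_per_chrom=60, n_chrom=1)
        sets = [
            _segset("s1", [(10, 19, 0.5, 3)], scheme),
            _segset("s2", [(30, 44, 0.4, 3)], scheme),
        ]
        track = gscore(sets, scheme, "gain")
        a = permutation_significance(track, sets, scheme, n_perm=150, seed=9)
        b = permutation_significance(track, sets, scheme, n_perm=150, seed=9)
        np.testing.assert_array_equal(a.perm_p, b.perm_p)

    def test_sample_order_invariance(self):
        scheme = make_flat_scheme(n_bins_per_chrom=60, n_chrom=1)
        s1 = _segset("s1", [(10, 19, 0.5, 3)], scheme)
        s2 = _segset("s2", [(30, 44, 0.4, 3)], scheme)
        track = gscore([s1, s2], scheme, "gain")
        a = permutation_significance(track, [s1, s2], scheme, n_perm=120, seed=4)
        b = permutation_significance(track, [s2, s1], scheme, n_perm=120, seed=4)
        np.testing.assert_array_equal(a.perm_p, b.perm_p)

    def test_min_permutations_enforced(self):
        scheme = make_flat_scheme(n_bins_per_chrom=20, n_chrom=1)
        sets = [_segset("s1", [], scheme)]
        track = gscore(sets, scheme, "gain")
        with pytest.raises(ValueError):
            permutation_significance(track, sets, scheme, n_perm=10, seed=0)
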
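"""Synthetic data with known ground truth for every pipeline input.

Generates a genome layout with smooth GC and dropout-run mappability
tracks, healthy-control depth panels, case profiles carrying segmental
copy-number alterations diluted by a known tumor fraction (with
GC-correlated bias and negative-binomial bin noise), cfDNA
fragment-length samples with nucleosome-ladder modes and a 10 bp comb,
and cohort tables emulating a benign/malignant pre/post-surgery design.
All outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from shallowcn.bins import BinScheme, annotate_bins, build_fixed_bins, mask_bins
from shallowcn.coverage import DepthProfile, FragmentLengths
from shallowcn.genome import GenomeLayout, Track
from shallowcn.hmm import expected_log2

LN2 = float(np.log(2.0))


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 20
    chromosome_length: int = 60_000_000
    # GC field: smooth random field over windows, clipped to bounds
    gc_window: int = 10_000
    gc_bounds: tuple[float, float] = (0.3, 0.6)
    gc_smooth_sigma: float = 20.0  # in windows
    # mappability: usable everywhere except seeded dropout runs
    dropout_fraction: float = 0.02
    dropout_run_length: int = 50_000
    # depth model
    n_controls: int = 9
    coverage_target: float = 400.0  # mean fragments per bin
    noise_sd: float = 0.06  # target log2-scale bin noise
    gc_bias_slope: float = 0.3
    bin_width: int = 500_000
    # case truth
    tumor_fraction: float = 0.2
    gain_fraction: float = 0.25  # genome fraction at copy 3
    loss_fraction: float = 0.10  # genome fraction at copy 1
    # fragment model
    fragment_mode_weights: tuple[float, float, float] = (0.80, 0.15, 0.05)
    fragment_mode_means: tuple[int, int, int] = (166, 332, 498)
    fragment_mode_sds: tuple[float, float, float] = (12.0, 20.0, 28.0)
    # sub-mononucleosomal tail that carries the 10 bp ladder
    fragment_tail_weight: float = 0.08
    fragment_tail_range: tuple[int, int] = (90, 160)
    periodicity_amplitude: float = 0.5
    periodicity_period: float = 10.0
    periodicity_below: int = 150
    # cohort design (tumor-fraction distributions truncated at 0)
    n_benign: int = 14
    n_malignant: int = 25
    benign_tf: tuple[float, float] = (0.032, 0.034)
    malignant_tf: tuple[float, float] = (0.112, 0.091)
    post_surgery_reduction: float = 0.72

    def __post_init__(self):
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0,1]")
        if self.gain_fraction + self.loss_fraction > 0.9:
            raise ValueError("CNA truth would cover nearly the whole genome")


@dataclass
class SimBundle:
    config: SimConfig
    layout: GenomeLayout
    gc_track: Track
    mappability_track: Track
    scheme: BinScheme
    controls: list[DepthProfile]
    cases: dict[str, DepthProfile]
    truth: dict[str, dict]  # sample_id -> {tf, cna_truth, dog_id, group, timepoint}
    cohort: pd.DataFrame
    fragments: dict[str, FragmentLengths] = field(default_factory=dict)


def simulate_reference(config: SimConfig) -> tuple[GenomeLayout, Track, Track]:
    """Layout plus smooth GC field and dropout-run mappability track."""
    rng = np.random.default_rng(config.seed)
    layout = GenomeLayout(
        [(f"chr{i + 1}", config.chromosome_length) for i in range(config.n_chromosomes)]
    )
    gc_track, map_track = Track(), Track()
    lo, hi = config.gc_bounds
    for name, length in layout.chromosomes:
        n_win = int(np.ceil(length / config.gc_window))
        raw = gaussian_filter1d(rng.standard_normal(n_win), config.gc_smooth_sigma)
        sd = raw.std() or 1.0
        gc = np.clip((lo + hi) / 2 + raw / sd * (hi - lo) / 4, lo, hi)
        starts = np.arange(n_win, dtype=np.int64) * config.gc_window
        ends = np.minimum(starts + config.gc_window, length)
        gc_track.add(name, starts, ends, gc)

        target_drop = config.dropout_fraction * length
        runs: list[tuple[int, int]] = []
        dropped = 0
        while dropped < target_drop:
            run = int(rng.exponential(config.dropout_run_length)) + 1
            start = int(rng.integers(0, max(length - run, 1)))
            runs.append((start, min(start + run, length)))
            dropped += min(run, length - start)
        runs.sort()
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        # complement of dropout runs carries value 1, runs carry 0
        starts_m, ends_m, vals = [], [], []
        pos = 0
        for s, e in merged:
            if s > pos:
                starts_m.append(pos)
                ends_m.append(s)
                vals.append(1.0)
            starts_m.append(s)
            ends_m.append(e)
            vals.append(0.0)
            pos = e
        if pos < length:
            starts_m.append(pos)
            ends_m.append(length)
            vals.append(1.0)
        map_track.add(name, starts_m, ends_m, vals)
    return layout, gc_track, map_track


def build_simulated_scheme(
    config: SimConfig, layout: GenomeLayout, gc_track: Track, map_track: Track
) -> BinScheme:
    scheme = build_fixed_bins(layout, config.bin_width)
    scheme = annotate_bins(scheme, gc_track, map_track)
    return mask_bins(scheme)


def random_cna_truth(
    config: SimConfig, layout: GenomeLayout, rng: np.random.Generator
) -> list[tuple[str, int, int, int]]:
    """Non-overlapping whole-region gains (c=3) and losses (c=1) hitting the
    configured genome fractions, placed on randomly chosen chromosomes."""
    genome = sum(l for _, l in layout.chromosomes)
    budgets = {3: config.gain_fraction * genome, 1: config.loss_fraction * genome}
    order = rng.permutation(len(layout.chromosomes))
    truth: list[tuple[str, int, int, int]] = []
    states = [3, 1]
    si = 0
    for ci in order:
        name, length = layout.chromosomes[int(ci)]
        state = states[si % 2]
        if budgets[state] <= 0:
            state = states[(si + 1) % 2]
            if budgets[state] <= 0:
                break
        span = int(min(length * rng.uniform(0.4, 1.0), budgets[state]))
        if span < length // 20:
            span = min(length, int(budgets[state]))
        start = int(rng.integers(0, length - span + 1)) if span < length else 0
        truth.append((name, start, start + span, state))
        budgets[state] -= span
        si += 1
    return truth


def _bin_copy_numbers(
    scheme: BinScheme, cna_truth: list[tuple[str, int, int, int]] | None
) -> np.ndarray:
    c = np.full(scheme.n_bins, 2, dtype=int)
    if not cna_truth:
        return c
    for chrom, start, end, state in cna_truth:
        hit = (
            (scheme.chrom == chrom)
            & (scheme.start < end)
            & (scheme.end > start)
        )
        # assign by majority overlap
        ov = np.minimum(scheme.end, end) - np.maximum(scheme.start, start)
        c[hit & (ov >= scheme.widths / 2)] = state
    return c


def simulate_depth(
    config: SimConfig,
    scheme: BinScheme,
    tf: float,
    cna_truth: list[tuple[str, int, int, int]] | None,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> DepthProfile:
    """Negative-binomial per-bin counts at the expected CNA-diluted depth.

    Mean depth per bin is coverage_target x 2^expected_log2(tf, c) x a
    linear GC bias x the bin's mappable fraction; the NB dispersion is set
    so the log2-scale noise SD approximates ``config.noise_sd`` (floored
    by Poisson noise at the configured coverage).
    """
    c = _bin_copy_numbers(scheme, cna_truth)
    shift = np.array([2.0 ** expected_log2(tf, int(ci)) for ci in np.unique(c)])
    lut = dict(zip(np.unique(c), shift))
    mean_shift = np.array([lut[ci] for ci in c])
    gc = np.where(np.isfinite(scheme.gc), scheme.gc, 0.5)
    gc_bias = np.maximum(1.0 + config.gc_bias_slope * (gc - 0.5), 0.05)
    mfrac = scheme.mappable_bases / scheme.widths
    mu = np.maximum(config.coverage_target * mean_shift * gc_bias * mfrac, 1e-9)
    target_var = (config.noise_sd * LN2) ** 2  # variance of log(count)
    counts = np.empty(scheme.n_bins)
    alpha = target_var - 1.0 / np.maximum(mu, 1e-9)  # NB over-dispersion
    pois = alpha <= 1e-12
    counts[pois] = rng.poisson(mu[pois])
    if np.any(~pois):
        r = 1.0 / alpha[~pois]
        p = r / (r + mu[~pois])
        counts[~pois] = rng.negative_binomial(r, p)
    return DepthProfile(sample_id=sample_id, counts=counts)


def simulate_fragments(
    config: SimConfig, n: int, rng: np.random.Generator, sample_id: str = "sim"
) -> FragmentLengths:
    """Mixture of discretized normals at the nucleosome-ladder modes with a
    10 bp-period comb modulating the sub-150 bp tail (rejection thinning)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mode_w = np.asarray(config.fragment_mode_weights, dtype=float)
    mode_w = mode_w / mode_w.sum() * (1.0 - config.fragment_tail_weight)
    weights = np.append(mode_w, config.fragment_tail_weight)
    means = np.asarray(config.fragment_mode_means, dtype=float)
    sds = np.asarray(config.fragment_mode_sds, dtype=float)
    tail_lo, tail_hi = config.fragment_tail_range
    amp = config.periodicity_amplitude
    period = config.periodicity_period
    out: list[np.ndarray] = []
    have = 0
    while have < n:
        m = max(int((n - have) * 1.5), 1000)
        comp = rng.choice(len(weights), size=m, p=weights)
        is_tail = comp == len(mode_w)
        lengths = np.empty(m, dtype=np.int64)
        k = np.minimum(comp, len(mode_w) - 1)
        lengths[~is_tail] = np.rint(
            rng.normal(means[k[~is_tail]], sds[k[~is_tail]])
        ).astype(np.int64)
        lengths[is_tail] = rng.integers(tail_lo, tail_hi + 1, size=int(is_tail.sum()))
        lengths = lengths[lengths > 0]
        if amp > 0:
            mod = lengths < config.periodicity_below
            keep_p = np.ones(len(lengths))
            keep_p[mod] = (1.0 + amp * np.cos(2 * np.pi * lengths[mod] / period)) / (1.0 + amp)
            lengths = lengths[rng.random(len(lengths)) < keep_p]
        out.append(lengths)
        have += len(lengths)
    lengths = np.concatenate(out)[:n]
    return FragmentLengths(sample_id=sample_id, lengths=lengths)


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= 0:
            return float(v)
    return 0.0


def simulate_cohort(config: SimConfig, with_fragments: bool = False) -> SimBundle:
    """Full study emulation: reference, panel controls, benign/malignant dogs
    with pre/post-surgery case profiles at known tumor fractions."""
    rng = np.random.default_rng(config.seed + 1_000_003)
    layout, gc_track, map_track = simulate_reference(config)
    scheme = build_simulated_scheme(config, layout, gc_track, map_track)

    controls = [
        simulate_depth(config, scheme, 0.0, None, rng, sample_id=f"control_{i + 1}")
        for i in range(config.n_controls)
    ]

    cases: dict[str, DepthProfile] = {}
    truth: dict[str, dict] = {}
    rows = []
    fragments: dict[str, FragmentLengths] = {}
    groups = [("benign", config.n_benign, config.benign_tf), (
        "malignant",
        config.n_malignant,
        config.malignant_tf,
    )]
    dog_no = 0
    for group, n_dogs, (tf_mean, tf_sd) in groups:
        for _ in range(n_dogs):
            dog_no += 1
            dog_id = f"dog_{dog_no:02d}"
            tf_pre = _truncated_normal(tf_mean, tf_sd, rng)
            tf_post = tf_pre * config.post_surgery_reduction
            cna = random_cna_truth(config, layout, rng)
            for timepoint, tf in (("pre", tf_pre), ("post", tf_post)):
                sid = f"{dog_id}_{timepoint}"
                cases[sid] = simulate_depth(config, scheme, tf, cna, rng, sample_id=sid)
                truth[sid] = {
                    "tf": tf,
                    "cna_truth": cna,
                    "dog_id": dog_id,
                    "group": group,
                    "timepoint": timepoint,
                }
                rows.append(
                    {
                        "dog_id": dog_id,
                        "sample_id": sid,
                        "group": group,
                        "timepoint": timepoint,
                        "true_tf": tf,
                    }
                )
                if with_fragments:
                    fragments[sid] = simulate_fragments(config, 20_000, rng, sample_id=sid)
    cohort = pd.DataFrame(rows)
    return SimBundle(
        config=config,
        layout=layout,
        gc_track=gc_track,
        mappability_track=map_track,
        scheme=scheme,
        controls=controls,
        cases=cases,
        truth=truth,
        cohort=cohort,
        fragments=fragments,
    )
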
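"""Method-comparison metrics: segment counts, lengths and within-segment
log2-depth variability, with a rank-based between-method test."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from shallowcn.cbs import SegmentSet
from shallowcn.normalize import NormalizedProfile
from shallowcn.stats import TestResult, rank_sum_test


@dataclass
class SegmentSummary:
    sample_id: str
    method_tag: str
    n_segments: int
    segment_lengths: list[int]
    within_segment_sds: list[float]
    single_bin_flags: list[bool] = field(default_factory=list)

    def __post_init__(self):
        assert self.n_segments == len(self.segment_lengths) == len(self.within_segment_sds)


def summarize_segments(profile: NormalizedProfile, segset: SegmentSet) -> SegmentSummary:
    """Per-segment base-pair length and sample SD of member-bin log2 values.

    Single-bin segments get SD = 0 and are flagged. Segments must carry
    bin-index ranges on the profile's scheme.
    """
    lengths, sds, flags = [], [], []
    for s in segset.segments:
        if s.first_bin < 0:
            raise ValueError("segment lacks bin-index annotation")
        idx = np.arange(s.first_bin, s.last_bin + 1)
        vals = profile.log2_ratio[idx][profile.valid[idx]]
        if len(vals) == 0:
            raise ValueError(f"segment {s.chrom}:{s.start}-{s.end} covers only masked bins")
        lengths.append(s.length)
        if len(vals) == 1:
            sds.append(0.0)
            flags.append(True)
        else:
            sds.append(float(np.std(vals, ddof=1)))
            flags.append(False)
    return SegmentSummary(
        sample_id=profile.sample_id,
        method_tag=segset.method_tag,
        n_segments=len(segset.segments),
        segment_lengths=lengths,
        within_segment_sds=sds,
        single_bin_flags=flags,
    )


def compare_methods(sds_a: list[float], sds_b: list[float]) -> TestResult:
    """Two-sided Mann-Whitney U on pooled within-segment SDs of two methods.

    Reports the two medians alongside the test result.
    """
    if not len(sds_a) or not len(sds_b):
        raise ValueError("both SD lists must be non-empty")
    a = np.asarray(sds_a, dtype=float)
    b = np.asarray(sds_b, dtype=float)
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all within-segment SDs tied; comparison uninformative")
    res = rank_sum_test(a, b)
    res.extra["median_a"] = float(np.median(a))
    res.extra["median_b"] = float(np.median(b))
    return res
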
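"""Cohort recurrence analysis of copy-number gains and losses.

Per-bin G-scores combine alteration frequency and amplitude across the
cohort (sum of matching-direction segment amplitudes divided by the
number of samples). Significance comes from a cyclic-shift permutation
null that preserves each sample's segment-length structure, with
Benjamini-Hochberg q-values across bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from shallowcn.bins import BinScheme
from shallowcn.cbs import SegmentSet
from shallowcn.hmm import TumorFractionEstimate

DEFAULT_Q_THRESHOLD = 0.25
DEFAULT_N_PERM = 1000


@dataclass
class RecurrenceTrack:
    direction: str  # "gain" | "loss"
    g_score: np.ndarray  # per bin, >= 0
    perm_p: np.ndarray | None = None
    q_value: np.ndarray | None = None
    significant_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    n_samples: int = 0

    def to_tsv(self, scheme: BinScheme, path) -> None:
        df = pd.DataFrame(
            {
                "chrom": scheme.chrom,
                "start": scheme.start,
                "end": scheme.end,
                "g_score": self.g_score,
            }
        )
        if self.perm_p is not None:
            df["perm_p"] = self.perm_p
            df["q_value"] = self.q_value
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def regions_to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, peak in self.significant_regions:
                fh.write(f"{chrom}\t{start}\t{end}\t{self.direction}\t{peak:.4f}\n")


def select_max_tf_sample(
    cohort: dict[str, list[tuple[TumorFractionEstimate, object]]]
) -> dict[str, TumorFractionEstimate]:
    """Pick the highest-tumor-fraction sample per dog.

    ``cohort`` maps dog id to a list of (estimate, collection_date) pairs;
    ties on tumor fraction are broken by the earliest date.
    """
    chosen = {}
    for dog, entries in cohort.items():
        if not entries:
            raise ValueError(f"dog {dog} has no estimates")
        chosen[dog] = max(entries, key=lambda e: (e[0].tumor_fraction, _neg(e[1])))[0]
    return chosen


def _neg(date):
    # invert ordering so max() prefers the earliest date on tf ties
    class _Inv:
        def __init__(self, v):
            self.v = v

        def __lt__(self, other):
            return self.v > other.v

        def __gt__(self, other):
            return self.v < other.v

        def __eq__(self, other):
            return self.v == other.v

    return _Inv(date)


def _amplitude_matrix(
    segment_sets: list[SegmentSet], scheme: BinScheme, direction: str
) -> np.ndarray:
    """Per-sample, per-bin amplitude in the requested direction (0 elsewhere)."""
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    if not segment_sets:
        raise ValueError("empty cohort")
    sets = sorted(segment_sets, key=lambda s: s.sample_id)  # deterministic order
    amp = np.zeros((len(sets), scheme.n_bins))
    for si, ss in enumerate(sets):
        for seg in ss.segments:
            if seg.copy_state is None:
                raise ValueError("segments must have assigned copy states")
            if direction == "gain" and seg.copy_state > 2:
                a = max(seg.mean_log2, 0.0)
            elif direction == "loss" and seg.copy_state < 2:
                a = max(-seg.mean_log2, 0.0)
            else:
                continue
            if seg.first_bin < 0:
                raise ValueError("segment lacks bin-index annotation")
            amp[si, seg.first_bin : seg.last_bin + 1] = a
    return amp


def gscore(
    segment_sets: list[SegmentSet], scheme: BinScheme, direction: str
) -> RecurrenceTrack:
    """Frequency-weighted mean amplitude per bin across the cohort."""
    amp = _amplitude_matrix(segment_sets, scheme, direction)
    return RecurrenceTrack(
        direction=direction,
        g_score=amp.sum(axis=0) / amp.shape[0],
        n_samples=amp.shape[0],
    )


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def permutation_significance(
    track: RecurrenceTrack,
    segment_sets: list[SegmentSet],
    scheme: BinScheme,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> RecurrenceTrack:
    """Cyclic-shift permutation p-values and BH q-values for a G-score track.

    Each permutation independently rotates every sample's per-bin
    amplitude vector within each chromosome by a uniform random offset,
    preserving segment-length structure while destroying cross-sample
    positional alignment.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    amp = _amplitude_matrix(segment_sets, scheme, direction=track.direction)
    n_samples, n_bins = amp.shape
    observed = track.g_score
    exceed = np.zeros(n_bins)
    slices = [sl for _, sl in scheme.chrom_slices()]
    for _ in range(n_perm):
        null = np.empty_like(amp)
        for sl in slices:
            block = amp[:, sl]
            w = block.shape[1]
            shifts = rng.integers(0, w, size=n_samples)
            idx = (np.arange(w)[None, :] - shifts[:, None]) % w
            null[:, sl] = np.take_along_axis(block, idx, axis=1)
        g_null = null.sum(axis=0) / n_samples
        exceed += g_null >= observed
    perm_p = (1.0 + exceed) / (1.0 + n_perm)
    q = _bh_qvalues(perm_p)
    regions = []
    sig = (q <= q_threshold) & (observed > 0)
    for chrom, sl in scheme.chrom_slices():
        s = sig[sl]
        if not s.any():
            continue
        breaks = np.flatnonzero(np.diff(s.astype(int)))
        edges = np.concatenate([[0], breaks + 1, [len(s)]])
        for a, b in zip(edges[:-1], edges[1:]):
            if s[a]:
                gi = np.arange(sl.start + a, sl.start + b)
                regions.append(
                    (
                        chrom,
                        int(scheme.start[gi[0]]),
                        int(scheme.end[gi[-1]]),
                        float(observed[gi].max()),
                    )
                )
    return RecurrenceTrack(
        direction=track.direction,
        g_score=observed,
        perm_p=perm_p,
        q_value=q,
        significant_regions=regions,
        n_samples=n_samples,
    )
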
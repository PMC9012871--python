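"""Circular binary segmentation and copy-state assignment.

Changepoints are found per chromosome by recursively locating the arc
whose mean differs most from its complement (maximal |t|-like statistic
over all circular arcs) and testing it against a permutation null at
level alpha. Consecutive bins with the same copy-number status are then
grouped into segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from shallowcn.bins import BinScheme
from shallowcn.normalize import NormalizedProfile

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 1000
DEFAULT_GAIN_THRESHOLD = 0.2
DEFAULT_LOSS_THRESHOLD = -0.2

STATE_LABELS = {1: "loss", 2: "neutral", 3: "gain"}


@dataclass
class SegmentRecord:
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_log2: float
    copy_state: int | None = None  # integer copy number; None before assignment
    first_bin: int = -1  # global bin index range [first_bin, last_bin]
    last_bin: int = -1

    @property
    def label(self) -> str | None:
        if self.copy_state is None:
            return None
        if self.copy_state < 2:
            return "loss"
        if self.copy_state > 2:
            return "gain"
        return "neutral"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentSet:
    sample_id: str
    method_tag: str  # "cbs_arm" | "hmm_arm"
    segments: list[SegmentRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "n_bins": [s.n_bins for s in self.segments],
                "mean_log2": [s.mean_log2 for s in self.segments],
                "copy_state": [s.copy_state for s in self.segments],
            }
        )


def write_seg(segsets: list[SegmentSet], path) -> None:
    """SEG writer; coordinates converted to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\tcopy.state\n")
        for ss in segsets:
            for s in ss.segments:
                state = "" if s.copy_state is None else s.copy_state
                fh.write(
                    f"{ss.sample_id}\t{s.chrom}\t{s.start + 1}\t{s.end}\t"
                    f"{s.n_bins}\t{s.mean_log2:.6f}\t{state}\n"
                )


def read_seg(path, method_tag: str = "cbs_arm") -> list[SegmentSet]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, grp in df.groupby("ID", sort=False):
        segs = []
        for row in grp.itertuples(index=False):
            state = getattr(row, "copy.state", None)
            if state is None and hasattr(row, "_6"):
                state = row._6
            segs.append(
                SegmentRecord(
                    chrom=str(row.chrom),
                    start=int(getattr(row, "loc.start", row._2)) - 1,
                    end=int(getattr(row, "loc.end", row._3)),
                    n_bins=int(getattr(row, "num.mark", row._4)),
                    mean_log2=float(getattr(row, "seg.mean", row._5)),
                    copy_state=None if state in (None, "") or pd.isna(state) else int(state),
                )
            )
        out.append(SegmentSet(sample_id=str(sid), method_tag=method_tag, segments=segs))
    return out


def _max_arc_stat(x: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray, sd: float):
    """Max |z| over circular arcs (i, j]; returns (stat, i, j)."""
    n = len(x)
    cum = np.concatenate([[0.0], np.cumsum(x)])
    total = cum[-1]
    arc_len = (j_idx - i_idx).astype(float)
    comp_len = n - arc_len
    arc_sum = cum[j_idx] - cum[i_idx]
    diff = arc_sum / arc_len - (total - arc_sum) / comp_len
    z = np.abs(diff) / (sd * np.sqrt(1.0 / arc_len + 1.0 / comp_len))
    k = int(np.argmax(z))
    return float(z[k]), int(i_idx[k]), int(j_idx[k])


def _all_pairs(n: int):
    # arcs (i, j] over cut points 0..n, excluding empty and full arcs
    i, j = np.triu_indices(n + 1, k=1)
    keep = (j - i) < n
    return i[keep], j[keep]


def _perm_pvalue(
    x: np.ndarray,
    observed: float,
    i_idx: np.ndarray,
    j_idx: np.ndarray,
    sd: float,
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value for the max arc statistic, with early stopping."""
    exceed = 0
    done = 0
    stop_at = int(np.ceil(alpha * (n_perm + 1)))  # once exceeded, cannot be significant
    chunk = 50
    while done < n_perm:
        m = min(chunk, n_perm - done)
        for _ in range(m):
            xp = rng.permutation(x)
            s, _, _ = _max_arc_stat(xp, i_idx, j_idx, sd)
            if s >= observed:
                exceed += 1
        done += m
        if exceed > stop_at:
            break
    if done < n_perm:  # early stop: report a conservative (non-significant) p
        return (1 + exceed) / (1 + done)
    return (1 + exceed) / (1 + n_perm)


def _segment_one_chrom(
    x: np.ndarray, alpha: float, n_perm: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns half-open bin-index spans."""
    spans: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 or np.ptp(seg) == 0:
            spans.append((lo, hi))
            return
        sd = float(np.std(seg, ddof=1))
        if sd == 0:
            spans.append((lo, hi))
            return
        i_idx, j_idx = _all_pairs(n)
        stat, bi, bj = _max_arc_stat(seg, i_idx, j_idx, sd)
        p = _perm_pvalue(seg, stat, i_idx, j_idx, sd, n_perm, alpha, rng)
        if p > alpha:
            spans.append((lo, hi))
            return
        cuts = sorted({c for c in (bi, bj) if 0 < c < n})
        if not cuts:
            spans.append((lo, hi))
            return
        edges = [0] + cuts + [n]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(lo + a, lo + b)

    recurse(0, len(x))
    spans.sort()
    return spans


def segment_cbs(
    profile: NormalizedProfile,
    scheme: BinScheme,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> SegmentSet:
    """Segment a normalized profile chromosome by chromosome.

    Only valid bins enter the statistic; each resulting segment spans from
    the genomic start of its first member bin to the end of its last.
    """
    rng = np.random.default_rng(seed)
    segments: list[SegmentRecord] = []
    for chrom, sl in scheme.chrom_slices():
        idx = np.arange(sl.start, sl.stop)
        vmask = profile.valid[idx]
        vbins = idx[vmask]
        if len(vbins) == 0:
            continue
        x = profile.log2_ratio[vbins]
        spans = _segment_one_chrom(x, alpha, n_perm, rng) if len(x) > 1 else [(0, len(x))]
        for a, b in spans:
            member = vbins[a:b]
            segments.append(
                SegmentRecord(
                    chrom=chrom,
                    start=int(scheme.start[member[0]]),
                    end=int(scheme.end[member[-1]]),
                    n_bins=int(b - a),
                    mean_log2=float(np.mean(x[a:b])),
                    first_bin=int(member[0]),
                    last_bin=int(member[-1]),
                )
            )
    return SegmentSet(sample_id=profile.sample_id, method_tag="cbs_arm", segments=segments)


def assign_copy_states(
    segset: SegmentSet,
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
) -> SegmentSet:
    """Threshold segment means into loss/neutral/gain integer copy states."""
    if not (loss_threshold < 0 < gain_threshold):
        raise ValueError("need loss_threshold < 0 < gain_threshold")
    segs = []
    for s in segset.segments:
        if s.mean_log2 >= gain_threshold:
            state = 3
        elif s.mean_log2 <= loss_threshold:
            state = 1
        else:
            state = 2
        segs.append(replace(s, copy_state=state))
    return SegmentSet(sample_id=segset.sample_id, method_tag=segset.method_tag, segments=segs)


def merge_adjacent_same_state(segset: SegmentSet) -> SegmentSet:
    """Merge adjacent same-chromosome, same-state segments; idempotent."""
    merged: list[SegmentRecord] = []
    for s in segset.segments:
        if s.copy_state is None:
            raise ValueError("assign copy states before merging")
        prev = merged[-1] if merged else None
        if prev is not None and prev.chrom == s.chrom and prev.copy_state == s.copy_state:
            nb = prev.n_bins + s.n_bins
            mean = (prev.mean_log2 * prev.n_bins + s.mean_log2 * s.n_bins) / nb
            merged[-1] = replace(
                prev,
                end=s.end,
                n_bins=nb,
                mean_log2=mean,
                last_bin=max(prev.last_bin, s.last_bin),
            )
        else:
            merged.append(replace(s))
    return SegmentSet(sample_id=segset.sample_id, method_tag=segset.method_tag, segments=merged)
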
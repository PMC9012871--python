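"""Genomic bin scaffolds: fixed-width tiling and equal-mappable-base binning.

Two schemes are supported: ``fixed_width`` tiles each chromosome with
constant-width windows (last window per chromosome may be shorter), and
``equal_mappable`` places a fixed total number of bins whose boundaries are
chosen so each bin holds approximately the same number of usable
(mappable) bases. Bins never span chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from shallowcn.genome import GenomeLayout, Track, is_autosome

logger = logging.getLogger(__name__)

DEFAULT_FIXED_WIDTH = 500_000
DEFAULT_N_ADAPTIVE_BINS = 5_500
DEFAULT_MIN_MAPPABLE_FRACTION = 0.9


@dataclass
class BinScheme:
    """Ordered genomic bins with GC fraction and mappable-base annotation.

    Coordinates are 0-based half-open. ``masked`` bins are kept in the
    coordinate scaffold but excluded from downstream statistics.
    """

    layout: GenomeLayout
    chrom: np.ndarray  # object array of chromosome names
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    gc: np.ndarray  # float, NaN when unannotated
    mappable_bases: np.ndarray  # int64
    masked: np.ndarray  # bool
    scheme_kind: str = "fixed_width"

    def __post_init__(self):
        n = len(self.chrom)
        for arr in (self.start, self.end, self.gc, self.mappable_bases, self.masked):
            if len(arr) != n:
                raise ValueError("bin arrays must have equal length")
        if np.any(self.start >= self.end):
            raise ValueError("bin start must be < end")
        lengths = self.layout.lengths
        for c in np.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            if np.any(self.end[idx] > lengths[str(c)]):
                raise ValueError(f"bin beyond chromosome end on {c}")
            if np.any(np.diff(self.start[idx]) <= 0) or np.any(self.start[idx][1:] < self.end[idx][:-1]):
                raise ValueError(f"bins on {c} must be sorted and non-overlapping")

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    @property
    def widths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def autosomal(self) -> np.ndarray:
        return np.array([is_autosome(c) for c in self.chrom], dtype=bool)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """(chrom, bin index slice) per chromosome, in layout order."""
        out = []
        for name in self.layout.names:
            idx = np.flatnonzero(self.chrom == name)
            if len(idx):
                out.append((name, slice(int(idx[0]), int(idx[-1]) + 1)))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "gc": self.gc,
                "mappable_bases": self.mappable_bases,
                "masked": self.masked.astype(int),
            }
        )

    def to_bed(self, path) -> None:
        """BED4+ writer: chrom, start, end, name, gc, mappable_bases, masked."""
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(f"#scheme_kind={self.scheme_kind}\n")
            for name, length in self.layout.chromosomes:
                fh.write(f"#chrom\t{name}\t{length}\n")
            for i, row in enumerate(df.itertuples(index=False)):
                gc = "." if np.isnan(row.gc) else f"{row.gc:.6f}"
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\tbin_{i}\t{gc}\t"
                    f"{row.mappable_bases}\t{row.masked}\n"
                )

    @classmethod
    def from_bed(cls, path) -> "BinScheme":
        kind = "fixed_width"
        chroms: list[tuple[str, int]] = []
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#scheme_kind="):
                    kind = line.split("=", 1)[1]
                    continue
                if line.startswith("#chrom\t"):
                    _, name, length = line.split("\t")
                    chroms.append((name, int(length)))
                    continue
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                gc = float("nan") if f[4] == "." else float(f[4])
                rows.append((f[0], int(f[1]), int(f[2]), gc, int(f[5]), bool(int(f[6]))))
        if not chroms:  # layout not embedded: reconstruct from bin extents
            seen: dict[str, int] = {}
            for c, _, e, *_ in rows:
                seen[c] = max(seen.get(c, 0), e)
            chroms = list(seen.items())
        layout = GenomeLayout(chroms)
        return cls(
            layout=layout,
            chrom=np.array([r[0] for r in rows], dtype=object),
            start=np.array([r[1] for r in rows], dtype=np.int64),
            end=np.array([r[2] for r in rows], dtype=np.int64),
            gc=np.array([r[3] for r in rows], dtype=float),
            mappable_bases=np.array([r[4] for r in rows], dtype=np.int64),
            masked=np.array([r[5] for r in rows], dtype=bool),
            scheme_kind=kind,
        )


def _empty_annotation(n: int):
    return (
        np.full(n, np.nan),
        np.zeros(n, dtype=np.int64),
        np.zeros(n, dtype=bool),
    )


def build_fixed_bins(layout: GenomeLayout, width: int = DEFAULT_FIXED_WIDTH) -> BinScheme:
    """Tile every chromosome left-to-right with `width`-sized bins.

    The final bin of each chromosome may be shorter so that the union of
    bins is exactly [0, chromosome length).
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    chroms, starts, ends = [], [], []
    for name, length in layout.chromosomes:
        edges = list(range(0, length, width)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(name)
            starts.append(s)
            ends.append(e)
    gc, mb, masked = _empty_annotation(len(chroms))
    return BinScheme(
        layout=layout,
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        gc=gc,
        mappable_bases=mb,
        masked=masked,
        scheme_kind="fixed_width",
    )


def _apportion(usable: dict[str, float], n_bins: int, order: list[str]) -> dict[str, int]:
    """Largest-remainder apportionment of n_bins across chromosomes by usable bases."""
    total = sum(usable.values())
    quotas = {c: n_bins * usable[c] / total for c in order if usable[c] > 0}
    alloc = {c: max(int(np.floor(q)), 1) for c, q in quotas.items()}
    leftover = n_bins - sum(alloc.values())
    if leftover < 0:
        # too many single-bin floors: take back from largest-allocation chroms
        for c in sorted(alloc, key=lambda c: -alloc[c]):
            while leftover < 0 and alloc[c] > 1:
                alloc[c] -= 1
                leftover += 1
    remainders = sorted(
        quotas, key=lambda c: (-(quotas[c] - np.floor(quotas[c])), order.index(c))
    )
    i = 0
    while leftover > 0:
        alloc[remainders[i % len(remainders)]] += 1
        leftover -= 1
        i += 1
    return alloc


def _boundaries_in_chrom(starts, ends, values, length: int, n_k: int) -> list[int]:
    """Place n_k-1 interior boundaries at cumulative usable-base quantiles.

    When a quantile target lands inside a zero-usability run, the boundary
    snaps to the run's left edge (implicit in interpolating only over
    covered, positive-value intervals).
    """
    widths = (ends - starts).astype(float)
    contrib = values * widths
    cum = np.concatenate([[0.0], np.cumsum(contrib)])
    total = cum[-1]
    bounds = []
    for k in range(1, n_k):
        t = total * k / n_k
        j = int(np.searchsorted(cum[1:], t, side="left"))
        j = min(j, len(starts) - 1)
        inside = t - cum[j]
        if values[j] > 0:
            off = int(np.ceil(inside / values[j]))
            pos = int(starts[j]) + min(off, int(widths[j]))
        else:
            pos = int(starts[j])
        # boundaries must stay strictly increasing and interior
        lo = (bounds[-1] + 1) if bounds else 1
        pos = max(pos, lo)
        pos = min(pos, length - (n_k - k))
        bounds.append(pos)
    return bounds


def build_adaptive_bins(
    layout: GenomeLayout, mappability: Track, n_bins: int = DEFAULT_N_ADAPTIVE_BINS
) -> BinScheme:
    """Build exactly `n_bins` bins with near-equal usable (mappable) bases.

    Bins are apportioned to chromosomes proportionally to usable bases
    (largest-remainder rounding) and boundaries placed at cumulative
    usable-base quantiles within each chromosome. Bins never span
    chromosomes; chromosomes with zero usable bases receive no bins.
    """
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    usable = {name: mappability.chrom_total(name) for name, _ in layout.chromosomes}
    total_usable = sum(usable.values())
    if total_usable <= 0:
        raise ValueError("mappability track has no usable bases")
    if n_bins > total_usable:
        raise ValueError("n_bins exceeds total usable bases")
    with_bases = [c for c in layout.names if usable[c] > 0]
    if len(with_bases) < len(layout.names):
        skipped = [c for c in layout.names if usable[c] <= 0]
        logger.warning("chromosomes with zero usable bases skipped: %s", ",".join(skipped))
    if n_bins < len(with_bases):
        raise ValueError("n_bins smaller than number of chromosomes with usable bases")

    alloc = _apportion(usable, n_bins, layout.names)
    chroms, starts_out, ends_out, mb = [], [], [], []
    for name, length in layout.chromosomes:
        n_k = alloc.get(name, 0)
        if n_k == 0:
            continue
        s, e, v = mappability.data.get(name, (np.array([]), np.array([]), np.array([])))
        bounds = [0] + _boundaries_in_chrom(s, e, v, length, n_k) + [length]
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            chroms.append(name)
            starts_out.append(b0)
            ends_out.append(b1)
            mb.append(int(round(mappability.integral(name, b0, b1))))
    assert len(chroms) == n_bins, "apportionment must yield the exact requested bin count"
    gc, _, masked = _empty_annotation(len(chroms))
    return BinScheme(
        layout=layout,
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts_out, dtype=np.int64),
        end=np.array(ends_out, dtype=np.int64),
        gc=gc,
        mappable_bases=np.array(mb, dtype=np.int64),
        masked=masked,
        scheme_kind="equal_mappable",
    )


def annotate_bins(scheme: BinScheme, gc_track: Track, mappability_track: Track) -> BinScheme:
    """Fill per-bin GC fraction and mappable-base counts from tracks.

    Bins whose GC is undefined over their whole span (e.g. all-N sequence,
    represented as track gaps) are flagged masked.
    """
    n = scheme.n_bins
    gc = np.full(n, np.nan)
    mb = np.zeros(n, dtype=np.int64)
    masked = scheme.masked.copy()
    for i in range(n):
        c, s, e = str(scheme.chrom[i]), int(scheme.start[i]), int(scheme.end[i])
        g = gc_track.mean(c, s, e)
        if np.isnan(g):
            masked[i] = True
        elif not (0.0 <= g <= 1.0):
            raise ValueError(f"GC fraction out of [0,1] for bin {c}:{s}-{e}")
        gc[i] = g
        mb[i] = int(round(mappability_track.integral(c, s, e)))
        if mb[i] > e - s:
            raise ValueError(f"mappable bases exceed bin width for {c}:{s}-{e}")
    return replace(scheme, gc=gc, mappable_bases=mb, masked=masked)


def mask_bins(scheme: BinScheme, min_mappable_fraction: float = DEFAULT_MIN_MAPPABLE_FRACTION) -> BinScheme:
    """Mask bins whose mappable fraction falls below the threshold."""
    if not 0.0 <= min_mappable_fraction <= 1.0:
        raise ValueError("min_mappable_fraction must be in [0,1]")
    frac = scheme.mappable_bases / scheme.widths
    masked = scheme.masked | (frac < min_mappable_fraction)
    return replace(scheme, masked=masked)
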
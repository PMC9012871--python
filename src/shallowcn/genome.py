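"""Genome layout and per-interval genomic tracks (bedGraph / fixed-step wiggle)."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

# chromosome names treated as sex chromosomes when deciding autosome-only stats
_SEX_CHROM = re.compile(r"^(chr)?[XYZW]$", re.IGNORECASE)


def is_autosome(name: str) -> bool:
    return _SEX_CHROM.match(name) is None


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes; the order defines genome-wide bin order.

    Parameters
    ----------
    chromosomes:
        Ordered list of ``(name, length)`` pairs. Names must be unique and
        lengths positive.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        if not chroms:
            raise ValueError("empty genome layout")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be > 0")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length_of(self, name: str) -> int:
        return self.lengths[name]

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        """Read a two-column chrom/length TSV (no header)."""
        chroms = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"malformed layout line: {line!r}")
                chroms.append((fields[0], int(fields[1])))
        return cls(chroms)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")


@dataclass
class Track:
    """Per-chromosome interval-valued track (bedGraph semantics, 0-based half-open).

    Intervals within a chromosome are stored sorted and non-overlapping;
    positions not covered by any interval have undefined value (NaN when
    queried).
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if not (len(starts) == len(ends) == len(values)):
            raise ValueError("starts/ends/values length mismatch")
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(ends <= starts):
            raise ValueError(f"empty or inverted interval on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping intervals on {chrom}")
        self.data[chrom] = (starts, ends, values)

    def chrom_total(self, chrom: str) -> float:
        """Integral of the track over one chromosome (value x width)."""
        if chrom not in self.data:
            return 0.0
        s, e, v = self.data[chrom]
        return float(np.sum(v * (e - s)))

    def total(self) -> float:
        return sum(self.chrom_total(c) for c in self.data)

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Integral of value over [start, end); uncovered bases contribute 0."""
        if chrom not in self.data:
            return 0.0
        s, e, v = self.data[chrom]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if lo >= hi:
            return 0.0
        ss = np.maximum(s[lo:hi], start)
        ee = np.minimum(e[lo:hi], end)
        return float(np.sum(v[lo:hi] * np.maximum(ee - ss, 0)))

    def covered_bases(self, chrom: str, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by any interval."""
        if chrom not in self.data:
            return 0
        s, e, _ = self.data[chrom]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if lo >= hi:
            return 0
        ss = np.maximum(s[lo:hi], start)
        ee = np.minimum(e[lo:hi], end)
        return int(np.sum(np.maximum(ee - ss, 0)))

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Coverage-weighted mean value over [start, end); NaN if uncovered."""
        nb = self.covered_bases(chrom, start, end)
        if nb == 0:
            return float("nan")
        return self.integral(chrom, start, end) / nb

    @classmethod
    def from_bedgraph(cls, path) -> "Track":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                c, s, e, v = line.split("\t")[:4]
                per_chrom.setdefault(c, []).append((int(s), int(e), float(v)))
        track = cls()
        for chrom, rows in per_chrom.items():
            track.add(chrom, [r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows])
        return track

    @classmethod
    def from_wiggle(cls, path) -> "Track":
        """Read a fixedStep wiggle file."""
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        chrom, pos, step, span = None, 0, 1, 1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    params = dict(kv.split("=") for kv in line.split()[1:])
                    chrom = params["chrom"]
                    pos = int(params["start"]) - 1  # wiggle is 1-based
                    step = int(params.get("step", 1))
                    span = int(params.get("span", step))
                    continue
                if chrom is None:
                    raise ValueError("wiggle data before fixedStep header")
                per_chrom.setdefault(chrom, []).append((pos, pos + span, float(line)))
                pos += step
        track = cls()
        for c, rows in per_chrom.items():
            track.add(c, [r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows])
        return track

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, (s, e, v) in self.data.items():
                for i in range(len(s)):
                    fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")
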
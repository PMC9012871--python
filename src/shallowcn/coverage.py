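"""Per-bin fragment counting and fragment-length extraction from alignments.

The count unit is the read PAIR (one cfDNA fragment), assigned to the bin
containing its leftmost mapped base. Duplicates are excluded and a MAPQ
floor applied by default. Depth profiles round-trip through a TSV matrix
(bin key columns then one column per sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from shallowcn.bins import BinScheme

DEFAULT_MIN_MAPQ = 20
DEFAULT_MAX_FRAGMENT_LENGTH = 1000


@dataclass
class DepthProfile:
    """Per-bin fragment counts for one sample on one bin scheme."""

    sample_id: str
    counts: np.ndarray  # float, one per bin, non-negative finite

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("depth counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("depth counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class FragmentLengths:
    """Multiset of fragment (template) lengths for one sample."""

    sample_id: str
    lengths: np.ndarray  # int, all > 0

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if self.lengths.size and np.any(self.lengths <= 0):
            raise ValueError("fragment lengths must be positive")


def _open_alignment(path):
    mode = "r" if str(path).endswith(".sam") else "rb"
    return pysam.AlignmentFile(str(path), mode, check_sq=False)


def count_reads_per_bin(
    alignments,
    scheme: BinScheme,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    dedup: bool = True,
) -> DepthProfile:
    """Count properly paired fragments per bin by leftmost mapped base.

    Each passing pair is counted exactly once (via its leftmost read, the
    one with positive template length). Masked bins are still counted;
    masking is applied downstream.
    """
    starts_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sl in scheme.chrom_slices():
        starts_by_chrom[chrom] = (scheme.start[sl], np.arange(sl.start, sl.stop))
    counts = np.zeros(scheme.n_bins)
    known = set(scheme.layout.names)
    bad_chroms: set[str] = set()
    with _open_alignment(alignments) as af:
        sample = af.header.get("RG", [{}])
        sample_id = sample[0].get("SM", "sample") if sample else "sample"
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or not read.is_paired or not read.is_proper_pair:
                continue
            if read.is_secondary or read.is_supplementary:
                continue
            if dedup and read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.template_length <= 0:  # count the leftmost mate only
                continue
            chrom = read.reference_name
            if chrom not in known:
                bad_chroms.add(chrom)
                continue
            if chrom not in starts_by_chrom:
                continue
            bin_starts, bin_idx = starts_by_chrom[chrom]
            pos = read.reference_start
            j = int(np.searchsorted(bin_starts, pos, side="right")) - 1
            if j < 0:
                continue
            gi = int(bin_idx[j])
            if pos < scheme.end[gi]:
                counts[gi] += 1
    if bad_chroms:
        raise ValueError(
            "alignment chromosomes absent from layout: " + ",".join(sorted(bad_chroms))
        )
    return DepthProfile(sample_id=sample_id, counts=counts)


def extract_fragment_lengths(
    alignments,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    max_length: int = DEFAULT_MAX_FRAGMENT_LENGTH,
) -> FragmentLengths:
    """Absolute template lengths of proper pairs, one per pair, in (0, max_length]."""
    lengths = []
    saw_paired = False
    saw_any = False
    with _open_alignment(alignments) as af:
        sample = af.header.get("RG", [{}])
        sample_id = sample[0].get("SM", "sample") if sample else "sample"
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            saw_any = True
            if not read.is_paired:
                continue
            saw_paired = True
            if not read.is_proper_pair or read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            tlen = read.template_length
            if tlen <= 0:  # one entry per pair, taken from the leftmost mate
                continue
            if tlen <= max_length:
                lengths.append(tlen)
    if saw_any and not saw_paired:
        raise ValueError("single-end data: fragment length undefined")
    return FragmentLengths(sample_id=sample_id, lengths=np.array(lengths, dtype=np.int64))


def write_depth_table(profiles: list[DepthProfile], scheme: BinScheme, path) -> None:
    """Write bin key columns plus one count column per sample."""
    df = pd.DataFrame({"chrom": scheme.chrom, "start": scheme.start, "end": scheme.end})
    for p in profiles:
        if len(p.counts) != scheme.n_bins:
            raise ValueError(f"profile {p.sample_id} length mismatch vs scheme")
        df[p.sample_id] = p.counts
    df.to_csv(path, sep="\t", index=False)


def load_depth_table(path, scheme: BinScheme) -> list[DepthProfile]:
    """Read a depth matrix back, validating bin order against the scheme."""
    df = pd.read_csv(path, sep="\t")
    if len(df) != scheme.n_bins:
        raise ValueError(
            f"depth table has {len(df)} rows but scheme has {scheme.n_bins} bins"
        )
    mism = (df["chrom"].to_numpy(dtype=object) != scheme.chrom) | (
        df["start"].to_numpy() != scheme.start
    )
    if np.any(mism):
        i = int(np.flatnonzero(mism)[0])
        raise ValueError(
            f"bin mismatch at row {i}: table {df['chrom'][i]}:{df['start'][i]} vs "
            f"scheme {scheme.chrom[i]}:{scheme.start[i]}"
        )
    samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
    profiles = []
    for s in samples:
        col = pd.to_numeric(df[s], errors="raise").to_numpy(dtype=float)
        profiles.append(DepthProfile(sample_id=s, counts=col))
    return profiles


def write_fragment_lengths(frags: FragmentLengths, path) -> None:
    pd.DataFrame({"length": frags.lengths}).to_csv(path, sep="\t", index=False)


def load_fragment_lengths(path, sample_id: str = "sample") -> FragmentLengths:
    df = pd.read_csv(path, sep="\t")
    return FragmentLengths(sample_id=sample_id, lengths=df["length"].to_numpy(dtype=np.int64))
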
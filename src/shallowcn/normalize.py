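"""GC-bias correction and panel-of-normals depth normalization.

Raw per-bin fragment counts are corrected for GC bias by dividing out a
local-regression (lowess) curve of count versus GC, library-size scaled,
and expressed as median-centered log2 ratios against a panel of healthy
controls. Two panel modes are supported: per-bin median of the controls
(default) and a merged-total reference built from the pooled controls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from shallowcn.bins import BinScheme
from shallowcn.coverage import DepthProfile

logger = logging.getLogger(__name__)

DEFAULT_LOWESS_SPAN = 0.3
LOG_PSEUDOCOUNT = 1.0
MIN_BINS_FOR_GC_FIT = 50


@dataclass
class PanelOfNormals:
    """Per-bin reference depth built from healthy controls."""

    reference: np.ndarray  # per-bin reference level, library-size scale of the panel
    dispersion: np.ndarray  # per-bin MAD across controls (zeros in merged mode)
    n_controls: int
    mode: str  # "median" | "merged"
    valid: np.ndarray  # bins usable for normalization

    def to_tsv(self, scheme: BinScheme, path) -> None:
        pd.DataFrame(
            {
                "chrom": scheme.chrom,
                "start": scheme.start,
                "end": scheme.end,
                "reference": self.reference,
                "dispersion": self.dispersion,
                "valid": self.valid.astype(int),
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, n_controls: int = 0, mode: str = "median") -> "PanelOfNormals":
        df = pd.read_csv(path, sep="\t")
        return cls(
            reference=df["reference"].to_numpy(dtype=float),
            dispersion=df["dispersion"].to_numpy(dtype=float),
            n_controls=n_controls,
            mode=mode,
            valid=df["valid"].to_numpy(dtype=bool),
        )


@dataclass
class NormalizedProfile:
    """Median-centered per-bin log2 depth ratios with a validity mask."""

    sample_id: str
    log2_ratio: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(~np.isfinite(self.log2_ratio[self.valid])):
            raise ValueError("log2 ratios must be finite on valid bins")

    def to_tsv(self, scheme: BinScheme, path) -> None:
        pd.DataFrame(
            {
                "chrom": scheme.chrom,
                "start": scheme.start,
                "end": scheme.end,
                "log2_ratio": self.log2_ratio,
                "valid": self.valid.astype(int),
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, sample_id: str = "sample") -> "NormalizedProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            sample_id=sample_id,
            log2_ratio=df["log2_ratio"].to_numpy(dtype=float),
            valid=df["valid"].to_numpy(dtype=bool),
        )


def correct_gc(
    profile: DepthProfile, scheme: BinScheme, span: float = DEFAULT_LOWESS_SPAN
) -> DepthProfile:
    """Divide out a lowess curve of count-vs-GC; total count is conserved.

    The curve is fit on unmasked autosomal bins with defined GC and
    evaluated for every bin with defined GC by interpolation; predictions
    are clamped to be positive. Bins without GC pass through unchanged.
    """
    gc = scheme.gc
    fit_mask = (~scheme.masked) & scheme.autosomal & np.isfinite(gc)
    if fit_mask.sum() < MIN_BINS_FOR_GC_FIT:
        raise ValueError(
            f"need >= {MIN_BINS_FOR_GC_FIT} unmasked annotated bins for GC fit, "
            f"got {int(fit_mask.sum())}"
        )
    x = gc[fit_mask]
    y = profile.counts[fit_mask]
    if np.ptp(x) == 0:
        warnings.warn("all bins share one GC value; GC correction is the identity")
        return DepthProfile(sample_id=profile.sample_id, counts=profile.counts.copy())
    fitted = lowess(y, x, frac=span, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    floor = max(np.median(y) * 1e-3, 1e-9)
    apply_mask = np.isfinite(gc)
    pred = np.interp(gc[apply_mask], xs, np.maximum(ys, floor))
    corrected = profile.counts.copy()
    corrected[apply_mask] = profile.counts[apply_mask] / np.maximum(pred, floor)
    # rescale so the total count over corrected bins is conserved
    before = profile.counts[apply_mask].sum()
    after = corrected[apply_mask].sum()
    if after > 0:
        corrected[apply_mask] *= before / after
    return DepthProfile(sample_id=profile.sample_id, counts=corrected)


def _library_scale(counts: np.ndarray, mask: np.ndarray, target: float) -> np.ndarray:
    tot = counts[mask].sum()
    if tot <= 0:
        raise ValueError("profile has zero total depth over usable bins")
    return counts * (target / tot)


def build_panel(
    controls: list[DepthProfile],
    scheme: BinScheme,
    mode: str = "median",
    span: float = DEFAULT_LOWESS_SPAN,
) -> PanelOfNormals:
    """Build a panel of normals from healthy-control depth profiles.

    ``median`` mode GC-corrects each control, scales all to a common
    library size, and stores per-bin median and MAD. ``merged`` mode pools
    the raw control counts into one virtual sample first, then GC-corrects
    the pool. Bins where any control has zero raw depth are invalidated.
    """
    if len(controls) < 2:
        raise ValueError("panel requires at least 2 controls")
    for c in controls:
        if len(c.counts) != scheme.n_bins:
            raise ValueError(f"control {c.sample_id} not on the panel's bin scheme")
    if mode not in ("median", "merged"):
        raise ValueError(f"unknown panel mode: {mode}")
    usable = ~scheme.masked
    raw = np.vstack([c.counts for c in controls])
    any_zero = np.any(raw == 0, axis=0)
    valid = usable & ~any_zero

    target = float(np.median([c.counts[usable].sum() for c in controls]))
    if mode == "median":
        corrected = np.vstack(
            [
                _library_scale(correct_gc(c, scheme, span=span).counts, usable, target)
                for c in controls
            ]
        )
        reference = np.median(corrected, axis=0)
        dispersion = np.median(np.abs(corrected - reference), axis=0)
    else:
        merged = DepthProfile(sample_id="merged_controls", counts=raw.sum(axis=0))
        corr = correct_gc(merged, scheme, span=span).counts
        reference = _library_scale(corr, usable, target)
        dispersion = np.zeros_like(reference)
    valid &= reference > 0
    return PanelOfNormals(
        reference=reference,
        dispersion=dispersion,
        n_controls=len(controls),
        mode=mode,
        valid=valid,
    )


def to_log2_ratio(
    profile: DepthProfile, pon: PanelOfNormals, scheme: BinScheme
) -> NormalizedProfile:
    """log2((count + eps) / (reference + eps)), median-centered on autosomes.

    The input profile must already be GC-corrected; it is library-size
    scaled onto the panel's scale here. (With a large fraction of the
    genome altered the median baseline sits slightly off the neutral peak;
    the HMM estimates that residual offset as a nuisance parameter.)
    """
    valid = pon.valid & ~scheme.masked
    if not valid.any():
        raise ValueError("all bins masked; cannot normalize")
    scaled = _library_scale(profile.counts, valid, pon.reference[valid].sum())
    eps = LOG_PSEUDOCOUNT
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2((scaled + eps) / (pon.reference + eps))
    r[~valid] = np.nan
    center_mask = valid & scheme.autosomal
    if not center_mask.any():
        center_mask = valid
    r = r - np.nanmedian(r[center_mask])
    return NormalizedProfile(sample_id=profile.sample_id, log2_ratio=r, valid=valid)


def normalize_profile(
    profile: DepthProfile,
    pon: PanelOfNormals,
    scheme: BinScheme,
    span: float = DEFAULT_LOWESS_SPAN,
) -> NormalizedProfile:
    """Convenience: GC-correct then convert to panel-normalized log2 ratios."""
    return to_log2_ratio(correct_gc(profile, scheme, span=span), pon, scheme)
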
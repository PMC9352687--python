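"""Conversion of segmented log2 ratios to absolute copy numbers.

A sample with tumor purity ``alpha`` and mean tumor ploidy ``tau`` mixes
tumor cells (copy number ``q`` per segment) with diploid normal cells.  The
relative copy number of a segment is then

    r = (alpha * q + 2 * (1 - alpha)) / (alpha * tau + 2 * (1 - alpha))

and the inverse used here is

    q = (r * (alpha * tau + 2 * (1 - alpha)) - 2 * (1 - alpha)) / alpha.

Negative ``q`` values are deliberately not clamped: the grid search may
probe mis-specified (alpha, tau) and the transform stays affine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .profiles import GenomeModel, GenomicInterval, SegmentedProfile


@dataclass(frozen=True)
class PurityPloidy:
    """A candidate tumor purity (0 < purity <= 1) and mean ploidy (> 0)."""

    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.purity) and math.isfinite(self.ploidy)):
            raise ValueError("purity and ploidy must be finite")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0.0:
            raise ValueError(f"ploidy must be positive, got {self.ploidy}")


@dataclass(frozen=True)
class AbsoluteProfile:
    """A profile's segments carrying purity/ploidy-corrected copy numbers."""

    sample_id: str
    genome: GenomeModel
    intervals: tuple[GenomicInterval, ...]
    copy_numbers: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.intervals) == 0:
            raise ValueError("absolute profile has no segments")
        if len(self.copy_numbers) != len(self.intervals) or len(self.weights) != len(
            self.intervals
        ):
            raise ValueError("array lengths must match the interval count")
        if not np.all(np.isfinite(self.copy_numbers)):
            raise ValueError("copy numbers must be finite")


def logr_to_relative(log_ratio):
    """Relative copy number ``r = 2**log_ratio``; accepts scalars or arrays."""
    arr = np.asarray(log_ratio, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("log ratio must be finite")
    out = np.exp2(arr)
    return float(out) if np.isscalar(log_ratio) or arr.ndim == 0 else out


def relative_to_absolute(r, pp: PurityPloidy):
    """Absolute copy number under (purity, ploidy); ``r = 1`` maps to ploidy."""
    alpha, tau = pp.purity, pp.ploidy
    arr = np.asarray(r, dtype=float)
    normal = 2.0 * (1.0 - alpha)
    out = (arr * (alpha * tau + normal) - normal) / alpha
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def transform_profile(
    profile: SegmentedProfile,
    pp: PurityPloidy,
    *,
    normalize: bool = True,
    weight_mode: str = "bp",
) -> AbsoluteProfile:
    """Apply the log2 -> relative -> absolute transform segment-wise.

    With ``normalize=True`` (default) the relative copy numbers are first
    rescaled so their weighted mean is exactly 1, matching the centering of
    segmentation output; the implied ploidy of the result then equals
    ``pp.ploidy`` identically.
    """
    w = profile.weights(weight_mode)
    r = logr_to_relative(profile.log_ratios)
    if normalize:
        r = r / (float(w @ r) / float(w.sum()))
    q = relative_to_absolute(r, pp)
    return AbsoluteProfile(profile.sample_id, profile.genome, profile.intervals, q, w)


def implied_ploidy(abs_profile: AbsoluteProfile) -> float:
    """Weighted mean copy number of an absolute profile."""
    return float(
        (abs_profile.weights @ abs_profile.copy_numbers) / abs_profile.weights.sum()
    )
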
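"""Invasion-front geometry from binary masks.

The scratch-assay readout is a binary image in which label 1 marks the
invading cell compartment advancing downward into a fibroblast monolayer.
The undisturbed front at time 0 defines a baseline row; per horizontal
position, invasion depth is how far the deepest labeled pixel sits below
that baseline, in micrometers. Deep invasive forks are the positions whose
depth exceeds a threshold (strictly), with 100 um and 200 um the standard
cutoffs; conditions are compared replicate-wise with an exact rank test.

Depth uses the deepest labeled pixel per column, so detached invading
columns still count toward fork depth; a ``contiguous`` flag restricts to
the unbroken front instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "InvasionMask",
    "FrontProfile",
    "read_mask",
    "write_mask",
    "front_profile",
    "depth_histogram",
    "count_deep_forks",
    "compare_conditions",
    "estimate_baseline_otsu",
]


@dataclass
class InvasionMask:
    """Binary invasion image: label 1 = invading compartment, invading downward."""

    pixels: np.ndarray
    pixel_size_um: float
    baseline_row: int

    def __post_init__(self):
        self.pixels = (np.asarray(self.pixels) > 0).astype(np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a single-channel 2-D image")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0 <= self.baseline_row < self.pixels.shape[0]:
            raise ValueError("baseline_row outside the image")


@dataclass
class FrontProfile:
    """Per-horizontal-position invasion depth beyond the baseline (um, >= 0)."""

    positions_um: np.ndarray
    depths_um: np.ndarray

    def __post_init__(self):
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        if (self.depths_um < 0).any():
            raise ValueError("depths must be >= 0")

    @property
    def n_positions(self) -> int:
        return self.depths_um.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_um": self.positions_um, "depth_um": self.depths_um})


def read_mask(path, pixel_size_um: float, baseline_row: int) -> InvasionMask:
    """Read an 8/16-bit single-channel PNG or TIFF mask (any nonzero = invading)."""
    import imageio.v3 as iio

    arr = iio.imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return InvasionMask(arr, pixel_size_um, baseline_row)


def write_mask(mask: InvasionMask, path) -> None:
    import imageio.v3 as iio

    arr = (mask.pixels > 0).astype(np.uint8) * 255
    iio.imwrite(str(Path(path)), arr)


def front_profile(
    mask: InvasionMask,
    stride_px: int = 1,
    smooth: int = 0,
    despeckle_px: int = 0,
    contiguous: bool = False,
) -> FrontProfile:
    """Per-column invasion depth of the front.

    For every ``stride_px``-th column, depth = (deepest row carrying the
    invading label - baseline_row) * pixel size, floored at 0; columns with
    no label report 0. ``despeckle_px`` (odd) applies a 2-D median filter to
    the mask first — the deepest-pixel rule is maximally sensitive to salt
    noise, so isolated flipped pixels must be removed spatially, not on the
    1-D profile. ``smooth`` (odd, in columns) additionally median-filters
    the sampled depth profile. ``contiguous`` measures the unbroken front
    from the baseline instead of the deepest (possibly detached) pixel.
    """
    if stride_px < 1:
        raise ValueError("stride_px must be >= 1")
    for name, v in (("smooth", smooth), ("despeckle_px", despeckle_px)):
        if v and v % 2 == 0:
            raise ValueError(f"{name} must be odd or 0")
    px = mask.pixels
    if despeckle_px:
        px = ndimage.median_filter(px, size=despeckle_px, mode="nearest")
    h, w = px.shape
    cols = np.arange(0, w, stride_px)
    sub = px[:, cols].astype(bool)
    rows = np.arange(h)[:, None]
    if contiguous:
        below = sub[mask.baseline_row :, :]
        run = np.cumprod(below, axis=0)  # 1 while unbroken from the baseline row
        depth_px = run.sum(axis=0) - 1  # exclude the baseline row itself
        depth_px = np.maximum(depth_px, 0)
    else:
        deepest = np.where(sub.any(axis=0), np.max(np.where(sub, rows, -1), axis=0), -1)
        depth_px = np.maximum(deepest - mask.baseline_row, 0)
        depth_px[deepest < 0] = 0
    depths = depth_px.astype(float) * mask.pixel_size_um
    if smooth:
        depths = ndimage.median_filter(depths, size=smooth, mode="nearest")
    positions = cols.astype(float) * mask.pixel_size_um
    return FrontProfile(positions, depths)


def depth_histogram(profile: FrontProfile, bin_width_um: float) -> pd.DataFrame:
    """Depth frequency table over half-open bins [lo, hi); total = n_positions."""
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    d = profile.depths_um
    n_bins = max(1, int(np.floor(d.max() / bin_width_um)) + 1) if d.size else 1
    edges = np.arange(n_bins + 1) * bin_width_um
    counts, _ = np.histogram(d, bins=edges)
    # np.histogram closes the last bin; values equal to the last edge cannot
    # occur because edges extend past max(d).
    return pd.DataFrame({"depth_lo_um": edges[:-1], "depth_hi_um": edges[1:], "count": counts})


def count_deep_forks(profile: FrontProfile, threshold_um: float) -> int:
    """Number of sampled positions invading strictly deeper than the threshold."""
    if threshold_um < 0:
        raise ValueError("threshold_um must be >= 0")
    return int((profile.depths_um > threshold_um).sum())


def summarize_profile(profile: FrontProfile, statistic: str, threshold_um: float) -> float:
    if statistic == "mean_depth":
        return float(profile.depths_um.mean()) if profile.n_positions else 0.0
    if statistic == "deep_fraction":
        if profile.n_positions == 0:
            return 0.0
        return count_deep_forks(profile, threshold_um) / profile.n_positions
    raise ValueError(f"unknown statistic {statistic!r}")


def compare_conditions(
    a: list[FrontProfile],
    b: list[FrontProfile],
    statistic: str = "mean_depth",
    threshold_um: float = 100.0,
) -> tuple[float, float | None]:
    """Replicate-level comparison of two conditions (e.g. scrambled vs silenced).

    Each profile is collapsed to one summary per replicate (mean depth, or
    fraction of positions deeper than the threshold); the two replicate sets
    are compared with an exact two-sided Mann-Whitney rank test. Returns
    (effect, p) with effect = mean(b) - mean(a); p is None when either arm
    has a single replicate.
    """
    if not a or not b:
        raise ValueError("both conditions need at least one profile")
    sa = np.array([summarize_profile(p, statistic, threshold_um) for p in a])
    sb = np.array([summarize_profile(p, statistic, threshold_um) for p in b])
    effect = float(sb.mean() - sa.mean())
    if len(sa) < 2 or len(sb) < 2:
        return effect, None
    method = "exact" if (len(sa) + len(sb)) <= 16 else "auto"
    res = stats.mannwhitneyu(sa, sb, alternative="two-sided", method=method)
    return effect, float(res.pvalue)


def estimate_baseline_otsu(image: np.ndarray) -> int:
    """Convenience baseline estimator for a time-0 grayscale frame.

    Binarizes at the Otsu threshold and takes the median over columns of the
    deepest labeled row. The assay's scratch edge defines the true baseline;
    prefer supplying it explicitly.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    mask = img > threshold_otsu(img)
    h = img.shape[0]
    rows = np.arange(h)[:, None]
    deepest = np.where(mask.any(axis=0), np.max(np.where(mask, rows, -1), axis=0), -1)
    return int(np.median(deepest[deepest >= 0]))
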
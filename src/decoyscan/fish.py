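"""Single-molecule FISH spot quantification in 3D image stacks.

The detection pipeline mirrors the classic single-molecule counting
recipe: the stack is filtered with a 3D Laplacian-of-Gaussian kernel
(support 15 px, sigma 1.5 px, negated so bright diffraction-limited spots
become positive peaks), binary images are formed over a uniform grid of
intensity thresholds, and the threshold where the connected-component
count is least sensitive to the choice of threshold is selected
automatically.  Components at that threshold become spots; background is
removed by size and by cross-channel co-occurrence; and spots are split
into nuclear vs cytoplasmic by a DAPI-derived nuclear mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

#: 26-connectivity structuring element for 3D component labelling.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class NoSignalError(ValueError):
    """Raised when a filtered stack has no dynamic range to threshold."""


@dataclass
class ImageStack:
    """A single-channel 3D stack, (z, y, x), with physical voxel sizes."""

    voxels: np.ndarray
    pixel_size_xy: float = 0.13  # micrometres
    z_spacing: float = 0.3  # micrometres
    channel: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("stack must be 3D (z, y, x)")
        if (self.voxels < 0).any():
            raise ValueError("negative intensities")


@dataclass
class ThresholdCurve:
    thresholds: np.ndarray
    component_counts: np.ndarray
    stability: np.ndarray  # smoothed |d(count)/d(threshold)|
    selected_threshold: float
    selected_index: int


@dataclass(frozen=True)
class Spot:
    z: float
    y: float
    x: float
    n_voxels: int
    peak: float
    channel: str = ""
    compartment: str | None = None  # "nuclear" | "cytoplasmic"


@dataclass
class SpotSet:
    spots: list[Spot]
    channel: str = ""
    selected_threshold: float | None = None
    no_signal: bool = False

    def __len__(self) -> int:
        return len(self.spots)

    def compartment_fractions(self) -> dict[str, float] | None:
        labelled = [s for s in self.spots if s.compartment is not None]
        if not labelled:
            return None
        n_nuc = sum(s.compartment == "nuclear" for s in labelled)
        return {
            "nuclear": n_nuc / len(labelled),
            "cytoplasmic": 1 - n_nuc / len(labelled),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.z, s.y, s.x, s.n_voxels, s.peak, s.channel, s.compartment)
             for s in self.spots],
            columns=["z", "y", "x", "n_voxels", "peak", "channel",
                     "compartment"],
        )


def log_kernel_3d(size: int = 15, sigma: float = 1.5) -> np.ndarray:
    """Negated zero-sum 3D Laplacian-of-Gaussian kernel.

    Truncated to a ``size``^3 support and shifted to sum to zero, so the
    response to a constant stack is (numerically) zero; negated so bright
    blobs of scale ~sigma give positive peaks.
    """
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    half = size // 2
    zz, yy, xx = np.mgrid[-half:half + 1, -half:half + 1, -half:half + 1]
    r2 = (zz ** 2 + yy ** 2 + xx ** 2).astype(float)
    g = np.exp(-r2 / (2 * sigma ** 2))
    g /= g.sum()
    log = g * (r2 - 3 * sigma ** 2) / sigma ** 4
    log -= log.mean()
    return -log


def log_filter_3d(
    stack: "ImageStack | np.ndarray", size: int = 15, sigma: float = 1.5
) -> np.ndarray:
    """Filter a stack with the negated 3D LoG, reflective edge padding."""
    vox = stack.voxels if isinstance(stack, ImageStack) else np.asarray(
        stack, dtype=float)
    if vox.ndim != 3 or min(vox.shape) < 2:
        raise ValueError("stack must be 3D with every axis of length >= 2")
    kernel = log_kernel_3d(size=size, sigma=sigma)
    return ndimage.convolve(vox, kernel, mode="reflect")


def _count_components(binary: np.ndarray) -> int:
    return ndimage.label(binary, structure=STRUCT_26)[1]


def select_threshold(
    filtered: np.ndarray, n_thresholds: int = 100
) -> ThresholdCurve:
    """Choose the detection threshold where the component count is stable.

    Components (26-connectivity) are counted over a uniform grid of
    thresholds spanning the filtered response's range.  Stability is the
    absolute derivative of the count with respect to the threshold,
    smoothed with a centred 3-point moving average; a plateau (a maximal
    run of constant count, i.e. minimal stability) is *credible* when it
    holds at least two components and spans at least 5% of the grid.  The
    selected threshold is the centre of the longest credible plateau, with
    ties broken toward the lowest threshold; when no credible plateau
    exists (e.g. a noise-only stack, where every multi-component count is
    fleeting) the longest plateau overall is used instead.
    """
    filtered = np.asarray(filtered, dtype=float)
    lo, hi = float(filtered.min()), float(filtered.max())
    if not np.isfinite([lo, hi]).all() or hi - lo <= 0:
        raise NoSignalError("no signal: filtered stack has no dynamic range")
    thresholds = np.linspace(lo, hi, n_thresholds)
    counts = np.array([_count_components(filtered > t) for t in thresholds],
                      dtype=float)
    deriv = np.abs(np.gradient(counts, thresholds))
    stability = np.convolve(deriv, np.ones(3) / 3, mode="same")

    runs = []  # (start, length, count)
    i = 0
    while i < len(counts):
        j = i
        while j + 1 < len(counts) and counts[j + 1] == counts[i]:
            j += 1
        runs.append((i, j - i + 1, counts[i]))
        i = j + 1
    min_len = max(3, n_thresholds // 20)
    credible = [r for r in runs if r[2] >= 2 and r[1] >= min_len]
    pool = credible if credible else runs
    start, length, _ = max(pool, key=lambda r: (r[1], -r[0]))
    sel = start + (length - 1) // 2
    return ThresholdCurve(
        thresholds=thresholds,
        component_counts=counts.astype(int),
        stability=stability,
        selected_threshold=float(thresholds[sel]),
        selected_index=int(sel),
    )


def detect_spots(
    stack: "ImageStack | np.ndarray",
    channel: str | None = None,
    size: int = 15,
    sigma: float = 1.5,
    n_thresholds: int = 100,
) -> SpotSet:
    """Detect diffraction-limited spots in one channel of a 3D stack.

    An all-flat stack is a "no signal" outcome: an empty SpotSet with
    ``no_signal=True``, not an error.
    """
    if isinstance(stack, ImageStack):
        channel = channel if channel is not None else stack.channel
        vox = stack.voxels
    else:
        vox = np.asarray(stack, dtype=float)
        channel = channel or ""
    filtered = log_filter_3d(vox, size=size, sigma=sigma)
    try:
        curve = select_threshold(filtered, n_thresholds=n_thresholds)
    except NoSignalError:
        return SpotSet(spots=[], channel=channel, no_signal=True)

    labels, n = ndimage.label(filtered > curve.selected_threshold,
                              structure=STRUCT_26)
    spots = []
    if n:
        idx = np.arange(1, n + 1)
        # intensity-weighted centroids on the positive filtered response
        weights = np.clip(filtered, 0, None)
        centroids = ndimage.center_of_mass(weights, labels, idx)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, idx)
        peaks = ndimage.maximum(vox, labels, idx)
        for (z, y, x), nv, pk in zip(centroids, sizes, peaks):
            spots.append(Spot(z=float(z), y=float(y), x=float(x),
                              n_voxels=int(nv), peak=float(pk),
                              channel=channel))
    return SpotSet(spots=spots, channel=channel,
                   selected_threshold=curve.selected_threshold)


def remove_background(
    spotsets: list[SpotSet],
    min_voxels: int = 2,
    max_voxels: int = 100,
    co_occurrence_radius_px: float = 2.0,
) -> tuple[list[SpotSet], float]:
    """Drop background spots by size and cross-channel co-occurrence.

    Spots outside ``[min_voxels, max_voxels]`` are removed, as are spots
    whose centroid lies within the given radius (voxel units) of a spot
    centroid in *another* channel.  Returns the filtered spot sets and the
    overall removed fraction.
    """
    total = sum(len(ss) for ss in spotsets)
    sized = [
        [s for s in ss.spots if min_voxels <= s.n_voxels <= max_voxels]
        for ss in spotsets
    ]
    trees = [
        cKDTree([(s.z, s.y, s.x) for s in spots]) if spots else None
        for spots in sized
    ]
    out = []
    kept_n = 0
    for i, (ss, spots) in enumerate(zip(spotsets, sized)):
        kept = []
        for s in spots:
            shared = any(
                trees[j] is not None
                and trees[j].query_ball_point((s.z, s.y, s.x),
                                              co_occurrence_radius_px)
                for j in range(len(spotsets)) if j != i
            )
            if not shared:
                kept.append(s)
        kept_n += len(kept)
        out.append(replace(ss, spots=kept))
    removed_fraction = 0.0 if total == 0 else 1 - kept_n / total
    return out, removed_fraction


def nuclear_mask_from_dapi(dapi: "ImageStack | np.ndarray") -> np.ndarray:
    """2D nuclear mask: Otsu threshold of the max-z DAPI projection,
    holes filled."""
    vox = dapi.voxels if isinstance(dapi, ImageStack) else np.asarray(
        dapi, dtype=float)
    proj = vox.max(axis=0)
    if proj.max() <= proj.min():
        raise NoSignalError("flat DAPI channel")
    mask = proj > threshold_otsu(proj)
    return ndimage.binary_fill_holes(mask)


def assign_compartment(
    spotset: SpotSet, dapi: "ImageStack | np.ndarray | None"
) -> SpotSet:
    """Label each spot nuclear or cytoplasmic via the DAPI nuclear mask.

    A spot is nuclear iff its (y, x) centroid falls inside the mask.  With
    no DAPI channel the labels are omitted with a warning.
    """
    if dapi is None:
        warnings.warn("no DAPI channel: compartment labels omitted")
        return spotset
    mask = nuclear_mask_from_dapi(dapi)
    spots = []
    for s in spotset.spots:
        yi = int(np.clip(round(s.y), 0, mask.shape[0] - 1))
        xi = int(np.clip(round(s.x), 0, mask.shape[1] - 1))
        comp = "nuclear" if mask[yi, xi] else "cytoplasmic"
        spots.append(replace(s, compartment=comp))
    return replace(spotset, spots=spots)


def read_stack(path: str | Path, channel: str = "",
               pixel_size_xy: float = 0.13,
               z_spacing: float = 0.3) -> ImageStack:
    """Read a multi-page TIFF z-stack into an ImageStack."""
    import tifffile

    vox = np.asarray(tifffile.imread(str(path)), dtype=float)
    if vox.ndim == 2:
        vox = vox[None]
    return ImageStack(voxels=vox, pixel_size_xy=pixel_size_xy,
                      z_spacing=z_spacing, channel=channel)
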
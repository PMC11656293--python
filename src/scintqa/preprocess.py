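"""Frame preprocessing: dark/pulse sorting, hot-pixel repair, background removal.

The camera is triggered on beam extraction, not beam presence, so a sizeable
fraction of frames are dark.  Pulse frames are identified by a connected
cluster of more than ``min_cluster`` pixels (default 50, strict) each above
the global dark standard deviation after mean-dark subtraction.  Hot pixels
(scattered radiation hitting the sensor) are found from their intensity and
spatial gradient and replaced by the neighbourhood median.  The static
background is the mean dark image; residual per-line drift is removed by
subtracting, for every sensor row, the mean of the leftmost margin columns
(a dark area that never sees scintillation light).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label

from .simulate import FrameStack, GeometryConfig

__all__ = [
    "DarkModel",
    "CleanPulseImage",
    "build_dark_model",
    "classify_frames",
    "repair_hot_pixels",
    "subtract_background",
    "preprocess_stack",
]


@dataclass(frozen=True)
class DarkModel:
    """Static dark-frame model: per-pixel mean image and one global sd."""

    mean_image: np.ndarray
    sd: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("dark model needs at least one frame")
        if self.sd <= 0:
            raise ValueError("dark sd must be > 0")


@dataclass
class CleanPulseImage:
    """A background-corrected pulse image with its view sub-regions.

    ``direct_bounds`` / ``mirror_bounds`` are (row0, row1, col0, col1)
    half-open slices into ``pixels``; they are disjoint and exclude the
    dark-margin columns.
    """

    pixels: np.ndarray  # float counts
    timestamp: float
    direct_bounds: tuple[int, int, int, int]
    mirror_bounds: tuple[int, int, int, int]
    n_hot_repaired: int = 0

    def __post_init__(self) -> None:
        h, w = self.pixels.shape
        for r0, r1, c0, c1 in (self.direct_bounds, self.mirror_bounds):
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError("view region outside the frame")
        dr0, dr1, dc0, dc1 = self.direct_bounds
        mr0, mr1, mc0, mc1 = self.mirror_bounds
        if not (dc0 >= mc1 or mc0 >= dc1 or dr0 >= mr1 or mr0 >= dr1):
            raise ValueError("view regions overlap")

    def direct_view(self) -> np.ndarray:
        r0, r1, c0, c1 = self.direct_bounds
        return self.pixels[r0:r1, c0:c1]

    def mirror_view(self) -> np.ndarray:
        r0, r1, c0, c1 = self.mirror_bounds
        return self.pixels[r0:r1, c0:c1]


# ---------------------------------------------------------------------------
# dark model bootstrap
# ---------------------------------------------------------------------------

def build_dark_model(stack: FrameStack, min_cluster: int = 50,
                     connectivity: int = 2) -> DarkModel:
    """Bootstrap a dark model from an unlabelled stack.

    A provisional sd is taken from the lowest-variance decile of frames, a
    first classification pass separates dark frames with it, and the final
    mean image / global sd are computed from those dark frames.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    variances = stack.pixels.astype(np.float64).var(axis=(1, 2))
    n_seed = max(1, len(stack) // 10)
    seed_idx = np.argsort(variances)[:n_seed]
    seed = stack.pixels[seed_idx].astype(np.float64)
    provisional = DarkModel(seed.mean(axis=0), max(float(seed.std()), 1e-6), n_seed)
    _, dark_idx = classify_frames(stack, provisional, min_cluster, connectivity)
    if len(dark_idx) == 0:  # stack contains no true darks; keep the seed model
        return provisional
    darks = stack.pixels[dark_idx].astype(np.float64)
    mean_image = darks.mean(axis=0)
    # robust global scalar: scaled MAD, insensitive to hot pixels on darks
    resid = darks - mean_image
    sd = 1.4826 * float(np.median(np.abs(resid)))
    return DarkModel(mean_image, max(sd, 1e-6), len(dark_idx))


# ---------------------------------------------------------------------------
# frame classification
# ---------------------------------------------------------------------------

def _is_pulse_frame(sub: np.ndarray, sd: float, min_cluster: int,
                    connectivity: int) -> bool:
    mask = sub > sd
    if int(mask.sum()) <= min_cluster:
        return False
    lab = label(mask, connectivity=connectivity)
    if lab.max() == 0:
        return False
    sizes = np.bincount(lab.ravel())[1:]
    return bool(sizes.max() > min_cluster)  # strictly more than min_cluster


def classify_frames(
    stack: FrameStack,
    dark: DarkModel,
    min_cluster: int = 50,
    connectivity: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a stack into pulse and dark frames.

    A frame is a pulse frame iff, after subtracting the mean dark image, it
    contains a connected component (8-connectivity by default) of strictly
    more than ``min_cluster`` pixels each above the global dark sd.  Returns
    (pulse_indices, dark_indices); the two index arrays partition the stack.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")
    pulse_idx, dark_idx = [], []
    for k in range(len(stack)):
        sub = stack.pixels[k].astype(np.float64) - dark.mean_image
        if _is_pulse_frame(sub, dark.sd, min_cluster, connectivity):
            pulse_idx.append(k)
        else:
            dark_idx.append(k)
    return np.asarray(pulse_idx, dtype=int), np.asarray(dark_idx, dtype=int)


# ---------------------------------------------------------------------------
# hot pixels
# ---------------------------------------------------------------------------

_RING = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)


def repair_hot_pixels(
    image: np.ndarray,
    dark_sd: float,
    intensity_factor: float = 2.0,
    gradient_factor: float = 5.0,
) -> tuple[np.ndarray, int]:
    """Detect and repair isolated hot pixels; returns (repaired copy, count).

    A pixel is hot iff its value exceeds ``intensity_factor`` times the median
    of its 8 neighbours AND its minimum absolute difference to the 8
    neighbours exceeds ``gradient_factor * dark_sd``.  Hot pixels are replaced
    by the neighbourhood median (hot neighbours excluded), which makes the
    operation idempotent.  Genuine scintillation peaks are smooth at the pixel
    scale and fail both criteria.
    """
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite-valued")
    med = ndimage.median_filter(img, footprint=_RING, mode="nearest")
    # min |gradient| over the 8 neighbours
    min_grad = np.full_like(img, np.inf)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(img, dr, axis=0), dc, axis=1)
            np.minimum(min_grad, np.abs(img - shifted), out=min_grad)
    hot = (img > intensity_factor * np.maximum(med, 1.0)) & (
        min_grad > gradient_factor * dark_sd
    )
    n_hot = int(hot.sum())
    if n_hot == 0:
        return img, 0
    out = img.copy()
    # median over non-hot neighbours
    masked = np.where(hot, np.nan, img)
    repl = _nanmedian_ring(masked)
    fallback = med  # ring of all-hot neighbours: fall back to plain median
    out[hot] = np.where(np.isnan(repl[hot]), fallback[hot], repl[hot])
    return out, n_hot


def _nanmedian_ring(img: np.ndarray) -> np.ndarray:
    stacks = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            stacks.append(np.roll(np.roll(img, dr, axis=0), dc, axis=1))
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(np.stack(stacks), axis=0)


# ---------------------------------------------------------------------------
# background subtraction
# ---------------------------------------------------------------------------

def subtract_background(
    image: np.ndarray,
    dark: DarkModel,
    margin: int,
    direct_bounds: tuple[int, int, int, int],
    mirror_bounds: tuple[int, int, int, int],
    timestamp: float = 0.0,
    n_hot_repaired: int = 0,
) -> CleanPulseImage:
    """Subtract the mean dark image and the per-row dynamic background.

    The dynamic term is, for each sensor row, the mean of the leftmost
    ``margin`` columns after static subtraction, broadcast along the row; in
    signal-free regions the output is therefore zero-mean.
    """
    if margin < 1:
        raise ValueError("margin must be >= 1")
    if margin > mirror_bounds[2]:
        raise ValueError("margin overlaps the mirror view region")
    img = np.asarray(image, dtype=np.float64) - dark.mean_image
    row_bg = img[:, :margin].mean(axis=1, keepdims=True)
    return CleanPulseImage(
        pixels=img - row_bg,
        timestamp=timestamp,
        direct_bounds=direct_bounds,
        mirror_bounds=mirror_bounds,
        n_hot_repaired=n_hot_repaired,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def preprocess_stack(
    stack: FrameStack,
    geom: GeometryConfig | None = None,
    dark: DarkModel | None = None,
    min_cluster: int = 50,
    connectivity: int = 2,
    intensity_factor: float = 2.0,
    gradient_factor: float = 5.0,
    margin: int | None = None,
) -> tuple[list[CleanPulseImage], pd.DataFrame, DarkModel]:
    """Run the full preprocessing chain on a stack.

    View bounds and the margin come from ``geom`` when given, else from the
    stack metadata written at render time.  Returns the cleaned pulse images
    (timestamp order), a per-frame manifest (frame index, class, timestamp,
    n_hot_repaired) and the dark model used.
    """
    if geom is not None:
        direct_bounds = geom.direct_bounds
        mirror_bounds = geom.mirror_bounds
        margin = geom.dark_margin_pixels if margin is None else margin
    else:
        meta = stack.metadata
        direct_bounds = tuple(meta["direct_bounds"])
        mirror_bounds = tuple(meta["mirror_bounds"])
        margin = meta["dark_margin_pixels"] if margin is None else margin
    if dark is None:
        dark = build_dark_model(stack, min_cluster, connectivity)
    pulse_idx, dark_idx = classify_frames(stack, dark, min_cluster, connectivity)
    cleaned: list[CleanPulseImage] = []
    manifest_rows = []
    pulse_set = set(pulse_idx.tolist())
    for k in range(len(stack)):
        if k in pulse_set:
            repaired, n_hot = repair_hot_pixels(
                stack.pixels[k], dark.sd, intensity_factor, gradient_factor
            )
            cleaned.append(
                subtract_background(
                    repaired, dark, margin, direct_bounds, mirror_bounds,
                    timestamp=float(stack.timestamps[k]), n_hot_repaired=n_hot,
                )
            )
            manifest_rows.append((k, "pulse", float(stack.timestamps[k]), n_hot))
        else:
            manifest_rows.append((k, "dark", float(stack.timestamps[k]), 0))
    manifest = pd.DataFrame(
        manifest_rows, columns=["frame_index", "class", "timestamp_ms", "n_hot_repaired"]
    )
    return cleaned, manifest, dark
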
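"""Frame standardization: segment the single worm in a raw grayscale frame
and produce a square, worm-centered image with a uniform background.

The segmentation recipe targets typical single-worm tracker footage: blur,
automatic Otsu threshold, morphological closing, connected components,
selection of the largest blob near the frame center. It is deliberately
simple and is exposed as a hook so datasets with unusual illumination can
substitute their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "FrameUnusableError",
    "ProcessedFrame",
    "segment_worm",
    "standardize_frame",
    "process_frame",
    "default_image_size",
    "iter_video_frames",
    "to_grayscale",
]

#: smallest supported standardized image side
MIN_IMAGE_SIZE = 32

#: Gaussian blur window (pixels) applied before thresholding; sigma follows
#: the usual kernel-size -> sigma rule for a 5 px window
BLUR_WINDOW = 5

#: fraction cropped per side when restricting blob *selection* to the
#: central region (the output geometry is unaffected)
CENTER_CROP_FRACTION = 0.15

#: foreground blobs smaller than this are treated as noise
MIN_WORM_AREA = 10


class FrameUnusableError(RuntimeError):
    """Raised when no worm object can be segmented in a frame."""


@dataclass
class ProcessedFrame:
    """A square standardized frame: worm centered, background uniform."""

    image: np.ndarray  # (L, L) uint8
    worm_mask: np.ndarray  # (L, L) bool
    background_value: float
    offset: tuple[int, int]  # (x, y) of the crop origin in the raw frame

    def __post_init__(self) -> None:
        if self.image.shape[0] != self.image.shape[1]:
            raise ValueError("processed frames are square")
        if self.image.shape[0] < MIN_IMAGE_SIZE:
            raise ValueError(f"minimum image size is {MIN_IMAGE_SIZE} x {MIN_IMAGE_SIZE}")

    @property
    def size(self) -> int:
        return self.image.shape[0]


def to_grayscale(raw: np.ndarray) -> np.ndarray:
    """Luminance conversion for color inputs; grayscale passes through."""
    raw = np.asarray(raw)
    if raw.ndim == 3:
        weights = np.array([0.299, 0.587, 0.114])
        raw = raw[..., :3] @ weights
    return raw.astype(float)


def _blur_sigma(window: int) -> float:
    # the conventional mapping from an odd kernel size to a Gaussian sigma
    return 0.3 * ((window - 1) * 0.5 - 1) + 0.8


def segment_worm(raw: np.ndarray) -> tuple[np.ndarray, float]:
    """Segment the single worm in a raw frame.

    Gaussian blur (5 px window) -> Otsu threshold -> morphological close
    (3x3) -> connected components (8-connectivity) -> keep the largest blob
    overlapping the central region (frame cropped 15% per side for the
    selection only).

    Returns ``(worm_mask, background_value)`` where the background value is
    the mean of non-foreground pixels of the *original* image.

    Raises
    ------
    FrameUnusableError
        if no foreground object of sufficient size is found.
    """
    raw = to_grayscale(raw)
    blurred = ndimage.gaussian_filter(raw, sigma=_blur_sigma(BLUR_WINDOW))
    if blurred.max() == blurred.min():
        raise FrameUnusableError("uniform frame, nothing to segment")
    thresh = threshold_otsu(blurred)
    below = blurred <= thresh
    # the worm is the minority class (dark worm on light background or the
    # reverse); pick the side covering less area
    foreground = below if below.sum() <= below.size / 2 else ~below
    foreground = ndimage.binary_closing(foreground, structure=np.ones((3, 3)))
    labels, n_labels = ndimage.label(foreground, structure=np.ones((3, 3)))
    if n_labels == 0:
        raise FrameUnusableError("no foreground object found")
    h, w = raw.shape
    ch, cw = int(h * CENTER_CROP_FRACTION), int(w * CENTER_CROP_FRACTION)
    central = labels[ch : h - ch, cw : w - cw]
    counts = np.bincount(central.ravel(), minlength=n_labels + 1)
    counts[0] = 0
    best = int(np.argmax(counts))
    if best == 0 or counts[best] < MIN_WORM_AREA:
        raise FrameUnusableError("no worm-sized object near the frame center")
    worm_mask = labels == best
    background_value = float(raw[~foreground].mean())
    return worm_mask, background_value


def standardize_frame(
    raw: np.ndarray,
    worm_mask: np.ndarray,
    background_value: float,
    size: int,
) -> ProcessedFrame:
    """Crop/pad to a ``size x size`` frame with the worm centered and every
    non-worm pixel set to the background value."""
    if size < MIN_IMAGE_SIZE:
        raise ValueError(f"minimum image size is {MIN_IMAGE_SIZE} x {MIN_IMAGE_SIZE}")
    raw = to_grayscale(raw)
    if not worm_mask.any():
        raise FrameUnusableError("empty worm mask")
    rows = np.any(worm_mask, axis=1).nonzero()[0]
    cols = np.any(worm_mask, axis=0).nonzero()[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    bh, bw = r1 - r0, c1 - c0
    if bh > size or bw > size:
        raise ValueError(
            f"worm bounding box ({bh} x {bw}) exceeds the requested image size "
            f"{size}; increase the image size or downscale the frames first"
        )
    out = np.full((size, size), background_value, dtype=float)
    out_mask = np.zeros((size, size), dtype=bool)
    top = (size - bh) // 2
    left = (size - bw) // 2
    crop_mask = worm_mask[r0:r1, c0:c1]
    crop_img = raw[r0:r1, c0:c1]
    region = out[top : top + bh, left : left + bw]
    region[crop_mask] = crop_img[crop_mask]
    out_mask[top : top + bh, left : left + bw] = crop_mask
    return ProcessedFrame(
        image=np.clip(np.rint(out), 0, 255).astype(np.uint8),
        worm_mask=out_mask,
        background_value=float(np.clip(round(background_value), 0, 255)),
        offset=(int(c0 - left), int(r0 - top)),
    )


def process_frame(raw: np.ndarray, size: int) -> ProcessedFrame:
    """Convenience: :func:`segment_worm` followed by :func:`standardize_frame`."""
    mask, background = segment_worm(raw)
    return standardize_frame(raw, mask, background, size)


def iter_video_frames(path):
    """Yield grayscale frames from a video file or a multi-page image
    (anything imageio can read), converting color by luminance."""
    import imageio.v3 as iio

    for chunk in iio.imiter(path):
        arr = np.asarray(chunk)
        if arr.ndim == 3 and arr.shape[-1] not in (3, 4):
            # a stacked container (e.g. multi-page TIFF volume)
            for frame in arr:
                yield to_grayscale(frame)
        else:
            yield to_grayscale(arr)


def default_image_size(worm_lengths_px) -> int:
    """Default standardized image side: the average length of the biggest
    worm in the dataset (rounded up to an even number of pixels), large
    enough to encompass any posture."""
    lengths = np.asarray(list(worm_lengths_px), dtype=float)
    if lengths.size == 0:
        raise ValueError("no worm lengths supplied")
    side = int(np.ceil(lengths.max()))
    side += side % 2
    return max(side, MIN_IMAGE_SIZE)
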
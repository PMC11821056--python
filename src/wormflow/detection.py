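"""Frame binarization, blob extraction, and collision judgement.

Worms are dark objects on a bright background.  Each frame is binarized with
a local-mean adaptive threshold followed by morphological opening and
closing; connected components become :class:`Blob` records.  A blob whose
area strictly exceeds the area threshold ``t_area`` is judged *collided* —
it contains more than one touching worm and must be split by the skeleton
stage before association.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from skimage.filters import threshold_local
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk, opening

from .config import DetectionConfig

__all__ = ["Blob", "binarize", "extract_blobs", "classify_collision", "detect_frame"]


@dataclass
class Blob:
    """One connected foreground component in a binarized frame."""

    frame: int
    coords: np.ndarray            # (n, 2) array of (row, col)
    area: int
    centroid: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # (left, top, w, h)
    is_collided: bool

    @cached_property
    def pixels(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.coords}

    @cached_property
    def mask(self) -> np.ndarray:
        """Boolean crop of the blob over its bounding box."""
        left, top, w, h = self.bbox
        m = np.zeros((h, w), dtype=bool)
        m[self.coords[:, 0] - top, self.coords[:, 1] - left] = True
        return m


def binarize(frame: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Adaptive-threshold a grayscale frame into a worm foreground mask.

    Foreground pixels are those darker than the local mean by at least
    ``adaptive_offset`` gray levels; opening removes speckle noise and
    closing fills hairline gaps in worm bodies.
    """
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale frame, got shape {frame.shape}")
    img = frame.astype(float)
    if config.invert:
        img = 255.0 - img
    thresh = threshold_local(img, block_size=config.adaptive_block,
                             method="mean", offset=config.adaptive_offset)
    mask = img < thresh
    if config.morph_radius > 0:
        footprint = disk(config.morph_radius)
        mask = opening(mask, footprint)
        mask = closing(mask, footprint)
    return mask


def extract_blobs(mask: np.ndarray, frame_idx: int,
                  config: DetectionConfig) -> list[Blob]:
    """Extract 8-connected components of at least ``min_area`` pixels.

    Blobs are returned sorted by (top, left) of their bounding boxes so the
    output order is independent of labelling internals.
    """
    labelled = label(mask, connectivity=2)
    H, W = mask.shape
    blobs: list[Blob] = []
    for region in regionprops(labelled):
        if region.area < config.min_area:
            continue
        top, left, bottom, right = region.bbox
        if config.drop_border and (top == 0 or left == 0
                                   or bottom == H or right == W):
            continue
        cy, cx = region.centroid
        blob = Blob(
            frame=frame_idx,
            coords=region.coords.copy(),
            area=int(region.area),
            centroid=(float(cx), float(cy)),
            bbox=(left, top, right - left, bottom - top),
            is_collided=False,
        )
        blob.is_collided = classify_collision(blob, config)
        blobs.append(blob)
    blobs.sort(key=lambda b: (b.bbox[1], b.bbox[0]))
    return blobs


def classify_collision(blob: Blob, config: DetectionConfig) -> bool:
    """Collision judgement: strictly greater than the area threshold."""
    return blob.area > config.t_area


def detect_frame(frame: np.ndarray, frame_idx: int,
                 config: DetectionConfig) -> list[Blob]:
    """Binarize one frame and extract its blobs."""
    return extract_blobs(binarize(frame, config), frame_idx, config)
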
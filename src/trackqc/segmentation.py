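"""Object isolation: thresholding, 8-connected labeling, watershed splitting.

Etch pits appear as dark objects on a bright background, so the
foreground is everything at or below the grey-level threshold. Connected
components use 8-connectivity (diagonal neighbours merge). Overlapping
pits are separated by a watershed on the distance transform, seeded at
distance-transform peaks with a minimum mutual separation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.segmentation import watershed as _watershed

from .objects import TrackObject

__all__ = [
    "DEFAULT_THRESHOLD",
    "binarize",
    "label_8connected",
    "watershed_split",
    "segment_image",
]

#: Default grey-level threshold for dark pits on a ~200-grey background.
DEFAULT_THRESHOLD = 120


def _as_gray(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return arr


def binarize(image: np.ndarray, threshold: float | str = DEFAULT_THRESHOLD) -> np.ndarray:
    """Foreground mask: pixels with intensity <= threshold (pits are dark).

    ``threshold="auto"`` selects the threshold by Otsu's method.
    """
    arr = _as_gray(image)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        threshold = threshold_otsu(arr)
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return arr <= threshold


def _raster_relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber labels 1..n in raster order of each component's first pixel."""
    flat = labels.ravel()
    present = flat[flat > 0]
    if present.size == 0:
        return np.zeros_like(labels), 0
    n = int(flat.max())
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    # reversed so earlier raster indices overwrite later ones
    first[flat[idx[::-1]]] = idx[::-1]
    order = np.argsort(first[1:], kind="stable")
    order = order[first[1:][order] < flat.size]  # drop ids absent from the grid
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, order.size + 1)
    return remap[labels], int(order.size)


def label_8connected(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labeling of a binary mask.

    Returns ``(labels, n_objects)`` with labels 1..n assigned in raster
    order of each component's first pixel (0 = background).
    """
    mask = np.asarray(mask, dtype=bool)
    raw = _cc_label(mask, connectivity=2)
    return _raster_relabel(raw)


def watershed_split(
    labels: np.ndarray, n_objects: int, min_peak_separation: int = 3
) -> tuple[np.ndarray, int]:
    """Split touching pits at distance-transform peaks.

    Components whose Euclidean distance transform has several local
    maxima at least ``min_peak_separation`` pixels apart are divided by a
    marker-seeded watershed; single-peak (convex) components are left
    untouched. Splitting never merges: pixel sets after the call
    partition the pixel sets before it.
    """
    mask = labels > 0
    if not mask.any():
        return labels.copy(), 0
    dist = ndi.distance_transform_edt(mask)
    size = 2 * min_peak_separation + 1
    is_max = mask & (dist == ndi.maximum_filter(dist, size=size))
    # one marker region per connected regional-maximum plateau, so a flat
    # ridge (e.g. a thin bar) counts as a single peak
    markers, _ = ndi.label(is_max, structure=np.ones((3, 3), dtype=bool))
    ws = _watershed(-dist, markers=markers, mask=mask, connectivity=2)
    # components that received no marker (tiny plateaus) keep their label
    orphan = mask & (ws == 0)
    if orphan.any():
        ws = ws.astype(np.int64)
        ws[orphan] = labels[orphan] + ws.max()
    return _raster_relabel(ws)


def segment_image(
    image: np.ndarray,
    threshold: float | str = DEFAULT_THRESHOLD,
    split: bool = True,
    min_size: int = 0,
    min_peak_separation: int = 3,
) -> list[TrackObject]:
    """Threshold, label and (optionally) watershed-split one micrograph.

    Each returned :class:`TrackObject` carries its pixel coordinates and
    the original grey intensities. No minimum-size filter is applied by
    default: isolated dark pixels are themselves diagnostic of poor
    acquisition conditions and feed the quality-control features.
    """
    arr = _as_gray(image)
    mask = binarize(arr, threshold)
    labels, n = label_8connected(mask)
    if split and n:
        labels, n = watershed_split(labels, n, min_peak_separation=min_peak_separation)
    objects: list[TrackObject] = []
    if n == 0:
        return objects
    slices = ndi.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        local = labels[sl] == i
        coords = np.argwhere(local)
        coords += np.array([sl[0].start, sl[1].start])
        if coords.shape[0] < max(min_size, 1):
            continue
        objects.append(TrackObject(coords, arr[coords[:, 0], coords[:, 1]]))
    return objects
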
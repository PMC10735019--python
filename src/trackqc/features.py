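"""Per-pit morphological descriptors and per-image summary features.

Six descriptors are computed for every segmented etch pit:

``area``
    Number of pixels in the object. Interior holes are not counted by
    default (``filled=True`` switches to the filled convention).
``diameter``
    Length of the longest line that passes through the object centroid and
    connects two opposite border pixels (border-pixel centre to centre).
``aspect``
    Major/minor axis ratio of the second-central-moment equivalent
    ellipse; 1 for circularly symmetric objects. Each pixel contributes
    the variance of a unit square (1/12 per axis) so one-pixel-wide
    objects have a finite ratio.
``roundness``
    P^2 / (4 pi A) where ``P`` is the perimeter and ``A`` the
    area, both in pixels; 1 for an ideal circle, larger for irregular
    outlines. The perimeter estimator is the weighted 4-neighbourhood
    chain-code length (:func:`skimage.measure.perimeter`), declared here
    and used consistently throughout the package.
``heterogeneity``
    Fraction of object pixels whose grey level deviates by more than 10%
    from the object's mean grey level.
``clumpiness``
    Heterogeneity recomputed after a single erosion with a full 3x3
    structuring element, i.e. after discarding the one-pixel border rim
    where etch pits carry their intensity gradient. Objects that erode to
    nothing score 0.

An image is summarized by six statistics (mean, median, interquartile
distance, standard deviation, 5th and 90th percentile) of each
descriptor over all objects: a 36-value feature vector plus the track
count.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import perimeter as _chain_perimeter

from .objects import TrackDescriptors, TrackObject

__all__ = [
    "DESCRIPTOR_NAMES",
    "STAT_NAMES",
    "FEATURE_COLUMNS",
    "PIXEL_AREA_UM2",
    "area",
    "diameter",
    "aspect_ratio",
    "roundness",
    "heterogeneity",
    "clumpiness",
    "describe",
    "summarize",
    "featurize_image",
    "parameter_histograms",
    "px_area_to_um2",
]

DESCRIPTOR_NAMES = ("area", "diameter", "aspect", "roundness", "heterogeneity", "clumpiness")
STAT_NAMES = ("mean", "median", "iqr", "std", "p5", "p90")

#: The 36 per-image feature columns, ``<stat>_<descriptor>``.
FEATURE_COLUMNS = tuple(f"{s}_{d}" for d in DESCRIPTOR_NAMES for s in STAT_NAMES)

#: Physical pixel area for a 1280x962 px frame imaging 211x158 um.
PIXEL_AREA_UM2 = (211.0 / 1280.0) * (158.0 / 962.0)

_SQUARE_3x3 = np.ones((3, 3), dtype=bool)


def area(obj: TrackObject, filled: bool = False) -> int:
    """Pixel count of the object; holes excluded unless ``filled``."""
    if filled:
        mask, _ = obj.mask()
        return int(ndi.binary_fill_holes(mask).sum())
    return obj.n_pixels


def _border_pixels(mask: np.ndarray) -> np.ndarray:
    """Object pixels with at least one 4-neighbour in the background."""
    interior = ndi.binary_erosion(
        mask, structure=ndi.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(mask & ~interior)


def diameter(obj: TrackObject) -> float:
    """Longest centroid-crossing chord between border-pixel centres.

    Among all pairs of border pixels whose connecting segment passes
    within half a pixel of the (intensity-unweighted) centroid, the
    maximum Euclidean centre-to-centre distance. A single pixel has
    diameter 0 by convention; if no pair qualifies (strongly non-convex
    objects whose centroid lies outside) the maximum border-to-border
    distance is returned.
    """
    mask, (roff, coff) = obj.mask()
    border = _border_pixels(mask).astype(np.float64)
    if border.shape[0] < 2:
        return 0.0
    centroid = obj.coords.mean(axis=0) - np.array([roff, coff], dtype=np.float64)

    p = border[:, None, :]  # (n,1,2)
    q = border[None, :, :]  # (1,n,2)
    d = q - p
    seg_len2 = np.einsum("ijk,ijk->ij", d, d)
    # parameter of centroid's projection on each segment, clipped to it
    w = centroid[None, None, :] - p
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.clip(np.einsum("ijk,ijk->ij", w, d) / np.where(seg_len2 > 0, seg_len2, 1.0), 0.0, 1.0)
    closest = p + t[..., None] * d
    dist2 = np.einsum("ijk,ijk->ij", closest - centroid[None, None, :], closest - centroid[None, None, :])
    through = dist2 <= 0.25  # within half a pixel of the centroid
    lengths = np.sqrt(seg_len2)
    if through.any():
        return float(lengths[through].max())
    return float(lengths.max())


def aspect_ratio(obj: TrackObject) -> float:
    """Equivalent-ellipse major/minor axis ratio (>= 1)."""
    coords = obj.coords.astype(np.float64)
    cov = np.cov(coords, rowvar=False, bias=True).reshape(2, 2) + np.eye(2) / 12.0
    eigvals = np.linalg.eigvalsh(cov)
    return float(np.sqrt(eigvals[1] / eigvals[0]))


def roundness(obj: TrackObject) -> float:
    """P^2 / (4 pi A) under the declared chain-code perimeter."""
    mask, _ = obj.mask()
    p = _chain_perimeter(mask, neighborhood=4)
    return float(p * p / (4.0 * np.pi * obj.n_pixels))


def _deviating_fraction(values: np.ndarray) -> float:
    mean = float(values.mean())
    if mean == 0.0:
        return 0.0
    return float(np.mean(np.abs(values - mean) > 0.10 * mean))


def heterogeneity(obj: TrackObject) -> float:
    """Fraction of pixels deviating >10% from the object mean grey level."""
    return _deviating_fraction(obj.intensities)


def clumpiness(obj: TrackObject) -> float:
    """Heterogeneity of the object after one 3x3 erosion; 0 if it vanishes."""
    mask, (roff, coff) = obj.mask()
    eroded = ndi.binary_erosion(mask, structure=_SQUARE_3x3, border_value=0)
    if not eroded.any():
        return 0.0
    keep = eroded[obj.coords[:, 0] - roff, obj.coords[:, 1] - coff]
    return _deviating_fraction(obj.intensities[keep])


def describe(obj: TrackObject, filled_area: bool = False) -> TrackDescriptors:
    """Compute all six descriptors for one object."""
    if obj.n_pixels == 1:
        # exact degenerate values of the general formulas for one pixel
        return TrackDescriptors(
            area=1.0, diameter=0.0, aspect=1.0, roundness=0.0,
            heterogeneity=0.0, clumpiness=0.0,
        )
    return TrackDescriptors(
        area=float(area(obj, filled=filled_area)),
        diameter=diameter(obj),
        aspect=aspect_ratio(obj),
        roundness=roundness(obj),
        heterogeneity=heterogeneity(obj),
        clumpiness=clumpiness(obj),
    )


def summarize(values) -> dict[str, float]:
    """Six summary statistics of a non-empty list of descriptor values.

    Percentiles use linear interpolation between closest ranks; the
    standard deviation is the population form (ddof=0); ``iqr`` is the
    75th minus the 25th percentile.
    """
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("summarize requires at least one value")
    p5, p25, p50, p75, p90 = np.percentile(arr, [5, 25, 50, 75, 90])
    return {
        "mean": float(arr.mean()),
        "median": float(p50),
        "iqr": float(p75 - p25),
        "std": float(arr.std(ddof=0)),
        "p5": float(p5),
        "p90": float(p90),
    }


def featurize_image(objects: list[TrackObject], filled_area: bool = False) -> dict[str, float]:
    """36 summary features plus ``track_count`` for one image.

    Raises ``ValueError`` for an empty object list: an image in which
    nothing was segmented has no defined feature vector.
    """
    if len(objects) == 0:
        raise ValueError("featurize_image requires at least one segmented object")
    described = [describe(o, filled_area=filled_area) for o in objects]
    record: dict[str, float] = {}
    for name in DESCRIPTOR_NAMES:
        stats = summarize([getattr(d, name) for d in described])
        for stat in STAT_NAMES:
            record[f"{stat}_{name}"] = stats[stat]
    record["track_count"] = float(len(objects))
    return record


_DEFAULT_BINS = {
    "area": np.arange(0.0, 105.0, 5.0),
    "diameter": np.arange(0.0, 21.0, 1.0),
    "aspect": np.arange(1.0, 2.05, 0.05),
    "roundness": np.arange(0.8, 2.05, 0.05),
    "heterogeneity": np.arange(0.0, 1.05, 0.05),
    "clumpiness": np.arange(0.0, 1.05, 0.05),
}


def parameter_histograms(
    objects: list[TrackObject], bins: dict[str, np.ndarray] | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Normalized per-descriptor histograms over all objects.

    Returns ``{descriptor: (fractions, bin_edges)}`` with fractions
    summing to 1. Values beyond the outermost edges are clipped into the
    first/last bin so that normalization is exact.
    """
    if len(objects) == 0:
        raise ValueError("parameter_histograms requires at least one object")
    edges = dict(_DEFAULT_BINS)
    if bins:
        edges.update({k: np.asarray(v, dtype=np.float64) for k, v in bins.items()})
    described = [describe(o) for o in objects]
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in DESCRIPTOR_NAMES:
        e = edges[name]
        vals = np.clip(
            [getattr(d, name) for d in described], e[0], np.nextafter(e[-1], -np.inf)
        )
        counts, _ = np.histogram(vals, bins=e)
        out[name] = (counts / counts.sum(), e)
    return out


def px_area_to_um2(area_px: float) -> float:
    """Convert a pixel area to um^2 using the 211x158 um field of view."""
    if area_px < 0:
        raise ValueError("area must be non-negative")
    return float(area_px) * PIXEL_AREA_UM2
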
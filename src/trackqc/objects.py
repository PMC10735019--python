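"""Containers for segmented etch-pit objects.

A :class:`TrackObject` is the unit every morphological descriptor operates
on: the set of pixel coordinates of one 8-connected segmented object
together with the original grey levels at those pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrackObject", "TrackDescriptors"]


@dataclass(frozen=True)
class TrackObject:
    """One segmented etch pit.

    Parameters
    ----------
    coords : (n, 2) integer array
        Pixel coordinates as ``(row, col)`` pairs, 0-based, origin at the
        image's top-left corner.
    intensities : (n,) array
        Original 8-bit grey level of each pixel, aligned with ``coords``.
    """

    coords: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))
        intensities = np.asarray(self.intensities, dtype=np.float64).ravel()
        if coords.size == 0:
            raise ValueError("TrackObject requires at least one pixel")
        if coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2) (row, col) pairs")
        if intensities.shape[0] != coords.shape[0]:
            raise ValueError("intensities must align with coords")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "intensities", intensities)

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    def mask(self) -> tuple[np.ndarray, np.ndarray]:
        """Return a tight boolean mask and its (row, col) offset.

        The mask is padded by one background pixel on every side so that
        morphological operations (erosion, border tracing) behave as if the
        object sat in an infinite background.
        """
        rmin, cmin = self.coords.min(axis=0)
        rmax, cmax = self.coords.max(axis=0)
        mask = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=bool)
        mask[self.coords[:, 0] - rmin + 1, self.coords[:, 1] - cmin + 1] = True
        return mask, (rmin - 1, cmin - 1)


@dataclass(frozen=True)
class TrackDescriptors:
    """The six per-pit measures used to characterize a track."""

    area: float
    diameter: float
    aspect: float
    roundness: float
    heterogeneity: float
    clumpiness: float

    def as_dict(self) -> dict[str, float]:
        return {
            "area": self.area,
            "diameter": self.diameter,
            "aspect": self.aspect,
            "roundness": self.roundness,
            "heterogeneity": self.heterogeneity,
            "clumpiness": self.clumpiness,
        }
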
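"""Seeded generator of synthetic autoradiographic images.

The generator emulates the image formation chain of neutron
autoradiography on a polycarbonate track detector:

* Boron neutron capture emits an alpha particle and a lithium-7 ion in
  near-opposite directions through two decay channels (93.7% / 6.3%);
  one of the two fragments enters the detector.
* Etched pit size depends on the particle's residual energy when it
  reaches the detector surface: lower energy means more damage near the
  Bragg peak and a larger pit. The mapping is encoded as a monotone
  piecewise-linear calibration anchored at measured mean areas
  (1.47 MeV -> 25 px, 1.0 MeV -> 33 px, 0.5 MeV -> 41 px).
* Capture sites lie at a range of depths, so residual energies spread
  continuously from the emission energy down to the registration
  threshold; this produces the broad, unimodal pit-area distribution
  centred at 30-40 px characteristic of BNC images.
* Pits are rendered as dark ellipses with a linear radial intensity ramp
  at the rim (the grey-level gradient sits on the border pixels), on a
  bright noisy background.
* Acquisition corruption: a global grey-level offset models the lamp
  (over-lighting shrinks pits below threshold, under-lighting drags
  background noise under it, creating spurious small objects), and a
  Gaussian defocus blur with rim speckle models lens-sample distance
  errors.

All randomness flows through explicit seeds; a fixed seed reproduces a
dataset bit for bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "DecayChannel",
    "BNC_CHANNELS",
    "EnergyAreaCalibration",
    "AcquisitionCondition",
    "PitRenderSpec",
    "SyntheticImage",
    "DEFAULT_SHAPE",
    "sample_bnc_decay",
    "energy_to_pit_area",
    "sample_pits",
    "render_image",
    "apply_light_offset",
    "apply_defocus",
    "generate_dataset",
    "save_dataset",
]

#: Default frame: 1280x962 px mapping 211x158 um (rows, cols).
DEFAULT_SHAPE = (962, 1280)

#: Background grey level and pit core grey level of an adequate image.
BACKGROUND_GREY = 200.0
CORE_GREY = 40.0

#: Grey-level swing of a full-scale light offset.
LIGHT_GAIN = 120.0

#: Tolerance band within which an acquisition counts as adequate.
ADEQUATE_LIGHT_TOL = 0.15
ADEQUATE_DEFOCUS_TOL = 0.8

#: Mean number of tracks in a full 1280x962 frame (typical ~30-60 ppm
#: boron solutions image at a few hundred tracks per field).
TRACKS_PER_FULL_FRAME = 200.0


@dataclass(frozen=True)
class DecayChannel:
    """One decay channel of the 10B(n,alpha)7Li capture reaction."""

    name: str
    alpha_energy: float  # MeV
    li_energy: float  # MeV
    intensity: float  # branching fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.alpha_energy <= 0 or self.li_energy <= 0:
            raise ValueError("energies must be strictly positive")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")


#: Ground-state and excited-state channels of the capture reaction.
BNC_CHANNELS = (
    DecayChannel("alpha0+Li0", alpha_energy=1.777, li_energy=1.013, intensity=0.063),
    DecayChannel("alpha1+Li1", alpha_energy=1.471, li_energy=0.839, intensity=0.937),
)


def sample_bnc_decay(rng_seed, n: int) -> list[tuple[str, float, float]]:
    """Draw ``n`` capture events as (channel name, alpha MeV, Li MeV).

    Channels are drawn with their branching intensities (93.7% / 6.3%);
    energies are the tabulated channel values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    probs = np.array([c.intensity for c in BNC_CHANNELS])
    idx = rng.choice(len(BNC_CHANNELS), size=n, p=probs / probs.sum())
    return [(BNC_CHANNELS[i].name, BNC_CHANNELS[i].alpha_energy, BNC_CHANNELS[i].li_energy) for i in idx]


@dataclass(frozen=True)
class EnergyAreaCalibration:
    """Monotone mapping from incident energy to mean etched-pit area.

    Anchors follow monoenergetic alpha irradiations (mean areas
    25 < 33 < 41 px for 1.47 > 1.0 > 0.5 MeV); lower energy deposits
    more near-surface damage (Bragg peak) and etches a larger pit.
    ``srm_alpha_area``/``srm_li_area`` anchor the bimodal distribution of
    the boron-implanted silicon standard (~12 px and ~55 px). ``rel_sd``
    is the per-pit log-normal relative spread of area about its mean.
    """

    energies: tuple[float, ...] = (0.5, 1.0, 1.47)
    areas: tuple[float, ...] = (41.0, 33.0, 25.0)
    srm_alpha_area: float = 12.0
    srm_li_area: float = 55.0
    rel_sd: float = 0.18

    def __post_init__(self) -> None:
        if not all(a > b for a, b in zip(self.areas, self.areas[1:])):
            raise ValueError("mean area must be strictly decreasing in energy")

    @property
    def min_energy(self) -> float:
        return self.energies[0]

    @property
    def max_energy(self) -> float:
        return self.energies[-1]


DEFAULT_CALIBRATION = EnergyAreaCalibration()


def energy_to_pit_area(energy: float, calibration: EnergyAreaCalibration = DEFAULT_CALIBRATION) -> float:
    """Mean pit area (px) for a particle of the given energy (MeV).

    Piecewise-linear through the calibration anchors; energies outside
    the anchored range are clamped to its ends.
    """
    if np.any(np.asarray(energy) < 0):
        raise ValueError("energy must be non-negative")
    return float(np.interp(energy, calibration.energies, calibration.areas))


@dataclass(frozen=True)
class AcquisitionCondition:
    """Lamp / focus / sensor state of one acquisition.

    ``light_offset`` is dimensionless in [-1, 1] (0 adequate, positive
    over-lit, negative under-lit); ``defocus_sigma`` is the blur width in
    px; ``noise_sd`` the additive sensor noise in grey levels.
    """

    light_offset: float = 0.0
    defocus_sigma: float = 0.0
    noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.light_offset <= 1.0:
            raise ValueError("light_offset must lie in [-1, 1]")
        if self.defocus_sigma < 0:
            raise ValueError("defocus_sigma must be >= 0")

    @property
    def is_adequate(self) -> bool:
        return (
            abs(self.light_offset) <= ADEQUATE_LIGHT_TOL
            and self.defocus_sigma <= ADEQUATE_DEFOCUS_TOL
        )


ADEQUATE = AcquisitionCondition()


@dataclass(frozen=True)
class PitRenderSpec:
    """Geometry and intensity of one rendered pit (ground truth)."""

    center: tuple[float, float]  # (row, col), px
    semi_major: float
    semi_minor: float
    orientation: float = 0.0  # radians
    core_intensity: float = CORE_GREY
    edge_width: float = 1.5

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise ValueError("require semi_major >= semi_minor > 0")
        if self.core_intensity >= BACKGROUND_GREY:
            raise ValueError("pit core must be darker than the background")

    @property
    def area(self) -> float:
        """Nominal ellipse area pi*a*b in px."""
        return float(np.pi * self.semi_major * self.semi_minor)


@dataclass(frozen=True)
class SyntheticImage:
    """Rendered frame plus its ground truth."""

    pixels: np.ndarray  # uint8, HxW
    truth: tuple[PitRenderSpec, ...]
    condition: AcquisitionCondition
    label: str  # "Accepted" | "Rejected"


def _axes_from_area(area_px: np.ndarray, aspect: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.sqrt(area_px * aspect / np.pi)
    b = np.sqrt(area_px / (aspect * np.pi))
    return a, b


def _pit_areas_bnc(n: int, rng: np.random.Generator, cal: EnergyAreaCalibration) -> np.ndarray:
    """Per-pit areas for capture-reaction images.

    One fragment (alpha or Li, equal odds) enters the detector per
    capture. Emission depth is uniform within the fragment's range; with
    a power-law range-energy relation R ~ E^1.8 the residual surface
    energy is E0 * u^(1/1.8), truncated at the registration threshold
    (the calibration's lowest anchored energy).
    """
    decays = sample_bnc_decay(rng, n)
    e0 = np.array([d[1] if rng.random() < 0.5 else d[2] for d in decays])
    u_min = (cal.min_energy / e0) ** 1.8
    u = rng.uniform(u_min, 1.0)
    energy = e0 * u ** (1.0 / 1.8)
    return np.interp(energy, cal.energies, cal.areas)


def sample_pits(
    n: int,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    rng_seed=0,
    mode: str = "bnc",
    energy: float | None = None,
    calibration: EnergyAreaCalibration = DEFAULT_CALIBRATION,
) -> list[PitRenderSpec]:
    """Draw ``n`` pit specifications for one frame.

    Modes: ``bnc`` (continuous-depth capture-reaction mixture),
    ``monoenergetic`` (single incident energy, requires ``energy``), and
    ``srm`` (bimodal alpha/Li mix of the implanted-silicon standard).
    """
    rng = np.random.default_rng(rng_seed)
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    if mode == "bnc":
        mean_area = _pit_areas_bnc(n, rng, calibration)
    elif mode == "monoenergetic":
        if energy is None:
            raise ValueError("monoenergetic mode requires an energy")
        mean_area = np.full(n, energy_to_pit_area(energy, calibration))
    elif mode == "srm":
        is_alpha = rng.random(n) < 0.5
        mean_area = np.where(is_alpha, calibration.srm_alpha_area, calibration.srm_li_area)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    sigma = np.sqrt(np.log1p(calibration.rel_sd**2))
    area = mean_area * np.exp(rng.normal(0.0, sigma, size=n) - sigma**2 / 2.0)
    area = np.maximum(area, 2.0)
    aspect = np.minimum(1.0 + np.abs(rng.normal(0.0, 0.12, size=n)), 1.6)
    a, b = _axes_from_area(area, aspect)
    margin = np.ceil(a) + 2
    rows = rng.uniform(margin, shape[0] - margin)
    cols = rng.uniform(margin, shape[1] - margin)
    core = np.clip(rng.normal(CORE_GREY, 6.0, size=n), 15.0, 80.0)
    edge = rng.uniform(1.0, 2.0, size=n)
    return [
        PitRenderSpec(
            center=(float(rows[i]), float(cols[i])),
            semi_major=float(a[i]),
            semi_minor=float(b[i]),
            orientation=float(rng.uniform(0.0, np.pi)),
            core_intensity=float(core[i]),
            edge_width=float(edge[i]),
        )
        for i in range(n)
    ]


def _draw_pit(canvas: np.ndarray, pit: PitRenderSpec) -> None:
    h, w = canvas.shape
    r0, c0 = pit.center
    ext = pit.semi_major + pit.edge_width + 1.0
    rlo, rhi = int(max(0, np.floor(r0 - ext))), int(min(h, np.ceil(r0 + ext) + 1))
    clo, chi = int(max(0, np.floor(c0 - ext))), int(min(w, np.ceil(c0 + ext) + 1))
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    ct, st = np.cos(pit.orientation), np.sin(pit.orientation)
    x = dr * ct + dc * st
    y = -dr * st + dc * ct
    # normalized elliptical radius: 1 on the nominal ellipse boundary
    f = np.sqrt((x / pit.semi_major) ** 2 + (y / pit.semi_minor) ** 2)
    # intensity ramp centred on the boundary, half a rim inside/outside
    half = pit.edge_width / (pit.semi_major + pit.semi_minor)  # in f units
    t = np.clip((f - (1.0 - half)) / (2.0 * half), 0.0, 1.0)
    vals = pit.core_intensity + (BACKGROUND_GREY - pit.core_intensity) * t
    region = canvas[rlo:rhi, clo:chi]
    np.minimum(region, vals, out=region)


def apply_light_offset(image: np.ndarray, light_offset: float) -> np.ndarray:
    """Shift all grey levels by the lamp offset (clipped to 8 bits).

    Positive offsets brighten the frame: rim pixels rise above the
    segmentation threshold and pits shrink. Negative offsets darken it:
    the low tail of the background noise drops below threshold and
    spurious few-pixel objects appear. A zero offset is the identity.
    """
    if not -1.0 <= light_offset <= 1.0:
        raise ValueError("light_offset must lie in [-1, 1]")
    if light_offset == 0.0:
        return image.copy()
    out = np.asarray(image, dtype=np.float64) + light_offset * LIGHT_GAIN
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_defocus(image: np.ndarray, defocus_sigma: float, rng_seed=None) -> np.ndarray:
    """Gaussian defocus blur plus rim speckle.

    Blur smears the rim gradient across several pixels; re-injected
    sensor noise (drawn from ``rng_seed`` when given) then cuts ragged,
    partly disconnected outlines at the threshold, which inflates the
    roundness/aspect tails exactly as out-of-focus acquisitions do. A
    zero sigma is the identity.
    """
    if defocus_sigma < 0:
        raise ValueError("defocus_sigma must be >= 0")
    if defocus_sigma == 0.0:
        return image.copy()
    out = gaussian_filter(np.asarray(image, dtype=np.float64), defocus_sigma, mode="nearest")
    if rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
        speckle_sd = 3.0 * min(defocus_sigma, 2.0)
        out = out + rng.normal(0.0, speckle_sd, size=out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def render_image(
    pits: list[PitRenderSpec],
    condition: AcquisitionCondition = ADEQUATE,
    rng_seed=0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
) -> SyntheticImage:
    """Render a frame: pits on noisy bright background, then corruption."""
    h, w = shape
    for pit in pits:
        r, c = pit.center
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"pit center {pit.center} outside the {shape} frame")
    rng = np.random.default_rng(rng_seed)
    canvas = np.full(shape, BACKGROUND_GREY, dtype=np.float64)
    for pit in pits:
        _draw_pit(canvas, pit)
    canvas += rng.normal(0.0, condition.noise_sd, size=shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    if condition.defocus_sigma > 0:
        pixels = apply_defocus(pixels, condition.defocus_sigma, rng_seed=rng)
    if condition.light_offset != 0.0:
        pixels = apply_light_offset(pixels, condition.light_offset)
    label = "Accepted" if condition.is_adequate else "Rejected"
    return SyntheticImage(pixels=pixels, truth=tuple(pits), condition=condition, label=label)


def _degraded_condition(rng: np.random.Generator) -> AcquisitionCondition:
    kind = rng.choice(["over", "under", "defocus"])
    if kind == "over":
        return AcquisitionCondition(light_offset=float(rng.uniform(0.35, 0.7)))
    if kind == "under":
        return AcquisitionCondition(light_offset=float(-rng.uniform(0.35, 0.7)))
    return AcquisitionCondition(defocus_sigma=float(rng.uniform(1.2, 2.2)))


def _adequate_condition(rng: np.random.Generator) -> AcquisitionCondition:
    return AcquisitionCondition(
        light_offset=float(rng.uniform(-0.1, 0.1)),
        defocus_sigma=float(rng.uniform(0.0, 0.4)),
    )


def generate_dataset(
    n_images: int,
    fraction_adequate: float = 0.5,
    rng_seed=0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    mode: str = "bnc",
    energy: float | None = None,
    mean_tracks: float | None = None,
    calibration: EnergyAreaCalibration = DEFAULT_CALIBRATION,
) -> list[SyntheticImage]:
    """Generate a labelled synthetic dataset.

    Exactly ``round(n_images * fraction_adequate)`` frames are acquired
    inside the adequate tolerance band (label ``Accepted``); the rest
    draw an out-of-band corruption (over-/under-lit or defocused,
    ``Rejected``). The per-frame track count is Poisson with a mean
    proportional to the frame area (200 tracks per full 1280x962 frame
    by default). Fixed seeds give bit-identical datasets.
    """
    if not 0.0 <= fraction_adequate <= 1.0:
        raise ValueError("fraction_adequate must lie in [0, 1]")
    if n_images < 0:
        raise ValueError("n_images must be >= 0")
    if mean_tracks is None:
        mean_tracks = TRACKS_PER_FULL_FRAME * (shape[0] * shape[1]) / (
            DEFAULT_SHAPE[0] * DEFAULT_SHAPE[1]
        )
    n_adequate = int(round(n_images * fraction_adequate))
    if isinstance(rng_seed, np.random.SeedSequence):
        master = rng_seed
    else:
        master = np.random.SeedSequence(rng_seed)
    order_rng = np.random.default_rng(master.spawn(1)[0])
    flags = np.array([True] * n_adequate + [False] * (n_images - n_adequate))
    order_rng.shuffle(flags)
    images: list[SyntheticImage] = []
    for adequate, seq in zip(flags, master.spawn(n_images)):
        rng = np.random.default_rng(seq)
        condition = _adequate_condition(rng) if adequate else _degraded_condition(rng)
        n_pits = int(rng.poisson(mean_tracks))
        pits = sample_pits(
            n_pits, shape=shape, rng_seed=rng, mode=mode, energy=energy, calibration=calibration
        )
        images.append(render_image(pits, condition, rng_seed=rng, shape=shape))
    return images


def save_dataset(images: list[SyntheticImage], out_dir: str | Path, fmt: str = "png") -> Path:
    """Write frames plus a manifest and per-image truth lists as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "light_offset", "defocus_sigma", "n_pits"])
        for i, img in enumerate(images):
            name = f"image_{i:05d}.{fmt}"
            iio.imwrite(out / name, img.pixels)
            writer.writerow(
                [name, img.label, img.condition.light_offset, img.condition.defocus_sigma, len(img.truth)]
            )
            with open(out / f"image_{i:05d}_truth.csv", "w", newline="") as th:
                tw = csv.writer(th)
                tw.writerow(["center_row", "center_col", "semi_major", "semi_minor", "orientation"])
                for pit in img.truth:
                    tw.writerow([*pit.center, pit.semi_major, pit.semi_minor, pit.orientation])
    return out
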
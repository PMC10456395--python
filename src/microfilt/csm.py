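"""Cell-size measurement (CSM) from stained-cell micrographs.

Pipeline for brightfield images of vital-stained cell suspensions on a
counting slide: grayscale conversion and denoising, global-threshold
segmentation with hole filling, then per-object triage — too-small objects
are noise, border-touching objects would bias sizing and are excluded,
low-circularity objects are cell aggregates, and objects whose interior is
dark relative to the background (vital-stain-positive) are dead cells.
Only live single cells contribute to the size statistics; each is measured
by its equivalent circular diameter, 2 sqrt(area / pi) scaled by the pixel
size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, filters, measure

from .sizing import ParticlePopulation

__all__ = [
    "CalibratedImage",
    "SegmentationConfig",
    "DetectedParticle",
    "preprocess",
    "segment",
    "measure_population",
    "read_image",
    "status_counts",
]

STATUSES = ("live", "dead", "aggregate", "noise", "border")


@dataclass(frozen=True)
class CalibratedImage:
    """A grayscale (or RGB, pre-:func:`preprocess`) image with its pixel
    size in um/px.  Pixel centres sit at integer coordinates, row-major,
    origin top-left."""

    pixels: np.ndarray
    pixel_size_um: float
    field_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim not in (2, 3):
            raise ValueError("pixels must be a 2-D grayscale or 3-D RGB array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable rules of the segmentation triage.

    threshold :
        "otsu" or a fixed numeric global threshold.
    min_area_px :
        Components smaller than this are labelled noise.
    aggregate_circularity :
        Components with 4 pi A / P^2 below this are aggregates (fused cells
        form two-lobed outlines far from circular).
    dead_intensity_fraction :
        A component is dead when its mean interior intensity falls below
        background + fraction * (foreground - background); the vital stain
        darkens dead-cell interiors while the rim stays bright.
    interior_erosion_px :
        Erosion depth that strips the bright rim before the interior
        intensity is measured.
    """

    threshold: str | float = "otsu"
    min_area_px: int = 20
    aggregate_circularity: float = 0.7
    dead_intensity_fraction: float = 0.25
    interior_erosion_px: int = 3
    exclude_border: bool = True
    median_size: int = 3


@dataclass(frozen=True)
class DetectedParticle:
    """One segmented object and its triage status."""

    centroid_px: tuple[float, float]  # (row, col)
    area_px: float
    equivalent_diameter_um: float
    circularity: float
    mean_interior_intensity: float
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")


def preprocess(image: CalibratedImage, *, median_size: int = 3) -> CalibratedImage:
    """Grayscale conversion (luminance weights for RGB) + median denoising.

    The median filter suppresses salt-and-pepper (shot/readout) noise while
    preserving cell edges; it is idempotent on already-clean images.
    """
    px = image.pixels
    if px.ndim == 3:
        px = color.rgb2gray(px)
    if px.size < 2 or min(px.shape) < 2:
        raise ValueError("image must have at least 2 pixels per axis")
    px = ndimage.median_filter(px, size=median_size)
    return CalibratedImage(px, image.pixel_size_um, image.field_id)


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0
    # digitization can push a small disk slightly above 1; cap at 1.1
    return min(4.0 * np.pi * area / perimeter**2, 1.1)


def segment(
    image: CalibratedImage, config: SegmentationConfig | None = None
) -> list[DetectedParticle]:
    """Segment a preprocessed grayscale image into triaged particles.

    Global threshold (Otsu by default), connected components (8-neighbour)
    with hole filling — dead cells present as bright rings whose dark
    interiors the filling closes — then the status rules of
    :class:`SegmentationConfig`, applied in the order noise, border,
    aggregate, dead, live.
    """
    if config is None:
        config = SegmentationConfig()
    px = image.pixels
    if px.ndim != 2:
        raise ValueError("segment expects a 2-D grayscale image; run preprocess first")
    if config.threshold == "otsu":
        if float(np.ptp(px)) == 0.0:
            raise ValueError(
                "degenerate image: uniform intensity, Otsu threshold undefined"
            )
        thr = float(filters.threshold_otsu(px))
    else:
        thr = float(config.threshold)

    fg = px > thr
    if not fg.any():
        return []
    # background/foreground reference levels for the dead-cell rule
    bg_level = float(px[~fg].mean()) if (~fg).any() else 0.0
    fg_level = float(px[fg].mean())
    dead_cut = bg_level + config.dead_intensity_fraction * (fg_level - bg_level)

    filled = ndimage.binary_fill_holes(fg)
    labels = measure.label(filled, connectivity=2)
    h, w = px.shape
    out: list[DetectedParticle] = []
    for region in measure.regionprops(labels, intensity_image=px):
        area = float(region.area)
        circ = _circularity(area, float(region.perimeter))
        eq_d_um = 2.0 * np.sqrt(area / np.pi) * image.pixel_size_um

        minr, minc, maxr, maxc = region.bbox
        touches_border = minr == 0 or minc == 0 or maxr == h or maxc == w

        mask = region.image
        interior = ndimage.binary_erosion(
            mask, iterations=max(config.interior_erosion_px, 1)
        )
        if not interior.any():
            interior = mask
        mean_interior = float(px[minr:maxr, minc:maxc][interior].mean())

        if area < config.min_area_px:
            status = "noise"
        elif config.exclude_border and touches_border:
            status = "border"
        elif circ < config.aggregate_circularity:
            status = "aggregate"
        elif mean_interior < dead_cut:
            status = "dead"
        else:
            status = "live"
        out.append(
            DetectedParticle(
                centroid_px=tuple(map(float, region.centroid)),
                area_px=area,
                equivalent_diameter_um=float(eq_d_um),
                circularity=float(circ),
                mean_interior_intensity=mean_interior,
                status=status,
            )
        )
    return out


def measure_population(
    particles: list[DetectedParticle],
    pixel_size_um: float,
    label: str = "original",
    source: str = "",
) -> ParticlePopulation:
    """Equivalent circular diameters (um) of the live particles only."""
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    diams = [
        2.0 * np.sqrt(p.area_px / np.pi) * pixel_size_um
        for p in particles
        if p.status == "live"
    ]
    return ParticlePopulation(np.asarray(diams, dtype=float), label=label, source=source)


def status_counts(particles: list[DetectedParticle]) -> dict[str, int]:
    """Per-status detection counts (the per-field QC record)."""
    counts = {s: 0 for s in STATUSES}
    for p in particles:
        counts[p.status] += 1
    return counts


def read_image(path, pixel_size_um: float, field_id: str = "") -> CalibratedImage:
    """Load an 8/16-bit grayscale or RGB PNG/TIFF as a calibrated image,
    intensities rescaled to [0, 1]."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3 and raw.shape[2] == 4:  # drop alpha
        raw = raw[:, :, :3]
    px = raw.astype(float)
    if raw.dtype == np.uint8:
        px /= 255.0
    elif raw.dtype == np.uint16:
        px /= 65535.0
    return CalibratedImage(px, pixel_size_um, field_id=field_id or str(path))
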
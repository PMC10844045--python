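"""Multi-material classification of a lifetime image.

The pipeline mirrors how an analyst separates materials in one FD-FLIM
frame:

1. intensity gate — pixels below 10 % of the image's maximum fluorescence
   intensity are discarded as noise/soil;
2. the gate masks the phase-dependent lifetime image;
3. per material, pixels whose lifetime falls inside that material's
   mu +/- 3*sigma window are extracted into a binary image;
4. morphological cleanup (erosion -> dilation -> closing -> erosion)
   removes lone noise pixels and fills in-body holes left by the window;
5. the cleaned mask yields the material's relative share of the frame,
   its lifetime statistics, and per-particle size measurements.

Relative shares are always normalized by the full frame pixel count, not
the gated foreground.  Outside-image pixels count as background in all
morphology, so structures shrink at the borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk

from .core import FLIMStack
from .errors import DomainError, StageError, ValidationError
from .histograms import GaussianFit, MaterialRange, gaussian_fit


@dataclass
class BinaryImage:
    """A 0/1 pixel mask with a provenance tag (material or stage name)."""

    pixels: np.ndarray
    label: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError("binary image must be 2-D")
        uniq = np.unique(px)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"binary image may contain only 0/1, got values {uniq}")
        self.pixels = px.astype(np.uint8)

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class MorphologyParams:
    """Structuring-element sizes for the four-step cleanup."""

    erode1_shape: tuple[int, int] = (3, 3)
    dilate_radius_px: int = 2
    close_radius_px: int = 2
    erode2_shape: tuple[int, int] = (3, 3)

    def __post_init__(self):
        sizes = (*self.erode1_shape, self.dilate_radius_px, self.close_radius_px, *self.erode2_shape)
        if any(s < 1 for s in sizes):
            raise ValidationError("all structuring-element sizes must be >= 1")


@dataclass(frozen=True)
class ParticleMeasurement:
    """Bounding-box size of one connected particle, in pixels and um."""

    bbox_rows_px: int
    bbox_cols_px: int
    height_um: float
    width_um: float
    area_px: int
    centroid: tuple[float, float]


@dataclass
class MaterialClassification:
    """Per-material output of the pipeline."""

    name: str
    raw_mask: BinaryImage
    cleaned_mask: BinaryImage
    relative_share_percent: float
    fit: GaussianFit | None
    particles: list[ParticleMeasurement]


@dataclass
class ClassificationResult:
    """Everything the multi-material pipeline produces for one stack."""

    materials: dict[str, MaterialClassification]
    intensity_mask: BinaryImage
    masked_tau: np.ndarray  # the preprocessed lifetime image (NaN = gated out)
    ambiguous_pixels: int  # pixels claimed by more than one material range
    threshold_fraction: float
    morphology: MorphologyParams
    stats_after_cleanup: bool


def intensity_mask(intensity_layer: np.ndarray, threshold_fraction: float = 0.10) -> BinaryImage:
    """Gate on fluorescence intensity: 1 iff >= threshold_fraction * image max.

    Pixels exactly at the threshold are kept as foreground.
    """
    img = np.asarray(intensity_layer, dtype=float)
    peak = np.nanmax(img) if img.size else 0.0
    if not np.isfinite(peak) or peak <= 0:
        raise DomainError("intensity image has no positive values to threshold against")
    with np.errstate(invalid="ignore"):
        mask = (img >= threshold_fraction * peak).astype(np.uint8)
    return BinaryImage(mask, label="intensity>=%.0f%%" % (100 * threshold_fraction))


def mask_lifetimes(tau_phase: np.ndarray, mask: BinaryImage) -> np.ndarray:
    """Apply the intensity gate to the lifetime image.

    Gated-out pixels become NaN so that they are excluded from every
    downstream statistic (the on-disk representation writes them as 0).
    """
    tau = np.asarray(tau_phase, dtype=float)
    if tau.shape != mask.pixels.shape:
        raise ValidationError(f"shape mismatch: {tau.shape} vs {mask.pixels.shape}")
    return np.where(mask.pixels == 1, tau, np.nan)


def extract_range(tau_img: np.ndarray, mat_range: MaterialRange) -> BinaryImage:
    """Binary image of valid pixels whose lifetime lies in the closed window."""
    return BinaryImage(mat_range.contains(tau_img).astype(np.uint8), label=mat_range.name)


def _rect(shape: tuple[int, int]) -> np.ndarray:
    return np.ones(shape, dtype=bool)


def _check_se(se: np.ndarray, img_shape: tuple[int, int]) -> None:
    if se.shape[0] > img_shape[0] or se.shape[1] > img_shape[1]:
        raise DomainError(
            f"structuring element {se.shape} larger than image {img_shape}"
        )


def binary_erosion(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary erosion; pixels outside the image count as background."""
    _check_se(np.asarray(se, bool), mask.shape)
    return ndimage.binary_erosion(mask.astype(bool), structure=se, border_value=0)


def binary_dilation(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary dilation; pixels outside the image count as background."""
    _check_se(np.asarray(se, bool), mask.shape)
    return ndimage.binary_dilation(mask.astype(bool), structure=se, border_value=0)


def binary_closing(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Dilation followed by erosion with the same element (fills small holes)."""
    return binary_erosion(binary_dilation(mask, se), se)


def morphological_cleanup(mask: BinaryImage, p: MorphologyParams = MorphologyParams()) -> BinaryImage:
    """Four-step cleanup: erosion(rect) -> dilation(disk) -> closing(disk) -> erosion(rect).

    The first erosion deletes isolated noise pixels, dilation and closing
    restore body pixels that fell outside the lifetime window, and the final
    erosion smooths edges back toward the original outline.
    """
    m = mask.pixels.astype(bool)
    m = binary_erosion(m, _rect(p.erode1_shape))
    m = binary_dilation(m, disk(p.dilate_radius_px).astype(bool))
    m = binary_closing(m, disk(p.close_radius_px).astype(bool))
    m = binary_erosion(m, _rect(p.erode2_shape))
    return BinaryImage(m.astype(np.uint8), label=mask.label + "|cleaned")


def relative_share(mask: BinaryImage) -> float:
    """Percentage of all image pixels set to 1."""
    return 100.0 * mask.count / mask.pixels.size


def pixel_size_um(magnification: float, sensor_pixel_um: float = 5.6) -> float:
    """Projected pixel edge in the sample plane: sensor pixel / magnification."""
    if magnification <= 0:
        raise DomainError("magnification must be > 0")
    return sensor_pixel_um / magnification


def measure_particles(
    mask: BinaryImage, pixel_size_um: float, connectivity: int = 2
) -> list[ParticleMeasurement]:
    """Connected components (8-connected by default) with physical bbox sizes.

    ``connectivity`` follows scikit-image: 2 = 8-connected, 1 = 4-connected.
    Returned sorted by area, largest first.
    """
    labelled = sk_label(mask.pixels, connectivity=connectivity)
    out = []
    for region in regionprops(labelled):
        r0, c0, r1, c1 = region.bbox
        out.append(
            ParticleMeasurement(
                bbox_rows_px=r1 - r0,
                bbox_cols_px=c1 - c0,
                height_um=(r1 - r0) * pixel_size_um,
                width_um=(c1 - c0) * pixel_size_um,
                area_px=int(region.area),
                centroid=tuple(float(x) for x in region.centroid),
            )
        )
    out.sort(key=lambda p: p.area_px, reverse=True)
    return out


def classify(
    stack: FLIMStack,
    materials: list[MaterialRange],
    threshold_fraction: float = 0.10,
    morphology: MorphologyParams = MorphologyParams(),
    stats_after_cleanup: bool = True,
) -> ClassificationResult:
    """Run the full multi-material pipeline on a 5-layer stack.

    For each material range: extract its lifetime window from the
    intensity-gated tau_PH image, clean it morphologically, and report the
    relative share, Gaussian lifetime statistics of the retained pixels,
    and per-particle sizes.  ``stats_after_cleanup=False`` computes the
    Gaussian statistics on the raw (pre-cleanup) extraction instead.
    """
    if len(materials) == 0:
        raise ValidationError("need at least one material range")

    try:
        gate = intensity_mask(stack.intensity, threshold_fraction)
    except Exception as e:  # noqa: BLE001 - re-raise with stage name
        raise StageError("intensity_mask", str(e)) from e
    try:
        masked_tau = mask_lifetimes(stack.tau_phase, gate)
    except Exception as e:
        raise StageError("mask_lifetimes", str(e)) from e

    px_um = stack.pixel_size_um
    per_material: dict[str, MaterialClassification] = {}
    claim_count = np.zeros(stack.shape, dtype=np.uint8)
    for mat in materials:
        try:
            raw = extract_range(masked_tau, mat)
            claim_count += raw.pixels
            cleaned = morphological_cleanup(raw, morphology)
            share = relative_share(cleaned)
            stats_mask = cleaned if stats_after_cleanup else raw
            tau_sel = masked_tau[stats_mask.pixels == 1]
            tau_sel = tau_sel[np.isfinite(tau_sel)]
            fit = gaussian_fit(tau_sel) if tau_sel.size >= 2 else None
            particles = measure_particles(cleaned, px_um)
        except Exception as e:
            raise StageError(mat.name or "material", str(e)) from e
        per_material[mat.name] = MaterialClassification(
            name=mat.name,
            raw_mask=raw,
            cleaned_mask=cleaned,
            relative_share_percent=share,
            fit=fit,
            particles=particles,
        )

    return ClassificationResult(
        materials=per_material,
        intensity_mask=gate,
        masked_tau=masked_tau,
        ambiguous_pixels=int(np.sum(claim_count > 1)),
        threshold_fraction=threshold_fraction,
        morphology=morphology,
        stats_after_cleanup=stats_after_cleanup,
    )
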
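"""Ground-truth-labelled synthetic FD-FLIM scenes and emission spectra.

The generator emulates a pco.flim-style acquisition: a 1004 x 1008 frame
where each placed region belongs to a material whose per-pixel lifetime is
drawn from a Gaussian (mu, sigma) — the same distributional assumption the
Gaussian evaluation makes — and whose raw phase/modulation layers are
produced by the single-exponential forward model, so the stack is
physically self-consistent.  The soil background is modelled as dim,
broadly distributed lifetime noise: intensity uniform in [0, 8 %] of the
brightest material so it falls below the 10 % intensity gate, lifetimes
uniform on [0.2, 5] ns.  That background model is an engineering stand-in,
not a measured soil characterisation.

Default material parameters are the calibration values measured per
optical filter (BP 495-550 nm unless suffixed ``_lp``): HDPE 3.52 +/- 0.21
ns, spruce 1.40 +/- 0.12 ns; under the LP filter grass 1.15 +/- 0.08 ns,
HDPE 1.68 +/- 0.07 ns, spruce 1.54 +/- 0.07 ns.  Emission spectra are sums
of Gaussian bands: HDPE at 528 nm (polymer) and 594 nm (red dye), spruce at
563 nm (lignin), grass at 691/719/741 nm (chlorophyll a) — the grass bands
lie entirely outside the 495-550 nm band-pass, so grass vanishes under the
BP filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as sk_polygon

from .core import FLIMStack, lifetime_to_modindex, lifetime_to_phase
from .errors import DomainError, ValidationError
from .spectral import Spectrum

DEFAULT_SHAPE = (1004, 1008)


@dataclass(frozen=True)
class MaterialModel:
    """Generative model of one material: lifetime distribution, brightness, spectrum."""

    name: str
    tau_mu_ns: float
    tau_sigma_ns: float
    mean_intensity: float = 1000.0
    #: list of (center nm, Gaussian width nm, relative amplitude)
    emission_peaks: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self):
        if self.tau_mu_ns <= 0 or self.tau_sigma_ns < 0 or self.mean_intensity <= 0:
            raise ValidationError(f"non-physical material parameters for {self.name!r}")


#: Calibration-derived material library (keys suffixed _lp are LP-filter values).
MATERIAL_LIBRARY: dict[str, MaterialModel] = {
    "HDPE": MaterialModel(
        "HDPE", 3.52, 0.21, mean_intensity=1000.0,
        emission_peaks=((528.0, 8.0, 1.0), (594.0, 10.0, 0.8)),
    ),
    "spruce": MaterialModel(
        "spruce", 1.40, 0.12, mean_intensity=800.0,
        emission_peaks=((563.0, 9.0, 1.0),),
    ),
    "grass": MaterialModel(
        "grass", 1.15, 0.08, mean_intensity=600.0,
        # widths narrow enough that the overlapping bands peak at the band
        # centres rather than pulling each other's apex
        emission_peaks=((691.0, 6.0, 1.0), (719.0, 6.0, 0.9), (741.0, 6.0, 0.75)),
    ),
    "HDPE_lp": MaterialModel(
        "HDPE_lp", 1.68, 0.07, mean_intensity=1200.0,
        emission_peaks=((528.0, 8.0, 1.0), (594.0, 10.0, 0.8)),
    ),
    "spruce_lp": MaterialModel(
        "spruce_lp", 1.54, 0.07, mean_intensity=900.0,
        emission_peaks=((563.0, 9.0, 1.0),),
    ),
    "grass_lp": MaterialModel(
        "grass_lp", 1.15, 0.08, mean_intensity=600.0,
        emission_peaks=((691.0, 6.0, 1.0), (719.0, 6.0, 0.9), (741.0, 6.0, 0.75)),
    ),
}


@dataclass(frozen=True)
class Region:
    """A placed sample piece: rectangle, ellipse or polygon of one material."""

    material: str
    shape: str = "rectangle"  # rectangle | ellipse | polygon
    origin: tuple[int, int] | None = None  # rectangle: top-left (row, col)
    size: tuple[int, int] | None = None  # rectangle: (height, width) px
    center: tuple[float, float] | None = None  # ellipse
    radii: tuple[float, float] | None = None  # ellipse: (row, col) semi-axes
    vertices: tuple[tuple[float, float], ...] | None = None  # polygon (row, col)


@dataclass(frozen=True)
class BackgroundModel:
    """Dim soil-like background under the intensity gate."""

    intensity_fraction: float = 0.08  # of the brightest material's mean
    tau_range_ns: tuple[float, float] = (0.2, 5.0)

    def __post_init__(self):
        if not 0 <= self.intensity_fraction < 1:
            raise ValidationError("background intensity fraction must be in [0, 1)")


@dataclass
class SceneSpec:
    """Declarative description of a synthetic scene."""

    shape: tuple[int, int] = DEFAULT_SHAPE
    regions: list[Region] = field(default_factory=list)
    background: BackgroundModel = field(default_factory=BackgroundModel)
    intensity_cv: float = 0.10  # multiplicative intensity noise, coefficient of variation
    magnification: float = 10.0
    seed: int = 0


def material_ids(spec: SceneSpec) -> dict[str, int]:
    """Material name -> integer label, in order of first appearance (0 = background)."""
    ids: dict[str, int] = {}
    for region in spec.regions:
        if region.material not in ids:
            ids[region.material] = len(ids) + 1
    return ids


def _region_mask(region: Region, shape: tuple[int, int]) -> np.ndarray:
    n_rows, n_cols = shape
    mask = np.zeros(shape, dtype=bool)
    if region.shape == "rectangle":
        if region.origin is None or region.size is None:
            raise ValidationError("rectangle region needs origin and size")
        r0, c0 = region.origin
        h, w = region.size
        if r0 < 0 or c0 < 0 or r0 + h > n_rows or c0 + w > n_cols or h < 1 or w < 1:
            raise DomainError(f"rectangle {region} out of bounds for {shape}")
        mask[r0 : r0 + h, c0 : c0 + w] = True
    elif region.shape == "ellipse":
        if region.center is None or region.radii is None:
            raise ValidationError("ellipse region needs center and radii")
        rc, cc = region.center
        rr, cr = region.radii
        if rc - rr < 0 or cc - cr < 0 or rc + rr > n_rows - 1 or cc + cr > n_cols - 1:
            raise DomainError(f"ellipse {region} out of bounds for {shape}")
        rows, cols = np.ogrid[:n_rows, :n_cols]
        mask |= ((rows - rc) / rr) ** 2 + ((cols - cc) / cr) ** 2 <= 1.0
    elif region.shape == "polygon":
        if region.vertices is None:
            raise ValidationError("polygon region needs vertices")
        verts = np.asarray(region.vertices, dtype=float)
        if verts[:, 0].min() < 0 or verts[:, 1].min() < 0 or verts[:, 0].max() > n_rows - 1 or verts[:, 1].max() > n_cols - 1:
            raise DomainError(f"polygon {region} out of bounds for {shape}")
        rr, cc = sk_polygon(verts[:, 0], verts[:, 1], shape=shape)
        mask[rr, cc] = True
    else:
        raise ValidationError(f"unknown region shape {region.shape!r}")
    return mask


def render_labels(spec: SceneSpec) -> np.ndarray:
    """Deterministic rasterization into a per-pixel material-id image.

    Later regions overwrite earlier ones; 0 is background.
    """
    ids = material_ids(spec)
    labels = np.zeros(spec.shape, dtype=np.int32)
    for region in spec.regions:
        labels[_region_mask(region, spec.shape)] = ids[region.material]
    return labels


def render_stack(
    spec: SceneSpec,
    materials: dict[str, MaterialModel] | None = None,
    mod_freq_hz: float = 30e6,
    seed: int | None = None,
) -> tuple[FLIMStack, np.ndarray]:
    """Render a physically self-consistent 5-layer stack plus its label image.

    Per foreground pixel, tau ~ Normal(mu, sigma) truncated at 0; the phase
    and modulation layers are the exact single-exponential forward model of
    that tau, so re-deriving lifetimes from the raw layers reproduces the
    drawn tau map.  Fully reproducible for a fixed seed.
    """
    if materials is None:
        materials = MATERIAL_LIBRARY
    ids = material_ids(spec)
    for name in ids:
        if name not in materials:
            raise ValidationError(f"unknown material {name!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    labels = render_labels(spec)
    tau = np.zeros(spec.shape, dtype=float)
    intensity = np.zeros(spec.shape, dtype=float)

    max_fg_intensity = max(
        (materials[n].mean_intensity for n in ids), default=1000.0
    )
    # background first so the draw order (background, then materials in id
    # order) is independent of region order
    bg = labels == 0
    n_bg = int(bg.sum())
    if n_bg:
        lo, hi = spec.background.tau_range_ns
        tau[bg] = rng.uniform(lo, hi, size=n_bg)
        intensity[bg] = rng.uniform(
            0.0, spec.background.intensity_fraction * max_fg_intensity, size=n_bg
        )
    for name, mid in ids.items():
        mat = materials[name]
        sel = labels == mid
        n = int(sel.sum())
        if n == 0:
            continue
        tau[sel] = np.clip(rng.normal(mat.tau_mu_ns, mat.tau_sigma_ns, size=n), 0.0, None)
        intensity[sel] = np.clip(
            mat.mean_intensity * (1.0 + spec.intensity_cv * rng.standard_normal(n)), 0.0, None
        )

    phase = lifetime_to_phase(tau, mod_freq_hz)
    mod_index = lifetime_to_modindex(tau, mod_freq_hz)
    stack = FLIMStack(
        intensity=intensity,
        phase_shift=phase,
        mod_index=mod_index,
        tau_phase=tau.copy(),
        tau_mod=tau.copy(),
        mod_freq_hz=mod_freq_hz,
        magnification=spec.magnification,
    )
    return stack, labels


def render_spectrum(
    material: MaterialModel,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Sum-of-Gaussian-bands emission spectrum on ``grid`` (default 200-1000 nm, 1 nm)."""
    if grid is None:
        grid = np.arange(200.0, 1001.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise ValidationError("wavelength grid must be strictly increasing")
    intens = np.zeros_like(grid)
    for center, width, amplitude in material.emission_peaks:
        intens += amplitude * np.exp(-0.5 * ((grid - center) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intens = intens + rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(wavelength_nm=grid, intensity=np.clip(intens, 0.0, None))


def experiment_iii_scene(seed: int = 0) -> SceneSpec:
    """Three large abutting samples (spruce top, HDPE lower-left, grass right).

    Mirrors the high-ratio arrangement imaged at 10x under the BP filter,
    where grass is spectrally blocked and survives only as noise.
    """
    n_rows, n_cols = DEFAULT_SHAPE
    return SceneSpec(
        shape=DEFAULT_SHAPE,
        regions=[
            Region("spruce", origin=(0, 0), size=(360, n_cols)),
            Region("HDPE", origin=(360, 0), size=(n_rows - 360, 560)),
            # grass under the BP filter: dim, noise-like — modelled as a
            # low-intensity material entry added by callers if desired;
            # left as soil-like background here.
        ],
        magnification=10.0,
        seed=seed,
    )


def experiment_iv_scene(seed: int = 0) -> SceneSpec:
    """Small HDPE chips and spruce splinters scattered on soil at 2x.

    Chip sizes follow the stated sample dimensions at the 2.8 um pixel
    scale, including a 25 x 35 px chip at the detection limit.
    """
    return SceneSpec(
        shape=DEFAULT_SHAPE,
        regions=[
            Region("spruce", origin=(120, 620), size=(520, 90)),
            Region("spruce", origin=(700, 150), size=(90, 420)),
            Region("HDPE", origin=(150, 120), size=(120, 100)),
            Region("HDPE", origin=(420, 350), size=(60, 50)),
            Region("HDPE", origin=(850, 700), size=(25, 35)),
        ],
        magnification=2.0,
        seed=seed,
    )


SCENE_PRESETS = {
    "experiment3": experiment_iii_scene,
    "experiment4": experiment_iv_scene,
}
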
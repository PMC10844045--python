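"""Reading and writing the on-disk formats.

Stacks are plain multi-page, single-channel, 32-bit float TIFFs with no
compression, one page per layer in the order intensity, phase shift,
modulation index, tau_PH, tau_M.  Because TIFF tags cannot carry the
acquisition parameters unambiguously, metadata lives in a human-readable
``key = value`` sidecar which also declares the pixel-value units (phase in
radians or degrees, lifetimes in ns).  Spectra and material databases are
small CSV files; binary masks are 8-bit 0/255 TIFFs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .classify import BinaryImage
from .core import FLIMStack, LAYER_NAMES
from .errors import FormatError, ValidationError
from .histograms import GaussianFit, MaterialRange, material_range
from .spectral import BP495_550, LP500, OpticalFilter, Spectrum
from .synthetic import BackgroundModel, Region, SceneSpec


@dataclass
class StackMetadata:
    """Acquisition metadata stored in the stack's sidecar file."""

    mod_freq_hz: float = 30e6
    magnification: float = 10.0
    exposure_ms: float = 400.0
    emission_filter: str = "BP495-550"
    sensor_pixel_um: float = 5.6
    phase_unit: str = "rad"  # rad | deg
    lifetime_unit: str = "ns"
    layer_order: tuple[str, ...] = LAYER_NAMES

    def __post_init__(self):
        if sorted(self.layer_order) != sorted(LAYER_NAMES):
            raise ValidationError(
                f"layer_order must be a permutation of {LAYER_NAMES}, got {self.layer_order}"
            )
        if self.phase_unit not in ("rad", "deg"):
            raise ValidationError("phase_unit must be 'rad' or 'deg'")
        if self.lifetime_unit != "ns":
            raise ValidationError("only ns lifetimes are supported on disk")


def parse_filter(descriptor: str) -> OpticalFilter:
    """Parse 'LP500' / 'BP495-550' style filter descriptors."""
    d = descriptor.strip().upper()
    try:
        if d.startswith("LP"):
            return OpticalFilter("LP", float(d[2:]))
        if d.startswith("BP"):
            lo, hi = d[2:].replace(":", "-").split("-")
            return OpticalFilter("BP", float(lo), float(hi))
    except (ValueError, ValidationError) as e:
        raise FormatError(f"cannot parse filter descriptor {descriptor!r}: {e}") from e
    raise FormatError(f"cannot parse filter descriptor {descriptor!r}")


def write_metadata(meta: StackMetadata, path: str | Path) -> None:
    lines = [
        f"mod_freq_hz = {meta.mod_freq_hz!r}",
        f"magnification = {meta.magnification!r}",
        f"exposure_ms = {meta.exposure_ms!r}",
        f"emission_filter = {meta.emission_filter}",
        f"sensor_pixel_um = {meta.sensor_pixel_um!r}",
        f"phase_unit = {meta.phase_unit}",
        f"lifetime_unit = {meta.lifetime_unit}",
        "layer_order = " + ",".join(meta.layer_order),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> StackMetadata:
    kv: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    try:
        return StackMetadata(
            mod_freq_hz=float(kv.get("mod_freq_hz", 30e6)),
            magnification=float(kv.get("magnification", 10.0)),
            exposure_ms=float(kv.get("exposure_ms", 400.0)),
            emission_filter=kv.get("emission_filter", "BP495-550"),
            sensor_pixel_um=float(kv.get("sensor_pixel_um", 5.6)),
            phase_unit=kv.get("phase_unit", "rad"),
            lifetime_unit=kv.get("lifetime_unit", "ns"),
            layer_order=tuple(kv["layer_order"].split(",")) if "layer_order" in kv else LAYER_NAMES,
        )
    except (ValueError, ValidationError) as e:
        raise FormatError(f"invalid metadata in {path}: {e}") from e


def write_stack(stack: FLIMStack, path: str | Path, metadata_path: str | Path | None = None,
                exposure_ms: float = 400.0, emission_filter: str = "BP495-550") -> StackMetadata:
    """Write a 5-page float32 TIFF plus its sidecar; bit-exact round trip."""
    pages = np.stack([stack.layers()[n].astype(np.float32) for n in LAYER_NAMES])
    tifffile.imwrite(str(path), pages, photometric="minisblack")
    meta = StackMetadata(
        mod_freq_hz=stack.mod_freq_hz,
        magnification=stack.magnification,
        exposure_ms=exposure_ms,
        emission_filter=emission_filter,
        sensor_pixel_um=stack.sensor_pixel_um,
    )
    if metadata_path is None:
        metadata_path = Path(path).with_suffix(".meta")
    write_metadata(meta, metadata_path)
    return meta


def read_stack(path: str | Path, metadata_path: str | Path | None = None,
               metadata: StackMetadata | None = None) -> FLIMStack:
    """Read a 5-page single-channel TIFF into a validated FLIMStack.

    Layer assignment follows the sidecar's ``layer_order``; defaults are
    used when no sidecar is present.  Phase layers declared in degrees are
    converted to radians.
    """
    if metadata is None:
        if metadata_path is None:
            candidate = Path(path).with_suffix(".meta")
            metadata = read_metadata(candidate) if candidate.exists() else StackMetadata()
        else:
            metadata = read_metadata(metadata_path)
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected single-channel pages, got array of ndim {arr.ndim}")
    if arr.shape[0] != 5:
        raise FormatError(f"{path}: expected a 5-page stack, got {arr.shape[0]} pages")
    layers = {name: arr[i].astype(float) for i, name in enumerate(metadata.layer_order)}
    if metadata.phase_unit == "deg":
        layers["phase_shift"] = np.deg2rad(layers["phase_shift"])
    return FLIMStack(
        **layers,
        mod_freq_hz=metadata.mod_freq_hz,
        magnification=metadata.magnification,
        sensor_pixel_um=metadata.sensor_pixel_um,
    )


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Two-column comma-separated text: wavelength nm, intensity a.u."""
    with open(path, "w") as fh:
        for wl, it in zip(s.wavelength_nm, s.intensity):
            fh.write(f"{float(wl)!r},{float(it)!r}\n")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column comma-separated spectrum file."""
    wavelengths: list[float] = []
    intensities: list[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 comma-separated columns")
        try:
            wavelengths.append(float(parts[0]))
            intensities.append(float(parts[1]))
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: non-numeric row {line!r}") from e
    wl = np.asarray(wavelengths)
    if wl.size >= 2 and not np.all(np.diff(wl) > 0):
        raise FormatError(f"{path}: wavelengths are not strictly increasing")
    return Spectrum(wavelength_nm=wl, intensity=np.asarray(intensities))


def write_mask(mask: BinaryImage, path: str | Path) -> None:
    """Write a binary mask as an 8-bit TIFF with 1 -> 255 (white)."""
    tifffile.imwrite(str(path), (mask.pixels * 255).astype(np.uint8), photometric="minisblack")


def read_mask(path: str | Path, label: str = "") -> BinaryImage:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be a single 2-D page")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 255))):
        raise FormatError(f"{path}: mask pixels must be 0 or 255, got {uniq}")
    return BinaryImage((arr > 0).astype(np.uint8), label=label or Path(path).stem)


def write_materials(ranges: list[MaterialRange], path: str | Path) -> None:
    """Material database CSV: name, mu_ns, sigma_ns, k."""
    with open(path, "w") as fh:
        fh.write("name,mu_ns,sigma_ns,k\n")
        for r in ranges:
            if r.source_fit is None:
                raise ValidationError(f"range {r.name!r} has no source fit to serialize")
            fh.write(f"{r.name},{r.source_fit.mu!r},{r.source_fit.sigma!r},{r.k!r}\n")


def read_materials(path: str | Path) -> list[MaterialRange]:
    """Read the material database and rebuild the mu +/- k*sigma windows."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip().lower() != "name,mu_ns,sigma_ns,k":
        raise FormatError(f"{path}: expected header 'name,mu_ns,sigma_ns,k'")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        try:
            name, mu, sigma, k = parts[0].strip(), float(parts[1]), float(parts[2]), float(parts[3])
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: non-numeric row {line!r}") from e
        fit = GaussianFit(mu=mu, sigma=sigma, n=1)
        out.append(material_range(fit, name=name, k=k))
    return out


def write_config(config: dict, path: str | Path) -> None:
    """Serialize a run configuration as sorted ``key = value`` lines."""
    with open(path, "w") as fh:
        for key in sorted(config):
            fh.write(f"{key} = {config[key]}\n")


def read_scene_spec(path: str | Path) -> SceneSpec:
    """Read a JSON scene description into a SceneSpec."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: invalid JSON scene spec: {e}") from e
    try:
        regions = [
            Region(
                material=r["material"],
                shape=r.get("shape", "rectangle"),
                origin=tuple(r["origin"]) if "origin" in r else None,
                size=tuple(r["size"]) if "size" in r else None,
                center=tuple(r["center"]) if "center" in r else None,
                radii=tuple(r["radii"]) if "radii" in r else None,
                vertices=tuple(tuple(v) for v in r["vertices"]) if "vertices" in r else None,
            )
            for r in raw.get("regions", [])
        ]
        background = BackgroundModel(**raw.get("background", {}))
        return SceneSpec(
            shape=tuple(raw.get("shape", (1004, 1008))),
            regions=regions,
            background=background,
            intensity_cv=raw.get("intensity_cv", 0.10),
            magnification=raw.get("magnification", 10.0),
            seed=raw.get("seed", 0),
        )
    except (KeyError, TypeError, ValidationError) as e:
        raise FormatError(f"{path}: invalid scene spec: {e}") from e


# expose the instrument's two emitters for CLI convenience
EMITTERS = {"LP500": LP500, "BP495-550": BP495_550}
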
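"""Emission-spectrum evaluation: background subtraction, replicate averaging,
fine-grid interpolation, ideal LP/BP filter models, peak maxima and Stokes
shifts.

The excitation line is 488 nm; a Stokes shift is the distance of an emission
maximum from it.  Filters are modelled as ideal boxcar transmissions (0/1):
a long-pass (LP) filter transmits everything at or above its cut-on, a
band-pass (BP) filter transmits only between cut-on and cut-off.
Anti-Stokes emission is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks as _scipy_find_peaks

from .errors import DomainError, ValidationError

EXCITATION_NM = 488.0


@dataclass(frozen=True)
class OpticalFilter:
    """An ideal emission filter: LP (cut-on only) or BP (cut-on and cut-off)."""

    kind: str  # "LP" or "BP"
    cuton_nm: float
    cutoff_nm: float | None = None

    def __post_init__(self):
        if self.kind not in ("LP", "BP"):
            raise ValidationError(f"filter kind must be 'LP' or 'BP', got {self.kind!r}")
        if self.kind == "BP":
            if self.cutoff_nm is None or not self.cuton_nm < self.cutoff_nm:
                raise ValidationError("BP filter requires cuton_nm < cutoff_nm")
        elif self.cutoff_nm is not None:
            raise ValidationError("LP filter takes no cutoff_nm")

    def transmission(self, wavelength_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelength_nm, dtype=float)
        if self.kind == "LP":
            return (wl >= self.cuton_nm).astype(float)
        return ((wl >= self.cuton_nm) & (wl <= self.cutoff_nm)).astype(float)

    def __str__(self) -> str:
        if self.kind == "LP":
            return f"LP{self.cuton_nm:g}"
        return f"BP{self.cuton_nm:g}-{self.cutoff_nm:g}"


#: The two emitters used on the instrument.
LP500 = OpticalFilter("LP", 500.0)
BP495_550 = OpticalFilter("BP", 495.0, 550.0)


@dataclass
class Spectrum:
    """A wavelength/intensity series with filter provenance."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    filter_applied: OpticalFilter | None = None

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape or self.wavelength_nm.ndim != 1:
            raise ValidationError("wavelength and intensity must be 1-D and equal length")
        if self.wavelength_nm.size >= 2 and not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValidationError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelength_nm.size


@dataclass(frozen=True)
class SpectralPeak:
    """An emission maximum and its Stokes shift relative to 488 nm excitation."""

    wavelength_nm: float
    intensity: float
    stokes_shift_nm: float


def _check_common_grid(a: Spectrum, b: Spectrum) -> None:
    if a.wavelength_nm.shape != b.wavelength_nm.shape or not np.array_equal(
        a.wavelength_nm, b.wavelength_nm
    ):
        raise ValidationError("spectra are not on a common wavelength grid")


def subtract_background(sample: Spectrum, background: Spectrum) -> Spectrum:
    """Pointwise sample - background, clamped at zero (noise floor removal)."""
    _check_common_grid(sample, background)
    diff = np.clip(sample.intensity - background.intensity, 0.0, None)
    return replace(sample, intensity=diff)


def average_spectra(replicates: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate measurements."""
    if len(replicates) == 0:
        raise ValidationError("need at least one replicate")
    first = replicates[0]
    for rep in replicates[1:]:
        _check_common_grid(first, rep)
    mean = np.mean([r.intensity for r in replicates], axis=0)
    return replace(first, intensity=mean)


def interpolate_spectrum(s: Spectrum, step_nm: float = 0.01, method: str = "linear") -> Spectrum:
    """Resample onto a uniform grid of ``step_nm`` covering the original range.

    Piecewise-linear by default (monotone, no overshoot); ``method="cubic"``
    uses a cubic spline.  Original sample points on the new grid are
    reproduced exactly; both endpoints are always included.
    """
    if step_nm <= 0:
        raise DomainError("interpolation step must be > 0 nm")
    if len(s) < 2:
        raise ValidationError("need at least 2 samples to interpolate")
    lo, hi = s.wavelength_nm[0], s.wavelength_nm[-1]
    n = int(np.floor((hi - lo) / step_nm + 1e-9)) + 1
    grid = lo + step_nm * np.arange(n)
    if grid[-1] < hi - 1e-12:
        grid = np.append(grid, hi)
    else:
        grid[-1] = hi
    if method == "linear":
        intens = np.interp(grid, s.wavelength_nm, s.intensity)
    elif method == "cubic":
        intens = CubicSpline(s.wavelength_nm, s.intensity)(grid)
    else:
        raise ValidationError(f"unknown interpolation method {method!r}")
    return replace(s, wavelength_nm=grid, intensity=intens)


def apply_filter(s: Spectrum, f: OpticalFilter) -> Spectrum:
    """Multiply by the ideal boxcar transmission of an LP or BP filter."""
    return Spectrum(
        wavelength_nm=s.wavelength_nm,
        intensity=s.intensity * f.transmission(s.wavelength_nm),
        filter_applied=f,
    )


def find_peaks(
    s: Spectrum,
    prominence_fraction: float = 0.05,
    excitation_nm: float = EXCITATION_NM,
) -> list[SpectralPeak]:
    """Local maxima with relative prominence >= ``prominence_fraction``.

    Prominence is measured relative to the global intensity maximum, which
    resolves closely spaced maxima (e.g. the chlorophyll triplet of grass)
    while ignoring noise.  Peaks are returned sorted by wavelength, each
    carrying its Stokes shift.
    """
    peak_max = float(np.max(s.intensity)) if len(s) else 0.0
    if peak_max <= 0:
        return []
    idx, _ = _scipy_find_peaks(s.intensity, prominence=prominence_fraction * peak_max)
    return [
        SpectralPeak(
            wavelength_nm=float(s.wavelength_nm[i]),
            intensity=float(s.intensity[i]),
            stokes_shift_nm=float(s.wavelength_nm[i] - excitation_nm),
        )
        for i in idx
    ]


def stokes_shift(peak_nm: float, excitation_nm: float = EXCITATION_NM) -> float:
    """Stokes shift = emission maximum - excitation wavelength, in nm."""
    if peak_nm < excitation_nm:
        raise DomainError(
            f"peak at {peak_nm} nm lies below the {excitation_nm} nm excitation "
            "(anti-Stokes emission is not modelled)"
        )
    return peak_nm - excitation_nm


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Divide by the maximum intensity so the peak value is exactly 1."""
    peak = float(np.max(s.intensity))
    if peak <= 0:
        raise DomainError("cannot normalize an all-zero spectrum")
    return replace(s, intensity=s.intensity / peak)
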
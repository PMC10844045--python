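"""Frequency-domain fluorimetry equations and the 5-layer image-stack model.

In frequency-domain FLIM the sample is excited with sinusoidally modulated
light at modulation frequency f (angular frequency omega = 2*pi*f).  The
emission is phase-shifted by phi and demodulated; for a single-exponential
decay the phase-dependent lifetime is

    tau_PH = tan(phi) / omega

and, from the modulation index M = (b/a)/(B/A),

    tau_M = sqrt(1/M**2 - 1) / omega.

Lifetimes are expressed in nanoseconds throughout the public API; seconds
appear only inside the formulas.  Invalid pixels (phi >= pi/2, M > 1, zero
intensity) are represented by NaN and excluded from all downstream
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InvalidPhaseError, ValidationError

NS_PER_S = 1e9

#: Canonical layer names, in on-disk order.
LAYER_NAMES = ("intensity", "phase_shift", "mod_index", "tau_phase", "tau_mod")


def angular_frequency(mod_freq_hz: float) -> float:
    """omega = 2*pi*f, in rad/s."""
    if mod_freq_hz <= 0:
        raise DomainError(f"modulation frequency must be > 0 Hz, got {mod_freq_hz}")
    return 2.0 * np.pi * mod_freq_hz


def phase_lifetime(phase_shift, mod_freq_hz: float):
    """Phase-dependent lifetime tau_PH = tan(phi)/omega, in ns.

    Parameters
    ----------
    phase_shift : float or ndarray
        Phase lag phi of the emission, radians, in [0, pi/2).
    mod_freq_hz : float
        Modulation frequency f in Hz.
    """
    omega = angular_frequency(mod_freq_hz)
    phi = np.asarray(phase_shift, dtype=float)
    if np.any((phi < 0) | (phi >= np.pi / 2)):
        raise InvalidPhaseError(
            "phase shift must lie in [0, pi/2) for a single-exponential decay"
        )
    tau = np.tan(phi) / omega * NS_PER_S
    return tau if tau.ndim else float(tau)


@dataclass(frozen=True)
class ModulationSignal:
    """Raw amplitudes of the excitation (B, A) and emission (b, a) oscillations.

    B/A are the excitation amplitude and offset; the emission is amplitude-
    damped to b and offset-shifted to a.
    """

    exc_amplitude: float  # B
    exc_offset: float  # A
    em_amplitude: float  # b
    em_offset: float  # a

    def __post_init__(self):
        vals = (self.exc_amplitude, self.exc_offset, self.em_amplitude, self.em_offset)
        if any(v <= 0 for v in vals):
            raise DomainError(f"all signal components must be > 0, got {vals}")
        # Emission cannot be more modulated than the excitation.
        if self.em_amplitude / self.em_offset > self.exc_amplitude / self.exc_offset * (1 + 1e-12):
            raise ValidationError(
                "emission modulation depth b/a exceeds excitation depth B/A"
            )


def modulation_index(sig: ModulationSignal) -> float:
    """Modulation index M = (b/a)/(B/A), dimensionless, in (0, 1]."""
    return (sig.em_amplitude / sig.em_offset) / (sig.exc_amplitude / sig.exc_offset)


def modulation_lifetime(mod_index, mod_freq_hz: float):
    """Modulation-dependent lifetime tau_M = sqrt(1/M**2 - 1)/omega, in ns."""
    omega = angular_frequency(mod_freq_hz)
    m = np.asarray(mod_index, dtype=float)
    if np.any((m <= 0) | (m > 1)):
        raise DomainError("modulation index must lie in (0, 1]")
    tau = np.sqrt(1.0 / m**2 - 1.0) / omega * NS_PER_S
    return tau if tau.ndim else float(tau)


def lifetime_to_phase(lifetime_ns, mod_freq_hz: float):
    """Analytic inverse of the phase equation: phi = arctan(omega*tau), radians."""
    omega = angular_frequency(mod_freq_hz)
    tau = np.asarray(lifetime_ns, dtype=float)
    if np.any(tau < 0):
        raise DomainError("lifetime must be >= 0 ns")
    phi = np.arctan(omega * tau / NS_PER_S)
    return phi if phi.ndim else float(phi)


def lifetime_to_modindex(lifetime_ns, mod_freq_hz: float):
    """Single-exponential forward model M = 1/sqrt(1 + (omega*tau)**2)."""
    omega = angular_frequency(mod_freq_hz)
    tau = np.asarray(lifetime_ns, dtype=float)
    if np.any(tau < 0):
        raise DomainError("lifetime must be >= 0 ns")
    m = 1.0 / np.sqrt(1.0 + (omega * tau / NS_PER_S) ** 2)
    return m if m.ndim else float(m)


@dataclass
class FLIMStack:
    """The 5-layer FD-FLIM image plus acquisition metadata.

    Layers (all 2-D, identical shape): fluorescence ``intensity`` (a.u.,
    >= 0), ``phase_shift`` phi (radians), ``mod_index`` M (dimensionless),
    ``tau_phase`` tau_PH (ns) and ``tau_mod`` tau_M (ns).  Invalid pixels
    hold NaN.
    """

    intensity: np.ndarray
    phase_shift: np.ndarray
    mod_index: np.ndarray
    tau_phase: np.ndarray
    tau_mod: np.ndarray
    mod_freq_hz: float = 30e6
    magnification: float = 10.0
    sensor_pixel_um: float = 5.6

    def __post_init__(self):
        layers = [np.asarray(getattr(self, n), dtype=float) for n in LAYER_NAMES]
        shapes = {l.shape for l in layers}
        if len(shapes) != 1 or layers[0].ndim != 2:
            raise ValidationError(f"all five layers must share one 2-D shape, got {shapes}")
        for name, layer in zip(LAYER_NAMES, layers):
            setattr(self, name, layer)
        if self.mod_freq_hz <= 0:
            raise ValidationError("mod_freq_hz must be > 0")
        if self.magnification <= 0:
            raise ValidationError("magnification must be > 0")
        m = self.mod_index
        if np.any((m[np.isfinite(m)] < 0) | (m[np.isfinite(m)] > 1)):
            raise ValidationError("mod_index values must lie in [0, 1] where defined")
        phi = self.phase_shift
        if np.any((phi[np.isfinite(phi)] < 0) | (phi[np.isfinite(phi)] >= np.pi / 2)):
            raise ValidationError("phase_shift values must lie in [0, pi/2) where defined")
        for name in ("tau_phase", "tau_mod"):
            t = getattr(self, name)
            if np.any(t[np.isfinite(t)] < 0):
                raise ValidationError(f"{name} values must be >= 0 where defined")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    @property
    def n_rows(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensity.shape[1]

    @property
    def pixel_size_um(self) -> float:
        """Projected pixel edge in the sample plane, um."""
        return self.sensor_pixel_um / self.magnification

    def layers(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in LAYER_NAMES}


def derive_lifetime_layers(
    intensity: np.ndarray,
    phase_shift: np.ndarray,
    mod_index: np.ndarray,
    mod_freq_hz: float,
    **stack_kwargs,
) -> FLIMStack:
    """Build a FLIMStack by applying the lifetime equations pixelwise.

    Pixels with non-physical phi (outside [0, pi/2)), M (outside (0, 1]) or
    zero intensity get NaN in the derived lifetime layers — never silently
    clipped.
    """
    intensity = np.asarray(intensity, dtype=float)
    phi = np.asarray(phase_shift, dtype=float)
    m = np.asarray(mod_index, dtype=float)
    if not (intensity.shape == phi.shape == m.shape):
        raise ValidationError(
            f"layer shapes differ: {intensity.shape}, {phi.shape}, {m.shape}"
        )
    omega = angular_frequency(mod_freq_hz)

    bad = ~np.isfinite(phi) | (phi < 0) | (phi >= np.pi / 2) | (intensity <= 0)
    with np.errstate(invalid="ignore"):
        tau_ph = np.where(bad, np.nan, np.tan(np.where(bad, 0.0, phi)) / omega * NS_PER_S)

    bad_m = ~np.isfinite(m) | (m <= 0) | (m > 1) | (intensity <= 0)
    safe_m = np.where(bad_m, 1.0, m)
    tau_m = np.where(bad_m, np.nan, np.sqrt(1.0 / safe_m**2 - 1.0) / omega * NS_PER_S)

    # the stack validator rejects out-of-range raw phi/M, so blank them too
    phi_clean = np.where(~np.isfinite(phi) | (phi < 0) | (phi >= np.pi / 2), np.nan, phi)
    m_clean = np.where(~np.isfinite(m) | (m < 0) | (m > 1), np.nan, m)
    return FLIMStack(
        intensity=intensity,
        phase_shift=phi_clean,
        mod_index=m_clean,
        tau_phase=tau_ph,
        tau_mod=tau_m,
        mod_freq_hz=mod_freq_hz,
        **stack_kwargs,
    )
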
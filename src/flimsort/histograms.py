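"""Single-material lifetime evaluation: histograms, Gaussian characterization
and the mu +/- k*sigma material acceptance windows.

A homogeneous material imaged by FD-FLIM yields roughly one million
per-pixel lifetimes whose distribution is well described by a normal
distribution.  Its expectation value and standard deviation identify the
material; the window mu +/- 3*sigma ("material range") is what the
multi-material classifier later searches for.

"Gaussian analysis" is implemented as moment estimation (sample mean and
standard deviation) — for Gaussian data this is equivalent to fitting the
histogram but independent of the bin width.  A least-squares histogram fit
is available via ``method="curve_fit"`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateRangeError, DomainError, ValidationError


@dataclass(frozen=True)
class GaussianFit:
    """Expectation value and standard deviation of a lifetime population."""

    mu: float  # ns
    sigma: float  # ns
    n: int  # contributing pixels

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.n < 1:
            raise ValidationError("n must be >= 1")


@dataclass(frozen=True)
class MaterialRange:
    """A named lifetime acceptance window [mu - k*sigma, mu + k*sigma], ns."""

    name: str
    lo: float
    hi: float
    source_fit: GaussianFit | None = None
    k: float = 3.0

    def __post_init__(self):
        if not self.lo < self.hi:
            raise DegenerateRangeError(f"range for {self.name!r} is degenerate: [{self.lo}, {self.hi}]")

    def contains(self, tau: np.ndarray) -> np.ndarray:
        """Closed-interval membership, False on NaN."""
        t = np.asarray(tau, dtype=float)
        with np.errstate(invalid="ignore"):
            return (t >= self.lo) & (t <= self.hi)


def valid_values(tau: np.ndarray) -> np.ndarray:
    """Flatten a lifetime layer and drop sentinel (NaN / non-finite) pixels."""
    t = np.asarray(tau, dtype=float).ravel()
    return t[np.isfinite(t)]


def lifetime_histogram(
    tau_layer: np.ndarray, bin_width_ns: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute-frequency histogram of the valid lifetimes in a layer.

    Returns ``(bin_edges, counts)``; counts sum to the number of valid
    pixels.  Bin edges are aligned to multiples of the bin width.
    """
    if bin_width_ns <= 0:
        raise DomainError("bin width must be > 0 ns")
    vals = valid_values(tau_layer)
    if vals.size == 0:
        raise ValidationError("no valid lifetime pixels to histogram")
    lo = np.floor(vals.min() / bin_width_ns) * bin_width_ns
    hi = np.ceil(vals.max() / bin_width_ns) * bin_width_ns
    if hi <= lo:  # all values in a single degenerate point
        hi = lo + bin_width_ns
    n_bins = int(round((hi - lo) / bin_width_ns))
    edges = lo + bin_width_ns * np.arange(n_bins + 1)
    counts, edges = np.histogram(vals, bins=edges)
    return edges, counts


def gaussian_fit(tau_values: np.ndarray, method: str = "moments") -> GaussianFit:
    """Characterize a lifetime population by expectation value and SD.

    ``method="moments"`` (default) uses the sample mean and sample standard
    deviation (ddof=1).  ``method="curve_fit"`` least-squares fits a Gaussian
    to the 0.05 ns histogram instead; both agree for Gaussian data.
    """
    vals = valid_values(tau_values)
    if vals.size < 2:
        raise ValidationError(f"need >= 2 valid values to fit, got {vals.size}")
    if method == "moments":
        return GaussianFit(mu=float(vals.mean()), sigma=float(vals.std(ddof=1)), n=vals.size)
    if method == "curve_fit":
        edges, counts = lifetime_histogram(vals, bin_width_ns=0.05)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def gauss(x, amp, mu, sigma):
            return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

        p0 = (counts.max(), vals.mean(), max(vals.std(ddof=1), 0.05))
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
        return GaussianFit(mu=float(popt[1]), sigma=float(abs(popt[2])), n=vals.size)
    raise ValidationError(f"unknown fit method {method!r}")


def material_range(fit: GaussianFit, name: str = "", k: float = 3.0) -> MaterialRange:
    """Build the mu +/- k*sigma acceptance window from a single-material fit."""
    if fit.sigma <= 0 or k <= 0:
        raise DegenerateRangeError(
            "sigma and k must be > 0 to define a range; supply an explicit "
            "width override for degenerate populations"
        )
    return MaterialRange(
        name=name, lo=fit.mu - k * fit.sigma, hi=fit.mu + k * fit.sigma, source_fit=fit, k=k
    )


def normalized_gaussian_curve(fit: GaussianFit, grid: np.ndarray) -> np.ndarray:
    """Gaussian density on ``grid`` scaled to peak value 1 (for plotting)."""
    if fit.sigma <= 0:
        raise ValidationError("sigma must be > 0 for a curve")
    x = np.asarray(grid, dtype=float)
    return np.exp(-0.5 * ((x - fit.mu) / fit.sigma) ** 2)
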
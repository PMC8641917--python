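"""Lamellar-period extraction from neutron diffraction peak tables.

Aligned membrane multilayers produce Bragg peaks where the specular
condition Gamma = 2 * Omega coincides with the Bragg condition
Gamma = 2 * arcsin(n * lambda / (2 * D)). The lamellar period D — equal to
the average membrane separation in the stack — follows by inverting the
Bragg condition per peak order and averaging. Angles are degrees at the
interface and radians internally. Detector-image reduction and peak
picking are out of scope; the input is a peak table
``omega_deg gamma_deg intensity``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import MalformedInputError, NumericError, UndefinedEstimateError, UsageError

__all__ = [
    "DiffractionPeak",
    "LamellarFit",
    "bragg_gamma",
    "check_specular",
    "lamellar_period",
    "simulate_peak_table",
    "read_peak_table",
    "write_peak_table",
]

DEFAULT_WAVELENGTH = 0.474  # nm, cold-neutron diffractometer setting


@dataclass
class DiffractionPeak:
    omega: float  # incidence angle, degrees
    gamma: float  # scattering angle, degrees
    intensity: float = 1.0
    order: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 180:
            raise UsageError(f"gamma must lie in (0, 180) degrees, got {self.gamma}")
        if self.intensity < 0:
            raise UsageError("intensity must be non-negative")


@dataclass
class LamellarFit:
    D: float  # nm, intensity-weighted mean over orders
    wavelength: float
    per_order: list[tuple[int, float]] = field(default_factory=list)  # (n, D_n)
    residuals: list[float] = field(default_factory=list)  # D_n - D

    def to_dict(self) -> dict:
        return {
            "D_nm": self.D,
            "wavelength_nm": self.wavelength,
            "per_order": [{"n": n, "D_nm": d} for n, d in self.per_order],
            "residuals_nm": self.residuals,
        }

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def bragg_gamma(D: float, wavelength: float, n: int) -> float:
    """Scattering angle (degrees) of order n: Gamma = 2 arcsin(n lambda / (2 D))."""
    if D <= 0 or wavelength <= 0 or n < 1:
        raise UsageError("need D > 0, wavelength > 0, n >= 1")
    x = n * wavelength / (2.0 * D)
    if x > 1:
        raise NumericError(
            f"order {n} has no Bragg solution: n*lambda/(2D) = {x:.4g} > 1"
        )
    return float(np.degrees(2.0 * np.arcsin(x)))


def check_specular(peak: DiffractionPeak, tolerance: float = 0.1) -> bool:
    """Accept a peak iff |Gamma - 2*Omega| <= tolerance (degrees)."""
    if tolerance <= 0:
        raise UsageError("tolerance must be positive")
    return abs(peak.gamma - 2.0 * peak.omega) <= tolerance


def lamellar_period(
    peaks: list[DiffractionPeak],
    wavelength: float = DEFAULT_WAVELENGTH,
    intensity_weighted: bool = True,
) -> LamellarFit:
    """Invert the Bragg condition per peak and average the period.

    Orders are assigned by ascending Gamma starting at n = 1 unless every
    peak already carries one. The average is intensity-weighted by default
    (uniform if intensities are absent or disabled); per-order estimates
    and residuals are reported alongside.
    """
    if not peaks:
        raise UndefinedEstimateError("no specular-accepted peaks: empty fit")
    if all(p.order is not None for p in peaks):
        ordered = sorted(peaks, key=lambda p: p.order)
        if any(
            b.gamma <= a.gamma for a, b in zip(ordered, ordered[1:])
        ):
            raise MalformedInputError(
                "assigned orders are not monotone in scattering angle"
            )
    else:
        ordered = sorted(peaks, key=lambda p: p.gamma)
        for i, p in enumerate(ordered, start=1):
            p.order = i
    per_order = []
    weights = []
    for p in ordered:
        d_n = p.order * wavelength / (2.0 * np.sin(np.radians(p.gamma) / 2.0))
        per_order.append((p.order, float(d_n)))
        weights.append(p.intensity if intensity_weighted else 1.0)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        weights = np.ones_like(weights)
    values = np.array([d for _, d in per_order])
    D = float(np.average(values, weights=weights))
    return LamellarFit(
        D=D,
        wavelength=wavelength,
        per_order=per_order,
        residuals=[float(v - D) for v in values],
    )


def simulate_peak_table(
    D: float,
    wavelength: float = DEFAULT_WAVELENGTH,
    orders: tuple[int, ...] = (1, 2, 3),
    angle_noise_sd: float = 0.0,
    seed: int = 0,
) -> list[DiffractionPeak]:
    """Forward model: specular peaks at the Bragg angles, optional Gaussian
    angle noise (degrees), intensities falling off as 1/n^2."""
    rng = np.random.default_rng(seed)
    peaks = []
    for n in orders:
        gamma = bragg_gamma(D, wavelength, n)
        if angle_noise_sd > 0:
            gamma += rng.normal(0.0, angle_noise_sd)
        peaks.append(
            DiffractionPeak(
                omega=gamma / 2.0, gamma=gamma, intensity=1.0 / n**2, order=None
            )
        )
    return peaks


def read_peak_table(path: str | os.PathLike) -> list[DiffractionPeak]:
    """Read text rows ``omega_deg gamma_deg intensity``."""
    peaks = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise MalformedInputError(
                    f"{path}:{lineno}: expected 'omega gamma [intensity]'"
                )
            peaks.append(
                DiffractionPeak(
                    omega=float(parts[0]),
                    gamma=float(parts[1]),
                    intensity=float(parts[2]) if len(parts) == 3 else 1.0,
                )
            )
    return peaks


def write_peak_table(peaks: list[DiffractionPeak], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# omega_deg gamma_deg intensity\n")
        for p in peaks:
            fh.write(f"{p.omega:.6f} {p.gamma:.6f} {p.intensity:.6g}\n")
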
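"""Spectral curves and their transformations.

Represents wavelength-indexed quantities (radiance, irradiance,
transmittance, sensitivity) and provides photon conversion, transmittance
ratios, band-integrated transmission efficiency, attenuation-coefficient
estimation and depth propagation for downwelling light.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "DEFAULT_GRID",
    "QUANTITIES",
    "SpectralCurve",
    "DepthSeries",
    "AttenuationSpectrum",
    "resample",
    "energy_to_photon",
    "transmittance",
    "band_ratio",
    "attenuation_coefficients",
    "propagate",
]

# CODATA to 6 significant digits
PLANCK_H = 6.62607e-34  # J s
SPEED_OF_LIGHT = 2.99792e8  # m/s

#: Working wavelength grid, 1 nm steps over 380-780 nm.
DEFAULT_GRID = np.arange(380.0, 781.0, 1.0)

QUANTITIES = frozenset(
    {
        "energy_radiance",  # W sr-1 m-2 nm-1
        "energy_irradiance",  # W m-2 nm-1
        "photon_radiance",  # photons s-1 sr-1 mm-2 nm-1
        "photon_irradiance",  # photons s-1 m-2 nm-1
        "transmittance",  # unitless
        "sensitivity",  # unitless
    }
)

_ENERGY_TO_PHOTON = {
    "energy_radiance": "photon_radiance",
    "energy_irradiance": "photon_irradiance",
}


@dataclass(frozen=True)
class SpectralCurve:
    """A quantity sampled on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    values: np.ndarray
    quantity: str = "energy_radiance"
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D arrays")
        if wl.size != vals.size:
            raise ValueError(
                f"wavelengths ({wl.size}) and values ({vals.size}) differ in length"
            )
        if wl.size == 0:
            raise ValueError("empty spectral curve")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValueError("non-finite entries in spectral curve")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.quantity in ("transmittance", "sensitivity") and np.any(vals < 0):
            raise ValueError(f"{self.quantity} values must be >= 0")

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def with_values(self, values: np.ndarray, quantity: str | None = None) -> "SpectralCurve":
        return replace(
            self, values=np.asarray(values, float), quantity=quantity or self.quantity
        )

    def scale(self, factor: float) -> "SpectralCurve":
        return self.with_values(self.values * factor)

    def same_grid(self, other: "SpectralCurve") -> bool:
        return (
            self.wavelengths.size == other.wavelengths.size
            and np.allclose(self.wavelengths, other.wavelengths)
        )


@dataclass(frozen=True)
class DepthSeries:
    """Photon-irradiance curves measured at several depths on one grid."""

    depths: np.ndarray
    curves: tuple[SpectralCurve, ...]

    def __post_init__(self):
        z = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "depths", z)
        object.__setattr__(self, "curves", tuple(self.curves))
        if z.size < 2:
            raise ValueError("a depth series needs at least 2 depths")
        if np.any(np.diff(z) <= 0):
            raise ValueError("depths must be strictly increasing")
        if len(self.curves) != z.size:
            raise ValueError("one curve per depth required")
        grid = self.curves[0].wavelengths
        for c in self.curves[1:]:
            if not (c.wavelengths.size == grid.size and np.allclose(c.wavelengths, grid)):
                raise ValueError("all curves in a depth series must share a grid")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.curves[0].wavelengths

    def matrix(self) -> np.ndarray:
        """(n_depths, n_wavelengths) value matrix."""
        return np.vstack([c.values for c in self.curves])


@dataclass(frozen=True)
class AttenuationSpectrum:
    """Diffuse attenuation coefficient K (per metre) per wavelength.

    Wavelengths where K could not be estimated carry NaN.
    """

    wavelengths: np.ndarray
    K: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        k = np.asarray(self.K, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "K", k)
        if wl.size != k.size:
            raise ValueError("wavelengths and K differ in length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.K)


def resample(curve: SpectralCurve, grid) -> SpectralCurve:
    """Linearly interpolate ``curve`` onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = curve.span
    bad = grid[(grid < lo) | (grid > hi)]
    if bad.size:
        raise ValueError(
            f"resample would extrapolate: wavelength {bad[0]:g} nm outside "
            f"curve span [{lo:g}, {hi:g}] nm"
        )
    vals = np.interp(grid, curve.wavelengths, curve.values)
    return SpectralCurve(grid, vals, quantity=curve.quantity, label=curve.label)


def common_grid(*curves: SpectralCurve, step: float = 1.0) -> np.ndarray:
    """Intersection grid of several curves at ``step`` nm resolution."""
    lo = max(c.span[0] for c in curves)
    hi = min(c.span[1] for c in curves)
    if hi <= lo:
        raise ValueError("curves have no overlapping wavelength range")
    return np.arange(lo, hi + step / 2, step)


def energy_to_photon(curve: SpectralCurve) -> SpectralCurve:
    """Convert an energy-flux curve to photon flux: N(l) = L(l) * l / (h c)."""
    if curve.quantity not in _ENERGY_TO_PHOTON:
        raise ValueError(
            f"energy_to_photon expects an energy flux, got {curve.quantity!r}"
        )
    if np.any(curve.values < 0):
        raise ValueError("negative energy flux values")
    lam_m = curve.wavelengths * 1e-9
    photons = curve.values * lam_m / (PLANCK_H * SPEED_OF_LIGHT)
    return curve.with_values(photons, quantity=_ENERGY_TO_PHOTON[curve.quantity])


def radiance_m2_to_mm2(curve: SpectralCurve) -> SpectralCurve:
    """Explicit per-m^2 -> per-mm^2 area rescaling (factor 1e-6)."""
    return curve.scale(1e-6)


def transmittance(sample: SpectralCurve, reference: SpectralCurve) -> SpectralCurve:
    """Element-wise sample/reference ratio, T(l) = L_sample(l) / L_ref(l)."""
    if not sample.same_grid(reference):
        raise ValueError("transmittance requires a common grid; resample first")
    ref = reference.values
    sam = sample.values
    bad = (ref == 0) & (sam != 0)
    if np.any(bad):
        wls = sample.wavelengths[bad]
        raise ValueError(
            "reference is zero with nonzero sample at wavelengths (nm): "
            + ", ".join(f"{w:g}" for w in wls[:10])
        )
    with np.errstate(invalid="ignore"):
        t = np.where(ref != 0, sam / np.where(ref != 0, ref, 1.0), 0.0)
    if np.any(t > 1.0):
        warnings.warn(
            f"transmittance exceeds 1 at {int(np.sum(t > 1.0))} wavelengths "
            "(kept; likely measurement noise)",
            stacklevel=2,
        )
    return SpectralCurve(
        sample.wavelengths, t, quantity="transmittance", label=sample.label
    )


def band_ratio(
    sample: SpectralCurve,
    reference: SpectralCurve,
    band: tuple[float, float] = (380.0, 780.0),
) -> float:
    """Band-integrated sample over band-integrated reference (trapezoid).

    This is the transmission-efficiency statistic: eyeshine photon radiance
    relative to the diffuse-white-standard radiance, integrated over ``band``.
    """
    if not sample.same_grid(reference):
        raise ValueError("band_ratio requires a common grid; resample first")
    lo, hi = float(band[0]), float(band[1])
    if hi <= lo:
        raise ValueError(f"empty band [{lo:g}, {hi:g}]")
    mask = (sample.wavelengths >= lo) & (sample.wavelengths <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"band [{lo:g}, {hi:g}] nm overlaps fewer than 2 grid points"
        )
    wl = sample.wavelengths[mask]
    num = np.trapezoid(sample.values[mask], wl)
    den = np.trapezoid(reference.values[mask], wl)
    if den == 0:
        raise ValueError("reference integrates to zero over the band")
    return float(num / den)


def attenuation_coefficients(series: DepthSeries) -> AttenuationSpectrum:
    """Per-wavelength K(l) = -slope of OLS of ln E(l, z) on depth z.

    Wavelengths with any non-positive irradiance get K = NaN (flagged
    missing rather than fabricated).
    """
    z = series.depths
    E = series.matrix()  # (nz, nwl)
    nwl = E.shape[1]
    K = np.full(nwl, np.nan)
    ok = np.all(E > 0, axis=0)
    if np.any(ok):
        logE = np.log(E[:, ok])
        zc = z - z.mean()
        denom = float(np.sum(zc**2))
        slopes = (zc @ logE) / denom
        K[ok] = -slopes
    return AttenuationSpectrum(series.wavelengths, K)


def propagate(surface: SpectralCurve, K: AttenuationSpectrum, z: float) -> SpectralCurve:
    """E(l, z) = E(l, 0) * exp(-K(l) * z) for depth z >= 0."""
    if z < 0:
        raise ValueError(f"depth must be >= 0, got {z}")
    wl = surface.wavelengths
    if K.wavelengths.size == wl.size and np.allclose(K.wavelengths, wl):
        k = K.K
    else:
        lo, hi = K.wavelengths[0], K.wavelengths[-1]
        if wl[0] < lo or wl[-1] > hi:
            raise ValueError(
                "attenuation spectrum does not cover the irradiance grid"
            )
        k = np.interp(wl, K.wavelengths, K.K)
    return surface.with_values(surface.values * np.exp(-k * z))
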
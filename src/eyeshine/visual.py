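"""Receptor-noise model of eyeshine conspicuousness.

Builds A1 visual-pigment templates, filters them through the ocular media,
computes quantum catches against photon spectra, and evaluates chromatic
(trichromatic, log-linear receptor-noise) and achromatic (double-cone)
contrasts in just-noticeable-difference (JND) units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectral import (
    AttenuationSpectrum,
    SpectralCurve,
    common_grid,
    propagate,
    resample,
)

__all__ = [
    "Photoreceptor",
    "VisualSystem",
    "ContrastResult",
    "pigment_template",
    "effective_sensitivity",
    "quantum_catch",
    "receptor_noise",
    "chromatic_contrast",
    "achromatic_contrast",
    "eyeshine_contrast_at_depth",
    "default_visual_system",
]

# A1 pigment alpha-band constants
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


@dataclass(frozen=True)
class Photoreceptor:
    label: str
    lambda_max: float  # nm
    relative_density: float
    achromatic_member: bool = False  # part of the double-cone channel

    def __post_init__(self):
        if not 330.0 <= self.lambda_max <= 650.0:
            raise ValueError(
                f"lambda_max {self.lambda_max} nm outside supported range [330, 650]"
            )
        if self.relative_density <= 0:
            raise ValueError("relative density must be > 0")


@dataclass(frozen=True)
class VisualSystem:
    """A trichromat with a Weber fraction for its most abundant class."""

    receptors: tuple[Photoreceptor, ...]
    weber_fraction: float
    ocular_media: SpectralCurve | None = None  # transmittance; None = clear

    def __post_init__(self):
        object.__setattr__(self, "receptors", tuple(self.receptors))
        if len(self.receptors) != 3:
            raise ValueError("exactly 3 chromatic receptor classes required")
        if self.weber_fraction <= 0:
            raise ValueError("Weber fraction must be > 0")

    @property
    def densities(self) -> np.ndarray:
        return np.array([r.relative_density for r in self.receptors])


@dataclass(frozen=True)
class ContrastResult:
    delta_S: float  # chromatic, JND
    delta_L: float  # achromatic, JND

    def __post_init__(self):
        if self.delta_S < 0 or self.delta_L < 0:
            raise ValueError("contrasts must be >= 0")


def pigment_template(lambda_max: float, grid=None) -> SpectralCurve:
    """A1 pigment absorbance template (alpha + beta band), peak-normalised.

    S_alpha(x) = 1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D) with
    x = lambda_max / lambda and a depending on lambda_max; the beta band is
    a Gaussian in lambda. The sum is normalised so the value at lambda_max
    is 1.
    """
    if not 330.0 <= lambda_max <= 650.0:
        raise ValueError(f"lambda_max {lambda_max} nm outside [330, 650]")
    if grid is None:
        grid = np.arange(300.0, 801.0, 1.0)
    grid = np.asarray(grid, dtype=float)

    def alpha_band(lam):
        x = lambda_max / lam
        a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
        return 1.0 / (
            np.exp(_A * (a - x))
            + np.exp(_B * (_b - x))
            + np.exp(_C * (_c - x))
            + _D
        )

    def beta_band(lam):
        a_beta = 0.26
        lam_m_beta = 189.0 + 0.315 * lambda_max
        bandwidth = -40.5 + 0.195 * lambda_max
        return a_beta * np.exp(-(((lam - lam_m_beta) / bandwidth) ** 2))

    vals = alpha_band(grid) + beta_band(grid)
    peak = float(alpha_band(np.array([lambda_max]))[0] + beta_band(np.array([lambda_max]))[0])
    vals = np.clip(vals / peak, 0.0, None)
    return SpectralCurve(grid, vals, quantity="sensitivity", label=f"A1 {lambda_max:g} nm")


def effective_sensitivity(
    receptor: Photoreceptor, media: SpectralCurve | None, grid
) -> SpectralCurve:
    """Pigment template filtered by ocular-media transmittance."""
    grid = np.asarray(grid, dtype=float)
    sens = pigment_template(receptor.lambda_max, grid)
    if media is None:
        return sens
    t = resample(media, grid)
    return SpectralCurve(
        grid, sens.values * t.values, quantity="sensitivity", label=receptor.label
    )


def quantum_catch(sens: SpectralCurve, stimulus: SpectralCurve) -> float:
    """Trapezoid integral of sensitivity times photon spectrum."""
    if not sens.same_grid(stimulus):
        raise ValueError("quantum_catch requires a common grid; resample first")
    return float(np.trapezoid(sens.values * stimulus.values, sens.wavelengths))


def receptor_noise(system: VisualSystem) -> np.ndarray:
    """Per-class noise omega_i = nu * sqrt(eta_max / eta_i)."""
    eta = system.densities
    return system.weber_fraction * np.sqrt(eta.max() / eta)


def chromatic_contrast(catch_target, catch_background, noise) -> float:
    """Trichromatic receptor-noise contrast (JND), log-linear signals."""
    qt = np.asarray(catch_target, dtype=float)
    qb = np.asarray(catch_background, dtype=float)
    w = np.asarray(noise, dtype=float)
    if qt.shape != (3,) or qb.shape != (3,) or w.shape != (3,):
        raise ValueError("three catches and three noise values required")
    if np.any(qt <= 0) or np.any(qb <= 0):
        raise ValueError("quantum catches must be > 0 for log signals")
    df = np.log(qt / qb)
    w1, w2, w3 = w
    num = (
        w1**2 * (df[2] - df[1]) ** 2
        + w2**2 * (df[2] - df[0]) ** 2
        + w3**2 * (df[1] - df[0]) ** 2
    )
    den = (w1 * w2) ** 2 + (w1 * w3) ** 2 + (w2 * w3) ** 2
    return float(math.sqrt(num / den))


def achromatic_contrast(catch_target: float, catch_background: float, omega_d: float) -> float:
    """Double-cone achromatic contrast |ln(Qt/Qb)| / omega (JND)."""
    if catch_target <= 0 or catch_background <= 0:
        raise ValueError("quantum catches must be > 0")
    if omega_d <= 0:
        raise ValueError("omega must be > 0")
    return abs(math.log(catch_target / catch_background)) / omega_d


def default_visual_system(ocular_media: SpectralCurve | None = None) -> VisualSystem:
    """Triplefin-like trichromat: single cone 468 nm, double cone 516/530 nm,
    density ratio 1:4:4, Weber fraction 0.05."""
    return VisualSystem(
        receptors=(
            Photoreceptor("single", 468.0, 1.0, achromatic_member=False),
            Photoreceptor("double_a", 516.0, 4.0, achromatic_member=True),
            Photoreceptor("double_b", 530.0, 4.0, achromatic_member=True),
        ),
        weber_fraction=0.05,
        ocular_media=ocular_media,
    )


def _catches(system: VisualSystem, stimulus: SpectralCurve, grid) -> tuple[np.ndarray, float]:
    """Chromatic catches for the 3 classes plus the double-cone catch."""
    chroma = []
    double_sens = None
    for r in system.receptors:
        sens = effective_sensitivity(r, system.ocular_media, grid)
        chroma.append(quantum_catch(sens, stimulus))
        if r.achromatic_member:
            double_sens = (
                sens.values if double_sens is None else double_sens + sens.values
            )
    if double_sens is None:
        raise ValueError("no achromatic (double-cone) members in visual system")
    dc = SpectralCurve(np.asarray(grid, float), double_sens, quantity="sensitivity")
    return np.array(chroma), quantum_catch(dc, stimulus)


def eyeshine_contrast_at_depth(
    surface_irradiance: SpectralCurve,
    K: AttenuationSpectrum,
    depth: float,
    ont_transmission: SpectralCurve,
    pet_transmission: SpectralCurve,
    system: VisualSystem,
) -> ContrastResult:
    """Chromatic and achromatic JND of nerve-lit vs fundus-lit pupil at depth.

    Downwelling irradiance is propagated to ``depth``; the target stimulus is
    the nerve-transmitted spectrum (ONT transmission times irradiance), the
    background the fundus-transmitted one (PET). Any common proportionality
    constant between irradiance and pupil radiance cancels in the log ratios.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    e_d = propagate(surface_irradiance, K, depth)
    curves = [e_d, ont_transmission, pet_transmission]
    if system.ocular_media is not None:
        curves.append(system.ocular_media)
    grid = common_grid(*curves)
    e_d = resample(e_d, grid)
    t_ont = resample(ont_transmission, grid)
    t_pet = resample(pet_transmission, grid)
    target = SpectralCurve(grid, t_ont.values * e_d.values, quantity="photon_irradiance")
    background = SpectralCurve(grid, t_pet.values * e_d.values, quantity="photon_irradiance")
    q_t, q_t_d = _catches(system, target, grid)
    q_b, q_b_d = _catches(system, background, grid)
    omega = receptor_noise(system)
    omega_d = system.weber_fraction
    return ContrastResult(
        delta_S=chromatic_contrast(q_t, q_b, omega),
        delta_L=achromatic_contrast(q_t_d, q_b_d, omega_d),
    )
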
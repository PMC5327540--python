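"""Length-weighted circular statistics and torsion fitting for pleated nerves.

Layer orientations are axial data (defined modulo 180 degrees). The
pipeline is: minimise the circular range by per-angle 180-degree shifts,
compute the length-weighted circular mean and circular SD per section,
unwrap the per-section means along the nerve, then fit mean angle against
distance from the optic disc by ordinary least squares. Fit coefficients
not significantly different from zero are set to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LayerMeasurement",
    "SectionSample",
    "SectionMean",
    "TorsionFit",
    "GroupSummary",
    "axial_transform",
    "weighted_circular_mean",
    "circular_sd",
    "section_mean",
    "unwrap_means",
    "fit_torsion",
    "summarize_group",
]

_RESULTANT_EPS = 1e-12


@dataclass(frozen=True)
class LayerMeasurement:
    """One nerve pleat layer: orientation angle (deg) and length (um)."""

    angle: float
    length: float

    def __post_init__(self):
        if not (math.isfinite(self.angle) and math.isfinite(self.length)):
            raise ValueError("angle and length must be finite")
        if self.length <= 0:
            raise ValueError(f"layer length must be > 0, got {self.length}")


@dataclass(frozen=True)
class SectionSample:
    """One transverse section: distance from the optic disc plus its layers."""

    distance: float  # mm
    layers: tuple[LayerMeasurement, ...]

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if not self.layers:
            raise ValueError("a section needs at least one layer")


@dataclass(frozen=True)
class SectionMean:
    """Per-section summary: weighted circular mean, SD and resultant length."""

    distance: float
    mean_angle: float
    circular_sd: float  # NaN when undefined (resultant length 0)
    resultant_length: float

    @property
    def sd_undefined(self) -> bool:
        return not math.isfinite(self.circular_sd)


@dataclass(frozen=True)
class TorsionFit:
    """Linear fit of unwrapped mean angle on distance along the nerve."""

    starting_angle: float  # intercept at distance 0, degrees
    torsion_rate: float  # slope, degrees per mm
    nerve_length: float  # mm
    total_torsion: float  # degrees
    intercept_zeroed: bool = False
    slope_zeroed: bool = False
    intercept_p: float = math.nan
    slope_p: float = math.nan


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- sample SD of fit parameters, with n."""

    n: int
    nerve_length: tuple[float, float]
    starting_angle: tuple[float, float]
    torsion_rate: tuple[float, float]
    total_torsion: tuple[float, float]


def _mod(x, period):
    return np.mod(np.asarray(x, dtype=float), period)


def axial_transform(angles) -> np.ndarray:
    """Shift each angle by a multiple of 180 so the spread is minimal.

    Layers are bidirectional axes, so x and x+180 are equivalent. Angles
    are reduced mod 180, the largest gap on the 180-degree circle is
    located, and the block below the gap is lifted by +180. Among equal
    minimal-spread solutions the one with the smallest non-negative mean
    is returned.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("axial_transform needs at least one angle")
    reduced = _mod(angles, 180.0)
    if angles.size == 1:
        return reduced
    order = np.argsort(reduced, kind="stable")
    s = reduced[order]
    # gap after s[i] is s[i+1]-s[i]; the wrap-around gap closes the circle
    gaps = np.empty(s.size)
    gaps[:-1] = np.diff(s)
    gaps[-1] = s[0] + 180.0 - s[-1]
    best = None
    max_gap = gaps.max()
    for i in np.flatnonzero(np.isclose(gaps, max_gap)):
        out = reduced.copy()
        if i < s.size - 1:
            # cut inside: lift everything at or below s[i]
            lift = reduced <= s[i] + 1e-12
            out = np.where(lift, reduced + 180.0, reduced)
        rng = out.max() - out.min()
        mean = out.mean()
        key = (round(rng, 9), round(mean, 9))
        if best is None or key < best[0]:
            best = (key, out)
    return best[1]


def _weighted_components(layers):
    angles = np.array([l.angle for l in layers], dtype=float)
    lengths = np.array([l.length for l in layers], dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("total layer length must be > 0")
    w = lengths / total
    rad = np.radians(angles)
    return float(np.sum(np.sin(rad) * w)), float(np.sum(np.cos(rad) * w))


def weighted_circular_mean(layers) -> float:
    """Length-weighted circular mean angle in [0, 360) degrees.

    Uses the two-argument arctangent of the weighted sine and cosine sums,
    which resolves the quadrant unambiguously.
    """
    s, c = _weighted_components(layers)
    if math.hypot(s, c) < _RESULTANT_EPS:
        raise ValueError("mean angle undefined: resultant vector has length ~0")
    ang = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return 0.0 if 360.0 - ang < 1e-9 else ang


def resultant_length(layers) -> float:
    s, c = _weighted_components(layers)
    return float(math.hypot(s, c))


def circular_sd(layers) -> float:
    """Circular SD v = sqrt(-2 ln R) in degrees; NaN when R == 0."""
    r = resultant_length(layers)
    if r < _RESULTANT_EPS:
        return math.nan
    r = min(r, 1.0)  # guard rounding above 1
    return float(np.degrees(math.sqrt(-2.0 * math.log(r))))


def section_mean(section: SectionSample, axial: bool = True) -> SectionMean:
    """Average one section's layers: axial transform, then weighted stats."""
    layers = section.layers
    if axial:
        new_angles = axial_transform([l.angle for l in layers])
        layers = tuple(
            LayerMeasurement(a, l.length) for a, l in zip(new_angles, layers)
        )
    r = resultant_length(layers)
    if r < _RESULTANT_EPS:
        return SectionMean(section.distance, math.nan, math.nan, r)
    return SectionMean(
        distance=section.distance,
        mean_angle=weighted_circular_mean(layers),
        circular_sd=circular_sd(layers),
        resultant_length=r,
    )


def unwrap_means(means: list[SectionMean]) -> list[SectionMean]:
    """Shift each mean by a multiple of 180 so successive steps are <= 90.

    Axial equivalence makes 180-degree shifts free; each successive mean is
    moved to the representative closest to its predecessor, with ties broken
    toward the smaller shift multiple.
    """
    if not means:
        return []
    dists = [m.distance for m in means]
    if any(b <= a for a, b in zip(dists, dists[1:])):
        raise ValueError("section distances must be strictly increasing")
    out = [means[0]]
    prev = means[0].mean_angle
    for m in means[1:]:
        x = (prev - m.mean_angle) / 180.0
        k0 = math.floor(x)
        candidates = sorted(
            (k0, k0 + 1),
            key=lambda k: (abs(prev - (m.mean_angle + 180.0 * k)), abs(k)),
        )
        k = candidates[0]
        shifted = m.mean_angle + 180.0 * k
        out.append(
            SectionMean(m.distance, shifted, m.circular_sd, m.resultant_length)
        )
        prev = shifted
    return out


def fit_torsion(
    means: list[SectionMean],
    alpha: float | None = 0.05,
    nerve_length: float | None = None,
) -> TorsionFit:
    """OLS of unwrapped mean angle on distance, with significance zeroing.

    For n >= 3 each coefficient gets a two-sided t-test (df = n - 2);
    coefficients with p >= ``alpha`` are set to 0 and flagged. With exactly
    two sections the line is determined and no test is run. ``alpha=None``
    reports the tests but never zeroes.
    """
    if len(means) < 2:
        raise ValueError("fit_torsion needs at least 2 sections")
    x = np.array([m.distance for m in means], dtype=float)
    y = np.array([m.mean_angle for m in means], dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("section distances must be strictly increasing")
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept, slope = float(beta[0]), float(beta[1])
    intercept_zeroed = slope_zeroed = False
    p_int = p_slope = math.nan
    if n >= 3:
        resid = y - X @ beta
        df = n - 2
        s2 = float(resid @ resid) / df
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        if se[0] > 0:
            t_int = intercept / se[0]
            p_int = 2 * stats.t.sf(abs(t_int), df)
        else:
            p_int = 0.0 if intercept != 0 else 1.0
        if se[1] > 0:
            t_slope = slope / se[1]
            p_slope = 2 * stats.t.sf(abs(t_slope), df)
        else:
            p_slope = 0.0 if slope != 0 else 1.0
        if alpha is not None:
            if p_int >= alpha:
                intercept, intercept_zeroed = 0.0, True
            if p_slope >= alpha:
                slope, slope_zeroed = 0.0, True
    length = nerve_length if nerve_length is not None else float(x[-1] - x[0])
    total = 0.0 if slope_zeroed else abs(slope) * length
    return TorsionFit(
        starting_angle=intercept,
        torsion_rate=slope,
        nerve_length=length,
        total_torsion=total,
        intercept_zeroed=intercept_zeroed,
        slope_zeroed=slope_zeroed,
        intercept_p=p_int,
        slope_p=p_slope,
    )


def _mean_sd(values) -> tuple[float, float]:
    a = np.asarray(values, dtype=float)
    mean = float(a.mean())
    sd = float(a.std(ddof=1)) if a.size > 1 else math.nan
    return mean, sd


def summarize_group(
    fits: list[TorsionFit], individuals: list | None = None
) -> GroupSummary:
    """Arithmetic mean +/- sample SD of fit parameters.

    When ``individuals`` labels are given, fits are first averaged per
    individual, then across individuals.
    """
    if not fits:
        raise ValueError("summarize_group needs at least one fit")
    rows = np.array(
        [
            (f.nerve_length, f.starting_angle, f.torsion_rate, f.total_torsion)
            for f in fits
        ],
        dtype=float,
    )
    if individuals is not None:
        if len(individuals) != len(fits):
            raise ValueError("one individual label per fit required")
        uniq = list(dict.fromkeys(individuals))
        rows = np.array(
            [
                rows[[i for i, ind in enumerate(individuals) if ind == u]].mean(axis=0)
                for u in uniq
            ]
        )
    stats_ = [_mean_sd(rows[:, j]) for j in range(4)]
    return GroupSummary(
        n=rows.shape[0],
        nerve_length=stats_[0],
        starting_angle=stats_[1],
        torsion_rate=stats_[2],
        total_torsion=stats_[3],
    )
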
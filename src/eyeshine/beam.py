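"""Angular width of the eyeshine emission beam.

The beam width is triangulated from the distance between the two observation
points where the eyeshine appears/disappears and the distances from each
point to the eye, then corrected for refraction at the flat tank wall.
A parallel-faced wall is assumed, so the glass index cancels and only the
entry/exit media matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "N_WATER",
    "N_AIR",
    "BeamTriangle",
    "angle_from_sides",
    "refract",
    "corrected_beam_width",
]

N_WATER = 1.333
N_AIR = 1.000


@dataclass(frozen=True)
class BeamTriangle:
    """Observation triangle: chord between onset/offset points, arms to the eye."""

    chord: float
    left_arm: float
    right_arm: float

    def __post_init__(self):
        sides = (self.chord, self.left_arm, self.right_arm)
        if any(not math.isfinite(s) or s <= 0 for s in sides):
            raise ValueError(f"all triangle sides must be positive, got {sides}")
        a, b, c = self.chord, self.left_arm, self.right_arm
        if a >= b + c or b >= a + c or c >= a + b:
            raise ValueError(
                f"triangle inequality violated for sides {sides}"
            )


def angle_from_sides(t: BeamTriangle) -> float:
    """Apex angle (degrees) at the eye, by the law of cosines."""
    a, b, c = t.chord, t.left_arm, t.right_arm
    cos_a = (b * b + c * c - a * a) / (2 * b * c)
    return math.degrees(math.acos(cos_a))


def refract(angle_in: float, n_in: float, n_out: float) -> float:
    """Snell refraction of an angle from the interface normal, in degrees."""
    if not 0 <= angle_in < 90:
        raise ValueError(f"angle must be in [0, 90) degrees, got {angle_in}")
    if n_in <= 0 or n_out <= 0:
        raise ValueError("refractive indices must be positive")
    s = n_in * math.sin(math.radians(angle_in)) / n_out
    if s > 1:
        raise ValueError(
            f"total internal reflection: sin(theta_out) = {s:.4f} > 1"
        )
    return math.degrees(math.asin(s))


def corrected_beam_width(
    t: BeamTriangle, n_water: float = N_WATER, n_air: float = N_AIR
) -> float:
    """In-water angular extent of the beam, degrees.

    The in-air apex angle is split at the foot of the chord's bisector into
    two half-angles, each refracted from air back into water through the
    flat wall, then summed. For ``n_water == n_air`` this reduces to
    :func:`angle_from_sides`.
    """
    full = angle_from_sides(t)
    # split the apex angle into the two half-angles made with the bisector;
    # for a symmetric triangle each is full/2. Asymmetric arms shift the
    # bisector: use the chord split given by the angle bisector theorem.
    b, c = t.left_arm, t.right_arm
    half_left = full * c / (b + c)
    half_right = full * b / (b + c)
    out = 0.0
    for half in (half_left, half_right):
        out += refract(half, n_air, n_water)
    return out
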
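"""Specimen morphometry arithmetic and mean +/- SD summaries."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "SpecimenRecord",
    "head_diameter",
    "head_csa",
    "relative_percent",
    "estimate_on_depth",
    "summarize",
]

#: length-unit factors relative to mm
UNIT_FACTORS = {"mm": 1.0, "um": 1e-3, "cm": 10.0, "m": 1e3}


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen's absolute morphometrics; None marks a missing value."""

    species: str
    total_length: float | None = None  # mm
    head_width: float | None = None  # mm
    head_height: float | None = None  # mm
    body_volume: float | None = None  # mm^3
    skull_thickness: float | None = None  # um
    dermis_thickness: float | None = None  # um
    on_depth: float | None = None  # mm
    on_layers: float | None = None  # count
    on_layer_thickness: float | None = None  # um
    on_csa: float | None = None  # mm^2

    def __post_init__(self):
        for f in fields(self):
            if f.name == "species":
                continue
            v = getattr(self, f.name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise ValueError(f"{f.name} must be > 0 when present, got {v}")

    @property
    def head_diameter(self) -> float | None:
        if self.head_width is None or self.head_height is None:
            return None
        return head_diameter(self.head_width, self.head_height)

    NUMERIC_FIELDS = (
        "total_length",
        "head_width",
        "head_height",
        "body_volume",
        "skull_thickness",
        "dermis_thickness",
        "on_depth",
        "on_layers",
        "on_layer_thickness",
        "on_csa",
    )


def head_diameter(width: float, height: float) -> float:
    """Head diameter as the mean of head width and height (mm)."""
    if width <= 0 or height <= 0:
        raise ValueError(f"width and height must be > 0, got ({width}, {height})")
    return (width + height) / 2.0


def head_csa(hd: float) -> float:
    """Head cross-sectional area, pi/4 * HD^2 (mm^2)."""
    if hd <= 0:
        raise ValueError(f"head diameter must be > 0, got {hd}")
    return math.pi / 4.0 * hd * hd


def relative_percent(
    value: float,
    reference: float,
    value_unit: str = "mm",
    reference_unit: str = "mm",
) -> float:
    """100 * value / reference after reconciling length units.

    Dimensionally matching non-length quantities (e.g. two areas) pass with
    both units left at the default.
    """
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    try:
        factor = UNIT_FACTORS[value_unit] / UNIT_FACTORS[reference_unit]
    except KeyError as exc:
        raise ValueError(
            f"unknown unit {exc.args[0]!r}; known units: {sorted(UNIT_FACTORS)}"
        ) from None
    return 100.0 * value * factor / reference


def estimate_on_depth(relative_depth: float, hd: float) -> float:
    """Optic-nerve depth (mm) from a relative depth (% of HD) and HD (mm).

    Rounded to 2 decimals, matching the reporting precision of the source
    tables.
    """
    if relative_depth <= 0 or hd <= 0:
        raise ValueError("relative depth and head diameter must be > 0")
    return round(relative_depth / 100.0 * hd, 2)


def summarize(records, field_names=None) -> dict[str, dict[str, float]]:
    """Per-field mean and sample SD (ddof=1), skipping missing values.

    Returns ``{field: {"mean": m, "sd": s, "n": n}}``; SD is NaN for n = 1.
    All-missing fields are omitted with a warning.
    """
    records = list(records)
    if not records:
        raise ValueError("summarize needs at least one record")
    if field_names is None:
        field_names = SpecimenRecord.NUMERIC_FIELDS
    out: dict[str, dict[str, float]] = {}
    for name in field_names:
        vals = [getattr(r, name) for r in records if getattr(r, name) is not None]
        if not vals:
            warnings.warn(f"field {name!r} is missing in all records; omitted")
            continue
        a = np.asarray(vals, dtype=float)
        out[name] = {
            "mean": float(a.mean()),
            "sd": float(a.std(ddof=1)) if a.size > 1 else math.nan,
            "n": int(a.size),
        }
    return out
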
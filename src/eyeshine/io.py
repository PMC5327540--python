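"""CSV readers/writers and the pipeline runner.

Formats
-------
Spectral CSV: header ``wavelength_nm,value``, one row per sample; an
optional sidecar ``<name>.meta`` holds ``key = value`` lines (quantity,
label). Depth series: a manifest CSV ``depth_m,file`` pointing at spectral
CSVs. Section CSV: ``individual,side,distance_mm,layer_index,angle_deg,
length_um``. Morphometry CSV: one row per specimen.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circular import (
    LayerMeasurement,
    SectionSample,
    fit_torsion,
    section_mean,
    summarize_group,
    unwrap_means,
)
from .morphometry import SpecimenRecord, summarize
from .spectral import AttenuationSpectrum, DepthSeries, SpectralCurve, band_ratio
from .synth import (
    GeneratorConfig,
    gen_depth_profiles,
    gen_eyeshine_spectra,
    gen_morphometry,
    gen_nerve_sections,
)

__all__ = [
    "read_spectral_csv",
    "write_spectral_csv",
    "read_depth_series",
    "write_depth_series",
    "read_sections_csv",
    "write_sections_csv",
    "read_morphometry_csv",
    "write_morphometry_csv",
    "RunConfig",
    "run_pipeline",
]

_SPECTRAL_HEADER = ["wavelength_nm", "value"]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta")


def read_spectral_csv(path, quantity: str | None = None) -> SpectralCurve:
    """Read a two-column spectral CSV, reporting offending line numbers."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != _SPECTRAL_HEADER:
        raise ValueError(
            f"{path}: expected header {','.join(_SPECTRAL_HEADER)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    for col in _SPECTRAL_HEADER:
        numeric = pd.to_numeric(df[col], errors="coerce")
        nonnum = numeric.isna()
        if nonnum.any():
            line = int(nonnum.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}:{line}: non-numeric {col!r} cell")
        df[col] = numeric
    wl = df["wavelength_nm"].to_numpy(float)
    dup = np.flatnonzero(np.diff(wl) == 0)
    if dup.size:
        raise ValueError(f"{path}:{int(dup[0]) + 3}: duplicated wavelength {wl[dup[0]]:g}")
    if np.any(np.diff(wl) < 0):
        i = int(np.flatnonzero(np.diff(wl) < 0)[0])
        raise ValueError(f"{path}:{i + 3}: wavelengths not sorted")
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        for raw in mp.read_text().splitlines():
            raw = raw.strip()
            if raw and not raw.startswith("#") and "=" in raw:
                k, v = raw.split("=", 1)
                meta[k.strip()] = v.strip()
    q = quantity or meta.get("quantity", "energy_radiance")
    return SpectralCurve(wl, df["value"].to_numpy(float), quantity=q,
                         label=meta.get("label", path.stem))


def write_spectral_csv(curve: SpectralCurve, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"wavelength_nm": curve.wavelengths, "value": curve.values}
    ).to_csv(path, index=False, float_format="%.17g")
    _meta_path(path).write_text(
        f"quantity = {curve.quantity}\nlabel = {curve.label}\n"
    )


def read_depth_series(manifest_path) -> DepthSeries:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    if list(df.columns) != ["depth_m", "file"]:
        raise ValueError(f"{manifest_path}: expected header 'depth_m,file'")
    df = df.sort_values("depth_m")
    curves = [
        read_spectral_csv(manifest_path.parent / f, quantity="photon_irradiance")
        for f in df["file"]
    ]
    return DepthSeries(df["depth_m"].to_numpy(float), tuple(curves))


def write_depth_series(series: DepthSeries, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for z, curve in zip(series.depths, series.curves):
        name = f"irradiance_z{z:g}.csv"
        write_spectral_csv(curve, directory / name)
        rows.append({"depth_m": z, "file": name})
    manifest = directory / "depths.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


_SECTION_COLS = ["individual", "side", "distance_mm", "layer_index", "angle_deg", "length_um"]


def read_sections_csv(path) -> dict[tuple[str, str], list[SectionSample]]:
    """Sections grouped by (individual, side), ordered by distance."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SECTION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[tuple[str, str], list[SectionSample]] = {}
    for (ind, side), g in df.groupby(["individual", "side"], sort=True):
        sections = []
        for dist, gg in g.groupby("distance_mm", sort=True):
            layers = tuple(
                LayerMeasurement(float(r.angle_deg), float(r.length_um))
                for r in gg.sort_values("layer_index").itertuples()
            )
            sections.append(SectionSample(float(dist), layers))
        out[(str(ind), str(side))] = sections
    return out


def write_sections_csv(groups: dict, path) -> None:
    rows = []
    for (ind, side), sections in groups.items():
        for s in sections:
            for i, layer in enumerate(s.layers):
                rows.append(
                    {
                        "individual": ind,
                        "side": side,
                        "distance_mm": s.distance,
                        "layer_index": i,
                        "angle_deg": layer.angle,
                        "length_um": layer.length,
                    }
                )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


_MORPHO_COLS = ["species"] + list(SpecimenRecord.NUMERIC_FIELDS)


def read_morphometry_csv(path) -> list[SpecimenRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _MORPHO_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for r in df.itertuples():
        kwargs = {"species": str(r.species)}
        for f in SpecimenRecord.NUMERIC_FIELDS:
            v = getattr(r, f)
            kwargs[f] = None if pd.isna(v) else float(v)
        records.append(SpecimenRecord(**kwargs))
    return records


def write_morphometry_csv(records, path) -> None:
    rows = [
        {
            "species": r.species,
            **{f: getattr(r, f) for f in SpecimenRecord.NUMERIC_FIELDS},
        }
        for r in records
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Configuration for the end-to-end pipeline."""

    out_dir: str = "eyeshine_out"
    seed: int = 0
    species: str = "T_delaisi"
    band: tuple[float, float] = (380.0, 780.0)
    alpha: float = 0.05
    depths: tuple[float, ...] = (5.0, 20.0)
    noise: float = 0.0
    # optional measured inputs; when None, synthetic data are generated
    dws_csv: str | None = None
    ont_csv: str | None = None
    pet_csv: str | None = None
    sections_csv: str | None = None
    morphometry_csv: str | None = None

    def validate(self) -> None:
        for name in ("dws_csv", "ont_csv", "pet_csv", "sections_csv", "morphometry_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.band[1] <= self.band[0]:
            raise ValueError("band upper bound must exceed lower bound")


def run_pipeline(config: RunConfig) -> dict:
    """Run spectra -> efficiency, sections -> torsion, morphometry summary
    and depth contrasts; write CSV outputs and a machine-readable run log."""
    from .circular import TorsionFit  # local to keep import surface tidy
    from .synth import default_attenuation, surface_irradiance
    from .visual import default_visual_system, eyeshine_contrast_at_depth

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(seed=config.seed, species=config.species,
                          noise=config.noise, band=config.band)
    results: dict = {}

    # --- spectra stage
    if config.dws_csv and config.ont_csv:
        dws = read_spectral_csv(config.dws_csv, quantity="photon_radiance")
        ont = read_spectral_csv(config.ont_csv, quantity="photon_radiance")
        pet = (
            read_spectral_csv(config.pet_csv, quantity="photon_radiance")
            if config.pet_csv
            else None
        )
    else:
        spectra = gen_eyeshine_spectra(cfg)
        dws, ont, pet = spectra["DWS"], spectra["ONT"], spectra["PET"]
        for name, c in spectra.items():
            write_spectral_csv(c, out / f"{name.lower()}.csv")
    eff = {"ONT": band_ratio(ont, dws, config.band)}
    if pet is not None:
        eff["PET"] = band_ratio(pet, dws, config.band)
    results["efficiency"] = eff

    # --- torsion stage
    if config.sections_csv:
        groups = read_sections_csv(config.sections_csv)
    else:
        groups = {(f"sim{i}", "L"): gen_nerve_sections(
            GeneratorConfig(seed=config.seed + i, species=config.species),
            noise_sd=5.0,
        ) for i in range(3)}
        write_sections_csv(groups, out / "sections.csv")
    fits, labels = [], []
    for (ind, side), sections in groups.items():
        means = unwrap_means([section_mean(s) for s in sections])
        fits.append(fit_torsion(means, alpha=config.alpha))
        labels.append(ind)
    summary = summarize_group(fits, individuals=labels)
    results["torsion"] = dataclasses.asdict(summary)
    pd.DataFrame(
        [
            {
                "individual": lab,
                "nerve_length_mm": f.nerve_length,
                "starting_angle_deg": f.starting_angle,
                "torsion_deg_per_mm": f.torsion_rate,
                "total_torsion_deg": f.total_torsion,
                "slope_zeroed": f.slope_zeroed,
                "intercept_zeroed": f.intercept_zeroed,
            }
            for lab, f in zip(labels, fits)
        ]
    ).to_csv(out / "torsion_fits.csv", index=False)

    # --- morphometry stage
    if config.morphometry_csv:
        records = read_morphometry_csv(config.morphometry_csv)
    else:
        records = gen_morphometry(cfg)
        write_morphometry_csv(records, out / "morphometry.csv")
    morpho = summarize(records)
    results["morphometry"] = morpho
    pd.DataFrame(morpho).T.to_csv(out / "morphometry_summary.csv")

    # --- visual stage
    e0 = surface_irradiance()
    K = default_attenuation()
    t_ont = SpectralCurve(dws.wavelengths, np.clip(ont.values / np.where(
        dws.values > 0, dws.values, 1.0), 0, None), quantity="transmittance")
    t_pet = None
    if pet is not None:
        t_pet = SpectralCurve(dws.wavelengths, np.clip(pet.values / np.where(
            dws.values > 0, dws.values, 1.0), 0, None), quantity="transmittance")
    system = default_visual_system()
    contrasts = {}
    if t_pet is not None:
        for z in config.depths:
            c = eyeshine_contrast_at_depth(e0, K, z, t_ont, t_pet, system)
            contrasts[f"{z:g}"] = {"delta_S": c.delta_S, "delta_L": c.delta_L}
    results["contrast_jnd_by_depth_m"] = contrasts

    log = {
        "seed": config.seed,
        "version": __version__,
        "config": dataclasses.asdict(config),
        "results": results,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=float))
    return results
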
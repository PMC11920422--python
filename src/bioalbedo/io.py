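"""Readers and writers for the package's delimited-text and raster formats.

* spectra: two-column CSV, header ``wavelength_nm,value``, optional
  ``#``-prefixed comment header carrying the quantity kind;
* density-IRF sample tables: ``cell_density_per_ml,irf_w_m2,group``;
* weather series: ``timestamp,par_umol_m2_s,air_temp_c,wind_m_s,rh_pct``
  with ISO-8601 timestamps; gaps of at most two steps are filled by linear
  interpolation with a logged warning, larger gaps are an error;
* scenes: multiband float TIFF with band definitions and pixel size in a
  JSON ImageDescription; classification masks as byte TIFF
  (1 = algae, 0 = not, 255 = invalid).  GeoTIFF georeferencing tags, when
  present on input, are passed through to outputs untouched.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ParseError, WeatherError
from .forcing import DensityIRFSample
from .mapping import BandDef, BloomMap, Scene
from .melt import WeatherSeries
from .spectra import Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_density_table",
    "write_density_table",
    "read_weather",
    "write_weather",
    "read_scene",
    "write_scene",
    "read_mask",
    "write_mask",
    "write_bloom_summary",
]

log = logging.getLogger("bioalbedo")

#: GeoTIFF tag codes passed through untouched between input and output.
GEO_TAGS = (33550, 33922, 34264, 34735, 34736, 34737)

SPECTRUM_HEADER = "wavelength_nm,value"
DENSITY_HEADER = "cell_density_per_ml,irf_w_m2,group"
WEATHER_COLUMNS = ["timestamp", "par_umol_m2_s", "air_temp_c", "wind_m_s", "rh_pct"]


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def write_spectrum(s: Spectrum, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# bioalbedo spectrum\n")
        fh.write(f"# quantity_kind: {s.kind}\n")
        fh.write(f"# samples: {len(s)}\n")
        fh.write(SPECTRUM_HEADER + "\n")
        for wl, v in zip(s.wavelengths, s.values):
            fh.write(f"{float(wl)!r},{float(v)!r}\n")


def read_spectrum(path, kind: str | None = None) -> Spectrum:
    """Read a two-column spectrum file; errors carry the offending line."""
    path = Path(path)
    wavelengths: list[float] = []
    values: list[float] = []
    file_kind = None
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("quantity_kind:"):
                    file_kind = body.split(":", 1)[1].strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != SPECTRUM_HEADER:
                    raise ParseError(
                        f"expected header {SPECTRUM_HEADER!r}, got {line!r}",
                        path,
                        lineno,
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError("expected two comma-separated values", path, lineno)
            try:
                wl, v = float(parts[0]), float(parts[1])
            except ValueError:
                raise ParseError(f"non-numeric cell in {line!r}", path, lineno)
            if wavelengths and wl <= wavelengths[-1]:
                raise ParseError(
                    f"wavelengths must be strictly increasing "
                    f"({wl:g} nm follows {wavelengths[-1]:g} nm)",
                    path,
                    lineno,
                )
            wavelengths.append(wl)
            values.append(v)
    if not header_seen:
        raise ParseError("missing header", path, 1)
    if len(wavelengths) < 2:
        raise ParseError("fewer than 2 data rows", path)
    return Spectrum(wavelengths, values, kind=kind or file_kind or "reflectance")


# ---------------------------------------------------------------------------
# Density-IRF sample tables
# ---------------------------------------------------------------------------

def write_density_table(samples: Sequence[DensityIRFSample], path) -> None:
    df = pd.DataFrame(
        {
            "cell_density_per_ml": [s.cell_density for s in samples],
            "irf_w_m2": [s.irf for s in samples],
            "group": [s.group_label for s in samples],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_density_table(path) -> list[DensityIRFSample]:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise ParseError(str(exc), path) from exc
    missing = set(DENSITY_HEADER.split(",")) - set(df.columns)
    if missing:
        raise ParseError(f"missing columns {sorted(missing)}", path, 1)
    samples = []
    for i, row in df.iterrows():
        try:
            samples.append(
                DensityIRFSample(
                    cell_density=float(row["cell_density_per_ml"]),
                    irf=float(row["irf_w_m2"]),
                    group_label=str(row["group"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(str(exc), path, int(i) + 2) from exc
    return samples


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

def write_weather(series: WeatherSeries, path) -> None:
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, float_format="%.10g")


def read_weather(path, max_gap_steps: int = 2) -> WeatherSeries:
    """Read and validate a weather CSV as a regular series.

    The cadence is the modal timestamp spacing.  Missing rows (or rows with
    missing cells) forming gaps of at most ``max_gap_steps`` consecutive
    steps are filled by linear interpolation with a logged ``GAPFILL``
    warning; longer gaps raise :class:`WeatherError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(str(exc), path) from exc
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"missing columns {sorted(missing)}", path, 1)
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"unparseable timestamp: {exc}", path) from exc
    if ts.duplicated().any() or not ts.is_monotonic_increasing:
        raise WeatherError(f"{path}: timestamps must be strictly increasing")
    if len(ts) < 2:
        raise WeatherError(f"{path}: need at least 2 records")

    deltas = ts.diff().dropna().dt.total_seconds()
    step = float(deltas.mode().iloc[0])
    if np.any(np.abs(np.mod(deltas, step)) > 1e-6):
        raise WeatherError(
            f"{path}: irregular cadence (not a multiple of the {step:g} s step)"
        )
    full_index = pd.date_range(ts.iloc[0], ts.iloc[-1], freq=pd.Timedelta(seconds=step))
    data = df.drop(columns=["timestamp"]).set_index(pd.DatetimeIndex(ts))
    data = data.reindex(full_index)

    isna = data.isna().any(axis=1).to_numpy()
    if isna.any():
        runs = np.diff(np.concatenate(([0], isna.view(np.int8), [0])))
        starts, ends = np.flatnonzero(runs == 1), np.flatnonzero(runs == -1)
        longest = int((ends - starts).max())
        if longest > max_gap_steps:
            raise WeatherError(
                f"{path}: gap of {longest} consecutive steps exceeds the "
                f"{max_gap_steps}-step fill limit"
            )
        log.warning(
            "GAPFILL: %s: filled %d missing step(s) in %d gap(s) by linear "
            "interpolation",
            path,
            int(isna.sum()),
            len(starts),
        )
        data = data.interpolate(method="time", limit_direction="both")
    return WeatherSeries(
        timestamps=pd.DatetimeIndex(data.index),
        par=data["par_umol_m2_s"].to_numpy(),
        air_temp=data["air_temp_c"].to_numpy(),
        wind=data["wind_m_s"].to_numpy(),
        rh=data["rh_pct"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Scenes and masks (multiband TIFF)
# ---------------------------------------------------------------------------

def _collect_geo_extratags(path) -> list[tuple]:
    tags = []
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        for code in GEO_TAGS:
            tag = page.tags.get(code)
            if tag is not None:
                tags.append((code, tag.dtype, tag.count, tag.value, True))
    return tags


def write_scene(scene: Scene, path) -> None:
    meta = {
        "pixel_size_m": scene.pixel_size,
        "bands": [
            {"name": b.name, "center": b.center, "lower": b.lower, "upper": b.upper}
            for b in scene.bands
        ],
    }
    extratags = [
        (code, dtype, count, value, True)
        for code, (dtype, count, value) in scene.geo.items()
    ]
    data = np.concatenate(
        [scene.grid.astype(np.float32), scene.validity_mask[None].astype(np.float32)]
    )
    tifffile.imwrite(
        path,
        data,
        description=json.dumps(meta),
        extratags=extratags,
        photometric="minisblack",
    )


def read_scene(path) -> Scene:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
        geo = {}
        for code in GEO_TAGS:
            tag = tif.pages[0].tags.get(code)
            if tag is not None:
                geo[code] = (tag.dtype, tag.count, tag.value)
    try:
        meta = json.loads(desc)
        bands = tuple(
            BandDef(b["name"], b["center"], b["lower"], b["upper"])
            for b in meta["bands"]
        )
        pixel_size = float(meta["pixel_size_m"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParseError(f"missing/invalid scene metadata: {exc}", path) from exc
    if data.ndim != 3 or data.shape[0] != len(bands) + 1:
        raise ParseError(
            f"expected {len(bands) + 1} planes (bands + validity), got shape "
            f"{data.shape}",
            path,
        )
    return Scene(
        bands=bands,
        grid=np.asarray(data[:-1], dtype=float),
        pixel_size=pixel_size,
        validity_mask=data[-1] > 0.5,
        geo=geo,
    )


def write_mask(bloom: BloomMap, path, validity_mask: np.ndarray | None = None,
               geo: dict | None = None) -> None:
    """Byte mask raster: 1 = algae, 0 = no algae, 255 = invalid/undefined."""
    out = np.zeros(bloom.algae_mask.shape, dtype=np.uint8)
    out[bloom.algae_mask] = 1
    invalid = ~np.isfinite(bloom.i_b5)
    if validity_mask is not None:
        invalid |= ~np.asarray(validity_mask, dtype=bool)
    out[invalid] = 255
    extratags = [
        (code, dtype, count, value, True)
        for code, (dtype, count, value) in (geo or {}).items()
    ]
    tifffile.imwrite(
        path,
        out,
        description=json.dumps({"coding": {"algae": 1, "no_algae": 0, "invalid": 255}}),
        extratags=extratags,
        photometric="minisblack",
    )


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path)


def write_bloom_summary(bloom: BloomMap, path) -> None:
    pd.DataFrame(
        [
            {
                "extent_km2": bloom.extent_km2,
                "fraction": bloom.fraction,
                "n_algae": bloom.n_algae,
                "n_valid": bloom.n_valid,
                "pixel_size_m": bloom.pixel_size,
                "detection_floor_cells_per_ml": bloom.metadata.get(
                    "detection_floor_cells_per_ml"
                ),
            }
        ]
    ).to_csv(path, index=False, float_format="%.10g")
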
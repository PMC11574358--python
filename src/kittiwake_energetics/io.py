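"""File readers/writers and run configuration.

All CSVs are UTF-8 with ISO-8601 UTC timestamps and dot decimal separators.
The land mask is a GeoJSON-style polygon (lon/lat ring) wrapped in a small
point-in-polygon helper so the signal layer needs no GIS dependency.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_accel_csv",
    "read_gps_csv",
    "read_isotope_csv",
    "LandMask",
    "RunConfig",
    "write_manifest",
]


def _seconds_since_start(ts: pd.Series, t0: pd.Timestamp | None = None) -> tuple[np.ndarray, pd.Timestamp]:
    t = pd.to_datetime(ts, utc=True, format="ISO8601")
    if t0 is None:
        t0 = t.iloc[0]
    return (t - t0).dt.total_seconds().to_numpy(), t0


def read_accel_csv(path: str | Path, t0: pd.Timestamp | None = None) -> tuple[pd.DataFrame, pd.Timestamp]:
    """Read an acceleration CSV (timestamp_utc, ax_g, ay_g, az_g).

    Returns a frame with t (seconds since ``t0``, default the first sample)
    plus ax/ay/az in g, and the reference timestamp.
    """
    df = pd.read_csv(path)
    secs, t0 = _seconds_since_start(df["timestamp_utc"], t0)
    return pd.DataFrame({"t": secs, "ax": df["ax_g"], "ay": df["ay_g"],
                         "az": df["az_g"]}), t0


def read_gps_csv(path: str | Path, t0: pd.Timestamp) -> pd.DataFrame:
    """Read a GPS CSV (timestamp_utc, lat_dd, lon_dd) onto the accel clock."""
    df = pd.read_csv(path)
    secs, _ = _seconds_since_start(df["timestamp_utc"], t0)
    return pd.DataFrame({"t": secs, "lat": df["lat_dd"], "lon": df["lon_dd"]})


def read_isotope_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass(frozen=True)
class LandMask:
    """Point-in-polygon land mask from a GeoJSON-style lon/lat ring."""

    ring: tuple[tuple[float, float], ...]  # (lon, lat) vertices

    @classmethod
    def from_geojson(cls, path: str | Path) -> "LandMask":
        gj = json.loads(Path(path).read_text())
        geom = gj["geometry"] if gj.get("type") == "Feature" else gj
        if geom["type"] != "Polygon":
            raise ValueError("land mask must be a Polygon")
        return cls(ring=tuple(map(tuple, geom["coordinates"][0])))

    def contains_point(self, lat: float, lon: float) -> bool:
        # even-odd ray casting
        inside = False
        n = len(self.ring)
        for i in range(n):
            x1, y1 = self.ring[i]
            x2, y2 = self.ring[(i + 1) % n]
            if (y1 > lat) != (y2 > lat):
                x_cross = x1 + (lat - y1) / (y2 - y1) * (x2 - x1)
                if lon < x_cross:
                    inside = not inside
        return inside


@dataclass
class RunConfig:
    """Paths, constants and settings for a pipeline run."""

    cohort_dir: str = "cohort"
    out_dir: str = "results"
    colony_lat: float = 59.43
    colony_lon: float = -146.33
    colony_radius_m: float = 200.0
    land_mask_path: str | None = None
    seed: int = 0
    budgets_from: str = "hmm"   # "hmm" or "truth" (validation mode)
    hmm_max_iter: int = 100
    hmm_tol: float = 1e-5
    hmm_restarts: int = 2
    constants_overrides: dict = field(default_factory=dict)
    simulation_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                **(extra or {})}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
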
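"""Signal metrics: from raw 25 Hz triaxial acceleration and 3-min GPS fixes
to the four 10 s predictor streams (wingbeat frequency, ground speed, presence
at the colony, presence on land) plus VeDBA.

Conventions: WGS-84 decimal degrees, haversine distances, speeds in km h^-1,
accelerations in g.  Bins are half-open [t, t+10) anchored to the trace start;
a partial trailing bin is dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0
BIN_SECONDS = 10.0

__all__ = [
    "AccelTrace",
    "AxisCalibration",
    "apply_axis_calibration",
    "compute_vedba",
    "estimate_wbf",
    "haversine_m",
    "interpolate_positions_and_speed",
    "assemble_bins",
]


@dataclass(frozen=True)
class AccelTrace:
    """Triaxial acceleration series (g) with timestamps in seconds."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("need at least two samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for name in ("ax", "ay", "az"):
            if len(getattr(self, name)) != len(t):
                raise ValueError(f"axis {name} length mismatch")
        # nominal 25 Hz; gaps are flagged, never silently filled
        dt = np.median(np.diff(t))
        gaps = np.diff(t) > 2.5 * dt
        if gaps.any():
            logger.warning("accel trace has %d sampling gaps > 2.5x nominal", gaps.sum())

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class AxisCalibration:
    """Per-axis linear recalibration x' = gain * x + offset (6-O style)."""

    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gain):
            raise ValueError("calibration gains must be > 0")


def apply_axis_calibration(trace: AccelTrace, cal: AxisCalibration) -> AccelTrace:
    """Map each axis through its gain/offset; timestamps unchanged."""
    return AccelTrace(
        t=trace.t,
        ax=cal.gain[0] * np.asarray(trace.ax, float) + cal.offset[0],
        ay=cal.gain[1] * np.asarray(trace.ay, float) + cal.offset[1],
        az=cal.gain[2] * np.asarray(trace.az, float) + cal.offset[2],
    )


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean with truncated windows at the edges."""
    csum = np.cumsum(np.concatenate(([0.0], x)))
    n = len(x)
    half = window // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + window - half, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_vedba(trace: AccelTrace, window_s: float = 10.0) -> np.ndarray:
    """Per-sample vectorial dynamic body acceleration (g).

    The static (gravitational) component of each axis is a centred running
    mean over ``window_s``; the dynamic residual's vector norm is VeDBA.
    Edge windows are truncated rather than reflected.
    """
    duration = trace.t[-1] - trace.t[0]
    if duration < window_s:
        raise ValueError("trace shorter than the smoothing window")
    window = max(1, int(round(window_s * trace.rate_hz)))
    dyn = []
    for name in ("ax", "ay", "az"):
        x = np.asarray(getattr(trace, name), float)
        if np.all(np.isnan(x)):
            raise ValueError(f"axis {name} is all-NaN")
        dyn.append(x - _running_mean(x, window))
    return np.sqrt(dyn[0] ** 2 + dyn[1] ** 2 + dyn[2] ** 2)


def estimate_wbf(heave: np.ndarray, rate_hz: float = 25.0,
                 fmin: float = 1.0, fmax: float = 10.0,
                 power_factor: float = 25.0) -> float:
    """Dominant wingbeat frequency (Hz) of a dorsoventral-axis segment.

    Spectral peak of the mean-removed signal over [fmin, fmax] Hz using a
    rectangular window; returns 0 when the peak power is below
    ``power_factor`` times the median spectral density (no flapping: for a
    white-noise bin the spectral max sits near ln(n_bins) ~ 5x the median,
    while a genuine wingbeat tone is orders of magnitude above it), and NaN
    for segments shorter than 2 s (logged as missing).
    """
    x = np.asarray(heave, float)
    x = x[~np.isnan(x)]
    if len(x) < 2 * rate_hz:
        logger.info("wbf: segment shorter than 2 s, returning missing")
        return math.nan
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate_hz)
    band = (freqs >= fmin) & (freqs <= fmax)
    if not band.any() or spec.max() == 0:
        return 0.0
    peak_idx = np.argmax(spec[band])
    ref = np.median(spec[1:])  # exclude DC
    if spec[band][peak_idx] < power_factor * ref or ref == 0:
        return 0.0
    return float(freqs[band][peak_idx])


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in metres between WGS-84 points (degrees)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def _to_unit_vec(lat_deg, lon_deg):
    lat, lon = np.radians(lat_deg), np.radians(lon_deg)
    return np.stack([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


def _from_unit_vec(v):
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1, 1)))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lat, lon


def interpolate_positions_and_speed(gps: pd.DataFrame,
                                    bin_starts: np.ndarray) -> pd.DataFrame:
    """Great-circle, linear-in-time interpolation of GPS fixes onto bin starts.

    ``gps`` must have columns t (s), lat, lon with strictly increasing unique
    timestamps.  Ground speed is the segment's great-circle distance divided
    by its duration (km h^-1), constant within each inter-fix segment.  Bins
    outside the fix range get NaN position and speed.
    """
    if len(gps) < 2:
        raise ValueError("need at least two GPS fixes")
    t = np.asarray(gps["t"], float)
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate GPS timestamps")
    if np.any(np.diff(t) < 0):
        raise ValueError("GPS fixes are not time-ordered")
    lat, lon = np.asarray(gps["lat"], float), np.asarray(gps["lon"], float)

    seg_dist_m = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    seg_speed_kmh = seg_dist_m / np.diff(t) * 3.6

    bins = np.asarray(bin_starts, float)
    idx = np.searchsorted(t, bins, side="right") - 1
    inside = (bins >= t[0]) & (bins <= t[-1])
    # bins exactly at the last fix belong to the final segment
    idx = np.clip(idx, 0, len(t) - 2)

    out_lat = np.full(len(bins), np.nan)
    out_lon = np.full(len(bins), np.nan)
    out_speed = np.full(len(bins), np.nan)
    if inside.any():
        i = idx[inside]
        frac = (bins[inside] - t[i]) / (t[i + 1] - t[i])
        v0 = _to_unit_vec(lat[i], lon[i])
        v1 = _to_unit_vec(lat[i + 1], lon[i + 1])
        # spherical linear interpolation; degenerate (identical) fixes fall
        # back to the endpoint
        dot = np.clip(np.sum(v0 * v1, axis=-1), -1.0, 1.0)
        omega = np.arccos(dot)
        small = omega < 1e-12
        w0 = np.where(small, 1.0 - frac, np.sin((1 - frac) * np.where(small, 1, omega))
                      / np.where(small, 1, np.sin(np.where(small, 1, omega))))
        w1 = np.where(small, frac, np.sin(frac * np.where(small, 1, omega))
                      / np.where(small, 1, np.sin(np.where(small, 1, omega))))
        v = w0[:, None] * v0 + w1[:, None] * v1
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        la, lo = _from_unit_vec(v)
        out_lat[inside], out_lon[inside] = la, lo
        out_speed[inside] = seg_speed_kmh[i]
    return pd.DataFrame({"t": bins, "lat": out_lat, "lon": out_lon,
                         "ground_speed_kmh": out_speed})


def assemble_bins(trace: AccelTrace, gps: pd.DataFrame,
                  colony_latlon: tuple[float, float],
                  colony_radius_m: float = 200.0,
                  land_mask=None,
                  heave_axis: str = "az",
                  bin_s: float = BIN_SECONDS) -> pd.DataFrame:
    """Build the 10 s predictor records from a calibrated trace and GPS fixes.

    Returns one row per complete bin with columns bin_start, wbf,
    ground_speed_kmh, at_colony, on_land, vedba, lat, lon.  ``at_colony`` is
    true within ``colony_radius_m`` of the colony; ``on_land`` requires the
    interpolated position to fall inside ``land_mask`` (an object with a
    ``contains_point(lat, lon)`` method or a shapely geometry in lon/lat) and
    not be at the colony.
    """
    t0 = float(trace.t[0])
    overlap_end = min(float(trace.t[-1]), float(np.asarray(gps["t"], float)[-1]))
    overlap_start = max(t0, float(np.asarray(gps["t"], float)[0]))
    if overlap_end <= overlap_start:
        raise ValueError("no temporal overlap between acceleration and GPS")

    n_bins = int(math.floor((float(trace.t[-1]) + 1.0 / trace.rate_hz - t0) / bin_s))
    if n_bins == 0:
        raise ValueError("trace shorter than one bin")
    starts = t0 + bin_s * np.arange(n_bins)

    vedba = compute_vedba(trace, window_s=bin_s)
    heave = np.asarray(getattr(trace, heave_axis), float)
    rel = np.asarray(trace.t, float) - t0
    bin_idx = np.minimum((rel / bin_s).astype(int), n_bins - 1)

    vedba_mean = np.full(n_bins, np.nan)
    wbf = np.full(n_bins, np.nan)
    rate = trace.rate_hz
    for b in range(n_bins):
        sel = bin_idx == b
        if not sel.any():
            continue
        vedba_mean[b] = float(np.nanmean(vedba[sel]))
        wbf[b] = estimate_wbf(heave[sel], rate_hz=rate)

    pos = interpolate_positions_and_speed(gps, starts)
    dist_colony = haversine_m(pos["lat"].to_numpy(), pos["lon"].to_numpy(),
                              colony_latlon[0], colony_latlon[1])
    with np.errstate(invalid="ignore"):
        at_colony = dist_colony <= colony_radius_m
    on_land = np.zeros(n_bins, dtype=bool)
    if land_mask is not None:
        for b in range(n_bins):
            la, lo = pos["lat"].iloc[b], pos["lon"].iloc[b]
            if np.isnan(la) or at_colony[b]:
                continue
            if hasattr(land_mask, "contains_point"):
                on_land[b] = land_mask.contains_point(la, lo)
            else:  # shapely geometry, x=lon y=lat
                from shapely.geometry import Point
                on_land[b] = land_mask.contains(Point(lo, la))

    return pd.DataFrame({
        "bin_start": starts,
        "wbf": wbf,
        "ground_speed_kmh": pos["ground_speed_kmh"].to_numpy(),
        "at_colony": np.where(np.isnan(dist_colony), False, at_colony),
        "on_land": on_land,
        "vedba": vedba_mean,
        "lat": pos["lat"].to_numpy(),
        "lon": pos["lon"].to_numpy(),
    })
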
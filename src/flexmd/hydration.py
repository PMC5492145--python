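"""Pore hydration and its coupling to ion flux.

A flexible channel conducts at highly non-uniform rates, and the rate
tracks how open — how water-filled — the pore is.  This module counts
water oxygens inside the pore cylinder per frame, bins crossing events
into time windows, and quantifies the flux–hydration relationship with a
windowed correlation coefficient.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, SelectionError
from .model import ChannelDefinition, Trajectory, minimum_image


@dataclass
class PoreWaterSeries:
    times: np.ndarray  # ns
    counts: np.ndarray  # integer water-oxygen counts per frame


@dataclass
class WindowedFlux:
    centers: np.ndarray  # ns
    counts: dict[str, np.ndarray]  # per-species crossings per window
    window: float  # ns


@dataclass
class CorrelationResult:
    """Pearson (or Spearman) r between windowed flux and mean pore water.

    ``undefined`` is set when either series has zero variance; r is then
    NaN rather than a silent 0.
    """

    r: float
    n_windows: int
    window: float
    undefined: bool = False
    method: str = "pearson"


def pore_water_count(
    traj: Trajectory,
    chan: ChannelDefinition,
    water_indices,
) -> PoreWaterSeries:
    """Count water oxygens inside the pore cylinder per frame.

    The cylinder has the channel's pore radius, runs along z through
    ``chan.axis_xy``, and spans the slab [z_lo, z_hi].  Radial distance is
    computed under minimum image in x and y; boundaries are inclusive.
    """
    if chan.pore_radius is None:
        raise ConfigError("pore_radius must be set to count pore water")
    water_indices = np.atleast_1d(np.asarray(water_indices, dtype=int))
    if len(water_indices) == 0:
        raise SelectionError("water selection is empty")
    xy = traj.coordinates[:, water_indices, :2] - np.asarray(chan.axis_xy)
    xy = minimum_image(xy, traj.boxes[:, None, :2])
    r2 = np.sum(xy * xy, axis=-1)
    z = traj.coordinates[:, water_indices, 2]
    inside = (
        (r2 <= chan.pore_radius**2) & (z >= chan.z_lo) & (z <= chan.z_hi)
    )
    return PoreWaterSeries(times=traj.times.copy(), counts=inside.sum(axis=1))


def windowed_flux(events, window: float, span: float, t0: float = 0.0) -> WindowedFlux:
    """Total (direction-summed) crossings per species per time window.

    Non-overlapping windows of length `window` tile [t0, t0 + span]; a
    trailing remainder shorter than one window is dropped so every window
    has equal length.
    """
    if window <= 0:
        raise ConfigError("window must be positive")
    if window > span:
        raise ConfigError(f"window ({window} ns) exceeds the record span ({span} ns)")
    n_win = int(span // window)
    edges = t0 + np.arange(n_win + 1) * window
    centers = 0.5 * (edges[:-1] + edges[1:])
    species = sorted({e.species for e in events})
    counts = {}
    for sp in species:
        t = np.array([e.completion_time for e in events if e.species == sp])
        hist, _ = np.histogram(t, bins=edges)
        counts[sp] = hist.astype(int)
    return WindowedFlux(centers=centers, counts=counts, window=float(window))


def flux_water_correlation(
    flux: WindowedFlux,
    water: PoreWaterSeries,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate per-window total crossings with per-window mean pore water.

    The water series is averaged over the same windows the flux was binned
    into; at least 10 windows are required for the coefficient to mean
    anything.  Zero variance in either series is flagged as undefined.
    """
    n_win = len(flux.centers)
    if n_win < 10:
        raise ConfigError(f"need ≥ 10 windows for a correlation, got {n_win}")
    total = np.zeros(n_win)
    for c in flux.counts.values():
        total += c
    edges = np.concatenate(
        [flux.centers - flux.window / 2, [flux.centers[-1] + flux.window / 2]]
    )
    which = np.digitize(water.times, edges) - 1
    ok = (which >= 0) & (which < n_win)
    sums = np.bincount(which[ok], weights=water.counts[ok], minlength=n_win)
    ns = np.bincount(which[ok], minlength=n_win)
    if np.any(ns == 0):
        raise ConfigError("water series does not cover every flux window")
    mean_water = sums / ns
    if np.ptp(total) == 0 or np.ptp(mean_water) == 0:
        return CorrelationResult(
            r=float("nan"), n_windows=n_win, window=flux.window,
            undefined=True, method=method,
        )
    if method == "pearson":
        r = stats.pearsonr(total, mean_water).statistic
    elif method == "spearman":
        r = stats.spearmanr(total, mean_water).statistic
    else:
        raise ConfigError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        r=float(r), n_windows=n_win, window=flux.window, method=method
    )
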
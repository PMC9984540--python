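"""Event-by-event TOF -> vertex inversion (prompt gamma time imaging).

Every detector gets a reference time map: the total proton + gamma time of
flight as a function of the PG vertex coordinate along the beam axis,
evaluated in the REFERENCE geometry.  Measured TOFs are inverted through
this map by piecewise-linear interpolation, converting TOF distributions
into spatial PG profiles that can be merged across detectors at different
angles.  Maps are deliberately never rebuilt for shifted geometries — the
proton transit term is determined in reference conditions, which biases the
recovered shift low by a known, slope-below-one factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NonMonotoneMapError
from .synthetic import gamma_flight_time_ps

RECONSTRUCTED_COLUMNS = ["event_id", "detector_id", "x_rec_cm", "in_range"]


@dataclass
class ReferenceTimeMap:
    """Monotone grid x -> T_p(x) + T_PG(x, r_d) for one detector."""

    detector_id: str
    grid_positions: np.ndarray
    total_tof: np.ndarray

    def __post_init__(self):
        self.grid_positions = np.asarray(self.grid_positions, dtype=float)
        self.total_tof = np.asarray(self.total_tof, dtype=float)
        diffs = np.diff(self.total_tof)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise NonMonotoneMapError(
                self.detector_id,
                (self.grid_positions[i], self.grid_positions[i + 1]))

    @property
    def tof_range(self):
        return float(self.total_tof[0]), float(self.total_tof[-1])

    def tof_at(self, x):
        return np.interp(x, self.grid_positions, self.total_tof)

    def write(self, path):
        np.savetxt(path, np.column_stack([self.grid_positions, self.total_tof]),
                   delimiter="\t", header=f"x_cm\ttof_ps\t# {self.detector_id}",
                   comments="")

    @classmethod
    def read(cls, path, detector_id):
        table = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        return cls(detector_id, table[:, 0], table[:, 1])


def build_reference_map(config, detector, grid_step=0.02, time_map=None,
                        x_max=None, detector_position=None):
    """Build the per-detector TOF-versus-vertex map in the reference geometry.

    The grid covers [0, emission fall-off + margin].  A non-monotone map
    (possible for far-upstream detectors whose gamma flight time shrinks
    faster than the proton transit time grows) raises an explicit error
    naming the offending interval.
    """
    from .physics import proton_time_map
    from .synthetic import pg_emission_profile

    if time_map is None:
        time_map = proton_time_map(config.slabs, config.beam_energy_mev,
                                   config.range_model, grid_step=grid_step)
    profile = pg_emission_profile(config, time_map=time_map)
    if x_max is None:
        # cover the fall-off plus a margin for resolution blur
        x_max = min(profile.falloff_x + 1.0, time_map.x_max)
    if detector_position is None:
        detector_position = detector.position(profile.falloff_x)

    n = max(2, int(round(x_max / grid_step)) + 1)
    grid = np.linspace(0.0, x_max, n)
    total = time_map.time_at(grid) + gamma_flight_time_ps(grid,
                                                          detector_position)
    return ReferenceTimeMap(detector.id, grid, total)


def invert_tof(tof, ref_map):
    """Invert one measured TOF into a vertex coordinate.

    Returns (x_rec, in_range).  Out-of-range TOFs are clamped to the map
    boundary and flagged rather than dropped, preserving count bookkeeping.
    """
    lo, hi = ref_map.tof_range
    in_range = lo <= tof <= hi
    x = float(np.interp(tof, ref_map.total_tof, ref_map.grid_positions))
    return x, bool(in_range)


def invert_tof_array(tofs, ref_map):
    """Vectorized :func:`invert_tof`."""
    tofs = np.asarray(tofs, dtype=float)
    lo, hi = ref_map.tof_range
    in_range = (tofs >= lo) & (tofs <= hi)
    x = np.interp(tofs, ref_map.total_tof, ref_map.grid_positions)
    return x, in_range


def reconstruct_dataset(events, maps):
    """Reconstruct every event through its detector's reference map.

    ``maps`` is a mapping detector_id -> ReferenceTimeMap.  The output is
    count-preserving: every input event appears exactly once, flagged
    ``in_range`` or not.  Returns a DataFrame with the reconstructed
    coordinate merged onto the input columns.
    """
    missing = set(events["detector_id"].unique()) - set(maps)
    if missing:
        raise ConfigurationError(
            f"no reference map for detector(s): {sorted(missing)}")
    out = events.copy()
    x_rec = np.empty(len(events))
    in_range = np.empty(len(events), dtype=bool)
    for det_id, group in events.groupby("detector_id"):
        x, ok = invert_tof_array(group["tof_ps"].to_numpy(), maps[det_id])
        x_rec[group.index] = x
        in_range[group.index] = ok
    out["x_rec_cm"] = x_rec
    out["in_range"] = in_range
    return out


def background_template(ref_map, tof_window, bin_edges, n_samples=200_000,
                        seed=0):
    """Spatial shape of a flat-in-TOF background after reconstruction.

    Uniform TOF samples over ``tof_window`` are pushed through the inverse
    map and histogrammed on ``bin_edges``; the result is normalized to unit
    sum so it can be amplitude-fitted to a reconstructed profile.  In-range
    samples only; deterministic under a fixed seed.
    """
    lo, hi = tof_window
    if not hi > lo:
        raise ValueError("degenerate TOF window")
    map_lo, map_hi = ref_map.tof_range
    if lo > map_lo + 1e-9 or hi < map_hi - 1e-9:
        raise ValueError("TOF window must cover the analysis (map) TOF range")
    rng = np.random.default_rng(seed)
    tofs = rng.uniform(lo, hi, int(n_samples))
    x, in_range = invert_tof_array(tofs, ref_map)
    counts, _ = np.histogram(x[in_range], bins=bin_edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no background samples fall inside the spatial bins")
    return counts / total
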
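"""Deterministic, seeded generators for every input class.

Three families of synthetic inputs drive the simulator and its tests:

* an idealized rectangular tidal channel (for hydrodynamic and transport
  oracles: seiches, standing waves, plumes);
* a toy two-bank tidal catchment emulating a polluted mangrove estuary — a
  deep north-south channel forced by a semidiurnal tide at its southern
  mouth, a mangrove floodplain on the west bank, an industrialized east
  bank with five point wastewater discharges, and monitoring stations at
  an upstream and a downstream location;
* greenhouse-style compartment datasets (pools sampled at months 0, 3 and
  6 under constant water concentration, with optional multiplicative
  noise) for parameter-estimation studies.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compartments import (AGE_CODES, AgeClass, CompartmentState, KineticParams,
                           SoilContext, analytic_compartments)
from .grid import (LANDTYPE_CODES, BoundarySegment, Grid, LandType, make_grid)
from .hydro import TideBoundary
from .transport import DischargeSource

#: Semidiurnal (M2) tidal period in seconds.
M2_PERIOD = 44712.0
#: Default tidal amplitude (m) of the emulated estuary.
DEFAULT_TIDE_AMPLITUDE = 2.7
MONTH_S = 30 * 86400.0


def default_tide(amplitude: float = DEFAULT_TIDE_AMPLITUDE,
                 period: float = M2_PERIOD, phase: float = 0.0,
                 mean_level: float = 0.0) -> TideBoundary:
    return TideBoundary(constituents=[(amplitude, period, phase)],
                        mean_level=mean_level)


def make_tidal_channel(length: float, width: float, depth: float, dx: float,
                       dy: float | None = None, tide: TideBoundary | None = None,
                       closed_both: bool = False, inflow_end: bool = False,
                       manning: float = 0.005):
    """Rectangular riverbed channel along x.

    One tidal open end at ``x = 0`` (unless ``closed_both``); the far end is
    closed, or an inflow boundary when ``inflow_end`` is set.  Returns
    ``(grid, tide)``; ``tide`` is None for a fully closed basin.
    """
    dy = dx if dy is None else dy
    if length <= 0 or width <= 0 or depth <= 0 or dx <= 0:
        raise ValueError("channel dimensions and resolution must be positive")
    nx, ny = round(length / dx), round(width / dy)
    if nx < 1 or ny < 1 or abs(nx * dx - length) > 1e-9 or abs(ny * dy - width) > 1e-9:
        raise ValueError("resolution must divide the channel dimensions")
    bed = np.full((ny, nx), float(depth))
    lt = np.full((ny, nx), LANDTYPE_CODES[LandType.RIVERBED], dtype=np.int8)
    segments = []
    if not closed_both:
        if tide is None:
            tide = default_tide()
        segments.append(BoundarySegment("tide", [(j, 0) for j in range(ny)]))
        if inflow_end:
            segments.append(BoundarySegment("inflow", [(j, nx - 1) for j in range(ny)]))
    else:
        tide = None
    grid = make_grid(bed, lt, dx, dy, open_boundary=segments,
                     manning=np.full((ny, nx), float(manning)))
    return grid, tide


@dataclass
class ToyCatchmentSpec:
    """Geometry and forcing of the toy two-bank catchment.

    The channel runs south-north (along y); the west bank is a mangrove
    floodplain slightly above datum that floods around high tide, the east
    bank is bare industrial ground carrying the discharge sources.
    """

    channel_length: float = 15000.0       # m, along-channel
    channel_width: float = 450.0          # m
    channel_depth: float = 10.0           # m below datum
    floodplain_width: float = 1350.0      # m, each bank
    floodplain_elevation: float = 0.3     # m above datum
    dx: float = 150.0
    dy: float = 150.0
    tide_amplitude: float = DEFAULT_TIDE_AMPLITUDE
    tide_period: float = M2_PERIOD
    inflow_discharge: float = 20.0        # m^3/s upstream freshwater
    source_window: tuple = (12.0, 14.0)   # daily discharge clock window, h
    # (name, relative along-channel position in (0, 1), rate mg/s)
    source_spec: tuple = (
        ("Go Dau", 0.88, 2.0),
        ("A2", 0.78, 0.5),
        ("A1", 0.68, 1.0),
        ("Phu My", 0.48, 0.2),
        ("Cai Mep", 0.38, 1.0),
    )
    station_spec: tuple = (("M1", 0.10), ("M5", 0.85))
    wetland_elevation: float = 5.0        # m above datum (never inundated)
    wetland_rows: tuple = (0.30, 0.93)    # strip extent, relative
    wetland_tau: float = 86400.0          # CSTR residence time, s
    wetland_depth: float = 0.5            # internal water depth, m
    wetland_halfwidth: int = 4            # member rows each side of a source

    def __post_init__(self):
        if min(self.channel_length, self.channel_width, self.channel_depth,
               self.floodplain_width, self.dx, self.dy) <= 0:
            raise ValueError("catchment dimensions must be positive")


@dataclass
class ToyCatchment:
    """Resolved toy domain: grid, forcing, sources, stations, templates."""

    spec: ToyCatchmentSpec
    grid: Grid
    tide: TideBoundary
    sources: list
    stations: dict                      # name -> (j, i)
    inflow_discharge: float
    age_field: np.ndarray               # AGE_CODES per cell (baseline)
    west_columns: np.ndarray            # bool mask of the mangrove bank
    wetland_cells: list                 # [(j, i)] strip cells used in SC3
    wetland_units: list                 # [{"id", "cells", "sources", "tau", "depth"}]
    kinetics: KineticParams = field(default_factory=KineticParams)
    soil: SoilContext = field(default_factory=SoilContext)


def make_toy_catchment(spec: ToyCatchmentSpec | None = None) -> ToyCatchment:
    """Build the deterministic toy catchment (no randomness involved)."""
    spec = spec or ToyCatchmentSpec()
    nfl = round(spec.floodplain_width / spec.dx)
    nch = round(spec.channel_width / spec.dx)
    ny = round(spec.channel_length / spec.dy)
    nx = 2 * nfl + nch
    if nch < 1 or nfl < 1 or ny < 2:
        raise ValueError("resolution too coarse for the requested geometry")

    west = slice(0, nfl)
    chan = slice(nfl, nfl + nch)
    east = slice(nfl + nch, nx)

    bed = np.full((ny, nx), -spec.floodplain_elevation)
    bed[:, chan] = spec.channel_depth
    lt = np.full((ny, nx), LANDTYPE_CODES[LandType.BARE], dtype=np.int8)
    lt[:, west] = LANDTYPE_CODES[LandType.MANGROVE_FLOODPLAIN]
    lt[:, chan] = LANDTYPE_CODES[LandType.RIVERBED]
    # the first east-bank column is a raised industrial platform above the
    # tidal range in every scenario; SC3 builds its wetlands there, so the
    # scenario comparison stays hydraulically controlled
    platform_col = nfl + nch
    bed[:, platform_col] = -spec.wetland_elevation

    chan_cols = range(nfl, nfl + nch)
    segments = [BoundarySegment("tide", [(0, i) for i in chan_cols]),
                BoundarySegment("inflow", [(ny - 1, i) for i in chan_cols])]
    grid = make_grid(bed, lt, spec.dx, spec.dy, open_boundary=segments)

    tide = default_tide(spec.tide_amplitude, spec.tide_period)

    east_chan_col = nfl + nch - 1     # channel column hugging the east bank
    sources = []
    for name, rel, rate in spec.source_spec:
        j = min(int(rel * ny), ny - 2)
        sources.append(DischargeSource(name=name, cell=(j, east_chan_col),
                                       rate=rate, window=spec.source_window))

    mid = nfl + nch // 2
    stations = {}
    for name, rel in spec.station_spec:
        j = min(int(rel * ny), ny - 2)
        stations[name] = (j, mid)
        if not (grid.bed_depth[j, mid] > 0):
            raise ValueError(f"station {name} is not inside the wet channel")

    age = np.full((ny, nx), AGE_CODES[AgeClass.NONE], dtype=np.int8)
    age[:, west] = AGE_CODES[AgeClass.MATURE]

    wet_col = nfl + nch               # first east-bank column
    j0, j1 = (min(int(r * ny), ny - 1) for r in spec.wetland_rows)
    wetland_cells = [(j, wet_col) for j in range(j0, j1 + 1)]
    units = []
    for idx, src in enumerate(sources):
        lo = max(src.cell[0] - spec.wetland_halfwidth, j0)
        hi = min(src.cell[0] + spec.wetland_halfwidth, j1)
        units.append({"id": f"W{idx + 1}", "cells": [(j, wet_col) for j in range(lo, hi + 1)],
                      "sources": [src.name], "tau": spec.wetland_tau,
                      "depth": spec.wetland_depth})

    west_mask = np.zeros((ny, nx), dtype=bool)
    west_mask[:, west] = True
    return ToyCatchment(spec=spec, grid=grid, tide=tide, sources=sources,
                        stations=stations, inflow_discharge=spec.inflow_discharge,
                        age_field=age, west_columns=west_mask,
                        wetland_cells=wetland_cells, wetland_units=units)


@dataclass
class GreenhouseDataset:
    """Synthetic pool observations under constant water concentration."""

    times: np.ndarray          # s
    observations: dict         # pool label -> values at times
    c0: float                  # g/m^3, held constant
    k_true: dict
    noise_sd: float
    seed: int
    initial_state: CompartmentState | None = None


def make_greenhouse_dataset(k_true: KineticParams | None = None, c0: float = 10.0,
                            noise_sd: float = 0.0, seed: int = 0,
                            times=(0.0, 3 * MONTH_S, 6 * MONTH_S),
                            observed=("Sl", "Ss", "Pl")) -> GreenhouseDataset:
    """Sample the analytic compartment trajectories at the given times.

    Noise is multiplicative Gaussian with relative standard deviation
    ``noise_sd`` (values floored at zero); ``noise_sd=0`` reproduces the
    closed-form solution exactly and the dataset is a pure function of the
    seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    k = k_true or KineticParams()
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    clean = {p: [] for p in observed}
    for t in times:
        st = analytic_compartments(k, c0, t, k13=k.k13_young)
        vals = {"Sl": st.Sl, "Ss": st.Ss, "Pl": st.Pl, "Sl+Ss": st.Sl + st.Ss,
                "c": c0}
        for p in observed:
            clean[p].append(vals[p])
    observations = {}
    for p in observed:
        v = np.asarray(clean[p], dtype=float)
        if noise_sd > 0:
            v = np.maximum(v * (1.0 + noise_sd * rng.standard_normal(v.shape)), 0.0)
        observations[p] = v
    truth = {"k01": k.k01, "k10": k.k10, "k12": k.k12, "k21": k.k21,
             "k13": k.k13_young}
    return GreenhouseDataset(times=times, observations=observations, c0=float(c0),
                             k_true=truth, noise_sd=float(noise_sd), seed=int(seed))
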
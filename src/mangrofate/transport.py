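"""Depth-averaged advection-dispersion of dissolved chromium.

Advances the water concentration ``c`` (g/m^3, equivalently mg/L) by

.. math::

    \\partial_t c + u\\,\\partial_x c + v\\,\\partial_y c
        - D_x \\partial_x^2 c - D_y \\partial_y^2 c
        = F(x, y, t) + \\gamma(-k_{01} c + k_{10} S_l)

where ``F`` collects point wastewater discharges and the last two terms
couple the water column to the soil-liquid pool.

Numerics: finite-volume update of the areal tracer mass ``m = c h``
(g/m^2) using the same face volume fluxes as the continuity equation, with
first-order upwind advection and central dispersion.  Because mass and
volume move through identical fluxes the scheme conserves tracer mass to
round-off and keeps ``c`` non-negative under the advective/diffusive
stability bound; at Courant number one, pure upwind advection is exact.

Open-boundary handling: concentration in tide-boundary cells is prescribed
(default 0 on inflow); outflow advects interior concentration into the
boundary cell.  Mass crossing the face between an interior and a boundary
cell is accounted as exported.  Dispersive fluxes are suppressed across
those faces so the zero-gradient outflow condition does not create
artificial exchange.

Sources discharging into momentarily dry cells buffer their mass and
release it on rewetting, so injected mass is never lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid
from .hydro import (HydroParams, HydroState, StabilityError, continuity_update,
                    face_fluxes)


@dataclass
class TransportParams:
    """Dispersion coefficients (m^2/s)."""

    Dx: float = 10.0
    Dy: float = 10.0
    inflow_concentration: float = 0.0   # c imposed on boundary inflow, g/m^3

    def __post_init__(self):
        if self.Dx < 0 or self.Dy < 0:
            raise ValueError("dispersion coefficients must be non-negative")


@dataclass
class DischargeSource:
    """Point chromium source with a daily clock window.

    ``rate`` is in mg/s while active; ``window`` is ``(start_hour,
    end_hour)`` within the 24-h day; ``routing`` is ``"direct"`` or
    ``("through_wetland", wetland_id)``.
    """

    name: str
    cell: tuple              # (j, i)
    rate: float              # mg/s
    window: tuple = (12.0, 14.0)
    routing: object = "direct"

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("source rate must be non-negative")
        s, e = self.window
        if not (0.0 <= s <= 24.0 and 0.0 <= e <= 24.0 and s <= e):
            raise ValueError("source window must lie within the 24-h day")

    def active(self, t: float) -> bool:
        hod = (t % 86400.0) / 3600.0
        s, e = self.window
        return s <= hod < e

    def active_seconds(self, t: float, dt: float) -> float:
        """Exact overlap (s) of ``[t, t+dt)`` with the daily clock window."""
        lo, hi = self.window[0] * 3600.0, self.window[1] * 3600.0
        sod = t % 86400.0
        total = max(min(sod + dt, hi) - max(sod, lo), 0.0)
        if sod + dt > 86400.0:  # step crosses midnight into the next day
            total += max(min(sod + dt - 86400.0, hi) - lo, 0.0)
        return total

    @property
    def wetland_id(self):
        if self.routing == "direct":
            return None
        kind, wid = self.routing
        if kind != "through_wetland":
            raise ValueError(f"unknown routing: {self.routing!r}")
        return wid


@dataclass
class TransportState:
    """Chromium in the water column.

    ``c`` is the concentration; ``m = c h`` is the areal mass (g/m^2) kept
    as the authoritative conserved variable when present, so repeated
    concentration/depth round trips cannot leak mass.  ``buffered`` holds
    source mass aimed at momentarily dry cells (grams per cell).
    """

    c: np.ndarray           # (ny, nx), g/m^3
    t: float = 0.0
    buffered: dict = field(default_factory=dict)   # (j,i) -> g held while dry
    m: np.ndarray | None = None                    # (ny, nx), g/m^2

    @classmethod
    def zeros(cls, grid: Grid, t: float = 0.0) -> "TransportState":
        return cls(c=np.zeros((grid.ny, grid.nx)), t=t)

    def copy(self) -> "TransportState":
        return TransportState(self.c.copy(), self.t, dict(self.buffered),
                              None if self.m is None else self.m.copy())


def stable_dt_transport(grid: Grid, hydro: HydroState, params: TransportParams) -> float:
    """Combined advective + diffusive explicit stability bound."""
    uc = np.abs(0.5 * (hydro.u[:, :-1] + hydro.u[:, 1:]))
    vc = np.abs(0.5 * (hydro.v[:-1, :] + hydro.v[1:, :]))
    rate = (uc / grid.dx + vc / grid.dy + 2.0 * params.Dx / grid.dx ** 2
            + 2.0 * params.Dy / grid.dy ** 2)
    mx = float(rate.max())
    return np.inf if mx == 0 else 1.0 / mx


def exchange_terms(c, Sl, k, wet, gamma):
    """Water-column source/sink from soil coupling: ``gamma(-k01 c + k10 Sl)``.

    Zero on dry cells: soil and plants only exchange mass while inundated.
    """
    if k.k01 < 0 or k.k10 < 0:
        raise ValueError("kinetic constants must be non-negative")
    c = np.asarray(c, dtype=float)
    Sl = np.asarray(Sl, dtype=float)
    out = np.asarray(gamma, dtype=float) * (-k.k01 * c + k.k10 * Sl)
    return np.where(np.asarray(wet, dtype=bool), out, 0.0)


def apply_sources(state: TransportState, sources, t: float, dt: float,
                  grid: Grid, h, wet=None, ledger: dict | None = None) -> TransportState:
    """Add source mass over ``[t, t+dt)`` to the water column.

    Mass enters as ``rate`` times the exact overlap of the step with the
    daily discharge window (mg -> g), divided by the wet cell volume; mass
    aimed at a dry cell is buffered in the state and released when the cell
    rewets.  ``ledger`` (if given) accumulates ``injected_g``.
    """
    h = np.asarray(h, dtype=float)
    wet = np.ones(state.c.shape, dtype=bool) if wet is None else np.asarray(wet, bool)
    new = state.copy()
    for src in sources:
        j, i = src.cell
        if not (0 <= j < grid.ny and 0 <= i < grid.nx):
            raise ValueError(f"source {src.name!r} cell {src.cell} outside grid")
        grams = src.rate * 1e-3 * src.active_seconds(t, dt)
        if grams and ledger is not None:
            ledger["injected_g"] = ledger.get("injected_g", 0.0) + grams
        pending = grams + new.buffered.pop((j, i), 0.0)
        if not pending:
            continue
        if wet[j, i]:
            new.c[j, i] += pending / (h[j, i] * grid.cell_area)
            if new.m is not None:
                new.m[j, i] += pending / grid.cell_area
        else:
            new.buffered[(j, i)] = pending
    return new


def _dispersion_fluxes(grid: Grid, c, fluxes, params: TransportParams,
                       exclude_u=None, exclude_v=None):
    """Central dispersive face fluxes (g/s), closed where faces are closed."""
    h_u, h_v = fluxes["h_u"], fluxes["h_v"]
    open_u, open_v = fluxes["open_u"], fluxes["open_v"]
    Du = np.where(open_u, -params.Dx * h_u * (c[:, 1:] - c[:, :-1]) / grid.dx * grid.dy, 0.0)
    Dv = np.where(open_v, -params.Dy * h_v * (c[1:, :] - c[:-1, :]) / grid.dy * grid.dx, 0.0)
    if exclude_u is not None:
        Du = np.where(exclude_u, 0.0, Du)
    if exclude_v is not None:
        Dv = np.where(exclude_v, 0.0, Dv)
    return Du, Dv


def step_transport(state: TransportState, hydro: HydroState, grid: Grid,
                   params: TransportParams, sources=(), k=None, Sl=None,
                   gamma=None, wet=None, hydro_params: HydroParams | None = None,
                   dt: float | None = None, inflow_discharge: float = 0.0,
                   ledger: dict | None = None, check: bool = True) -> TransportState:
    """Advance the concentration one step against the given hydro state.

    The step mirrors the continuity update of the flow solver: the areal
    mass ``m = c h`` moves with the same upwind face fluxes, then the new
    concentration is recovered with the updated depth.  Optional exchange
    with the soil-liquid pool uses :func:`exchange_terms` (explicit); the
    scenario engine instead couples through the exact compartment update.
    """
    hp = hydro_params or HydroParams()
    if dt is None:
        dt = stable_dt_transport(grid, hydro, params)
    elif check:
        bound = stable_dt_transport(grid, hydro, params)
        if dt > bound * (1.0 + 1e-9):
            raise StabilityError(f"transport dt={dt:g}s exceeds stability bound {bound:g}s")

    zeta = hydro.zeta
    h_old = np.maximum(grid.bed_depth + zeta, 0.0)
    fluxes = face_fluxes(grid, hydro, hp)
    bc = grid.boundary_mask("tide")

    c = state.c.copy()
    if bc.any():
        # boundary cells hold the imposed inflow concentration; outflow picks
        # up interior values through upwinding automatically
        c[bc] = params.inflow_concentration

    # upwind advective mass fluxes (g/s) through interior faces
    Fu, Fv = fluxes["Fu"], fluxes["Fv"]
    cu = np.where(Fu > 0, c[:, :-1], c[:, 1:])
    cv = np.where(Fv > 0, c[:-1, :], c[1:, :])
    Mu = Fu * cu
    Mv = Fv * cv

    bc_u = bc[:, :-1] | bc[:, 1:]
    bc_v = bc[:-1, :] | bc[1:, :]
    Du, Dv = _dispersion_fluxes(grid, c, fluxes, params, exclude_u=bc_u,
                                exclude_v=bc_v)
    Mu = Mu + Du
    Mv = Mv + Dv

    A = grid.cell_area
    m = state.m if state.m is not None else c * h_old
    div = np.zeros_like(m)
    div[:, 1:] += Mu
    div[:, :-1] -= Mu
    div[1:, :] += Mv
    div[:-1, :] -= Mv
    m_new = m + dt * div / A

    if ledger is not None and bc.any():
        # net export: mass crossing faces into boundary cells
        out = 0.0
        out += float((Mu * (bc[:, 1:] & ~bc[:, :-1])).sum())
        out -= float((Mu * (bc[:, :-1] & ~bc[:, 1:])).sum())
        out += float((Mv * (bc[1:, :] & ~bc[:-1, :])).sum())
        out -= float((Mv * (bc[:-1, :] & ~bc[1:, :])).sum())
        ledger["exported_g"] = ledger.get("exported_g", 0.0) + out * dt

    h_new = np.maximum(continuity_update(grid, zeta, fluxes, dt, inflow_discharge)
                       + grid.bed_depth, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_new = np.where(h_new > 1e-12, m_new / np.maximum(h_new, 1e-12), 0.0)

    new = TransportState(c=c_new, t=state.t + dt, buffered=dict(state.buffered),
                         m=m_new if state.m is not None else None)
    if bc.any():
        new.c[bc] = params.inflow_concentration

    wet_new = grid.active & (h_new > hp.h_dry)

    # cells that dried out completely pond their remaining mass
    dried = (h_new <= 1e-12) & (m_new > 0) & grid.active & ~bc
    if dried.any():
        for j, i in np.argwhere(dried):
            new.buffered[(j, i)] = new.buffered.get((j, i), 0.0) + m_new[j, i] * A
            if new.m is not None:
                new.m[j, i] = 0.0
            new.c[j, i] = 0.0
    # rewetted cells recover any ponded mass
    if new.buffered:
        for cell in list(new.buffered):
            j, i = cell
            if wet_new[j, i]:
                g = new.buffered.pop(cell)
                new.c[j, i] += g / (h_new[j, i] * A)
                if new.m is not None:
                    new.m[j, i] += g / A

    if sources:
        new = apply_sources(new, sources, state.t, dt, grid, np.maximum(h_new, hp.h_dry),
                            wet=wet_new, ledger=ledger)

    if k is not None and Sl is not None:
        g = 1.0 if gamma is None else gamma
        w = wet_new if wet is None else wet
        dc = dt * exchange_terms(new.c, Sl, k, w, g)
        new.c = new.c + dc
        if new.m is not None:
            new.m = new.m + dc * h_new

    if check and not np.all(np.isfinite(new.c)):
        j, i = np.argwhere(~np.isfinite(new.c))[0]
        raise StabilityError(f"non-finite concentration at cell ({j}, {i})")
    return new
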
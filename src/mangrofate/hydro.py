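"""Depth-averaged shallow-water solver.

Solves the 2-D continuity and momentum equations

.. math::

    \\partial_t \\zeta + \\partial_x[(d+\\zeta)u] + \\partial_y[(d+\\zeta)v] = 0

    \\partial_t u + u\\,\\partial_x u + v\\,\\partial_y u
        = -g\\,\\partial_x \\zeta + f v - \\tau_{bx}/(\\rho_w h) + F_x/(\\rho_w h)
          + K \\nabla^2 u

and the analogous ``v`` equation (with pressure gradient
``-g \\partial_y \\zeta`` and Coriolis ``-f u``), with a quadratic bed
friction law through the Chezy coefficient ``C = h^{1/6}/n``.

Numerics: Arakawa C-grid (``zeta`` at cell centers, ``u`` on x-faces, ``v``
on y-faces), explicit forward-backward time stepping (water level first,
then momentum against the new level), first-order upwind momentum
advection, semi-implicit bed friction, and hysteresis-free flooding/drying
(a face is open when the water level on its higher side stands more than
``h_dry`` above the higher of the two adjacent bed levels).  The water-level
update is in flux form, so volume is conserved to round-off in closed
basins.

Open boundaries are cell-based: "tide" cells carry a Dirichlet water level
synthesized from harmonic constituents; "inflow" cells receive a prescribed
bulk discharge as a distributed volume source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, wet_mask

#: Earth's angular velocity (rad/s) for the Coriolis default.
OMEGA_EARTH = 7.2921e-5
#: Default latitude (deg N) of the emulated estuary for the Coriolis parameter.
DEFAULT_LATITUDE = 10.5


def coriolis_parameter(latitude_deg: float = DEFAULT_LATITUDE) -> float:
    """``f = 2 Omega sin(latitude)`` in 1/s."""
    return 2.0 * OMEGA_EARTH * math.sin(math.radians(latitude_deg))


@dataclass
class HydroParams:
    """Physical constants and solver settings for the shallow-water step."""

    g: float = 9.81                      # gravitational acceleration, m/s^2
    f: float = field(default_factory=coriolis_parameter)  # Coriolis, 1/s
    K: float = 1.0                       # horizontal eddy viscosity, m^2/s
    rho_w: float = 1000.0                # water density, kg/m^3
    h_dry: float = 0.01                  # drying threshold, m
    cfl: float = 0.7                     # Courant safety factor, <= 1
    Fx: float | np.ndarray = 0.0         # external surface force, N/m^2
    Fy: float | np.ndarray = 0.0

    def __post_init__(self):
        if self.g <= 0 or self.rho_w <= 0 or self.h_dry <= 0:
            raise ValueError("g, rho_w and h_dry must be positive")
        if self.K < 0:
            raise ValueError("eddy viscosity K must be non-negative")
        if not (0 < self.cfl <= 1):
            raise ValueError("CFL safety factor must lie in (0, 1]")


@dataclass
class TideBoundary:
    """Harmonic water-level forcing: ``zeta(t) = mean + sum A cos(2 pi t/T - phi)``."""

    constituents: list  # of (amplitude m, period s, phase rad)
    mean_level: float = 0.0

    def __post_init__(self):
        for A, T, _phi in self.constituents:
            if A < 0:
                raise ValueError("tidal amplitude must be non-negative")
            if T <= 0:
                raise ValueError("tidal period must be positive")


def tide_elevation(boundary: TideBoundary, t: float) -> float:
    """Water level (m above datum) of the harmonic boundary at time ``t``."""
    z = boundary.mean_level
    for A, T, phi in boundary.constituents:
        z += A * math.cos(2.0 * math.pi * t / T - phi)
    return z


@dataclass
class HydroState:
    """Free-surface elevation and face-normal depth-averaged velocities."""

    zeta: np.ndarray      # (ny, nx), m above datum
    u: np.ndarray         # (ny, nx+1), m/s on x-faces
    v: np.ndarray         # (ny+1, nx), m/s on y-faces
    t: float = 0.0        # s

    @classmethod
    def at_rest(cls, grid: Grid, zeta0: float = 0.0, t: float = 0.0) -> "HydroState":
        ny, nx = grid.ny, grid.nx
        return cls(zeta=np.full((ny, nx), float(zeta0)),
                   u=np.zeros((ny, nx + 1)), v=np.zeros((ny + 1, nx)), t=t)

    def copy(self) -> "HydroState":
        return HydroState(self.zeta.copy(), self.u.copy(), self.v.copy(), self.t)


class StabilityError(RuntimeError):
    """Raised when a step violates its stability bound or goes non-finite."""


def chezy(h, n):
    """2-D Chezy coefficient ``C = h^(1/6) / n`` for total depth h and Manning n."""
    h = np.asarray(h, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(h <= 0):
        raise ValueError("Chezy coefficient requires positive total depth h")
    if np.any(n <= 0):
        raise ValueError("Manning roughness must be positive")
    out = h ** (1.0 / 6.0) / n
    return float(out) if out.ndim == 0 else out


def bed_shear(u, v, h, n, g: float = 9.81, rho_w: float = 1000.0):
    """Quadratic-law bed shear stress ``(tau_bx, tau_by)`` in N/m^2."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    C = chezy(h, n)
    speed = np.sqrt(u * u + v * v)
    tbx = rho_w * g * speed * u / C ** 2
    tby = rho_w * g * speed * v / C ** 2
    if np.ndim(tbx) == 0:
        return float(tbx), float(tby)
    return tbx, tby


def courant_dt(grid: Grid, state: HydroState, params: HydroParams) -> float:
    """Largest stable explicit step: ``cfl * min dx / (sqrt(g h) + |U|)`` over wet cells."""
    wet = wet_mask(grid, state.zeta, params.h_dry)
    if not wet.any():
        raise ValueError("all-dry domain: no wet cell to bound the time step")
    h = grid.bed_depth + state.zeta
    uc = 0.5 * (state.u[:, :-1] + state.u[:, 1:])
    vc = 0.5 * (state.v[:-1, :] + state.v[1:, :])
    speed = np.sqrt(params.g * h[wet]) + np.hypot(uc[wet], vc[wet])
    return params.cfl * min(grid.dx, grid.dy) / float(speed.max())


# ---------------------------------------------------------------------------
# internal face machinery (shared with the transport module)

def face_geometry(grid: Grid, zeta: np.ndarray, h_dry: float):
    """Face openness and face depths for the current water level.

    Returns ``(open_u, h_u, open_v, h_v)`` where ``h_*`` is the face depth
    from the max-water-level / max-bed-level rule (used for friction and
    pressure coupling); fluxes use the upwind variant from
    :func:`face_fluxes`.
    """
    zb = -grid.bed_depth  # bed elevation above datum
    act = grid.active

    zb_u = np.maximum(zb[:, :-1], zb[:, 1:])
    zmax_u = np.maximum(zeta[:, :-1], zeta[:, 1:])
    h_u = np.maximum(zmax_u - zb_u, 0.0)
    open_u = act[:, :-1] & act[:, 1:] & (h_u > h_dry)

    zb_v = np.maximum(zb[:-1, :], zb[1:, :])
    zmax_v = np.maximum(zeta[:-1, :], zeta[1:, :])
    h_v = np.maximum(zmax_v - zb_v, 0.0)
    open_v = act[:-1, :] & act[1:, :] & (h_v > h_dry)
    return open_u, h_u, open_v, h_v


def face_fluxes(grid: Grid, state: HydroState, params: HydroParams):
    """Volume fluxes (m^3/s) through interior faces, positivity-safe upwind depth.

    Returns a dict with ``Fu`` (ny, nx-1), ``Fv`` (ny-1, nx) and the face
    openness masks.  Edge faces of the grid are walls and carry no flux.
    """
    zeta = state.zeta
    zb = -grid.bed_depth
    open_u, h_u, open_v, h_v = face_geometry(grid, zeta, params.h_dry)

    ui = state.u[:, 1:-1]
    zb_u = np.maximum(zb[:, :-1], zb[:, 1:])
    z_up_u = np.where(ui > 0, zeta[:, :-1], zeta[:, 1:])
    hq_u = np.maximum(z_up_u - zb_u, 0.0)
    Fu = np.where(open_u, ui * hq_u * grid.dy, 0.0)

    vi = state.v[1:-1, :]
    zb_v = np.maximum(zb[:-1, :], zb[1:, :])
    z_up_v = np.where(vi > 0, zeta[:-1, :], zeta[1:, :])
    hq_v = np.maximum(z_up_v - zb_v, 0.0)
    Fv = np.where(open_v, vi * hq_v * grid.dx, 0.0)

    return {"Fu": Fu, "Fv": Fv, "open_u": open_u, "open_v": open_v,
            "h_u": h_u, "h_v": h_v}


def continuity_update(grid: Grid, zeta: np.ndarray, fluxes: dict, dt: float,
                      inflow_discharge: float = 0.0) -> np.ndarray:
    """Advance the water level one step in flux form (no boundary override)."""
    Fu, Fv = fluxes["Fu"], fluxes["Fv"]
    div = np.zeros_like(zeta)
    div[:, 1:] += Fu
    div[:, :-1] -= Fu
    div[1:, :] += Fv
    div[:-1, :] -= Fv
    zeta_new = zeta + dt * div / grid.cell_area
    if inflow_discharge:
        cells = grid.boundary_cells("inflow")
        if not cells:
            raise ValueError("inflow discharge prescribed but grid has no inflow cells")
        dz = inflow_discharge * dt / (len(cells) * grid.cell_area)
        for j, i in cells:
            zeta_new[j, i] += dz
    return zeta_new


def _pad_y(a):
    return np.pad(a, ((1, 1), (0, 0)), mode="edge")


def _pad_x(a):
    return np.pad(a, ((0, 0), (1, 1)), mode="edge")


def step_hydro(state: HydroState, grid: Grid, params: HydroParams,
               tide: TideBoundary | None = None, inflow_discharge: float = 0.0,
               dt: float | None = None, check: bool = True) -> HydroState:
    """Advance the shallow-water state by one explicit step of length ``dt``.

    Water level first (flux-form continuity, then Dirichlet tide override),
    then momentum against the new level.  Dry faces are closed and carry no
    velocity.  Raises :class:`StabilityError` on a CFL violation or when the
    state goes non-finite.
    """
    if dt is None:
        dt = courant_dt(grid, state, params)
    elif check:
        bound = courant_dt(grid, state, params) / params.cfl
        if dt > bound * (1.0 + 1e-12):
            raise StabilityError(f"dt={dt:g}s exceeds the explicit stability bound "
                                 f"{bound:g}s")

    fluxes = face_fluxes(grid, state, params)
    zeta_new = continuity_update(grid, state.zeta, fluxes, dt, inflow_discharge)

    t_new = state.t + dt
    if tide is not None:
        z_bc = tide_elevation(tide, t_new)
        for j, i in grid.boundary_cells("tide"):
            zeta_new[j, i] = z_bc

    open_u, h_u, open_v, h_v = face_geometry(grid, zeta_new, params.h_dry)
    g, f, K, rho = params.g, params.f, params.K, params.rho_w
    dx, dy = grid.dx, grid.dy
    n = grid.manning

    # --- u momentum on interior x-faces -----------------------------------
    U = state.u[:, 1:-1]
    vc = 0.5 * (state.v[:-1, :] + state.v[1:, :])           # v at centers
    vbar = 0.5 * (vc[:, :-1] + vc[:, 1:])                   # v at u-faces
    dzdx = (zeta_new[:, 1:] - zeta_new[:, :-1]) / dx

    uL, uR = state.u[:, :-2], state.u[:, 2:]
    adv_x = np.where(U > 0, U * (U - uL) / dx, U * (uR - U) / dx)
    Up = _pad_y(U)
    adv_y = np.where(vbar > 0, vbar * (U - Up[:-2]) / dy, vbar * (Up[2:] - U) / dy)
    lap = (uL - 2 * U + uR) / dx ** 2 + (Up[:-2] - 2 * U + Up[2:]) / dy ** 2

    h_eff = np.maximum(h_u, params.h_dry)
    n_u = 0.5 * (n[:, :-1] + n[:, 1:])
    Fx = params.Fx if np.isscalar(params.Fx) else 0.5 * (params.Fx[:, :-1] + params.Fx[:, 1:])
    rhs = (-g * dzdx - adv_x - adv_y + f * vbar + K * lap + Fx / (rho * h_eff))
    speed = np.hypot(U, vbar)
    fric = dt * g * n_u ** 2 * speed / h_eff ** (4.0 / 3.0)
    u_new = np.where(open_u, (U + dt * rhs) / (1.0 + fric), 0.0)

    # --- v momentum on interior y-faces -----------------------------------
    V = state.v[1:-1, :]
    uc = 0.5 * (state.u[:, :-1] + state.u[:, 1:])           # u at centers
    ubar = 0.5 * (uc[:-1, :] + uc[1:, :])                   # u at v-faces
    dzdy = (zeta_new[1:, :] - zeta_new[:-1, :]) / dy

    vD, vU2 = state.v[:-2, :], state.v[2:, :]
    adv_yv = np.where(V > 0, V * (V - vD) / dy, V * (vU2 - V) / dy)
    Vp = _pad_x(V)
    adv_xv = np.where(ubar > 0, ubar * (V - Vp[:, :-2]) / dx,
                      ubar * (Vp[:, 2:] - V) / dx)
    lap_v = (Vp[:, :-2] - 2 * V + Vp[:, 2:]) / dx ** 2 + (vD - 2 * V + vU2) / dy ** 2

    h_eff_v = np.maximum(h_v, params.h_dry)
    n_v = 0.5 * (n[:-1, :] + n[1:, :])
    Fy = params.Fy if np.isscalar(params.Fy) else 0.5 * (params.Fy[:-1, :] + params.Fy[1:, :])
    rhs_v = (-g * dzdy - adv_xv - adv_yv - f * ubar + K * lap_v + Fy / (rho * h_eff_v))
    speed_v = np.hypot(V, ubar)
    fric_v = dt * g * n_v ** 2 * speed_v / h_eff_v ** (4.0 / 3.0)
    v_new = np.where(open_v, (V + dt * rhs_v) / (1.0 + fric_v), 0.0)

    u_full = np.zeros_like(state.u)
    u_full[:, 1:-1] = u_new
    v_full = np.zeros_like(state.v)
    v_full[1:-1, :] = v_new

    if check:
        for name, arr in (("zeta", zeta_new), ("u", u_full), ("v", v_full)):
            if not np.all(np.isfinite(arr)):
                j, i = np.argwhere(~np.isfinite(arr))[0]
                raise StabilityError(f"non-finite {name} at cell ({j}, {i}) "
                                     f"after step to t={t_new:g}s")

    return HydroState(zeta=zeta_new, u=u_full, v=v_full, t=t_new)
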
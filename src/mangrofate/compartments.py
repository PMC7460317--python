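"""Linear water-soil-plant compartment kinetics for chromium.

Per cell, chromium partitions between the water column (concentration ``c``,
g/m^3) and three soil-bound pools expressed per kilogram of active soil:
soil liquid phase ``Sl``, soil solid phase ``Ss`` and plant tissue ``Pl``
(all mg/kg).  With linear first-order kinetics the pool balances are

.. math::

    dS_l/dt &= k_{01} c - (k_{12} + k_{13} + k_{10}) S_l + k_{21} S_s \\\\
    dS_s/dt &= k_{12} S_l - k_{21} S_s \\\\
    dP_l/dt &= k_{13} S_l

The plant pool has no loss term, so ``Pl`` is non-decreasing.  ``k13``
depends on mangrove age: young trees take up fastest, mature forest an
order of magnitude slower, unvegetated cells not at all.

Unit closure.  The pools are carried per kg of soil in an active layer of
thickness ``z_s`` and bulk density ``rho_b``, so the areal pool mass is
``pool * rho_b * z_s * 1e-3`` g/m^2 (mg -> g).  Exchange with a water
column of depth ``h`` then enters the water as

.. math::

    dc/dt = \\gamma\\,(-k_{01} c + k_{10} S_l),\\qquad
    \\gamma = \\rho_b z_s / (1000\\,h)

which makes the water loss exactly equal the pool gain; all three pools use
the soil-mass basis for accounting so the internal transfers (k12, k21,
k13) cancel from the budget.  The plant biomass density ``B`` converts
``Pl`` to a per-plant-biomass concentration for reporting only.

Exchange is gated on inundation: dry cells neither gain nor lose mass.

Integration uses the exact affine update of the linear system (matrix
exponential with the water concentration frozen over the step), which is
unconditionally stable for stiff rate combinations; a forward-Euler variant
is kept for cross-checks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.linalg import expm


class AgeClass(enum.Enum):
    """Mangrove age class of a cell; selects the uptake rate k13."""

    NONE = "none"
    YOUNG = "young"
    MATURE = "mature"


AGE_CODES = {a: i for i, a in enumerate(AgeClass)}
AGE_FROM_CODE = {i: a for a, i in AGE_CODES.items()}


@dataclass(frozen=True)
class KineticParams:
    """First-order rate constants (1/s).

    Defaults are order-of-magnitude working values exercised mainly through
    fitting and the analytic oracle, except the young-tree uptake rate which
    comes from greenhouse phytoremediation experiments; the mature rate is
    set one order of magnitude lower (configurable).
    """

    k01: float = 1e-6     # water -> soil liquid
    k10: float = 1e-8     # soil liquid -> water
    k12: float = 1e-6     # soil liquid -> soil solid (sorption)
    k21: float = 1e-7     # soil solid -> soil liquid (desorption)
    k13_young: float = 7e-8    # soil liquid -> plant, young trees
    k13_mature: float = 7e-9   # soil liquid -> plant, mature forest

    def __post_init__(self):
        for name in ("k01", "k10", "k12", "k21", "k13_young", "k13_mature"):
            if getattr(self, name) < 0:
                raise ValueError(f"kinetic constant {name} must be non-negative")

    def k13_for(self, age: AgeClass) -> float:
        return {AgeClass.NONE: 0.0, AgeClass.YOUNG: self.k13_young,
                AgeClass.MATURE: self.k13_mature}[age]

    def with_(self, **kw) -> "KineticParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SoilContext:
    """Conversion constants closing the mass balance between media."""

    rho_b: float = 1300.0        # soil bulk density, kg/m^3
    z_s: float = 0.3             # active soil layer thickness, m
    B: float = 10.0              # plant biomass areal density, kg/m^2 (reporting)

    def __post_init__(self):
        if self.rho_b <= 0 or self.z_s <= 0 or self.B <= 0:
            raise ValueError("soil context constants must be positive")

    @property
    def soil_areal_mass(self) -> float:
        """kg of active soil per m^2."""
        return self.rho_b * self.z_s

    def gamma(self, h):
        """Soil-to-water conversion ``rho_b z_s / (1000 h)`` (dimensionless)."""
        return self.soil_areal_mass / (1000.0 * np.asarray(h, dtype=float))

    def pool_areal_mass_g(self, pool_mg_per_kg):
        """Areal mass (g/m^2) of a pool given in mg per kg soil."""
        return np.asarray(pool_mg_per_kg, dtype=float) * self.soil_areal_mass * 1e-3


@dataclass
class CompartmentState:
    """Per-cell chromium pools (mg per kg soil)."""

    Sl: np.ndarray
    Ss: np.ndarray
    Pl: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "CompartmentState":
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape))

    def copy(self) -> "CompartmentState":
        return CompartmentState(self.Sl.copy(), self.Ss.copy(), self.Pl.copy())

    @property
    def total(self) -> np.ndarray:
        return self.Sl + self.Ss + self.Pl


def rate_matrix(k: KineticParams, k13: float) -> np.ndarray:
    """Homogeneous part of the (Sl, Ss, Pl) system."""
    return np.array([
        [-(k.k10 + k.k12 + k13), k.k21, 0.0],
        [k.k12, -k.k21, 0.0],
        [k13, 0.0, 0.0],
    ])


def compartment_rhs(c, state: CompartmentState, k: KineticParams,
                    k13=None, gamma=1.0):
    """Time derivatives of the pools and the induced water source term.

    ``k13`` may be a scalar or per-cell field (default: young-tree value).
    ``gamma`` is the soil-to-water conversion (see :meth:`SoilContext.gamma`);
    the returned ``water_exchange`` is ``gamma * (-k01 c + k10 Sl)`` in
    g/m^3/s so that water loss equals pool gain.
    """
    if k13 is None:
        k13 = k.k13_young
    k13 = np.asarray(k13, dtype=float)
    if np.any(k13 < 0):
        raise ValueError("k13 must be non-negative")
    c = np.asarray(c, dtype=float)
    dSl = k.k01 * c - (k.k12 + k13 + k.k10) * state.Sl + k.k21 * state.Ss
    dSs = k.k12 * state.Sl - k.k21 * state.Ss
    dPl = k13 * state.Sl
    water_exchange = np.asarray(gamma, dtype=float) * (-k.k01 * c + k.k10 * state.Sl)
    return dSl, dSs, dPl, water_exchange


@lru_cache(maxsize=256)
def affine_propagator(k: KineticParams, k13: float, dt: float):
    """Exact one-step update operators for frozen water concentration.

    Returns ``(M, w)`` with ``x(t+dt) = M @ x(t) + w * c`` where
    ``x = (Sl, Ss, Pl)``; obtained from the augmented matrix exponential of
    the forced linear system.  Cached: a fixed-step run reuses one
    propagator per age class.
    """
    A = rate_matrix(k, k13)
    aug = np.zeros((4, 4))
    aug[:3, :3] = A
    aug[0, 3] = k.k01
    E = expm(aug * dt)
    M, w = E[:3, :3].copy(), E[:3, 3].copy()
    M.setflags(write=False)
    w.setflags(write=False)
    return M, w


def step_compartments(state: CompartmentState, c, k: KineticParams, wet,
                      dt: float, h=None, soil: SoilContext | None = None,
                      age_field=None, method: str = "exact"):
    """Advance the pools one step; return ``(new_state, dc)``.

    Exchange acts only on wet cells.  ``dc`` (g/m^3) is the water
    concentration change implied by exact mass transfer; it is zero when
    ``h``/``soil`` are omitted (pools driven by a prescribed concentration,
    as in greenhouse settings).

    ``age_field`` is an integer array of :data:`AGE_CODES` (default:
    young everywhere), letting k13 vary per cell by age class.
    """
    c = np.asarray(c, dtype=float)
    wet = np.asarray(wet, dtype=bool)
    new = state.copy()
    dc = np.zeros_like(c)
    if age_field is None:
        age_field = np.full(c.shape, AGE_CODES[AgeClass.YOUNG], dtype=np.int8)

    for age in AgeClass:
        mask = wet & (age_field == AGE_CODES[age])
        if not mask.any():
            continue
        k13 = k.k13_for(age)
        x = np.stack([state.Sl[mask], state.Ss[mask], state.Pl[mask]])
        cm = c[mask]
        if method == "exact":
            M, w = affine_propagator(k, k13, dt)
            x_new = M @ x + np.outer(w, cm)
        elif method == "euler":
            ktot = (k.k10 + k.k12 + k13 + k.k21) * dt
            if ktot >= 1.0:
                raise ValueError(f"explicit Euler unstable: dt*sum(k)={ktot:g} >= 1")
            A = rate_matrix(k, k13)
            x_new = x + dt * (A @ x + np.outer([k.k01, 0.0, 0.0], cm))
        else:
            raise ValueError(f"unknown integration method: {method!r}")
        new.Sl[mask], new.Ss[mask], new.Pl[mask] = x_new
        if h is not None and soil is not None:
            dm = (x_new.sum(axis=0) - x.sum(axis=0)) * soil.soil_areal_mass * 1e-3
            hm = np.broadcast_to(np.asarray(h, dtype=float), c.shape)[mask]
            dc[mask] = -dm / hm
    return new, dc


def analytic_compartments(k: KineticParams, c_const: float, t: float,
                          initial: CompartmentState | None = None,
                          k13: float | None = None) -> CompartmentState:
    """Closed-form solution of the pool system for constant water concentration.

    Serves as the independent oracle for the stepping integrators; computed
    from a single augmented matrix exponential over the whole interval.
    """
    if k13 is None:
        k13 = k.k13_young
    M, w = affine_propagator(k, k13, t)
    if initial is None:
        x0 = np.zeros((3, 1))
        shape = ()
    else:
        x0 = np.stack([np.atleast_1d(np.asarray(initial.Sl, float)).ravel(),
                       np.atleast_1d(np.asarray(initial.Ss, float)).ravel(),
                       np.atleast_1d(np.asarray(initial.Pl, float)).ravel()])
        shape = np.asarray(initial.Sl).shape
    x = M @ x0 + np.outer(w, np.atleast_1d(c_const) * np.ones(x0.shape[1]))
    Sl, Ss, Pl = (xi.reshape(shape) if shape else float(xi[0]) for xi in x)
    return CompartmentState(Sl=Sl, Ss=Ss, Pl=Pl)


def uptake_rate_field(run, window) -> np.ndarray:
    """Average plant uptake rate (mg/kg/day) over a time window of a run.

    ``run`` must expose ``snapshot_times`` (s) and ``Pl_snapshots`` (list of
    per-cell fields); the window ``(t0, t1)`` must be bracketed by snapshots.
    The nearest snapshots at or outside the window bound it.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    times = np.asarray(run.snapshot_times, dtype=float)
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError("window outside the run's snapshot range")
    i0 = int(np.argmin(np.abs(times - t0)))
    i1 = int(np.argmin(np.abs(times - t1)))
    if i1 <= i0:
        raise ValueError("window does not span two distinct snapshots")
    days = (times[i1] - times[i0]) / 86400.0
    rate = (run.Pl_snapshots[i1] - run.Pl_snapshots[i0]) / days
    return np.maximum(rate, 0.0)
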
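"""Model-efficiency metrics and kinetic-parameter estimation.

Implements the three efficiency criteria commonly used to judge estuarine
model skill — Nash-Sutcliffe efficiency (NSE), Willmott's index of
agreement (d) and the root mean square error (RMSE) — plus bounded
nonlinear least-squares estimation of the compartment rate constants from
greenhouse-style pool observations, and 1-D tuning of the mature-forest
uptake rate against field plant-concentration series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .compartments import KineticParams, analytic_compartments

PARAM_NAMES = ("k01", "k10", "k12", "k21", "k13")


@dataclass
class StationSeries:
    """A labelled time series sampled at strictly increasing times (s)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def _aligned(obs, sim):
    o = obs.values if isinstance(obs, StationSeries) else np.asarray(obs, dtype=float)
    s = sim.values if isinstance(sim, StationSeries) else np.asarray(sim, dtype=float)
    if o.shape != s.shape:
        raise ValueError("observed and simulated series must be aligned")
    if isinstance(obs, StationSeries) and isinstance(sim, StationSeries):
        if not np.array_equal(obs.times, sim.times):
            raise ValueError("observed and simulated series must share sample times")
    return o, s


def nse(obs, sim) -> float:
    """Nash-Sutcliffe efficiency: 1 perfect, 0 as good as the observed mean."""
    o, s = _aligned(obs, sim)
    if o.size < 2:
        raise ValueError("NSE needs at least two samples")
    denom = float(((o - o.mean()) ** 2).sum())
    if denom == 0.0:
        raise ValueError("NSE undefined for a constant observed series")
    return 1.0 - float(((o - s) ** 2).sum()) / denom


def index_of_agreement(obs, sim) -> float:
    """Willmott's index of agreement d in [0, 1]; 1 is a perfect match.

    ``d = 1 - sum (o - s)^2 / sum (|s - mean(o)| + |o - mean(o)|)^2``.
    A zero potential error can only occur together with zero error
    (both series constant and equal); that 0/0 case returns 1 by convention.
    """
    o, s = _aligned(obs, sim)
    if o.size < 2:
        raise ValueError("index of agreement needs at least two samples")
    mo = o.mean()
    num = float(((o - s) ** 2).sum())
    denom = float(((np.abs(s - mo) + np.abs(o - mo)) ** 2).sum())
    if denom == 0.0:
        return 1.0
    return 1.0 - num / denom


def rmse(obs, sim) -> float:
    """Root mean square error, in the units of the series."""
    o, s = _aligned(obs, sim)
    if o.size == 0:
        raise ValueError("RMSE of an empty series")
    return float(np.sqrt(((o - s) ** 2).mean()))


@dataclass
class FitResult:
    """Outcome of a compartment-parameter fit."""

    estimates: dict
    rss: float
    conf_intervals: dict
    success: bool
    identifiable: bool = True
    message: str = ""

    def __getitem__(self, name):
        return self.estimates[name]


def _predict(theta, free, fixed, times, c0, initial):
    p = dict(fixed)
    p.update(dict(zip(free, theta)))
    k = KineticParams(k01=p["k01"], k10=p["k10"], k12=p["k12"], k21=p["k21"],
                      k13_young=p["k13"], k13_mature=p["k13"])
    out = {}
    for t in times:
        st = analytic_compartments(k, c0, t, initial=initial, k13=p["k13"])
        out[t] = {"Sl": st.Sl, "Ss": st.Ss, "Pl": st.Pl,
                  "Sl+Ss": st.Sl + st.Ss, "c": c0}
    return out


def fit_compartment_params(dataset, initial_guess: dict | None = None,
                           bounds: dict | None = None, free=PARAM_NAMES,
                           cond_threshold: float = 1e8) -> FitResult:
    """Bounded least-squares fit of the rate constants to pool observations.

    ``dataset`` must expose ``times`` (s), ``observations`` (mapping pool
    label -> values at those times; labels among ``c, Sl, Ss, Pl, Sl+Ss``),
    ``c0`` (constant water concentration, g/m^3) and optionally
    ``initial_state``.  Pools are weighted by the standard deviation of
    their observed series so mg/L and mg/kg scales contribute comparably.

    Identifiability is assessed from the Jacobian at the solution: a
    rank-deficient or extremely ill-conditioned sensitivity matrix flags the
    result as non-identifiable.
    """
    times = np.asarray(dataset.times, dtype=float)
    obs = {k_: np.asarray(v, dtype=float) for k_, v in dataset.observations.items()
           if k_ != "c"}
    n_obs = sum(v.size for v in obs.values())
    if len(times) < 3:
        raise ValueError("need at least three sample times")
    if n_obs < len(free):
        raise ValueError(
            f"only {n_obs} pool observations for {len(free)} free parameters: "
            "the fit is not identifiable")

    defaults = {"k01": 1e-6, "k10": 1e-8, "k12": 1e-6, "k21": 1e-7, "k13": 7e-8}
    guess = dict(defaults)
    if initial_guess:
        guess.update(initial_guess)
    fixed = {n: guess[n] for n in PARAM_NAMES if n not in free}
    x0 = np.array([guess[n] for n in free], dtype=float)
    lo = np.array([(bounds or {}).get(n, (0.0, np.inf))[0] for n in free])
    hi = np.array([(bounds or {}).get(n, (0.0, np.inf))[1] for n in free])

    initial = getattr(dataset, "initial_state", None)
    weights = {p: (float(np.std(v)) or 1.0) for p, v in obs.items()}

    def residuals(theta):
        pred = _predict(theta, free, fixed, times, dataset.c0, initial)
        res = []
        for pool, vals in obs.items():
            for t, ob in zip(times, vals):
                res.append((pred[t][pool] - ob) / weights[pool])
        return np.asarray(res, dtype=float)

    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                 x_scale=np.maximum(x0, 1e-12),
                                 ftol=1e-12, xtol=1e-12, gtol=1e-12)
    rss = float(2.0 * sol.cost)

    J = sol.jac
    sv = np.linalg.svd(J, compute_uv=False)
    identifiable = bool(sv.size == len(free) and sv[-1] > 0
                        and sv[0] / sv[-1] < cond_threshold)
    message = sol.message if identifiable else (
        "sensitivity matrix is rank-deficient or ill-conditioned; "
        "parameters " + ",".join(free) + " are not jointly identifiable "
        "from the observed pools")

    ci = {}
    dof = max(n_obs - len(free), 1)
    try:
        cov = np.linalg.inv(J.T @ J) * rss / dof
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(len(free), np.nan)
    for name, est, s_ in zip(free, sol.x, se):
        ci[name] = (max(est - 1.96 * s_, 0.0), est + 1.96 * s_)

    estimates = dict(fixed)
    estimates.update(dict(zip(free, sol.x)))
    return FitResult(estimates={n: float(estimates[n]) for n in PARAM_NAMES},
                     rss=rss, conf_intervals=ci, success=bool(sol.success),
                     identifiable=identifiable, message=message)


def tune_k13(field_obs: StationSeries, runner, bracket=(1e-10, 1e-7)):
    """Tune the mature-forest uptake rate against observed plant concentrations.

    ``runner`` maps a candidate ``k13`` to the simulated plant series at the
    observation times (array or StationSeries).  Returns ``(k13_hat,
    achieved_rmse)`` from bounded scalar minimization of the RMSE; if the
    objective is monotone over the bracket the boundary minimizer is
    returned.
    """
    lo, hi = bracket
    if not (0 <= lo < hi):
        raise ValueError("bracket must satisfy 0 <= lo < hi")

    def objective(k13):
        sim = runner(k13)
        return rmse(field_obs, sim)

    sol = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                   options={"xatol": (hi - lo) * 1e-8})
    k_hat, f_hat = float(sol.x), float(sol.fun)
    # a monotone objective leaves the true optimum at a bracket edge
    for edge in (lo, hi):
        fe = objective(edge)
        if fe < f_hat:
            k_hat, f_hat = edge, fe
    return k_hat, f_hat
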
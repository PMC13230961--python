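"""Delayed dynamical model of cancer stem cells under radioimmunotherapy.

Four coupled populations evolve in years: cancer stem cells S, differentiated
cancer cells D, Wnt-beta-catenin pathway proteins a, and microRNAs m:

    dS/dt = (2 p(D,a) - 1) eps S + q(m(t-tau)) D(t-tau) - upsilon R_imm S
    dD/dt = 2 (1 - p(D,a)) eps S - (d + q(m)) D      - theta  R_imm D
    da/dt = a (beta S a/(1+a) - alpha)
    dm/dt = gamma exp(-S/S0) - alpha m

p(D,a) = eta a / ((1+eta a)(1+psi D)) is the probability that a stem-cell
division is symmetric self-renewal (Wnt-driven, braked by crowding with D);
q(m) = (q0/2)(1 + tanh((m-m0)/sigma)) is the microRNA-activated
dedifferentiation rate of D back to S, acting after a conversion delay tau.
Radioimmunotherapy enters as the dimensionless coupling R_imm (computed by
:mod:`cscrit.radiobiology`), switched on at a therapy start time.

The integrator is fixed-step classical RK4 with cubic-Hermite dense output;
delayed values are read from the dense interpolant (method of steps), or
from the history function before the start time.  Note the deliberate
asymmetry of the printed system: the delayed dedifferentiation source feeds
dS/dt while dD/dt uses the instantaneous q(m).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import radiobiology as rb
from .radionuclides import RadionuclidePhysics
from .units import dose_rate_to_per_day

__all__ = [
    "ModelParams",
    "TherapySchedule",
    "Trajectory",
    "IntegrationError",
    "symmetric_division_probability",
    "dedifferentiation_rate",
    "dde_rhs",
    "integrate_dde",
    "default_initial_state",
    "equilibria",
    "eradication_time",
    "percent_reduction",
]

STATE_LABELS = ("S", "D", "a", "m")


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelParams:
    """Rates and scales of the cell-population model (time unit: years).

    Defaults are the standard prostate-cancer parameterization used by the
    package's reference scenarios; d is a death rate in 36.5-109.5 /y and
    q0 must exceed d for the mixed equilibrium to be meaningful.
    """

    eta: float = 1.0  # Wnt feedback strength [mm^3/molecule]
    psi: float = 0.5  # DC brake intensity [mm^3/cell]
    epsilon: float = 1.0  # CSC mitotic rate [1/year]
    q0: float = 40.0  # max dedifferentiation rate [1/year]
    tau: float = 8.8964  # DC->CSC conversion delay [year]
    m0: float = 0.05  # minimal microRNA concentration [molecule/mm^3]
    sigma: float = 0.05  # microRNA sensitivity [molecule/mm^3]
    upsilon: float = 25.0  # CSC radio-kill rate [1/year]
    d: float = 36.5  # DC death rate [1/year]
    theta: float = 50.0  # DC radio-kill rate [1/year]
    alpha: float = 0.3  # protein/molecule degradation rate
    beta: float = 1.0  # Wnt self-renewal aggressiveness [mm^3/(cell*year)]
    gamma: float = 1.0  # max microRNA production [molecule/(mm^3*year)]
    S0: float = 0.038  # minimal CSC concentration [cell/mm^3]

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma == 0:
            raise ValueError("sigma must be positive")
        if self.S0 == 0:
            raise ValueError("S0 must be positive")
        if self.q0 <= self.d:
            warnings.warn(
                f"q0={self.q0} should exceed d={self.d} for the mixed "
                "equilibrium to exist",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TherapySchedule:
    """Radioimmunotherapy coupling for the dynamical model.

    ``R_imm`` is the time-constant multiplier of the radio-kill terms,
    switched on at ``t_start`` (years).  ``time_resolved=True`` replaces the
    constant with alpha_c * r(t - t_start) * RE, an alternative reading in
    which the kill follows the instantaneous dose rate.
    """

    radionuclide: str
    r0: float  # stored in Gy/day
    t_start: float  # [year]
    R_imm: float
    time_resolved: bool = False
    _sched: rb.DoseSchedule | None = None
    _lq: rb.LQParams | None = None
    days_per_year: float = 365.0

    def __post_init__(self) -> None:
        if self.t_start < 0:
            raise ValueError("t_start must be non-negative")
        if self.R_imm < 0:
            raise ValueError("R_imm must be non-negative")
        if (self.R_imm == 0) != (self.r0 == 0):
            raise ValueError("R_imm must vanish exactly when r0 does")

    @classmethod
    def build(
        cls,
        radionuclide: str,
        r0: float,
        unit: str = "Gy/year",
        t_start: float = 8.8964,
        lq: rb.LQParams = rb.LQParams(),
        oer_value: float = 1.0,
        registry: dict[str, RadionuclidePhysics] | None = None,
        time_resolved: bool = False,
        days_per_year: float = 365.0,
    ) -> "TherapySchedule":
        """Compute R_imm from the radiobiology stack and wrap it as a schedule."""
        r0_day = dose_rate_to_per_day(r0, unit, days_per_year)
        sched = rb.DoseSchedule.for_radionuclide(radionuclide, r0_day, "Gy/day", registry)
        R = rb.rit_rate(sched, lq, oer_value) if r0_day > 0 else 0.0
        return cls(
            radionuclide=radionuclide,
            r0=r0_day,
            t_start=t_start,
            R_imm=R,
            time_resolved=time_resolved,
            _sched=sched,
            _lq=lq,
            days_per_year=days_per_year,
        )

    def coupling(self, t_year: float) -> float:
        """Kill-term multiplier at time t (years)."""
        if t_year < self.t_start - 1e-12 or self.R_imm == 0.0:
            return 0.0
        if not self.time_resolved:
            return self.R_imm
        t_day = (t_year - self.t_start) * self.days_per_year
        re = rb.relative_effectiveness(self._sched, self._lq)
        return self._lq.alpha_c * rb.dose_rate(t_day, self._sched) * re


NO_THERAPY = TherapySchedule(radionuclide="none", r0=0.0, t_start=0.0, R_imm=0.0)


def symmetric_division_probability(D: float, a: float, eta: float, psi: float) -> float:
    """Probability p(D,a) in [0,1) that a CSC division yields two CSCs."""
    if D < 0 or a < 0:
        raise ValueError("D and a must be non-negative")
    return eta * a / ((1.0 + eta * a) * (1.0 + psi * D))


def dedifferentiation_rate(m_delayed: float, q0: float, m0: float, sigma: float) -> float:
    """Dedifferentiation rate q(m) in (0, q0), half-maximal at m = m0."""
    return 0.5 * q0 * (1.0 + math.tanh((m_delayed - m0) / sigma))


def dde_rhs(
    t: float,
    state,
    delayed: tuple[float, float],
    params: ModelParams,
    therapy: TherapySchedule = NO_THERAPY,
) -> np.ndarray:
    """Right-hand side of the delayed system at one time point.

    ``delayed`` carries (D(t - tau), m(t - tau)).  The therapy coupling is
    zero before the start time.
    """
    S, D, a, m = state
    if min(S, D, a, m) < 0 or min(delayed) < 0:
        raise ValueError("state and delayed values must be non-negative")
    D_del, m_del = delayed
    p = symmetric_division_probability(D, a, params.eta, params.psi)
    q_del = dedifferentiation_rate(m_del, params.q0, params.m0, params.sigma)
    q_now = dedifferentiation_rate(m, params.q0, params.m0, params.sigma)
    R = therapy.coupling(t)
    dS = (2.0 * p - 1.0) * params.epsilon * S + q_del * D_del - params.upsilon * R * S
    dD = 2.0 * (1.0 - p) * params.epsilon * S - (params.d + q_now) * D - params.theta * R * D
    da = a * (params.beta * S * a / (1.0 + a) - params.alpha)
    dm = params.gamma * math.exp(-S / params.S0) - params.alpha * m
    return np.array([dS, dD, da, dm])


def default_initial_state(params: ModelParams) -> np.ndarray:
    """Default initial state (S, D, a, m) for the therapy scenarios.

    A pre-recurrence tumor near the Wnt-inactive branch: S at its minimal
    concentration S0, D at the matching turnover level S0/d, a residual Wnt
    signal, and a sub-threshold microRNA level (m < m0) so the
    dedifferentiation machinery is still ramping up when therapy begins.
    """
    return np.array([params.S0, params.S0 / params.d, 0.01, 0.01])


@dataclass
class Trajectory:
    """Dense RK4 solution: node times/states/derivatives plus metadata."""

    times: np.ndarray  # [year], strictly increasing
    states: np.ndarray  # shape (n, 4), columns S, D, a, m
    derivs: np.ndarray  # RHS at the nodes, for Hermite interpolation
    params: ModelParams
    therapy: TherapySchedule
    dt: float
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.states[:, STATE_LABELS.index(label)]

    def interpolate(self, t: float) -> np.ndarray:
        """Cubic-Hermite value of the state at any time within range."""
        ts = self.times
        if t < ts[0] - 1e-12 or t > ts[-1] + 1e-12:
            raise ValueError(f"t={t} outside trajectory range [{ts[0]}, {ts[-1]}]")
        i = min(int((t - ts[0]) / self.dt), len(ts) - 2)
        return _hermite(t, ts[i], self.dt, self.states[i], self.states[i + 1],
                        self.derivs[i], self.derivs[i + 1])

    def at(self, t: float) -> dict[str, float]:
        vals = self.interpolate(t)
        return dict(zip(STATE_LABELS, map(float, vals)))


def _hermite(t, t0, h, y0, y1, f0, f1):
    s = (t - t0) / h
    h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
    h10 = s * (1.0 - s) ** 2
    h01 = s * s * (3.0 - 2.0 * s)
    h11 = s * s * (s - 1.0)
    return h00 * y0 + h10 * h * f0 + h01 * y1 + h11 * h * f1


def integrate_dde(
    params: ModelParams,
    therapy: TherapySchedule = NO_THERAPY,
    history=None,
    t_end: float = 16.0,
    dt: float = 0.01,
    t0: float = 0.0,
) -> Trajectory:
    """Integrate the delayed system with fixed-step RK4 + Hermite dense output.

    ``history`` supplies the state on [t0 - tau, t0]: a constant state
    vector, a callable t -> state, or None for :func:`default_initial_state`.
    With tau = 0 the scheme degrades to a plain RK4 ODE solve.  The therapy
    switch is applied from the first step boundary at or after
    ``therapy.t_start``.
    """
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = params.tau
    if tau > 0 and dt > tau / 2:
        warnings.warn(
            f"dt={dt} does not resolve the delay tau={tau}; results may be inaccurate",
            stacklevel=2,
        )
    if callable(history):
        hist = history
        y_init = np.asarray(hist(t0), dtype=float)
    else:
        y_const = (
            default_initial_state(params)
            if history is None
            else np.asarray(history, dtype=float)
        )
        hist = lambda t: y_const  # noqa: E731
        y_init = y_const.copy()
    if y_init.shape != (4,) or np.any(y_init < 0):
        raise ValueError("history must produce a non-negative state vector of length 4")

    n = int(round((t_end - t0) / dt))
    times = t0 + dt * np.arange(n + 1)
    states = np.empty((n + 1, 4))
    derivs = np.empty((n + 1, 4))
    states[0] = y_init

    # therapy switched on at the first step boundary >= t_start
    if therapy.R_imm > 0 and therapy.t_start > t0:
        k_on = math.ceil((therapy.t_start - t0) / dt - 1e-9)
        t_on = t0 + k_on * dt
        therapy_eff = replace(therapy, t_start=t_on)
    else:
        therapy_eff = therapy

    filled = 0  # index of last completed node

    def delayed_at(tq: float) -> tuple[float, float]:
        if tau == 0.0:
            raise AssertionError("delayed_at must not be called for tau=0")
        if tq <= t0 + 1e-15:
            y = np.asarray(hist(tq), dtype=float)
            return float(y[1]), float(y[3])
        i = min(int((tq - t0) / dt), filled - 1)
        y = _hermite(tq, times[i], dt, states[i], states[i + 1], derivs[i], derivs[i + 1])
        return float(max(y[1], 0.0)), float(max(y[3], 0.0))

    def f(t: float, y: np.ndarray) -> np.ndarray:
        if tau == 0.0:
            del_vals = (max(float(y[1]), 0.0), max(float(y[3]), 0.0))
        else:
            del_vals = delayed_at(t - tau)
        y_clip = np.maximum(y, 0.0)  # guard against RK4 stage round-off
        return dde_rhs(t, y_clip, del_vals, params, therapy_eff)

    derivs[0] = f(times[0], states[0])
    filled = 1
    for i in range(n):
        t, y = times[i], states[i]
        k1 = derivs[i]
        k2 = f(t + dt / 2, y + dt / 2 * k1)
        k3 = f(t + dt / 2, y + dt / 2 * k2)
        k4 = f(t + dt, y + dt * k3)
        y_next = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y_next)):
            raise IntegrationError(f"non-finite state at t={times[i + 1]:.4f}")
        states[i + 1] = y_next
        derivs[i + 1] = f(times[i + 1], y_next)
        filled = i + 2
    return Trajectory(
        times=times,
        states=states,
        derivs=derivs,
        params=params,
        therapy=therapy_eff,
        dt=dt,
        metadata={"t0": t0, "t_end": t_end, "dt": dt, "min_state": float(states.min())},
    )


# ---------------------------------------------------------------------------
# Equilibria of the therapy-free system
# ---------------------------------------------------------------------------

def _wnt_ratio(params: ModelParams) -> float:
    return params.psi * params.alpha / (params.d * params.beta)


def equilibria(params: ModelParams, m1: float = 1.0, m2: float | None = None) -> dict:
    """Closed-form equilibria of the therapy-free system.

    E1 = (0, 0, 0, m1): extinction of both cell populations; the microRNA
    level ``m1`` is arbitrary on this invariant manifold's slow direction.

    E2(m2) = (S2, D2, 0, m2): Wnt-inactive coexistence with
    S2 = -S0*ln(alpha*m2/gamma) and D2 = S2/d.  By default m2 is placed
    where dedifferentiation balances DC turnover, q(m2) = d (requires
    d < q0), which makes the point an exact equilibrium; any other m2 is
    accepted and its residual annotated.

    E3 = (S3, D3, a3, m3): Wnt-active point from the closed-form root a3 of
    the symmetric-division balance 2 p(D3(a), a) = 1, with
    S3 = alpha(1+a3)/(beta a3), D3 = S3/d, m3 = (gamma/alpha) e^{-S3/S0}.
    The closed forms neglect the dedifferentiation inflow q(m3) D3, so two
    residuals are reported: ``residual`` for the defining conditions and
    ``rhs_residual`` for the full vector field.
    """
    out: dict[str, dict] = {}

    # --- E1 -----------------------------------------------------------------
    e1_state = np.array([0.0, 0.0, 0.0, m1])
    dm1 = params.gamma - params.alpha * m1  # dm at extinction; 0 only at m = gamma/alpha
    rhs1 = dde_rhs(0.0, e1_state, (0.0, m1), params)
    out["E1"] = {
        "state": e1_state,
        "residual": float(np.max(np.abs(rhs1[:3]))),  # S, D, a conditions are exact
        "rhs_residual": float(np.max(np.abs(rhs1))),
        "valid": True,
        "note": f"m relaxes toward gamma/alpha={params.gamma / params.alpha:.6g} (dm={dm1:.3g})",
    }

    # --- E2 -----------------------------------------------------------------
    if m2 is None:
        if not params.d < params.q0:
            raise ValueError("default E2 placement q(m2)=d requires d < q0")
        x = 2.0 * params.d / params.q0 - 1.0
        m2 = params.m0 + params.sigma * math.atanh(x)
    e2_valid = 0.0 < m2 < params.gamma / params.alpha
    if e2_valid:
        S2 = -params.S0 * math.log(params.alpha * m2 / params.gamma)
        D2 = S2 / params.d
        e2_state = np.array([S2, D2, 0.0, m2])
        rhs2 = dde_rhs(0.0, e2_state, (D2, m2), params)
        res2 = float(np.max(np.abs(rhs2)))
        note2 = ""
    else:
        e2_state = np.array([math.nan, math.nan, 0.0, m2])
        res2 = math.nan
        note2 = "m2 outside (0, gamma/alpha): S2 <= 0 (invalid)"
    out["E2"] = {
        "state": e2_state,
        "m2": m2,
        "residual": res2,
        "rhs_residual": res2,
        "valid": bool(e2_valid),
        "note": note2,
    }

    # --- E3 -----------------------------------------------------------------
    rho = _wnt_ratio(params)
    note3 = ""
    if rho >= 1:
        note3 = f"psi*alpha/(d*beta)={rho:.4g} >= 1: a3 branch denominator changes sign"
    pref = (1.0 + rho * (1.0 + params.eta)) / (2.0 * params.eta * (1.0 - rho))
    disc = 1.0 + 4.0 * rho * params.eta * (1.0 - rho) / (1.0 + rho * (1.0 + params.eta)) ** 2
    a3 = pref * (1.0 + math.sqrt(disc)) if disc >= 0 else math.nan
    if math.isfinite(a3) and a3 > 0:
        S3 = params.alpha * (1.0 + a3) / (params.beta * a3)
        D3 = S3 / params.d
        m3 = params.gamma / params.alpha * math.exp(-S3 / params.S0)
        e3_state = np.array([S3, D3, a3, m3])
        p3 = symmetric_division_probability(D3, a3, params.eta, params.psi)
        defining = np.array(
            [
                2.0 * p3 - 1.0,  # symmetric-division balance fixing a3
                params.beta * S3 * a3 / (1.0 + a3) - params.alpha,  # da/dt / a
                params.d * D3 - S3,  # DC turnover balance (epsilon = 1 scaling)
                params.gamma * math.exp(-S3 / params.S0) - params.alpha * m3,  # dm/dt
            ]
        )
        res3 = float(np.max(np.abs(defining)))
        rhs3 = float(np.max(np.abs(dde_rhs(0.0, e3_state, (D3, m3), params))))
        valid3 = rho < 1
    else:
        e3_state = np.full(4, math.nan)
        res3 = rhs3 = math.nan
        valid3 = False
    out["E3"] = {
        "state": e3_state,
        "a3": a3,
        "residual": res3,
        "rhs_residual": rhs3,
        "valid": valid3,
        "note": note3,
    }
    return out


# ---------------------------------------------------------------------------
# Trajectory post-processing
# ---------------------------------------------------------------------------

def eradication_time(traj: Trajectory, component: str, threshold: float) -> float | None:
    """First time the component falls below ``threshold`` and stays there.

    None when the component never settles below the threshold by the end of
    the trajectory.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    vals = traj[component]
    below = vals < threshold
    if not below[-1]:
        return None
    # last index where the component is at or above threshold
    above_idx = np.nonzero(~below)[0]
    if above_idx.size == 0:
        return float(traj.times[0])
    first = above_idx[-1] + 1
    return float(traj.times[first]) if first < len(vals) else None


def percent_reduction(c_before: float, c_after: float) -> float:
    """Percent reduction 100*(1 - after/before); full precision retained."""
    if c_before <= 0:
        raise ValueError("c_before must be positive")
    if c_after < 0:
        raise ValueError("c_after must be non-negative")
    return 100.0 * (1.0 - c_after / c_before)
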
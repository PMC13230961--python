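"""2-D oxygen reaction-diffusion field with Michaelis-Menten consumption.

Oxygen partial pressure P_o(x, y, t) on a square tissue domain obeys

    dP_o/dt = -C_max * P_o / (k + P_o) * (S + D) + D_O2 * Laplacian(P_o),

with Dirichlet boundary P_o = P_c on the domain edge (capillary supply) and
a small structured perturbation of the capillary pressure as the initial
condition.  Time is in seconds here — oxygen dynamics are fast compared to
the cell populations, which enter only through their summed concentration
``cell_density``.  Summaries of the field (interior mean, minimum, OER
histograms and the empirical pressure density) feed the surviving-fraction
integration of :mod:`cscrit.radiobiology`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radiobiology import OERParams, oer

__all__ = [
    "OxygenFieldParams",
    "PressureField",
    "initial_pressure_field",
    "consumption",
    "integrate_field",
    "field_summaries",
]


@dataclass(frozen=True)
class OxygenFieldParams:
    """Grid, solver and physiology parameters of the oxygen field.

    Defaults: 20 mm domain at 0.2 mm spacing (101x101 nodes), 0.01 s time
    step, capillary pressure 40 mmHg, and a sparse tumor cell density of
    0.001 cell/mm^3.  The explicit stability number D_O2*dt/dx^2 must stay
    at or below 0.25.
    """

    D_O2: float = 0.002  # oxygen diffusion coefficient [mm^2/s]
    C_max: float = 15.0  # maximum metabolism [mmHg*mm^3/(cell*s)]
    k: float = 2.5  # half-maximum partial pressure [mmHg]
    P_c: float = 40.0  # capillary boundary pressure [mmHg]
    l: float = 20.0  # domain width [mm]
    dx: float = 0.2  # grid spacing [mm]
    dt: float = 0.01  # time step [s]
    cell_density: float = 0.001  # S + D [cell/mm^3]

    def __post_init__(self) -> None:
        for name in ("D_O2", "C_max", "k", "P_c", "l", "dx", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.cell_density < 0:
            raise ValueError("cell_density must be non-negative")
        if self.stability_number > 0.25:
            raise ValueError(
                f"explicit scheme unstable: D_O2*dt/dx^2 = {self.stability_number:.3g} > 0.25"
            )

    @property
    def stability_number(self) -> float:
        return self.D_O2 * self.dt / self.dx**2

    @property
    def n_nodes(self) -> int:
        """Nodes per side, l/dx + 1."""
        return int(round(self.l / self.dx)) + 1

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Centered node coordinates x, y in [-l/2, l/2]."""
        axis = np.linspace(-self.l / 2, self.l / 2, self.n_nodes)
        return np.meshgrid(axis, axis, indexing="xy")


@dataclass
class PressureField:
    """Oxygen pressure grid [mmHg] at one time stamp [s], centered coordinates."""

    P: np.ndarray
    t: float
    params: OxygenFieldParams

    def interior(self) -> np.ndarray:
        return self.P[1:-1, 1:-1]


def initial_pressure_field(
    params: OxygenFieldParams,
    P_initial: float = 40.0,
    reading: str = "additive",
) -> PressureField:
    """Structured initial condition around the capillary pressure.

    The perturbation is a pair of radially symmetric ripples in x^2 + y^2;
    the canonical ``additive`` reading is

        P(x,y,0) = P_initial + 0.1 cos((x^2+y^2-55) pi) - 0.01 sin((x^2+y^2+91) pi),

    bounded within +-0.11 mmHg of P_initial.  The ``nested`` reading places
    the sine ripple inside the cosine argument instead; the two differ by
    at most the ripple amplitude.  The boundary ring is overwritten with
    the Dirichlet value P_c.
    """
    x, y = params.coordinates()
    r2 = x**2 + y**2
    if reading == "additive":
        P = P_initial + 0.1 * np.cos((r2 - 55.0) * np.pi) - 0.01 * np.sin((r2 + 91.0) * np.pi)
    elif reading == "nested":
        P = P_initial + 0.1 * np.cos((r2 - 55.0) * np.pi - 0.01 * np.sin((r2 + 91.0) * np.pi))
    else:
        raise ValueError(f"unknown reading {reading!r}")
    _impose_boundary(P, params.P_c)
    return PressureField(P=P, t=0.0, params=params)


def consumption(P_o, params: OxygenFieldParams, cell_density: float | np.ndarray | None = None):
    """Michaelis-Menten oxygen sink rate [mmHg/s], saturating at C_max*(S+D)."""
    P = np.asarray(P_o, dtype=float)
    if np.any(P < 0):
        raise ValueError("oxygen partial pressure must be non-negative")
    rho = params.cell_density if cell_density is None else cell_density
    val = params.C_max * P / (params.k + P) * rho
    return val if val.ndim else float(val)


def _impose_boundary(P: np.ndarray, P_c: float) -> None:
    P[0, :] = P_c
    P[-1, :] = P_c
    P[:, 0] = P_c
    P[:, -1] = P_c


def _rhs(P: np.ndarray, params: OxygenFieldParams, rho) -> np.ndarray:
    out = np.zeros_like(P)
    lap = (
        P[:-2, 1:-1] + P[2:, 1:-1] + P[1:-1, :-2] + P[1:-1, 2:] - 4.0 * P[1:-1, 1:-1]
    ) / params.dx**2
    inner = P[1:-1, 1:-1]
    rho_in = rho[1:-1, 1:-1] if isinstance(rho, np.ndarray) else rho
    out[1:-1, 1:-1] = (
        -params.C_max * inner / (params.k + inner) * rho_in + params.D_O2 * lap
    )
    return out


def integrate_field(
    params: OxygenFieldParams,
    t_end: float,
    initial: PressureField | None = None,
    snapshot_times=(),
    method: str = "rk4",
    cell_density: float | np.ndarray | None = None,
) -> list[PressureField]:
    """March the field to ``t_end`` [s]; returns snapshots plus the final field.

    Explicit RK4 (default) or forward Euler on the 5-point Laplacian
    semi-discretization, with the Dirichlet ring re-imposed after every
    stage.  Snapshot times are rounded to the step grid.
    """
    if method not in ("rk4", "euler"):
        raise ValueError(f"unknown method {method!r}")
    field0 = initial_pressure_field(params) if initial is None else initial
    rho = params.cell_density if cell_density is None else cell_density
    P = field0.P.copy()
    dt = params.dt
    n = int(round(t_end / dt))
    want = sorted({min(int(round(ts / dt)), n) for ts in snapshot_times} - {n})
    out: list[PressureField] = []

    def stage(Q):
        F = _rhs(Q, params, rho)
        return F

    for step in range(n + 1):
        t = step * dt
        if step in want:
            out.append(PressureField(P=P.copy(), t=t, params=params))
        if step == n:
            break
        if method == "euler":
            P = P + dt * stage(P)
        else:
            k1 = stage(P)
            Q = P + dt / 2 * k1
            _impose_boundary(Q, params.P_c)
            k2 = stage(Q)
            Q = P + dt / 2 * k2
            _impose_boundary(Q, params.P_c)
            k3 = stage(Q)
            Q = P + dt * k3
            _impose_boundary(Q, params.P_c)
            k4 = stage(Q)
            P = P + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        _impose_boundary(P, params.P_c)
        if P.min() < -1e-9:
            raise RuntimeError(f"negative oxygen pressure at t={t + dt:.4f} s")
    out.append(PressureField(P=P, t=n * dt, params=params))
    return out


def field_summaries(
    field: PressureField,
    oer_params: OERParams = OERParams(),
    include_boundary: bool = False,
    bins: int = 30,
) -> dict:
    """Scalar and histogram summaries of a pressure field.

    Returns interior mean and minimum pressure, the per-node OER histogram
    (both orientations: node counts binned by OER, and mean OER binned by
    pressure), and the unit-normalized empirical pressure density
    (pressures, weights) consumed by the surviving-fraction integration.
    """
    P = field.P if include_boundary else field.interior()
    flat = P.ravel()
    oer_vals = oer(flat, oer_params)
    counts, edges = np.histogram(oer_vals, bins=bins, range=(1.0, oer_params.OER_max))
    p_edges = np.histogram_bin_edges(flat, bins=bins)
    p_idx = np.clip(np.digitize(flat, p_edges) - 1, 0, bins - 1)
    oer_by_pressure = np.full(bins, np.nan)
    for b in range(bins):
        sel = p_idx == b
        if sel.any():
            oer_by_pressure[b] = float(np.mean(oer_vals[sel]))
    weights = np.full(flat.size, 1.0 / flat.size)
    return {
        "mean_interior": float(np.mean(P)),
        "min": float(np.min(P)),
        "oer_histogram": {"edges": edges, "counts": counts},
        "pressure_histogram": {"edges": p_edges, "mean_oer": oer_by_pressure},
        "density": {"pressures": flat.copy(), "weights": weights},
    }
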
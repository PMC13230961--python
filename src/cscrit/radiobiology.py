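"""Linear-quadratic radiobiology of protracted radioimmunotherapy.

The tumor dose rate follows the bi-exponential uptake/clearance curve

    r(t) = r0 * (2^(-t/Te) - 2^(-t/Teu)),          t in days,

whose integral is the total dose  D = r0 * tau_e / ln 2.  Protracted
irradiation competing with sublethal-damage repair (repair half-time T_mu)
is folded into a relative effectiveness per unit dose

    RE = 1 + r0 * Lambda / (ln2 * (alpha_c/beta_c) * OER),

with the closed-form protraction factor ``Lambda`` below.  The biologically
effective dose is BED = (D/OER) * RE, optionally reduced by a repopulation
term when treatment outlasts the kick-off time.  Cell kill enters both the
dynamical model (through the dimensionless coupling R_imm = alpha_c * BED)
and the dose-response surface: SF = exp(-R_imm) averaged over an oxygen
partial-pressure density, and the Poisson tumor control probability
TCP = exp(-N * SF) for N clonogens.

All times are in days and dose rates in Gy/day; use
:func:`cscrit.units.dose_rate_to_per_day` on entry for year-based inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radionuclides import EffectiveTimes, RadionuclidePhysics, builtin_registry, effective_times, lookup
from .units import dose_rate_to_per_day

__all__ = [
    "LQParams",
    "RepopulationParams",
    "OERParams",
    "TumorBurden",
    "DoseSchedule",
    "dose_rate",
    "peak_dose_rate",
    "total_dose",
    "protraction_lambda",
    "relative_effectiveness",
    "oer",
    "bed",
    "rit_rate",
    "surviving_fraction_point",
    "surviving_fraction_integrated",
    "tcp",
    "dose_response_table",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic radiosensitivities and repair half-time.

    Defaults are the cancer-stem-cell values used throughout the package:
    alpha_c = 0.46 /Gy, beta_c = 0.30 /Gy^2, T_mu = 0.062 day.
    """

    alpha_c: float = 0.46  # [Gy^-1]
    beta_c: float = 0.30  # [Gy^-2]
    T_mu: float = 0.062  # repair half-time [day]

    def __post_init__(self) -> None:
        if not (self.alpha_c > 0 and self.beta_c > 0 and self.T_mu > 0):
            raise ValueError("alpha_c, beta_c and T_mu must all be positive")

    @property
    def alpha_beta(self) -> float:
        """alpha/beta ratio [Gy]."""
        return self.alpha_c / self.beta_c


@dataclass(frozen=True)
class RepopulationParams:
    """Overall treatment time, repopulation kick-off time and doubling time (days)."""

    T: float
    T_k: float
    T_d: float

    def __post_init__(self) -> None:
        if self.T < 0 or self.T_k < 0 or self.T_d < 0:
            raise ValueError("repopulation times must be non-negative")


@dataclass(frozen=True)
class OERParams:
    """Oxygen-enhancement-ratio saturation curve: maximum ratio and half-effect pressure."""

    OER_max: float = 3.0  # dimensionless
    K_m: float = 3.28  # [mmHg]

    def __post_init__(self) -> None:
        if self.OER_max < 1:
            raise ValueError("OER_max must be >= 1")
        if not self.K_m > 0:
            raise ValueError("K_m must be positive")


@dataclass(frozen=True)
class TumorBurden:
    """Clonogen concentration [cell/mm^3] and tumor volume [mm^3]."""

    varsigma: float
    V: float

    def __post_init__(self) -> None:
        if self.varsigma < 0 or self.V < 0:
            raise ValueError("clonogen concentration and volume must be non-negative")

    @property
    def N(self) -> float:
        """Initial clonogen number N = varsigma * V."""
        return self.varsigma * self.V


@dataclass(frozen=True)
class DoseSchedule:
    """Extrapolated initial dose rate [Gy/day] plus effective half-times."""

    r0: float
    times: EffectiveTimes

    def __post_init__(self) -> None:
        if self.r0 < 0:
            raise ValueError("r0 must be non-negative")

    @classmethod
    def for_radionuclide(
        cls,
        name: str,
        r0: float,
        unit: str = "Gy/day",
        registry: dict[str, RadionuclidePhysics] | None = None,
    ) -> "DoseSchedule":
        """Build a schedule from a registry entry, converting r0 to Gy/day."""
        phys = lookup(name, registry)
        return cls(r0=dose_rate_to_per_day(r0, unit), times=effective_times(phys))


def dose_rate(t, sched: DoseSchedule):
    """Tumor dose rate r(t) [Gy/day] at time(s) t >= 0 [day].

    Zero at t=0 (uptake has not started delivering), rises to a single peak
    and decays to zero; non-negative for all t because Te > Teu.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("dose_rate is defined for t >= 0 only")
    r = sched.r0 * (2.0 ** (-t / sched.times.Te) - 2.0 ** (-t / sched.times.Teu))
    return r if r.ndim else float(r)


def peak_dose_rate(sched: DoseSchedule) -> tuple[float, float]:
    """Closed-form maximizer of the dose-rate curve: (t_peak [day], r_peak [Gy/day]).

    Setting dr/dt = 0 gives t_peak = ln(Te/Teu) / (ln2 * (1/Teu - 1/Te)).
    Returns (0, 0) by convention when r0 = 0.
    """
    if sched.r0 == 0:
        return 0.0, 0.0
    Te, Teu = sched.times.Te, sched.times.Teu
    t_peak = math.log(Te / Teu) / (LN2 * (1.0 / Teu - 1.0 / Te))
    return t_peak, float(dose_rate(t_peak, sched))


def total_dose(sched: DoseSchedule) -> float:
    """Total dose D = r0 * tau_e / ln2 [Gy], the full integral of r(t)."""
    return sched.r0 * sched.times.tau_e / LN2


def protraction_lambda(T_mu: float, times: EffectiveTimes, tol: float = 1e-9) -> float:
    """Closed-form protraction factor Lambda [day].

    Encodes the interplay of bi-exponential dose delivery with first-order
    sublethal-damage repair (repair half-time ``T_mu``); equals, up to the
    r0/(ln2 * alpha/beta) prefactor, the quadratic-damage excess RE - 1 of
    the standard LQ dose-protraction double integral.  Singular when T_mu
    coincides with either effective half-time.
    """
    Te, Teu = times.Te, times.Teu
    if abs(T_mu - Te) < tol or abs(T_mu - Teu) < tol:
        raise ValueError(
            f"T_mu={T_mu} too close to an effective half-time (Te={Te}, Teu={Teu}): "
            "the closed form is singular there"
        )
    term1 = 2.0 * T_mu**4 * (Te - Teu) / ((T_mu**2 - Te**2) * (T_mu**2 - Teu**2))
    term2 = (
        2.0 * Te * Teu * T_mu / (Te**2 - Teu**2)
        * (Te / (T_mu - Te) + Teu / (T_mu - Teu))
    )
    term3 = (
        T_mu / (Te - Teu)
        * (Te**2 / (T_mu - Te) + Teu**2 / (T_mu - Teu))
    )
    return term1 + term2 - term3


def relative_effectiveness(
    sched: DoseSchedule,
    lq: LQParams,
    oer_value: float = 1.0,
    re_convention: str = "alpha_beta",
) -> float:
    """Relative effectiveness per unit dose, RE >= 1.

    The canonical convention divides the protraction term by
    (alpha_c/beta_c) * OER, which carries correct units (Lambda and r0
    combine to Gy, normalized by the alpha/beta dose).  The dimensionally
    bare variant ``re_convention="plain"`` (RE = 1 + r0*Lambda/ln2) is
    exposed for comparison only.
    """
    if oer_value < 1.0:
        raise ValueError("oer_value must be >= 1")
    lam = protraction_lambda(lq.T_mu, sched.times)
    if re_convention == "alpha_beta":
        return 1.0 + sched.r0 * lam / (LN2 * lq.alpha_beta * oer_value)
    if re_convention == "plain":
        return 1.0 + sched.r0 * lam / LN2
    raise ValueError(f"unknown re_convention {re_convention!r}")


def oer(P_o, params: OERParams = OERParams()):
    """Oxygen enhancement ratio at partial pressure(s) P_o [mmHg].

    Saturating form: OER(0) = OER_max (full hypoxic protection), decreasing
    to 1 as P_o -> infinity; half-maximum effect at P_o = K_m.
    """
    P = np.asarray(P_o, dtype=float)
    if np.any(P < 0):
        raise ValueError("oxygen partial pressure must be non-negative")
    val = params.OER_max * (P + params.K_m) / (params.OER_max * P + params.K_m)
    return val if val.ndim else float(val)


def bed(
    sched: DoseSchedule,
    lq: LQParams,
    oer_value: float = 1.0,
    repop: RepopulationParams | None = None,
) -> float:
    """Biologically effective dose [Gy] under hypoxia scaling and optional repopulation.

    BED = (D / OER) * RE(OER), minus ln2*(T - T_k)/(alpha_c*T_d) when a
    repopulation parameter set is given and treatment time exceeds the
    kick-off time.  With ``oer_value=1`` and no repopulation this is the
    plain protracted-irradiation BED = D * RE.
    """
    D_eff = total_dose(sched) / oer_value
    value = D_eff * relative_effectiveness(sched, lq, oer_value)
    if repop is not None and repop.T > repop.T_k:
        if repop.T_d == 0:
            raise ZeroDivisionError("T_d must be positive when repopulation is active")
        value -= LN2 * (repop.T - repop.T_k) / (lq.alpha_c * repop.T_d)
    return value


def rit_rate(sched: DoseSchedule, lq: LQParams, oer_value: float = 1.0) -> float:
    """Dimensionless therapy coupling R_imm = alpha_c * BED (no repopulation).

    This scalar multiplies the radio-kill terms of the cell-population model.
    """
    return lq.alpha_c * bed(sched, lq, oer_value)


def surviving_fraction_point(
    sched: DoseSchedule,
    lq: LQParams,
    P_o: float,
    oer_params: OERParams = OERParams(),
) -> float:
    """Clonogen surviving fraction exp(-alpha_c * BED) at a single oxygen pressure."""
    return math.exp(-rit_rate(sched, lq, oer(P_o, oer_params)))


def surviving_fraction_integrated(
    sched: DoseSchedule,
    lq: LQParams,
    pressures,
    weights,
    oer_params: OERParams = OERParams(),
    tol: float = 1e-6,
) -> float:
    """Surviving fraction averaged over an oxygen-pressure probability density.

    ``pressures`` and ``weights`` give a discrete representation of the
    density f(P_o): probability masses at the listed pressures (an empirical
    field histogram, a quadrature rule, or a single point mass).  Weights
    must sum to 1 within ``tol``.  Collapses to
    :func:`surviving_fraction_point` for a point mass.
    """
    P = np.asarray(pressures, dtype=float)
    w = np.asarray(weights, dtype=float)
    if P.shape != w.shape:
        raise ValueError("pressures and weights must have matching shapes")
    total = float(w.sum())
    if abs(total - 1.0) > tol:
        raise ValueError(f"density weights must sum to 1 (got {total})")
    sf = np.array([surviving_fraction_point(sched, lq, p, oer_params) for p in P.ravel()])
    return float(np.dot(sf, w.ravel()))


def tcp(
    sched: DoseSchedule,
    lq: LQParams,
    burden: TumorBurden,
    P_o: float | None = None,
    pressures=None,
    weights=None,
    oer_params: OERParams = OERParams(),
) -> float:
    """Poisson tumor control probability exp(-N * SF).

    The oxygen setting is either a single pressure ``P_o`` or a discrete
    density (``pressures``, ``weights``); omitting both evaluates the
    oxygen-free limit (OER = 1).
    """
    if P_o is not None:
        sf = surviving_fraction_point(sched, lq, P_o, oer_params)
    elif pressures is not None:
        sf = surviving_fraction_integrated(sched, lq, pressures, weights, oer_params)
    else:
        sf = math.exp(-rit_rate(sched, lq, 1.0))
    return math.exp(-burden.N * sf)


def dose_response_table(
    radionuclides,
    r0_grid,
    lq: LQParams = LQParams(),
    burden: TumorBurden | None = None,
    P_o: float | None = None,
    oer_params: OERParams = OERParams(),
    registry: dict[str, RadionuclidePhysics] | None = None,
    unit: str = "Gy/day",
) -> pd.DataFrame:
    """Long-format dose-response table over radionuclides and an r0 grid.

    Columns: radionuclide, r0_gy_per_day, P_o_mmHg, D_gy, RE, BED_gy, SF,
    TCP.  Every cell is recomputable by the scalar operations above; TCP is
    reported only when a tumor burden is given.
    """
    r0_grid = np.atleast_1d(np.asarray(r0_grid, dtype=float))
    if r0_grid.size == 0:
        raise ValueError("r0 grid must be non-empty")
    reg = builtin_registry() if registry is None else registry
    oer_value = oer(P_o, oer_params) if P_o is not None else 1.0
    rows = []
    for name in radionuclides:
        for r0 in r0_grid:
            sched = DoseSchedule.for_radionuclide(name, r0, unit, reg)
            bed_val = bed(sched, lq, oer_value)
            sf = math.exp(-lq.alpha_c * bed_val)
            rows.append(
                {
                    "radionuclide": name,
                    "r0_gy_per_day": sched.r0,
                    "P_o_mmHg": P_o if P_o is not None else np.nan,
                    "D_gy": total_dose(sched),
                    "RE": relative_effectiveness(sched, lq, oer_value),
                    "BED_gy": bed_val,
                    "SF": sf,
                    "TCP": math.exp(-burden.N * sf) if burden is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def tcp_saturation_dose(
    table: pd.DataFrame, radionuclide: str, threshold: float = 1e-3
) -> float | None:
    """Smallest grid r0 [Gy/day] whose TCP reaches 1 within ``threshold``.

    None when the grid never reaches it.
    """
    sub = table[table["radionuclide"] == radionuclide].sort_values("r0_gy_per_day")
    hit = sub[sub["TCP"] >= 1.0 - threshold]
    return None if hit.empty else float(hit["r0_gy_per_day"].iloc[0])
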
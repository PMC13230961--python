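"""Time-unit bridge between the dynamical model (years) and dosimetry (days).

The cell-population model runs in years while radionuclide kinetics and the
linear-quadratic stack run in days.  Every conversion in the package goes
through this module so that no formula silently mixes the two scales.
"""

from __future__ import annotations

#: Days per year used by the canonical conversion layer.  365.25 selectable
#: by passing ``days_per_year`` explicitly where a function accepts it.
DAYS_PER_YEAR: float = 365.0

HOURS_PER_DAY: float = 24.0


def years_to_days(t_years: float, days_per_year: float = DAYS_PER_YEAR) -> float:
    return t_years * days_per_year


def days_to_years(t_days: float, days_per_year: float = DAYS_PER_YEAR) -> float:
    return t_days / days_per_year


def hours_to_days(t_hours: float) -> float:
    return t_hours / HOURS_PER_DAY


def dose_rate_to_per_day(r0: float, unit: str, days_per_year: float = DAYS_PER_YEAR) -> float:
    """Convert an extrapolated initial dose rate to Gy/day.

    Parameters
    ----------
    r0 : dose rate value.
    unit : ``"Gy/day"`` or ``"Gy/year"`` (case-insensitive; ``gy_per_day`` /
        ``gy_per_year`` accepted).
    """
    u = unit.strip().lower().replace("_per_", "/").replace("·", "/").replace("-1", "")
    if u in ("gy/day", "gy/d", "gy.day"):
        return float(r0)
    if u in ("gy/year", "gy/y", "gy/yr", "gy.year"):
        return float(r0) / days_per_year
    raise ValueError(f"unknown dose-rate unit {unit!r}; expected 'Gy/day' or 'Gy/year'")
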
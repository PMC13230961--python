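"""Radionuclide parameter registry and effective half-time derivation.

Internally administered radionuclides irradiate the tumor with a
bi-exponential dose rate: activity is taken up with a biological uptake
half-time ``Tu`` and cleared with a biological clearance half-time ``Tb``,
both racing against physical decay with half-life ``Tp``.  The harmonic
combinations

    Te  = Tp*Tb / (Tp + Tb)      (effective clearance half-time)
    Teu = Tp*Tu / (Tp + Tu)      (effective uptake half-time)

govern the rising and falling branches of the dose-rate curve; their
difference ``tau_e = Te - Teu`` is the effective irradiation time.  All
times in this module are in days.
"""

from __future__ import annotations

from dataclasses import dataclass

from .units import hours_to_days

__all__ = [
    "RadionuclidePhysics",
    "EffectiveTimes",
    "effective_times",
    "builtin_registry",
]


@dataclass(frozen=True)
class RadionuclidePhysics:
    """Physical and biological half-times of one radionuclide, in days.

    ``Tb > Tu`` is required: clearance slower than uptake is what makes the
    effective clearance half-time exceed the effective uptake half-time, and
    hence the total dose positive.
    """

    name: str
    Tp: float  # physical half-life [day]
    Tb: float  # biological clearance half-time [day]
    Tu: float  # biological uptake half-time [day]

    def __post_init__(self) -> None:
        for field in ("Tp", "Tb", "Tu"):
            value = getattr(self, field)
            if not value > 0:
                raise ValueError(
                    f"{self.name}: {field} must be strictly positive, got {value}"
                )
        if not self.Tb > self.Tu:
            raise ValueError(
                f"{self.name}: biological clearance half-time Tb={self.Tb} must "
                f"exceed uptake half-time Tu={self.Tu} (otherwise Te <= Teu and "
                "the dose-rate curve degenerates)"
            )


@dataclass(frozen=True)
class EffectiveTimes:
    """Effective clearance/uptake half-times (days) with ``Te > Teu > 0``."""

    Te: float
    Teu: float

    def __post_init__(self) -> None:
        if not (self.Te > self.Teu > 0):
            raise ValueError(f"require Te > Teu > 0, got Te={self.Te}, Teu={self.Teu}")

    @property
    def tau_e(self) -> float:
        """Effective irradiation time Te - Teu [day]."""
        return self.Te - self.Teu


def effective_times(phys: RadionuclidePhysics) -> EffectiveTimes:
    """Derive the effective half-times from physical/biological half-times.

    Each effective time is the harmonic combination ``x*y/(x+y)`` of the
    physical half-life with the corresponding biological half-time, so it is
    always below both of its inputs.
    """
    Te = phys.Tp * phys.Tb / (phys.Tp + phys.Tb)
    Teu = phys.Tp * phys.Tu / (phys.Tp + phys.Tu)
    return EffectiveTimes(Te=Te, Teu=Teu)


def builtin_registry() -> dict[str, RadionuclidePhysics]:
    """Default registry of the four radionuclides the package models.

    Nominal half-lives: 64.1 h for 90Y, and the rounded 8 d (131I) and 10 d
    (225Ac) literature values; exact isotope half-lives (8.02 d, 9.92 d) can
    be supplied through a custom ``RadionuclidePhysics``.  Returns a fresh
    dict so callers may override entries freely.
    """
    entries = [
        RadionuclidePhysics("90Y", Tp=hours_to_days(64.1), Tb=8.00, Tu=3.00),
        RadionuclidePhysics("131I", Tp=8.0, Tb=2.50, Tu=1.20),
        RadionuclidePhysics("177Lu", Tp=6.7, Tb=3.50, Tu=1.15),
        RadionuclidePhysics("225Ac", Tp=10.0, Tb=9.50, Tu=3.20),
    ]
    return {p.name: p for p in entries}


def lookup(name: str, registry: dict[str, RadionuclidePhysics] | None = None) -> RadionuclidePhysics:
    """Fetch a radionuclide by name, with a helpful error on unknown keys."""
    reg = builtin_registry() if registry is None else registry
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown radionuclide {name!r}; available: {sorted(reg)}"
        ) from None
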
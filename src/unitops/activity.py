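"""Radioactive decay arithmetic and simulated radiation readings.

Activities are tracked in relative units (the instrument's solid-state
sensors give relative, not absolute, readings). The simulator's activity
ledger stores where the radiolabel resides in amounts referenced to clock
zero; physical decay is applied on read:

    A(t) = A(0) * 2^(-t / t_half)

The F-18 half-life is the standard physical constant 109.77 min.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict

from .errors import NegativeElapsedError, ZeroStartActivityError
from .virtual_hardware import HardwareState


class Isotope(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    half_life_s: float


F18 = Isotope(name="F-18", half_life_s=6586.2)   # 109.77 min

ISOTOPES: dict[str, Isotope] = {"F18": F18, "F-18": F18}


def decay_factor(isotope: Isotope, elapsed_s: float) -> float:
    """Fraction of activity remaining after ``elapsed_s`` seconds, in (0, 1]."""
    if elapsed_s < 0:
        raise NegativeElapsedError(f"elapsed_s={elapsed_s} must be >= 0")
    return 2.0 ** (-elapsed_s / isotope.half_life_s)


def decay_corrected_yield(
    product_activity: float,
    start_activity: float,
    elapsed_s: float,
    isotope: Isotope = F18,
) -> float:
    """Radiochemical yield in percent with physical decay removed.

    ``product_activity`` is measured ``elapsed_s`` seconds after
    ``start_activity``; the correction divides out the decay over that
    interval so the number reflects chemistry alone.
    """
    if start_activity <= 0:
        raise ZeroStartActivityError("start_activity must be > 0")
    return 100.0 * (product_activity / start_activity) / decay_factor(isotope, elapsed_s)


class ActivityLedger(BaseModel):
    """Per-location activity at a reference clock, for one isotope."""

    model_config = ConfigDict(frozen=True)

    isotope: Isotope
    reference_clock_s: float
    amounts: dict[str, float]

    def at(self, clock_s: float) -> dict[str, float]:
        """Decayed per-location activity at ``clock_s`` (>= reference)."""
        f = decay_factor(self.isotope, clock_s - self.reference_clock_s)
        return {loc: a * f for loc, a in self.amounts.items()}

    def total_at(self, clock_s: float) -> float:
        return sum(self.at(clock_s).values())


def ledger_from_state(state: HardwareState, isotope: Isotope = F18) -> ActivityLedger:
    """The simulator stores label amounts referenced to clock zero."""
    return ActivityLedger(
        isotope=isotope, reference_clock_s=0.0, amounts=dict(state.activity)
    )


def sensor_readings(
    state: HardwareState,
    ledger: ActivityLedger | None = None,
    clock_s: float | None = None,
) -> dict[int, float]:
    """Relative per-reactor radiation readings at the (simulated) moment.

    Decayed activity is apportioned by where the labeled material currently
    resides; reactors without label read zero.
    """
    ledger = ledger if ledger is not None else ledger_from_state(state)
    clock = state.clock_s if clock_s is None else clock_s
    decayed = ledger.at(clock)
    return {r: decayed.get(f"reactor{r}", 0.0) for r in state.reactors}
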
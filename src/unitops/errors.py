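"""Exception hierarchy for unitops.

Errors that a validator is expected to *report* (bad parameter ranges,
unresolved reagent names) are returned as ``ValidationIssue`` records, not
raised; the exceptions here cover contract violations: malformed files,
illegal edits, unsafe hardware streams, and misuse of the run engine.
"""

from __future__ import annotations


class UnitOpsError(Exception):
    """Base class for all unitops errors."""


# --- program model -----------------------------------------------------------

class LayoutError(UnitOpsError):
    """Invalid reagent/cassette layout operation (slot occupied, duplicate
    name, out-of-range slot, volume over vial capacity)."""

    def __init__(self, code: str, message: str) -> None:
        super().__init__(message)
        self.code = code


class UnknownReagentError(UnitOpsError):
    """A reagent name does not resolve against the layout."""


class EditIndexError(UnitOpsError, IndexError):
    """A program edit addressed an out-of-range operation index."""


class ProgramParseError(UnitOpsError):
    """Malformed program file; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str) -> None:
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class SchemaViolation(UnitOpsError):
    """Structurally valid file whose content violates the program schema
    (e.g. an unknown unit-operation kind); carries the 1-based op index."""

    def __init__(self, op_index: int, message: str) -> None:
        super().__init__(f"op {op_index}: {message}")
        self.op_index = op_index


# --- compiler ----------------------------------------------------------------

class CompileError(UnitOpsError):
    """Expansion failure. ``code`` is ``missing-template`` or
    ``context-inconsistent``; ``op_index`` is 1-based (0 if unknown)."""

    def __init__(self, code: str, message: str, op_index: int = 0) -> None:
        super().__init__(message)
        self.code = code
        self.op_index = op_index


# --- virtual hardware --------------------------------------------------------

class HardwareError(UnitOpsError):
    """Base for simulated-hardware faults."""


class IllegalTransition(HardwareError):
    """A low-level op violated a safety-ordering rule (R1–R4)."""

    def __init__(self, rule_id: str, message: str) -> None:
        super().__init__(f"{rule_id}: {message}")
        self.rule_id = rule_id


class VesselOverflow(HardwareError):
    """Liquid routed into a vessel beyond its capacity."""


class EmptySlotError(HardwareError):
    """PICK_VIAL addressed a cassette slot with no vial installed."""


class SimulationError(UnitOpsError):
    """Wraps a hardware error with the position of the failing low-level op
    and the partial trace/state accumulated up to that point."""

    def __init__(self, index: int, cause: Exception, state, trace) -> None:
        super().__init__(f"low-level op {index}: {cause}")
        self.index = index
        self.cause = cause
        self.state = state
        self.trace = trace


# --- run engine --------------------------------------------------------------

class RunError(UnitOpsError):
    """Run-engine misuse; ``code`` identifies the condition
    (validation-failed, not-awaiting-prompt, no-timed-phase-active,
    record-missing, record-terminal, run-not-terminal, run-terminal)."""

    def __init__(self, code: str, message: str) -> None:
        super().__init__(message)
        self.code = code


# --- activity ----------------------------------------------------------------

class NegativeElapsedError(UnitOpsError, ValueError):
    """Decay queried for a negative elapsed time."""


class ZeroStartActivityError(UnitOpsError, ZeroDivisionError):
    """Yield computation with zero starting activity."""
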
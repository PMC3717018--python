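"""Compilation of unit operations into low-level hardware operations.

Each unit operation expands into an ordered stream of atomic instrument
actions — reactor motions, seal raises, gripper moves, valve switches,
pressure/temperature set-points, timed waits — following per-kind templates
loaded from a shipped, versioned YAML document (:data:`DEFAULT_TABLE_PATH`).
The templates are *data*: the granularity of the reconstruction (settle
waits, per-stopcock valve switching, the initialization routine) can be
revised without touching code.

The module also provides the static safety checker. Four ordering rules are
enforced over any stream:

R1  no gripper motion while a pressurized line is open to an unsealed vessel
R2  a line may only be pressurized when a vessel is sealed at its station
    (supply lines with no vessel on the path, e.g. the trap push, are exempt)
R3  a reactor never moves while its seal is raised
R4  vial accounting: a picked vial is returned before the next pick

``check_safety`` must return no violations for any output of
``compile_program`` — the virtual hardware enforces the identical rules at
execution time through the same :class:`SafetyTracker`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

import yaml

from .errors import CompileError, UnknownReagentError
from .program_model import (
    CassetteLayout,
    SynthesisProgram,
    UnitOp,
    apply_defaults,
)

# The five gasket sealing stations plus the off-gasket service position.
GASKET_STATIONS: tuple[str, ...] = ("ADD", "EVAPORATE", "TRANSFER", "REACT_A", "REACT_B")
INSTALL_STATION = "INSTALL"
STATIONS: tuple[str, ...] = GASKET_STATIONS + (INSTALL_STATION,)

#: Pressurizable supply lines; R2 requires a sealed vessel at the mapped
#: station. The trap line pushes through the QMA cartridge to waste and has
#: no vessel on its path.
LINE_STATION: dict[str, str] = {
    "add": "ADD",
    "evaporate": "EVAPORATE",
    "transfer": "TRANSFER",
}
LINES: tuple[str, ...] = ("add", "evaporate", "transfer", "trap")


@dataclass
class LowLevelOp:
    """One atomic hardware action.

    ``origin`` is the 1-based index of the source unit operation (0 for
    hand-built streams); ``phase`` tags the user-adjustable dwell waits.
    """

    verb: str
    args: dict[str, Any] = field(default_factory=dict)
    origin: int = 0
    phase: Optional[str] = None

    def render(self) -> str:
        pairs = " ".join(f"{k}={self.args[k]}" for k in self.args)
        return f"{self.verb}{(' ' + pairs) if pairs else ''}"


@dataclass(frozen=True)
class CompiledProgram:
    llops: tuple[LowLevelOp, ...]
    source: str

    @property
    def n_llops(self) -> int:
        return len(self.llops)

    def by_origin(self) -> dict[int, list[LowLevelOp]]:
        groups: dict[int, list[LowLevelOp]] = {}
        for llop in self.llops:
            groups.setdefault(llop.origin, []).append(llop)
        return groups

    def render(self) -> str:
        return "\n".join(
            f"{llop.origin}\t{llop.render()}" for llop in self.llops
        ) + ("\n" if self.llops else "")


@dataclass(frozen=True)
class SafetyViolation:
    llop_index: int      # 0-based position in the stream
    rule_id: str
    message: str


# --- expansion table ---------------------------------------------------------

DEFAULT_TABLE_PATH = importlib.resources.files("unitops.data") / "expansion_table.yaml"


class ExpansionTable:
    """Per-kind templates mapping a bound unit op to a LowLevelOp sequence."""

    def __init__(self, doc: dict[str, Any]) -> None:
        self.version: str = str(doc.get("version", "unversioned"))
        self.settle_s: float = float(doc.get("settle_s", 2.0))
        self.ambient_C: float = float(doc.get("ambient_C", 25.0))
        self.hplc_pressure_psi: float = float(doc.get("hplc_pressure_psi", 10.0))
        self.hplc_duration_s: float = float(doc.get("hplc_duration_s", 30.0))
        self.measure_s: float = float(doc.get("measure_s", 2.0))
        self.kinds: dict[str, list[dict[str, Any]]] = doc["kinds"]

    @classmethod
    def load(cls, path=None) -> "ExpansionTable":
        source = DEFAULT_TABLE_PATH if path is None else path
        with open(str(source), "r", encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))


_DEFAULT_TABLE: ExpansionTable | None = None


def default_table() -> ExpansionTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ExpansionTable.load()
    return _DEFAULT_TABLE


def _build_context(op: UnitOp, table: ExpansionTable, layout: CassetteLayout,
                   op_index: int) -> dict[str, Any]:
    """Bind op parameters plus derived routing facts for the template."""
    ctx: dict[str, Any] = dict(op.model_dump())
    ctx["settle"] = table.settle_s
    ctx["ambient"] = table.ambient_C

    def slot(name_field: str) -> None:
        name = getattr(op, name_field)
        try:
            spec = layout.by_name(name)
        except UnknownReagentError as exc:
            raise CompileError("context-inconsistent", str(exc), op_index) from exc
        ctx["cassette"] = spec.cassette_id
        ctx["position"] = spec.position

    if op.kind == "ADD":
        slot("reagent_name")
        ctx["needle"] = f"needle{op.delivery_position}"
        ctx["vent_valve"] = f"add.vent{op.delivery_position}"
    elif op.kind == "ELUTEF18":
        slot("reagent_name")
    elif op.kind == "EXTERNALADD":
        slot("reagent_name")
    elif op.kind == "REACT":
        ctx["station"] = "REACT_A" if op.reaction_position == 1 else "REACT_B"
    elif op.kind == "TRANSFER":
        if op.mode == "Trap":
            ctx["route_valve"] = "route.waste"
        elif op.target_reactor == op.source_reactor:
            ctx["route_valve"] = "route.collect"
        else:
            ctx["route_valve"] = f"route.r{op.target_reactor}"
        ctx["gas_push"] = True
    elif op.kind == "TRAPF18":
        ctx["gas_push"] = not op.cyclotron_flag
    elif op.kind == "TRANSFERTOHPLC":
        ctx["pressure_psi"] = table.hplc_pressure_psi
        ctx["duration_s"] = table.hplc_duration_s
    elif op.kind == "MEASURERADIATION":
        ctx["measure_s"] = table.measure_s
    return ctx


def _resolve(value: Any, ctx: dict[str, Any], op_index: int) -> Any:
    if isinstance(value, str):
        if value.startswith("$"):
            key = value[1:]
            if key not in ctx:
                raise CompileError(
                    "context-inconsistent",
                    f"template placeholder ${key} unbound", op_index,
                )
            return ctx[key]
        if "{" in value:
            return value.format(**ctx)
    return value


def _condition(expr: str, ctx: dict[str, Any]) -> bool:
    expr = expr.strip()
    if expr.startswith("not "):
        return not bool(ctx.get(expr[4:].strip()))
    return bool(ctx.get(expr))


def expand_unit_op(
    op: UnitOp,
    table: ExpansionTable | None = None,
    layout: CassetteLayout | None = None,
    origin: int = 0,
) -> list[LowLevelOp]:
    """Expand one unit operation into its low-level stream.

    Deterministic in (op, table, layout). Raises :class:`CompileError` with
    code ``missing-template`` for a kind absent from the table and
    ``context-inconsistent`` for unresolvable reagent references or unbound
    template placeholders.
    """
    table = table or default_table()
    layout = layout if layout is not None else CassetteLayout()
    normalized = apply_defaults(op)
    if normalized.kind not in table.kinds:
        raise CompileError(
            "missing-template", f"no expansion template for {normalized.kind}", origin
        )
    ctx = _build_context(normalized, table, layout, origin)
    out: list[LowLevelOp] = []
    for step in table.kinds[normalized.kind]:
        if "when" in step and not _condition(step["when"], ctx):
            continue
        args = {
            k: _resolve(v, ctx, origin)
            for k, v in step.items()
            if k not in ("verb", "when", "phase")
        }
        out.append(
            LowLevelOp(
                verb=step["verb"], args=args, origin=origin,
                phase=step.get("phase"),
            )
        )
    return out


def compile_program(
    program: SynthesisProgram, table: ExpansionTable | None = None
) -> CompiledProgram:
    """Expand every unit op in order; origin indices are 1-based and
    non-decreasing, so partitioning by origin recovers per-op expansions."""
    table = table or default_table()
    llops: list[LowLevelOp] = []
    for i, op in enumerate(program.ops, start=1):
        llops.extend(expand_unit_op(op, table, program.layout, origin=i))
    return CompiledProgram(llops=tuple(llops), source=program.name)


# --- safety checking ---------------------------------------------------------

class SafetyTracker:
    """Incremental stream-state machine behind both the static checker and
    the virtual hardware's execution-time interlocks."""

    def __init__(self) -> None:
        self.sealed: dict[int, bool] = {1: False, 2: False, 3: False}
        self.station: dict[int, str] = {r: INSTALL_STATION for r in (1, 2, 3)}
        self.vial_out: bool = False
        self.line_psi: dict[str, float] = {line: 0.0 for line in LINES}

    def _sealed_at(self, station: str) -> bool:
        return any(
            self.sealed[r] and self.station[r] == station for r in self.sealed
        )

    def inspect(self, llop: LowLevelOp) -> Optional[SafetyViolation]:
        """Return the rule violated by applying ``llop`` next, if any."""
        verb, args = llop.verb, llop.args
        if verb == "MOVE_REACTOR":
            r = int(args["reactor"])
            if self.sealed.get(r):
                return SafetyViolation(
                    -1, "R3", f"reactor {r} moved while its seal is raised"
                )
        elif verb == "GRIPPER_MOVE":
            for line, psi in self.line_psi.items():
                station = LINE_STATION.get(line)
                if psi > 0 and station is not None and not self._sealed_at(station):
                    return SafetyViolation(
                        -1, "R1",
                        f"gripper moved while {line} line at {psi} psi is open "
                        f"to an unsealed vessel",
                    )
        elif verb == "SET_PRESSURE":
            line = str(args["line"])
            psi = float(args["psi"])
            station = LINE_STATION.get(line)
            if psi > 0 and station is not None and not self._sealed_at(station):
                return SafetyViolation(
                    -1, "R2",
                    f"{line} line pressurized to {psi} psi with no vessel "
                    f"sealed at {station}",
                )
        elif verb == "PICK_VIAL":
            if self.vial_out:
                return SafetyViolation(
                    -1, "R4", "vial picked while a previous vial is not returned"
                )
        elif verb == "RETURN_VIAL":
            if not self.vial_out:
                return SafetyViolation(-1, "R4", "no vial out to return")
        return None

    def update(self, llop: LowLevelOp) -> None:
        verb, args = llop.verb, llop.args
        if verb == "MOVE_REACTOR":
            self.station[int(args["reactor"])] = str(args["station"])
        elif verb == "RAISE_SEAL":
            self.sealed[int(args["reactor"])] = True
        elif verb == "LOWER_VESSEL":
            self.sealed[int(args["reactor"])] = False
        elif verb == "PICK_VIAL":
            self.vial_out = True
        elif verb == "RETURN_VIAL":
            self.vial_out = False
        elif verb == "SET_PRESSURE":
            self.line_psi[str(args["line"])] = float(args["psi"])


def check_stream(llops: Iterable[LowLevelOp]) -> list[SafetyViolation]:
    """Run the R1–R4 rules over a raw stream, collecting all violations."""
    tracker = SafetyTracker()
    violations: list[SafetyViolation] = []
    for i, llop in enumerate(llops):
        v = tracker.inspect(llop)
        if v is not None:
            violations.append(SafetyViolation(i, v.rule_id, v.message))
        tracker.update(llop)
    return violations


def check_safety(compiled: CompiledProgram) -> list[SafetyViolation]:
    return check_stream(compiled.llops)
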
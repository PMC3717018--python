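"""Synthesis programs as typed data.

A synthesis program is a reagent/cassette layout plus an ordered list of
high-level unit operations (ADD, REACT, EVAPORATE, ...). This module defines
the operation types with their chemist-facing parameters and defaults,
validation (range checks, reagent-name resolution), list-style editing,
program metrics, and a line-oriented plain-text file format.

Conventions
-----------
* Cassettes, vial slots, reactors, needles, reaction positions and unit-op
  indices are all 1-based, matching how protocols are written down.
* Required parameters (the ones a chemist must choose) have no default and
  must be supplied at construction; secondary parameters (driving pressure,
  delivery time, stir speed, ...) may be left unset and are filled by
  :func:`apply_defaults` — explicitly set values are never overwritten.
* Range violations are *reported* by :func:`validate_program` as
  :class:`ValidationIssue` records, never raised at construction, so that a
  partially wrong program can be loaded, inspected and fixed.
"""

from __future__ import annotations

import shlex
from collections import Counter
from typing import Annotated, Any, Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, TypeAdapter

from .errors import (
    EditIndexError,
    LayoutError,
    ProgramParseError,
    SchemaViolation,
    UnknownReagentError,
)

# --- instrument geometry and permitted parameter ranges ----------------------

N_CASSETTES = 3
SLOTS_PER_CASSETTE = 11          # 3 x 11 = 33 stored reagent vials
VIAL_CAPACITY_ML = 3.0           # sealed vial liquid capacity

#: Permitted parameter ranges, config-table driven (the instrument's printed
#: working points — e.g. sealed reactions in acetonitrile at 180 °C — sit
#: well inside them).
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "temp_C": (-20.0, 200.0),
    "pressure_psi": (0.0, 60.0),
    "duration_s": (0.0, float("inf")),
    "stir_speed": (0.0, 100.0),
}

#: Secondary-parameter defaults per unit-op kind (field -> value).
DEFAULTS: dict[str, dict[str, Any]] = {
    "ADD": {"pressure_psi": 3.0, "duration_s": 15.0},
    "TRANSFER": {"pressure_psi": 10.0, "duration_s": 30.0},
    "EVAPORATE": {"final_temp_C": 35.0, "stir_speed": 0.0},
    "REACT": {"stir_speed": 0.0, "cool_delay_s": 0.0},
    "TRAPF18": {"pressure_psi": 3.0},
    "ELUTEF18": {"pressure_psi": 3.0},
}


# --- reagents and cassette layout --------------------------------------------

class ReagentSpec(BaseModel):
    """One reagent vial: where it is stored and what is in it."""

    model_config = ConfigDict(frozen=True)

    cassette_id: int
    position: int
    name: str
    description: str = ""
    volume_mL: float


class CassetteLayout(BaseModel):
    """Reagent-to-slot mapping over the three disposable cassettes."""

    model_config = ConfigDict(frozen=True)

    reagents: tuple[ReagentSpec, ...] = ()
    n_cassettes: int = N_CASSETTES
    slots_per_cassette: int = SLOTS_PER_CASSETTE

    @property
    def n_positions(self) -> int:
        return self.n_cassettes * self.slots_per_cassette

    def by_name(self, name: str) -> ReagentSpec:
        for r in self.reagents:
            if r.name == name:
                return r
        raise UnknownReagentError(f"no reagent named {name!r} in layout")

    def names(self) -> set[str]:
        return {r.name for r in self.reagents}


def define_reagent(
    layout: CassetteLayout,
    cassette_id: int,
    position: int,
    name: str,
    description: str = "",
    volume_mL: float = 1.0,
) -> CassetteLayout:
    """Return a new layout with one more reagent vial defined.

    Raises :class:`LayoutError` with a machine-readable ``code`` on an
    out-of-range slot, an occupied slot, a duplicate name, or a volume
    exceeding the vial capacity. The input layout is never modified.
    """
    if not name:
        raise LayoutError("empty-name", "reagent name must be non-empty")
    if not (1 <= cassette_id <= layout.n_cassettes):
        raise LayoutError(
            "out-of-range-slot",
            f"cassette_id {cassette_id} outside 1..{layout.n_cassettes}",
        )
    if not (1 <= position <= layout.slots_per_cassette):
        raise LayoutError(
            "out-of-range-slot",
            f"position {position} outside 1..{layout.slots_per_cassette}",
        )
    if not (0.0 < volume_mL <= VIAL_CAPACITY_ML):
        raise LayoutError(
            "volume-over-capacity",
            f"volume {volume_mL} mL outside (0, {VIAL_CAPACITY_ML}] mL",
        )
    for r in layout.reagents:
        if (r.cassette_id, r.position) == (cassette_id, position):
            raise LayoutError(
                "slot-occupied",
                f"slot ({cassette_id}, {position}) already holds {r.name!r}",
            )
        if r.name == name:
            raise LayoutError("duplicate-name", f"reagent {name!r} already defined")
    new = ReagentSpec(
        cassette_id=cassette_id,
        position=position,
        name=name,
        description=description,
        volume_mL=volume_mL,
    )
    return layout.model_copy(update={"reagents": layout.reagents + (new,)})


def resolve_reagent(
    program_or_layout: "SynthesisProgram | CassetteLayout", reagent_name: str
) -> tuple[int, int]:
    """Return the ``(cassette_id, position)`` storage slot for a reagent name."""
    layout = (
        program_or_layout.layout
        if isinstance(program_or_layout, SynthesisProgram)
        else program_or_layout
    )
    r = layout.by_name(reagent_name)
    return (r.cassette_id, r.position)


# --- unit operations ---------------------------------------------------------

class _OpBase(BaseModel):
    model_config = ConfigDict(frozen=True)

    note: str = ""


class InitializeOp(_OpBase):
    """Home robots, close valves, park reactors: no parameters."""

    kind: Literal["INITIALIZE"] = "INITIALIZE"


class AddOp(_OpBase):
    """Deliver a stored reagent vial to a reaction vessel."""

    kind: Literal["ADD"] = "ADD"
    reagent_name: str
    reactor: int
    delivery_position: int   # 1 or 2: the two addition needles
    pressure_psi: Optional[float] = None
    duration_s: Optional[float] = None


class EvaporateOp(_OpBase):
    """Evaporate vessel contents under inert-gas flow and vacuum."""

    kind: Literal["EVAPORATE"] = "EVAPORATE"
    reactor: int
    evaporation_temp_C: float
    evaporation_pressure_psi: float
    duration_s: float
    final_temp_C: Optional[float] = None
    stir_speed: Optional[float] = None


class TransferOp(_OpBase):
    """Push vessel contents through the cassette cartridge path.

    ``mode`` is ``Trap`` (send to waste, species retained on the cartridge)
    or ``Elute`` (send onward). With ``Elute``, ``target_reactor`` equal to
    ``source_reactor`` addresses the cassette output line feeding the product
    collection vial.
    """

    kind: Literal["TRANSFER"] = "TRANSFER"
    source_reactor: int
    target_reactor: int
    mode: Literal["Trap", "Elute"]
    pressure_psi: Optional[float] = None
    duration_s: Optional[float] = None


class ReactOp(_OpBase):
    """Seal the vessel at a reaction position and heat."""

    kind: Literal["REACT"] = "REACT"
    reactor: int
    reaction_temp_C: float
    reaction_position: int   # 1 or 2: two sealed-reaction gasket stations
    duration_s: float
    final_temp_C: float
    stir_speed: Optional[float] = None
    cool_delay_s: Optional[float] = None


class PromptOp(_OpBase):
    """Pause the run and show a message to the operator."""

    kind: Literal["PROMPT"] = "PROMPT"
    message: str


class InstallOp(_OpBase):
    """Move a reactor to the off-gasket install position and prompt."""

    kind: Literal["INSTALL"] = "INSTALL"
    reactor: int
    message: str


class CommentOp(_OpBase):
    """Documentation-only entry; no hardware action."""

    kind: Literal["COMMENT"] = "COMMENT"
    comment: str


class TrapF18Op(_OpBase):
    """Trap [18F]fluoride on the QMA cartridge.

    ``cyclotron_flag`` True means the cyclotron pushes the target water;
    False means the synthesizer pushes with inert gas at ``pressure_psi``.
    """

    kind: Literal["TRAPF18"] = "TRAPF18"
    reactor: int
    cyclotron_flag: bool = False
    duration_s: float = 0.0
    pressure_psi: Optional[float] = None


class EluteF18Op(_OpBase):
    """Elute the QMA cartridge with a named reagent into a reactor."""

    kind: Literal["ELUTEF18"] = "ELUTEF18"
    reactor: int
    reagent_name: str
    duration_s: float
    pressure_psi: Optional[float] = None


class MixOp(_OpBase):
    """Stir vessel contents for a fixed time."""

    kind: Literal["MIX"] = "MIX"
    reactor: int
    duration_s: float
    stir_speed: float


class ExternalAddOp(_OpBase):
    """Prompt the operator to add a reagent through external tubing."""

    kind: Literal["EXTERNALADD"] = "EXTERNALADD"
    reactor: int
    reagent_name: str
    message: str


class TransferToHplcOp(_OpBase):
    """Load vessel contents onto the HPLC injection loop."""

    kind: Literal["TRANSFERTOHPLC"] = "TRANSFERTOHPLC"
    source_reactor: int
    mobile_phase_reagent_name: str


class MeasureRadiationOp(_OpBase):
    """Read the solid-state radiation sensor for one reactor."""

    kind: Literal["MEASURERADIATION"] = "MEASURERADIATION"
    reactor: int


UnitOp = Annotated[
    Union[
        InitializeOp,
        AddOp,
        EvaporateOp,
        TransferOp,
        ReactOp,
        PromptOp,
        InstallOp,
        CommentOp,
        TrapF18Op,
        EluteF18Op,
        MixOp,
        ExternalAddOp,
        TransferToHplcOp,
        MeasureRadiationOp,
    ],
    Field(discriminator="kind"),
]

UNIT_OP_KINDS: tuple[str, ...] = (
    "INITIALIZE", "ADD", "EVAPORATE", "TRANSFER", "REACT", "PROMPT",
    "INSTALL", "COMMENT", "TRAPF18", "ELUTEF18", "MIX", "EXTERNALADD",
    "TRANSFERTOHPLC", "MEASURERADIATION",
)

_UNIT_OP_ADAPTER: TypeAdapter = TypeAdapter(UnitOp)


def unit_op_from_dict(data: dict[str, Any]) -> UnitOp:
    """Build a unit op from a plain mapping (inverse of ``model_dump``)."""
    return _UNIT_OP_ADAPTER.validate_python(data)


def apply_defaults(op: UnitOp) -> UnitOp:
    """Return ``op`` with every unset secondary parameter filled in.

    Explicitly set values are never overwritten; the function is idempotent.
    Raises ``ValueError`` for an unknown kind (unreachable through the typed
    constructors, reachable through hand-built mappings).
    """
    if op.kind not in UNIT_OP_KINDS:   # defensive: op built outside the union
        raise ValueError(f"unknown unit-op kind {op.kind!r}")
    updates = {
        field: value
        for field, value in DEFAULTS.get(op.kind, {}).items()
        if getattr(op, field, None) is None
    }
    return op.model_copy(update=updates) if updates else op


# --- programs ----------------------------------------------------------------

class SynthesisProgram(BaseModel):
    """A named, ordered unit-operation sequence bound to a cassette layout."""

    model_config = ConfigDict(frozen=True)

    name: str
    layout: CassetteLayout
    ops: tuple[UnitOp, ...] = ()

    @property
    def n_ops(self) -> int:
        return len(self.ops)

    def op(self, index: int) -> UnitOp:
        """1-based access, matching protocol listings."""
        if not (1 <= index <= len(self.ops)):
            raise EditIndexError(f"op index {index} outside 1..{len(self.ops)}")
        return self.ops[index - 1]


class ValidationIssue(BaseModel):
    """One problem found in a program; ``op_index`` is 1-based, 0 for
    layout-level issues."""

    model_config = ConfigDict(frozen=True)

    op_index: int
    severity: Literal["error", "warning"]
    code: str
    message: str


class ProgramMetrics(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_unit_ops: int
    n_reagents: int
    per_kind_counts: dict[str, int]


# range checks per kind: (field, range-class)
_RANGE_FIELDS: dict[str, list[tuple[str, str]]] = {
    "ADD": [("pressure_psi", "pressure_psi"), ("duration_s", "duration_s")],
    "EVAPORATE": [
        ("evaporation_temp_C", "temp_C"),
        ("evaporation_pressure_psi", "pressure_psi"),
        ("final_temp_C", "temp_C"),
        ("duration_s", "duration_s"),
        ("stir_speed", "stir_speed"),
    ],
    "TRANSFER": [("pressure_psi", "pressure_psi"), ("duration_s", "duration_s")],
    "REACT": [
        ("reaction_temp_C", "temp_C"),
        ("final_temp_C", "temp_C"),
        ("duration_s", "duration_s"),
        ("stir_speed", "stir_speed"),
        ("cool_delay_s", "duration_s"),
    ],
    "TRAPF18": [("pressure_psi", "pressure_psi"), ("duration_s", "duration_s")],
    "ELUTEF18": [("pressure_psi", "pressure_psi"), ("duration_s", "duration_s")],
    "MIX": [("duration_s", "duration_s"), ("stir_speed", "stir_speed")],
}

_REAGENT_FIELDS: dict[str, list[str]] = {
    "ADD": ["reagent_name"],
    "ELUTEF18": ["reagent_name"],
    "EXTERNALADD": ["reagent_name"],
    "TRANSFERTOHPLC": ["mobile_phase_reagent_name"],
}

_REACTOR_FIELDS: dict[str, list[str]] = {
    "ADD": ["reactor"], "EVAPORATE": ["reactor"], "REACT": ["reactor"],
    "INSTALL": ["reactor"], "TRAPF18": ["reactor"], "ELUTEF18": ["reactor"],
    "MIX": ["reactor"], "EXTERNALADD": ["reactor"],
    "MEASURERADIATION": ["reactor"],
    "TRANSFER": ["source_reactor", "target_reactor"],
    "TRANSFERTOHPLC": ["source_reactor"],
}


def validate_program(program: SynthesisProgram) -> list[ValidationIssue]:
    """Check a program for runnability; pure, returns issues (never raises).

    An empty list means the program is runnable: every reagent reference
    resolves, every parameter is in its permitted range, and the op list is
    non-empty.
    """
    issues: list[ValidationIssue] = []

    def issue(i: int, code: str, message: str, severity: str = "error") -> None:
        issues.append(
            ValidationIssue(op_index=i, severity=severity, code=code, message=message)
        )

    names = program.layout.names()
    if not program.ops:
        issue(0, "empty-program", "a runnable program needs at least one unit operation")

    for i, raw in enumerate(program.ops, start=1):
        op = apply_defaults(raw)
        for field in _REAGENT_FIELDS.get(op.kind, []):
            name = getattr(op, field)
            if name not in names:
                issue(i, "unresolved-reagent",
                      f"{op.kind} references undefined reagent {name!r}")
        for field in _REACTOR_FIELDS.get(op.kind, []):
            r = getattr(op, field)
            if not (1 <= r <= N_CASSETTES):
                issue(i, "param-out-of-range",
                      f"{op.kind}.{field}={r} outside 1..{N_CASSETTES}")
        if op.kind == "ADD" and op.delivery_position not in (1, 2):
            issue(i, "param-out-of-range",
                  f"ADD.delivery_position={op.delivery_position} not in {{1, 2}}")
        if op.kind == "REACT" and op.reaction_position not in (1, 2):
            issue(i, "param-out-of-range",
                  f"REACT.reaction_position={op.reaction_position} not in {{1, 2}}")
        for field, klass in _RANGE_FIELDS.get(op.kind, []):
            value = getattr(op, field)
            if value is None:
                continue
            lo, hi = PARAM_RANGES[klass]
            if not (lo <= value <= hi):
                issue(i, "param-out-of-range",
                      f"{op.kind}.{field}={value} outside [{lo}, {hi}]")
    return issues


# --- editing -----------------------------------------------------------------

def edit_program(program: SynthesisProgram, edit: dict[str, Any]) -> SynthesisProgram:
    """Apply one list edit and return the edited program (1-based indices).

    ``edit`` is one of::

        {"insert": {"op": <UnitOp>, "index": i}}   # new op becomes op i
        {"delete": {"index": i}}
        {"move":   {"from": a, "to": b}}

    The original program is unchanged; the layout is never touched.
    """
    ops = list(program.ops)
    if "insert" in edit:
        spec = edit["insert"]
        i = spec["index"]
        if not (1 <= i <= len(ops) + 1):
            raise EditIndexError(f"insert index {i} outside 1..{len(ops) + 1}")
        ops.insert(i - 1, spec["op"])
    elif "delete" in edit:
        i = edit["delete"]["index"]
        if not (1 <= i <= len(ops)):
            raise EditIndexError(f"delete index {i} outside 1..{len(ops)}")
        del ops[i - 1]
    elif "move" in edit:
        a, b = edit["move"]["from"], edit["move"]["to"]
        for label, i in (("from", a), ("to", b)):
            if not (1 <= i <= len(ops)):
                raise EditIndexError(f"move {label} index {i} outside 1..{len(ops)}")
        op = ops.pop(a - 1)
        ops.insert(b - 1, op)
    else:
        raise ValueError(f"unknown edit {sorted(edit)}")
    return program.model_copy(update={"ops": tuple(ops)})


def insert_op(program: SynthesisProgram, op: UnitOp, index: int) -> SynthesisProgram:
    return edit_program(program, {"insert": {"op": op, "index": index}})


def delete_op(program: SynthesisProgram, index: int) -> SynthesisProgram:
    return edit_program(program, {"delete": {"index": index}})


def move_op(program: SynthesisProgram, src: int, dst: int) -> SynthesisProgram:
    return edit_program(program, {"move": {"from": src, "to": dst}})


# --- metrics -----------------------------------------------------------------

def program_metrics(program: SynthesisProgram) -> ProgramMetrics:
    counts = Counter(op.kind for op in program.ops)
    return ProgramMetrics(
        n_unit_ops=len(program.ops),
        n_reagents=len(program.layout.reagents),
        per_kind_counts=dict(counts),
    )


# --- structured serialization ------------------------------------------------

def program_to_dict(program: SynthesisProgram) -> dict[str, Any]:
    """Key-value tree form for machine exchange (JSON/YAML-friendly)."""
    return program.model_dump(mode="json")


def program_from_dict(data: dict[str, Any]) -> SynthesisProgram:
    return SynthesisProgram.model_validate(data)


# --- plain-text program file format ------------------------------------------
#
# Line-oriented, UTF-8, '#' comments. One stanza kind per line:
#
#   program "<name>"
#   reagent <cassette>.<position> "<name>" volume=<mL> [desc="..."]
#   op <KIND> key=value ...
#
# Values: true/false, integers, floats, or (quoted) strings. Unset optional
# parameters are simply omitted and remain unset on load, so a round trip
# preserves whether a value was defaulted or explicit.

def _format_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        if isinstance(value, float) and value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    text = str(value)
    if text == "" or any(c in text for c in ' \t"#=') or text != shlex.quote(text):
        return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'
    return text


def _parse_value(token: str) -> Any:
    low = token.lower()
    if low == "true":
        return True
    if low == "false":
        return False
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError:
        pass
    return token


def save_program(program: SynthesisProgram) -> str:
    """Render a program as the plain-text program file format."""
    lines = ["# unitops program file v1", f"program {_format_value(program.name)}"]
    for r in program.layout.reagents:
        line = (
            f"reagent {r.cassette_id}.{r.position} {_format_value(r.name)}"
            f" volume={_format_value(r.volume_mL)}"
        )
        if r.description:
            line += f" desc={_format_value(r.description)}"
        lines.append(line)
    for op in program.ops:
        fields = op.model_dump(exclude_none=True, exclude_defaults=False)
        fields.pop("kind")
        if not fields.get("note"):
            fields.pop("note", None)
        pairs = " ".join(f"{k}={_format_value(v)}" for k, v in fields.items())
        lines.append(f"op {op.kind}{(' ' + pairs) if pairs else ''}")
    return "\n".join(lines) + "\n"


def load_program(text: str) -> SynthesisProgram:
    """Parse the plain-text program file format.

    Raises :class:`ProgramParseError` (with line number) on malformed lines
    and :class:`SchemaViolation` (with 1-based op index) on unknown unit-op
    kinds or invalid parameter sets.
    """
    name = ""
    layout = CassetteLayout()
    ops: list[UnitOp] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            tokens = shlex.split(line, comments=True)
        except ValueError as exc:
            raise ProgramParseError(line_no, f"unbalanced quoting ({exc})") from exc
        if not tokens:
            continue
        head, rest = tokens[0], tokens[1:]
        if head == "program":
            if len(rest) != 1:
                raise ProgramParseError(line_no, "expected: program \"<name>\"")
            name = rest[0]
        elif head == "reagent":
            if len(rest) < 2 or "." not in rest[0]:
                raise ProgramParseError(
                    line_no, "expected: reagent <cassette>.<position> \"<name>\" ..."
                )
            slot, rname = rest[0], rest[1]
            try:
                cassette_s, position_s = slot.split(".", 1)
                cassette, position = int(cassette_s), int(position_s)
            except ValueError as exc:
                raise ProgramParseError(line_no, f"bad slot {slot!r}") from exc
            kv = _parse_pairs(rest[2:], line_no)
            try:
                layout = define_reagent(
                    layout, cassette, position, rname,
                    description=str(kv.get("desc", "")),
                    volume_mL=float(kv.get("volume", 1.0)),
                )
            except LayoutError as exc:
                raise ProgramParseError(line_no, str(exc)) from exc
        elif head == "op":
            if not rest:
                raise ProgramParseError(line_no, "expected: op <KIND> key=value ...")
            kind = rest[0]
            op_index = len(ops) + 1
            if kind not in UNIT_OP_KINDS:
                raise SchemaViolation(op_index, f"unknown unit-op kind {kind!r}")
            data: dict[str, Any] = {"kind": kind}
            data.update(_parse_pairs(rest[1:], line_no))
            try:
                ops.append(unit_op_from_dict(data))
            except Exception as exc:
                raise SchemaViolation(op_index, f"invalid {kind} parameters: {exc}") from exc
        else:
            raise ProgramParseError(line_no, f"unknown stanza {head!r}")
    return SynthesisProgram(name=name, layout=layout, ops=tuple(ops))


def _parse_pairs(tokens: list[str], line_no: int) -> dict[str, Any]:
    kv: dict[str, Any] = {}
    for token in tokens:
        if "=" not in token:
            raise ProgramParseError(line_no, f"expected key=value, got {token!r}")
        key, _, value = token.partition("=")
        kv[key] = _parse_value(value)
    return kv
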
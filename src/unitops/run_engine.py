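"""Run-time execution of validated programs on the virtual hardware.

Semantics mirror how the real instrument runs a protocol:

* unit operations execute strictly in order; the engine acts autonomously
  once started (a failing notification hook never disturbs the run);
* PROMPT / INSTALL / EXTERNALADD block awaiting operator acknowledgment;
* the dwell phase of REACT, EVAPORATE and MIX can be overridden — finished
  early or extended — and the *actual* duration of every operation is
  recorded to the run history;
* the full system state is snapshotted at a fixed rate (default 4 per
  simulated second) and appended, together with every prompt, override and
  status change, to a crash-safe JSON-lines run record that supports
  resume-after-crash and batch-record export.

All timing is in simulated seconds (the virtual clock), which makes runs
fast and exactly reproducible: an interrupted run, resumed, reaches a final
state identical to an uninterrupted one.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

from .compiler import CompiledProgram, ExpansionTable, LowLevelOp, compile_program
from .errors import HardwareError, RunError
from .program_model import (
    SynthesisProgram,
    program_from_dict,
    program_to_dict,
    save_program,
    validate_program,
)
from .virtual_hardware import Engine, HardwareConfig, default_config, initial_state

#: unit-op kinds whose dwell phase the operator may shorten or extend
ADJUSTABLE_KINDS = ("REACT", "EVAPORATE", "MIX")

#: unit-op kinds that block awaiting operator acknowledgment
PROMPTING_KINDS = ("PROMPT", "INSTALL", "EXTERNALADD")

NotifyHook = Callable[[str, dict[str, Any]], None]


@dataclass(frozen=True)
class RunOptions:
    snapshot_hz: float = 4.0
    persist_path: str = "run_record.jsonl"
    notify_hook: Optional[NotifyHook] = None
    auto_ack_prompts: bool = False

    def __post_init__(self) -> None:
        if self.snapshot_hz <= 0:
            raise ValueError("snapshot_hz must be > 0")


def program_hash(program: SynthesisProgram) -> str:
    return hashlib.sha256(save_program(program).encode()).hexdigest()


def state_fingerprint(state) -> str:
    """Order-independent digest of the full hardware state, for
    resume-equivalence comparisons."""
    doc = {
        "clock_s": round(state.clock_s, 9),
        "reactors": {
            str(r): [rs.station, rs.sealed, round(rs.temp_C, 9), rs.stir_speed,
                     [[n, round(v, 9)] for n, v in rs.contents]]
            for r, rs in sorted(state.reactors.items())
        },
        "vials": {f"{c}.{p}": round(v, 9) for (c, p), v in sorted(state.vials.items())},
        "waste": round(state.waste_mL, 9),
        "collected": [[n, round(v, 9)] for n, v in state.collected],
        "hplc": [[n, round(v, 9)] for n, v in state.hplc_loop],
        "vapor": round(state.vapor_mL, 9),
        "activity": {k: round(v, 12) for k, v in sorted(state.activity.items())},
        "valves": {k: v for k, v in sorted(state.valves.items())},
        "line_psi": {k: v for k, v in sorted(state.line_psi.items())},
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


class RunHandle:
    """Live handle on a (possibly resumed) production run."""

    def __init__(
        self,
        program: SynthesisProgram,
        config: HardwareConfig,
        options: RunOptions,
        table: ExpansionTable | None = None,
        _append: bool = False,
    ) -> None:
        self.program = program
        self.config = config
        self.options = options
        self.compiled: CompiledProgram = compile_program(program, table)
        groups = self.compiled.by_origin()
        self._op_llops: dict[int, list[LowLevelOp]] = {
            i: groups.get(i, []) for i in range(1, len(program.ops) + 1)
        }
        self.state = initial_state(config, program.layout)
        self._engine = Engine(self.state, config)
        self.status = "running"
        self.op_index = 1
        self._resume_pos = 0
        self._op_start_clock = 0.0
        self._last_tick = 0
        self._pending_prompt: Optional[str] = None
        self._ack_next = False
        self._overrides: list[tuple[str, float]] = []
        self._replay_overrides: dict[int, list[tuple[str, float]]] = {}
        self._silent = False       # True while replaying a resumed prefix
        self._fh = open(options.persist_path, "a" if _append else "w", encoding="utf-8")
        if not _append:
            self._emit({
                "event": "header",
                "program": program_to_dict(program),
                "content_hash": program_hash(program),
                "snapshot_hz": options.snapshot_hz,
            })
            self._notify("start", {"program": program.name})

    # -- plumbing ------------------------------------------------------------

    def _emit(self, event: dict[str, Any]) -> None:
        if self._silent:
            return
        self._fh.write(json.dumps(event) + "\n")
        self._fh.flush()

    def _notify(self, event: str, payload: dict[str, Any]) -> None:
        hook = self.options.notify_hook
        if hook is None or self._silent:
            return
        try:
            hook(event, payload)
        except Exception as exc:   # observer isolation: never disturb the run
            self._emit({"event": "notify-error", "error": repr(exc)})

    def _snapshot_to(self, op_index: int) -> None:
        hz = self.options.snapshot_hz
        tick_limit = math.floor(self.state.clock_s * hz + 1e-9)
        while self._last_tick < tick_limit:
            self._last_tick += 1
            self._emit({
                "event": "snapshot",
                "clock_s": self._last_tick / hz,
                "op_index": op_index,
                "state": self.state.summary(),
            })

    def close(self) -> None:
        if not self._fh.closed:
            self._fh.close()

    # -- execution -----------------------------------------------------------

    def _dwell_seconds(self, programmed: float) -> float:
        """Apply scheduled dwell overrides; returns the realized dwell."""
        if not self._overrides:
            return programmed
        actual = programmed
        extended = False
        for action, at_s in sorted(self._overrides, key=lambda e: e[1]):
            self._emit({
                "event": "override", "op_index": self.op_index,
                "action": action, "at_elapsed_s": at_s,
                "clock_s": self.state.clock_s,
            })
            if action == "finish_now":
                actual = at_s
                extended = False
                break
            if action == "extend":
                extended = True
        if extended:
            raise RunError(
                "no-timed-phase-active",
                "extend scheduled without a subsequent finish_now",
            )
        self._overrides = []
        return actual

    def _execute_current(self) -> str:
        i = self.op_index
        op = self.program.ops[i - 1]
        llops = self._op_llops[i]
        if self._resume_pos == 0:
            self._op_start_clock = self.state.clock_s
            self._emit({"event": "op_start", "op_index": i, "kind": op.kind,
                        "clock_s": self.state.clock_s})
            if op.kind == "COMMENT":
                self._notify("comment", {"op_index": i, "comment": op.comment})
        j = self._resume_pos
        while j < len(llops):
            llop = llops[j]
            if llop.verb == "USER_WAIT" and not self._silent and not self._ack_next:
                message = str(llop.args.get("message", ""))
                self._emit({"event": "prompt", "op_index": i, "message": message,
                            "clock_s": self.state.clock_s})
                if not self.options.auto_ack_prompts:
                    self._pending_prompt = message
                    self._resume_pos = j    # re-entered by respond_prompt
                    self.status = "awaiting-prompt"
                    return self.status
                self._emit({"event": "response", "op_index": i,
                            "acknowledgement": "auto",
                            "clock_s": self.state.clock_s})
            self._ack_next = False
            if llop.phase == "dwell" and op.kind in ADJUSTABLE_KINDS:
                pending = self._replay_overrides.get(i) if self._silent else None
                if pending is not None:
                    self._overrides = list(pending)
                seconds = self._dwell_seconds(float(llop.args["seconds"]))
                llop = LowLevelOp(
                    verb="WAIT", args={**llop.args, "seconds": seconds},
                    origin=llop.origin, phase="dwell",
                )
            try:
                self._engine.apply(llop)
            except HardwareError as exc:
                self.status = "failed"
                self._emit({"event": "terminal", "status": "failed",
                            "op_index": i, "error": str(exc),
                            "clock_s": self.state.clock_s})
                self._notify("fail", {"op_index": i, "error": str(exc)})
                return self.status
            self._snapshot_to(i)
            j += 1
        programmed = sum(
            float(l.args["seconds"]) for l in llops if l.verb == "WAIT"
        )
        self._emit({
            "event": "op_done", "op_index": i, "kind": op.kind,
            "clock_s": self.state.clock_s,
            "actual_duration_s": round(self.state.clock_s - self._op_start_clock, 9),
            "programmed_duration_s": round(programmed, 9),
        })
        self._resume_pos = 0
        self._overrides = []
        self.op_index += 1
        if self.op_index > len(self.program.ops):
            self.status = "completed"
            self._emit({"event": "terminal", "status": "completed",
                        "clock_s": self.state.clock_s})
            self._notify("complete", {"program": self.program.name})
        return self.status

    def advance(self) -> str:
        """Execute the current unit operation (up to any prompt)."""
        if self.status in ("completed", "failed", "aborted"):
            raise RunError("run-terminal", f"run already {self.status}")
        if self.status == "awaiting-prompt":
            raise RunError(
                "awaiting-prompt", "respond_prompt before advancing further"
            )
        return self._execute_current()

    def respond_prompt(self, acknowledgement: str = "ok") -> str:
        if self.status != "awaiting-prompt":
            raise RunError("not-awaiting-prompt", f"run is {self.status}")
        self._emit({"event": "response", "op_index": self.op_index,
                    "acknowledgement": acknowledgement,
                    "clock_s": self.state.clock_s})
        self.status = "running"
        self._pending_prompt = None
        self._ack_next = True      # apply the USER_WAIT itself, then continue
        return self._execute_current()

    def override_timer(self, action: str, at_elapsed_s: float) -> str:
        """Schedule a dwell override for the current unit operation.

        ``finish_now`` truncates the dwell at ``at_elapsed_s`` simulated
        seconds into it; ``extend`` keeps the dwell running past its
        programmed time until a later ``finish_now``.
        """
        if self.status in ("completed", "failed", "aborted"):
            raise RunError("run-terminal", f"run already {self.status}")
        if action not in ("finish_now", "extend"):
            raise ValueError(f"unknown override action {action!r}")
        op = self.program.ops[self.op_index - 1]
        if op.kind not in ADJUSTABLE_KINDS:
            raise RunError(
                "no-timed-phase-active",
                f"{op.kind} has no user-adjustable timed phase",
            )
        self._overrides.append((action, float(at_elapsed_s)))
        return self.status

    def abort(self) -> str:
        if self.status in ("completed", "failed", "aborted"):
            raise RunError("run-terminal", f"run already {self.status}")
        self.status = "aborted"
        self._emit({"event": "terminal", "status": "aborted",
                    "clock_s": self.state.clock_s})
        self._notify("fail", {"reason": "aborted"})
        return self.status

    def run_to_completion(self, acknowledgement: str = "ok") -> str:
        """Advance repeatedly, acknowledging any prompts, until terminal."""
        while self.status == "running":
            status = self.advance()
            while status == "awaiting-prompt":
                status = self.respond_prompt(acknowledgement)
        return self.status

    @property
    def pending_prompt(self) -> Optional[str]:
        return self._pending_prompt


def start_run(
    program: SynthesisProgram,
    config: HardwareConfig | None = None,
    options: RunOptions | None = None,
    table: ExpansionTable | None = None,
) -> RunHandle:
    """Validate, persist the run header, and return a live handle."""
    issues = validate_program(program)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise RunError(
            "validation-failed",
            "; ".join(f"op {i.op_index}: {i.message}" for i in errors),
        )
    return RunHandle(program, config or default_config(),
                     options or RunOptions(), table)


# --- persisted records and resume --------------------------------------------

@dataclass
class RunRecord:
    """Parsed view of a persisted run history."""

    program: SynthesisProgram
    content_hash: str
    snapshot_hz: float
    events: list[dict[str, Any]] = field(default_factory=list)

    @property
    def snapshots(self) -> list[dict[str, Any]]:
        return [e for e in self.events if e["event"] == "snapshot"]

    @property
    def op_durations(self) -> dict[int, dict[str, float]]:
        return {
            e["op_index"]: {
                "actual_duration_s": e["actual_duration_s"],
                "programmed_duration_s": e["programmed_duration_s"],
                "kind": e["kind"],
            }
            for e in self.events if e["event"] == "op_done"
        }

    @property
    def prompts(self) -> list[dict[str, Any]]:
        return [e for e in self.events if e["event"] in ("prompt", "response")]

    @property
    def overrides(self) -> list[dict[str, Any]]:
        return [e for e in self.events if e["event"] == "override"]

    @property
    def status(self) -> Optional[str]:
        for e in reversed(self.events):
            if e["event"] == "terminal":
                return e["status"]
        return None

    @property
    def completed_ops(self) -> int:
        return max((e["op_index"] for e in self.events if e["event"] == "op_done"),
                   default=0)


def load_run_record(persist_path: str) -> RunRecord:
    if not os.path.exists(persist_path):
        raise RunError("record-missing", f"no run record at {persist_path}")
    events: list[dict[str, Any]] = []
    with open(persist_path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                events.append(json.loads(line))
    if not events or events[0].get("event") != "header":
        raise RunError("record-missing", f"{persist_path} has no run header")
    header = events[0]
    return RunRecord(
        program=program_from_dict(header["program"]),
        content_hash=header["content_hash"],
        snapshot_hz=header["snapshot_hz"],
        events=events[1:],
    )


def resume_run(
    persist_path: str,
    config: HardwareConfig | None = None,
    notify_hook: Optional[NotifyHook] = None,
    table: ExpansionTable | None = None,
) -> RunHandle:
    """Rebuild a crashed run from its record and continue at the last
    completed unit-operation boundary.

    The completed prefix is re-executed silently (determinism makes this
    exact, including recorded dwell overrides); the run record is appended
    to, never rewritten, so pre-crash snapshots are preserved.
    """
    record = load_run_record(persist_path)
    if record.status is not None:
        raise RunError("record-terminal", f"run already {record.status}")
    options = RunOptions(
        snapshot_hz=record.snapshot_hz, persist_path=persist_path,
        notify_hook=notify_hook,
    )
    handle = RunHandle(record.program, config or default_config(), options,
                       table, _append=True)
    for e in record.events:
        if e["event"] == "override":
            handle._replay_overrides.setdefault(e["op_index"], []).append(
                (e["action"], e["at_elapsed_s"])
            )
    completed = record.completed_ops
    handle._silent = True
    saved_auto = handle.options
    handle.options = RunOptions(
        snapshot_hz=options.snapshot_hz, persist_path=persist_path,
        notify_hook=None, auto_ack_prompts=True,
    )
    while handle.op_index <= completed and handle.status == "running":
        handle._execute_current()
    handle.options = saved_auto
    handle._silent = False
    handle._last_tick = math.floor(
        handle.state.clock_s * options.snapshot_hz + 1e-9
    )
    handle._emit({"event": "resumed", "op_index": handle.op_index,
                  "clock_s": handle.state.clock_s})
    return handle


def export_batch_record(record: RunRecord | str) -> str:
    """Human-readable batch record for a terminal run."""
    if isinstance(record, str):
        record = load_run_record(record)
    if record.status is None:
        raise RunError("run-not-terminal", "run has not reached a terminal status")
    lines = [
        "BATCH RECORD",
        f"program:       {record.program.name}",
        f"content hash:  {record.content_hash}",
        f"status:        {record.status}",
        f"unit ops:      {len(record.program.ops)}",
        f"snapshots:     {len(record.snapshots)} at {record.snapshot_hz}/s (simulated)",
        "",
        "op  kind              programmed_s  actual_s",
    ]
    durations = record.op_durations
    for i in sorted(durations):
        d = durations[i]
        lines.append(
            f"{i:<3d} {d['kind']:<17s} {d['programmed_duration_s']:>11.1f}"
            f"  {d['actual_duration_s']:>8.1f}"
        )
    transcript = record.prompts
    if transcript:
        lines += ["", "prompt transcript:"]
        for e in transcript:
            if e["event"] == "prompt":
                lines.append(
                    f"  [{e['clock_s']:.1f} s] op {e['op_index']}: {e['message']}"
                )
            else:
                lines.append(
                    f"  [{e['clock_s']:.1f} s] op {e['op_index']}: "
                    f"acknowledged ({e['acknowledgement']})"
                )
    if record.overrides:
        lines += ["", "override events:"]
        for e in record.overrides:
            lines.append(
                f"  [{e['clock_s']:.1f} s] op {e['op_index']}: {e['action']}"
                f" at {e['at_elapsed_s']:.1f} s into dwell"
            )
    return "\n".join(lines) + "\n"
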
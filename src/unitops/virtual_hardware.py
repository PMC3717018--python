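"""Deterministic discrete-event simulator of the synthesizer.

The simulator executes low-level operation streams produced by the compiler
(or hand-built ones), tracking reactor poses, seal state, temperatures,
vessel contents, valve and regulator state, the vial store, a product
collection vial, waste, the HPLC loop and a simulated clock.

Liquid accounting is a closed ledger: at all times

    vials + reactors + waste + collected + hplc + vapor
        == initial vial volumes + external inputs

to floating-point precision. Liquid moves only while a *path* is active —
the right valves open, the right line pressurized, a vessel sealed at the
right station — and only during WAIT steps, mirroring how the real
instrument's flow happens while the controller holds a pressurized
configuration. Evaporation removes tracked volume (all tracked volume is
solvent; non-volatile solutes, including the radiolabel, are massless
labels that stay put).

Safety is enforced at execution time through the same
:class:`~unitops.compiler.SafetyTracker` rules the static checker uses, so
the simulator raises :class:`IllegalTransition` exactly where
``check_stream`` reports a violation.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

import yaml
from pydantic import BaseModel, ConfigDict

from .compiler import (
    GASKET_STATIONS,
    INSTALL_STATION,
    LINES,
    LowLevelOp,
    SafetyTracker,
)
from .errors import (
    EmptySlotError,
    HardwareError,
    IllegalTransition,
    SimulationError,
    VesselOverflow,
)
from .program_model import CassetteLayout

DEFAULT_CONFIG_PATH = importlib.resources.files("unitops.data") / "hardware_config.yaml"


class HardwareConfig(BaseModel):
    """Geometry and kinetics of the simulated instrument."""

    model_config = ConfigDict(frozen=True)

    n_reactors: int = 3
    vessel_capacity_mL: float = 5.0
    ambient_C: float = 25.0
    ramp_C_per_s: float = 2.0
    evap_rate_mL_per_s: float = 0.005
    f18_delivery_mL: float = 1.0
    f18_activity_units: float = 1.0
    external_add_fraction: float = 1.0
    verb_durations_s: dict[str, float] = {}

    @property
    def gasket_stations(self) -> tuple[str, ...]:
        return GASKET_STATIONS

    @classmethod
    def load(cls, path=None) -> "HardwareConfig":
        source = DEFAULT_CONFIG_PATH if path is None else path
        with open(str(source), "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


_DEFAULT_CONFIG: HardwareConfig | None = None


def default_config() -> HardwareConfig:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = HardwareConfig.load()
    return _DEFAULT_CONFIG


@dataclass
class ReactorState:
    station: str
    sealed: bool
    temp_C: float
    setpoint_C: float
    stir_speed: float
    contents: list[list]          # [reagent_name, volume_mL] pairs

    def volume(self) -> float:
        return sum(v for _, v in self.contents)


#: activity ledger locations
ACTIVITY_LOCATIONS = (
    "external", "qma", "reactor1", "reactor2", "reactor3",
    "waste", "collected", "hplc",
)


@dataclass
class HardwareState:
    """Full simulated instrument state."""

    clock_s: float
    reactors: dict[int, ReactorState]
    vials: dict[tuple[int, int], float]       # (cassette, position) -> remaining mL
    vial_names: dict[tuple[int, int], str]
    gripper_location: str
    held_vial: Optional[tuple[int, int]]
    engaged_vial: Optional[tuple[str, int, int]]   # (needle, cassette, position)
    valves: dict[str, bool]                   # True = open
    line_psi: dict[str, float]
    waste_mL: float
    collected: list[list]
    hplc_loop: list[list]
    vapor_mL: float
    external_in_mL: float
    f18_available_mL: float
    initial_liquid_mL: float
    activity: dict[str, float]                # relative units at clock 0

    def collected_mL(self) -> float:
        return sum(v for _, v in self.collected)

    def hplc_mL(self) -> float:
        return sum(v for _, v in self.hplc_loop)

    def total_liquid_mL(self) -> float:
        return (
            sum(self.vials.values())
            + sum(r.volume() for r in self.reactors.values())
            + self.waste_mL
            + self.collected_mL()
            + self.hplc_mL()
            + self.vapor_mL
        )

    def liquid_imbalance_mL(self) -> float:
        """Ledger residual; zero (to rounding) for a conserving simulation."""
        return self.total_liquid_mL() - (self.initial_liquid_mL + self.external_in_mL)

    def clone(self) -> "HardwareState":
        return copy.deepcopy(self)

    def summary(self) -> dict[str, Any]:
        """Compact serializable snapshot used by run records."""
        return {
            "clock_s": round(self.clock_s, 6),
            "reactors": {
                r: {
                    "station": s.station,
                    "sealed": s.sealed,
                    "temp_C": round(s.temp_C, 3),
                    "stir": s.stir_speed,
                    "volume_mL": round(s.volume(), 6),
                }
                for r, s in self.reactors.items()
            },
            "waste_mL": round(self.waste_mL, 6),
            "collected_mL": round(self.collected_mL(), 6),
            "vapor_mL": round(self.vapor_mL, 6),
            "activity": {k: round(v, 9) for k, v in self.activity.items() if v},
        }


@dataclass
class TraceStep:
    clock_s: float
    llop: str
    origin: int
    note: str = ""


@dataclass
class Trace:
    steps: list[TraceStep] = field(default_factory=list)

    def render(self) -> str:
        lines = ["clock_s\torigin\top\tnote"]
        for s in self.steps:
            lines.append(f"{s.clock_s:.3f}\t{s.origin}\t{s.llop}\t{s.note}")
        return "\n".join(lines) + "\n"


def initial_state(
    config: HardwareConfig | None = None, layout: CassetteLayout | None = None
) -> HardwareState:
    """All reactors lowered at the install position at ambient temperature,
    every valve closed, every regulator at zero, vials filled per layout,
    clock zero."""
    config = config or default_config()
    layout = layout or CassetteLayout()
    vials = {(r.cassette_id, r.position): r.volume_mL for r in layout.reagents}
    names = {(r.cassette_id, r.position): r.name for r in layout.reagents}
    return HardwareState(
        clock_s=0.0,
        reactors={
            r: ReactorState(
                station=INSTALL_STATION, sealed=False,
                temp_C=config.ambient_C, setpoint_C=config.ambient_C,
                stir_speed=0.0, contents=[],
            )
            for r in range(1, config.n_reactors + 1)
        },
        vials=vials,
        vial_names=names,
        gripper_location="home",
        held_vial=None,
        engaged_vial=None,
        valves={},
        line_psi={line: 0.0 for line in LINES},
        waste_mL=0.0,
        collected=[],
        hplc_loop=[],
        vapor_mL=0.0,
        external_in_mL=0.0,
        f18_available_mL=config.f18_delivery_mL,
        initial_liquid_mL=sum(vials.values()),
        activity={loc: 0.0 for loc in ACTIVITY_LOCATIONS},
    )


class Engine:
    """Mutating executor; the module-level functions wrap it functionally."""

    def __init__(self, state: HardwareState, config: HardwareConfig) -> None:
        self.state = state
        self.config = config
        self.tracker = SafetyTracker()
        # adopt pre-existing pose (resumed or hand-built states)
        for r, rs in state.reactors.items():
            self.tracker.sealed[r] = rs.sealed
            self.tracker.station[r] = rs.station
        self.tracker.vial_out = (
            state.held_vial is not None or state.engaged_vial is not None
        )
        self.tracker.line_psi = dict(state.line_psi)

    # -- helpers ------------------------------------------------------------

    def _open(self, valve: str) -> bool:
        return self.state.valves.get(valve, False)

    def _reactor_sealed_at(self, station: str) -> Optional[int]:
        for r, rs in self.state.reactors.items():
            if rs.sealed and rs.station == station:
                return r
        return None

    def _pour_into_reactor(self, r: int, additions: list[list]) -> None:
        rs = self.state.reactors[r]
        new_volume = rs.volume() + sum(v for _, v in additions)
        if new_volume > self.config.vessel_capacity_mL + 1e-9:
            raise VesselOverflow(
                f"reactor {r}: {new_volume:.3f} mL exceeds "
                f"{self.config.vessel_capacity_mL} mL capacity"
            )
        rs.contents.extend([name, vol] for name, vol in additions if vol > 0)

    def _move_activity(self, src: str, dst: str) -> None:
        amount = self.state.activity.get(src, 0.0)
        if amount:
            self.state.activity[src] = 0.0
            self.state.activity[dst] = self.state.activity.get(dst, 0.0) + amount

    # -- liquid paths (evaluated during WAIT) --------------------------------

    def _flow(self, dt: float) -> str:
        st = self.state
        notes = []
        # reagent dispense: vial engaged on an addition needle
        if (
            st.engaged_vial is not None
            and st.engaged_vial[0] in ("needle1", "needle2")
            and self._open("add.gas")
            and st.line_psi.get("add", 0.0) > 0
        ):
            r = self._reactor_sealed_at("ADD")
            if r is not None:
                _, c, p = st.engaged_vial
                vol = st.vials.get((c, p), 0.0)
                if vol > 0:
                    st.vials[(c, p)] = 0.0
                    name = st.vial_names.get((c, p), f"vial {c}.{p}")
                    self._pour_into_reactor(r, [[name, vol]])
                    notes.append(f"dispense {vol:.3f} mL {name} -> reactor {r}")
        # QMA elution: eluent vial on the elute needle, through the cartridge
        if (
            st.engaged_vial is not None
            and st.engaged_vial[0] == "elute"
            and self._open("elute.vial")
            and self._open("qma.elute")
            and self._open("add.gas")
            and st.line_psi.get("add", 0.0) > 0
        ):
            r = self._reactor_sealed_at("ADD")
            if r is not None:
                _, c, p = st.engaged_vial
                vol = st.vials.get((c, p), 0.0)
                if vol > 0:
                    st.vials[(c, p)] = 0.0
                    name = st.vial_names.get((c, p), f"vial {c}.{p}")
                    self._pour_into_reactor(r, [[name, vol]])
                    notes.append(f"elute {vol:.3f} mL {name} -> reactor {r}")
                self._move_activity("qma", f"reactor{r}")
        # F18 trap: target water through the QMA to waste, label retained
        if (
            self._open("f18.inlet")
            and self._open("qma.waste")
            and st.f18_available_mL > 0
        ):
            st.waste_mL += st.f18_available_mL
            st.external_in_mL += st.f18_available_mL
            notes.append(f"trap: {st.f18_available_mL:.3f} mL target water -> waste")
            st.f18_available_mL = 0.0
            st.activity["external"] = 0.0
            st.activity["qma"] += self.config.f18_activity_units
        # transfer out of a sealed vessel through the cartridge path
        if self._open("xfer.inlet") and st.line_psi.get("transfer", 0.0) > 0:
            r = self._reactor_sealed_at("TRANSFER")
            if r is not None and st.reactors[r].contents:
                moved = st.reactors[r].contents
                st.reactors[r].contents = []
                vol = sum(v for _, v in moved)
                if self._open("route.waste"):
                    st.waste_mL += vol
                    self._move_activity(f"reactor{r}", "waste")
                    notes.append(f"transfer {vol:.3f} mL reactor {r} -> waste")
                elif self._open("route.collect"):
                    st.collected.extend(moved)
                    self._move_activity(f"reactor{r}", "collected")
                    notes.append(f"transfer {vol:.3f} mL reactor {r} -> collection vial")
                elif self._open("hplc.load"):
                    st.hplc_loop.extend(moved)
                    self._move_activity(f"reactor{r}", "hplc")
                    notes.append(f"transfer {vol:.3f} mL reactor {r} -> HPLC loop")
                else:
                    for k in st.reactors:
                        if self._open(f"route.r{k}"):
                            self._pour_into_reactor(k, moved)
                            self._move_activity(f"reactor{r}", f"reactor{k}")
                            notes.append(
                                f"transfer {vol:.3f} mL reactor {r} -> reactor {k}"
                            )
                            break
                    else:
                        # no destination open: liquid stays put
                        st.reactors[r].contents = moved
        # evaporation: heated, gas + vacuum open
        if (
            self._open("evap.gas")
            and self._open("evap.vacuum")
            and st.line_psi.get("evaporate", 0.0) > 0
        ):
            r = self._reactor_sealed_at("EVAPORATE")
            if r is not None:
                rs = st.reactors[r]
                total = rs.volume()
                removable = min(total, self.config.evap_rate_mL_per_s * dt)
                if removable > 0 and total > 0:
                    factor = (total - removable) / total
                    for entry in rs.contents:
                        entry[1] *= factor
                    rs.contents = [e for e in rs.contents if e[1] > 1e-12]
                    st.vapor_mL += removable
                    notes.append(f"evaporate {removable:.3f} mL from reactor {r}")
        return "; ".join(notes)

    # -- single-op application ----------------------------------------------

    def apply(self, llop: LowLevelOp) -> str:
        violation = self.tracker.inspect(llop)
        if violation is not None:
            raise IllegalTransition(violation.rule_id, violation.message)

        st, cfg = self.state, self.config
        verb, args = llop.verb, llop.args
        note = ""
        dt = cfg.verb_durations_s.get(verb, 0.0)

        if verb == "MOVE_REACTOR":
            st.reactors[int(args["reactor"])].station = str(args["station"])
        elif verb == "RAISE_SEAL":
            st.reactors[int(args["reactor"])].sealed = True
        elif verb == "LOWER_VESSEL":
            st.reactors[int(args["reactor"])].sealed = False
        elif verb == "GRIPPER_MOVE":
            st.gripper_location = str(args["target"])
        elif verb == "PICK_VIAL":
            slot = (int(args["cassette"]), int(args["position"]))
            if slot not in st.vials:
                raise EmptySlotError(f"no vial installed at {slot[0]}.{slot[1]}")
            st.held_vial = slot
        elif verb == "PLACE_VIAL":
            if st.held_vial is None:
                raise HardwareError("PLACE_VIAL with no vial in the gripper")
            st.engaged_vial = (str(args["needle"]),) + st.held_vial
            st.held_vial = None
        elif verb == "RETURN_VIAL":
            st.engaged_vial = None
            st.held_vial = None
        elif verb == "SET_VALVE":
            st.valves[str(args["valve"])] = str(args["state"]) == "open"
        elif verb == "SET_PRESSURE":
            st.line_psi[str(args["line"])] = float(args["psi"])
        elif verb == "SET_TEMP":
            st.reactors[int(args["reactor"])].setpoint_C = float(args["temp_C"])
        elif verb == "WAIT_TEMP":
            rs = st.reactors[int(args["reactor"])]
            dt = abs(rs.setpoint_C - rs.temp_C) / cfg.ramp_C_per_s
            rs.temp_C = rs.setpoint_C
        elif verb == "SET_STIR":
            st.reactors[int(args["reactor"])].stir_speed = float(args["speed"])
        elif verb == "WAIT":
            dt = float(args["seconds"])
            note = self._flow(dt)
        elif verb == "USER_WAIT":
            # prompt acknowledgment is external; an EXTERNALADD acknowledgment
            # delivers the named reagent's declared volume through the tubing
            reagent = args.get("deliver_reagent")
            if reagent:
                slot = next(
                    (k for k, n in st.vial_names.items() if n == reagent), None
                )
                if slot is not None and st.vials.get(slot, 0.0) > 0:
                    vol = st.vials[slot] * cfg.external_add_fraction
                    st.vials[slot] -= vol
                    self._pour_into_reactor(int(args["reactor"]), [[reagent, vol]])
                    note = f"external add {vol:.3f} mL {reagent}"
        elif verb == "LOG":
            note = str(args.get("text", ""))
        else:
            raise HardwareError(f"unknown verb {verb!r}")

        self.tracker.update(llop)
        st.clock_s += dt
        return note


def apply_llop(
    state: HardwareState, llop: LowLevelOp, config: HardwareConfig | None = None
) -> HardwareState:
    """Pure single-step application: returns the successor state."""
    successor = state.clone()
    Engine(successor, config or default_config()).apply(llop)
    return successor


def run_llops(
    state: HardwareState,
    llops: list[LowLevelOp],
    observer: Optional[Callable[[HardwareState, LowLevelOp], None]] = None,
    config: HardwareConfig | None = None,
) -> tuple[HardwareState, Trace]:
    """Fold a stream over the state, returning final state and trace.

    The input state is not modified. On the first hardware error a
    :class:`SimulationError` is raised carrying the failing index, the
    partial trace and the state reached so far.
    """
    working = state.clone()
    engine = Engine(working, config or default_config())
    trace = Trace()
    for i, llop in enumerate(llops):
        try:
            note = engine.apply(llop)
        except HardwareError as exc:
            raise SimulationError(i, exc, working, trace) from exc
        trace.steps.append(
            TraceStep(clock_s=working.clock_s, llop=llop.render(),
                      origin=llop.origin, note=note)
        )
        if observer is not None:
            observer(working, llop)
    return working, trace
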
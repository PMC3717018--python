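# unitops

Unit-operation programming, compilation and virtual execution for
cassette-based automated radiosynthesizers.

## The problem

Automated synthesizers for PET probes (positron-emission-tomography
imaging tracers such as [¹⁸F]FDG) are usually programmed at the level of
individual valves and actuator motions — hundreds of cryptic steps per
protocol, written with an engineer rather than a radiochemist in mind. A
unit-operation paradigm instead lets the chemist describe a synthesis as a
short ordered list of familiar steps — *add this reagent*, *react at
130 °C for 300 s*, *evaporate*, *transfer through the purification
cartridge* — and leaves the hardware choreography to a compiler that
guarantees a safe actuation order.

`unitops` implements that paradigm end to end for a three-reactor,
three-cassette instrument (3 × 11 = 33 stored reagent vials of up to 3 mL;
five gasket sealing stations per cassette plus an off-gasket install
position):

* **program model** — typed unit operations (`ADD`, `EVAPORATE`,
  `TRANSFER`, `REACT`, `PROMPT`, `INSTALL`, `COMMENT`, `TRAPF18`,
  `ELUTEF18`, `MIX`, `EXTERNALADD`, `TRANSFERTOHPLC`, `MEASURERADIATION`,
  `INITIALIZE`) with chemist-facing parameters, automatic defaults,
  name-based reagent lookup, validation, list editing, and a plain-text
  program file format;
* **compiler** — expands each unit op into atomic hardware operations via
  a shipped, data-driven expansion table, and statically checks four
  safety-ordering rules (no motion while sealed, no pressure without a
  sealed vessel on the path, no gripper motion over an open pressurized
  path, strict vial accounting);
* **virtual hardware** — a deterministic discrete-event simulator with a
  closed liquid ledger (vials + vessels + waste + product + HPLC loop +
  vapor is conserved to machine precision) and a simulated clock;
* **run engine** — sequential execution with operator prompts, dwell-timer
  override (finish-now / extend), 4 Hz state snapshots in simulated time,
  an append-only crash-safe run record, resume-after-crash that exactly
  reproduces an uninterrupted run, and batch-record export;
* **activity** — F-18 decay arithmetic (half-life 109.77 min),
  decay-corrected radiochemical yield, and simulated per-reactor radiation
  readings driven by where the radiolabel resides.

The reference fixture is the classic one-pot [¹⁸F]FDG protocol: trap and
elute [¹⁸F]fluoride, azeotropic drying with acetonitrile, fluorination of
mannose triflate, HCl deprotection, and cartridge purification into the
product vial — **7 reagents, 18 unit operations, compiling to 476
low-level hardware operations**.

## Worked example

```python
from unitops import build_fdg_program, compile_program, program_metrics
from unitops import initial_state, run_llops

program = build_fdg_program()
m = program_metrics(program)
compiled = compile_program(program)
print(m.n_unit_ops, m.n_reagents, compiled.n_llops)   # 18 7 476

final, trace = run_llops(initial_state(layout=program.layout),
                         list(compiled.llops))
```

Running `python examples/03_simulate_run.py` prints:

```
loaded vials:        9.8 mL in 7 vials
simulated time:      3107.2 s (51.8 min)
ledger worst error:  1.78e-15 mL (conservation holds)
collected product:   7.17 mL
reactor 1 residual:  0.00 mL
waste:               1.00 mL (trapped target water)
evaporated solvent:  2.63 mL
label location:      {'collected': 1.0}
```

The 9.8 mL of loaded reagents plus the 1.0 mL trapped target-water bolus
are fully accounted for: 7.17 mL reaches the product vial, 2.63 mL leaves
as vapor during the three dry-downs, 1.0 mL goes to waste, and the
radiolabel (relative activity 1.0) rides the eluate into the collection
vial. The other scripts in `examples/` walk through program authoring and
validation, compilation and the safety checker, prompts/override/resume
with batch records, and decay accounting.

A thin CLI wraps the same library:

```sh
uo validate examples/fdg.program
uo compile examples/fdg.program --count-only     # 476
uo run examples/fdg.program --persist run.jsonl --auto-ack-prompts
uo batch-record run.jsonl
uo decay --isotope F18 --elapsed 2700            # 0.752650
```

## Layout

```
src/unitops/            the library (program_model, compiler,
                        virtual_hardware, run_engine, activity, fixtures,
                        cli) and its data/ (expansion table, hardware config)
examples/               narrative scripts, one per capability
docs/methods.md         the model, its assumptions and design choices
docs/program_format.md  the program file format and its schema
tests/                  pytest suite (unit, property and acceptance tests)
```
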
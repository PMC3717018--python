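# Methods

This note documents the model behind `unitops`: what is simulated, what is
deliberately idealized, which parameters matter, and where design choices
were genuinely open.

## The programming model

A synthesis program is a cassette/reagent layout plus an ordered list of
unit operations. Reagents are declared once with a storage slot (cassette
1–3, position 1–11, ≤ 3.0 mL) and a unique human-readable name; every
later reference is by name, so moving a vial only changes one line.
Fourteen operation kinds cover the syntheses this instrument class runs;
each carries a small set of chemist-facing parameters. Parameters split
into *required* choices (which reagent, which reactor, which needle) and
*secondary* ones (driving pressure, delivery time, stir speed) that are
auto-filled from a defaults table and may be overridden. Defaults are
ADD 3 psi/15 s, TRANSFER 10 psi/30 s, TRAPF18/ELUTEF18 3 psi, EVAPORATE
final temperature 35 °C, stir 0, REACT cool-delay 0 — chosen so the
reference FDG listing reproduces its printed pressures and times without
explicit overrides where the listing is silent.

Validation is a pure function returning issue records (never exceptions):
unresolved reagent names, out-of-range parameters, empty programs. The
permitted ranges (−20…200 °C, 0…60 psi, stir 0…100, durations ≥ 0) are a
config table, not hard-coded: the instrument's published working points
(sealed acetonitrile reactions at 180 °C, 3–15 psi gas) sit well inside
them, and no tighter limits are published, so the caps are deliberately
generous envelope values.

`REACT` carries a `cool_delay_s` parameter because working protocols use a
post-cool hold (the FDG reactions specify an extra 120 s after reaching
the final temperature) that the basic parameter set has no slot for.

Indices are 1-based throughout (matching how protocol listings are
numbered); list edits (insert/delete/move) return new programs and never
touch the layout.

## Compilation and the expansion table

Each unit operation expands into a stream of fifteen low-level verbs
(reactor motion, seal raise/vessel lower, gripper motion, vial
pick/place/return, valve, pressure, temperature and stir set-points,
temperature-wait, timed wait, operator wait, log). The per-kind templates
are *data* — a shipped, versioned YAML document — so the reconstruction's
granularity can be revised without code changes. Granularity follows one
rule: servo motions complete synchronously, while every pneumatic
actuation (seals, vessel lowering, vial engagement, pressurization,
venting) is followed by a fixed 2-s settle wait, and flow paths are
switched one physical valve at a time (including the three per-cassette
stopcocks on the cartridge path).

The detailed per-operation listings for the real instrument are not
reproduced in the published text, only the aggregate: the 18-operation FDG
program corresponds to 476 low-level operations. The shipped table is
therefore a reconstruction calibrated once against that single aggregate
and then frozen (a content-pinned fixture test fails on any accidental
edit). Per-kind sub-counts have no external anchor and should be read as
plausible, not authoritative.

Station mapping: the five gasket stations are ADD, EVAPORATE, TRANSFER,
REACT_A and REACT_B (the two sealed-reaction positions); INSTALL is the
off-gasket service position. The two ADD "delivery positions" are two
needle targets at the single ADD station. TRANSFER routing: `Trap` opens
the waste route; `Elute` opens the route to the target reactor, except
that a target equal to the source addresses the cassette output line
feeding the product collection vial — the path the FDG purification
transfers use (the published listing prints no mode/target for them, only
"through the purification cartridge to the collection vial").

### Safety rules

Four ordering rules are checked statically over any stream and enforced
identically at simulation time (both go through one shared tracker, so
checker and simulator cannot disagree):

* **R1** no gripper motion while a pressurized line is open to an
  unsealed vessel;
* **R2** a line may be pressurized only while a vessel is sealed at the
  station it serves (the trap line, which pushes through the QMA cartridge
  to waste with no vessel on the path, is exempt);
* **R3** a reactor never moves while its seal is raised;
* **R4** vial accounting: a picked vial is returned before the next pick.

Compiler correctness means `check_safety(compile_program(p)) == []` for
every valid program; this is exercised over 1000 randomly generated
programs in the acceptance suite.

## The virtual hardware

A deterministic discrete-event simulator. Time advances only through
operations: timed waits by their argument, temperature waits by
|ΔT|/ramp, motions by fixed per-verb costs; set-points are instantaneous.
Liquid moves only during WAIT steps and only while a complete path is
active (correct valves open, line pressurized, vessel sealed at the right
station); a transfer moves the entire source contents in one dwell —
flow-rate modeling is out of scope, and the published practice of sizing
transfer durations empirically is mirrored by the operator override
instead.

The ledger is closed: vials + vessels + waste + collected + HPLC loop +
vapor equals initial vial volumes + external inputs (the trapped
target-water bolus, external additions) after every operation, to
≤ 1e−9 mL. Evaporation removes tracked volume at a fixed rate while the
evaporation path is active; all tracked volume is solvent, and solutes —
including the radiolabel — are massless labels that stay put. Cartridge
chemistry (QMA trap/elute, purification train) is routing plus label
transformation only: retention efficiencies are deliberately not modeled,
so the label routes ideally (100 %) with the aqueous/eluate stream.

Model parameters (config, with defaults): vessel capacity 5.0 mL (no
published reactor volume; it must exceed the FDG program's ~2.5 mL peak
load), heater ramp 2 °C/s, evaporation rate 0.005 mL/s, target-water
bolus 1.0 mL at relative activity 1.0, and per-verb motion costs of a few
seconds each. Timing-dependent tests use these values symbolically, so
retuning the config does not invalidate them. With the defaults the full
FDG run spans 3107 s (≈ 52 min) of simulated time.

## The run engine

Execution is synchronous in *simulated* time: snapshots are taken on a
fixed grid of the simulator clock (default 4 per simulated second), which
makes runs fast and exactly reproducible while preserving the
floor(d·hz)±1 per-phase snapshot count a wall-clock logger would give.
PROMPT, INSTALL and EXTERNALADD block awaiting acknowledgment (an
EXTERNALADD acknowledgment is the moment the declared reagent volume
enters the vessel). The dwell phases of REACT, EVAPORATE and MIX — the
operations whose optimal length is found empirically — are operator
adjustable: because the run is synchronous, "pressing override at
t seconds into the dwell" is expressed by scheduling `(action,
at_elapsed_s)` on the handle before the dwell executes; `finish_now`
truncates, `extend` holds the dwell open until a later `finish_now`. The
recorded per-operation durations are actuals, not programmed values.

The run record is an append-only JSON-lines file (header, op start/done,
snapshots, prompts/responses, overrides, terminal status), flushed per
event. Resume reads the record, silently re-executes the completed prefix
(replaying recorded overrides — determinism makes this exact), and
continues appending; crash points are modeled at operation boundaries
only. A resumed run's final state is bit-identical (by state digest) to an
uninterrupted run. Notification hooks (run start/complete/fail and COMMENT
checkpoints) are isolated: a raising hook is logged and never alters the
run.

## Activity accounting

Decay follows A(t) = A(0)·2^(−t/t½) with the F-18 half-life 6586.2 s
(109.77 min, the standard physical constant). The decay-corrected
radiochemical yield is 100·(product/start)/2^(−Δt/t½). Routing never
creates or destroys label, so total decayed activity is conserved through
any sequence of trap/elute/transfer moves; per-reactor sensor readings
report the decayed ledger entry for whatever label currently sits in each
vessel. Published yield figures for the real chemistry (decay-corrected
65 % ± 2 %, uncorrected 52 %) depend on activity timestamps that are not
printed and on real cartridge losses, so they are outside what this
idealized model can or should reproduce; the arithmetic that produces
them is what is implemented and tested.

## What the synthetic programs do and do not show

The random-program generator emulates the *space of authorable programs*
(all fourteen kinds, parameters uniform inside their permitted ranges,
reagent references drawn from a generated layout), not chemically
sensible syntheses. Passing the generator-closure and safety-closure
properties therefore demonstrates that validation, compilation and the
interlock rules are total over the program space — it says nothing about
chemical yield or the wisdom of any particular sequence, which is exactly
the division of labor the unit-operation paradigm intends.

## Known limitations

* No pressure dynamics, thermodynamics beyond linear set-point ramps, or
  radiolysis/yield chemistry; no cartridge retention efficiencies.
* Transfers and dispenses are all-or-nothing per dwell; durations do not
  limit moved volume.
* Mid-expansion resume is unsupported (operation boundaries only).
* The expansion table is a calibrated reconstruction; only its aggregate
  count for the FDG protocol is externally anchored.
* Cited program-step counts for other vendors' synthesizers are stored
  literals for context reporting, never recomputed — including one
  internally inconsistent pair (72 vs 87 steps for the same FLT program)
  that is preserved verbatim with both values flagged.
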
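# Program file format

A synthesis program serializes to a line-oriented, UTF-8 plain-text file
(`save_program` / `load_program`) and, equivalently, to a key-value tree
(`program_to_dict` / `program_from_dict`) for machine exchange.

## Text format

Blank lines are ignored; `#` starts a comment. Three stanza kinds, one per
line, quoted with shell-style rules (double quotes, backslash escapes):

```
program "<name>"
reagent <cassette>.<position> "<name>" volume=<mL> [desc="<description>"]
op <KIND> key=value ...
```

* `program` — at most one; names the program.
* `reagent` — one per vial. `<cassette>` is 1–3, `<position>` 1–11,
  `volume` in (0, 3.0] mL. Names must be unique; slots must not collide.
* `op` — one per unit operation, in execution order. `<KIND>` is one of
  `INITIALIZE`, `ADD`, `EVAPORATE`, `TRANSFER`, `REACT`, `PROMPT`,
  `INSTALL`, `COMMENT`, `TRAPF18`, `ELUTEF18`, `MIX`, `EXTERNALADD`,
  `TRANSFERTOHPLC`, `MEASURERADIATION`. Keys are the operation's field
  names; values are `true`/`false`, integers, floats or strings.
  **Omitted optional keys stay unset** and receive defaults at
  compile/validation time, so a round trip preserves whether a value was
  explicit or defaulted.

Errors: malformed lines raise a parse error carrying the 1-based line
number; an unknown `<KIND>` or invalid parameter set raises a schema
violation carrying the 1-based op index.

Example (`examples/fdg.program` is the full reference protocol):

```
# unitops program file v1
program "FDG (one-pot)"
reagent 1.6 "Mannose triflate" volume=1 desc="30 mg mannose triflate dissolved in 1.0 mL acetonitrile"
reagent 1.7 HCl volume=1 desc="1.0 mL of 1 N HCl"
op ADD reagent_name="Mannose triflate" reactor=1 delivery_position=1
op REACT reactor=1 reaction_temp_C=130 reaction_position=1 duration_s=300 final_temp_C=35 cool_delay_s=120
```

## Per-kind parameters

| kind             | required                                            | optional (default)                          |
|------------------|-----------------------------------------------------|---------------------------------------------|
| INITIALIZE       | —                                                   | —                                           |
| ADD              | reagent_name, reactor, delivery_position (1–2)      | pressure_psi (3), duration_s (15)           |
| EVAPORATE        | reactor, evaporation_temp_C, evaporation_pressure_psi, duration_s | final_temp_C (35), stir_speed (0) |
| TRANSFER         | source_reactor, target_reactor, mode (Trap\|Elute)  | pressure_psi (10), duration_s (30)          |
| REACT            | reactor, reaction_temp_C, reaction_position (1–2), duration_s, final_temp_C | stir_speed (0), cool_delay_s (0) |
| PROMPT           | message                                             | —                                           |
| INSTALL          | reactor, message                                    | —                                           |
| COMMENT          | comment                                             | —                                           |
| TRAPF18          | reactor, duration_s                                 | cyclotron_flag (false), pressure_psi (3)    |
| ELUTEF18         | reactor, reagent_name, duration_s                   | pressure_psi (3)                            |
| MIX              | reactor, duration_s, stir_speed                     | —                                           |
| EXTERNALADD      | reactor, reagent_name, message                      | —                                           |
| TRANSFERTOHPLC   | source_reactor, mobile_phase_reagent_name           | —                                           |
| MEASURERADIATION | reactor                                             | —                                           |

Every op also accepts a free-text `note`. Reactor fields are 1–3;
temperatures −20…200 °C; pressures 0…60 psi; stir 0…100; durations ≥ 0.
`TRANSFER` with mode `Elute` and `target_reactor == source_reactor`
addresses the cassette output line to the product collection vial.

## Structured form

`program_to_dict` produces the JSON/YAML-friendly tree validated by the
same pydantic models:

```json
{
  "name": "FDG (one-pot)",
  "layout": {
    "reagents": [
      {"cassette_id": 1, "position": 6, "name": "Mannose triflate",
       "description": "…", "volume_mL": 1.0}
    ],
    "n_cassettes": 3,
    "slots_per_cassette": 11
  },
  "ops": [
    {"kind": "ADD", "reagent_name": "Mannose triflate", "reactor": 1,
     "delivery_position": 1, "pressure_psi": null, "duration_s": null,
     "note": ""}
  ]
}
```

`null` means "unset, use the default" — identical semantics to an omitted
key in the text format.
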
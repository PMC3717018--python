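"""Radioactive decay arithmetic and simulated radiation readings.

F-18 decays with a 109.77-min half-life; a decay-corrected radiochemical
yield divides the measured product/start activity ratio by the decay
factor over the synthesis, isolating the chemistry from the physics.
"""

from unitops import (
    F18,
    build_fdg_program,
    compile_program,
    decay_corrected_yield,
    decay_factor,
    initial_state,
    ledger_from_state,
    run_llops,
    sensor_readings,
)

elapsed = 45 * 60   # a 45-minute synthesis
f = decay_factor(F18, elapsed)
print(f"F-18 half-life:        {F18.half_life_s} s ({F18.half_life_s / 60:.2f} min)")
print(f"decay factor (45 min): {f:.4f}")
print(f"semigroup check:       {decay_factor(F18, 2 * elapsed):.6f} == "
      f"{f * f:.6f}")

# an uncorrected yield of 52% measured 45 min after start
corrected = decay_corrected_yield(52.0, 100.0, elapsed)
print(f"uncorrected 52% at 45 min -> decay-corrected {corrected:.1f}%")

# readings over the simulated FDG run: the label enters on the QMA, moves
# with the eluate into reactor 1, and leaves with the product
program = build_fdg_program()
final, _ = run_llops(
    initial_state(layout=program.layout),
    list(compile_program(program).llops),
)
ledger = ledger_from_state(final)
print(f"\nsimulated run end at {final.clock_s:.0f} s:")
print(f"per-reactor sensors:   {sensor_readings(final)}")
print(f"decayed total:         {ledger.total_at(final.clock_s):.4f} "
      f"(= start x {decay_factor(F18, final.clock_s):.4f})")
print(f"label in collection:   {ledger.at(final.clock_s)['collected']:.4f}")
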
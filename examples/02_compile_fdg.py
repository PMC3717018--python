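"""Compile the reference FDG protocol into low-level hardware operations.

The 18 chemist-facing unit operations expand to 476 atomic instrument
actions (motions, seals, valve switches, set-points, waits). The static
safety checker proves the stream respects the interlock ordering rules.
"""

from collections import Counter

from unitops import (
    build_fdg_program,
    check_safety,
    compile_program,
    program_metrics,
)

program = build_fdg_program()
metrics = program_metrics(program)
compiled = compile_program(program)
violations = check_safety(compiled)

print(f"program:        {program.name}")
print(f"unit ops:       {metrics.n_unit_ops}   reagents: {metrics.n_reagents}")
print(f"low-level ops:  {compiled.n_llops}")
print(f"safety:         {len(violations)} violations")

verbs = Counter(l.verb for l in compiled.llops)
print("\nverb histogram:")
for verb, count in verbs.most_common():
    print(f"  {verb:<14} {count}")

print("\nexpansion of op 9 (ADD mannose triflate):")
for llop in compiled.by_origin()[9]:
    print(f"  {llop.render()}")
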
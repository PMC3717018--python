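"""Author a small synthesis program in Python and validate it.

Builds a two-reagent layout and a four-operation program (add, react,
add, mix), then shows what the validator reports when a parameter is out
of range or a reagent name does not resolve.
"""

from unitops import (
    AddOp,
    CassetteLayout,
    MixOp,
    ReactOp,
    SynthesisProgram,
    apply_defaults,
    define_reagent,
    insert_op,
    program_metrics,
    save_program,
    validate_program,
)

layout = CassetteLayout()
layout = define_reagent(layout, 1, 1, "Precursor",
                        "5 mg precursor in 1 mL MeCN", volume_mL=1.0)
layout = define_reagent(layout, 1, 2, "Quench", "2 mL water", volume_mL=2.0)

program = SynthesisProgram(
    name="demo labeling",
    layout=layout,
    ops=(
        AddOp(reagent_name="Precursor", reactor=1, delivery_position=1),
        ReactOp(reactor=1, reaction_temp_C=95, reaction_position=1,
                duration_s=600, final_temp_C=30),
        AddOp(reagent_name="Quench", reactor=1, delivery_position=2),
        MixOp(reactor=1, duration_s=60, stir_speed=50),
    ),
)

issues = validate_program(program)
metrics = program_metrics(program)
print(f"program:      {program.name}")
print(f"unit ops:     {metrics.n_unit_ops}, reagents: {metrics.n_reagents}")
print(f"issues:       {issues or 'none — program is runnable'}")

# unset secondary parameters (gas pressure, delivery time) get defaults
add = apply_defaults(program.ops[0])
print(f"ADD defaults: pressure {add.pressure_psi} psi, {add.duration_s} s delivery")

# a temperature outside the permitted range is reported, not raised
too_hot = ReactOp(reactor=1, reaction_temp_C=250, reaction_position=1,
                  duration_s=60, final_temp_C=25)
broken = insert_op(program, too_hot, 3)
for issue in validate_program(broken):
    print(f"reported:     op {issue.op_index} [{issue.code}] {issue.message}")

print("\nprogram file representation:\n")
print(save_program(program))
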
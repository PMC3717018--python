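"""Program model: layout, defaults, validation, edits, metrics, round trips."""

import pytest
from hypothesis import given, settings, strategies as st

from unitops import (
    AddOp,
    CassetteLayout,
    EluteF18Op,
    ReactOp,
    apply_defaults,
    build_fdg_layout,
    define_reagent,
    delete_op,
    insert_op,
    load_program,
    move_op,
    program_from_dict,
    program_metrics,
    program_to_dict,
    random_program,
    resolve_reagent,
    save_program,
    validate_program,
)
from unitops.errors import (
    EditIndexError,
    LayoutError,
    ProgramParseError,
    SchemaViolation,
    UnknownReagentError,
)
from unitops.program_model import SynthesisProgram


class TestLayout:
    def test_fdg_layout_has_seven_named_reagents(self):
        layout = build_fdg_layout()
        assert len(layout.reagents) == 7
        assert layout.names() >= {"Eluent", "Mannose triflate", "HCl"}

    @pytest.mark.parametrize(
        "name, slot", [("Mannose triflate", (1, 6)), ("HCl", (1, 7)), ("Eluent", (1, 2))]
    )
    def test_resolve_reagent_returns_storage_slot(self, fdg_program, name, slot):
        assert resolve_reagent(fdg_program, name) == slot

    def test_resolve_unknown_name_raises(self, fdg_program):
        with pytest.raises(UnknownReagentError):
            resolve_reagent(fdg_program, "Unobtainium")

    @pytest.mark.parametrize(
        "kwargs, code",
        [
            (dict(cassette_id=1, position=12, name="X"), "out-of-range-slot"),
            (dict(cassette_id=4, position=1, name="X"), "out-of-range-slot"),
            (dict(cassette_id=1, position=6, name="X"), "slot-occupied"),
            (dict(cassette_id=2, position=1, name="HCl"), "duplicate-name"),
            (dict(cassette_id=2, position=1, name="X", volume_mL=3.1),
             "volume-over-capacity"),
            (dict(cassette_id=2, position=1, name="X", volume_mL=0.0),
             "volume-over-capacity"),
            (dict(cassette_id=2, position=1, name=""), "empty-name"),
        ],
    )
    def test_define_reagent_rejections(self, kwargs, code):
        layout = build_fdg_layout()
        with pytest.raises(LayoutError) as err:
            define_reagent(layout, **kwargs)
        assert err.value.code == code

    def test_vial_capacity_boundary_accepts_three_mL(self):
        layout = define_reagent(CassetteLayout(), 1, 1, "Full vial", volume_mL=3.0)
        assert layout.by_name("Full vial").volume_mL == 3.0

    def test_define_reagent_leaves_input_unchanged(self):
        layout = build_fdg_layout()
        define_reagent(layout, 3, 1, "New")
        assert len(layout.reagents) == 7


class TestDefaults:
    def test_add_defaults_fill_pressure_and_time(self):
        op = apply_defaults(AddOp(reagent_name="MeCN-2", reactor=1, delivery_position=1))
        assert (op.pressure_psi, op.duration_s) == (3.0, 15.0)

    def test_explicit_values_never_overwritten(self):
        op = AddOp(reagent_name="X", reactor=1, delivery_position=2,
                   pressure_psi=7.5, duration_s=99)
        assert apply_defaults(op) == op

    def test_react_cool_delay_defaults_to_zero(self):
        op = apply_defaults(ReactOp(reactor=1, reaction_temp_C=130,
                                    reaction_position=1, duration_s=300,
                                    final_temp_C=35))
        assert op.cool_delay_s == 0.0

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_apply_defaults_idempotent(self, seed):
        for op in random_program(seed, n_ops=8).ops:
            once = apply_defaults(op)
            assert apply_defaults(once) == once


class TestValidation:
    def test_fdg_program_is_runnable(self, fdg_program):
        assert validate_program(fdg_program) == []

    def test_unresolved_reagent_reported_with_op_index(self, fdg_program):
        bad = insert_op(
            fdg_program,
            EluteF18Op(reactor=1, reagent_name="Eluent2", duration_s=10),
            4,
        )
        issues = validate_program(bad)
        assert [(i.op_index, i.code) for i in issues] == [(4, "unresolved-reagent")]

    def test_out_of_range_temperature_reported(self, fdg_program):
        hot = ReactOp(reactor=1, reaction_temp_C=250, reaction_position=1,
                      duration_s=10, final_temp_C=25)
        issues = validate_program(insert_op(fdg_program, hot, 1))
        assert [(i.op_index, i.code) for i in issues] == [(1, "param-out-of-range")]

    def test_empty_program_not_runnable(self):
        empty = SynthesisProgram(name="empty", layout=build_fdg_layout())
        assert [i.code for i in validate_program(empty)] == ["empty-program"]

    def test_validation_is_pure(self, fdg_program):
        before = save_program(fdg_program)
        validate_program(fdg_program)
        assert save_program(fdg_program) == before


class TestEditing:
    def test_move_onto_itself_is_identity(self, fdg_program):
        assert move_op(fdg_program, 3, 3) == fdg_program

    def test_delete_then_insert_restores(self, fdg_program):
        op = fdg_program.ops[9]
        assert insert_op(delete_op(fdg_program, 10), op, 10) == fdg_program

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10**6), data=st.data())
    def test_move_there_and_back_is_identity(self, seed, data):
        program = random_program(seed, n_ops=10)
        a = data.draw(st.integers(1, 10))
        b = data.draw(st.integers(1, 10))
        assert move_op(move_op(program, a, b), b, a) == program

    def test_edits_never_touch_layout(self, fdg_program):
        edited = delete_op(fdg_program, 1)
        assert edited.layout == fdg_program.layout

    def test_out_of_range_indices_raise(self, fdg_program):
        with pytest.raises(EditIndexError):
            delete_op(fdg_program, 19)
        with pytest.raises(EditIndexError):
            move_op(fdg_program, 0, 5)

    def test_install_after_fluorination_gives_19_ops(self, fdg_with_install):
        assert fdg_with_install.n_ops == 19
        assert fdg_with_install.ops[10].kind == "INSTALL"


class TestMetrics:
    def test_fdg_counts(self, fdg_program):
        m = program_metrics(fdg_program)
        assert (m.n_unit_ops, m.n_reagents) == (18, 7)
        assert m.per_kind_counts["ADD"] == 5
        assert m.per_kind_counts["TRANSFER"] == 3
        assert sum(m.per_kind_counts.values()) == m.n_unit_ops

    def test_empty_program_counts_zero(self):
        empty = SynthesisProgram(name="empty", layout=CassetteLayout())
        assert program_metrics(empty).n_unit_ops == 0

    def test_metrics_add_under_concatenation(self, fdg_program):
        doubled = fdg_program.model_copy(
            update={"ops": fdg_program.ops + fdg_program.ops}
        )
        single = program_metrics(fdg_program).per_kind_counts
        double = program_metrics(doubled).per_kind_counts
        assert double == {k: 2 * v for k, v in single.items()}


class TestSerialization:
    def test_fdg_round_trip(self, fdg_program):
        assert load_program(save_program(fdg_program)) == fdg_program

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_random_program_round_trip(self, seed):
        program = random_program(seed, n_ops=12)
        assert load_program(save_program(program)) == program

    def test_dict_round_trip(self, fdg_program):
        assert program_from_dict(program_to_dict(fdg_program)) == fdg_program

    def test_unknown_kind_is_schema_violation_with_op_index(self, fdg_program):
        text = save_program(fdg_program).replace("op TRAPF18", "op FROBNICATE")
        with pytest.raises(SchemaViolation) as err:
            load_program(text)
        assert err.value.op_index == 2

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ProgramParseError) as err:
            load_program('program "x"\nreagent nonsense\n')
        assert err.value.line_no == 2
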
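"""Run engine: snapshots, prompts, overrides, resume, batch records."""

import math
import os

import pytest

from unitops import (
    RunOptions,
    export_batch_record,
    insert_op,
    load_run_record,
    resume_run,
    start_run,
    state_fingerprint,
)
from unitops.errors import RunError
from unitops.program_model import EluteF18Op, PromptOp


def _run_all(handle, ack="ok"):
    status = handle.run_to_completion(ack)
    handle.close()
    return status


@pytest.fixture()
def persist(tmp_path):
    return str(tmp_path / "run.jsonl")


class TestStart:
    def test_start_validates_first(self, fdg_program, persist):
        bad = insert_op(
            fdg_program, EluteF18Op(reactor=1, reagent_name="Ghost", duration_s=5), 3
        )
        with pytest.raises(RunError) as err:
            start_run(bad, options=RunOptions(persist_path=persist))
        assert err.value.code == "validation-failed"
        assert "Ghost" in str(err.value)

    def test_record_persisted_before_first_op(self, fdg_program, persist):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        assert handle.status == "running" and handle.op_index == 1
        record = load_run_record(persist)   # readable immediately
        assert record.program == fdg_program
        assert record.completed_ops == 0
        handle.close()


class TestAdvance:
    def test_full_fdg_run_records_18_durations(self, fdg_program, persist):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        assert _run_all(handle) == "completed"
        record = load_run_record(persist)
        assert sorted(record.op_durations) == list(range(1, 19))
        assert all(d["actual_duration_s"] > 0 for d in record.op_durations.values())
        assert record.status == "completed"

    def test_initialize_does_not_prompt(self, fdg_program, persist):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        assert handle.advance() == "running"
        assert handle.op_index == 2
        handle.close()

    def test_snapshot_density_matches_four_per_second(self, fdg_program, persist):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        _run_all(handle)
        record = load_run_record(persist)
        expected = math.floor(handle.state.clock_s * 4.0)
        # one grid slip allowed per op boundary
        assert abs(len(record.snapshots) - expected) <= 18
        clocks = [s["clock_s"] for s in record.snapshots]
        assert clocks == sorted(clocks)
        assert max(b - a for a, b in zip(clocks, clocks[1:])) == pytest.approx(0.25)


class TestPrompts:
    def test_install_blocks_until_acknowledged(self, fdg_with_install, persist):
        handle = start_run(fdg_with_install, options=RunOptions(persist_path=persist))
        for _ in range(10):
            assert handle.advance() == "running"
        assert handle.advance() == "awaiting-prompt"
        assert "TLC" in handle.pending_prompt
        with pytest.raises(RunError) as err:
            handle.advance()
        assert err.value.code == "awaiting-prompt"
        assert handle.respond_prompt("sample taken") == "running"
        assert handle.op_index == 12
        handle.close()

    def test_respond_while_running_is_an_error(self, fdg_program, persist):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        with pytest.raises(RunError) as err:
            handle.respond_prompt("ok")
        assert err.value.code == "not-awaiting-prompt"
        handle.close()

    def test_transcript_matches_prompting_ops(self, fdg_with_install, persist):
        program = insert_op(
            fdg_with_install, PromptOp(message="verify dose calibrator"), 1
        )
        handle = start_run(program, options=RunOptions(persist_path=persist))
        _run_all(handle, ack="done")
        record = load_run_record(persist)
        prompting = sum(
            1 for op in program.ops if op.kind in ("PROMPT", "INSTALL", "EXTERNALADD")
        )
        assert prompting == 2
        assert len([e for e in record.prompts if e["event"] == "prompt"]) == prompting
        assert len([e for e in record.prompts if e["event"] == "response"]) == prompting


class TestOverride:
    @pytest.fixture()
    def react_reference_s(self, fdg_program, tmp_path):
        """Actual duration of op 10 (REACT, 300 s dwell) with no override."""
        path = str(tmp_path / "nooverride.jsonl")
        handle = start_run(fdg_program, options=RunOptions(persist_path=path))
        for _ in range(10):
            handle.advance()
        handle.close()
        return load_run_record(path).op_durations[10]["actual_duration_s"]

    def test_finish_now_truncates_the_dwell(self, fdg_program, persist,
                                            react_reference_s):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        for _ in range(9):
            handle.advance()
        baseline = load_run_record(persist)
        handle.override_timer("finish_now", 100.0)   # op 10: REACT, 300 s dwell
        handle.advance()
        handle.close()
        record = load_run_record(persist)
        d = record.op_durations[10]
        # the 300 s dwell ran for 100 s; ramps and motions are untouched
        assert react_reference_s - d["actual_duration_s"] == pytest.approx(200.0)
        assert record.overrides[-1]["action"] == "finish_now"
        assert baseline.overrides == []

    def test_extend_then_finish_runs_past_programmed_time(self, fdg_program, persist,
                                                          react_reference_s):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        for _ in range(9):
            handle.advance()
        handle.override_timer("extend", 250.0)
        handle.override_timer("finish_now", 450.0)
        handle.advance()
        handle.close()
        d = load_run_record(persist).op_durations[10]
        # dwell held open past 300 s and finished at 450 s
        assert d["actual_duration_s"] - react_reference_s == pytest.approx(150.0)

    def test_override_needs_an_adjustable_phase(self, fdg_program, persist):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        # op 1 is INITIALIZE: nothing to adjust
        with pytest.raises(RunError) as err:
            handle.override_timer("finish_now", 5.0)
        assert err.value.code == "no-timed-phase-active"
        for _ in range(6):
            handle.advance()
        # op 7 is ADD: delivery time is not operator-adjustable
        with pytest.raises(RunError):
            handle.override_timer("finish_now", 5.0)
        handle.close()


class TestResume:
    def test_resume_mid_run_reproduces_uninterrupted_state(self, fdg_program,
                                                           tmp_path):
        ref = start_run(
            fdg_program, options=RunOptions(persist_path=str(tmp_path / "ref.jsonl"))
        )
        _run_all(ref)
        reference = state_fingerprint(ref.state)

        for boundary in (1, 9, 17):
            path = str(tmp_path / f"crash{boundary}.jsonl")
            crashed = start_run(fdg_program, options=RunOptions(persist_path=path))
            for _ in range(boundary):
                crashed.advance()
            pre_crash = len(load_run_record(path).snapshots)
            crashed.close()   # simulated crash at the op boundary
            resumed = resume_run(path)
            assert resumed.op_index == boundary + 1
            _run_all(resumed)
            assert state_fingerprint(resumed.state) == reference
            record = load_run_record(path)
            assert record.status == "completed"
            assert len(record.snapshots) >= pre_crash

    def test_resume_replays_recorded_overrides(self, fdg_program, persist):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        for _ in range(9):
            handle.advance()
        handle.override_timer("finish_now", 100.0)
        handle.advance()   # op 10 with shortened dwell
        clock_after_10 = handle.state.clock_s
        handle.close()
        resumed = resume_run(persist)
        assert resumed.state.clock_s == pytest.approx(clock_after_10)
        _run_all(resumed)
        assert resumed.status == "completed"

    def test_resume_of_terminal_record_refused(self, fdg_program, persist):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        _run_all(handle)
        with pytest.raises(RunError) as err:
            resume_run(persist)
        assert err.value.code == "record-terminal"

    def test_resume_of_missing_record_refused(self, tmp_path):
        with pytest.raises(RunError) as err:
            resume_run(str(tmp_path / "nope.jsonl"))
        assert err.value.code == "record-missing"


class TestNotifyHook:
    def test_hook_sees_start_comments_and_completion(self, fdg_program, persist):
        from unitops.program_model import CommentOp

        program = insert_op(fdg_program, CommentOp(comment="eluent loaded"), 2)
        events = []
        handle = start_run(
            program,
            options=RunOptions(
                persist_path=persist, notify_hook=lambda e, p: events.append(e)
            ),
        )
        _run_all(handle)
        assert events == ["start", "comment", "complete"]

    def test_raising_hook_never_changes_the_outcome(self, fdg_program, tmp_path):
        def bomb(event, payload):
            raise RuntimeError("notification transport down")

        quiet = start_run(
            fdg_program, options=RunOptions(persist_path=str(tmp_path / "a.jsonl"))
        )
        _run_all(quiet)
        noisy = start_run(
            fdg_program,
            options=RunOptions(persist_path=str(tmp_path / "b.jsonl"),
                               notify_hook=bomb),
        )
        _run_all(noisy)
        assert noisy.status == "completed"
        assert state_fingerprint(noisy.state) == state_fingerprint(quiet.state)
        errors = [e for e in load_run_record(str(tmp_path / "b.jsonl")).events
                  if e["event"] == "notify-error"]
        assert errors   # failure was logged, not raised


class TestBatchRecord:
    def test_report_lists_all_ops_in_order(self, fdg_program, persist):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        for _ in range(9):
            handle.advance()
        handle.override_timer("finish_now", 100.0)
        _run_all(handle)
        text = export_batch_record(persist)
        lines = text.splitlines()
        op_lines = [l for l in lines if l[:3].strip().isdigit()]
        assert len(op_lines) == 18
        assert [int(l.split()[0]) for l in op_lines] == list(range(1, 19))
        assert "finish_now at 100.0 s" in text
        assert "status:        completed" in text

    def test_non_terminal_run_cannot_be_exported(self, fdg_program, persist):
        handle = start_run(fdg_program, options=RunOptions(persist_path=persist))
        handle.advance()
        handle.close()
        with pytest.raises(RunError) as err:
            export_batch_record(persist)
        assert err.value.code == "run-not-terminal"
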
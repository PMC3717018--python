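"""Run a program with the full production semantics.

Shows the prompt/acknowledge cycle (INSTALL pauses for a TLC sample), an
operator override shortening a reaction dwell, a simulated crash at an
operation boundary with resume, and the exported batch record.
"""

import os
import tempfile

from unitops import (
    RunOptions,
    build_fdg_with_install,
    export_batch_record,
    load_run_record,
    resume_run,
    start_run,
    state_fingerprint,
)

program = build_fdg_with_install()          # FDG + INSTALL after fluorination
tmp = tempfile.mkdtemp()
path = os.path.join(tmp, "run.jsonl")

handle = start_run(program, options=RunOptions(persist_path=path))
while handle.status == "running" and handle.op_index <= 9:
    handle.advance()

# op 10 is the fluorination REACT: finish its 300-s dwell after 120 s
handle.override_timer("finish_now", 120.0)
status = handle.advance()
print(f"after override:   op {handle.op_index}, status {status}")

status = handle.advance()                   # op 11: INSTALL blocks
print(f"prompt:           {handle.pending_prompt!r}")
handle.respond_prompt("TLC sample taken")

handle.advance()                            # op 12 done; now simulate a crash
handle.close()
print(f"crashed after:    op {handle.op_index - 1} "
      f"at {handle.state.clock_s:.1f} s simulated")

resumed = resume_run(path)
print(f"resumed at:       op {resumed.op_index}")
resumed.run_to_completion()
resumed.close()
print(f"final status:     {resumed.status}")
print(f"state digest:     {state_fingerprint(resumed.state)[:16]}…")

record = load_run_record(path)
print(f"snapshots logged: {len(record.snapshots)} "
      f"(4 per simulated second)")
print("\nbatch record (head):")
print("\n".join(export_batch_record(path).splitlines()[:16]))
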
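"""Full synthetic end-to-end run: census + readout + ITC with stage checks.

Equivalent to `myb demo --seed 1 --out-dir demo_out`; writes report.json
and report.md into the output directory and prints the stage checks.
"""

import json
import sys

from mybdna.pipeline import run_demo

out_dir = sys.argv[1] if len(sys.argv) > 1 else "demo_out"
report = run_demo(seed=1, out_dir=out_dir)
print(json.dumps(report["checks"], indent=1))
print(f"all stage checks pass: {report['all_checks_pass']}")
print(f"report written to {out_dir}/report.md")
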
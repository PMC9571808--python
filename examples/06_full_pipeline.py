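"""The whole chain as one call: simulate → preprocess → features → select →
classify → quantify, with every artifact written to a run directory.

Equivalent to the CLI:  cyclenose all --fixture tiny --seed 5 --out <dir>
"""

import tempfile
from pathlib import Path

from cyclenose import make_fixtures, run_pipeline

config = make_fixtures("tiny", seed=5)
with tempfile.TemporaryDirectory() as tmp:
    out = run_pipeline(config, Path(tmp) / "run")
    print("artifacts:")
    for p in sorted(out.iterdir()):
        print("  ", p.name)
    print()
    print((out / "report.md").read_text())
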
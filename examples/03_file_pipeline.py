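"""File-based pipeline with manifest, checksums and resume.

Runs a reduced pipeline twice in a temporary directory: the first run
executes every stage and records per-file checksums in a manifest; the
second run verifies the checksums and skips everything.  Equivalent CLI:

    sfmap run --seed 5 --output-dir /tmp/sfmap_demo --config small.yaml

Run:  python examples/03_file_pipeline.py
"""

import tempfile
import time
from pathlib import Path

from sfmap.pipeline import desk_config, run_pipeline

root = Path(tempfile.mkdtemp(prefix="sfmap_demo_"))
config = desk_config(seed=5, output_dir=str(root), n_eyes=10, epochs=5)

print(f"first run (all stages) in {root} ...")
t0 = time.perf_counter()
manifest = run_pipeline(config)
print(f"  finished in {time.perf_counter() - t0:.1f}s")
for stage, rec in manifest.stages.items():
    print(f"  {stage:10s} {len(rec['files']):3d} files  "
          f"{rec['elapsed_s']:6.1f}s")

print("\nsecond run (everything clean, stages skipped) ...")
t0 = time.perf_counter()
run_pipeline(config)
print(f"  finished in {time.perf_counter() - t0:.1f}s")

print("\noutputs:")
for p in sorted(root.rglob("*")):
    if p.is_file() and p.parts[-2:][0] != "volumes":
        print(f"  {p.relative_to(root)}")
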
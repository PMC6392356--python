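"""Run the end-to-end pipeline and write every result table + manifest.

Uses the bundled synthetic study conditions (no input paths configured)
with scaled-down resampling sizes so the demo finishes in about a minute.
Outputs land under scratch/pipeline_demo/.
"""

import json
from pathlib import Path

import reefranges as rr

cfg = rr.RunConfig(out_dir="scratch/pipeline_demo", seed=7,
                   n_draws=2000, n_replicates=25)
out_dir = rr.run_pipeline(cfg)

manifest = json.loads((Path(out_dir) / "manifest.json").read_text())
print("outputs:", ", ".join(manifest["outputs"]))
print("species:", manifest["n_species"], "| focal:", manifest["n_focal"])
print("null-model characteristics flagged:",
      manifest["null_model_n_significant"])
# Re-running with the same config reproduces every CSV byte-for-byte; the
# manifest records all seeds actually consumed.
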
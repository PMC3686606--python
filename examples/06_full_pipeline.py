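"""Run the complete pipeline and inspect the run manifest.

Equivalent to `bicarotid all --config cfg.yaml --outdir out/`: simulate (or
ingest a CSV), apply exclusions, classify, and write the medians,
concordance, phenotype, diagnostics and Cox reports plus a manifest whose
row counts always reconcile.
"""

import json
import tempfile
from pathlib import Path

from bicarotid import run_pipeline

config = {
    "simulate": {"n_subjects": 7437, "seed": 42, "p_prevalent_stroke": 0.022},
    "n_boot": 500,
}
outdir = Path(tempfile.mkdtemp()) / "run"
manifest = run_pipeline(config, outdir)

print("outputs:", sorted(p.name for p in outdir.iterdir()))
print(json.dumps({
    "stage_counts": manifest.stage_counts,
    "exclusions": manifest.exclusions,
}, indent=2))
# loaded - missing_measures - prevalent_stroke == analysis == classified:
# the subject-flow ledger reconciles exactly, and a rerun with the same
# seed regenerates every report byte-for-byte.
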
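"""The whole study in one call: simulate -> extract -> compare -> train -> predict.

Writes per-subject EDFs and a manifest, extracts features back out of the
EDFs, runs the group comparison, trains the nested-CV model on the
discovery cohort and predicts an independent validation cohort — all the
artifacts land as plain TSV/JSON in the output directory.
"""

import json
import tempfile
from pathlib import Path

from eegsync.config import PipelineConfig, SimulateConfig
from eegsync.pipeline import run_pipeline

cfg = PipelineConfig(seed=3)
cfg.simulate = SimulateConfig(
    n_subjects=30, n_validation=8, n_channels=4, duration_s=10.0,
    responder_coupling=0.8, nonresponder_coupling=0.4)
cfg.model.outer_k = 5
cfg.model.c_grid = [0.1, 1.0, 10.0]
cfg.model.k_grid = [5, 15, 43]

with tempfile.TemporaryDirectory() as out:
    artifacts = run_pipeline(cfg, out)
    for stage, path in artifacts.items():
        print(f"{stage:>9}: {Path(path).name}")
    report = json.loads(Path(artifacts["train"]).read_text())
    print(f"\ndiscovery nested-CV: accuracy {report['accuracy']:.3f}, "
          f"precision {report['precision']:.3f}, AUC {report['auc']:.3f}")
    val = json.loads((Path(out) / "validation_summary.json").read_text())
    print(f"external validation: accuracy {val['external_accuracy']:.3f} "
          f"on {val['n_external']} held-out subjects")
print("\nEvery artifact embeds the config hash and seed; rerunning with "
      "the same config reproduces the files byte-for-byte.")
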
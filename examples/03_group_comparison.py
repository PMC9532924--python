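"""Responder vs non-responder comparison of the synchronization features.

Generates a 70-child synthetic cohort in which responders carry stronger
high-beta phase coupling (0.8 vs 0.4), extracts per-subject PLI in the
five tested bands, and runs the Mann-Whitney + Benjamini-Hochberg battery.
Only the high-beta row (and sometimes its low-beta neighbour, which the
oscillator's spectral skirt touches) should reach significance.
"""

import pandas as pd

from eegsync import (
    CohortSpec,
    CouplingSpec,
    PreprocessConfig,
    compare_sync_by_group,
    extract_sync_features,
    generate_cohort,
)
from eegsync.recording import TESTED_BANDS

spec = CohortSpec(
    n_subjects=70, responder_fraction=37 / 70,
    responder_coupling=CouplingSpec(coupling_strength=0.8),
    nonresponder_coupling=CouplingSpec(coupling_strength=0.4),
    duration_s=8.0, n_channels=3, fs=250.0, seed=0,
)
rows, labels = [], []
for subj in generate_cohort(spec):
    vec = extract_sync_features(subj.recording, bands=TESTED_BANDS,
                                montage_pairs=None, metrics=["pli"],
                                config=PreprocessConfig(target_fs=250.0))
    rows.append(vec.values)
    labels.append(subj.true_label)

table = pd.DataFrame(rows)
print(f"{sum(labels)} responders, {len(labels) - sum(labels)} non-responders\n")
print(f"{'band':>10} {'R mean+-SD':>16} {'NR mean+-SD':>16} {'p (FDR)':>9}  sig")
for r in compare_sync_by_group(table, pd.Series(labels).to_numpy(), "pli"):
    s = r.group_summary
    print(f"{r.band:>10} {s['responder_mean']:.3f} +- {s['responder_sd']:.3f}"
          f"   {s['nonresponder_mean']:.3f} +- {s['nonresponder_sd']:.3f}"
          f" {r.p_adjusted:>9.4f}  {'*' if r.significant else ''}")
print("\n'*' marks bands significant at alpha = 0.05 after FDR correction "
      "within the PLI family.")
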
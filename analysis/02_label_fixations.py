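"""Label each participant's gaze log and apply the cohort filters.

Applies the dwell taxonomy (voluntary / spontaneous / excluded with reason),
balances classes by random subsampling of the larger (spontaneous) class,
and applies the minimum-voluntary-trials participant filter.  Writes
results/labels/<pid>_labels.csv and a summary table.
"""

from pathlib import Path

import pandas as pd

from megfix import labeling

DATA = Path("results/data")
OUT = Path("results/labels")
OUT.mkdir(parents=True, exist_ok=True)

rows = []
counts = {}
for gaze_csv in sorted(DATA.glob("*_gaze.csv")):
    pid = gaze_csv.name.split("_")[0]
    events = labeling.events_from_frame(pd.read_csv(gaze_csv))
    trials = labeling.label_fixations(events)
    labeling.labels_to_frame(trials).to_csv(OUT / f"{pid}_labels.csv", index=False)
    n = {"voluntary": 0, "spontaneous": 0, "excluded": 0}
    for t in trials:
        n[t.label] += 1
    vol_idx, spo_idx = labeling.balance_classes(trials, seed=0)
    counts[pid] = n["voluntary"]
    rows.append({"participant": pid, **n, "balanced_per_class": len(vol_idx)})

df = pd.DataFrame(rows)
df.to_csv(OUT / "summary.csv", index=False)
print(df.to_string(index=False))

# cohort filter: a desk-scale run keeps everyone above a proportionally
# reduced threshold (the full-study rule is >= 70 voluntary trials)
kept = labeling.participant_filter(counts, min_trials=30)
print(f"participants retained (>=30 voluntary dwells): {kept}")
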
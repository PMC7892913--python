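"""Generate the synthetic cohort: MEG epochs, sensor layout, gaze logs.

Three synthetic participants, each with a planted voluntary-fixation slow
deflection and a post-feedback evoked response, plus a per-participant gaze
log for the dwell-taxonomy analysis.  Outputs go to results/data/.
"""

import sys
from pathlib import Path

from megfix.io import save_dataset
from megfix.pipeline import _participant_seed
from megfix.synthetic import SimulationConfig, simulate_epochs, simulate_gaze_log

OUT = Path("results/data")
N_PARTICIPANTS = 3
BASE_SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

OUT.mkdir(parents=True, exist_ok=True)
for p in range(N_PARTICIPANTS):
    seed = _participant_seed(BASE_SEED, p)
    pid = f"S{p + 1:02d}"
    cfg = SimulationConfig(n_voluntary=100, n_spontaneous=100, evoked_amplitude=1.0, seed=seed)
    ds = simulate_epochs(cfg)
    save_dataset(ds, OUT / f"{pid}_epochs.h5")
    ds.layout.to_csv(OUT / f"{pid}_layout.csv")
    gaze = simulate_gaze_log(250, p_spontaneous=0.6, seed=seed, boundary_fraction=0.1)
    gaze.to_csv(OUT / f"{pid}_gaze.csv", index=False)
    n_vol = int((ds.labels == 1).sum())
    print(f"{pid}: {ds.epochs.shape} epochs ({n_vol} voluntary), {len(gaze)} gaze events, seed {seed}")
print(f"wrote cohort to {OUT}/")
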
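"""Preprocess each participant's epochs for both analysis windows.

Crop -> 45 Hz zero-phase lowpass -> per-trial normalization -> decimation to
125 Hz.  The short window (-0.2..0.5 s, pre-feedback) yields 204 x 87 inputs;
the long window (-0.2..1.0 s, including the feedback response) yields
204 x 150.
"""

from pathlib import Path

from megfix.io import load_epochs, save_epochs
from megfix.preprocessing import preprocess

DATA = Path("results/data")
OUT = Path("results/prep")
OUT.mkdir(parents=True, exist_ok=True)

for h5 in sorted(DATA.glob("*_epochs.h5")):
    pid = h5.name.split("_")[0]
    raw = load_epochs(h5)
    for tag, window in (("short", (-0.2, 0.5)), ("long", (-0.2, 1.0))):
        prep = preprocess(raw, window)
        save_epochs(prep, OUT / f"{pid}_{tag}.h5")
        print(f"{pid} {tag}: {prep.data.shape} at {prep.fs:g} Hz")
print(f"wrote preprocessed epochs to {OUT}/")
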
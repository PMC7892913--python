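"""Interpretability chain: patterns, class weights, FVE maps, artifact check.

For each participant, trains an LF-CNN on the short (pre-feedback) window,
recovers activation patterns via the covariance transform, computes the
per-class latent-source weights and the fraction of explained variance per
gradiometer, runs the frontal-artifact diagnostic, and renders topographic
maps.  Outputs under results/interpretation/.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from megfix.interpretation import (
    average_pattern,
    compute_patterns,
    frontal_diagnostic,
    fve_map,
    ls_class_weights,
)
from megfix.io import load_epochs
from megfix.models import ModelConfig, build_model, train
from megfix.preprocessing import EpochSet
from megfix.synthetic import SensorLayout

PREP = Path("results/prep")
DATA = Path("results/data")
OUT = Path("results/interpretation")
OUT.mkdir(parents=True, exist_ok=True)


def topomap(ax, layout, values, title):
    sc = ax.scatter(layout.positions[:, 0], layout.positions[:, 1], c=values, s=28, cmap="RdBu_r")
    ax.set_title(title, fontsize=9)
    ax.set_aspect("equal")
    ax.axis("off")
    return sc


def sub(e, i):
    return EpochSet(e.data[i], e.fs, e.window, np.asarray(e.labels)[i], e.channel_ids)


summary = []
for h5 in sorted(PREP.glob("*_short.h5")):
    pid = h5.name.split("_")[0]
    prep = load_epochs(h5)
    layout = SensorLayout.from_csv(DATA / f"{pid}_layout.csv")
    seed = abs(hash(pid)) % 100000

    cfg = ModelConfig(max_iterations=200, seed=seed)
    model = build_model("LF", prep.n_channels, prep.n_times, cfg)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(prep.n_trials)
    n_val = prep.n_trials // 4
    train(model, sub(prep, idx[n_val:]), sub(prep, idx[:n_val]), cfg)

    ps = compute_patterns(model.W, sub(prep, idx[n_val:]))
    w_vol = ls_class_weights(model.output_weights, 1)
    w_spo = ls_class_weights(model.output_weights, 0)
    fm = fve_map(sub(prep, idx[n_val:]), ps.A, ps.S_hat)
    diag = frontal_diagnostic(ps, model.output_weights, layout.frontal_mask, 1)

    pd.DataFrame(
        {
            "channel_id": prep.channel_ids,
            "mean_pattern": average_pattern(ps),
            "weighted_pattern_vol": average_pattern(ps, w_vol),
            "fve": fm.fve,
        }
    ).to_csv(OUT / f"{pid}_patterns.csv", index=False)

    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    topomap(axes[0], layout, average_pattern(ps), "mean pattern")
    topomap(axes[1], layout, average_pattern(ps, w_vol), "voluntary-weighted")
    sc = topomap(axes[2], layout, fm.fve, "FVE")
    fig.colorbar(sc, ax=axes[2], shrink=0.7)
    fig.savefig(OUT / f"{pid}_topomaps.png", dpi=110, bbox_inches="tight")
    plt.close(fig)

    summary.append(
        {
            "participant": pid,
            "full_fve_pct": round(100 * fm.full_fve, 2),
            "frontal_output_r": round(diag.pearson_r, 3) if diag.defined else None,
            "max_ls_weight_vol": round(float(w_vol.max()), 4),
            "mean_ls_weight": round(1 / model.config.k, 4),
        }
    )
    print(f"{pid}: full FVE {summary[-1]['full_fve_pct']}%, frontal/output r {summary[-1]['frontal_output_r']}")

(OUT / "summary.json").write_text(json.dumps(summary, indent=2))
print(f"wrote interpretation outputs to {OUT}/")
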
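"""End-to-end orchestration: simulate -> label -> preprocess -> decode -> interpret.

``run_experiment`` produces, for a cohort of synthetic participants, the
study's full result set: a per-participant classification table (validation /
naive / ensemble AUC with permutation flags), a group table (variant x
analysis window x testing method), activation-pattern / FVE / artifact
outputs for the interpretable variant, and a machine-readable manifest with
every seed used.  Each stage is a thin call into the corresponding library
module, so everything here is reproducible piecewise from the CLI or the
numbered analysis scripts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import labeling
from .errors import InsufficientDataError
from .evaluation import CVPlan, ParticipantResult, group_summary, nested_cv
from .interpretation import compute_patterns, frontal_diagnostic, fve_map, ls_class_weights
from .models import ModelConfig, build_model, train
from .preprocessing import EpochSet, preprocess
from .synthetic import SimulationConfig, simulate_epochs, simulate_gaze_log

log = logging.getLogger("megfix")

__all__ = ["RunConfig", "run_experiment", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    """Desk-scale experiment configuration (one seed drives every stage)."""

    outdir: str = "results/run"
    n_participants: int = 3
    windows: tuple = ((-0.2, 0.5), (-0.2, 1.0))
    variants: tuple = ("LF", "VAR")
    sim: SimulationConfig = SimulationConfig(n_voluntary=100, n_spontaneous=100, evoked_amplitude=1.0)
    model: ModelConfig = ModelConfig(max_iterations=100)
    cv: CVPlan = CVPlan()
    n_perm: int = 500
    n_moves: int = 250
    seed: int = 0


def _participant_seed(base: int, p: int) -> int:
    return int(np.random.SeedSequence([base, p]).generate_state(1)[0] % (2**31))


def load_run_config(path, seed: int | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Top-level keys mirror the RunConfig fields; the nested ``sim``, ``model``
    and ``cv`` mappings feed SimulationConfig / ModelConfig / CVPlan.  A
    ``seed`` argument overrides the file's seed and cascades to every stage.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "sim" in raw:
        sim = dict(raw.pop("sim"))
        if "epoch_window" in sim:
            sim["epoch_window"] = tuple(sim["epoch_window"])
        kwargs["sim"] = SimulationConfig(**sim)
    if "model" in raw:
        kwargs["model"] = ModelConfig(**raw.pop("model"))
    if "cv" in raw:
        kwargs["cv"] = CVPlan(**raw.pop("cv"))
    if "windows" in raw:
        kwargs["windows"] = tuple(tuple(w) for w in raw.pop("windows"))
    if "variants" in raw:
        kwargs["variants"] = tuple(raw.pop("variants"))
    kwargs.update(raw)
    if seed is not None:
        kwargs["seed"] = seed
    return RunConfig(**kwargs)


def run_experiment(config: RunConfig) -> Path:
    """Run the whole pipeline; returns the report directory.

    Stages per participant: gaze simulation and labeling (sets the trial
    budget via class balancing), MEG simulation, preprocessing per analysis
    window, nested CV per variant, and interpretation of the LF decoder on
    the short window.  Aborts with the failed stage's name; the manifest
    written so far is preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "participants": [],
        "stages_completed": [],
    }
    t_start = time.time()
    stage = "init"
    try:
        per_participant_rows = []
        results: dict[tuple[str, tuple], list[ParticipantResult]] = {}
        trial_counts: list[int] = []
        interp_rows = []
        diag_rows = []

        for p in range(config.n_participants):
            pseed = _participant_seed(config.seed, p)
            pid = f"S{p + 1:02d}"
            log.info("participant %s (seed %d)", pid, pseed)

            stage = f"{pid}:gaze"
            t0 = time.time()
            gaze = simulate_gaze_log(config.n_moves, p_spontaneous=0.6, seed=pseed, boundary_fraction=0.1)
            events = labeling.events_from_frame(gaze)
            trials = labeling.label_fixations(events)
            vol_idx, spo_idx = labeling.balance_classes(trials, seed=pseed)
            n_per_class = min(len(vol_idx), config.sim.n_voluntary)
            log.info("  gaze: %d dwells -> %d/class after balancing (%.1fs)", len(trials), n_per_class, time.time() - t0)
            if n_per_class < config.cv.outer_folds:
                raise InsufficientDataError(f"{pid}: only {n_per_class} trials per class")

            stage = f"{pid}:simulate"
            sim = dataclasses.replace(config.sim, n_voluntary=n_per_class, n_spontaneous=n_per_class, seed=pseed)
            ds = simulate_epochs(sim)
            raw = EpochSet(ds.epochs, sim.fs, sim.epoch_window, ds.labels, ds.layout.channel_ids)

            trial_counts.append(n_per_class)
            manifest["participants"].append(
                {"id": pid, "seed": pseed, "n_trials_per_class": int(n_per_class)}
            )

            for window in config.windows:
                stage = f"{pid}:preprocess{window}"
                prep = preprocess(raw, window)
                for variant in config.variants:
                    stage = f"{pid}:{variant}:cv{window}"
                    t0 = time.time()
                    plan = dataclasses.replace(config.cv, seed=pseed)
                    mcfg = dataclasses.replace(config.model, seed=pseed)
                    res = nested_cv(prep, variant, plan, mcfg, n_perm=config.n_perm)
                    results.setdefault((variant, window), []).append(res)
                    row = {
                        "participant": pid,
                        "variant": variant,
                        "window": f"{window[0]}..{window[1]}",
                        "n_trials_per_class": n_per_class,
                    }
                    for met in ("auc_val", "auc_naive", "auc_ensemble"):
                        mu, sd = res.mean_sd(met)
                        row[met] = round(mu, 4)
                        row[met + "_sd"] = round(sd, 4)
                    row["permutation_flag"] = res.nonrandom_flag
                    per_participant_rows.append(row)
                    log.info("  %s %s window %s: ens %.3f (%.1fs)", pid, variant, window, row["auc_ensemble"], time.time() - t0)

            # interpretation: LF on the short (pre-feedback) window
            stage = f"{pid}:interpret"
            if "LF" in config.variants:
                prep_short = preprocess(raw, config.windows[0])
                mcfg = dataclasses.replace(config.model, seed=pseed + 1)
                model = build_model("LF", prep_short.n_channels, prep_short.n_times, mcfg)
                rng = np.random.default_rng(pseed)
                idx = rng.permutation(prep_short.n_trials)
                n_val = max(2, prep_short.n_trials // 4)
                train(model, _sub(prep_short, idx[n_val:]), _sub(prep_short, idx[:n_val]), mcfg)
                ps = compute_patterns(model.W, _sub(prep_short, idx[n_val:]))
                wv = ls_class_weights(model.output_weights, 1)
                fm = fve_map(_sub(prep_short, idx[n_val:]), ps.A, ps.S_hat)
                diag = frontal_diagnostic(ps, model.output_weights, ds.layout.frontal_mask, 1)
                for c, ch in enumerate(ds.layout.channel_ids):
                    interp_rows.append(
                        {
                            "participant": pid,
                            "channel_id": ch,
                            "mean_pattern": float(ps.A.mean(axis=1)[c]),
                            "fve": float(fm.fve[c]),
                        }
                    )
                diag_rows.append(
                    {
                        "participant": pid,
                        "pearson_r": diag.pearson_r,
                        "full_fve_pct": round(100 * fm.full_fve, 2),
                        "max_class_weight": float(wv.max()),
                    }
                )

        stage = "group"
        group = None
        if len(trial_counts) >= 3 and {"LF", "VAR"} <= set(config.variants):
            group = {}
            for window in config.windows:
                group[window] = group_summary(
                    results[("LF", window)], results[("VAR", window)], trial_counts
                )

        stage = "report"
        write_report(
            per_participant_rows,
            results,
            group,
            interp_rows,
            diag_rows,
            outdir,
            insufficient_group=len(trial_counts) < 3,
        )
        manifest["stages_completed"] = ["gaze", "simulate", "preprocess", "cv", "interpret", "report"]
        manifest["wall_time_s"] = round(time.time() - t_start, 1)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _sub(epochs: EpochSet, idx) -> EpochSet:
    return EpochSet(epochs.data[idx], epochs.fs, epochs.window, np.asarray(epochs.labels)[idx], epochs.channel_ids)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["windows"] = [list(w) for w in config.windows]
    return d


def write_report(per_participant_rows, results, group, interp_rows, diag_rows, outdir, insufficient_group=False) -> None:
    """Write the CSV/JSON result set; deterministic bytes for fixed inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(per_participant_rows).to_csv(outdir / "participants.csv", index=False)

    group_rows = []
    if group is not None:
        for window, g in group.items():
            for (variant, met), (mu, sd) in g.mean_sd.items():
                if met == "auc_val":
                    continue
                group_rows.append(
                    {
                        "window": f"{window[0]}..{window[1]}",
                        "variant": variant,
                        "testing": met.replace("auc_", ""),
                        "auc_mean": round(mu, 4),
                        "auc_sd": round(sd, 4),
                    }
                )
        pd.DataFrame(group_rows).to_csv(outdir / "group.csv", index=False)
        stats = {
            f"{w[0]}..{w[1]}": {
                "correlation": {f"{v}:{m}": list(np.round(rp, 5)) for (v, m), rp in g.correlation.items()},
                "wilcoxon_lf_vs_var": {m: list(np.round(sp, 5)) for m, sp in g.wilcoxon.items()},
            }
            for w, g in group.items()
        }
        (outdir / "group_stats.json").write_text(json.dumps(stats, indent=2))
    elif insufficient_group:
        (outdir / "group_stats.json").write_text(json.dumps({"note": "insufficient n"}, indent=2))

    if interp_rows:
        pd.DataFrame(interp_rows).to_csv(outdir / "patterns_fve.csv", index=False)
    if diag_rows:
        pd.DataFrame(diag_rows).to_csv(outdir / "artifact_diagnostics.csv", index=False)
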
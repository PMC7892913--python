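"""Nested cross-validation, ROC AUC, permutation significance, group stats.

The evaluation protocol is a 5 x 4 nested cross-validation.  For each of the
5 stratified outer folds, a 4-fold inner CV on the outer-training set
produces (a) the optimal number of training iterations — the mean, across
inner folds, of the iteration at which the validation AUC peaked — and
(b) four trained networks.  Test performance is then measured two ways:

* **naive** — a fresh network retrained on the entire outer-training set for
  the optimal number of iterations, scored on the held-out test fold;
* **ensemble** — the four inner networks' target-class probabilities averaged
  over the test fold.

Chance level is calibrated per fold by a label-permutation test (default 1000
permutations) on the test-fold scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .errors import InsufficientDataError, UndefinedAUCError
from .models import ModelConfig, TrainedModel, build_model, predict_proba, train
from .preprocessing import EpochSet

__all__ = [
    "CVPlan",
    "FoldResult",
    "ParticipantResult",
    "GroupResult",
    "roc_auc",
    "select_iterations",
    "nested_cv",
    "permutation_test",
    "group_summary",
]


@dataclass(frozen=True)
class CVPlan:
    outer_folds: int = 5
    inner_folds: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise InsufficientDataError("outer_folds and inner_folds must be >= 2")


@dataclass
class FoldResult:
    fold_index: int
    auc_val: float  # mean of the inner folds' peak validation AUC
    auc_naive: float
    auc_ensemble: float
    p_naive: float
    p_ensemble: float
    optimal_iterations: int
    n_ensemble_models: int = 0  # inner models averaged for auc_ensemble
    test_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))


@dataclass
class ParticipantResult:
    variant: str
    folds: list[FoldResult]
    n_trials_per_class: int

    def metric(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.folds])

    def mean_sd(self, name: str) -> tuple[float, float]:
        x = self.metric(name)
        return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0

    @property
    def nonrandom_flag(self) -> str:
        """"+" if all fold p-values < 0.05, "-" if none, blank otherwise."""
        p = self.metric("p_ensemble")
        if (p < 0.05).all():
            return "+"
        if not (p < 0.05).any():
            return "-"
        return ""


@dataclass
class GroupResult:
    mean_sd: dict  # (variant, metric) -> (mean, sd) across participants
    correlation: dict  # (variant, metric) -> (r, p) of AUC vs trials per class
    wilcoxon: dict  # metric -> (statistic, p) for LF vs VAR


def roc_auc(scores, labels) -> float:
    """Mann-Whitney concordance: P(score_pos > score_neg), ties credited 0.5."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise UndefinedAUCError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def select_iterations(traces: list[np.ndarray]) -> int:
    """Mean (over folds) of the earliest trace-maximum iteration, rounded.

    Iterations are 1-based; flat traces give iteration 1; the result is at
    least 1.
    """
    if not traces or any(len(t) == 0 for t in traces):
        raise InsufficientDataError("every validation trace must be non-empty")
    peaks = [int(np.argmax(t)) + 1 for t in traces]
    return max(1, int(round(float(np.mean(peaks)))))


def permutation_test(scores, labels, n_perm: int = 1000, seed: int = 0) -> float:
    """Add-one permutation p-value for the observed AUC.

    p = (1 + #{permuted AUC >= observed}) / (n_perm + 1), with uniform random
    relabelings of the test set.
    """
    if n_perm < 1:
        raise InsufficientDataError("n_perm must be >= 1")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    observed = roc_auc(scores, labels)
    null = permutation_null(scores, labels, n_perm, seed)
    count = int((null >= observed - 1e-12).sum())
    return (1 + count) / (n_perm + 1)


def permutation_null(scores, labels, n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """AUC values under uniform random relabelings (the permutation null)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n = labels.size
    n1 = int((labels == 1).sum())
    n0 = n - n1
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(scores)
    # each permutation is a uniformly random choice of which trials are "positive"
    keys = rng.random((n_perm, n))
    pos_sets = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
    u = ranks[pos_sets].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u / (n0 * n1)


def _derive_seed(base: int, *parts: int) -> int:
    return int(np.random.SeedSequence([base, *parts]).generate_state(1)[0] % (2**31))


def nested_cv(
    epochs: EpochSet,
    variant: str,
    plan: CVPlan = CVPlan(),
    config: ModelConfig = ModelConfig(),
    n_perm: int = 1000,
) -> ParticipantResult:
    """Full nested CV for one participant's epochs; seed-reproducible."""
    y = np.asarray(epochs.labels, int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < plan.outer_folds:
        raise InsufficientDataError(
            f"need >= {plan.outer_folds} trials per class, got {dict(zip(classes.tolist(), counts.tolist()))}"
        )

    outer = StratifiedKFold(n_splits=plan.outer_folds, shuffle=True, random_state=plan.seed % (2**31))
    folds: list[FoldResult] = []
    for f, (tr_idx, te_idx) in enumerate(outer.split(np.zeros(y.size), y)):
        Xtr = _subset(epochs, tr_idx)
        Xte = _subset(epochs, te_idx)

        inner = StratifiedKFold(
            n_splits=plan.inner_folds, shuffle=True, random_state=_derive_seed(plan.seed, f) % (2**31)
        )
        inner_models: list[TrainedModel] = []
        traces: list[np.ndarray] = []
        for g, (itr, ival) in enumerate(inner.split(np.zeros(len(tr_idx)), Xtr.labels)):
            cfg = replace(config, seed=_derive_seed(config.seed, f, g))
            model = build_model(variant, epochs.n_channels, epochs.n_times, cfg)
            train(model, _subset(Xtr, itr), _subset(Xtr, ival), cfg)
            inner_models.append(model)
            traces.append(model.trace)

        n_opt = select_iterations(traces)
        auc_val = float(np.mean([t.max() for t in traces]))

        # naive: fresh model, full outer-training set, optimal iteration count
        cfg = replace(config, seed=_derive_seed(config.seed, f, 999), max_iterations=n_opt)
        naive = build_model(variant, epochs.n_channels, epochs.n_times, cfg)
        train(naive, Xtr, None, cfg)
        scores_naive = predict_proba(naive, Xte)[:, 1]
        auc_naive = roc_auc(scores_naive, Xte.labels)
        p_naive = permutation_test(scores_naive, Xte.labels, n_perm, _derive_seed(plan.seed, f, 1))

        # ensemble: average the 4 inner models' target-class probabilities
        scores_ens = np.mean([predict_proba(mdl, Xte)[:, 1] for mdl in inner_models], axis=0)
        auc_ens = roc_auc(scores_ens, Xte.labels)
        p_ens = permutation_test(scores_ens, Xte.labels, n_perm, _derive_seed(plan.seed, f, 2))

        folds.append(
            FoldResult(
                fold_index=f,
                auc_val=auc_val,
                auc_naive=float(auc_naive),
                auc_ensemble=float(auc_ens),
                p_naive=float(p_naive),
                p_ensemble=float(p_ens),
                optimal_iterations=n_opt,
                n_ensemble_models=len(inner_models),
                test_indices=np.asarray(te_idx),
            )
        )
    return ParticipantResult(variant=variant, folds=folds, n_trials_per_class=int(counts.min()))


def _subset(epochs: EpochSet, idx) -> EpochSet:
    return EpochSet(
        data=epochs.data[idx],
        fs=epochs.fs,
        window=epochs.window,
        labels=np.asarray(epochs.labels)[idx],
        channel_ids=epochs.channel_ids,
    )


def group_summary(
    lf_results: list[ParticipantResult],
    var_results: list[ParticipantResult],
    trial_counts: list[int],
) -> GroupResult:
    """Group statistics across participants.

    Mean +- SD per metric and variant; Pearson correlation of each AUC metric
    with trials-per-class; two-sided Wilcoxon signed-rank test comparing LF
    and VAR per testing method (p defined as 1 when the paired differences
    are all zero).
    """
    if len(lf_results) != len(var_results) or len(lf_results) != len(trial_counts):
        raise InsufficientDataError("participant sets for LF, VAR and trial counts must match")
    n = len(lf_results)
    if n < 3:
        raise InsufficientDataError("need >= 3 participants for group correlations")

    metrics = ("auc_val", "auc_naive", "auc_ensemble")
    per_variant = {"LF": lf_results, "VAR": var_results}
    mean_sd: dict = {}
    correlation: dict = {}
    for variant, results in per_variant.items():
        for met in metrics:
            vals = np.array([r.metric(met).mean() for r in results])
            mean_sd[(variant, met)] = (float(vals.mean()), float(vals.std(ddof=1)))
            if met != "auc_val":
                counts_arr = np.asarray(trial_counts, float)
                if np.ptp(vals) == 0 or np.ptp(counts_arr) == 0:
                    correlation[(variant, met)] = (float("nan"), float("nan"))
                else:
                    r, p = stats.pearsonr(vals, counts_arr)
                    correlation[(variant, met)] = (float(r), float(p))

    wilcoxon: dict = {}
    for met in ("auc_naive", "auc_ensemble"):
        a = np.array([r.metric(met).mean() for r in lf_results])
        b = np.array([r.metric(met).mean() for r in var_results])
        if np.allclose(a, b):
            wilcoxon[met] = (0.0, 1.0)
        else:
            w, p = stats.wilcoxon(a, b, alternative="two-sided")
            wilcoxon[met] = (float(w), float(p))
    return GroupResult(mean_sd=mean_sd, correlation=correlation, wilcoxon=wilcoxon)
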
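"""Interpreting the spatial filters of a trained decoder.

A discriminative spatial filter bank ``W`` is not directly interpretable as a
source projection; the corresponding forward-model *activation patterns* are
recovered through the covariance transform

    S_hat = W^T X,          A = Sigma_X  W  Sigma_Shat^{-1},

where ``Sigma_X`` is the channel covariance of the data (concatenated over
trials and time) and ``Sigma_Shat`` the covariance of the latent time
courses.  Each column of ``A`` is the sensor-space pattern of one latent
source.

Per-class source importance is the normalized L1 norm of the dense-layer
weights belonging to that source and class,

    w_s^c = sum_j |w_{j,s}^c| / sum_i sum_j |w_{j,i}^c|,

which sums to 1 over sources.  The fraction of explained variance (FVE) per
channel is the squared Pearson correlation between the recorded signal and
its reconstruction ``X_rec = A S_hat``; it measures how much of each sensor's
signal passes through the latent subspace the classifier uses.  The frontal
diagnostic correlates, across sources, the L1 norm of frontal-sensor pattern
weights with the L1 norm of output weights — a positive relationship flags a
classifier leaning on oculomotor artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateLatentsWarning,
    InsufficientDataError,
    UndefinedWeightsError,
)
from .preprocessing import EpochSet

__all__ = [
    "PatternSet",
    "FVEMap",
    "ArtifactDiagnostic",
    "latent_timecourses",
    "compute_patterns",
    "ls_class_weights",
    "average_pattern",
    "fve_map",
    "frontal_diagnostic",
]

#: condition-number threshold above which Sigma_Shat is flagged degenerate
CONDITION_LIMIT = 1e10


@dataclass
class PatternSet:
    A: np.ndarray  # activation patterns, channels x k
    sigma_X: np.ndarray  # channels x channels
    sigma_S: np.ndarray  # k x k
    S_hat: np.ndarray  # trials x k x time
    degenerate: bool = False  # latent covariance ill-conditioned

    @property
    def k(self) -> int:
        return self.A.shape[1]


@dataclass
class FVEMap:
    fve: np.ndarray  # per channel, in [0, 1]; NaN where undefined
    full_fve: float  # mean over defined channels
    valid: np.ndarray  # per-channel definedness mask


@dataclass
class ArtifactDiagnostic:
    frontal_l1: np.ndarray  # f_s, per source
    output_l1: np.ndarray  # o_s, per source
    pearson_r: float  # NaN when undefined
    defined: bool
    auc: float | None = None  # participant AUC, for the group scatter


def latent_timecourses(W: np.ndarray, epochs: EpochSet | np.ndarray) -> np.ndarray:
    """Project epochs onto the latent sources: per trial, S_hat = W^T X."""
    X = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs, float)
    W = np.asarray(W, float)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"W has {W.shape[0]} channels but data has {X.shape[1]}")
    return np.einsum("ck,bct->bkt", W, X)


def compute_patterns(W: np.ndarray, epochs: EpochSet | np.ndarray) -> PatternSet:
    """Recover activation patterns from spatial filters via the covariance transform."""
    X = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs, float)
    if X.ndim == 2:
        X = X[None]
    n_trials, n_channels, n_times = X.shape
    if n_trials * n_times < 2:
        raise InsufficientDataError("need at least two timepoints overall")

    S_hat = latent_timecourses(W, X)
    Xc = X.transpose(1, 0, 2).reshape(n_channels, -1)
    Sc = S_hat.transpose(1, 0, 2).reshape(W.shape[1], -1)
    sigma_X = np.cov(Xc)
    sigma_S = np.atleast_2d(np.cov(Sc))

    degenerate = bool(np.linalg.cond(sigma_S) > CONDITION_LIMIT)
    if degenerate:
        warnings.warn(
            "latent covariance is ill-conditioned; patterns computed via pseudo-inverse",
            DegenerateLatentsWarning,
        )
    A = np.atleast_2d(sigma_X) @ np.asarray(W, float) @ np.linalg.pinv(sigma_S, rcond=1e-10)
    return PatternSet(A=A, sigma_X=np.atleast_2d(sigma_X), sigma_S=sigma_S, S_hat=S_hat, degenerate=degenerate)


def ls_class_weights(output_weights: np.ndarray, class_index: int) -> np.ndarray:
    """Normalized per-source L1 norm of the dense weights for one class.

    ``output_weights`` has shape (pooled_time, k, 2); the result is
    nonnegative and sums to 1 over the k sources.
    """
    w = np.asarray(output_weights, float)
    if not np.isfinite(w).all():
        raise ValueError("output weights contain non-finite values")
    per_source = np.abs(w[:, :, class_index]).sum(axis=0)
    denom = per_source.sum()
    if denom == 0:
        raise UndefinedWeightsError(f"all output weights for class {class_index} are zero")
    return per_source / denom


def average_pattern(patterns: PatternSet, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted average of pattern columns; uniform weights 1/k by default."""
    k = patterns.k
    if weights is None:
        weights = np.full(k, 1.0 / k)
    weights = np.asarray(weights, float)
    if weights.shape != (k,):
        raise ValueError(f"weights must have length {k}")
    return patterns.A @ weights


def fve_map(epochs: EpochSet | np.ndarray, A: np.ndarray, S_hat: np.ndarray) -> FVEMap:
    """Fraction of explained variance per channel.

    FVE_i = r(X_i, X_rec_i)^2 with X_rec = A S_hat, both concatenated over
    trials and time.  Channels where either signal is constant are flagged
    undefined (NaN) and excluded from the ``full_fve`` mean.
    """
    X = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs, float)
    if X.ndim == 2:
        X = X[None]
    if S_hat.ndim == 2:
        S_hat = S_hat[None]
    X_rec = np.einsum("ck,bkt->bct", np.asarray(A, float), S_hat)
    if X_rec.shape != X.shape:
        raise ValueError(f"reconstruction shape {X_rec.shape} does not match data {X.shape}")

    n_channels = X.shape[1]
    x = X.transpose(1, 0, 2).reshape(n_channels, -1)
    r = X_rec.transpose(1, 0, 2).reshape(n_channels, -1)
    xc = x - x.mean(axis=1, keepdims=True)
    rc = r - r.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sr = np.sqrt((rc**2).sum(axis=1))
    valid = (sx > 0) & (sr > 0)
    fve = np.full(n_channels, np.nan)
    fve[valid] = ((xc[valid] * rc[valid]).sum(axis=1) / (sx[valid] * sr[valid])) ** 2
    if not valid.any():
        raise InsufficientDataError("FVE undefined for every channel")
    return FVEMap(fve=fve, full_fve=float(np.nanmean(fve)), valid=valid)


def frontal_diagnostic(
    patterns: PatternSet,
    output_weights: np.ndarray,
    frontal_mask: np.ndarray,
    class_index: int = 1,
    use: str = "patterns",
) -> ArtifactDiagnostic:
    """Correlate frontal pattern mass with output-weight mass across sources.

    ``f_s`` is the L1 norm of source s's weights over the frontal sensors
    (taken from the activation patterns A by default, from the raw filters W
    is possible upstream by passing a PatternSet built from W); ``o_s`` is the
    L1 norm of the class's output weights for source s.  A strong positive
    Pearson correlation across sources indicates the classifier relies on
    frontal (oculomotor) signal.
    """
    mask = np.asarray(frontal_mask, bool)
    if not mask.any():
        raise InsufficientDataError("frontal mask selects no channels")
    if use not in ("patterns",):
        raise ValueError("use must be 'patterns' (pass a PatternSet built from W to use raw filters)")
    k = patterns.k
    if k < 3:
        raise InsufficientDataError("need k >= 3 sources for the correlation")

    f = np.abs(patterns.A[mask, :]).sum(axis=0)
    o = np.abs(np.asarray(output_weights, float)[:, :, class_index]).sum(axis=0)
    if f.std() == 0 or o.std() == 0:
        return ArtifactDiagnostic(frontal_l1=f, output_l1=o, pearson_r=float("nan"), defined=False)
    r, _ = stats.pearsonr(f, o)
    return ArtifactDiagnostic(frontal_l1=f, output_l1=o, pearson_r=float(r), defined=True)
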
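"""Synthetic MEG epochs and gaze logs with known ground truth.

The generator emulates the statistical structure assumed by the decoding
analysis: each epoch is a linear mixture of a small number of latent source
time courses plus white Gaussian observation noise,

    X = A S + eps,    X in R^(n_channels x n_times),

time-locked to the onset of an eye dwell at t = 0.  The voluntary class
carries a slow deflection — a quarter-period sine ramp rising from fixation
onset to the 0.5 s feedback time — in a source loading over left
central/parietal sensors; an optional evoked response after 0.5 s models the
reaction to the selection feedback; an optional frontal step-like source
models an oculomotor artifact.  Oscillatory background sources (10 Hz, random
phase per trial) are class-neutral.

Sensor geometry is a planar-gradiometer-like layout: channel pairs on
concentric rings of the unit disc, with a "frontal" flag for the top band of
the head projection (used by the artifact diagnostic).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidLayoutError

__all__ = [
    "SimulationConfig",
    "SensorLayout",
    "GroundTruth",
    "SyntheticDataset",
    "make_layout",
    "make_ground_truth",
    "simulate_sources",
    "simulate_epochs",
    "simulate_gaze_log",
]

#: time (s) at which interface feedback appears, relative to fixation onset
FEEDBACK_TIME = 0.5

#: frequency (Hz) of the oscillatory background sources
OSC_FREQ = 10.0

#: frequency (Hz) and decay constant (s) of the evoked feedback response
EVOKED_FREQ = 5.0
EVOKED_TAU = 0.12
EVOKED_END = 0.9


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic participant's dataset.

    Amplitudes are unitless scales relative to the per-channel noise standard
    deviation (``noise_sd``); an amplitude of 0 removes the component.
    """

    n_voluntary: int = 200
    n_spontaneous: int = 200
    n_channels: int = 204
    fs: float = 1000.0
    epoch_window: tuple[float, float] = (-0.2, 1.0)
    k_true: int = 6
    slow_amplitude: float = 1.0
    evoked_amplitude: float = 0.0
    artifact_amplitude: float = 0.0
    background_amplitude: float = 1.0  # 10 Hz background, in units of noise_sd
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voluntary <= 0 or self.n_spontaneous <= 0:
            raise InvalidConfigError("trial counts must be positive")
        if self.n_channels < 2 or self.n_channels % 2:
            raise InvalidConfigError("n_channels must be even and >= 2 (gradiometer pairs)")
        if self.fs <= 0:
            raise InvalidConfigError("fs must be positive")
        start, end = self.epoch_window
        if not (start < 0.0 < end):
            raise InvalidConfigError("epoch window must straddle the fixation onset (start < 0 < end)")
        if self.k_true < 1:
            raise InvalidConfigError("k_true must be >= 1")
        for name in (
            "slow_amplitude",
            "evoked_amplitude",
            "artifact_amplitude",
            "background_amplitude",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.n_voluntary + self.n_spontaneous

    @property
    def n_times(self) -> int:
        start, end = self.epoch_window
        return int(round((end - start) * self.fs))

    def times(self) -> np.ndarray:
        """Sample times (s) relative to fixation onset."""
        start, _ = self.epoch_window
        return start + np.arange(self.n_times) / self.fs

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["epoch_window"] = tuple(d["epoch_window"])
        return cls(**d)


@dataclass
class SensorLayout:
    """2-D head-projection positions of the channels, plus a frontal flag."""

    channel_ids: list[str]
    positions: np.ndarray  # (n_channels, 2) in the unit disc
    frontal_mask: np.ndarray  # (n_channels,) bool

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": self.channel_ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "frontal": self.frontal_mask.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorLayout":
        df = pd.read_csv(path)
        return cls(
            channel_ids=df["channel_id"].astype(str).tolist(),
            positions=df[["x", "y"]].to_numpy(float),
            frontal_mask=df["frontal"].to_numpy().astype(bool),
        )


@dataclass
class GroundTruth:
    """Planted mixing matrix and per-source class structure.

    ``class_gain[s]`` is the (spontaneous, voluntary) amplitude multiplier of
    source ``s``; the defaults make the slow and evoked sources informative
    about the class while oscillatory background is class-neutral.
    """

    A_true: np.ndarray  # (n_channels, k_true), unit-norm columns
    source_kinds: list[str]  # slow-deflection | evoked | oscillatory | artifact | noise
    class_gain: np.ndarray  # (k_true, 2)

    @property
    def k_true(self) -> int:
        return self.A_true.shape[1]

    def columns_of_kind(self, kind: str) -> np.ndarray:
        idx = [i for i, k in enumerate(self.source_kinds) if k == kind]
        return self.A_true[:, idx]


@dataclass
class SyntheticDataset:
    """Epochs with labels, layout, and the generating ground truth."""

    epochs: np.ndarray  # (n_trials, n_channels, n_times)
    labels: np.ndarray  # (n_trials,)  0 = spontaneous, 1 = voluntary
    layout: SensorLayout
    truth: GroundTruth
    config: SimulationConfig


def make_layout(n_channels: int, frontal_fraction: float = 0.1, seed: int = 0) -> SensorLayout:
    """Arrange ``n_channels`` gradiometer-pair channels on the unit disc.

    Pair positions sit on concentric rings; the two channels of a pair are
    offset vertically by a small amount so every channel position is unique.
    Channels whose vertical coordinate exceeds the ``1 - frontal_fraction``
    quantile are flagged frontal (the top band of the head map).
    """
    if n_channels < 2 or n_channels % 2:
        raise InvalidLayoutError("n_channels must be even and >= 2")
    if not 0.0 < frontal_fraction < 1.0:
        raise InvalidLayoutError("frontal_fraction must lie strictly between 0 and 1")

    n_pairs = n_channels // 2
    rng = np.random.default_rng(seed)

    # concentric rings: point budget proportional to circumference
    n_rings = max(1, int(np.ceil(np.sqrt(n_pairs / 3.0))))
    radii = (np.arange(n_rings) + 1) / n_rings * 0.92
    weights = radii / radii.sum()
    counts = np.maximum(1, np.floor(weights * n_pairs).astype(int))
    while counts.sum() < n_pairs:
        counts[np.argmax(radii)] += 1
    while counts.sum() > n_pairs:
        counts[np.argmax(counts)] -= 1

    centers = []
    for r, m in zip(radii, counts):
        phase = rng.uniform(0, 2 * np.pi)
        ang = phase + 2 * np.pi * np.arange(m) / m
        centers.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    centers = np.concatenate(centers, axis=0)[:n_pairs]

    delta = 0.012  # vertical pair offset; keeps per-channel positions unique
    positions = np.empty((n_channels, 2))
    positions[0::2] = centers + np.array([0.0, -delta])
    positions[1::2] = centers + np.array([0.0, +delta])

    ids = [f"MEG{p:04d}{c}" for p in range(1, n_pairs + 1) for c in (2, 3)]

    y = positions[:, 1]
    thresh = np.quantile(y, 1.0 - frontal_fraction)
    mask = y > thresh
    if not mask.any():  # degenerate quantile: force a proper, non-empty subset
        mask[np.argmax(y)] = True
    if mask.all():
        mask[np.argmin(y)] = False
    return SensorLayout(channel_ids=ids, positions=positions, frontal_mask=mask)


def _gaussian_column(layout: SensorLayout, center: np.ndarray, width: float) -> np.ndarray:
    d2 = ((layout.positions - center) ** 2).sum(axis=1)
    col = np.exp(-d2 / (2.0 * width**2))
    return col / np.linalg.norm(col)


# head-map centers of the planted sources (x, y): y > 0 is frontal
_SLOW_CENTER = np.array([-0.45, -0.05])  # left central/parietal
_EVOKED_CENTER = np.array([0.1, -0.45])  # parieto-occipital
_ARTIFACT_WIDTH = 0.22
_SOURCE_WIDTH = 0.35


def make_ground_truth(config: SimulationConfig, layout: SensorLayout, seed: int | None = None) -> GroundTruth:
    """Build the planted mixing matrix for ``config`` on ``layout``.

    Source order: slow-deflection, evoked, artifact, then oscillatory
    background for the remaining columns (``k_true`` truncates this list).
    Mixing columns are unit-norm spatial Gaussians on the head map; the
    artifact column is centred on the frontal band.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frontal_center = layout.positions[layout.frontal_mask].mean(axis=0)

    kinds: list[str] = []
    cols: list[np.ndarray] = []
    gains: list[tuple[float, float]] = []

    base = [
        ("slow-deflection", _SLOW_CENTER, _SOURCE_WIDTH, (0.0, 1.0)),
        ("evoked", _EVOKED_CENTER, _SOURCE_WIDTH, (0.5, 1.0)),
        ("artifact", frontal_center, _ARTIFACT_WIDTH, (0.0, 1.0)),
    ]
    centers = []
    for kind, center, width, gain in base[: config.k_true]:
        kinds.append(kind)
        cols.append(_gaussian_column(layout, center, width))
        gains.append(gain)
        centers.append(center)
    while len(kinds) < config.k_true:
        # background sources on the lower 3/4 of the head map, kept spatially
        # separated from every planted source so the ground truth stays
        # identifiable (overlapping bumps would make "the slow source's
        # pattern" ill-defined)
        for _ in range(200):
            center = rng.uniform([-0.7, -0.7], [0.7, 0.4])
            if all(np.linalg.norm(center - c) >= 0.55 for c in centers):
                break
        kinds.append("oscillatory")
        cols.append(_gaussian_column(layout, center, _SOURCE_WIDTH))
        gains.append((1.0, 1.0))
        centers.append(center)

    return GroundTruth(
        A_true=np.column_stack(cols),
        source_kinds=kinds,
        class_gain=np.asarray(gains, float),
    )


def _slow_waveform(t: np.ndarray) -> np.ndarray:
    """Quarter-sine ramp: 0 before onset, sin(pi/2 * t/0.5) to 0.5 s, 1 after."""
    u = np.clip(t / FEEDBACK_TIME, 0.0, 1.0)
    return np.where(t < 0.0, 0.0, np.sin(0.5 * np.pi * u))


def _evoked_waveform(t: np.ndarray) -> np.ndarray:
    """Damped 5 Hz transient in the 0.5-0.9 s feedback-response window."""
    dt = t - FEEDBACK_TIME
    active = (dt >= 0.0) & (t <= EVOKED_END)
    return np.where(active, np.sin(2 * np.pi * EVOKED_FREQ * dt) * np.exp(-dt / EVOKED_TAU), 0.0)


def simulate_sources(
    config: SimulationConfig,
    truth: GroundTruth,
    label: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Latent source time courses ``(k_true, n_times)`` for one trial.

    ``label`` is 0 (spontaneous) or 1 (voluntary); class-dependent amplitudes
    are ``amplitude * class_gain[source, label]``.  Oscillatory phase and the
    artifact step time are randomized per call via ``rng``.
    """
    if label not in (0, 1):
        raise InvalidConfigError("label must be 0 or 1")
    rng = np.random.default_rng() if rng is None else rng
    t = config.times()
    S = np.zeros((truth.k_true, t.size))
    for s, kind in enumerate(truth.source_kinds):
        g = truth.class_gain[s, label]
        if kind == "slow-deflection":
            S[s] = config.slow_amplitude * g * _slow_waveform(t)
        elif kind == "evoked":
            S[s] = config.evoked_amplitude * g * _evoked_waveform(t)
        elif kind == "oscillatory":
            phase = rng.uniform(0, 2 * np.pi)
            amp = config.background_amplitude * config.noise_sd
            S[s] = amp * g * np.sin(2 * np.pi * OSC_FREQ * t + phase)
        elif kind == "artifact":
            t0 = rng.uniform(0.1, 0.6)
            S[s] = config.artifact_amplitude * g / (1.0 + np.exp(-(t - t0) / 0.02))
        # "noise" kind: stays zero (structure carried by the additive eps)
    return S


def simulate_epochs(config: SimulationConfig, layout: SensorLayout | None = None) -> SyntheticDataset:
    """Generate a full dataset: ``X = A_true S(label) + noise`` per trial.

    Deterministic under ``config.seed``; trial order is a seeded shuffle of
    the labels so classes are interleaved.  Epochs are stored as float32
    (single precision is ample for unit-scale signals and halves memory for
    the 204-channel, 1.2 s default).
    """
    layout = make_layout(config.n_channels, seed=config.seed) if layout is None else layout
    if layout.n_channels != config.n_channels:
        raise InvalidConfigError("layout channel count does not match config")
    truth = make_ground_truth(config, layout)
    rng = np.random.default_rng(config.seed)

    labels = np.concatenate(
        [np.ones(config.n_voluntary, dtype=int), np.zeros(config.n_spontaneous, dtype=int)]
    )
    rng.shuffle(labels)

    A32 = truth.A_true.astype(np.float32)
    epochs = np.empty((config.n_trials, config.n_channels, config.n_times), dtype=np.float32)
    for i, lab in enumerate(labels):
        S = simulate_sources(config, truth, int(lab), rng)
        epochs[i] = A32 @ S.astype(np.float32)
    if config.noise_sd > 0:
        epochs += np.float32(config.noise_sd) * rng.standard_normal(epochs.shape, dtype=np.float32)
    return SyntheticDataset(epochs=epochs, labels=labels, layout=layout, truth=truth, config=config)


# ---------------------------------------------------------------------------
# gaze log generation
# ---------------------------------------------------------------------------

GAZE_COLUMNS = [
    "event_id",
    "kind",
    "target_id",
    "onset_ms",
    "offset_ms",
    "initial_onset_latency_ms",
    "truth_intent",
]

#: cycle of boundary-case kinds emitted when boundary_fraction > 0
_BOUNDARY_CYCLE = ("delayed-confirmation", "late-onset", "below-threshold")


def simulate_gaze_log(
    n_moves: int,
    p_spontaneous: float,
    seed: int = 0,
    boundary_fraction: float = 0.0,
) -> pd.DataFrame:
    """Emit a gaze event log with known ground-truth intent per ball dwell.

    Each "move" is one ball dwell.  Voluntary moves (probability
    ``1 - p_spontaneous``) last 520-980 ms and are followed by a confirmatory
    fixation within 200 ms of the dwell end; spontaneous moves are ball dwells
    of >= 520 ms followed by unrelated fixations.  With
    ``boundary_fraction > 0`` a fixed rotation of boundary cases (delayed
    confirmation, late initial onset, below-threshold dwell) is interleaved;
    their ``truth_intent`` is ``excluded-<reason>``.
    """
    if not 0.0 <= p_spontaneous <= 1.0:
        raise InvalidConfigError("p_spontaneous must lie in [0, 1]")
    if not 0.0 <= boundary_fraction < 1.0:
        raise InvalidConfigError("boundary_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    clock = 1000.0
    event_id = 0
    boundary_i = 0

    def emit(kind, target, onset, offset, latency, truth):
        nonlocal event_id
        rows.append(
            {
                "event_id": event_id,
                "kind": kind,
                "target_id": target,
                "onset_ms": round(onset, 1),
                "offset_ms": round(offset, 1),
                "initial_onset_latency_ms": round(latency, 1),
                "truth_intent": truth,
            }
        )
        event_id += 1

    for move in range(n_moves):
        target = f"ball{move:03d}"
        if boundary_fraction > 0 and rng.random() < boundary_fraction:
            case = _BOUNDARY_CYCLE[boundary_i % len(_BOUNDARY_CYCLE)]
            boundary_i += 1
        elif rng.random() < p_spontaneous:
            case = "spontaneous"
        else:
            case = "voluntary"

        if case == "voluntary":
            dur = rng.uniform(520, 980)
            lat = rng.uniform(0, 45)
            emit("ball_dwell", target, clock, clock + dur, lat, "voluntary")
            confirm_on = clock + dur + rng.uniform(40, 190)
            confirm_dur = rng.uniform(500, 700)
            emit("confirm_fix", "confirm", confirm_on, confirm_on + confirm_dur, 0.0, "voluntary")
            clock = confirm_on + confirm_dur + rng.uniform(200, 800)
        elif case == "spontaneous":
            dur = rng.uniform(520, 1400)
            lat = rng.uniform(0, 45)
            emit("ball_dwell", target, clock, clock + dur, lat, "spontaneous")
            clock += dur + rng.uniform(30, 150)
            if rng.random() < 0.5:
                other_dur = rng.uniform(150, 400)
                emit("other_fix", "board", clock, clock + other_dur, 0.0, "spontaneous")
                clock += other_dur + rng.uniform(200, 800)
        elif case == "delayed-confirmation":
            dur = rng.uniform(520, 980)
            emit("ball_dwell", target, clock, clock + dur, rng.uniform(0, 45), "excluded-delayed-confirmation")
            confirm_on = clock + dur + rng.uniform(260, 500)
            confirm_dur = rng.uniform(500, 700)
            emit("confirm_fix", "confirm", confirm_on, confirm_on + confirm_dur, 0.0,
                 "excluded-delayed-confirmation")
            clock = confirm_on + confirm_dur + rng.uniform(200, 800)
        elif case == "late-onset":
            dur = rng.uniform(520, 980)
            emit("ball_dwell", target, clock, clock + dur, rng.uniform(60, 150), "excluded-late-onset")
            clock += dur + rng.uniform(200, 800)
        else:  # below-threshold
            dur = rng.uniform(150, 450)
            emit("ball_dwell", target, clock, clock + dur, rng.uniform(0, 45), "excluded-below-threshold")
            clock += dur + rng.uniform(200, 800)
        clock += rng.uniform(100, 400)

    return pd.DataFrame(rows, columns=GAZE_COLUMNS)
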
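"""Trial taxonomy for gaze dwells: voluntary, spontaneous, or excluded.

A ball dwell becomes a *voluntary* trial when the participant used it to issue
a command: the dwell reached the 500 ms threshold (triggering interface
feedback at onset + 500 ms), ended with a saccade within 500 ms of the
feedback, and was followed by a confirmatory fixation within 200 ms of the
dwell end.  Dwells of sufficient length whose next fixation is *not* a
confirmation are *spontaneous* — the gaze landed on a ball during natural
exploration.  Everything else is excluded with a reason: too short, unclear
initial fixation onset, or a confirmation arriving too late (which may mean
the decision was made only after seeing the feedback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MalformedLogError

__all__ = [
    "GazeEvent",
    "LabeledTrial",
    "label_fixations",
    "balance_classes",
    "participant_filter",
    "events_from_frame",
    "labels_to_frame",
]

VOLUNTARY = "voluntary"
SPONTANEOUS = "spontaneous"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class GazeEvent:
    kind: str  # ball_dwell | confirm_fix | other_fix
    target_id: str
    onset: float  # ms
    offset: float  # ms
    initial_onset_latency: float = 0.0  # ms between dwell onset and first detected fixation

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise MalformedLogError(f"event offset must exceed onset ({self.onset}..{self.offset})")
        if self.initial_onset_latency < 0:
            raise MalformedLogError("initial_onset_latency must be >= 0")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class LabeledTrial:
    event: GazeEvent
    label: str  # voluntary | spontaneous | excluded
    reason: str = ""  # non-empty iff excluded
    feedback_time: float | None = None  # ms; onset + dwell_threshold when feedback was issued


def _check_ordering(events: list[GazeEvent]) -> None:
    for a, b in zip(events, events[1:]):
        if b.onset < a.onset:
            raise MalformedLogError("events are not time-ordered")
        if b.onset < a.offset:
            raise MalformedLogError(
                f"overlapping events at {a.onset}..{a.offset} and {b.onset}..{b.offset}"
            )


def label_fixations(
    events: list[GazeEvent],
    dwell_threshold: float = 500.0,
    saccade_window: float = 500.0,
    confirm_window: float = 200.0,
    onset_tolerance: float = 50.0,
    confirm_anchor: str = "dwell_end",
) -> list[LabeledTrial]:
    """Assign exactly one label to every ball dwell in a time-ordered log.

    ``confirm_anchor`` selects the reference time for the ``confirm_window``:
    ``"dwell_end"`` (default) measures the confirmation latency from the end
    of the dwell, ``"feedback"`` from the feedback onset.  All windows are in
    milliseconds and inclusive at the boundary.
    """
    if confirm_anchor not in ("dwell_end", "feedback"):
        raise ValueError("confirm_anchor must be 'dwell_end' or 'feedback'")
    _check_ordering(events)

    out: list[LabeledTrial] = []
    for i, ev in enumerate(events):
        if ev.kind != "ball_dwell":
            continue
        if ev.duration < dwell_threshold:
            out.append(LabeledTrial(ev, EXCLUDED, "below-threshold"))
            continue
        feedback = ev.onset + dwell_threshold
        if ev.initial_onset_latency > onset_tolerance:
            out.append(LabeledTrial(ev, EXCLUDED, "late-onset", feedback))
            continue
        nxt = events[i + 1] if i + 1 < len(events) else None
        if nxt is not None and nxt.kind == "confirm_fix":
            anchor = ev.offset if confirm_anchor == "dwell_end" else feedback
            timely = (ev.offset - feedback <= saccade_window) and (nxt.onset - anchor <= confirm_window)
            if timely:
                out.append(LabeledTrial(ev, VOLUNTARY, "", feedback))
            else:
                out.append(LabeledTrial(ev, EXCLUDED, "delayed-confirmation", feedback))
        else:
            out.append(LabeledTrial(ev, SPONTANEOUS, "", feedback))
    return out


def balance_classes(labels: list[LabeledTrial], seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class sizes by randomly dropping trials from the larger class.

    Returns (voluntary_indices, spontaneous_indices) into ``labels``, each of
    length ``min(class sizes)``, sorted; the smaller class is untouched.
    """
    vol = np.array([i for i, t in enumerate(labels) if t.label == VOLUNTARY])
    spo = np.array([i for i, t in enumerate(labels) if t.label == SPONTANEOUS])
    if vol.size == 0 or spo.size == 0:
        raise InsufficientDataError("both classes must contain at least one trial")
    n = min(vol.size, spo.size)
    rng = np.random.default_rng(seed)
    if vol.size > n:
        vol = np.sort(rng.choice(vol, size=n, replace=False))
    if spo.size > n:
        spo = np.sort(rng.choice(spo, size=n, replace=False))
    return vol, spo


def participant_filter(trial_counts: dict, min_trials: int = 70) -> list:
    """Participants retained for analysis: voluntary trial count >= ``min_trials``."""
    return [p for p, n in trial_counts.items() if n >= min_trials]


# ---------------------------------------------------------------------------
# CSV plumbing (schema shared with synthetic.simulate_gaze_log)
# ---------------------------------------------------------------------------

def events_from_frame(df: pd.DataFrame) -> list[GazeEvent]:
    return [
        GazeEvent(
            kind=row.kind,
            target_id=str(row.target_id),
            onset=float(row.onset_ms),
            offset=float(row.offset_ms),
            initial_onset_latency=float(row.initial_onset_latency_ms),
        )
        for row in df.itertuples(index=False)
    ]


def labels_to_frame(trials: list[LabeledTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target_id": [t.event.target_id for t in trials],
            "onset_ms": [t.event.onset for t in trials],
            "offset_ms": [t.event.offset for t in trials],
            "label": [t.label for t in trials],
            "reason": [t.reason for t in trials],
            "feedback_time_ms": [t.feedback_time for t in trials],
        }
    )
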
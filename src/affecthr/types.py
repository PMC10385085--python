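"""Core domain types shared across the pipeline.

The label spaces come in two granularities: an 8-class fine facial-expression
vocabulary (six basic expressions plus neutral and contempt, the output space
of a frame-level FER model) and the coarse 3-class affect space
(negative / positive / neutral) that the heart-rate classifier predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

BPM_MIN = 30.0
BPM_MAX = 220.0


class AffectState(str, Enum):
    """Coarse 3-class affective state."""

    NEGATIVE = "negative"
    POSITIVE = "positive"
    NEUTRAL = "neutral"


class FineEmotion(str, Enum):
    """Fine-grained facial-expression class emitted per video frame."""

    FEAR = "fear"
    ANGER = "anger"
    SADNESS = "sadness"
    DISGUST = "disgust"
    SURPRISE = "surprise"
    HAPPINESS = "happiness"
    NEUTRAL = "neutral"
    CONTEMPT = "contempt"


#: Order used everywhere a 3-vector or confusion-matrix axis is indexed:
#: Neg, Pos, Nu.
CLASS_ORDER: tuple[AffectState, ...] = (
    AffectState.NEGATIVE,
    AffectState.POSITIVE,
    AffectState.NEUTRAL,
)

#: Fine emotions that are *consistent* with each coarse state.  Surprise and
#: contempt belong to no cluster: the generator emits them only as recognizer
#: noise, and the annotation mapping assigns them via a configurable
#: extension (see :func:`affecthr.annotation.map_to_affect`).
TRUTH_CLUSTERS: dict[AffectState, tuple[FineEmotion, ...]] = {
    AffectState.NEGATIVE: (
        FineEmotion.FEAR,
        FineEmotion.ANGER,
        FineEmotion.SADNESS,
        FineEmotion.DISGUST,
    ),
    AffectState.POSITIVE: (FineEmotion.HAPPINESS,),
    AffectState.NEUTRAL: (FineEmotion.NEUTRAL,),
}


@dataclass(frozen=True)
class StateSequence:
    """Latent per-second affect trajectory of one session."""

    states: tuple[AffectState, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("StateSequence must contain at least one second")

    @property
    def duration_s(self) -> int:
        return len(self.states)

    def state_at(self, t_s: float) -> AffectState:
        """State at time ``t_s`` seconds (floor to the containing second)."""
        idx = min(int(t_s), len(self.states) - 1)
        return self.states[idx]


@dataclass(frozen=True)
class HRSeries:
    """One subject's uniformly sampled heart-rate stream in BPM."""

    subject_id: str
    sampling_rate_hz: float
    bpm: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bpm", np.asarray(self.bpm, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.bpm.size == 0:
            raise ValueError("HRSeries must be non-empty")
        if np.any(self.bpm < BPM_MIN) or np.any(self.bpm > BPM_MAX):
            raise ValueError(f"BPM values must lie in [{BPM_MIN}, {BPM_MAX}]")

    @property
    def n_samples(self) -> int:
        return int(self.bpm.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class FramePrediction:
    """One frame's FER output: fine label plus prediction confidence."""

    frame_index: int
    label: FineEmotion
    confidence: float

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class LabeledWindow:
    """A fixed-length HR window paired with its 3-class affect label.

    ``provenance`` records whether the label came from the automatic FER
    path ("auto") or from human escalation ("human").
    """

    subject_id: str
    window_index: int
    hr_vector: np.ndarray
    affect: AffectState
    provenance: str
    confidence: float = float("nan")

    def __post_init__(self) -> None:
        self.hr_vector = np.asarray(self.hr_vector, dtype=float)
        if self.provenance not in ("auto", "human"):
            raise ValueError("provenance must be 'auto' or 'human'")


@dataclass
class FeatureVector:
    """A classifier input row: raw HR samples or concatenated DWT bands."""

    scheme: str  # "raw_hr" | "dwt"
    values: np.ndarray
    label: AffectState
    subject_id: str = ""
    window_index: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scheme not in ("raw_hr", "dwt"):
            raise ValueError(f"unknown feature scheme {self.scheme!r}")


def validate_simplex(probs: Sequence[float], atol: float = 1e-9) -> np.ndarray:
    """Validate a probability vector over the three affect states."""
    p = np.asarray(probs, dtype=float)
    if p.shape != (3,):
        raise ValueError("state_probs must have exactly three entries")
    if np.any(p < 0) or abs(p.sum() - 1.0) > atol:
        raise ValueError(f"state_probs must be a 3-simplex, got {probs}")
    return p
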
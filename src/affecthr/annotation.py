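"""Semi-automated emotion annotation of heart-rate windows.

A session video is cut into fixed-length clips of ``nf = fps * window_s``
frames.  Each clip is summarized by a representative frame — the modal fine
label, represented by its highest-confidence frame — whose label either
passes automatically to the coarse 3-class mapping or, when confidence
falls below a threshold, is escalated to a human annotator (modeled here as
an oracle interface; in tests, the synthetic ground truth).  Because the
heart-rate stream is time-aligned with the video, clip k's affect label is
attached to heart-rate window k.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

from .types import (
    AffectState,
    FineEmotion,
    FramePrediction,
    HRSeries,
    LabeledWindow,
    StateSequence,
    TRUTH_CLUSTERS,
)

#: Coarse cluster of each fine emotion, where stated: fear/anger/sadness/
#: disgust are negative, happiness positive, neutral neutral.
BASE_MAPPING: dict[FineEmotion, AffectState] = {
    fine: state for state, fines in TRUTH_CLUSTERS.items() for fine in fines
}

#: Surprise and contempt belong to no stated cluster; these defaults
#: (surprise -> positive, contempt -> negative) are configurable guesses.
DEFAULT_EXTENSION: dict[FineEmotion, AffectState] = {
    FineEmotion.SURPRISE: AffectState.POSITIVE,
    FineEmotion.CONTEMPT: AffectState.NEGATIVE,
}


@dataclass(frozen=True)
class Clip:
    """A contiguous run of exactly nf frame predictions."""

    clip_index: int
    frame_predictions: tuple[FramePrediction, ...]
    start_time_s: float

    def __post_init__(self) -> None:
        if len(self.frame_predictions) == 0:
            raise ValueError("Clip must contain at least one frame")


@dataclass
class RepresentativeFrame:
    """The single frame that labels an entire clip."""

    frame_index: int
    fine_label: FineEmotion
    confidence: float
    escalated: bool = False


HumanOracle = Callable[[RepresentativeFrame, dict], AffectState]


def clip_frame_count(fps: float, window_s: float) -> int:
    """nf = fps * window_s; must be a whole number of frames >= 1."""
    nf = fps * window_s
    if abs(nf - round(nf)) > 1e-9 or round(nf) < 1:
        raise ValueError(
            f"fps * window_s must be a positive integer frame count, got {nf}"
        )
    return int(round(nf))


def segment_clips(
    predictions: Sequence[FramePrediction], fps: float, window_s: float
) -> list[Clip]:
    """Cut a prediction stream into consecutive non-overlapping nf-frame clips.

    A trailing remainder shorter than nf frames is discarded.
    """
    if len(predictions) == 0:
        raise ValueError("prediction stream is empty")
    nf = clip_frame_count(fps, window_s)
    n_clips = len(predictions) // nf
    return [
        Clip(
            clip_index=k,
            frame_predictions=tuple(predictions[k * nf : (k + 1) * nf]),
            start_time_s=k * window_s,
        )
        for k in range(n_clips)
    ]


def select_representative(clip: Clip) -> RepresentativeFrame:
    """Choose the clip's representative frame by the two-criteria rule.

    (1) the representative label is the most frequent label in the clip;
    (2) among frames bearing that label, the one with maximal confidence is
    chosen.  Modal-count ties and equal-confidence ties are both resolved
    toward the lowest frame index, which makes the rule total and
    order-stable.
    """
    frames = clip.frame_predictions
    counts = Counter(f.label for f in frames)
    # sort key realizes the rule: frequency desc, confidence desc, index asc
    best = min(frames, key=lambda f: (-counts[f.label], -f.confidence, f.frame_index))
    return RepresentativeFrame(
        frame_index=best.frame_index,
        fine_label=best.label,
        confidence=best.confidence,
    )


def map_to_affect(
    fine: FineEmotion,
    extension: dict[FineEmotion, AffectState] | None = None,
) -> AffectState:
    """Cluster a fine emotion into the 3-class affect space (total mapping)."""
    if not isinstance(fine, FineEmotion):
        try:
            fine = FineEmotion(fine)
        except ValueError as exc:
            raise ValueError(f"unknown fine emotion label {fine!r}") from exc
    mapping = {**BASE_MAPPING, **(extension or DEFAULT_EXTENSION)}
    return mapping[fine]


def decide_escalation(
    rep: RepresentativeFrame,
    threshold: float,
    oracle: HumanOracle,
    context: dict | None = None,
    extension: dict[FineEmotion, AffectState] | None = None,
) -> tuple[AffectState, str]:
    """Auto-label or escalate to the human oracle.

    Escalation is strict: the oracle is consulted only when confidence is
    strictly below the threshold; the boundary value stays automatic.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    context = context or {}
    if rep.confidence >= threshold:
        rep.escalated = False
        return map_to_affect(rep.fine_label, extension), "auto"
    rep.escalated = True
    try:
        affect = oracle(rep, context)
    except Exception as exc:
        raise RuntimeError(
            f"human oracle failed on clip {context.get('clip_index', '?')}"
        ) from exc
    if not isinstance(affect, AffectState):
        raise ValueError(f"oracle returned invalid affect state {affect!r}")
    return affect, "human"


class TruthOracle:
    """Human-annotator stand-in backed by the synthetic ground truth.

    Returns the modal true state over the clip's time span; span ties are
    broken toward the earlier-occurring state, mimicking an annotator who
    labels by the dominant affect of the clip.
    """

    def __init__(self, truth: StateSequence, window_s: float):
        self.truth = truth
        self.window_s = window_s

    def __call__(self, rep: RepresentativeFrame, context: dict) -> AffectState:
        k = context["clip_index"]
        lo = int(k * self.window_s)
        hi = int(min((k + 1) * self.window_s, self.truth.duration_s))
        span = self.truth.states[lo:hi]
        if not span:
            return self.truth.states[-1]
        counts = Counter(span)
        return max(counts, key=lambda s: (counts[s], -span.index(s)))


def synchronize(
    hr: HRSeries,
    clip_labels: Sequence[tuple[int, AffectState, str]],
    window_s: float,
    confidences: Sequence[float] | None = None,
    offset_s: float = 0.0,
) -> list[LabeledWindow]:
    """Attach clip labels to index-aligned heart-rate windows.

    Window k holds HR samples [k*n, (k+1)*n) with n = window_s *
    sampling_rate_hz; the output is limited by whichever stream is shorter.
    ``offset_s`` shifts the HR indexing when the streams start at different
    times.
    """
    n_f = window_s * hr.sampling_rate_hz
    if abs(n_f - round(n_f)) > 1e-9 or round(n_f) < 1:
        raise ValueError(
            f"window_s * sampling_rate_hz must be a positive integer, got {n_f}"
        )
    n = int(round(n_f))
    start = int(round(offset_s * hr.sampling_rate_hz))
    usable = hr.n_samples - start
    n_windows = min(len(clip_labels), max(usable, 0) // n)
    if n_windows == 0:
        raise ValueError("zero overlapping windows between HR and clip streams")

    out: list[LabeledWindow] = []
    for k in range(n_windows):
        clip_index, affect, provenance = clip_labels[k]
        conf = float("nan") if confidences is None else float(confidences[k])
        out.append(
            LabeledWindow(
                subject_id=hr.subject_id,
                window_index=k,
                hr_vector=hr.bpm[start + k * n : start + (k + 1) * n],
                affect=affect,
                provenance=provenance,
                confidence=conf,
            )
        )
    return out


def annotate_session(
    fer: Sequence[FramePrediction],
    hr: HRSeries,
    fps: float,
    window_s: float,
    threshold: float,
    oracle: HumanOracle,
    extension: dict[FineEmotion, AffectState] | None = None,
    offset_s: float = 0.0,
) -> tuple[list[LabeledWindow], list[dict]]:
    """Run the full annotation chain for one session.

    Returns the labeled HR windows and an audit log with one record per
    clip (modal label, confidence, escalation flag).
    """
    clips = segment_clips(fer, fps, window_s)
    clip_labels: list[tuple[int, AffectState, str]] = []
    confidences: list[float] = []
    audit: list[dict] = []
    for clip in clips:
        rep = select_representative(clip)
        affect, provenance = decide_escalation(
            rep,
            threshold,
            oracle,
            context={"clip_index": clip.clip_index, "subject_id": hr.subject_id},
            extension=extension,
        )
        clip_labels.append((clip.clip_index, affect, provenance))
        confidences.append(rep.confidence)
        audit.append(
            {
                "clip_index": clip.clip_index,
                "modal_label": rep.fine_label.value,
                "confidence": rep.confidence,
                "escalated": rep.escalated,
                "affect": affect.value,
                "provenance": provenance,
            }
        )
    windows = synchronize(
        hr, clip_labels, window_s, confidences=confidences, offset_s=offset_s
    )
    return windows, audit
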
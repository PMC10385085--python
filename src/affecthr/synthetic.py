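"""Synthetic cohort generator.

Emulates the statistical structure of a nine-child study session: a latent
3-state affect process (semi-Markov, geometric dwell times) drives both a
smartwatch heart-rate stream (baseline + per-state BPM offset + Gaussian
noise, clipped to a physiological range) and a noisy frame-level
facial-expression prediction stream at video frame rate.  The ground-truth
state sequence is retained alongside each session so downstream stages can
be evaluated against a known truth.

Calibration targets: cohort mean heart rate near 96.8 BPM with individual
extremes inside 62-124 BPM, session durations 480-846 s, 25 fps video.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    BPM_MAX,
    BPM_MIN,
    CLASS_ORDER,
    AffectState,
    FineEmotion,
    FramePrediction,
    HRSeries,
    StateSequence,
    TRUTH_CLUSTERS,
    validate_simplex,
)

ALL_FINE: tuple[FineEmotion, ...] = tuple(FineEmotion)


@dataclass(frozen=True)
class ConfidenceParams:
    """Beta parameters of the FER confidence distributions.

    Cluster-consistent predictions draw from Beta(correct_a, correct_b)
    (mean 0.8 by default) and inconsistent ones from Beta(incorrect_a,
    incorrect_b) (mean 1/3), so confidence correlates with correctness and
    threshold-based human escalation is meaningful.
    """

    correct_a: float = 8.0
    correct_b: float = 2.0
    incorrect_a: float = 2.0
    incorrect_b: float = 4.0

    def validate(self) -> None:
        for v in (self.correct_a, self.correct_b, self.incorrect_a, self.incorrect_b):
            if v <= 0:
                raise ValueError("Beta parameters must be positive")


def _default_offsets() -> dict[AffectState, float]:
    return {
        AffectState.NEGATIVE: 12.0,
        AffectState.POSITIVE: -6.0,
        AffectState.NEUTRAL: 0.0,
    }


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the emulated study: 9 subjects, 480-846 s sessions,
    96.8 BPM mean heart rate, 25 fps video, 1 Hz heart-rate sampling.
    Negative affect raises heart rate (+12 BPM) and positive affect lowers
    it slightly (-6 BPM), consistent with arousal-driven cardiac response.
    """

    n_subjects: int = 9
    duration_range_s: tuple[int, int] = (480, 846)
    baseline_bpm_mean: float = 96.8
    baseline_bpm_sd: float = 8.0
    state_offsets: dict[AffectState, float] = field(default_factory=_default_offsets)
    hr_noise_sd: float = 3.0
    sampling_rate_hz: float = 1.0
    fps: int = 25
    fer_accuracy: float = 0.8
    dwell_mean_s: float = 20.0
    state_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    confidence: ConfidenceParams = field(default_factory=ConfidenceParams)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.duration_range_s
        if not (1 <= lo <= hi <= 86400):
            raise ValueError("duration_range_s must satisfy 1 <= lo <= hi <= 86400")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.fer_accuracy <= 1.0:
            raise ValueError("fer_accuracy must lie in [0, 1]")
        if self.sampling_rate_hz <= 0 or self.fps <= 0:
            raise ValueError("sampling_rate_hz and fps must be positive")
        if self.hr_noise_sd < 0:
            raise ValueError("hr_noise_sd must be non-negative")
        if self.dwell_mean_s < 1:
            raise ValueError("dwell_mean_s must be >= 1")
        validate_simplex(self.state_probs)
        self.confidence.validate()
        missing = [s for s in AffectState if s not in self.state_offsets]
        if missing:
            raise ValueError(f"state_offsets missing states: {missing}")


@dataclass
class Session:
    """One generated subject session with its retained ground truth."""

    subject_id: str
    hr: HRSeries
    fer: list[FramePrediction]
    truth: StateSequence
    baseline_bpm: float


def generate_state_sequence(
    duration_s: int,
    dwell_mean_s: float = 20.0,
    state_probs: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> StateSequence:
    """Draw a per-second latent affect trajectory.

    Segments alternate by drawing a state i.i.d. from ``state_probs`` and a
    dwell time from Geometric(1/dwell_mean_s) (support >= 1 s), giving
    contiguous affect episodes whose long-run state frequencies converge to
    ``state_probs``.
    """
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1")
    if dwell_mean_s < 1:
        raise ValueError("dwell_mean_s must be >= 1")
    p = validate_simplex(state_probs)
    if rng is None:
        rng = np.random.default_rng(seed)

    states: list[AffectState] = []
    while len(states) < duration_s:
        s = CLASS_ORDER[rng.choice(3, p=p)]
        dwell = int(rng.geometric(1.0 / dwell_mean_s))
        states.extend([s] * dwell)
    return StateSequence(states=tuple(states[:duration_s]))


def generate_hr(
    seq: StateSequence,
    baseline_bpm: float,
    state_offsets: dict[AffectState, float],
    noise_sd: float,
    sampling_rate_hz: float = 1.0,
    seed: int | None = 0,
    subject_id: str = "S0",
    t0: float = 0.0,
    rng: np.random.Generator | None = None,
) -> HRSeries:
    """Render a BPM stream from a latent state trajectory.

    bpm[k] = baseline + offset(state at k/rate) + N(0, noise_sd), clipped to
    the physiological range [30, 220].
    """
    missing = [s for s in AffectState if s not in state_offsets]
    if missing:
        raise ValueError(f"state_offsets missing states: {missing}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)

    n = int(round(seq.duration_s * sampling_rate_hz))
    sample_times = np.arange(n) / sampling_rate_hz
    offsets = np.array(
        [state_offsets[seq.state_at(t)] for t in sample_times], dtype=float
    )
    bpm = baseline_bpm + offsets
    if noise_sd > 0:
        bpm = bpm + rng.normal(0.0, noise_sd, size=n)
    bpm = np.clip(bpm, BPM_MIN, BPM_MAX)
    return HRSeries(
        subject_id=subject_id, sampling_rate_hz=sampling_rate_hz, bpm=bpm, t0=t0
    )


def generate_fer_stream(
    seq: StateSequence,
    fps: int = 25,
    fer_accuracy: float = 0.8,
    confidence_params: ConfidenceParams | None = None,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[FramePrediction]:
    """Emit one fine-grained prediction per video frame.

    With probability ``fer_accuracy`` the frame's label is drawn uniformly
    from the fine classes consistent with the true coarse state; otherwise
    uniformly from the complement (which is where surprise and contempt
    appear, since no latent state maps to them).  Confidence is drawn from
    the correct/incorrect Beta distribution accordingly.
    """
    if not 0.0 <= fer_accuracy <= 1.0:
        raise ValueError("fer_accuracy must lie in [0, 1]")
    if fps <= 0:
        raise ValueError("fps must be positive")
    cp = confidence_params or ConfidenceParams()
    cp.validate()
    if rng is None:
        rng = np.random.default_rng(seed)

    n_frames = seq.duration_s * fps
    # per-frame true state index into CLASS_ORDER
    state_idx = np.fromiter(
        (CLASS_ORDER.index(seq.states[f // fps]) for f in range(n_frames)),
        dtype=np.int64,
        count=n_frames,
    )
    consistent = rng.random(n_frames) < fer_accuracy

    labels: np.ndarray = np.empty(n_frames, dtype=object)
    for si, state in enumerate(CLASS_ORDER):
        pool_ok = TRUTH_CLUSTERS[state]
        pool_bad = tuple(f for f in ALL_FINE if f not in pool_ok)
        for ok, pool in ((True, pool_ok), (False, pool_bad)):
            mask = (state_idx == si) & (consistent == ok)
            cnt = int(mask.sum())
            if cnt:
                picks = rng.integers(0, len(pool), size=cnt)
                labels[mask] = np.array(pool, dtype=object)[picks]

    conf = np.empty(n_frames, dtype=float)
    n_ok = int(consistent.sum())
    conf[consistent] = rng.beta(cp.correct_a, cp.correct_b, size=n_ok)
    conf[~consistent] = rng.beta(cp.incorrect_a, cp.incorrect_b, size=n_frames - n_ok)

    return [
        FramePrediction(frame_index=i, label=labels[i], confidence=float(conf[i]))
        for i in range(n_frames)
    ]


def generate_cohort(config: CohortConfig) -> list[Session]:
    """Generate the full cohort, reproducible bit-for-bit from config.seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    root = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(config.n_subjects + 1)[1:]

    lo, hi = config.duration_range_s
    durations = root.integers(lo, hi + 1, size=config.n_subjects)
    baselines = root.normal(
        config.baseline_bpm_mean, config.baseline_bpm_sd, size=config.n_subjects
    )

    sessions: list[Session] = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(child_seeds[i])
        sid = f"P{i + 1}"
        seq = generate_state_sequence(
            int(durations[i]),
            dwell_mean_s=config.dwell_mean_s,
            state_probs=config.state_probs,
            rng=rng,
        )
        hr = generate_hr(
            seq,
            baseline_bpm=float(baselines[i]),
            state_offsets=config.state_offsets,
            noise_sd=config.hr_noise_sd,
            sampling_rate_hz=config.sampling_rate_hz,
            subject_id=sid,
            rng=rng,
        )
        fer = generate_fer_stream(
            seq,
            fps=config.fps,
            fer_accuracy=config.fer_accuracy,
            confidence_params=config.confidence,
            rng=rng,
        )
        sessions.append(
            Session(
                subject_id=sid,
                hr=hr,
                fer=fer,
                truth=seq,
                baseline_bpm=float(baselines[i]),
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

def hr_to_frame(hr: HRSeries) -> pd.DataFrame:
    return pd.DataFrame({"t_s": hr.times_s, "bpm": hr.bpm})


def fer_to_frame(fer: Sequence[FramePrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame_index": [p.frame_index for p in fer],
            "label": [p.label.value for p in fer],
            "confidence": [p.confidence for p in fer],
        }
    )


def truth_to_frame(seq: StateSequence) -> pd.DataFrame:
    return pd.DataFrame(
        {"t_s": np.arange(seq.duration_s), "state": [s.value for s in seq.states]}
    )


def read_hr_csv(path: Path | str, subject_id: str, sampling_rate_hz: float = 1.0) -> HRSeries:
    df = pd.read_csv(path)
    return HRSeries(
        subject_id=subject_id,
        sampling_rate_hz=sampling_rate_hz,
        bpm=df["bpm"].to_numpy(dtype=float),
        t0=float(df["t_s"].iloc[0]),
    )


def read_fer_csv(path: Path | str) -> list[FramePrediction]:
    df = pd.read_csv(path)
    return [
        FramePrediction(
            frame_index=int(r.frame_index),
            label=FineEmotion(r.label),
            confidence=float(r.confidence),
        )
        for r in df.itertuples(index=False)
    ]


def read_truth_csv(path: Path | str) -> StateSequence:
    df = pd.read_csv(path)
    return StateSequence(states=tuple(AffectState(s) for s in df["state"]))


def write_cohort(
    sessions: Sequence[Session], out_dir: Path | str, config: CohortConfig
) -> dict:
    """Write per-subject CSVs plus a JSON manifest echoing the config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict[str, str]] = {}
    for s in sessions:
        paths = {
            "hr": out / f"hr_{s.subject_id}.csv",
            "fer": out / f"fer_{s.subject_id}.csv",
            "truth": out / f"truth_{s.subject_id}.csv",
        }
        hr_to_frame(s.hr).to_csv(paths["hr"], index=False, float_format="%.6f")
        fer_to_frame(s.fer).to_csv(paths["fer"], index=False, float_format="%.6f")
        truth_to_frame(s.truth).to_csv(paths["truth"], index=False)
        files[s.subject_id] = {k: p.name for k, p in paths.items()}

    cfg = asdict(config)
    cfg["state_offsets"] = {k.value: v for k, v in config.state_offsets.items()}
    manifest = {"config": cfg, "seed": config.seed, "files": files}
    with open(out / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
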
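"""Annotation chain tests: clip segmentation, representative-frame rule,
escalation, 8-to-3 clustering, and HR/video synchronization."""

from collections import Counter

import numpy as np
import pytest

from affecthr.annotation import (
    Clip,
    TruthOracle,
    annotate_session,
    decide_escalation,
    map_to_affect,
    segment_clips,
    select_representative,
    synchronize,
)
from affecthr.synthetic import generate_fer_stream, generate_hr, generate_state_sequence
from affecthr.types import (
    CLASS_ORDER,
    FineEmotion,
    FramePrediction,
    HRSeries,
    StateSequence,
)

NEG, POS, NEU = CLASS_ORDER
FINES = list(FineEmotion)


def make_stream(n, label=FineEmotion.HAPPINESS, conf=0.9):
    return [FramePrediction(i, label, conf) for i in range(n)]


class TestSegmentClips:
    def test_two_second_windows_at_25fps_give_50_frames(self):
        clips = segment_clips(make_stream(200), fps=25, window_s=2)
        assert all(len(c.frame_predictions) == 50 for c in clips)

    def test_exact_division(self):
        clips = segment_clips(make_stream(100), fps=25, window_s=2)
        assert len(clips) == 2
        assert [f.frame_index for f in clips[0].frame_predictions] == list(range(50))
        assert [f.frame_index for f in clips[1].frame_predictions] == list(range(50, 100))

    def test_trailing_remainder_discarded(self):
        clips = segment_clips(make_stream(125), fps=25, window_s=2)
        assert len(clips) == 2
        assert sum(len(c.frame_predictions) for c in clips) == 100

    def test_non_integer_frame_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            segment_clips(make_stream(100), fps=25, window_s=0.1)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            segment_clips([], fps=25, window_s=2)


def brute_force_representative(clip):
    """Independent realization of the two-criteria rule by full enumeration."""
    counts = Counter(f.label for f in clip.frame_predictions)
    max_count = max(counts.values())
    candidates = []
    for label in counts:
        if counts[label] == max_count:
            frames = [f for f in clip.frame_predictions if f.label == label]
            best_conf = max(f.confidence for f in frames)
            best = min(
                f.frame_index for f in frames if f.confidence == best_conf
            )
            candidates.append((label, best_conf, best))
    # among tied modal labels: highest confidence, then lowest frame index
    label, conf, idx = max(candidates, key=lambda c: (c[1], -c[2]))
    return label, conf, idx


class TestSelectRepresentative:
    def test_unanimous_clip(self):
        clip = Clip(0, tuple(make_stream(50, FineEmotion.HAPPINESS, 0.9)), 0.0)
        rep = select_representative(clip)
        assert rep.fine_label is FineEmotion.HAPPINESS
        assert rep.confidence == 0.9

    def test_mode_wins_over_raw_confidence(self):
        frames = (
            FramePrediction(0, FineEmotion.NEUTRAL, 0.5),
            FramePrediction(1, FineEmotion.NEUTRAL, 0.7),
            FramePrediction(2, FineEmotion.NEUTRAL, 0.6),
            FramePrediction(3, FineEmotion.FEAR, 0.99),
            FramePrediction(4, FineEmotion.FEAR, 0.98),
        )
        rep = select_representative(Clip(0, frames, 0.0))
        assert rep.fine_label is FineEmotion.NEUTRAL
        assert rep.confidence == 0.7
        assert rep.frame_index == 1

    def test_modal_tie_equal_confidence_resolved_by_lowest_index(self):
        frames = tuple(
            [FramePrediction(i, FineEmotion.HAPPINESS, 0.8 if i == 3 else 0.1)
             for i in range(25)]
            + [FramePrediction(25 + i, FineEmotion.SADNESS, 0.8 if i == 0 else 0.1)
               for i in range(25)]
        )
        rep = select_representative(Clip(0, frames, 0.0))
        # happiness's best frame (index 3) precedes sadness's best (index 25)
        assert rep.fine_label is FineEmotion.HAPPINESS
        assert rep.frame_index == 3

    def test_matches_brute_force_on_random_clips(self, rng):
        for _ in range(1000):
            nf = int(rng.integers(2, 60))
            labels = rng.integers(0, len(FINES), size=nf)
            # coarse confidence grid to provoke frequent exact ties
            confs = rng.integers(0, 5, size=nf) / 4.0
            frames = tuple(
                FramePrediction(i, FINES[labels[i]], float(confs[i]))
                for i in range(nf)
            )
            rep = select_representative(Clip(0, frames, 0.0))
            label, conf, idx = brute_force_representative(Clip(0, frames, 0.0))
            assert (rep.fine_label, rep.confidence, rep.frame_index) == (
                label, conf, idx,
            )


class TestMapToAffect:
    def test_stated_clusters(self):
        for fine in (FineEmotion.FEAR, FineEmotion.ANGER, FineEmotion.SADNESS,
                     FineEmotion.DISGUST):
            assert map_to_affect(fine) is NEG
        assert map_to_affect(FineEmotion.HAPPINESS) is POS
        assert map_to_affect(FineEmotion.NEUTRAL) is NEU

    def test_extension_defaults(self):
        assert map_to_affect(FineEmotion.SURPRISE) is POS
        assert map_to_affect(FineEmotion.CONTEMPT) is NEG

    def test_extension_is_configurable(self):
        ext = {FineEmotion.SURPRISE: NEU, FineEmotion.CONTEMPT: NEU}
        assert map_to_affect(FineEmotion.SURPRISE, extension=ext) is NEU

    def test_mapping_is_total_with_three_class_image(self):
        image = {map_to_affect(f) for f in FineEmotion}
        assert image == set(CLASS_ORDER)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            map_to_affect("boredom")


class TestEscalation:
    @staticmethod
    def oracle_negative(rep, context):
        return NEG

    def test_above_threshold_stays_automatic(self):
        rep = select_representative(
            Clip(0, tuple(make_stream(10, FineEmotion.HAPPINESS, 0.9)), 0.0)
        )
        affect, prov = decide_escalation(rep, 0.5, self.oracle_negative)
        assert (affect, prov) == (POS, "auto")
        assert rep.escalated is False

    def test_below_threshold_goes_to_oracle(self):
        rep = select_representative(
            Clip(0, tuple(make_stream(10, FineEmotion.HAPPINESS, 0.3)), 0.0)
        )
        affect, prov = decide_escalation(rep, 0.5, self.oracle_negative)
        assert (affect, prov) == (NEG, "human")
        assert rep.escalated is True

    def test_boundary_confidence_is_automatic(self):
        rep = select_representative(
            Clip(0, tuple(make_stream(10, FineEmotion.NEUTRAL, 0.5)), 0.0)
        )
        _, prov = decide_escalation(rep, 0.5, self.oracle_negative)
        assert prov == "auto"

    def test_oracle_failure_carries_clip_context(self):
        def broken(rep, context):
            raise KeyError("nope")

        rep = select_representative(
            Clip(0, tuple(make_stream(10, FineEmotion.NEUTRAL, 0.1)), 0.0)
        )
        with pytest.raises(RuntimeError, match="clip 7"):
            decide_escalation(rep, 0.9, broken, context={"clip_index": 7})

    def test_escalated_fraction_monotone_in_threshold(self):
        seq = generate_state_sequence(300, dwell_mean_s=10, seed=2)
        fer = generate_fer_stream(seq, fps=25, fer_accuracy=0.7, seed=2)
        hr = generate_hr(seq, 96.8, {NEG: 12.0, POS: -6.0, NEU: 0.0}, 2.0, seed=2)
        oracle = TruthOracle(seq, 2.0)
        fractions = []
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
            _, audit = annotate_session(
                fer, hr, fps=25, window_s=2.0, threshold=thr, oracle=oracle
            )
            fractions.append(np.mean([a["escalated"] for a in audit]))
        assert fractions[0] == 0.0
        assert fractions[-1] == 1.0
        assert all(a <= b + 1e-12 for a, b in zip(fractions, fractions[1:]))


class TestSynchronize:
    OFFSETS = {NEG: 12.0, POS: -6.0, NEU: 0.0}

    def test_828s_session_gives_414_windows(self):
        hr = HRSeries("P1", 1.0, np.full(828, 96.8))
        clip_labels = [(k, NEU, "auto") for k in range(414)]
        windows = synchronize(hr, clip_labels, window_s=2.0)
        assert len(windows) == 414
        assert all(len(w.hr_vector) == 2 for w in windows)

    def test_hr_limited_min_rule(self):
        hr = HRSeries("P1", 1.0, np.full(10, 90.0))
        clip_labels = [(k, NEU, "auto") for k in range(10)]  # 20 s of video
        windows = synchronize(hr, clip_labels, window_s=2.0)
        assert len(windows) == 5

    def test_zero_overlap_rejected(self):
        hr = HRSeries("P1", 1.0, np.full(3, 90.0))
        with pytest.raises(ValueError, match="zero overlapping"):
            synchronize(hr, [], window_s=2.0)

    def test_offset_shifts_hr_indexing(self):
        bpm = np.arange(30, 50, dtype=float) + 40
        hr = HRSeries("P1", 1.0, bpm)
        windows = synchronize(
            hr, [(0, NEU, "auto"), (1, NEU, "auto")], window_s=2.0, offset_s=4.0
        )
        assert windows[0].hr_vector.tolist() == [74.0, 75.0]

    def test_perfect_fer_recovers_modal_ground_truth(self):
        seq = generate_state_sequence(400, dwell_mean_s=15, seed=3)
        fer = generate_fer_stream(seq, fps=25, fer_accuracy=1.0, seed=3)
        hr = generate_hr(seq, 96.8, self.OFFSETS, 2.0, seed=3)
        windows, _ = annotate_session(
            fer, hr, fps=25, window_s=2.0, threshold=0.0,
            oracle=TruthOracle(seq, 2.0),
        )
        n_match = 0
        n_pure = 0
        for w in windows:
            span = seq.states[w.window_index * 2 : (w.window_index + 1) * 2]
            modal = max(set(span), key=span.count)
            if len(set(span)) == 1:
                n_pure += 1
                assert w.affect is modal  # state-pure windows must match
            if w.affect is modal:
                n_match += 1
        assert n_match >= n_pure

    def test_provenance_counts_conserve_window_total(self):
        seq = generate_state_sequence(300, dwell_mean_s=10, seed=5)
        fer = generate_fer_stream(seq, fps=25, fer_accuracy=0.7, seed=5)
        hr = generate_hr(seq, 96.8, self.OFFSETS, 2.0, seed=5)
        windows, _ = annotate_session(
            fer, hr, fps=25, window_s=2.0, threshold=0.6,
            oracle=TruthOracle(seq, 2.0),
        )
        n_auto = sum(w.provenance == "auto" for w in windows)
        n_human = sum(w.provenance == "human" for w in windows)
        assert n_auto + n_human == len(windows) == min(300 * 25 // 50, 300 // 2)
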
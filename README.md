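# affecthr

Heart-rate-based recognition of coarse affective state (negative /
positive / neutral) for children with autism spectrum disorder in
naturalistic settings, where a smartwatch streams beats-per-minute (BPM)
values while the child works through an interactive learning session.
Because the true internal affect of a child with ASD is hard to elicit
directly, ground-truth labels come from a *semi-automated* annotation
chain: a frame-level facial-expression recognizer proposes a label for
each short video clip, and a human annotator steps in only when the
recognizer's confidence is low.

This package implements that full analysis pipeline as tested, reusable
code, exercised end to end on a synthetic cohort generator (the study's
video/HR recordings are not public), so every stage can be validated
against a known ground truth.

## The pipeline

1. **Simulation** (`affecthr.synthetic`) — a latent 3-state semi-Markov
   affect process per subject drives both a 1 Hz heart-rate stream
   (`bpm[k] = baseline + offset(state) + N(0, σ)`, clipped to 30–220 BPM)
   and a noisy 25 fps facial-expression prediction stream over 8 fine
   classes with Beta-distributed confidences. Defaults: 9 subjects,
   480–846 s sessions, cohort mean ≈ 97 BPM.
2. **Annotation** (`affecthr.annotation`) — the prediction stream is cut
   into clips of `nf = fps × window_s` frames (50 frames for 2 s windows at
   25 fps). Each clip is reduced to a *representative frame*: the modal
   fine label, represented by its highest-confidence frame. If that
   confidence is below a threshold the clip escalates to a human oracle;
   otherwise the fine label is clustered into the 3-class space
   (fear/anger/sadness/disgust → negative, happiness → positive,
   neutral → neutral). Labels transfer to the index-aligned HR windows.
3. **Features** (`affecthr.features`) — each labeled window
   `V = (h(t−(n−1)), …, h(t))` is fed to the classifier either raw or as
   its orthonormal Haar discrete-wavelet decomposition (from-scratch
   filter-and-downsample sub-band coding):
   `A[i] = (s[2i]+s[2i+1])/√2`, `D[i] = (s[2i]−s[2i+1])/√2`, recursed on
   the approximation band; the feature vector is `[A_L, D_L, …, D_1]`.
4. **Evaluation** (`affecthr.evaluate`) — stratified ten-fold
   cross-validation of SVM (RBF, C=1), 5-NN and 100-tree random-forest
   classifiers, in two regimes: *intra-subject* (train/test within one
   child) and *inter-subject* (pooled cohort). Reported: per-fold
   accuracy (= trace/total of the pooled 3×3 confusion matrix), macro
   precision/recall, and their harmonic-mean F1.

## Worked example

Run the numbered analysis scripts in order (each is a thin driver over
the package):

```bash
python analysis/01_simulate.py --seed 1 --out scratch/cohort
python analysis/02_annotate.py --cohort scratch/cohort --out scratch/labels
python analysis/03_featurize.py --cohort scratch/cohort --labels scratch/labels --out scratch/features
python analysis/04_evaluate.py --features scratch/features --out scratch/reports --seed 1
```

Output of the run above:

```
wrote 9 sessions to scratch/cohort
durations: 485-784 s
cohort HR: mean 99.0 BPM, min 70.1 BPM, max 125.0 BPM
...
inter-subject mean accuracy:
classifier    knn  random_forest    svm
scheme
dwt         0.609          0.611    0.604
raw_hr      0.611          0.591    0.627

intra-subject mean accuracy (all subjects): 0.927
```

Reading this: the generated cohort's heart-rate envelope sits in the
calibrated physiological range; with per-subject baseline variation of
8 BPM the pooled (inter-subject) task is much harder (~0.6) than the
subject-dependent one (~0.93), reproducing the qualitative gap between
the two regimes — individual differences in resting heart rate dominate
the pooled feature space. With 2-sample windows the DWT is an orthonormal
rotation of the raw features, so the two schemes perform comparably.

`analysis/05_report.py` runs the same flow under a single `RunConfig`
(YAML-serializable), writes a SHA-256 manifest for reproducibility
checking, and renders a markdown summary with confusion matrices and the
escalation rate.

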
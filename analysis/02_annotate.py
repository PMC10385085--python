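"""Semi-automated annotation of the simulated cohort.

Reads the cohort written by 01_simulate.py, segments each session's
prediction stream into 2 s clips (nf = 50 frames at 25 fps), picks each
clip's representative frame, escalates low-confidence clips to the
ground-truth-backed human oracle, and attaches the resulting 3-class
labels to the aligned heart-rate windows.  Writes per-subject label and
audit CSVs and prints the overall escalation rate.
"""

import argparse
from pathlib import Path

import pandas as pd

from affecthr.annotation import TruthOracle, annotate_session
from affecthr.synthetic import read_fer_csv, read_hr_csv, read_truth_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/labels"))
    ap.add_argument("--window-s", type=float, default=2.0)
    ap.add_argument("--fps", type=float, default=25.0)
    ap.add_argument("--threshold", type=float, default=0.5)
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    escalated = total = 0
    for hr_path in sorted(args.cohort.glob("hr_*.csv")):
        sid = hr_path.stem.removeprefix("hr_")
        hr = read_hr_csv(hr_path, subject_id=sid)
        fer = read_fer_csv(args.cohort / f"fer_{sid}.csv")
        truth = read_truth_csv(args.cohort / f"truth_{sid}.csv")
        windows, audit = annotate_session(
            fer,
            hr,
            fps=args.fps,
            window_s=args.window_s,
            threshold=args.threshold,
            oracle=TruthOracle(truth, args.window_s),
        )
        pd.DataFrame(
            {
                "window_index": [w.window_index for w in windows],
                "affect": [w.affect.value for w in windows],
                "provenance": [w.provenance for w in windows],
                "confidence": [w.confidence for w in windows],
            }
        ).to_csv(args.out / f"labels_{sid}.csv", index=False, float_format="%.6f")
        pd.DataFrame(audit).to_csv(
            args.out / f"audit_{sid}.csv", index=False, float_format="%.6f"
        )
        escalated += sum(a["escalated"] for a in audit)
        total += len(audit)
        print(f"{sid}: {len(windows)} labeled windows")

    print(f"escalation rate at threshold {args.threshold}: {escalated / total:.3f}")


if __name__ == "__main__":
    main()
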
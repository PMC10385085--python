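"""Extract classifier features from the labeled heart-rate windows.

Builds both feature schemes for every subject: the raw n-sample BPM
vector, and the from-scratch orthonormal Haar DWT coefficient vector
[A_L, D_L, ..., D_1] at maximal depth.  Writes features_<scheme>_<id>.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from affecthr.features import assemble_features
from affecthr.synthetic import read_hr_csv
from affecthr.types import AffectState, LabeledWindow


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--labels", type=Path, default=Path("results/labels"))
    ap.add_argument("--out", type=Path, default=Path("results/features"))
    ap.add_argument("--window-s", type=float, default=2.0)
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    for labels_path in sorted(args.labels.glob("labels_*.csv")):
        sid = labels_path.stem.removeprefix("labels_")
        hr = read_hr_csv(args.cohort / f"hr_{sid}.csv", subject_id=sid)
        labels = pd.read_csv(labels_path)
        n = int(args.window_s * hr.sampling_rate_hz)
        windows = [
            LabeledWindow(
                subject_id=sid,
                window_index=int(r.window_index),
                hr_vector=hr.bpm[int(r.window_index) * n : (int(r.window_index) + 1) * n],
                affect=AffectState(r.affect),
                provenance=r.provenance,
            )
            for r in labels.itertuples(index=False)
        ]
        for scheme in ("raw_hr", "dwt"):
            feats = assemble_features(windows, scheme=scheme)
            mat = np.vstack([f.values for f in feats])
            df = pd.DataFrame(mat, columns=[f"f{i + 1}" for i in range(mat.shape[1])])
            df.insert(0, "window_index", [f.window_index for f in feats])
            df.insert(1, "scheme", scheme)
            df["label"] = [f.label.value for f in feats]
            df.to_csv(
                args.out / f"features_{scheme}_{sid}.csv",
                index=False,
                float_format="%.6f",
            )
        print(f"{sid}: {len(windows)} windows -> {mat.shape[1]} features/scheme")


if __name__ == "__main__":
    main()
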
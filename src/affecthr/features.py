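"""Heart-rate window vectors and Haar wavelet features.

The classifier input for each labeled window is either the raw vector of
the n most recent BPM samples, V = (h(t-(n-1)), ..., h(t)), or its Haar
discrete-wavelet decomposition.  The DWT here is implemented directly as
the orthonormal filter-and-downsample cascade (sub-band coding): each level
splits the current approximation into a half-length approximation
(pairwise sums / sqrt(2)) and a half-length detail (pairwise differences /
sqrt(2)).  The orthonormal convention makes energy conservation (Parseval)
and perfect reconstruction exactly testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import FeatureVector, LabeledWindow

_SQRT2 = math.sqrt(2.0)


@dataclass
class HRWindow:
    """An n-sample heart-rate vector, the classification unit."""

    values: np.ndarray
    subject_id: str = ""
    window_index: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("HRWindow requires a non-empty 1-D vector")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class DWTDecomposition:
    """Multi-level Haar decomposition: final approximation plus all details.

    ``details`` is ordered deepest first, [D_L, ..., D_1].  ``input_lengths``
    records the length fed to each analysis level (deepest last) so that
    reconstruction can trim any repeat-padding applied to odd-length bands.
    """

    levels: int
    approx: np.ndarray
    details: list[np.ndarray]
    input_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.approx = np.asarray(self.approx, dtype=float)
        self.details = [np.asarray(d, dtype=float) for d in self.details]
        if self.levels != len(self.details):
            raise ValueError("levels must equal the number of detail bands")

    def coefficient_vector(self) -> np.ndarray:
        """Concatenation [A_L, D_L, ..., D_1]."""
        return np.concatenate([self.approx, *self.details])


def max_dwt_level(n: int) -> int:
    """Deepest admissible decomposition level for an n-sample window."""
    if n < 2:
        return 0
    return int(math.floor(math.log2(n)))


def haar_step(
    signal: Sequence[float] | np.ndarray, strict: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """One orthonormal Haar analysis step.

    approx[i] = (s[2i] + s[2i+1]) / sqrt(2); detail[i] = (s[2i] - s[2i+1]) /
    sqrt(2).  Odd-length input errors in strict mode; otherwise the final
    sample is repeated once so the pairing is total.
    """
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("haar_step requires a 1-D signal of length >= 2")
    if s.size % 2 == 1:
        if strict:
            raise ValueError(f"odd-length signal ({s.size}) in strict mode")
        s = np.append(s, s[-1])
    approx = (s[0::2] + s[1::2]) / _SQRT2
    detail = (s[0::2] - s[1::2]) / _SQRT2
    return approx, detail


def multilevel_dwt(
    window: HRWindow | Sequence[float] | np.ndarray,
    levels: int | None = None,
    strict: bool = False,
) -> DWTDecomposition:
    """Recursive Haar sub-band coding of a window.

    Each level halves the sample count, re-decomposing the approximation
    band; the decomposition retains A_L together with D_L ... D_1.  Depth
    defaults to the maximal admissible floor(log2(n)).
    """
    values = window.values if isinstance(window, HRWindow) else np.asarray(window, float)
    n = values.size
    lmax = max_dwt_level(n)
    if levels is None:
        levels = lmax
    if not 1 <= levels <= lmax:
        raise ValueError(
            f"levels={levels} outside admissible range [1, {lmax}] for n={n}"
        )

    approx = values
    details: list[np.ndarray] = []
    input_lengths: list[int] = []
    for _ in range(levels):
        input_lengths.append(int(approx.size))
        approx, detail = haar_step(approx, strict=strict)
        details.append(detail)
    details.reverse()  # [D_L, ..., D_1]
    return DWTDecomposition(
        levels=levels, approx=approx, details=details, input_lengths=input_lengths
    )


def inverse_dwt(dec: DWTDecomposition) -> np.ndarray:
    """Invert the Haar cascade: s[2i] = (a[i]+d[i])/sqrt(2), s[2i+1] = (a[i]-d[i])/sqrt(2).

    Each synthesis level trims back to the recorded input length, undoing
    any repeat-padding, so reconstruction is exact for all inputs.
    """
    approx = np.asarray(dec.approx, dtype=float)
    lengths = dec.input_lengths or [2 * d.size for d in reversed(dec.details)]
    for level in range(dec.levels):
        detail = dec.details[level]
        if detail.size != approx.size:
            raise ValueError(
                f"band length mismatch at level {dec.levels - level}: "
                f"approx {approx.size} vs detail {detail.size}"
            )
        up = np.empty(2 * approx.size, dtype=float)
        up[0::2] = (approx + detail) / _SQRT2
        up[1::2] = (approx - detail) / _SQRT2
        approx = up[: lengths[dec.levels - 1 - level]]
    return approx


def window_hr(labeled: Sequence[LabeledWindow]) -> list[HRWindow]:
    """Lift labeled windows into HR window vectors (order preserved)."""
    if not labeled:
        return []
    n0 = len(labeled[0].hr_vector)
    for w in labeled:
        if len(w.hr_vector) != n0:
            raise ValueError(
                f"inconsistent window lengths: {len(w.hr_vector)} != {n0}"
            )
    return [
        HRWindow(values=w.hr_vector, subject_id=w.subject_id, window_index=w.window_index)
        for w in labeled
    ]


def subband_stats(dec: DWTDecomposition) -> np.ndarray:
    """Per-band (energy, mean, sd) summary, an alternative to raw coefficients."""
    bands = [dec.approx, *dec.details]
    rows = [
        (float(np.sum(b**2)), float(np.mean(b)), float(np.std(b))) for b in bands
    ]
    return np.asarray(rows, dtype=float).ravel()


def assemble_features(
    labeled: Sequence[LabeledWindow],
    scheme: str = "dwt",
    levels: int | None = None,
    use_subband_stats: bool = False,
    zscore_per_subject: bool = False,
) -> list[FeatureVector]:
    """Turn labeled HR windows into classifier feature rows.

    raw_hr keeps the n BPM samples verbatim; dwt concatenates
    [A_L, D_L, ..., D_1] (length n when every band splits evenly).  Labels
    ride along unchanged.  Optional per-subject z-scoring of the BPM values
    is applied before either scheme.
    """
    if scheme not in ("raw_hr", "dwt"):
        raise ValueError(f"unknown scheme {scheme!r}")
    windows = window_hr(labeled)
    if scheme == "dwt" and windows and windows[0].n < 2:
        raise ValueError("dwt scheme requires windows of length >= 2")

    values_by_window = [w.values for w in windows]
    if zscore_per_subject and windows:
        allv = np.concatenate(values_by_window)
        mu, sd = float(allv.mean()), float(allv.std())
        sd = sd if sd > 0 else 1.0
        values_by_window = [(v - mu) / sd for v in values_by_window]

    out: list[FeatureVector] = []
    for lw, vals in zip(labeled, values_by_window):
        if scheme == "raw_hr":
            feat = np.asarray(vals, dtype=float)
        else:
            dec = multilevel_dwt(vals, levels=levels)
            feat = subband_stats(dec) if use_subband_stats else dec.coefficient_vector()
        out.append(
            FeatureVector(
                scheme=scheme,
                values=feat,
                label=lw.affect,
                subject_id=lw.subject_id,
                window_index=lw.window_index,
            )
        )
    return out
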
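"""Tabular assay computations: SOCE traces, DNA normalisation, XBP1 ratio.

Store-operated calcium entry (SOCE) is assessed with a calcium-readdition
protocol: cells are washed in Ca2+-free buffer (5 min), the ER store is
depleted with thapsigargin (30 min), then extracellular Ca2+ is
reintroduced and the cytosolic indicator is read every 5 s. The summary
statistic is the maximal post-readdition fluorescence normalised to the
pre-readdition baseline.

Metabolic readouts (OCR/ECAR/ATP) from tissue constructs are normalised by
each sample's DNA content. ER-stress is read from XBP1 splicing gels as
spliced / (unspliced + spliced) band intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .errors import DomainError, FormatError

SOCE_SAMPLING_INTERVAL_S = 5.0


@dataclass
class SoceTrace:
    """Uniformly sampled Ca2+ indicator trace with protocol phase marks.

    ``phase_marks`` gives the times (s) of the Ca2+-free wash start, the
    store-depletion start, and the Ca2+ readdition, in that order within
    the record.
    """

    time_s: np.ndarray
    F: np.ndarray
    phase_marks: dict[str, float]

    REQUIRED_MARKS = ("ca_free_start_s", "depletion_start_s", "readdition_s")

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.F, dtype=float)
        if t.shape != f.shape or t.ndim != 1 or t.size < 2:
            raise FormatError("time and F must be equal-length 1D arrays")
        if np.any(np.diff(t) <= 0):
            raise FormatError("time must be strictly increasing")
        missing = [k for k in self.REQUIRED_MARKS if k not in self.phase_marks]
        if missing:
            raise FormatError(f"missing phase marks: {missing}")
        marks = [self.phase_marks[k] for k in self.REQUIRED_MARKS]
        if not (marks[0] <= marks[1] <= marks[2]):
            raise FormatError("phase marks must be ordered in time")
        if not (t[0] <= marks[0] and marks[2] <= t[-1]):
            raise FormatError("phase marks must lie within the record")
        self.time_s, self.F = t, f

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_s": self.time_s, "F": self.F})
        for k in self.REQUIRED_MARKS:
            df[k] = self.phase_marks[k]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SoceTrace":
        df = pd.read_csv(path)
        if not {"time_s", "F"} <= set(df.columns):
            raise FormatError(f"{path}: expected columns time_s, F")
        marks = {
            k: float(df[k].iloc[0]) for k in cls.REQUIRED_MARKS if k in df.columns
        }
        return cls(df["time_s"].to_numpy(), df["F"].to_numpy(), marks)


def soce_normalized_max(
    trace: SoceTrace,
    baseline_window_s: float = 60.0,
    mode: str = "F/F0",
    smoothing: str = "none",
) -> float:
    """Normalised maximal SOCE response of one trace.

    F0 is the mean fluorescence over the ``baseline_window_s`` seconds
    immediately preceding Ca2+ readdition; the statistic is the maximum
    post-readdition fluorescence divided by F0 (``mode="F/F0"``, default)
    or the baseline-subtracted form ``(max - F0) / F0`` (``mode="dF/F0"``).

    ``smoothing`` preconditions noisy recordings before the peak search:
    ``"median3"`` (3-point median) suppresses single-sample spikes;
    ``"mean3"`` (3-point moving average) additionally shrinks the upward
    bias that taking a maximum over broadband noise incurs. The default is
    no smoothing, which is exact on clean traces.
    """
    if mode not in ("F/F0", "dF/F0"):
        raise DomainError(f"unknown normalisation mode {mode!r}")
    t_re = trace.phase_marks["readdition_s"]
    t, f = trace.time_s, trace.F
    if smoothing == "median3":
        f = medfilt(f, kernel_size=3)
    elif smoothing == "mean3":
        f = np.convolve(f, np.ones(3) / 3.0, mode="same")
        f[0], f[-1] = trace.F[0], trace.F[-1]  # edges keep raw values
    elif smoothing != "none":
        raise DomainError(f"unknown smoothing {smoothing!r}")
    base = (t >= t_re - baseline_window_s) & (t < t_re)
    if not base.any():
        raise DomainError("baseline window contains no samples")
    F0 = float(f[base].mean())
    if F0 <= 0:
        raise DomainError("baseline fluorescence must be positive")
    post = t >= t_re
    if not post.any():
        raise DomainError("no samples after Ca2+ readdition")
    peak = float(f[post].max())
    return peak / F0 if mode == "F/F0" else (peak - F0) / F0


def normalize_by_dna(
    values: np.ndarray,
    dna_amounts: np.ndarray,
) -> np.ndarray:
    """Elementwise assay readout / DNA content normalisation."""
    v = np.asarray(values, dtype=float)
    d = np.asarray(dna_amounts, dtype=float)
    if v.shape != d.shape:
        raise FormatError("values and dna_amounts must have matching shapes")
    if np.any(d <= 0):
        raise DomainError("DNA amounts must be positive")
    return v / d


@dataclass(frozen=True)
class SplicingBands:
    """XBP1 RT-PCR band intensities: unspliced (205 bp) and spliced (179 bp)."""

    u_intensity: float
    s_intensity: float

    def __post_init__(self) -> None:
        if self.u_intensity < 0 or self.s_intensity < 0:
            raise DomainError("band intensities must be non-negative")
        if self.u_intensity == 0 and self.s_intensity == 0:
            raise DomainError("at least one band must be nonzero")


def xbp1_splicing_ratio(bands: SplicingBands) -> float:
    """Spliced fraction s / (u + s); total XBP1 is defined as u + s."""
    return bands.s_intensity / (bands.u_intensity + bands.s_intensity)
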
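"""Scotopic ERG feature extraction.

The analysis chain mirrors common full-field ERG practice in rodents:

1. zero-center each trace on its pre-stimulus baseline;
2. low-pass the trace twice, zero-phase (forward + backward Butterworth):
   a wide 235 Hz path that keeps the fast photoreceptor a-wave but
   removes instrument noise, and a narrow 30 Hz path that additionally
   strips the oscillatory potentials riding on the b-wave;
3. locate the a-trough on the wide path and the b-peak on the narrow
   path with prominence-based peak picking, but read both amplitudes
   off the *unfiltered* trace at the selected latencies;
4. absolute b-wave = b-amplitude − a-amplitude (the a-trough is
   negative, so this is the trough-to-peak excursion);
5. flicker responses are characterized on the raw trace only: P1 = time
   to the first peak, P2 = amplitude of the second peak.

Traces are 512 samples over 350 ms by default (fs ≈ 1463 Hz), with the
flash at 20 ms so the first <20 ms serve as baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

__all__ = [
    "ErgTrace",
    "FilterSpec",
    "PeakSearchWindows",
    "ErgFeatures",
    "A_WAVE_FILTER",
    "B_WAVE_FILTER",
    "zero_center",
    "lowpass_zero_phase",
    "extract_features",
    "extract_flicker",
    "features_table",
    "normalize_features",
]

DEFAULT_N_SAMPLES = 512
DEFAULT_DURATION_S = 0.350
DEFAULT_STIMULUS_ONSET_S = 0.020


@dataclass
class ErgTrace:
    """One stimulus-locked voltage trace (µV) with acquisition metadata."""

    samples: np.ndarray
    dt: float = DEFAULT_DURATION_S / DEFAULT_N_SAMPLES
    stimulus_onset: float = DEFAULT_STIMULUS_ONSET_S
    intensity: float = 30.0  # cd·s/m²
    mode: str = "single-flash"  # or "flicker"
    flicker_hz: float | None = None
    animal_id: str = ""
    genotype: str = "+/+"
    age_weeks: float | None = None
    eye: str = "OD"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 8:
            raise ValueError("trace must be a 1-D array of at least 8 samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 <= self.stimulus_onset < self.duration):
            raise ValueError("stimulus_onset must lie within the trace")
        if self.intensity <= 0:
            raise ValueError("stimulus intensity must be positive")
        if self.mode not in ("single-flash", "flicker"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "flicker" and not self.flicker_hz:
            raise ValueError("flicker traces need flicker_hz")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def time(self) -> np.ndarray:
        """Sample times in s from trace start."""
        return np.arange(self.n) * self.dt


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass design: Butterworth of ``order`` at ``cutoff`` Hz.

    ``order`` is the per-pass design order; with ``bidirectional`` the
    filter runs forward and backward (zero net phase, squared magnitude
    response).
    """

    order: int = 4
    cutoff: float = 30.0
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


A_WAVE_FILTER = FilterSpec(order=4, cutoff=235.0)
B_WAVE_FILTER = FilterSpec(order=4, cutoff=30.0)


@dataclass(frozen=True)
class PeakSearchWindows:
    """Peak-search windows in ms post-stimulus, plus a prominence floor."""

    a_window: tuple[float, float] = (5.0, 60.0)
    b_window: tuple[float, float] = (20.0, 150.0)
    min_prominence: float = 10.0  # µV

    def __post_init__(self) -> None:
        for name in ("a_window", "b_window"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"{name} must satisfy 0 <= start < end")
        if self.a_window[0] >= self.b_window[1]:
            raise ValueError("a_window must start before b_window ends")
        if self.min_prominence < 0:
            raise ValueError("min_prominence must be >= 0")


@dataclass
class ErgFeatures:
    """Extracted waveform descriptors; latencies in ms post-stimulus, amplitudes in µV."""

    a_latency: float | None = None
    a_amplitude: float | None = None
    b_latency: float | None = None
    b_amplitude: float | None = None
    b_absolute: float | None = None
    p1_latency: float | None = None
    p2_amplitude: float | None = None
    a_detected: bool = False
    b_detected: bool = False
    flicker_detected: bool = False
    meta: dict = field(default_factory=dict)


def zero_center(trace: ErgTrace, baseline_end: float | None = None) -> ErgTrace:
    """Subtract the mean of the pre-stimulus baseline from the whole trace.

    ``baseline_end`` defaults to the stimulus onset and may not exceed
    it; the baseline window must contain at least 2 samples.
    """
    if baseline_end is None:
        baseline_end = trace.stimulus_onset
    if baseline_end > trace.stimulus_onset + 1e-12:
        raise ValueError("baseline_end must not exceed stimulus_onset")
    mask = trace.time() < baseline_end
    if mask.sum() < 2:
        raise ValueError("baseline window holds fewer than 2 samples; trace unusable")
    return replace(trace, samples=trace.samples - trace.samples[mask].mean())


def lowpass_zero_phase(trace: ErgTrace, spec: FilterSpec) -> ErgTrace:
    """Low-pass a trace with zero net phase shift.

    Butterworth of the given per-pass order, applied forward and
    backward (two passes square the magnitude response and cancel the
    phase).  Edges are handled by reflecting the trace over at least
    three filter lengths to suppress startup transients.
    """
    nyq = trace.fs / 2
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist {nyq:.1f} Hz")
    b, a = butter(spec.order, spec.cutoff, btype="low", fs=trace.fs)
    if spec.bidirectional:
        padlen = min(3 * 3 * (max(len(a), len(b)) - 1), trace.n - 1)
        y = filtfilt(b, a, trace.samples, padtype="even", padlen=padlen)
    else:
        from scipy.signal import lfilter

        y = lfilter(b, a, trace.samples)
    return replace(trace, samples=y)


def _window_indices(trace: ErgTrace, window_ms: tuple[float, float]) -> np.ndarray:
    t_ms = (trace.time() - trace.stimulus_onset) * 1e3
    return np.flatnonzero((t_ms >= window_ms[0]) & (t_ms <= window_ms[1]))


def _most_prominent_peak(y: np.ndarray, idx: np.ndarray, min_prominence: float) -> int | None:
    """Index (into y) of the most prominent peak of y within idx; ties
    break toward the earliest latency.  None when nothing clears the
    prominence floor."""
    if idx.size < 3:
        return None
    seg = y[idx[0]:idx[-1] + 1]
    peaks, props = find_peaks(seg, prominence=min_prominence)
    if peaks.size == 0:
        return None
    best = np.argmax(props["prominences"])  # argmax returns the first maximum
    return int(idx[0] + peaks[best])


def extract_features(
    trace: ErgTrace,
    windows: PeakSearchWindows = PeakSearchWindows(),
    a_filter: FilterSpec = A_WAVE_FILTER,
    b_filter: FilterSpec = B_WAVE_FILTER,
) -> ErgFeatures:
    """Extract a-/b-wave latencies and amplitudes from a single-flash trace.

    The a-trough is the most prominent negative excursion of the wide
    (235 Hz) path inside ``a_window``; the b-peak is the most prominent
    positive peak of the narrow (30 Hz) path inside ``b_window``.  Both
    amplitudes are the values of the unfiltered trace at those
    latencies.  Components with no peak clearing ``min_prominence`` are
    flagged undetected rather than raising.
    """
    if trace.mode != "single-flash":
        raise ValueError("extract_features handles single-flash traces; use extract_flicker")
    wide = lowpass_zero_phase(trace, a_filter)
    narrow = lowpass_zero_phase(trace, b_filter)
    out = ErgFeatures(meta=_trace_meta(trace))

    ia = _most_prominent_peak(-wide.samples, _window_indices(trace, windows.a_window),
                              windows.min_prominence)
    if ia is not None:
        out.a_detected = True
        out.a_latency = (ia * trace.dt - trace.stimulus_onset) * 1e3
        out.a_amplitude = float(trace.samples[ia])

    ib = _most_prominent_peak(narrow.samples, _window_indices(trace, windows.b_window),
                              windows.min_prominence)
    if ib is not None:
        out.b_detected = True
        out.b_latency = (ib * trace.dt - trace.stimulus_onset) * 1e3
        out.b_amplitude = float(trace.samples[ib])

    if out.a_detected and out.b_detected:
        out.b_absolute = out.b_amplitude - out.a_amplitude
    return out


def extract_flicker(trace: ErgTrace, min_prominence: float = 10.0) -> ErgFeatures:
    """P1 latency and P2 amplitude of a flicker response.

    Both are read from the original unfiltered trace: P1 is the time
    from stimulus onset to the first positive peak, P2 the amplitude of
    the second peak.  Fewer than two detectable peaks flag the response
    (partially) unrecordable, the expected knockout outcome.
    """
    if trace.mode != "flicker":
        raise ValueError("extract_flicker requires a flicker-mode trace")
    idx = np.flatnonzero(trace.time() >= trace.stimulus_onset)
    out = ErgFeatures(meta=_trace_meta(trace))
    if idx.size < 3:
        return out
    seg = trace.samples[idx[0]:]
    peaks, _ = find_peaks(seg, prominence=min_prominence)
    if peaks.size >= 1:
        out.p1_latency = ((idx[0] + peaks[0]) * trace.dt - trace.stimulus_onset) * 1e3
    if peaks.size >= 2:
        out.p2_amplitude = float(seg[peaks[1]])
        out.flicker_detected = True
    return out


def _trace_meta(trace: ErgTrace) -> dict:
    return {
        "animal_id": trace.animal_id,
        "genotype": trace.genotype,
        "age_weeks": trace.age_weeks,
        "eye": trace.eye,
        "intensity": trace.intensity,
        "mode": trace.mode,
    }


_FEATURE_COLS = ("a_latency", "a_amplitude", "b_latency", "b_amplitude",
                 "b_absolute", "p1_latency", "p2_amplitude")


def features_table(features: Iterable[ErgFeatures]) -> pd.DataFrame:
    """Flatten ErgFeatures records (metadata + descriptors) to a table."""
    rows = []
    for f in features:
        row = dict(f.meta)
        for c in _FEATURE_COLS:
            row[c] = getattr(f, c)
        row["a_detected"], row["b_detected"] = f.a_detected, f.b_detected
        row["flicker_detected"] = f.flicker_detected
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_features(
    table: pd.DataFrame,
    value_cols: Sequence[str] = ("a_amplitude", "b_amplitude", "b_absolute"),
    reference_genotype: str = "+/+",
    reference_intensity: float = 30.0,
    group_cols: Sequence[str] = ("genotype", "intensity"),
) -> pd.DataFrame:
    """Group-mean each feature and normalize to the wildtype reference.

    The reference for each feature is the wildtype group mean at the
    reference intensity (the brightest flash), so that entry maps to
    exactly 1.0.  A zero or missing reference is an error.
    """
    means = table.groupby(list(group_cols), dropna=False)[list(value_cols)].mean().reset_index()
    ref_rows = means[
        (means["genotype"] == reference_genotype)
        & np.isclose(means["intensity"].astype(float), reference_intensity)
    ]
    if ref_rows.empty:
        raise ValueError(
            f"no reference group (genotype {reference_genotype!r} at "
            f"{reference_intensity} cd·s/m²) in the table")
    out = means.copy()
    for c in value_cols:
        ref = float(ref_rows.iloc[0][c])
        if not np.isfinite(ref) or ref == 0:
            raise ValueError(f"reference mean for {c!r} is zero or undefined")
        out[f"{c}_norm"] = means[c] / ref
    return out
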
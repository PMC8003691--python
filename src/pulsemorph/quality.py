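"""Signal-quality stages: Flat, Peak (saturation), PPG-SQ and ABP-SQ.

A 15-s segment pair survives only if, for both windows: neither channel
contains flatline or clipped runs; the band-pass-filtered PPG yields a valid
pulse delineation; and the delineated ABP pulses satisfy every printed
threshold — pulse duration in [0.5, 1.5] s (inclusive), 10–30 pulses per
segment (inclusive), pulse pressure strictly above 10 mmHg and moment
skewness strictly positive for every pulse.

Pulse onsets are located with a slope-sum-function (SSF) detector: the SSF
accumulates positive slopes over a ~128 ms window, its peaks mark systolic
upstrokes, and each onset is the waveform minimum in a short window
preceding the upstroke.  The contract downstream stages rely on is onset
recovery within +/-3 samples on clean signals, not numerical equivalence
with any particular published delineator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks
from scipy.stats import skew as _scipy_skew


@dataclass
class QualityConfig:
    """All thresholds of the quality stages (defaults = printed values)."""

    fs: float = 125.0
    flat_min_len_s: float = 0.2
    flat_tol: float = 0.0
    sat_min_run: int = 3
    ppg_band_hz: tuple = (0.5, 8.0)
    butter_order: int = 4
    pulse_duration_s: tuple = (0.5, 1.5)
    pulses_per_segment: tuple = (10, 30)
    min_pulse_pressure: float = 10.0
    min_pulse_skewness: float = 0.0


@dataclass
class Pulse:
    """One onset-to-onset beat cut from a segment."""

    samples: np.ndarray
    onset_idx: int
    fs: float = 125.0

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def dbp(self) -> float:
        return float(np.min(self.samples))

    @property
    def sbp(self) -> float:
        return float(np.max(self.samples))

    @property
    def skewness(self) -> float:
        return moment_skewness(self.samples)


@dataclass
class QualityVerdict:
    failed_checks: list = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.failed_checks


def _runs(mask: np.ndarray):
    """Start/stop (half-open) index pairs of True runs in a boolean mask."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def detect_flat(series: np.ndarray, min_len_s: float = 0.2, tol: float = 0.0, fs: float = 125.0):
    """Maximal runs of null data: |successive difference| <= tol for >= min_len.

    NaN samples are flagged unconditionally.  Runs sitting on the global
    extremes of a non-constant series are left to :func:`detect_saturation`
    so the two stages report disjoint regions.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    flatmask = np.concatenate([[False], np.abs(np.diff(x)) <= tol])
    # a run of k True diffs spans k+1 samples: extend run starts left by one
    regions = []
    min_n = max(2, int(round(min_len_s * fs)))
    rng = np.nanmax(x) - np.nanmin(x)
    for start, stop in _runs(flatmask):
        start -= 1  # include the sample the first flat diff starts from
        if stop - start < min_n:
            continue
        level = x[start]
        if rng > 0 and (np.isclose(level, np.nanmax(x)) or np.isclose(level, np.nanmin(x))):
            continue  # clipping, reported by detect_saturation
        regions.append((int(start), int(stop)))
    for start, stop in _runs(np.isnan(x)):
        regions.append((int(start), int(stop)))
    return sorted(set(regions))


def detect_saturation(series: np.ndarray, min_run: int = 3):
    """Clipped plateaus: runs resting on the global max or min of the series."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    hi, lo = np.nanmax(x), np.nanmin(x)
    if hi - lo <= 0:
        return []
    regions = []
    for level in (hi, lo):
        mask = np.isclose(x, level)
        for start, stop in _runs(mask):
            if stop - start >= min_run:
                regions.append((int(start), int(stop)))
    return sorted(regions)


def filter_ppg_sq(segment: np.ndarray, fs: float = 125.0, band=(0.5, 8.0), order: int = 4):
    """Band-pass [0.5, 8] Hz (zero-phase Butterworth) then MinMax to [0, 1]."""
    x = np.asarray(segment, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate segment: constant input")
    b, a = butter(order, [band[0] / (fs / 2), band[1] / (fs / 2)], btype="band")
    y = filtfilt(b, a, x)
    lo, hi = y.min(), y.max()
    if hi - lo <= 0:
        raise ValueError("degenerate segment: constant after filtering")
    return (y - lo) / (hi - lo)


def slope_sum_function(x: np.ndarray, fs: float = 125.0, window_s: float = 0.128) -> np.ndarray:
    """Windowed sum of positive slopes; peaks align with systolic upstrokes."""
    d = np.clip(np.diff(np.asarray(x, dtype=float), prepend=x[0]), 0.0, None)
    w = max(2, int(round(window_s * fs)))
    return np.convolve(d, np.ones(w), mode="full")[: len(x)]


def detect_onsets(segment: np.ndarray, fs: float = 125.0) -> np.ndarray:
    """SSF onset detector; returns sample indices of pulse feet."""
    x = np.asarray(segment, dtype=float)
    ssf = slope_sum_function(x, fs)
    if ssf.max() <= 0:
        return np.array([], dtype=int)
    # upstrokes: SSF peaks at least 40% of the median prominent peak,
    # separated by the shortest physiological period
    min_dist = int(round(0.4 * fs))
    peaks, props = find_peaks(ssf, distance=min_dist, height=0.2 * ssf.max())
    if peaks.size == 0:
        return np.array([], dtype=int)
    height_ref = np.median(props["peak_heights"])
    peaks = peaks[props["peak_heights"] >= 0.4 * height_ref]
    back = int(round(0.30 * fs))
    onsets = []
    for p in peaks:
        if p < back:  # upstroke truncated by the segment edge
            continue
        lo = p - back
        onsets.append(lo + int(np.argmin(x[lo : p + 1])))
    onsets = np.unique(onsets)
    return onsets.astype(int)


def delineate_pulses(segment: np.ndarray, fs: float = 125.0) -> list[Pulse]:
    """Cut a segment into onset-to-onset pulses.

    Returns an empty list (marker failure) when fewer than two onsets are
    found.  The tail after the last onset is not a complete pulse and is
    discarded.
    """
    onsets = detect_onsets(segment, fs)
    if len(onsets) < 2:
        return []
    return [
        Pulse(samples=np.asarray(segment[a:b], dtype=float), onset_idx=int(a), fs=fs)
        for a, b in zip(onsets[:-1], onsets[1:])
    ]


def moment_skewness(x: np.ndarray) -> float:
    """Moment coefficient of skewness: m3 / m2**1.5 (population moments)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.var(x) == 0:
        raise ValueError("skewness undefined for zero variance")
    return float(_scipy_skew(x, bias=True))


def abp_sq(pulses: list[Pulse], config: QualityConfig | None = None) -> QualityVerdict:
    """ABP-SQ verdict for the pulses of one 15-s segment."""
    cfg = config or QualityConfig()
    verdict = QualityVerdict()
    if not pulses:
        verdict.failed_checks.append("marker")
        return verdict
    lo_n, hi_n = cfg.pulses_per_segment
    if not (lo_n <= len(pulses) <= hi_n):
        verdict.failed_checks.append("pulse_count")
    lo_d, hi_d = cfg.pulse_duration_s
    if any(not (lo_d <= p.duration <= hi_d) for p in pulses):
        verdict.failed_checks.append("pulse_duration")
    if any(p.sbp - p.dbp <= cfg.min_pulse_pressure for p in pulses):
        verdict.failed_checks.append("pulse_pressure")
    try:
        if any(p.skewness <= cfg.min_pulse_skewness for p in pulses):
            verdict.failed_checks.append("skewness")
    except ValueError:
        verdict.failed_checks.append("skewness")
    return verdict


def segment_quality(abp_seg: np.ndarray, ppg_seg: np.ndarray, config: QualityConfig | None = None):
    """Full quality cascade for one 15-s window of both channels.

    Returns ``(verdict, abp_pulses)``; the pulses are reused by the
    morphology stage when the verdict is an acceptance.
    """
    cfg = config or QualityConfig()
    verdict = QualityVerdict()
    for name, sig in (("abp", abp_seg), ("ppg", ppg_seg)):
        if detect_flat(sig, cfg.flat_min_len_s, cfg.flat_tol, cfg.fs):
            verdict.failed_checks.append(f"flat_{name}")
        if detect_saturation(sig, cfg.sat_min_run):
            verdict.failed_checks.append(f"peak_{name}")
    try:
        ppg_f = filter_ppg_sq(ppg_seg, cfg.fs, cfg.ppg_band_hz, cfg.butter_order)
        if len(delineate_pulses(ppg_f, cfg.fs)) == 0:
            verdict.failed_checks.append("marker")
    except ValueError:
        verdict.failed_checks.append("marker")
    abp_pulses = delineate_pulses(abp_seg, cfg.fs)
    abp_verdict = abp_sq(abp_pulses, cfg)
    verdict.failed_checks.extend(c for c in abp_verdict.failed_checks if c not in verdict.failed_checks)
    return verdict, abp_pulses


def pair_quality(pair, config: QualityConfig | None = None):
    """Quality verdicts (and pulses) for both windows of a segment pair."""
    out = {}
    for label, _start, abp_seg, ppg_seg in pair.segments():
        out[label] = segment_quality(abp_seg, ppg_seg, config)
    accepted = all(v.accepted for v, _ in out.values())
    return accepted, out
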
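"""Model inputs and homogenized, masked targets.

The network sees 5-s random windows (625 steps at 125 Hz) of the prepared
PPG and its first derivative, each min-max scaled over the window, plus an
optional demographic vector (age affinely mapped from [18, 89] to [0, 1],
gender as a binary indicator).  Targets are the averaged ABP pulses, scaled
with a single global affine map fitted on the training set, cyclically
repeated to a fixed length T = (longest pulse + 15 steps); repeated steps
carry the extra "ended" class and the value loss is masked to the true
pulse plus 15 steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, savgol_filter

from .morphology import C_ED, AveragePulseMorphology

FS = 125.0
SEGMENT_SAMPLES = 1875        # 15 s
PREPARED_SAMPLES = 1625       # 13 s after trimming 1 s per end
TRIM_SAMPLES = 125
WINDOW_STEPS = 625            # 5 s
INPUT_BAND_HZ = (0.5, 45.0)
SAVGOL_WINDOW = 7
SAVGOL_DEGREE = 3
PAD_STEPS = 15                # 0.12 s at 125 Hz
AGE_RANGE = (18.0, 89.0)


def prepare_ppg_input(raw_ppg: np.ndarray, fs: float = FS) -> np.ndarray:
    """15-s raw PPG -> 13-s two-channel (PPG, PPG') array of shape (1625, 2).

    Band-pass [0.5, 45] Hz (zero-phase Butterworth, order 4), first
    derivative via a Savitzky-Golay filter (window 7, degree 3, analytic
    derivative coefficients), then 1 s trimmed from each end to discard
    filter edge artifacts.
    """
    x = np.asarray(raw_ppg, dtype=float)
    if len(x) != SEGMENT_SAMPLES:
        raise ValueError(f"expected {SEGMENT_SAMPLES} samples (15 s at 125 Hz), got {len(x)}")
    b, a = butter(4, [INPUT_BAND_HZ[0] / (fs / 2), INPUT_BAND_HZ[1] / (fs / 2)], btype="band")
    filt = filtfilt(b, a, x)
    deriv = savgol_filter(filt, SAVGOL_WINDOW, SAVGOL_DEGREE, deriv=1, delta=1.0 / fs)
    out = np.column_stack([filt, deriv])[TRIM_SAMPLES:-TRIM_SAMPLES]
    assert out.shape == (PREPARED_SAMPLES, 2)
    return out


def minmax_per_channel(window: np.ndarray) -> np.ndarray:
    lo = window.min(axis=0, keepdims=True)
    hi = window.max(axis=0, keepdims=True)
    span = hi - lo
    if np.any(span <= 0):
        raise ValueError("degenerate channel: constant over the window")
    return (window - lo) / span


def sample_window(prepared: np.ndarray, rng) -> tuple[np.ndarray, int]:
    """Draw a 5-s window with uniform random start; scale channels to [0, 1].

    ``rng`` is a ``numpy.random.Generator`` (or an integer seed).  Returns
    ``(window, start)`` with window shape (625, 2).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    max_start = len(prepared) - WINDOW_STEPS
    start = int(rng.integers(0, max_start + 1))
    win = prepared[start : start + WINDOW_STEPS]
    return minmax_per_channel(win), start


@dataclass(frozen=True)
class TargetScaler:
    """Single affine map [global min, global max] mmHg <-> [0, 1]."""

    vmin: float
    vmax: float

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.vmin) / (self.vmax - self.vmin)

    def inverse(self, x):
        return np.asarray(x, dtype=float) * (self.vmax - self.vmin) + self.vmin

    def to_dict(self):
        return {"vmin": self.vmin, "vmax": self.vmax}

    @classmethod
    def from_dict(cls, d):
        return cls(vmin=float(d["vmin"]), vmax=float(d["vmax"]))


def scale_target_global(morphologies: list[AveragePulseMorphology]) -> TargetScaler:
    """Fit the global target scaler on a (training) morphology collection."""
    if not morphologies:
        raise ValueError("empty morphology collection")
    vmin = min(float(np.min(m.values)) for m in morphologies)
    vmax = max(float(np.max(m.values)) for m in morphologies)
    if vmax - vmin <= 0:
        raise ValueError("degenerate global value range")
    return TargetScaler(vmin=vmin, vmax=vmax)


def fixed_length(morphologies: list[AveragePulseMorphology], pad_steps: int = PAD_STEPS) -> int:
    """T = longest average-pulse length in steps + the mask padding."""
    if not morphologies:
        raise ValueError("empty morphology collection")
    return max(len(m.values) for m in morphologies) + pad_steps


@dataclass
class HomogenizedTarget:
    values: np.ndarray   # (T,) scaled to [0, 1]
    classes: np.ndarray  # (T,) int codes, C_ED after the first pulse copy
    mask: np.ndarray     # (T,) {0, 1}
    true_len: int
    T: int


def homogenize_target(morphology: AveragePulseMorphology, T: int,
                      scaler: TargetScaler, pad_steps: int = PAD_STEPS) -> HomogenizedTarget:
    """Cyclically repeat a scaled pulse to length T; mask the true pulse + pad.

    Values repeat with period ``len(pulse)``; class labels keep the original
    cardiac-cycle sequence on the first copy and become "ended" on every
    repeated step; the mask is one on the first ``min(len + pad, T)`` steps.
    """
    n = len(morphology.values)
    if n > T:
        raise ValueError(f"morphology length {n} exceeds fixed length {T}")
    reps = int(np.ceil(T / n))
    values = np.tile(scaler.transform(morphology.values), reps)[:T]
    classes = np.full(T, C_ED, dtype=np.int64)
    classes[:n] = morphology.classes
    mask = np.zeros(T, dtype=np.int64)
    mask[: min(n + pad_steps, T)] = 1
    return HomogenizedTarget(values=values, classes=classes, mask=mask, true_len=n, T=T)


def encode_demographics(age: float, gender: str) -> np.ndarray:
    """(scaled age, gender indicator); female -> 0, male -> 1."""
    if age is None or gender is None:
        raise ValueError("demographics required in a DI-enabled scenario")
    lo, hi = AGE_RANGE
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside [{lo}, {hi}]")
    g = {"female": 0.0, "male": 1.0}.get(gender)
    if g is None:
        raise ValueError(f"unknown gender {gender!r}")
    return np.array([(age - lo) / (hi - lo), g])
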
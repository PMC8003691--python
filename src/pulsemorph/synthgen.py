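"""Synthetic paired ABP/PPG records with exact beat-level ground truth.

Every downstream stage of the pipeline (segment selection, signal quality,
pulse averaging, model training, clinical evaluation) is exercised against
records produced here, so the generator keeps full book-keeping: for every
rendered beat it reports the onset, systolic-peak and dicrotic-notch sample
indices and the true DBP/SBP in mmHg.

The arterial pulse is modelled as a sum of two Gaussian lobes -- a main
systolic ejection lobe and a smaller diastolic lobe -- separated by a local
minimum that plays the role of the dicrotic notch.  The PPG channel is
derived from the ABP channel by a fixed, documented transform: unit
normalization, an 80 ms transit delay, a 2nd-order 8 Hz low-pass, and a mild
monotone nonlinearity (x -> x**0.9), plus optional additive Gaussian noise.
Keeping the transform fixed and near-invertible makes model-learnability
tests meaningful: a model that cannot recover the pulse from this PPG has a
defect, not an impossible task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

DEFAULT_FS = 125.0
#: PPG transit delay relative to ABP, seconds (10 samples at 125 Hz).
PPG_DELAY_S = 0.080
#: Cutoff of the low-pass applied inside the ABP->PPG transform, Hz.
PPG_LOWPASS_HZ = 8.0
#: Exponent of the monotone nonlinearity applied after unit scaling.
PPG_NONLINEARITY = 0.9

HEART_PERIOD_RANGE = (0.5, 1.5)
AGE_RANGE = (18.0, 89.0)


@dataclass(frozen=True)
class SyntheticSubject:
    """A virtual subject with demographics and haemodynamic baselines."""

    subject_id: str
    age: float
    gender: str
    baseline_dbp: float
    baseline_sbp: float
    mean_heart_period: float

    def __post_init__(self) -> None:
        if not (AGE_RANGE[0] <= self.age <= AGE_RANGE[1]):
            raise ValueError(f"age {self.age} outside {AGE_RANGE}")
        if self.gender not in ("female", "male"):
            raise ValueError(f"gender must be female/male, got {self.gender!r}")
        if self.baseline_sbp - self.baseline_dbp <= 10.0:
            raise ValueError("pulse pressure must exceed 10 mmHg")
        lo, hi = HEART_PERIOD_RANGE
        if not (lo <= self.mean_heart_period <= hi):
            raise ValueError(f"heart period {self.mean_heart_period} outside [{lo}, {hi}] s")


@dataclass(frozen=True)
class BeatTemplate:
    """One parametric beat: duration, pressures, and lobe shape parameters.

    ``shape_params`` holds (mu1, sigma1, amp2, mu2, sigma2) as fractions of
    the beat duration (amplitudes relative to the systolic lobe).
    """

    duration: float
    onset_value: float
    systolic_value: float
    shape_params: tuple[float, float, float, float, float] = (0.30, 0.085, 0.32, 0.62, 0.115)

    def __post_init__(self) -> None:
        lo, hi = HEART_PERIOD_RANGE
        if not (lo <= self.duration <= hi):
            raise ValueError(f"beat duration {self.duration} s outside [{lo}, {hi}] s")
        if self.systolic_value <= self.onset_value:
            raise ValueError("systolic value must exceed onset value")


@dataclass(frozen=True)
class ArtifactSpec:
    """An injectable corruption of the rendered record."""

    kind: str  # flatline | saturation_high | saturation_low | noise_burst
    start: float
    duration: float
    level: float = 0.0

    _KINDS = ("flatline", "saturation_high", "saturation_low", "noise_burst")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("artifact duration must be positive")


def make_subject(seed: int) -> SyntheticSubject:
    """Draw a deterministic subject from a seed.

    Ages are uniform over [18, 89]; DBP/SBP baselines are drawn near the
    adult ICU means (DBP ~ N(64, 8), SBP ~ N(125, 14) mmHg, clipped so the
    morphology post-filters can be satisfied); resting heart periods are
    uniform over [0.65, 1.1] s, comfortably inside the physiological
    [0.5, 1.5] s band.
    """
    rng = np.random.default_rng(seed)
    age = float(rng.uniform(*AGE_RANGE))
    gender = "female" if rng.random() < 0.5 else "male"
    dbp = float(np.clip(rng.normal(64.0, 8.0), 45.0, 90.0))
    sbp = float(np.clip(rng.normal(125.0, 14.0), dbp + 25.0, 172.0))
    period = float(rng.uniform(0.65, 1.10))
    return SyntheticSubject(
        subject_id=f"synth-{seed:06d}",
        age=age,
        gender=gender,
        baseline_dbp=dbp,
        baseline_sbp=sbp,
        mean_heart_period=period,
    )


def synth_abp_beat(template: BeatTemplate, fs: float = DEFAULT_FS):
    """Render one ABP beat; return (waveform, landmarks).

    ``landmarks`` is a dict with exact sample indices ``onset_idx`` (always
    0), ``sp_idx`` and ``dn_idx``, plus ``dbp``/``sbp`` in mmHg.  The
    rendered waveform attains its minimum exactly at the onset and its
    maximum exactly at the systolic peak by construction: the two-lobe shape
    is re-anchored so that shape(0) = 0 is the global minimum before the
    affine map onto [onset_value, systolic_value].
    """
    n = int(round(template.duration * fs))
    t = np.arange(n) / (n - 1)  # normalized time in [0, 1]
    mu1, s1, a2, mu2, s2 = template.shape_params
    lobe1 = np.exp(-0.5 * ((t - mu1) / s1) ** 2)
    lobe2 = a2 * np.exp(-0.5 * ((t - mu2) / s2) ** 2)
    shape = lobe1 + lobe2
    # tilt so the onset is the strict global minimum (the raw Gaussian tails
    # can leave the end of the beat marginally below the start)
    shape = shape + 0.02 * t
    shape = shape - shape[0]
    if shape.min() < 0:  # pragma: no cover - guarded by parameter ranges
        shape = shape - shape.min()
    shape = shape / shape.max()
    wave = template.onset_value + (template.systolic_value - template.onset_value) * shape

    sp_idx = int(np.argmax(wave))
    # dicrotic notch: the local minimum between the two lobe centres
    lo = max(sp_idx + 1, int(mu1 * n))
    hi = min(n - 1, int(mu2 * n) + 1)
    dn_idx = lo + int(np.argmin(wave[lo:hi]))
    if not (0 < sp_idx < dn_idx < n - 1):
        raise ValueError("degenerate beat: landmark ordering violated")
    landmarks = {
        "onset_idx": 0,
        "sp_idx": sp_idx,
        "dn_idx": dn_idx,
        "dbp": float(wave.min()),
        "sbp": float(wave.max()),
    }
    return wave, landmarks


def ppg_from_abp(abp: np.ndarray, fs: float = DEFAULT_FS) -> np.ndarray:
    """The fixed ABP -> PPG forward transform (noise-free part).

    Unit normalization, 80 ms delay, 2nd-order low-pass at 8 Hz
    (zero-phase), then x**0.9.  Output lies in [0, 1].
    """
    x = (abp - abp.min()) / (abp.max() - abp.min())
    delay = int(round(PPG_DELAY_S * fs))
    x = np.concatenate([np.full(delay, x[0]), x[:-delay]]) if delay else x
    b, a = butter(2, PPG_LOWPASS_HZ / (fs / 2.0), btype="low")
    x = filtfilt(b, a, x)
    x = np.clip(x, 0.0, None) ** PPG_NONLINEARITY
    return x


def _apply_artifacts(abp, ppg, artifacts: Sequence[ArtifactSpec], fs: float, rng) -> None:
    n = len(abp)
    for art in artifacts:
        i0 = int(round(art.start * fs))
        i1 = i0 + int(round(art.duration * fs))
        if not (0 <= i0 < i1 <= n):
            raise ValueError(f"artifact [{art.start}, {art.start + art.duration}] s outside record")
        sl = slice(i0, i1)
        if art.kind == "flatline":
            abp[sl] = abp[i0]
            ppg[sl] = ppg[i0]
        elif art.kind == "saturation_high":
            abp[sl] = np.maximum(abp[sl], abp.max())
            ppg[sl] = np.maximum(ppg[sl], ppg.max())
        elif art.kind == "saturation_low":
            abp[sl] = np.minimum(abp[sl], abp.min())
            ppg[sl] = np.minimum(ppg[sl], ppg.min())
        elif art.kind == "noise_burst":
            lvl = art.level if art.level else 1.0
            abp[sl] += rng.normal(0.0, lvl * 10.0, i1 - i0)
            ppg[sl] += rng.normal(0.0, lvl * 0.3, i1 - i0)


def synth_record(
    subject: SyntheticSubject,
    duration: float,
    noise_sd: float = 0.0,
    artifacts: Sequence[ArtifactSpec] = (),
    seed: int = 0,
    fs: float = DEFAULT_FS,
):
    """Render a paired ABP/PPG record of at least ``duration`` seconds.

    Beats are concatenated with multiplicative jitter (<= 5 %) on period and
    on the DBP/SBP excursion.  Returns ``(record, truth)`` where ``record``
    is a :class:`pulsemorph.record_io.WaveformRecord` and ``truth`` a
    DataFrame with one row per beat: onset_idx, sp_idx, dn_idx, dbp, sbp
    (indices in the ABP frame; the PPG lags by exactly
    ``round(PPG_DELAY_S * fs)`` samples).
    """
    from .record_io import WaveformRecord  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    n_target = int(round(duration * fs))
    pieces: list[np.ndarray] = []
    rows: list[dict] = []
    cursor = 0
    while cursor < n_target:
        jp = 1.0 + rng.uniform(-0.05, 0.05)
        ja = 1.0 + rng.uniform(-0.05, 0.05)
        period = float(np.clip(subject.mean_heart_period * jp, *HEART_PERIOD_RANGE))
        pp = (subject.baseline_sbp - subject.baseline_dbp) * ja
        tpl = BeatTemplate(
            duration=period,
            onset_value=subject.baseline_dbp,
            systolic_value=subject.baseline_dbp + pp,
        )
        wave, lm = synth_abp_beat(tpl, fs)
        rows.append(
            {
                "onset_idx": cursor,
                "sp_idx": cursor + lm["sp_idx"],
                "dn_idx": cursor + lm["dn_idx"],
                "dbp": lm["dbp"],
                "sbp": lm["sbp"],
            }
        )
        pieces.append(wave)
        cursor += len(wave)
    abp = np.concatenate(pieces)[: max(n_target, 1)]
    truth = pd.DataFrame(rows)
    truth = truth[truth["onset_idx"] < len(abp)].reset_index(drop=True)

    ppg = ppg_from_abp(abp, fs)
    if noise_sd > 0:
        abp = abp + rng.normal(0.0, noise_sd, len(abp))
        ppg = ppg + rng.normal(0.0, noise_sd / 100.0, len(ppg))
    _apply_artifacts(abp, ppg, artifacts, fs, rng)

    record = WaveformRecord(
        record_id=f"{subject.subject_id}-r{seed}",
        subject_id=subject.subject_id,
        fs=fs,
        abp=abp,
        ppg=ppg,
        demographics={"age": subject.age, "gender": subject.gender},
    )
    return record, truth


def write_truth_table(truth: pd.DataFrame, path) -> None:
    """Persist the per-beat ground-truth table as TSV."""
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
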
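"""Onset-synchronized average ABP pulse (ABPM) with sigma-band rejection.

The accepted ABP pulses of a segment are aligned at their onsets into a
ragged matrix; per time-step the mean and the population standard deviation
over the contributing pulses are computed, and the average value retains
only contributors inside mu +/- 1.25 sigma (inclusive band, single pass).
The averaged pulse is then labelled with cardiac-cycle classes delimited by
its systolic peak and dicrotic notch, and dataset-level post-filters remove
averages exceeding 180 mmHg or 1.2 s, or with moment skewness <= 0.2.
Finally each subject contributes at most 10 segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelmin, savgol_filter

from .quality import Pulse, moment_skewness

logger = logging.getLogger(__name__)

SIGMA_BAND = 1.25
MAX_ABP_MMHG = 180.0
MAX_DURATION_S = 1.2
MIN_SKEWNESS = 0.2
SEGMENTS_PER_SUBJECT = 10

#: integer codes of the cardiac-cycle classes
C_O_SP, C_SP_DN, C_DN_E, C_ED = 0, 1, 2, 3
CLASS_NAMES = {C_O_SP: "C[O,SP]", C_SP_DN: "C[SP,DN]", C_DN_E: "C[DN,E]", C_ED: "C[ED]"}


@dataclass
class AveragePulseMorphology:
    """The averaged pulse: per-step values (mmHg), classes and statistics."""

    values: np.ndarray
    classes: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    sp_idx: int
    dn_idx: int
    fs: float = 125.0
    subject_id: str = ""
    segment_id: str = ""

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    @property
    def skewness(self) -> float:
        return moment_skewness(self.values)


def align_pulses(pulses: list[Pulse]) -> np.ndarray:
    """Onset-synchronized ragged matrix (NaN where a pulse has ended).

    Row p, column i holds pulse p's value i samples after its onset.
    """
    if len(pulses) < 2:
        raise ValueError("need at least 2 pulses to average")
    width = max(len(p.samples) for p in pulses)
    mat = np.full((len(pulses), width), np.nan)
    for r, p in enumerate(pulses):
        mat[r, : len(p.samples)] = p.samples
    return mat


def average_pulse(aligned: np.ndarray):
    """Refined column means under the mu +/- 1.25 sigma band.

    Per column: mu and population sigma over the non-NaN contributors; the
    refined mean uses only contributors inside [mu - 1.25 sigma,
    mu + 1.25 sigma] (inclusive, so sigma = 0 keeps everything).  A column
    emptied by the band (cannot happen with the inclusive band, kept as a
    guard) falls back to the unrefined mu.  Columns beyond the median pulse
    length are dropped so the tail with few contributors does not dominate.
    """
    lengths = np.sum(~np.isnan(aligned), axis=1)
    keep = int(np.median(lengths))
    aligned = aligned[:, :keep]
    mu = np.nanmean(aligned, axis=0)
    sigma = np.nanstd(aligned, axis=0)  # population (divide-by-n) form
    lo = mu - SIGMA_BAND * sigma
    hi = mu + SIGMA_BAND * sigma
    inside = (aligned >= lo) & (aligned <= hi)
    counts = inside.sum(axis=0)
    sums = np.where(inside, aligned, 0.0).sum(axis=0)
    values = np.where(counts > 0, sums / np.maximum(counts, 1), mu)
    if (counts == 0).any():  # pragma: no cover - inclusive band guard
        logger.warning("%d columns emptied by sigma band; fell back to mu", int((counts == 0).sum()))
    return values, mu, sigma


def detect_landmarks(avg_values: np.ndarray, fs: float = 125.0):
    """Locate the systolic peak and the dicrotic notch on an averaged pulse.

    SP is the global maximum.  DN is the most prominent local minimum after
    SP; when the decay is monotone the point of maximal curvature (largest
    smoothed second derivative) after SP is used instead.
    """
    x = np.asarray(avg_values, dtype=float)
    sp_idx = int(np.argmax(x))
    tail = x[sp_idx + 1 : -1]
    if tail.size < 5:
        raise ValueError("no room for a dicrotic notch after the systolic peak")
    rel = argrelmin(x[sp_idx + 1 :], order=2)[0]
    # keep candidates away from the very end of the pulse
    rel = rel[rel < len(x) - sp_idx - 3]
    if rel.size:
        # most prominent: deepest relative to surrounding values
        prom = []
        for r in rel:
            i = sp_idx + 1 + r
            left = x[max(sp_idx, i - 10) : i].max(initial=x[i])
            right = x[i + 1 : min(len(x), i + 11)].max(initial=x[i])
            prom.append(min(left, right) - x[i])
        dn_idx = int(sp_idx + 1 + rel[int(np.argmax(prom))])
    else:
        win = min(11, (tail.size // 2) * 2 + 1)
        if win < 5:
            raise ValueError("tail too short for curvature fallback")
        d2 = savgol_filter(x[sp_idx + 1 : -1], win, 3, deriv=2)
        dn_idx = int(sp_idx + 1 + np.argmax(d2))
    if not sp_idx < dn_idx:
        raise ValueError("landmark ordering violated")
    return sp_idx, dn_idx


def assign_classes(avg_values: np.ndarray, sp_idx: int, dn_idx: int) -> np.ndarray:
    """Per-step cardiac-cycle class labels from the two landmarks.

    [0, sp] -> C[O,SP]; (sp, dn] -> C[SP,DN]; (dn, end] -> C[DN,E].
    """
    n = len(avg_values)
    if not (0 < sp_idx < dn_idx < n):
        raise ValueError("need 0 < sp_idx < dn_idx < len")
    classes = np.full(n, C_DN_E, dtype=np.int64)
    classes[: sp_idx + 1] = C_O_SP
    classes[sp_idx + 1 : dn_idx + 1] = C_SP_DN
    return classes


def morphology_from_pulses(pulses: list[Pulse], fs: float = 125.0,
                           subject_id: str = "", segment_id: str = "") -> AveragePulseMorphology:
    """Full ABPM computation for one segment's accepted pulses."""
    aligned = align_pulses(pulses)
    values, mu, sigma = average_pulse(aligned)
    sp_idx, dn_idx = detect_landmarks(values, fs)
    classes = assign_classes(values, sp_idx, dn_idx)
    return AveragePulseMorphology(
        values=values, classes=classes, mu=mu, sigma=sigma,
        sp_idx=sp_idx, dn_idx=dn_idx, fs=fs,
        subject_id=subject_id, segment_id=segment_id,
    )


def postfilter(morphologies: list[AveragePulseMorphology]):
    """Dataset-level filters: max <= 180 mmHg, duration <= 1.2 s, skew > 0.2."""
    kept, rejected = [], []
    for m in morphologies:
        reasons = []
        if np.max(m.values) > MAX_ABP_MMHG:
            reasons.append("max_abp")
        if m.duration > MAX_DURATION_S:
            reasons.append("duration")
        try:
            if m.skewness <= MIN_SKEWNESS:
                reasons.append("skewness")
        except ValueError:
            reasons.append("skewness")
        (kept if not reasons else rejected).append((m, reasons))
    return [m for m, _ in kept], rejected


def cap_subject_segments(manifest: pd.DataFrame, cap: int = SEGMENTS_PER_SUBJECT,
                         seed: int = 0) -> pd.DataFrame:
    """Randomly subsample each subject's segments down to ``cap``."""
    rng = np.random.default_rng(seed)
    parts = []
    for _sid, grp in manifest.groupby("subject_id", sort=True):
        if len(grp) > cap:
            parts.append(grp.iloc[np.sort(rng.choice(len(grp), cap, replace=False))])
        else:
            parts.append(grp)
    return pd.concat(parts).reset_index(drop=True)
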
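"""Clinical evaluation: marker extraction, error metrics, BHS grade, Bland-Altman.

Predicted sequences are first restored from the [0, 1] training scale to
mmHg with the global target scaler.  From each predicted pulse the clinical
markers are read off: DBP as the mean of the first and last in-pulse value,
SBP as the in-pulse maximum, the dicrotic notch at the last step classified
peak-to-notch, its time of occurrence (DNTO), and the pulse duration at the
first "ended" step.  Marker errors are summarized with RMSE / MAE / error
STD / R^2, waveforms with Pearson R (truncating to the shorter sequence),
agreement with BHS cumulative-error grades and Bland-Altman limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .morphology import C_SP_DN, C_ED

logger = logging.getLogger(__name__)

BHS_THRESHOLDS_MMHG = (5.0, 10.0, 15.0)
#: minimum cumulative percentages (<5, <10, <15 mmHg) per grade
BHS_GRADES = {"A": (60.0, 85.0, 95.0), "B": (50.0, 75.0, 90.0), "C": (40.0, 65.0, 85.0)}


@dataclass
class PredictedMarkers:
    dbp: float
    sbp: float
    dn_value: float | None
    dnto_ms: float | None
    duration_ms: float


def extract_markers(values_mmhg: np.ndarray, classes: np.ndarray, fs: float = 125.0) -> PredictedMarkers:
    """Read the clinical markers off one predicted (or true) sequence.

    ``classes`` are integer codes (argmax of the class head).  Steps before
    the first "ended" step are in-pulse; if no "ended" step is predicted
    the whole sequence counts as the pulse (logged).
    """
    values = np.asarray(values_mmhg, dtype=float)
    classes = np.asarray(classes, dtype=int)
    if len(values) != len(classes):
        raise ValueError("values and classes must be the same length")
    ended = np.flatnonzero(classes == C_ED)
    if ended.size:
        end = int(ended[0])
    else:
        end = len(values)
        logger.debug("no ended class predicted; using full length %d", end)
    end = max(end, 2)
    pulse = values[:end]
    dbp = float((pulse[0] + pulse[-1]) / 2.0)
    sbp = float(pulse.max())
    dn_steps = np.flatnonzero(classes[:end] == C_SP_DN)
    if dn_steps.size:
        dn_idx = int(dn_steps[-1])
        dn_value = float(values[dn_idx])
        dnto_ms = dn_idx / fs * 1000.0
    else:
        dn_value = None
        dnto_ms = None
        logger.debug("no peak-to-notch class predicted; DN undefined")
    return PredictedMarkers(
        dbp=dbp, sbp=sbp, dn_value=dn_value, dnto_ms=dnto_ms,
        duration_ms=end / fs * 1000.0,
    )


def restore_scale(scaled_values, scaler):
    """Inverse of the global target scaling (back to mmHg)."""
    return scaler.inverse(scaled_values)


@dataclass
class MetricReport:
    rmse: float
    mae: float
    std: float
    r2: float
    r: float
    n: int


def metrics(truth, pred) -> MetricReport:
    """RMSE, MAE, error STD (n-1), R^2 and Pearson R of paired values.

    For waveform use, sequences of different length are truncated to the
    shorter one before comparison.
    """
    z = np.asarray(truth, dtype=float).ravel()
    zh = np.asarray(pred, dtype=float).ravel()
    n = min(len(z), len(zh))
    if n < 2:
        raise ValueError("need at least 2 paired values")
    z, zh = z[:n], zh[:n]
    err = z - zh
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    std = float(np.std(err, ddof=1))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 and R undefined: truth has zero variance")
    r2 = 1.0 - ss_res / ss_tot
    r = float(pearsonr(z, zh).statistic) if np.std(zh) > 0 else 0.0
    return MetricReport(rmse=rmse, mae=mae, std=std, r2=r2, r=r, n=n)


@dataclass
class AgreementReport:
    cumulative_pct: tuple
    bhs_grade: str
    mean_diff: float | None = None
    limits: tuple | None = None


def bhs_grade(abs_errors_mmhg) -> AgreementReport:
    """Cumulative percentages below 5/10/15 mmHg and the resulting grade.

    A grade requires all three of its row thresholds; below grade C the
    device fails.
    """
    e = np.abs(np.asarray(abs_errors_mmhg, dtype=float))
    if e.size == 0:
        raise ValueError("empty error vector")
    pct = tuple(float(100.0 * np.mean(e < thr)) for thr in BHS_THRESHOLDS_MMHG)
    grade = "fail"
    for g, req in BHS_GRADES.items():
        if all(p >= r for p, r in zip(pct, req)):
            grade = g
            break
    return AgreementReport(cumulative_pct=pct, bhs_grade=grade)


def bland_altman(truth, pred):
    """Mean difference and limits of agreement mu_d +/- 1.96 sigma_d.

    Differences are pred - truth; sigma uses the sample (n-1) denominator.
    Returns (mean_diff, (lower, upper)).
    """
    z = np.asarray(truth, dtype=float).ravel()
    zh = np.asarray(pred, dtype=float).ravel()
    if len(z) != len(zh) or len(z) < 2:
        raise ValueError("need >= 2 paired values of equal length")
    d = zh - z
    mu = float(d.mean())
    sd = float(d.std(ddof=1))
    return mu, (mu - 1.96 * sd, mu + 1.96 * sd)


def evaluate_predictions(truth_pairs, fs: float = 125.0) -> pd.DataFrame:
    """Per-segment marker table from (true values, true classes, predicted
    values, predicted classes) tuples, all in mmHg / class codes."""
    rows = []
    for tv, tc, pv, pc in truth_pairs:
        mt = extract_markers(tv, tc, fs)
        mp = extract_markers(pv, pc, fs)
        wf = metrics(tv, pv)
        rows.append(
            {
                "dbp_true": mt.dbp, "dbp_pred": mp.dbp,
                "sbp_true": mt.sbp, "sbp_pred": mp.sbp,
                "dn_true": mt.dn_value, "dn_pred": mp.dn_value,
                "dnto_true_ms": mt.dnto_ms, "dnto_pred_ms": mp.dnto_ms,
                "duration_true_ms": mt.duration_ms, "duration_pred_ms": mp.duration_ms,
                "waveform_r": wf.r, "waveform_rmse": wf.rmse, "waveform_mae": wf.mae,
            }
        )
    return pd.DataFrame(rows)


def marker_metric_table(per_segment: pd.DataFrame) -> pd.DataFrame:
    """Marker x metric grid (one fold): DBP/DN/SBP in mmHg, DNTO/duration in ms."""
    rows = []
    for marker, (tc, pc) in {
        "DBP": ("dbp_true", "dbp_pred"),
        "DN": ("dn_true", "dn_pred"),
        "SBP": ("sbp_true", "sbp_pred"),
        "DNTO": ("dnto_true_ms", "dnto_pred_ms"),
        "duration": ("duration_true_ms", "duration_pred_ms"),
    }.items():
        sub = per_segment[[tc, pc]].dropna()
        if len(sub) < 2:
            continue
        z, zh = sub[tc].to_numpy(), sub[pc].to_numpy()
        err = z - zh
        row = {"marker": marker,
               "RMSE": float(np.sqrt(np.mean(err**2))),
               "MAE": float(np.mean(np.abs(err))),
               "STD": float(np.std(err, ddof=1)),
               "n": len(z)}
        try:
            row["R2"] = metrics(z, zh).r2
        except ValueError:  # degenerate truth (tiny fold): R^2 undefined
            row["R2"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("marker")


def evaluate_scenario(fold_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-fold marker tables into mean +/- sd across folds."""
    stacked = pd.concat(
        [marker_metric_table(t).assign(fold=i) for i, t in enumerate(fold_tables)]
    )
    agg = stacked.groupby(level=0)[["R2", "RMSE", "MAE", "STD"]].agg(["mean", "std"])
    agg.columns = [f"{metric}_{stat}" for metric, stat in agg.columns]
    return agg
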
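"""Waveform record containers, file formats, and the segment-selection protocol.

Records are paired single-channel ABP (mmHg) and PPG (arbitrary units)
series sampled at 125 Hz.  Selection proceeds record by record: a record is
eligible when it lasts at least 15 minutes, carries both channels, and its
subject has demographics with age in [18, 89].  Within an eligible record,
two 15-s windows separated by a 5-minute start-to-start gap are proposed,
starting after a 10-minute rest interval; each time a proposal fails the
quality checks the cursor advances one minute and a fresh pair is analyzed,
until the record is exhausted (then it is excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FS_DEFAULT = 125.0
SEGMENT_S = 15.0
REST_INTERVAL_S = 600.0
PAIR_GAP_S = 300.0
RETRY_STEP_S = 60.0
MIN_RECORD_S = 900.0


@dataclass
class WaveformRecord:
    """A paired ABP/PPG record with subject linkage and demographics."""

    record_id: str
    subject_id: str
    fs: float
    abp: Optional[np.ndarray]
    ppg: Optional[np.ndarray]
    start_offset: float = 0.0
    demographics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.abp is not None and self.ppg is not None and len(self.abp) != len(self.ppg):
            raise ValueError("abp and ppg must be the same length")

    @property
    def duration(self) -> float:
        sig = self.abp if self.abp is not None else self.ppg
        return 0.0 if sig is None else len(sig) / self.fs

    @property
    def has_both_channels(self) -> bool:
        return self.abp is not None and self.ppg is not None


@dataclass
class SegmentPair:
    """Two 15-s windows of both channels, starts 5 minutes apart."""

    record_id: str
    start_a: float
    start_b: float
    abp_a: np.ndarray
    ppg_a: np.ndarray
    abp_b: np.ndarray
    ppg_b: np.ndarray
    attempt_index: int = 0

    @property
    def gap(self) -> float:
        return self.start_b - self.start_a

    def segments(self):
        yield "a", self.start_a, self.abp_a, self.ppg_a
        yield "b", self.start_b, self.abp_b, self.ppg_b


class RecordExhausted(Exception):
    """No further segment pair fits inside the record."""


# ---------------------------------------------------------------------------
# plain two-column text format and a minimal WFDB-style format
# ---------------------------------------------------------------------------

def write_two_column(record: WaveformRecord, path) -> None:
    """Write ``abp<TAB>ppg`` rows with a one-line ``#`` header."""
    path = Path(path)
    header = f"# record_id={record.record_id} subject_id={record.subject_id} fs={record.fs}"
    data = np.column_stack([record.abp, record.ppg])
    np.savetxt(path, data, fmt="%.6f", delimiter="\t", header=header[2:], comments="# ")


def read_two_column(path, demographics: dict | None = None) -> WaveformRecord:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    data = np.loadtxt(path, delimiter="\t", comments="#")
    return WaveformRecord(
        record_id=meta.get("record_id", path.stem),
        subject_id=meta.get("subject_id", path.stem),
        fs=float(meta.get("fs", FS_DEFAULT)),
        abp=data[:, 0],
        ppg=data[:, 1],
        demographics=demographics or {},
    )


def write_wfdb_style(record: WaveformRecord, directory, gains=(100.0, 10000.0)) -> Path:
    """Write a minimal WFDB-style pair: ``<id>.hea`` header + ``<id>.dat``.

    The signal file holds interleaved 16-bit little-endian samples (WFDB
    format 16); the header records fs, sample count, and per-channel
    gain/baseline.  This is a deliberately small subset of the WFDB spec —
    enough to round-trip records produced by this package.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    n = len(record.abp)
    base = 0
    ints = np.empty((n, 2), dtype="<i2")
    for ch, (sig, gain) in enumerate(zip((record.abp, record.ppg), gains)):
        ints[:, ch] = np.round(sig * gain).astype("<i2")
    dat = directory / f"{name}.dat"
    ints.tofile(dat)
    hea = directory / f"{name}.hea"
    lines = [f"{name} 2 {record.fs:g} {n}"]
    for ch, (label, gain) in enumerate(zip(("ABP", "PLETH"), gains)):
        lines.append(f"{name}.dat 16 {gain:g}({base})/{'mmHg' if label == 'ABP' else 'NU'} 0 0 0 0 0 {label}")
    lines.append(f"# subject_id={record.subject_id}")
    hea.write_text("\n".join(lines) + "\n")
    return hea


def read_wfdb_style(header_path, demographics: dict | None = None) -> WaveformRecord:
    header_path = Path(header_path)
    lines = [ln for ln in header_path.read_text().splitlines() if ln.strip()]
    name, n_sig, fs, n = lines[0].split()[:4]
    n_sig, fs, n = int(n_sig), float(fs), int(n)
    gains, labels = [], []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        gains.append(float(parts[2].split("(")[0]))
        labels.append(parts[-1])
    subject_id = name
    for ln in lines[1 + n_sig:]:
        if ln.startswith("#") and "subject_id=" in ln:
            subject_id = ln.split("subject_id=")[1].strip()
    raw = np.fromfile(header_path.with_suffix(".dat"), dtype="<i2").reshape(n, n_sig)
    sig = {lab: raw[:, ch] / gains[ch] for ch, lab in enumerate(labels)}
    return WaveformRecord(
        record_id=name,
        subject_id=subject_id,
        fs=fs,
        abp=sig.get("ABP"),
        ppg=sig.get("PLETH"),
        demographics=demographics or {},
    )


def read_demographics(path) -> pd.DataFrame:
    """Load a delimited (subject_id, age, gender) table."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "age", "gender"}
    if not required.issubset(df.columns):
        raise ValueError(f"demographics table must have columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# selection protocol
# ---------------------------------------------------------------------------

def scan_eligible(records: Iterable[WaveformRecord]) -> list[WaveformRecord]:
    """Keep records >= 15 min with both channels and in-range demographics."""
    kept = []
    for rec in records:
        try:
            ok_duration = rec.duration >= MIN_RECORD_S
            ok_channels = rec.has_both_channels
        except Exception:  # malformed metadata
            logger.warning("record %s skipped: unreadable channel metadata", getattr(rec, "record_id", "?"))
            continue
        age = rec.demographics.get("age")
        ok_age = age is not None and 18.0 <= float(age) <= 89.0
        if ok_duration and ok_channels and ok_age:
            kept.append(rec)
        else:
            logger.info(
                "record %s excluded (duration_ok=%s channels_ok=%s age_ok=%s)",
                rec.record_id, ok_duration, ok_channels, ok_age,
            )
    return kept


def propose_segment_pair(record: WaveformRecord, cursor: float, attempt_index: int = 0) -> SegmentPair:
    """Two 15-s windows starting at ``cursor`` and ``cursor + 300`` s.

    Windows are half-open [start, start + 15 s) — exactly 1875 samples at
    125 Hz.  Raises :class:`RecordExhausted` when the second window would
    run past the end of the record.
    """
    fs = record.fs
    n_seg = int(round(SEGMENT_S * fs))
    i_a = int(round(cursor * fs))
    i_b = int(round((cursor + PAIR_GAP_S) * fs))
    if i_b + n_seg > len(record.abp):
        raise RecordExhausted(
            f"record {record.record_id}: no pair fits at cursor {cursor:.0f} s"
        )
    return SegmentPair(
        record_id=record.record_id,
        start_a=cursor,
        start_b=cursor + PAIR_GAP_S,
        abp_a=record.abp[i_a : i_a + n_seg].copy(),
        ppg_a=record.ppg[i_a : i_a + n_seg].copy(),
        abp_b=record.abp[i_b : i_b + n_seg].copy(),
        ppg_b=record.ppg[i_b : i_b + n_seg].copy(),
        attempt_index=attempt_index,
    )


def acceptance_loop(
    record: WaveformRecord,
    quality_fn: Callable[[SegmentPair], bool],
    start_cursor: float = REST_INTERVAL_S,
) -> Optional[SegmentPair]:
    """Advance a 60-s cursor until ``quality_fn`` accepts a pair.

    Returns the accepted pair, or ``None`` when the record is exhausted
    without an acceptable pair (the record is then excluded).
    """
    cursor = start_cursor
    attempt = 0
    while True:
        try:
            pair = propose_segment_pair(record, cursor, attempt_index=attempt)
        except RecordExhausted:
            logger.info("record %s excluded: cursor exhausted after %d attempts", record.record_id, attempt)
            return None
        if quality_fn(pair):
            return pair
        cursor += RETRY_STEP_S
        attempt += 1


# ---------------------------------------------------------------------------
# hierarchical container
# ---------------------------------------------------------------------------

class SegmentContainer:
    """HDF5 container of raw accepted segments and their processed products.

    Layout: one group per segment under ``/segments/<segment_id>`` with
    datasets ``abp_raw``, ``ppg_raw`` and, once processing attaches them,
    ``avg_values``, ``avg_classes``, ``ppg_input``; attributes hold subject
    linkage, demographics, landmarks and timing.
    """

    def __init__(self, path, mode="a"):
        self.path = Path(path)
        self._h5 = h5py.File(self.path, mode)
        self._h5.require_group("segments")

    def close(self):
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def add_segment(self, segment_id: str, abp: np.ndarray, ppg: np.ndarray, **attrs) -> None:
        grp = self._h5["segments"].create_group(segment_id)
        grp.create_dataset("abp_raw", data=abp)
        grp.create_dataset("ppg_raw", data=ppg)
        for k, v in attrs.items():
            grp.attrs[k] = v

    def attach(self, segment_id: str, name: str, data: np.ndarray, **attrs) -> None:
        grp = self._h5["segments"][segment_id]
        if name in grp:
            del grp[name]
        ds = grp.create_dataset(name, data=data)
        for k, v in attrs.items():
            ds.attrs[k] = v

    def set_attrs(self, segment_id: str, **attrs) -> None:
        grp = self._h5["segments"][segment_id]
        for k, v in attrs.items():
            grp.attrs[k] = v

    def segment_ids(self) -> list[str]:
        return sorted(self._h5["segments"].keys())

    def get(self, segment_id: str, name: str) -> np.ndarray:
        return np.asarray(self._h5["segments"][segment_id][name])

    def has(self, segment_id: str, name: str) -> bool:
        return name in self._h5["segments"][segment_id]

    def attrs(self, segment_id: str) -> dict:
        return dict(self._h5["segments"][segment_id].attrs)
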
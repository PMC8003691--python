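"""End-to-end orchestration: records -> quality -> morphology -> model dataset.

This module glues the stages together in processing order: record
eligibility and the retry-based segment selection, the quality cascade on
each proposed pair, average-pulse computation with its post-filters, the
per-subject segment cap, and finally the homogenized, masked training
samples the model consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features, record_io, synthgen
from .features import TargetScaler, encode_demographics, fixed_length, homogenize_target, prepare_ppg_input
from .morphology import AveragePulseMorphology, cap_subject_segments, morphology_from_pulses, postfilter
from .quality import QualityConfig, pair_quality
from .record_io import WaveformRecord, acceptance_loop
from .training import TrainingSample

logger = logging.getLogger(__name__)


@dataclass
class SegmentProduct:
    """One accepted 15-s segment with everything downstream stages need."""

    segment_id: str
    subject_id: str
    record_id: str
    start_s: float
    abp_raw: np.ndarray
    ppg_raw: np.ndarray
    morphology: AveragePulseMorphology
    demographics: dict = field(default_factory=dict)


@dataclass
class StageCounts:
    records_in: int = 0
    records_eligible: int = 0
    records_accepted: int = 0
    segments_accepted: int = 0
    morphologies_kept: int = 0
    morphologies_rejected: dict = field(default_factory=dict)


def process_record(record: WaveformRecord, quality_config: QualityConfig | None = None):
    """Run selection + quality + morphology for one record.

    Returns a list of :class:`SegmentProduct` (two per accepted pair) or an
    empty list when the record is excluded.
    """
    cfg = quality_config or QualityConfig()
    pulses_by_label = {}

    def quality_fn(pair):
        accepted, out = pair_quality(pair, cfg)
        if accepted:
            pulses_by_label.clear()
            pulses_by_label.update({lab: pulses for lab, (_, pulses) in out.items()})
        return accepted

    pair = acceptance_loop(record, quality_fn)
    if pair is None:
        return []
    products = []
    for label, start, abp_seg, ppg_seg in pair.segments():
        seg_id = f"{record.record_id}-{int(start)}{label}"
        try:
            morph = morphology_from_pulses(
                pulses_by_label[label], fs=record.fs,
                subject_id=record.subject_id, segment_id=seg_id,
            )
        except ValueError as exc:
            logger.info("segment %s dropped at morphology stage: %s", seg_id, exc)
            continue
        products.append(
            SegmentProduct(
                segment_id=seg_id,
                subject_id=record.subject_id,
                record_id=record.record_id,
                start_s=start,
                abp_raw=abp_seg,
                ppg_raw=ppg_seg,
                morphology=morph,
                demographics=dict(record.demographics),
            )
        )
    return products


def process_records(records, quality_config: QualityConfig | None = None,
                    cap_seed: int = 0):
    """Full processing stage over a record collection.

    Returns ``(products, manifest, counts)`` where the manifest is the
    post-filtered, per-subject-capped segment table.
    """
    counts = StageCounts(records_in=len(records))
    eligible = record_io.scan_eligible(records)
    counts.records_eligible = len(eligible)
    all_products: list[SegmentProduct] = []
    for rec in eligible:
        prods = process_record(rec, quality_config)
        if prods:
            counts.records_accepted += 1
        all_products.extend(prods)
    counts.segments_accepted = len(all_products)

    morphs = [p.morphology for p in all_products]
    kept, rejected = postfilter(morphs)
    for _m, reasons in rejected:
        for r in reasons:
            counts.morphologies_rejected[r] = counts.morphologies_rejected.get(r, 0) + 1
    kept_ids = {id(m) for m in kept}
    products = [p for p in all_products if id(p.morphology) in kept_ids]
    counts.morphologies_kept = len(products)

    manifest = pd.DataFrame(
        [{"subject_id": p.subject_id, "segment_id": p.segment_id, "record_id": p.record_id}
         for p in products]
    )
    if len(manifest):
        manifest = cap_subject_segments(manifest, seed=cap_seed)
        keep_ids = set(manifest["segment_id"])
        products = [p for p in products if p.segment_id in keep_ids]
    return products, manifest, counts


def build_training_samples(products, scaler: TargetScaler | None = None,
                           T: int | None = None, use_di: bool = True):
    """Homogenized, masked samples from processed segments.

    The scaler and fixed length are fitted on ``products`` when not given
    (pass the training-fold values when preparing a test fold).
    Returns (samples, scaler, T).
    """
    if not products:
        raise ValueError("no segment products")
    morphs = [p.morphology for p in products]
    if scaler is None:
        scaler = features.scale_target_global(morphs)
    if T is None:
        T = fixed_length(morphs)
    samples = []
    for p in products:
        target = homogenize_target(p.morphology, T, scaler)
        di = None
        if use_di:
            di = encode_demographics(p.demographics.get("age"), p.demographics.get("gender"))
        samples.append(
            TrainingSample(
                prepared=prepare_ppg_input(p.ppg_raw),
                target=target,
                di=di,
                subject_id=p.subject_id,
                segment_id=p.segment_id,
            )
        )
    return samples, scaler, T


def make_synthetic_cohort(n_subjects: int, record_duration_s: float = 960.0,
                          noise_sd: float = 0.0, seed: int = 0):
    """Records + truth tables for a cohort of synthetic subjects.

    One record per subject; the default 16-minute duration leaves room for
    one segment pair after the 10-minute rest interval.
    """
    records, truths = [], {}
    for i in range(n_subjects):
        subject = synthgen.make_subject((seed * 10_007 + i) % (2**31 - 1))
        rec, truth = synthgen.synth_record(
            subject, duration=record_duration_s, noise_sd=noise_sd,
            seed=(seed * 20_011 + i) % (2**31 - 1),
        )
        records.append(rec)
        truths[rec.record_id] = truth
    return records, truths


def dataset_hours(n_segments: int, seconds_each: float) -> float:
    """Total waveform hours represented by a segment collection."""
    return n_segments * seconds_each / 3600.0


def cohort_size(demographics: pd.DataFrame) -> dict:
    """Subject counts overall and per gender from a demographics table."""
    counts = demographics["gender"].value_counts().to_dict()
    return {"total": int(len(demographics)), **{k: int(v) for k, v in counts.items()}}


def save_products(products, container_path) -> None:
    """Persist processed segments into the hierarchical container."""
    with record_io.SegmentContainer(container_path, "w") as con:
        for p in products:
            con.add_segment(
                p.segment_id, p.abp_raw, p.ppg_raw,
                subject_id=p.subject_id, record_id=p.record_id, start_s=p.start_s,
                age=float(p.demographics.get("age", np.nan)),
                gender=str(p.demographics.get("gender", "")),
            )
            m = p.morphology
            con.attach(p.segment_id, "avg_values", m.values)
            con.attach(p.segment_id, "avg_classes", m.classes)
            con.set_attrs(p.segment_id, sp_idx=m.sp_idx, dn_idx=m.dn_idx, fs=m.fs)
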
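import pytest

from pulsemorph.pipeline import build_training_samples, make_synthetic_cohort, process_records


@pytest.fixture(scope="session")
def subject():
    from pulsemorph.synthgen import make_subject

    return make_subject(0)


@pytest.fixture(scope="session")
def clean_record(subject):
    """A 16-minute noise-free record with its beat-level ground truth."""
    from pulsemorph.synthgen import synth_record

    return synth_record(subject, duration=960.0, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_segment(clean_record):
    """One 15-s window (both channels) starting at the 10-min mark, plus the
    ground-truth beats whose onsets fall inside it (segment-local indices)."""
    record, truth = clean_record
    i0 = int(600 * record.fs)
    n = int(15 * record.fs)
    sel = truth[(truth.onset_idx >= i0) & (truth.onset_idx < i0 + n)].copy()
    for col in ("onset_idx", "sp_idx", "dn_idx"):
        sel[col] = sel[col] - i0
    return record.abp[i0 : i0 + n], record.ppg[i0 : i0 + n], sel


@pytest.fixture(scope="session")
def small_cohort():
    """Four noise-free records processed end to end."""
    records, truths = make_synthetic_cohort(4, seed=3)
    products, manifest, counts = process_records(records)
    return records, truths, products, manifest, counts


@pytest.fixture(scope="session")
def training_setup(small_cohort):
    _records, _truths, products, _manifest, _counts = small_cohort
    samples, scaler, T = build_training_samples(products)
    return samples, scaler, T, products
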
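"""Shared fixtures: small cohorts and featurized channel sets."""

import numpy as np
import pytest

from ictalflow.orchestrate import featurize_records
from ictalflow.synthdata import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def easy_cohort():
    """Mixed seizure/non-seizure cohort, unambiguous channels (10 patients)."""
    cfg = CohortConfig(n_patients=10, records_per_patient=2,
                       seizure_record_fraction=0.5,
                       ambiguity_low=0.0, ambiguity_high=0.0, seed=42)
    records, truths = generate_cohort(cfg)
    return cfg, records, truths


@pytest.fixture(scope="session")
def easy_features(easy_cohort):
    """Spectrogram images + seizure labels aligned with channel metadata."""
    _, records, truths = easy_cohort
    X, meta = featurize_records(records)
    truth_map = {(t.record_id, t.channel_index): t.is_seizure for t in truths}
    y = np.array([truth_map[(r.record_id, r.channel_index)]
                  for r in meta.itertuples()], dtype=float)
    return X, y, meta


@pytest.fixture(scope="session")
def sod_training_set():
    """Onset-biased seizure-only cohort and a uniform-onset validation cohort."""
    train_cfg = CohortConfig(n_patients=8, records_per_patient=2,
                             seizure_record_fraction=1.0, onset_center_s=30.0,
                             onset_spread_s=3.0, ambiguity_low=0.0,
                             ambiguity_high=0.0, seed=7)
    val_cfg = CohortConfig(n_patients=4, records_per_patient=2,
                           seizure_record_fraction=1.0, onset_center_s=45.0,
                           onset_spread_s=35.0, onset_distribution="uniform",
                           ambiguity_low=0.0, ambiguity_high=0.0, seed=8)
    rec_t, tru_t = generate_cohort(train_cfg)
    rec_v, tru_v = generate_cohort(val_cfg)
    for r in rec_v:
        r.patient_id = "V" + r.patient_id
    return (rec_t, tru_t), (rec_v, tru_v)
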
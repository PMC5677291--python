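import numpy as np
import pandas as pd
import pytest

import stresskit as sk
from stresskit.features import FEATURE_COLUMNS


@pytest.fixture(scope="session")
def cohort_features():
    """Feature table of the default high-separability 12-subject cohort.

    Session-scoped: generation plus feature extraction takes about a
    minute and several end-to-end tests share it.
    """
    cohort = sk.generate_cohort(12, seed=1, separability="high")
    return sk.extract_cohort_features(cohort)


@pytest.fixture()
def blob_table():
    """Synthetic 24-feature table: one tight Gaussian blob per session.

    Two subjects, 10 epochs per session, class means separated by 6
    within-class SDs in every feature - trivially separable, for
    classifier plumbing tests that should reach 100%.
    """
    rng = np.random.default_rng(0)
    rows = []
    for subject in ("A", "B"):
        for ci, session in enumerate(sk.SESSIONS):
            for ep in range(10):
                x = rng.normal(0.0, 1.0, len(FEATURE_COLUMNS))
                x += 6.0 * ci
                rows.append({"subject": subject, "session": session,
                             "epoch": ep,
                             **dict(zip(FEATURE_COLUMNS, x))})
    return pd.DataFrame(rows)


@pytest.fixture()
def quiet_params():
    """SessionParams with every stochastic term switched off."""
    def make(label="BA-S", **kw):
        base = dict(sd_rr=0.0, rsa_amp_ms=0.0, scr_rate=0.0,
                    tonic_drift=0.0, tonic_wander_sd=0.0, skt_drift=0.0,
                    skt_wander_sd=0.0, ppg_noise_sd=0.0, eda_noise_sd=0.0,
                    skt_noise_sd=0.0)
        base.update(kw)
        return sk.SessionParams(session_label=label, **base)
    return make
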
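"""Assemble the 24-feature table from a recording.

Per session: the PPG channel is band-pass filtered and epoched, pulse
peaks detected independently in each 6 s epoch, and the 15 HRV features
computed from the epoch's NN intervals. The EDA channel is decomposed
once over the whole session (the deconvolution needs more context than a
single epoch) and the 6 electrodermal features are read off each epoch's
slice of the decomposition. The 3 skin-temperature features come from
the raw epoch.

Epochs whose features cannot be computed (too few beats, no spectral
support) receive NaN markers, which are then imputed from the
subject-session median of the same feature so the classifier input is
rectangular; the imputation count is logged.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import eda, hrv, preprocess, skt
from .errors import InsufficientPeaksError
from .signals import SESSIONS
from .synth import SubjectRecording

log = logging.getLogger(__name__)

META_COLUMNS = ["subject", "session", "epoch"]
FEATURE_COLUMNS = hrv.HRV_FEATURES + eda.EDA_FEATURES + skt.SKT_FEATURES

FEATURE_SETS = {
    "HRV": hrv.HRV_FEATURES,
    "SC": eda.EDA_FEATURES,
    "SKT": skt.SKT_FEATURES,
    "IT": FEATURE_COLUMNS,
}


def extract_subject_features(rec: SubjectRecording,
                             discard_lead: float = preprocess.DEFAULT_DISCARD,
                             epoch_duration: float = preprocess.DEFAULT_EPOCH,
                             whole_session_peaks: bool = False,
                             ) -> pd.DataFrame:
    """Feature rows (one per epoch) for all five sessions of a subject.

    ``whole_session_peaks`` switches pulse-peak detection from the
    default per-epoch mode to a single pass over the filtered session,
    with each epoch reading the peaks that fall inside it.
    """
    rows = []
    for label in SESSIONS:
        chans = rec.sessions[label]
        filt = preprocess.bandpass_ppg(chans["ppg"])
        ppg_epochs = preprocess.segment_epochs(
            filt, discard_lead, epoch_duration, rec.subject_id, label)
        skt_epochs = preprocess.segment_epochs(
            chans["skt"], discard_lead, epoch_duration, rec.subject_id, label)
        dec = eda.decompose_sc(chans["eda"])
        session_peaks = None
        if whole_session_peaks:
            session_peaks = preprocess.detect_peaks(filt)
        for i, ep in enumerate(ppg_epochs):
            t_end = ep.t0 + epoch_duration
            row = {"subject": rec.subject_id, "session": label, "epoch": i}
            try:
                if session_peaks is not None:
                    pk = session_peaks[(session_peaks >= ep.t0)
                                       & (session_peaks < t_end)]
                    if pk.size < 2:
                        raise InsufficientPeaksError("too few peaks in epoch")
                else:
                    pk = preprocess.detect_peaks(ep)
                nns = preprocess.compute_nn(pk)
            except InsufficientPeaksError:
                nns = None
            row.update(hrv.hrv_features(nns))
            dec_ep = eda.slice_decomposition(dec, ep.t0, t_end)
            x_ep = chans["eda"].slice_time(ep.t0, t_end)
            row.update(eda.eda_features(x_ep, dec_ep))
            row.update(skt.skt_features(skt_epochs.epochs[i]))
            rows.append(row)
    df = pd.DataFrame(rows)
    return impute_missing(df)


def impute_missing(df: pd.DataFrame) -> pd.DataFrame:
    """Replace NaN feature markers by the subject-session median.

    Falls back to the subject median, then to the column median, for the
    rare case of a feature missing in every epoch of a session.
    """
    df = df.copy()
    n_missing = int(df[FEATURE_COLUMNS].isna().sum().sum())
    if n_missing:
        log.info("imputing %d missing feature values", n_missing)
        for level in (["subject", "session"], ["subject"]):
            med = df.groupby(level)[FEATURE_COLUMNS].transform("median")
            df[FEATURE_COLUMNS] = df[FEATURE_COLUMNS].fillna(med)
        df[FEATURE_COLUMNS] = df[FEATURE_COLUMNS].fillna(
            df[FEATURE_COLUMNS].median())
        # a feature undefined on every row carries no information; zero it
        # so standardization passes it through harmlessly
        df[FEATURE_COLUMNS] = df[FEATURE_COLUMNS].fillna(0.0)
    return df


def extract_cohort_features(cohort, **kwargs) -> pd.DataFrame:
    """Concatenate per-subject feature tables for a list of recordings."""
    return pd.concat(
        [extract_subject_features(rec, **kwargs) for rec in cohort],
        ignore_index=True)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    return df
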
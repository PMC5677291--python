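"""PPG conditioning, session epoching, pulse-peak detection, NN intervals.

The pulse channel is band-pass filtered to 0.5–4 Hz: slow motion
artifacts sit below 0.1 Hz and the heartbeat fundamental near 1 Hz, so
this band isolates the cardiac component. Sessions are epoched into
consecutive 6 s windows after discarding an unstable 35 s lead-in.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .errors import EmptySegmentError, InsufficientPeaksError, InvalidArgumentError
from .signals import EpochSet, NNSeries, TimeSeries

DEFAULT_BAND = (0.5, 4.0)
DEFAULT_DISCARD = 35.0
DEFAULT_EPOCH = 6.0
DEFAULT_MIN_RR = 0.3  # s; refractory period, caps HR at 200 bpm


def bandpass_ppg(x: TimeSeries, low: float = DEFAULT_BAND[0],
                 high: float = DEFAULT_BAND[1], order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth band-pass of a PPG series.

    Forward-backward filtering (``filtfilt``) preserves peak timing,
    which matters because beat intervals are read straight off the
    filtered peaks.
    """
    if x.channel != "ppg":
        raise InvalidArgumentError("bandpass_ppg expects a ppg channel")
    nyq = x.fs / 2.0
    if not (0 < low < high < nyq):
        raise InvalidArgumentError(
            f"band ({low}, {high}) must satisfy 0 < low < high < fs/2={nyq}")
    # second-order sections: the polynomial (b, a) form of a narrow
    # low-frequency band-pass is numerically fragile at high rates
    sos = butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    y = sosfiltfilt(sos, x.samples)
    return TimeSeries(y, x.fs, "ppg", t0=x.t0)


def segment_epochs(x: TimeSeries, discard_lead: float = DEFAULT_DISCARD,
                   epoch_duration: float = DEFAULT_EPOCH,
                   subject_id: str = "", session_label: str = "") -> EpochSet:
    """Cut a session into consecutive non-overlapping epochs.

    The first ``discard_lead`` seconds are dropped, then epoch *i* covers
    the half-open interval ``[discard_lead + i*d, discard_lead + (i+1)*d)``;
    a trailing remainder shorter than one epoch is discarded. A 240 s
    session with the defaults yields 34 epochs.
    """
    if epoch_duration <= 0:
        raise InvalidArgumentError("epoch_duration must be positive")
    usable = x.duration - discard_lead
    n_epochs = int(np.floor(usable / epoch_duration + 1e-9))
    if usable <= 0 or n_epochs < 1:
        raise EmptySegmentError(
            f"signal of {x.duration:.1f} s yields no epochs after "
            f"discarding {discard_lead:.1f} s")
    n_per = int(round(epoch_duration * x.fs))
    i0 = int(round(discard_lead * x.fs))
    epochs = []
    for i in range(n_epochs):
        lo = i0 + i * n_per
        seg = x.samples[lo:lo + n_per]
        if seg.size < n_per:
            break
        epochs.append(TimeSeries(seg, x.fs, x.channel,
                                 t0=x.t0 + lo / x.fs))
    return EpochSet(epochs, epoch_duration, discard_lead,
                    subject_id, session_label)


def detect_peaks(x: TimeSeries, min_rr: float = DEFAULT_MIN_RR) -> np.ndarray:
    """Detect pulse peaks in a band-passed PPG series; returns times (s).

    Local maxima above an adaptive amplitude threshold — the larger of
    (median + 0.5 * IQR) and 20% of the 98th amplitude percentile of the
    filtered signal — are kept, subject to a ``min_rr`` refractory
    period that retains the larger of two close candidates.
    """
    s = x.samples
    q1, med, q3 = np.percentile(s, [25, 50, 75])
    # the IQR term adapts to noise; the percentile floor rejects filter
    # ripple between sparse pulses
    thresh = max(med + 0.5 * (q3 - q1), 0.2 * np.percentile(s, 98))
    distance = max(int(round(min_rr * x.fs)), 1)
    idx, _ = find_peaks(s, height=thresh, distance=distance)
    if idx.size < 2:
        raise InsufficientPeaksError(
            f"found {idx.size} peaks; need at least 2")
    return x.t0 + idx / x.fs


def compute_nn(peak_times: np.ndarray) -> NNSeries:
    """Normal-to-normal intervals (ms) from detected peak times."""
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        raise InsufficientPeaksError("need at least 2 peaks for NN intervals")
    return NNSeries(peak_times)


def epoch_manifest(es: EpochSet):
    """Rows (subject, session, epoch_index, t_start, t_end) for an EpochSet."""
    rows = []
    for i, ep in enumerate(es.epochs):
        rows.append({"subject": es.subject_id, "session": es.session_label,
                     "epoch_index": i, "t_start": ep.t0,
                     "t_end": ep.t0 + ep.duration})
    return rows
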
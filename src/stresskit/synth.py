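"""Synthetic PPG/EDA/SKT recordings with session-dependent structure.

The generator emulates the autonomic signatures of graded mental stress:
rising heart rate (shorter RR intervals) with reduced beat-to-beat
variability, more frequent and larger skin-conductance responses on a
higher tonic level, and a shifted skin-temperature level. Five sessions
are produced per subject — baseline (BA-S), mild (MIS-S), moderate
(MOS-S) and severe (SES-S) stress, then recovery (RE-S) — each four
minutes long and sampled at 400 Hz by default.

Every stochastic element flows from a single master seed through
per-subject, per-session, per-channel derived streams, so cohorts are
bit-reproducible.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError
from .signals import SESSIONS, TimeSeries

DEFAULT_FS = 400.0
DEFAULT_DURATION = 240.0

# RR clipping bounds (ms): physiological limits ~30-200 bpm.
RR_MIN, RR_MAX = 300.0, 2000.0


@dataclass(frozen=True)
class SessionParams:
    """Generative parameters of one session's three channels.

    Heart: RR intervals follow mean_rr + sd_rr * AR(1) noise plus a
    respiratory sinus-arrhythmia sinusoid of amplitude rsa_amp_ms at
    resp_freq. EDA: a linear tonic trend plus Poisson-timed
    skin-conductance responses shaped by a Bateman biexponential. SKT: a
    linear trend in degrees Celsius. All noise_sd values are per-sample
    additive Gaussian noise in channel units.
    """

    session_label: str
    mean_rr: float = 800.0        # ms
    sd_rr: float = 50.0           # ms
    resp_freq: float = 0.25       # Hz
    rsa_amp_ms: float = 20.0      # ms
    ar1_phi: float = 0.3          # AR(1) coefficient of RR noise
    scr_rate: float = 4.0         # SCR events per minute
    scr_amp_mean: float = 0.4     # µS, mean event peak amplitude
    tonic_level: float = 2.0      # µS
    tonic_drift: float = 0.02     # µS per minute
    tonic_wander_sd: float = 0.35  # µS, slow Ornstein-Uhlenbeck wander
    skt_mean: float = 33.0        # °C
    skt_drift: float = 0.0        # °C per minute
    skt_wander_sd: float = 0.15   # °C, slow vasomotor wander
    wander_tau: float = 60.0      # s, wander correlation time
    ppg_noise_sd: float = 0.02
    eda_noise_sd: float = 0.005   # µS
    skt_noise_sd: float = 0.05    # °C

    def __post_init__(self) -> None:
        if self.session_label not in SESSIONS:
            raise InvalidArgumentError(
                f"unknown session label {self.session_label!r}")
        if self.mean_rr <= 0:
            raise InvalidArgumentError("mean_rr must be positive")
        if self.sd_rr < 0 or self.scr_rate < 0:
            raise InvalidArgumentError("sd_rr and scr_rate must be >= 0")
        if min(self.ppg_noise_sd, self.eda_noise_sd, self.skt_noise_sd) < 0:
            raise InvalidArgumentError("noise SDs must be >= 0")


# Baseline-to-severe gradients: heart rate and sudomotor drive increase
# monotonically with stress level; skin temperature rises; recovery sits
# between baseline and mild. Contrasts are sized so, relative to the slow
# within-session wander of each channel, heart-derived features carry the
# most class information, electrodermal features somewhat less, and skin
# temperature the least — the discriminability ordering observed for
# these signals in seated mental-arithmetic stress.
_SESSION_DELTAS = {
    #            mean_rr sd_rr  rsa  scr_rate scr_amp tonic  skt
    "BA-S": dict(mean_rr=900.0, sd_rr=52.0, rsa_amp_ms=26.0, scr_rate=2.0,
                 scr_amp_mean=0.30, tonic_level=2.19, skt_mean=33.0),
    "MIS-S": dict(mean_rr=795.0, sd_rr=40.0, rsa_amp_ms=19.0, scr_rate=4.5,
                  scr_amp_mean=0.40, tonic_level=2.58, skt_mean=33.13),
    "MOS-S": dict(mean_rr=720.0, sd_rr=31.0, rsa_amp_ms=14.0, scr_rate=6.5,
                  scr_amp_mean=0.47, tonic_level=2.87, skt_mean=33.24),
    "SES-S": dict(mean_rr=645.0, sd_rr=22.0, rsa_amp_ms=9.0, scr_rate=9.0,
                  scr_amp_mean=0.55, tonic_level=3.26, skt_mean=33.40),
    # recovery is asymmetric across effector systems: mean heart rate is
    # back near baseline, but vagally mediated variability stays
    # suppressed, sudomotor activity stays elevated, and skin temperature
    # lags with thermal inertia -- so the recovery session is not a
    # replay of baseline on any single axis
    "RE-S": dict(mean_rr=855.0, sd_rr=30.0, rsa_amp_ms=13.0, scr_rate=5.0,
                 scr_amp_mean=0.38, tonic_level=2.42, skt_mean=33.30),
}

#: How much the separability knob compresses/expands session contrasts.
_SEPARABILITY_SCALE = {"low": 0.4, "medium": 1.0, "high": 2.0}
#: How it scales sensor noise ...
_SEPARABILITY_NOISE = {"low": 2.0, "medium": 1.0, "high": 0.4}
#: ... and the slow physiological wander (less compressible than sensor
#: noise: even a cooperative subject's tonic level drifts).
_SEPARABILITY_WANDER = {"low": 1.5, "medium": 1.0, "high": 0.5}


def default_session_params(separability: str = "medium") -> dict:
    """Session-keyed default :class:`SessionParams` for one cohort.

    ``separability`` scales between-session contrasts about the cohort
    grand value and inversely scales channel noise; ``high`` produces a
    cohort the downstream classifier separates almost perfectly, ``low``
    a heavily overlapping one.
    """
    if separability not in _SEPARABILITY_SCALE:
        raise InvalidArgumentError(
            f"separability must be one of {sorted(_SEPARABILITY_SCALE)}")
    s = _SEPARABILITY_SCALE[separability]
    w = _SEPARABILITY_NOISE[separability]
    wd = _SEPARABILITY_WANDER[separability]
    keys = list(next(iter(_SESSION_DELTAS.values())))
    grand = {k: np.mean([d[k] for d in _SESSION_DELTAS.values()]) for k in keys}
    out = {}
    for label in SESSIONS:
        d = _SESSION_DELTAS[label]
        scaled = {k: grand[k] + s * (d[k] - grand[k]) for k in keys}
        for k in ("scr_rate", "sd_rr", "rsa_amp_ms", "scr_amp_mean"):
            scaled[k] = max(scaled[k], 0.0)
        out[label] = SessionParams(
            session_label=label,
            ppg_noise_sd=0.02 * w,
            eda_noise_sd=0.005 * w,
            skt_noise_sd=0.05 * w,
            tonic_wander_sd=0.35 * wd,
            skt_wander_sd=0.15 * wd,
            **scaled,
        )
    return out


@dataclass
class SessionGroundTruth:
    """Exact latent variables used to synthesize one session."""

    params: SessionParams
    rr_ms: np.ndarray            # RR sequence actually used
    scr_times: np.ndarray        # event onset times (s)
    scr_amps: np.ndarray         # event peak amplitudes (µS)


@dataclass
class SubjectRecording:
    """All five sessions of one subject plus generator ground truth."""

    subject_id: str
    sessions: dict               # label -> {"ppg","eda","skt": TimeSeries}
    ground_truth: dict           # label -> SessionGroundTruth

    def channels(self):
        """Iterate (session_label, channel_name, TimeSeries)."""
        for label in SESSIONS:
            for ch, ts in self.sessions[label].items():
                yield label, ch, ts


def _derived_rng(seed: int, *streams: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes, unlike builtin str hashing
    ss = np.random.SeedSequence(seed, spawn_key=tuple(
        zlib.crc32(s.encode()) for s in streams))
    return np.random.default_rng(ss)


def _ou_wander(n: int, fs: float, sd: float, tau: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck wander with SD ``sd`` and time
    constant ``tau`` (s), simulated at 4 Hz and interpolated to ``fs``."""
    if sd <= 0:
        return np.zeros(n)
    fs_c = min(4.0, fs)
    n_c = max(int(np.ceil(n / fs * fs_c)) + 2, 2)
    dt = 1.0 / fs_c
    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    w = np.empty(n_c)
    w[0] = sd * rng.standard_normal()
    eps = rng.standard_normal(n_c - 1)
    for k in range(1, n_c):
        w[k] = a * w[k - 1] + innov_sd * eps[k - 1]
    t_c = np.arange(n_c) / fs_c
    return np.interp(np.arange(n) / fs, t_c, w)


def generate_rr_sequence(params: SessionParams, duration: float,
                         seed: int) -> np.ndarray:
    """Generate an RR-interval sequence (ms) covering ``duration`` seconds.

    Each interval is ``mean_rr + sd_rr * z_i + rsa_amp_ms * sin(2π f t_i)``
    where ``z`` is a unit-variance AR(1) process and ``t_i`` the beat time;
    intervals are clipped to [300, 2000] ms. The cumulative sum of the
    returned sequence is at least ``duration * 1000``.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    rng = _derived_rng(seed, "rr")
    phi = params.ar1_phi
    rr = []
    t = 0.0  # running beat time, s
    z = rng.standard_normal() if params.sd_rr > 0 else 0.0
    while t * 1000.0 < duration * 1000.0:
        resp = params.rsa_amp_ms * np.sin(2 * np.pi * params.resp_freq * t)
        val = params.mean_rr + params.sd_rr * z + resp
        val = float(np.clip(val, RR_MIN, RR_MAX))
        rr.append(val)
        t += val / 1000.0
        z = phi * z + np.sqrt(1 - phi ** 2) * rng.standard_normal()
    return np.asarray(rr)


def synthesize_ppg(rr_ms: np.ndarray, fs: float = DEFAULT_FS,
                   pulse_width: float = 0.15, noise_sd: float = 0.0,
                   duration: float | None = None,
                   seed: int = 0) -> TimeSeries:
    """Render a pulse train from RR intervals as a PPG-like waveform.

    One Gaussian lobe (sigma = pulse_width / 2) is centred at each
    cumulative RR time; a slow 0.05 Hz baseline wander and white noise are
    added. Peak times are recoverable by the preprocessing stage to within
    ±25 ms at low noise.
    """
    rr_ms = np.asarray(rr_ms, dtype=float)
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    if rr_ms.size == 0:
        raise InvalidArgumentError("RR sequence must be non-empty")
    beat_times = np.cumsum(rr_ms) / 1000.0
    if duration is None:
        duration = beat_times[-1] + 0.5
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    sigma = pulse_width / 2.0
    half = int(round(4 * sigma * fs))
    win_t = np.arange(-half, half + 1) / fs
    template = np.exp(-0.5 * (win_t / sigma) ** 2)
    for bt in beat_times:
        if bt >= duration:
            break
        c = int(round(bt * fs))
        lo, hi = c - half, c + half + 1
        s0 = max(0, -lo)
        s1 = len(template) - max(0, hi - n)
        x[max(lo, 0):min(hi, n)] += template[s0:s1]
    rng = _derived_rng(seed, "ppg")
    # slow baseline wander well below the 0.5 Hz filter cut
    x += 0.3 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    return TimeSeries(x, fs, "ppg")


def bateman_kernel(t: np.ndarray, tau1: float = 0.75,
                   tau2: float = 2.0) -> np.ndarray:
    """Biexponential SCR impulse response, normalized to unit peak."""
    if tau1 <= 0 or tau2 <= 0 or tau1 >= tau2:
        raise InvalidArgumentError("require 0 < tau1 < tau2")
    k = np.exp(-t / tau2) - np.exp(-t / tau1)
    peak = k.max()
    if peak > 0:
        k = k / peak
    return k


def synthesize_eda(params: SessionParams, duration: float = DEFAULT_DURATION,
                   fs: float = DEFAULT_FS, seed: int = 0,
                   tau1: float = 0.75, tau2: float = 2.0):
    """Synthesize a skin-conductance trace.

    Returns ``(TimeSeries, event_times, event_amps)``. The trace is
    ``tonic_level + tonic_drift * t + sum of Bateman-shaped events +
    noise``; event onsets follow a homogeneous Poisson process at
    ``scr_rate`` per minute and peak amplitudes are log-normal around
    ``scr_amp_mean``. The returned events are the ground truth used by
    decomposition round-trip tests.
    """
    if fs <= 0 or duration <= 0:
        raise InvalidArgumentError("fs and duration must be positive")
    rng = _derived_rng(seed, "eda")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = params.tonic_level + params.tonic_drift * (t / 60.0)
    x = x + _ou_wander(n, fs, params.tonic_wander_sd, params.wander_tau, rng)

    n_events = rng.poisson(params.scr_rate * duration / 60.0)
    times = np.sort(rng.uniform(0.0, max(duration - 5.0, 0.0), n_events))
    if params.scr_amp_mean > 0 and n_events > 0:
        sig = 0.4
        amps = rng.lognormal(np.log(params.scr_amp_mean) - sig ** 2 / 2,
                             sig, n_events)
    else:
        amps = np.zeros(n_events)
    if n_events:
        impulses = np.zeros(n)
        for et, a in zip(times, amps):
            impulses[int(round(et * fs))] += a
        kt = np.arange(0, min(8 * tau2, duration), 1 / fs)
        kern = bateman_kernel(kt, tau1, tau2)
        phasic = np.convolve(impulses, kern)[:n]
        x = x + phasic
    if params.eda_noise_sd > 0:
        x = x + params.eda_noise_sd * rng.standard_normal(n)
    return TimeSeries(x, fs, "eda"), times, amps


def synthesize_skt(params: SessionParams, duration: float = DEFAULT_DURATION,
                   fs: float = DEFAULT_FS, seed: int = 0) -> TimeSeries:
    """Skin temperature: linear trend plus white noise."""
    if fs <= 0 or duration <= 0:
        raise InvalidArgumentError("fs and duration must be positive")
    rng = _derived_rng(seed, "skt")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = params.skt_mean + params.skt_drift * (t / 60.0)
    x = x + _ou_wander(n, fs, params.skt_wander_sd, params.wander_tau, rng)
    if params.skt_noise_sd > 0:
        x = x + params.skt_noise_sd * rng.standard_normal(n)
    return TimeSeries(x, fs, "skt")


def generate_subject(subject_id: str, session_params: dict, seed: int,
                     duration: float = DEFAULT_DURATION,
                     fs: float = DEFAULT_FS) -> SubjectRecording:
    """Generate all five sessions of one subject.

    ``session_params`` must map every label in :data:`SESSIONS` to a
    :class:`SessionParams`. Per-session seeds are derived from ``seed``
    and the subject/session identity.
    """
    missing = [s for s in SESSIONS if s not in session_params]
    if missing:
        raise InvalidArgumentError(f"missing session params for {missing}")
    sessions, truth = {}, {}
    for label in SESSIONS:
        p = session_params[label]
        sseed = int(_derived_rng(seed, subject_id, label).integers(0, 2 ** 31))
        rr = generate_rr_sequence(p, duration, sseed)
        ppg = synthesize_ppg(rr, fs=fs, noise_sd=p.ppg_noise_sd,
                             duration=duration, seed=sseed)
        eda, ev_t, ev_a = synthesize_eda(p, duration, fs, seed=sseed)
        skt = synthesize_skt(p, duration, fs, seed=sseed)
        sessions[label] = {"ppg": ppg, "eda": eda, "skt": skt}
        truth[label] = SessionGroundTruth(p, rr, ev_t, ev_a)
    return SubjectRecording(subject_id, sessions, truth)


def generate_cohort(n_subjects: int = 12, seed: int = 0,
                    separability: str = "medium",
                    duration: float = DEFAULT_DURATION,
                    fs: float = DEFAULT_FS) -> list:
    """Generate a cohort of subjects with mild between-subject variation.

    Each subject gets small seeded offsets to mean RR, tonic level and
    skin temperature (individual physiology); session contrasts come from
    :func:`default_session_params`.
    """
    base = default_session_params(separability)
    cohort = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        rng = _derived_rng(seed, sid, "offsets")
        d_rr = rng.normal(0, 25.0)
        d_tonic = rng.normal(0, 0.3)
        d_skt = rng.normal(0, 0.2)
        params = {
            label: replace(p,
                           mean_rr=p.mean_rr + d_rr,
                           tonic_level=max(p.tonic_level + d_tonic, 0.2),
                           skt_mean=p.skt_mean + d_skt)
            for label, p in base.items()
        }
        cohort.append(generate_subject(sid, params, seed, duration, fs))
    return cohort


# ---------------------------------------------------------------------------
# CSV interchange: one file per subject-session-channel plus a JSON sidecar.

def write_recording(rec: SubjectRecording, out_dir) -> None:
    """Write a recording as CSV files (time_s,value) with JSON sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, ch, ts in rec.channels():
        stem = f"{rec.subject_id}_{label}_{ch}"
        data = np.column_stack([ts.times, ts.samples])
        np.savetxt(out / f"{stem}.csv", data, delimiter=",",
                   header="time_s,value", comments="", fmt="%.6f")
        meta = {"subject": rec.subject_id, "session": label, "channel": ch,
                "fs_hz": ts.fs,
                "params": asdict(rec.ground_truth[label].params)}
        (out / f"{stem}.json").write_text(json.dumps(meta, indent=1))


def read_recording(in_dir, subject_id: str) -> SubjectRecording:
    """Read a recording previously written by :func:`write_recording`.

    Ground truth is not round-tripped; only params survive via sidecars.
    """
    src = Path(in_dir)
    sessions, truth = {}, {}
    for label in SESSIONS:
        chans = {}
        for ch in ("ppg", "eda", "skt"):
            stem = src / f"{subject_id}_{label}_{ch}"
            meta = json.loads((stem.with_suffix(".json")).read_text())
            arr = np.loadtxt(stem.with_suffix(".csv"), delimiter=",",
                             skiprows=1)
            chans[ch] = TimeSeries(arr[:, 1], meta["fs_hz"], ch,
                                   t0=float(arr[0, 0]))
        p = SessionParams(**meta["params"])
        sessions[label] = chans
        truth[label] = SessionGroundTruth(p, np.array([]), np.array([]),
                                          np.array([]))
    return SubjectRecording(subject_id, sessions, truth)
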
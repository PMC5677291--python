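"""The 15 heart-rate-variability features computed per epoch.

Time domain (7): HRavg, NNavg, SDNN, SDSD, RMSSD, pNN20, pNN50.
Frequency domain (3): normalized LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz)
power of the NN tachogram's autoregressive spectrum, and their ratio.
Nonlinear (5): approximate and sample entropy (m=2, r=0.2*SDNN) and the
Poincare descriptors SD1, SD2, SD1/SD2.

Conventions: sample standard deviation (n-1 denominator) throughout; the
pNNx denominator is the total number of NN intervals (a configurable
flag switches to the number of successive pairs). Features that cannot
be computed on a given epoch are returned as NaN markers; the feature
table builder imputes them from the subject-session median so the
classifier input stays rectangular.

A caveat worth stating: 6 s epochs hold only ~5-9 NN intervals, so the
0.04 Hz edge of the LF band is formally unresolvable at that length. The
spectral features are computed anyway on the short tachogram, and should
be read as short-window surrogates rather than guideline-grade LF/HF.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import cdist

from .errors import InvalidArgumentError
from .signals import NNSeries

log = logging.getLogger(__name__)

HRV_FEATURES = ["HRavg", "NNavg", "SDNN", "SDSD", "RMSSD", "pNN20", "pNN50",
                "LFnormal", "HFnormal", "LF_HF", "ApEn", "SampEn",
                "SD1", "SD2", "SD1_SD2"]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
LF_HF_CAP = 100.0  # reported ratio when HF power integrates to zero


def time_domain(nn: np.ndarray, pnn_denominator: str = "intervals") -> dict:
    """Time-domain statistics of an NN-interval sequence (ms).

    ``pnn_denominator`` selects the normalization of pNN20/pNN50:
    ``"intervals"`` divides the count of successive differences exceeding
    the threshold by the total number of NN intervals, ``"pairs"`` by the
    number of successive pairs.
    """
    nn = np.asarray(nn, dtype=float)
    if pnn_denominator not in ("intervals", "pairs"):
        raise InvalidArgumentError("pnn_denominator: 'intervals' or 'pairs'")
    if nn.size < 2:
        return {k: np.nan for k in HRV_FEATURES[:7]}
    d = np.diff(nn)
    nnavg = float(np.mean(nn))
    denom = nn.size if pnn_denominator == "intervals" else d.size
    return {
        "HRavg": 60000.0 / nnavg,
        "NNavg": nnavg,
        "SDNN": float(np.std(nn, ddof=1)),
        "SDSD": float(np.std(d, ddof=1)) if d.size >= 2 else np.nan,
        "RMSSD": float(np.sqrt(np.mean(d ** 2))),
        "pNN20": float(np.sum(np.abs(d) > 20.0) / denom),
        "pNN50": float(np.sum(np.abs(d) > 50.0) / denom),
    }


def nn_tachogram(nns: NNSeries, resample_hz: float = 4.0):
    """Uniformly resample NN intervals by cubic-spline interpolation.

    Each NN value is anchored at the time of the beat that closes it;
    the spline is evaluated on a uniform grid at ``resample_hz`` spanning
    the anchored range (no extrapolation). Returns ``(t, v)`` with v in
    ms, or None when fewer than 3 intervals are available.
    """
    if len(nns) < 3:
        return None
    t_anchor = nns.peak_times[1:]
    spline = CubicSpline(t_anchor, nns.nn)
    n = max(int(np.floor((t_anchor[-1] - t_anchor[0]) * resample_hz)) + 1, 2)
    t = t_anchor[0] + np.arange(n) / resample_hz
    t = t[t <= t_anchor[-1] + 1e-12]
    return t, spline(t)


def burg_ar(x: np.ndarray, order: int):
    """Burg's method: AR coefficients (leading 1) and driving variance.

    Reflection coefficients are chosen to minimize the summed forward and
    backward prediction error at each model order.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if order < 1 or n < 2:
        raise InvalidArgumentError("need order >= 1 and len(x) >= 2")
    a = np.array([1.0])
    ef = x.copy()
    eb = x.copy()
    e = float(np.dot(x, x)) / n
    for _ in range(order):
        efp = ef[1:]
        ebp = eb[:-1]
        den = np.dot(efp, efp) + np.dot(ebp, ebp)
        k = -2.0 * np.dot(efp, ebp) / den if den > 0 else 0.0
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
        ef, eb = efp + k * ebp, ebp + k * efp
        e *= (1.0 - k * k)
    return a, max(e, 0.0)


def ar_psd(tach, order: int = 16, n_freq: int = 512):
    """One-sided AR power spectral density of a tachogram.

    ``tach`` is the ``(t, v)`` pair from :func:`nn_tachogram`. The series
    is mean-centred first so the spectral bands see no DC leakage. The
    order is capped at ``floor(len/2) - 1`` for short epochs (logged).
    Returns ``(f, p)`` on [0, resample_hz/2], or None if the tachogram is
    too short or has zero variance handling falls out naturally (p = 0).
    """
    if tach is None:
        return None
    t, v = tach
    fs = 1.0 / np.median(np.diff(t))
    x = np.asarray(v, dtype=float) - np.mean(v)
    max_order = x.size // 2 - 1
    if max_order < 1:
        return None
    if order > max_order:
        log.debug("AR order reduced from %d to %d (len %d)",
                  order, max_order, x.size)
        order = max_order
    a, e = burg_ar(x, order)
    f = np.linspace(0.0, fs / 2.0, n_freq)
    z = np.exp(-2j * np.pi * np.outer(f, np.arange(a.size)) / fs)
    denom = np.abs(z @ a) ** 2
    denom = np.maximum(denom, 1e-300)
    p = 2.0 * e / fs / denom
    return f, p


def band_powers(psd) -> dict:
    """Normalized LF/HF band powers and their ratio from a PSD.

    Trapezoidal integration over 0.04-0.15 Hz (LF) and 0.15-0.4 Hz (HF),
    with band edges interpolated onto the PSD grid. When HF integrates to
    zero the ratio is capped at 100 rather than reported infinite.
    """
    if psd is None:
        return {"LFnormal": np.nan, "HFnormal": np.nan, "LF_HF": np.nan}
    f, p = psd
    lf = _band_integral(f, p, *LF_BAND)
    hf = _band_integral(f, p, *HF_BAND)
    tot = lf + hf
    if tot <= 0:
        return {"LFnormal": np.nan, "HFnormal": np.nan, "LF_HF": np.nan}
    ratio = lf / hf if hf > 0 else LF_HF_CAP
    return {"LFnormal": lf / tot, "HFnormal": hf / tot,
            "LF_HF": min(ratio, LF_HF_CAP)}


def _band_integral(f, p, f1, f2):
    f = np.asarray(f)
    p = np.asarray(p)
    f2 = min(f2, f[-1])
    if f1 >= f2:
        return 0.0
    inner = (f > f1) & (f < f2)
    fs_ = np.concatenate([[f1], f[inner], [f2]])
    ps_ = np.concatenate([[np.interp(f1, f, p)], p[inner],
                          [np.interp(f2, f, p)]])
    return float(np.trapezoid(ps_, fs_))


def _templates(x: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)


def approximate_entropy(x: np.ndarray, m: int = 2,
                        r: float | None = None) -> float:
    """Approximate entropy (Pincus) with self-matches included.

    ``r`` defaults to 0.2 times the sample SD of the series; Chebyshev
    distance between length-m templates. A constant series is perfectly
    regular and returns 0 by definition.
    """
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        return np.nan
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    if r <= 0:
        if np.ptp(x) == 0:
            return 0.0
        raise InvalidArgumentError("r must be positive for non-constant input")

    def phi(mm: int) -> float:
        tpl = _templates(x, mm)
        d = cdist(tpl, tpl, metric="chebyshev")
        c = np.mean(d <= r, axis=1)   # includes self-match
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2,
                   r: float | None = None) -> float:
    """Sample entropy (Richman-Moorman): -ln(A/B), self-matches excluded.

    B counts template pairs of length m within r (Chebyshev), A the same
    at length m+1, over the N-m templates common to both lengths. Returns
    0 for a constant series and NaN when no matches exist at either
    length (undefined).
    """
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        return np.nan
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    if r <= 0:
        if np.ptp(x) == 0:
            return 0.0
        raise InvalidArgumentError("r must be positive for non-constant input")
    tpl_m = _templates(x, m)[:-1]       # N - m templates at both lengths
    tpl_m1 = _templates(x, m + 1)
    dm = cdist(tpl_m, tpl_m, metric="chebyshev")
    dm1 = cdist(tpl_m1, tpl_m1, metric="chebyshev")
    iu = np.triu_indices(tpl_m.shape[0], k=1)
    b = int(np.sum(dm[iu] <= r))
    a = int(np.sum(dm1[iu] <= r))
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def poincare(nn: np.ndarray) -> dict:
    """Poincare-plot dispersion of successive NN pairs.

    SD1 measures spread perpendicular to the identity line (short-term
    variability), SD2 along it (long-term); both use the sample-SD
    convention. The ratio is NaN when SD2 is zero.
    """
    nn = np.asarray(nn, dtype=float)
    if nn.size < 3:
        return {"SD1": np.nan, "SD2": np.nan, "SD1_SD2": np.nan}
    x1, x2 = nn[:-1], nn[1:]
    sd1 = float(np.std((x2 - x1) / np.sqrt(2), ddof=1))
    sd2 = float(np.std((x2 + x1) / np.sqrt(2), ddof=1))
    return {"SD1": sd1, "SD2": sd2,
            "SD1_SD2": sd1 / sd2 if sd2 > 0 else np.nan}


def hrv_features(nns: NNSeries | None, resample_hz: float = 4.0,
                 ar_order: int = 16,
                 pnn_denominator: str = "intervals") -> dict:
    """All 15 HRV features of one epoch; NaN markers where undefined."""
    out = {k: np.nan for k in HRV_FEATURES}
    if nns is None or len(nns) < 2:
        return out
    nn = nns.nn
    out.update(time_domain(nn, pnn_denominator))
    out.update(band_powers(ar_psd(nn_tachogram(nns, resample_hz), ar_order)))
    out["ApEn"] = approximate_entropy(nn)
    out["SampEn"] = sample_entropy(nn)
    out.update(poincare(nn))
    return out
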
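"""Skin-temperature features: level, excursion, dispersion."""
from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .signals import TimeSeries

SKT_FEATURES = ["SKTavg", "SKTslope", "SKTstd"]


def skt_features(x: TimeSeries) -> dict:
    """SKTavg (mean, °C), SKTslope (max - min, °C), SKTstd (sample SD, °C).

    The "slope" is the total excursion over the window, not a rate; the
    name follows common usage for this feature set. Returns NaN markers
    for windows shorter than 2 samples.
    """
    if x.channel != "skt":
        raise InvalidArgumentError("skt_features expects an skt channel")
    s = x.samples
    if s.size < 2:
        return {k: np.nan for k in SKT_FEATURES}
    return {
        "SKTavg": float(np.mean(s)),
        "SKTslope": float(np.ptp(s)),
        "SKTstd": float(np.std(s, ddof=1)),
    }
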
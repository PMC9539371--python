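"""Time- and frequency-domain EEG features for preictal/ictal windows.

Three feature families are used downstream:

* **basic** — spike-band power (15-50 Hz), wave-band power (2.5-6 Hz) and,
  for the ictal window only, the discharge duration;
* **extended** — the basic spectral quantities plus Hjorth parameters, RMS
  amplitude, six canonical band powers (delta through high gamma), the first
  four moments of voltage and of instantaneous power, and multiscale
  permutation entropy;
* **CSP** — log-variance features of supervised spatial filters
  (:mod:`swdspare.csp`).

Scalar features are computed per channel and averaged across channels, so a
window of any channel count collapses onto one named value per feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .io import WindowPair

SPIKE_BAND = (15.0, 50.0)
WAVE_BAND = (2.5, 6.0)

#: canonical EEG band edges in Hz; the high-gamma upper edge is clipped to
#: Nyquist-1 at computation time
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "low_gamma": (30.0, 50.0),
    "high_gamma": (50.0, 100.0),
}

PE_ORDER = 4
PE_DELAY = 1
PE_SCALES = (1, 2, 3)


@dataclass
class FeatureVector:
    values: dict[str, float]
    window_tag: str  # "preictal" | "ictal"
    set_tag: str  # "basic" | "extended" | "csp"

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


def _as_2d(window: np.ndarray) -> np.ndarray:
    x = np.asarray(window, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def _psd(window: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    # segments up to 4 s give 0.25 Hz resolution, enough to separate the
    # wave band from delta; short analysis windows fall back to a single
    # segment (plain periodogram)
    x = _as_2d(window)
    nperseg = min(x.shape[1], int(4 * rate_hz))
    return sps.welch(x, fs=rate_hz, nperseg=nperseg, axis=1)


def band_power(window: np.ndarray, rate_hz: float, lo: float, hi: float) -> float:
    """Mean (across channels) integrated Welch PSD over [lo, hi] Hz, in µV²."""
    freqs, psd = _psd(window, rate_hz)
    hi = min(hi, rate_hz / 2)
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    per_channel = np.trapezoid(psd[:, mask], freqs[mask], axis=1)
    return float(per_channel.mean())


def hjorth_parameters(x: np.ndarray) -> tuple[float, float, float]:
    """(activity, mobility, complexity) of one channel.

    Mobility uses the per-sample first difference; a constant signal has
    mobility and complexity defined as 0.
    """
    x = np.asarray(x, dtype=float)
    activity = float(np.var(x))
    if activity == 0.0:
        return 0.0, 0.0, 0.0
    d1 = np.diff(x)
    v1 = float(np.var(d1))
    mobility = np.sqrt(v1 / activity)
    if v1 == 0.0:
        return activity, 0.0, 0.0
    d2 = np.diff(d1)
    mob_d = np.sqrt(float(np.var(d2)) / v1)
    return activity, float(mobility), float(mob_d / mobility)


def permutation_entropy(x: np.ndarray, order: int = PE_ORDER,
                        delay: int = PE_DELAY) -> float:
    """Shannon entropy (nats) of ordinal patterns of one channel.

    Upper bound is ln(order!); a strictly monotone signal yields a single
    pattern, hence entropy 0. Ties are broken by temporal position (stable
    argsort), the usual convention.
    """
    x = np.asarray(x, dtype=float)
    n_patterns = x.size - (order - 1) * delay
    if n_patterns < 1:
        raise ValueError("signal too short for the requested order/delay")
    idx = np.arange(n_patterns)[:, None] + np.arange(order)[None, :] * delay
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    codes = (patterns * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def multiscale_permutation_entropy(x: np.ndarray, order: int = PE_ORDER,
                                   delay: int = PE_DELAY,
                                   scales: tuple[int, ...] = PE_SCALES) -> float:
    """Mean permutation entropy over non-overlapping coarse-grained scales."""
    x = np.asarray(x, dtype=float)
    vals = []
    for s in scales:
        n = (x.size // s) * s
        coarse = x[:n].reshape(-1, s).mean(axis=1) if s > 1 else x
        vals.append(permutation_entropy(coarse, order=order, delay=delay))
    return float(np.mean(vals))


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """mean, variance, skewness, kurtosis (non-excess: Gaussian -> 3)."""
    if np.var(x) == 0.0:
        return float(np.mean(x)), 0.0, 0.0, 0.0
    return (
        float(np.mean(x)),
        float(np.var(x)),
        float(sstats.skew(x)),
        float(sstats.kurtosis(x, fisher=False)),
    )


def basic_features(wp: WindowPair) -> tuple[FeatureVector, FeatureVector]:
    """(preictal, ictal) basic vectors; duration sits on the ictal one."""
    out = []
    for tag, win in (("preictal", wp.preictal), ("ictal", wp.ictal)):
        values = {
            "spike_power": band_power(win, wp.rate_hz, *SPIKE_BAND),
            "wave_power": band_power(win, wp.rate_hz, *WAVE_BAND),
        }
        if tag == "ictal":
            values["duration_ms"] = wp.event.duration_ms
        out.append(FeatureVector(values, window_tag=tag, set_tag="basic"))
    return out[0], out[1]


def _extended_one_window(win: np.ndarray, rate_hz: float) -> dict[str, float]:
    x = _as_2d(win)
    n_ch = x.shape[0]
    per_channel: dict[str, list[float]] = {}

    freqs, psd = _psd(x, rate_hz)
    for name, (lo, hi) in BANDS.items():
        hi = min(hi, rate_hz / 2 - 1.0)
        mask = (freqs >= lo) & (freqs <= hi)
        bp = (np.trapezoid(psd[:, mask], freqs[mask], axis=1)
              if mask.sum() >= 2 else np.zeros(n_ch))
        per_channel[f"{name}_power"] = list(bp)

    for c in range(n_ch):
        xc = x[c]
        act, mob, comp = hjorth_parameters(xc)
        per_channel.setdefault("hjorth_activity", []).append(act)
        per_channel.setdefault("hjorth_mobility", []).append(mob)
        per_channel.setdefault("hjorth_complexity", []).append(comp)
        per_channel.setdefault("mean_vrms", []).append(float(np.sqrt(np.mean(xc**2))))
        vm, vv, vs, vk = _moments(xc)
        per_channel.setdefault("voltage_mean", []).append(vm)
        per_channel.setdefault("voltage_variance", []).append(vv)
        per_channel.setdefault("voltage_skewness", []).append(vs)
        per_channel.setdefault("voltage_kurtosis", []).append(vk)
        p = xc**2
        pm, pv, ps, pk = _moments(p)
        per_channel.setdefault("power_mean", []).append(pm)
        per_channel.setdefault("power_variance", []).append(pv)
        per_channel.setdefault("power_skewness", []).append(ps)
        per_channel.setdefault("power_kurtosis", []).append(pk)
        per_channel.setdefault("mspe", []).append(multiscale_permutation_entropy(xc))

    values = {k: float(np.mean(v)) for k, v in per_channel.items()}
    values["spike_power"] = band_power(x, rate_hz, *SPIKE_BAND)
    values["wave_power"] = band_power(x, rate_hz, *WAVE_BAND)
    return values


def extended_features(wp: WindowPair) -> tuple[FeatureVector, FeatureVector]:
    """(preictal, ictal) extended vectors; duration sits on the ictal one."""
    min_len = (PE_ORDER - 1) * PE_DELAY * max(PE_SCALES) + max(PE_SCALES)
    for win in (wp.preictal, wp.ictal):
        if _as_2d(win).shape[1] < max(min_len, 26):
            raise ValueError("window too short for extended features")
    out = []
    for tag, win in (("preictal", wp.preictal), ("ictal", wp.ictal)):
        values = _extended_one_window(win, wp.rate_hz)
        if tag == "ictal":
            values["duration_ms"] = wp.event.duration_ms
        out.append(FeatureVector(values, window_tag=tag, set_tag="extended"))
    return out[0], out[1]


def feature_table(pairs: list[WindowPair], set_tag: str,
                  window_tag: str) -> pd.DataFrame:
    """Event x feature matrix for the basic or extended family of one window."""
    fn = {"basic": basic_features, "extended": extended_features}[set_tag]
    rows = []
    index = []
    for wp in pairs:
        pre, ict = fn(wp)
        fv = pre if window_tag == "preictal" else ict
        rows.append(fv.values)
        index.append(wp.event.swd_id)
    return pd.DataFrame(rows, index=index, dtype=float)
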
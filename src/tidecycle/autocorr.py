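"""Correlogram analysis: the second, independent test of rhythmicity.

The autocorrelation coefficient at lag k uses the biased (divide-by-N,
single-denominator) normalization so that |r| ≤ 1, with the large-sample
white-noise 99% band ±2.576/√N drawn as a constant line across lags.
A record corroborates a spectral period when a significant positive
correlogram peak sits near that period, or near twice it (a circalunidian
doublet supporting a circatidal call).
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

from .types import ActivityRecord, Correlogram
from .spectral import DegenerateInputError

Z99 = 2.5758293035489004  # two-sided 99% normal quantile


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-bin moving average with shrunk ends (used only for peak picking)."""
    k = np.ones(3) / 3.0
    out = np.convolve(y, k, mode="same")
    out[0] = (y[0] + y[1]) / 2.0
    out[-1] = (y[-2] + y[-1]) / 2.0
    return out


def _local_extrema(y: np.ndarray):
    """Indices of strict local maxima and minima; ties break to smaller lag."""
    dy = np.diff(y)
    sign = np.sign(dy)
    # collapse flat stretches so a plateau yields its leading edge
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turn = np.diff(sign)
    maxima = np.flatnonzero(turn < 0) + 1
    minima = np.flatnonzero(turn > 0) + 1
    return maxima, minima


def correlogram(
    record: ActivityRecord,
    max_lag_h: float = 100.0,
    n_cycles: int = 4,
    smooth: bool = True,
) -> Correlogram:
    """Autocorrelation function with confidence band and cycle amplitudes.

    Peaks and troughs are located on a lightly smoothed copy of r (count
    data give jagged correlograms); reported r values are unsmoothed.
    ``period_acf`` is the lag of the first significant positive peak
    beyond lag 0; ``cycle_amplitudes`` are peak-minus-following-trough
    differences for the first ``n_cycles`` full cycles.
    """
    x = record.counts.astype(float)
    if np.ptp(x) == 0:
        raise DegenerateInputError(f"{record.animal_id}: constant series has no correlogram")
    n = x.size
    nlags = min(n - 1, int(round(max_lag_h / record.bin_width_h)))
    r = _sm_acf(x, nlags=nlags, fft=True, adjusted=False)
    lags_h = np.arange(nlags + 1) * record.bin_width_h
    ci99 = Z99 / np.sqrt(n)

    rs = _smooth3(r) if smooth else r
    maxima, minima = _local_extrema(rs)
    maxima = maxima[maxima > 0]

    sig_peaks = [int(i) for i in maxima if r[i] > ci99]
    peak_lags_h = [float(lags_h[i]) for i in sig_peaks]
    period_acf: Optional[float] = peak_lags_h[0] if peak_lags_h else None

    amplitudes = []
    for i in maxima[:n_cycles]:
        following = minima[minima > i]
        if following.size:
            amplitudes.append(float(r[i] - r[following[0]]))
    return Correlogram(
        lag_h=lags_h,
        r=r,
        ci99=ci99,
        cycle_amplitudes=amplitudes,
        significant=period_acf is not None,
        period_acf=period_acf,
        peak_lags_h=peak_lags_h,
    )


def acf_supports(
    corr: Correlogram, period_spectral_h: float, tol_fraction: float = 0.10
) -> bool:
    """Does the correlogram corroborate the spectral period?

    True iff a significant positive peak lies within ``tol_fraction`` of
    the spectral period or of twice it (the doublet may carry the
    significant autocorrelation for a circatidal call).
    """
    for lag in corr.peak_lags_h:
        for target in (period_spectral_h, 2.0 * period_spectral_h):
            if abs(lag - target) <= tol_fraction * target:
                return True
    return False
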
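"""Frequency-domain HRV indices: LF, HF, LF/HF, LFnorm, HFnorm.

The irregularly sampled interval sequence (tachogram) is resampled onto a
uniform grid by cubic-spline interpolation of (beat end-time, interval)
pairs, its power spectral density is estimated by Welch's method, and band
powers are integrated over the low-frequency band [0.04, 0.15) Hz and the
high-frequency band [0.15, 0.4] Hz.  The seam at 0.15 Hz is assigned to HF
so no power is counted twice; frequencies below 0.04 Hz contribute to no
index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .io import RRISeries

logger = logging.getLogger(__name__)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

DEFAULT_RESAMPLE_RATE_HZ = 4.0
DEFAULT_WELCH_SEGMENT = 1024  # 256 s at 4 Hz
DEFAULT_WELCH_OVERLAP = 0.5


@dataclass(frozen=True)
class Tachogram:
    """RRI value as a function of time on a uniform grid."""

    sample_times: np.ndarray  # s
    values: np.ndarray  # ms
    rate: float  # Hz


@dataclass(frozen=True)
class SpectralEstimate:
    frequencies: np.ndarray  # Hz, ascending
    psd: np.ndarray  # ms^2/Hz, one-sided
    resolution: float  # Hz


@dataclass(frozen=True)
class FrequencyDomainIndices:
    lf: float  # ms^2
    hf: float  # ms^2
    lf_hf: float  # ratio; nan when hf == 0
    lfnorm: float  # %
    hfnorm: float  # %


def resample_tachogram(
    series: RRISeries, rate: float = DEFAULT_RESAMPLE_RATE_HZ
) -> Tachogram:
    """Cubic-spline resampling of the tachogram onto a uniform grid.

    The grid starts at the first beat end-time and covers the recording at
    ``rate`` Hz.  The mean is left in place (spectral estimation removes it).
    """
    if len(series) < 4:
        raise ValueError("too short to interpolate: need at least 4 beats")
    t = series.end_times_ms / 1000.0
    spline = CubicSpline(t, series.intervals)
    n = int(math.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    return Tachogram(sample_times=grid, values=spline(grid), rate=rate)


def power_spectrum(
    tach: Tachogram,
    segment_samples: int = DEFAULT_WELCH_SEGMENT,
    overlap: float = DEFAULT_WELCH_OVERLAP,
) -> SpectralEstimate:
    """Welch PSD of the mean-removed tachogram (Hann window, 50% overlap).

    Falls back to a single full-length periodogram, with a logged warning,
    when the record is shorter than one Welch segment.
    """
    x = tach.values - np.mean(tach.values)
    if x.size >= segment_samples:
        freqs, psd = signal.welch(
            x,
            fs=tach.rate,
            window="hann",
            nperseg=segment_samples,
            noverlap=int(segment_samples * overlap),
            detrend=False,
        )
    else:
        logger.warning(
            "tachogram of %d samples is shorter than one %d-sample Welch "
            "segment; using a single periodogram",
            x.size,
            segment_samples,
        )
        freqs, psd = signal.periodogram(x, fs=tach.rate, window="hann", detrend=False)
    return SpectralEstimate(
        frequencies=freqs, psd=psd, resolution=float(freqs[1] - freqs[0])
    )


def band_power(spec: SpectralEstimate, lo: float, hi: float, include_hi: bool) -> float:
    """Trapezoidal integral of the PSD over [lo, hi) or [lo, hi]."""
    f, p = spec.frequencies, spec.psd
    mask = (f >= lo) & ((f <= hi) if include_hi else (f < hi))
    if np.count_nonzero(mask) < 2:
        return 0.0
    return float(np.trapezoid(p[mask], f[mask]))


def compute_frequency_domain(
    series: RRISeries,
    rate: float = DEFAULT_RESAMPLE_RATE_HZ,
    segment_samples: int = DEFAULT_WELCH_SEGMENT,
    overlap: float = DEFAULT_WELCH_OVERLAP,
) -> FrequencyDomainIndices:
    """LF/HF band powers and the derived ratios for one recording.

    LFnorm and HFnorm sum to exactly 100 by construction.  When HF power is
    zero, LF/HF is reported as NaN and a warning is logged.
    """
    spec = power_spectrum(resample_tachogram(series, rate), segment_samples, overlap)
    lf = band_power(spec, *LF_BAND, include_hi=False)
    hf = band_power(spec, *HF_BAND, include_hi=True)
    if hf > 0:
        lf_hf = lf / hf
    else:
        logger.warning("zero HF power; LF/HF undefined")
        lf_hf = math.nan
    total = lf + hf
    if total > 0:
        lfnorm = 100.0 * lf / total
        hfnorm = 100.0 - lfnorm
    else:
        lfnorm = hfnorm = math.nan
    return FrequencyDomainIndices(lf=lf, hf=hf, lf_hf=lf_hf, lfnorm=lfnorm, hfnorm=hfnorm)
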
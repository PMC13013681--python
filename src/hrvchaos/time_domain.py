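"""Time-domain HRV indices: SDNN, SDSD, RMSSD, pNN50.

SDNN and SDSD are reported with sample (n-1) normalisation.  pNN50 divides
the count of adjacent pairs differing by more than 50 ms by the total number
of NN intervals (not the pair count) — this follows the index table of the
study being replicated and differs from the Task-Force convention by a
factor of (n-1)/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RRISeries

#: Threshold (ms) for the pNN50 successive-difference count.
PNN_THRESHOLD_MS = 50.0


@dataclass(frozen=True)
class TimeDomainIndices:
    sdnn: float
    sdsd: float
    rmssd: float
    pnn50: float


def compute_time_domain(series: RRISeries | np.ndarray) -> TimeDomainIndices:
    """Compute the four time-domain indices of a windowed recording.

    Requires at least 3 intervals so that successive differences have a
    dispersion.  All outputs are in ms except pNN50 (a ratio in [0, 1]).
    """
    x = series.intervals if isinstance(series, RRISeries) else np.asarray(series, float)
    n = x.size
    if n < 3:
        raise ValueError("series too short: need at least 3 intervals")
    d = np.diff(x)
    return TimeDomainIndices(
        sdnn=float(np.std(x, ddof=1)),
        sdsd=float(np.std(d, ddof=1)),
        rmssd=float(np.sqrt(np.mean(d**2))),
        pnn50=float(np.count_nonzero(np.abs(d) > PNN_THRESHOLD_MS)) / n,
    )


def sdsd_population(series: RRISeries | np.ndarray) -> float:
    """Population-normalised SDSD; satisfies SD1 = sdsd_population/sqrt(2)
    and rmssd**2 = sdsd_population**2 + mean(diff)**2."""
    x = series.intervals if isinstance(series, RRISeries) else np.asarray(series, float)
    if x.size < 2:
        raise ValueError("series too short")
    return float(np.std(np.diff(x), ddof=0))
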
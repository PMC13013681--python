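"""Reading, validating, windowing and writing R-R interval recordings.

An RRI recording is an ordered sequence of beat-to-beat intervals in
milliseconds.  Two plain-text layouts are supported: one numeric value per
line, or CSV with an ``rri_ms`` column (an optional ``t_ms`` column of beat
end-times is written alongside).  Cohorts are described by a manifest CSV
with columns ``participant_id, condition, set_index, path``.

Quality control follows the rule used for chest-strap recordings: a
recording is discarded whole when 1% or more of its intervals fall outside
the physiologically plausible 200-2000 ms range; individual beats are never
edited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Condition labels used by the study replica (free labels are also accepted).
CONDITIONS = ("rest1", "rest2", "standing", "cognitive1", "cognitive2")


class RRIParseError(ValueError):
    """Raised when an RRI file cannot be parsed."""


@dataclass
class RRISeries:
    """An ordered sequence of beat-to-beat intervals in milliseconds.

    Parameters
    ----------
    intervals
        Positive, finite interval durations in ms, in acquisition order.
    participant_id, condition, set_index, source
        Cohort metadata; ``source`` is a file path or ``"synthetic"``.
    """

    intervals: np.ndarray
    participant_id: str = "unknown"
    condition: str = "rest1"
    set_index: int = 1
    source: str = "synthetic"

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if iv.ndim != 1 or iv.size < 1:
            raise ValueError("no intervals")
        if not np.all(np.isfinite(iv)):
            raise ValueError("intervals must be finite")
        if np.any(iv <= 0):
            raise ValueError("intervals must be positive")
        self.intervals = iv
        if self.set_index < 1:
            raise ValueError("set_index must be >= 1")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def end_times_ms(self) -> np.ndarray:
        """Cumulative beat end-times in ms (strictly increasing)."""
        return np.cumsum(self.intervals)

    @property
    def duration_s(self) -> float:
        """Total recorded duration in seconds."""
        return float(self.intervals.sum()) / 1000.0


@dataclass(frozen=True)
class QualityReport:
    """Outcome of the out-of-range beat count for one recording."""

    n_total: int
    n_out_of_range: int
    fraction_out_of_range: float
    valid: bool
    range_lo: float
    range_hi: float


def read_rri(path: str | Path, format: str | None = None, **meta) -> RRISeries:
    """Read one RRI recording from ``path``.

    ``format`` is ``"plain"`` (one ms value per line) or ``"csv"`` (header
    with an ``rri_ms`` column); when omitted it is inferred from the file
    suffix.  Blank lines in plain files are skipped.  Extra keyword
    arguments fill the series metadata.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "plain"
    if format not in ("plain", "csv"):
        raise ValueError(f"unknown format {format!r}")

    if format == "csv":
        df = pd.read_csv(path)
        if "rri_ms" not in df.columns:
            raise RRIParseError(f"{path}: missing required column 'rri_ms'")
        values = df["rri_ms"].to_numpy(dtype=float)
        if values.size == 0:
            raise RRIParseError(f"{path}: no intervals")
    else:
        values = []
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                token = line.strip()
                if not token:
                    continue
                try:
                    values.append(float(token))
                except ValueError:
                    raise RRIParseError(
                        f"{path}: non-numeric value {token!r} at line {lineno}"
                    ) from None
        if not values:
            raise RRIParseError(f"{path}: no intervals")
        values = np.asarray(values, dtype=float)

    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise RRIParseError(f"{path}: intervals must be positive and finite")
    meta.setdefault("source", str(path))
    return RRISeries(values, **meta)


def write_rri(series: RRISeries, path: str | Path, format: str | None = None) -> None:
    """Write a recording so that :func:`read_rri` round-trips it exactly.

    Plain format emits one full-precision value per line; CSV emits
    ``rri_ms`` plus the cumulative ``t_ms`` end-times.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "plain"
    if format == "csv":
        pd.DataFrame(
            {"rri_ms": series.intervals, "t_ms": series.end_times_ms}
        ).to_csv(path, index=False, float_format="%.12g")
    elif format == "plain":
        with open(path, "w", encoding="utf-8") as fh:
            for v in series.intervals:
                fh.write(f"{v:.12g}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def quality_check(
    series: RRISeries,
    lo: float = 200.0,
    hi: float = 2000.0,
    max_fraction: float = 0.01,
) -> QualityReport:
    """Count beats outside the plausible range ``[lo, hi]`` ms.

    The recording is ``valid`` iff the out-of-range fraction is strictly
    below ``max_fraction`` (a fraction of exactly 1% already fails, matching
    the "1% or more" exclusion rule).  Bounds are inclusive: a beat equal to
    ``lo`` or ``hi`` is in range.  The series is never modified.
    """
    iv = series.intervals
    n_total = iv.size
    n_out = int(np.count_nonzero((iv < lo) | (iv > hi)))
    frac = n_out / n_total
    return QualityReport(
        n_total=n_total,
        n_out_of_range=n_out,
        fraction_out_of_range=frac,
        valid=frac < max_fraction,
        range_lo=lo,
        range_hi=hi,
    )


def extract_window(series: RRISeries, duration: float = 420.0) -> RRISeries:
    """Keep the maximal prefix of beats fitting in ``duration`` seconds.

    A beat belongs to the window iff its cumulative end-time is at or below
    ``duration`` (no partial beats).  If the recording is shorter than the
    requested window the whole series is returned and a warning is logged.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    limit_ms = duration * 1000.0
    end = series.end_times_ms
    count = int(np.searchsorted(end, limit_ms, side="right"))
    if count == len(series):
        if end[-1] < limit_ms:
            logger.warning(
                "recording %s/%s/set%d is %.1f s, shorter than the %.0f s window",
                series.participant_id,
                series.condition,
                series.set_index,
                series.duration_s,
                duration,
            )
        return replace(series, intervals=series.intervals.copy())
    if count == 0:
        raise ValueError("first interval exceeds the requested window")
    return replace(series, intervals=series.intervals[:count].copy())


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV and validate triple uniqueness."""
    df = pd.read_csv(path)
    required = ["participant_id", "condition", "set_index", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RRIParseError(f"{path}: manifest missing columns {missing}")
    dup = df.duplicated(subset=["participant_id", "condition", "set_index"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (participant_id, condition, set_index) triples"
        )
    return df[required].copy()


def load_cohort(manifest: pd.DataFrame, base_dir: str | Path = ".") -> list[RRISeries]:
    """Materialise every manifest row as an :class:`RRISeries`."""
    base = Path(base_dir)
    out = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        out.append(
            read_rri(
                p,
                participant_id=str(row.participant_id),
                condition=str(row.condition),
                set_index=int(row.set_index),
            )
        )
    return out
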
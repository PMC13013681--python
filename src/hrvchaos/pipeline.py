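"""End-to-end study replica: QC -> 420-s window -> 15 indices ->
set-averaging -> paired comparisons -> chaos-indicator-ratio report.

Every recording passes the 200-2000 ms / 1% quality gate whole (invalid
recordings are dropped, never edited), is trimmed to the leading 420 s,
and yields a 15-slot index vector; indices that fail on a given recording
are carried as NaN and the participant is dropped pairwise for that index
only.  Per participant and condition the five sets are averaged before any
testing.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chaos, frequency_domain, io, stats, time_domain

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"  # fixed output precision for reproducible diffs


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, mirroring the module defaults."""

    window_s: float = 420.0
    quality_lo_ms: float = 200.0
    quality_hi_ms: float = 2000.0
    quality_max_fraction: float = 0.01
    resample_rate_hz: float = 4.0
    welch_segment_samples: int = 1024
    welch_overlap: float = 0.5
    apen_m: int = 2
    apen_r_factor: float = 0.2
    cd_cells: int = 20
    icd_cells: int = 10
    icd_subcells: int = 4
    partition_sigma_mult: float = 2.0
    higuchi_kmax: int = 10
    out_of_range_policy: str = "drop"
    alpha: float = 0.01
    holm_family: str = "per_comparison"
    cir_bin_width: float = 0.05

    def chaos_config(self) -> chaos.ChaosConfig:
        return chaos.ChaosConfig(
            entropy=chaos.EntropyParams(m=self.apen_m, r_factor=self.apen_r_factor),
            cd_cells=self.cd_cells,
            icd_cells=self.icd_cells,
            icd_subcells=self.icd_subcells,
            partition_sigma_mult=self.partition_sigma_mult,
            higuchi_kmax=self.higuchi_kmax,
            out_of_range_policy=self.out_of_range_policy,
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def compute_index_vector(
    series: io.RRISeries, config: AnalysisConfig = AnalysisConfig()
) -> dict:
    """The 15 named index values of one windowed recording.

    Failed indices are NaN; the companion ``flags`` dict names the cause.
    """
    values: dict[str, float] = dict.fromkeys(stats.INDEX_NAMES, math.nan)
    flags: dict[str, str] = {}

    try:
        td = time_domain.compute_time_domain(series)
        values.update(sdnn=td.sdnn, sdsd=td.sdsd, rmssd=td.rmssd, pnn50=td.pnn50)
    except ValueError as exc:
        for name in ("sdnn", "sdsd", "rmssd", "pnn50"):
            flags[name] = str(exc)

    try:
        fd = frequency_domain.compute_frequency_domain(
            series,
            rate=config.resample_rate_hz,
            segment_samples=config.welch_segment_samples,
            overlap=config.welch_overlap,
        )
        values.update(
            lf=fd.lf, hf=fd.hf, lf_hf=fd.lf_hf, lfnorm=fd.lfnorm, hfnorm=fd.hfnorm
        )
        if math.isnan(fd.lf_hf):
            flags["lf_hf"] = "zero HF power"
    except ValueError as exc:
        for name in ("lf", "hf", "lf_hf", "lfnorm", "hfnorm"):
            flags[name] = str(exc)

    ci = chaos.compute_chaos_indices(series, config.chaos_config())
    values.update(
        apen=ci.apen,
        sampen=ci.sampen,
        fractal_dimension=ci.fractal_dimension,
        sd1_sd2=ci.sd1_sd2,
        cd=ci.cd,
        icd=ci.icd,
    )
    flags.update(ci.flags)
    return {"values": values, "flags": flags}


def build_index_table(
    recordings: list[io.RRISeries], config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Quality-gate, window and index every recording.

    Returns one row per valid recording with metadata plus the 15 index
    columns; invalid recordings are dropped whole with a logged reason.
    """
    rows = []
    n_dropped = 0
    for rec in recordings:
        report = io.quality_check(
            rec,
            lo=config.quality_lo_ms,
            hi=config.quality_hi_ms,
            max_fraction=config.quality_max_fraction,
        )
        if not report.valid:
            n_dropped += 1
            logger.warning(
                "dropping %s/%s/set%d: %.2f%% of beats out of range",
                rec.participant_id,
                rec.condition,
                rec.set_index,
                100 * report.fraction_out_of_range,
            )
            continue
        windowed = io.extract_window(rec, config.window_s)
        result = compute_index_vector(windowed, config)
        row = {
            "participant_id": rec.participant_id,
            "condition": rec.condition,
            "set_index": rec.set_index,
            "n_beats": len(windowed),
        }
        row.update(result["values"])
        row["n_flags"] = len(result["flags"])
        rows.append(row)
    if n_dropped:
        logger.info("quality gate dropped %d recordings", n_dropped)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# chaos indicator ratio report


#: (task condition, paired rest condition, task type) for the CIR report.
CIR_PAIRINGS = [
    ("standing", "rest1", "physical"),
    ("cognitive1", "rest1", "mental"),
    ("cognitive2", "rest2", "mental"),
]


@dataclass
class CIRReport:
    """Per-participant chaos-indicator ratios and their separation summary.

    ``table`` has one gamma per (participant, chaos index, task);
    ``summary`` reports the fraction of physical-task gammas below 1 and
    mental-task gammas above 1, with gammas exactly at 1 counted half.
    """

    table: pd.DataFrame
    histograms: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def cir_report(
    index_table: pd.DataFrame,
    pairings=CIR_PAIRINGS,
    bin_width: float = 0.05,
) -> CIRReport:
    """Chaos-indicator ratios from set-averaged index values."""
    means = (
        index_table.groupby(["participant_id", "condition"])[stats.CHAOS_INDEX_NAMES]
        .mean()
        .reset_index()
    )
    rows = []
    for task_cond, rest_cond, task_type in pairings:
        rest = means[means["condition"] == rest_cond].set_index("participant_id")
        task = means[means["condition"] == task_cond].set_index("participant_id")
        common = rest.index.intersection(task.index)
        missing = rest.index.union(task.index).difference(common)
        if len(missing):
            logger.info("CIR %s: skipped %d unpaired participants", task_cond, len(missing))
        for pid in common:
            for name in stats.CHAOS_INDEX_NAMES:
                cci_rest = float(rest.at[pid, name])
                cci_task = float(task.at[pid, name])
                if math.isnan(cci_rest) or math.isnan(cci_task) or cci_rest == 0:
                    logger.info("CIR %s/%s/%s skipped (flagged or zero rest value)",
                                pid, name, task_cond)
                    continue
                rows.append(
                    {
                        "participant_id": pid,
                        "index": name,
                        "task": task_cond,
                        "task_type": task_type,
                        "gamma": chaos.chaos_indicator_ratio(cci_rest, cci_task),
                    }
                )
    table = pd.DataFrame(rows)
    histograms = {}
    summary = {}
    for task_type in ("physical", "mental"):
        g = table.loc[table["task_type"] == task_type, "gamma"].to_numpy(float)
        if g.size == 0:
            continue
        lo = math.floor(g.min() / bin_width) * bin_width
        hi = math.ceil(g.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(g, bins=edges)
        histograms[task_type] = {"counts": counts, "edges": edges}
        below = float(np.mean(g < 1) + 0.5 * np.mean(g == 1))
        summary[f"{task_type}_fraction_below_1"] = below
        summary[f"{task_type}_fraction_above_1"] = 1.0 - below
    return CIRReport(table=table, histograms=histograms, summary=summary)


# --------------------------------------------------------------------------
# orchestration


def run_pipeline(
    recordings: list[io.RRISeries],
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, CIRReport]:
    """Full study replica on a list of recordings.

    Returns (per-recording index table, comparison table, CIR report).
    """
    index_table = build_index_table(recordings, config)
    if index_table.empty:
        raise ValueError("no valid recordings survived the quality gate")
    comparison = stats.compare_conditions(
        index_table, alpha=config.alpha, holm_family=config.holm_family
    )
    cir = cir_report(index_table, bin_width=config.cir_bin_width)
    return index_table, comparison, cir


def write_outputs(
    out_dir,
    index_table: pd.DataFrame,
    comparison: pd.DataFrame,
    cir: CIRReport,
    config: AnalysisConfig,
) -> None:
    """Write tidy CSVs plus JSON mirrors with fixed float formatting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index_table.to_csv(out / "indices.csv", index=False, float_format=FLOAT_FORMAT)
    comparison.to_csv(out / "comparisons.csv", index=False, float_format=FLOAT_FORMAT)
    cir.table.to_csv(out / "cir.csv", index=False, float_format=FLOAT_FORMAT)
    payload = {
        "config": asdict(config),
        "cir_summary": cir.summary,
        "comparisons": json.loads(comparison.to_json(orient="records")),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=True)
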
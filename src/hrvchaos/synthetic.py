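"""Synthetic RRI cohorts via integral pulse frequency modulation (IPFM).

The IPFM model emits a beat whenever the integral of the instantaneous
rate (1 + m(t)) / T0 reaches the next integer.  The modulation

    m(t) = a_lf sin(2 pi f_lf t + phi1) + a_hf sin(2 pi f_hf t + phi2)
           + chaos_gain * z(t) + noise(t)

combines a low-frequency (Mayer-wave-like, default 0.10 Hz) and a
high-frequency (respiratory-like, default 0.25 Hz) oscillation, a
deterministic chaotic component z(t) — a zero-centred, unit-scaled
logistic-map sequence held constant over each beat — and beat-held
Gaussian noise clipped at 4 standard deviations.  The amplitude budget
a_lf + a_hf + chaos_gain + 4 noise_sd < 1 keeps the rate positive, so all
intervals are positive by construction.

Condition presets rescale a participant's baseline ("rest") bundle:
standing raises the LF amplitude, lowers the HF amplitude and the chaotic
gain, and shortens the base interval (orthostatic sympathetic shift);
the cognitive preset raises only the chaotic gain (mental load expressed
as stronger deterministic irregularity).  The preset magnitudes are
calibration constants chosen so the chaos-index contrast reaches a paired
effect size near d = 1 in a 27-participant cohort; they are conveniences
of the generator, not physiological claims.

The module also provides logistic-map fixtures and a numeric Lyapunov
exponent used as the independent oracle for the improved chaos degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import RRISeries

TWO_PI = 2.0 * math.pi

_COHORT_CONDITIONS = ("rest1", "rest2", "standing", "cognitive1", "cognitive2")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameter bundle of one IPFM recording.

    Amplitudes are dimensionless fractions of the mean rate; ``t0`` is the
    baseline interval in ms; ``duration`` in seconds is generated long
    enough (default 480 s) that a 420-s analysis window always fits.
    """

    t0: float = 850.0
    a_lf: float = 0.04
    a_hf: float = 0.01
    f_lf: float = 0.10
    f_hf: float = 0.25
    chaos_gain: float = 0.004
    noise_sd: float = 0.0005
    duration: float = 480.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t0 <= 0 or self.duration <= 0:
            raise ValueError("t0 and duration must be positive")
        if min(self.a_lf, self.a_hf, self.chaos_gain, self.noise_sd) < 0:
            raise ValueError("amplitudes must be nonnegative")
        if not (0.04 <= self.f_lf < 0.15):
            raise ValueError("f_lf must lie in the LF band [0.04, 0.15) Hz")
        if not (0.15 <= self.f_hf <= 0.4):
            raise ValueError("f_hf must lie in the HF band [0.15, 0.4] Hz")
        if self.modulation_budget >= 1.0:
            raise ValueError(
                "a_lf + a_hf + chaos_gain + 4*noise_sd must be < 1 "
                "(modulation would drive the rate nonpositive)"
            )

    @property
    def modulation_budget(self) -> float:
        return self.a_lf + self.a_hf + self.chaos_gain + 4.0 * self.noise_sd


@dataclass(frozen=True)
class PresetScales:
    """Multiplicative deltas a condition applies to the rest bundle."""

    a_lf: float = 1.0
    a_hf: float = 1.0
    chaos_gain: float = 1.0
    t0: float = 1.0


#: Condition presets (calibration constants; see module docstring).
PRESETS: dict[str, PresetScales] = {
    "rest": PresetScales(),
    "standing": PresetScales(a_lf=1.8, a_hf=0.35, chaos_gain=0.25, t0=0.85),
    "cognitive": PresetScales(chaos_gain=5.0),
}

_CONDITION_TO_PRESET = {
    "rest1": "rest",
    "rest2": "rest",
    "standing": "standing",
    "cognitive1": "cognitive",
    "cognitive2": "cognitive",
}


def apply_preset(base: SyntheticConfig, condition: str) -> SyntheticConfig:
    """Derive a condition's config from a participant's rest bundle."""
    scales = PRESETS[_CONDITION_TO_PRESET.get(condition, condition)]
    return replace(
        base,
        a_lf=base.a_lf * scales.a_lf,
        a_hf=base.a_hf * scales.a_hf,
        chaos_gain=base.chaos_gain * scales.chaos_gain,
        t0=base.t0 * scales.t0,
    )


# --------------------------------------------------------------------------
# logistic-map fixtures and Lyapunov oracle


def logistic_map_series(
    r: float, x0: float, length: int, burn_in: int = 1000
) -> np.ndarray:
    """Orbit of x_{n+1} = r x_n (1 - x_n) after discarding ``burn_in`` steps."""
    if not (0 < r <= 4):
        raise ValueError("r must lie in (0, 4]")
    if not (0 < x0 < 1):
        raise ValueError("x0 must lie in (0, 1)")
    if length < 1:
        raise ValueError("length must be >= 1")
    x = x0
    for _ in range(burn_in):
        x = r * x * (1.0 - x)
    out = np.empty(length)
    for i in range(length):
        out[i] = x
        x = r * x * (1.0 - x)
    return out


def numeric_lyapunov(
    r: float, length: int = 100_000, seed: int = 0, burn_in: int = 1000
) -> float:
    """Lyapunov exponent of the logistic map: mean ln|r(1 - 2x_n)| (nats).

    Orbit points at exactly x = 0.5 (derivative zero) are skipped.  At
    r = 4 the analytic value is ln 2.
    """
    rng = np.random.default_rng(seed)
    x0 = float(rng.uniform(0.05, 0.95))
    orbit = logistic_map_series(r, x0, length, burn_in)
    terms = np.abs(r * (1.0 - 2.0 * orbit))
    ok = terms > 0
    return float(np.mean(np.log(terms[ok])))


# --------------------------------------------------------------------------
# IPFM generation


def ipfm_generate(config: SyntheticConfig) -> RRISeries:
    """Generate one RRI recording from an IPFM model.

    Beat times solve the threshold crossings of the integrated rate; the
    sinusoidal part is integrated in closed form and each crossing is
    root-found to high precision, so the only discretisation is the
    beat-holding of the chaotic and noise terms.  Phases, the logistic-map
    start and the noise stream all come from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    phi1 = float(rng.uniform(0, TWO_PI))
    phi2 = float(rng.uniform(0, TWO_PI))
    t0_s = config.t0 / 1000.0
    w1 = TWO_PI * config.f_lf
    w2 = TWO_PI * config.f_hf
    k1 = config.a_lf / w1
    k2 = config.a_hf / w2

    # chaotic modulation: r=4 logistic map, zero-centred to [-1, 1]
    x = float(rng.uniform(0.05, 0.95))
    for _ in range(1000):
        x = 4.0 * x * (1.0 - x)

    budget = config.modulation_budget
    cos, sin = math.cos, math.sin
    intervals = []
    t = 0.0
    while t < config.duration:
        z = 2.0 * x - 1.0
        noise = 0.0
        if config.noise_sd > 0:
            noise = float(
                np.clip(rng.normal(0.0, config.noise_sd),
                        -4 * config.noise_sd, 4 * config.noise_sd)
            )
        c = 1.0 + config.chaos_gain * z + noise
        s_t = -k1 * cos(w1 * t + phi1) - k2 * cos(w2 * t + phi2)

        def crossing(delta: float) -> float:
            s_end = -k1 * cos(w1 * (t + delta) + phi1) - k2 * cos(
                w2 * (t + delta) + phi2
            )
            return c * delta + s_end - s_t - t0_s

        if budget == 0.0:
            delta = t0_s
        else:
            lo = t0_s / (1.0 + budget)
            hi = t0_s / (1.0 - budget)
            if crossing(lo) >= 0.0:
                delta = lo
            elif crossing(hi) <= 0.0:
                delta = hi
            else:
                delta = brentq(crossing, lo, hi, xtol=1e-6 * t0_s)
        intervals.append(delta * 1000.0)
        t += delta
        x = 4.0 * x * (1.0 - x)

    return RRISeries(
        np.asarray(intervals),
        participant_id="synthetic",
        condition="rest1",
        set_index=1,
        source="synthetic",
    )


# --------------------------------------------------------------------------
# cohort generation


def draw_base_config(rng: np.random.Generator, duration: float = 480.0) -> SyntheticConfig:
    """Draw one participant's rest bundle with inter-individual spread."""
    jitter = lambda: 1.0 + rng.uniform(-0.25, 0.25)  # noqa: E731
    return SyntheticConfig(
        t0=float(rng.uniform(700.0, 1000.0)),
        a_lf=0.04 * jitter(),
        a_hf=0.01 * jitter(),
        chaos_gain=0.004 * jitter(),
        noise_sd=0.0005 * jitter(),
        duration=duration,
        seed=0,
    )


def generate_cohort(
    n_participants: int = 27,
    n_sets: int = 5,
    seed: int = 0,
    conditions=_COHORT_CONDITIONS,
    duration: float = 480.0,
) -> tuple[pd.DataFrame, dict[tuple[str, str, int], RRISeries]]:
    """Generate a full participants x conditions x sets cohort.

    Each participant gets a seeded rest bundle; every (condition, set)
    recording reuses that bundle through its condition preset with fresh
    phases, noise and chaotic start per set.  Fully reproducible from the
    master seed.  Returns a manifest frame (paths filled with canonical
    file names; use :func:`write_cohort` to materialise them) and a dict
    keyed by (participant_id, condition, set_index).
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    manifest_rows = []
    series: dict[tuple[str, str, int], RRISeries] = {}
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        base = draw_base_config(np.random.default_rng([seed, p]), duration)
        for s in range(1, n_sets + 1):
            for ci, cond in enumerate(conditions):
                cfg = apply_preset(base, cond)
                # per-recording reseed: mix master seed, participant, set, condition
                rec_rng = np.random.default_rng([seed, p, s, ci])
                cfg = replace(cfg, seed=int(rec_rng.integers(0, 2**31 - 1)))
                rec = ipfm_generate(cfg)
                rec = replace(
                    rec, participant_id=pid, condition=cond, set_index=s
                )
                series[(pid, cond, s)] = rec
                manifest_rows.append(
                    {
                        "participant_id": pid,
                        "condition": cond,
                        "set_index": s,
                        "path": f"{pid}_{cond}_set{s}.txt",
                    }
                )
    return pd.DataFrame(manifest_rows), series


def write_cohort(manifest: pd.DataFrame, series: dict, out_dir) -> None:
    """Write every cohort recording as plain text plus the manifest CSV."""
    from pathlib import Path

    from .io import write_rri

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for row in manifest.itertuples(index=False):
        rec = series[(row.participant_id, row.condition, row.set_index)]
        write_rri(rec, out / row.path, format="plain")
    manifest.to_csv(out / "manifest.csv", index=False)
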
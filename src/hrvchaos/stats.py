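"""Paired condition comparisons: Wilcoxon signed-rank, Holm-Bonferroni,
effect sizes and post-hoc power, reproducing the structure of a
15-index x 5-comparison HRV comparison table.

The signed-rank test drops zero differences (Wilcoxon's original
convention), assigns average ranks to tied absolute differences, and uses
the exact null distribution of W+ (dynamic programming over rank subsets)
when n <= 12 with no ties, otherwise a normal approximation with tie and
continuity corrections.  The standardised Z is reported with the sign of
the mean paired difference.

Power and sensitivity for the Wilcoxon test follow the standard
noncentral-t approximation: a matched-pairs t power computation at the
effective sample size n' = n * ARE with ARE = 3/pi for a normal parent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: Asymptotic relative efficiency of the Wilcoxon signed-rank test vs the
#: paired t-test under a normal parent.
NORMAL_ARE = 3.0 / math.pi

#: The 15 index names, in the reporting order of the comparison table.
INDEX_NAMES = [
    "sdnn", "sdsd", "rmssd", "pnn50",
    "lf", "hf", "lf_hf", "lfnorm", "hfnorm",
    "apen", "sampen", "fractal_dimension", "sd1_sd2", "cd", "icd",
]

CHAOS_INDEX_NAMES = ["apen", "sampen", "fractal_dimension", "sd1_sd2", "cd", "icd"]

#: The five labelled paired comparisons (name, reference condition, task).
COMPARISONS = [
    ("rest1_vs_standing", "rest1", "standing"),
    ("rest1_vs_cognitive1", "rest1", "cognitive1"),
    ("rest2_vs_cognitive2", "rest2", "cognitive2"),
    ("rest1_vs_rest2", "rest1", "rest2"),
    ("cognitive1_vs_cognitive2", "cognitive1", "cognitive2"),
]


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    z_stat: float
    w_plus: float
    n: int
    exact: bool


def _signrank_pmf_counts(ranks: np.ndarray) -> np.ndarray:
    """Number of sign assignments achieving each value of W+.

    Dynamic programme over the (integer) ranks: counts[s] = number of
    subsets of ranks summing to s.  Total mass is 2**n.
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for k in ranks.astype(int):
        counts[k:] = counts[k:] + counts[:-k]
    return counts


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples a, b.

    Differences are b - a.  Zero differences are dropped; if none remain a
    ValueError("no nonzero differences") is raised.  Exact two-sided
    p-value (doubled smaller tail, capped at 1) when n <= 12 and all
    absolute differences are distinct, otherwise the tie-corrected normal
    approximation with a 0.5 continuity correction.  Z carries the sign of
    the mean difference.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("no nonzero differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n

    # normal approximation (always computed: it supplies Z)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sigma = math.sqrt(sigma2)
    dev = w_plus - mu
    if sigma > 0:
        z_abs = max(abs(dev) - 0.5, 0.0) / sigma
    else:
        z_abs = 0.0

    if n <= 12 and not has_ties:
        counts = _signrank_pmf_counts(ranks)
        total = 2.0**n
        w = int(round(w_plus))
        lower = counts[: w + 1].sum() / total
        upper = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        exact = True
    else:
        p = 2.0 * stats.norm.sf(z_abs)
        p = min(1.0, max(p, np.finfo(float).tiny))
        exact = False

    sign = 1.0 if float(np.mean(b - a)) >= 0 else -1.0
    return WilcoxonResult(p_value=p, z_stat=sign * z_abs, w_plus=w_plus, n=n, exact=exact)


def holm_bonferroni(p_values, alpha: float = 0.01) -> np.ndarray:
    """Step-down Holm significance flags at familywise level alpha.

    Sorted ascending, p_(k) is compared with alpha/(m-k+1); rejection stops
    at the first failure.  NaN p-values are never significant and do not
    count toward the family size.
    """
    p = np.asarray(p_values, float)
    flags = np.zeros(p.shape, dtype=bool)
    valid = ~np.isnan(p)
    m = int(valid.sum())
    if m == 0:
        return flags
    order = np.argsort(np.where(valid, p, np.inf))
    for k, idx in enumerate(order[:m]):
        if p[idx] <= alpha / (m - k):
            flags[idx] = True
        else:
            break
    return flags


def effect_sizes(z_stat: float, n: int, differences) -> tuple[float, float]:
    """Rank-based r = Z/sqrt(N) and Cohen's d = mean(D)/sd(D) (n-1 norm).

    d is NaN (logged) when the differences have zero spread.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    r = z_stat / math.sqrt(n)
    d = np.asarray(differences, float)
    s = float(np.std(d, ddof=1))
    if s == 0:
        logger.warning("zero-spread differences: Cohen's d undefined")
        return r, math.nan
    return r, float(np.mean(d)) / s


def wilcoxon_power(
    n: int, alpha: float, d: float, are: float = NORMAL_ARE
) -> float:
    """Achieved power of a two-tailed matched-pairs test at effect size d.

    Noncentral-t approximation at effective sample size n' = n * are:
    df = n' - 1, noncentrality d * sqrt(n'), critical value from the
    central t at alpha/2 per tail.  are = 1 gives the plain paired-t power.
    """
    n_eff = n * are
    df = n_eff - 1
    if df <= 0:
        raise ValueError("effective sample size too small")
    ncp = d * math.sqrt(n_eff)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    # the far tail can underflow to nan inside scipy's nct; it is negligible there
    if math.isnan(upper):
        upper = 1.0 if ncp > tcrit else 0.0
    if math.isnan(lower):
        lower = 1.0 if ncp < -tcrit else 0.0
    return float(min(1.0, upper + lower))


def sensitivity_d(
    n: int,
    alpha: float = 0.01,
    power: float = 0.8,
    are: float = NORMAL_ARE,
) -> float:
    """Minimal detectable Cohen's d for a two-tailed matched-pairs design.

    Root-finds the d at which :func:`wilcoxon_power` reaches ``power``.
    With the default are = 3/pi this is the Wilcoxon signed-rank
    sensitivity under a normal parent; are = 1 gives the paired-t value.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    return float(
        optimize.brentq(lambda d: wilcoxon_power(n, alpha, d, are) - power, 1e-6, 10.0)
    )


def compare_conditions(
    index_table: pd.DataFrame,
    alpha: float = 0.01,
    comparisons=COMPARISONS,
    index_names=INDEX_NAMES,
    holm_family: str = "per_comparison",
) -> pd.DataFrame:
    """Paired Wilcoxon comparisons of per-participant set-averaged indices.

    ``index_table`` is a tidy frame with columns ``participant_id``,
    ``condition``, ``set_index`` and one column per index.  Index values
    are first averaged over sets within participant x condition; each of
    the labelled comparisons then tests each index across participants
    having both conditions (others are dropped pairwise, with a logged
    count).  Holm correction is applied within the index family of each
    comparison (``holm_family="all"`` pools every test into one family).

    Returns a tidy frame with one row per (comparison, index) and columns
    ``p, z, r, d, power, direction, significant, n``.
    """
    means = (
        index_table.groupby(["participant_id", "condition"])[list(index_names)]
        .mean()
        .reset_index()
    )
    rows = []
    for comp_name, cond_a, cond_b in comparisons:
        wide_a = means[means["condition"] == cond_a].set_index("participant_id")
        wide_b = means[means["condition"] == cond_b].set_index("participant_id")
        common = wide_a.index.intersection(wide_b.index)
        n_dropped = len(wide_a.index.union(wide_b.index)) - len(common)
        if n_dropped:
            logger.info(
                "%s: dropped %d participants missing a condition", comp_name, n_dropped
            )
        for index_name in index_names:
            va = wide_a.loc[common, index_name].to_numpy(float)
            vb = wide_b.loc[common, index_name].to_numpy(float)
            ok = ~(np.isnan(va) | np.isnan(vb))
            if ok.sum() < len(common):
                logger.info(
                    "%s/%s: %d participants dropped for flagged values",
                    comp_name, index_name, int(len(common) - ok.sum()),
                )
            va, vb = va[ok], vb[ok]
            row = {
                "comparison": comp_name,
                "index": index_name,
                "n": int(ok.sum()),
                "p": math.nan,
                "z": math.nan,
                "r": math.nan,
                "d": math.nan,
                "power": math.nan,
                "direction": "none",
            }
            if va.size >= 5:
                try:
                    res = wilcoxon_signed_rank(va, vb)
                    r_eff, d_eff = effect_sizes(res.z_stat, res.n, vb - va)
                    row.update(
                        p=res.p_value,
                        z=res.z_stat,
                        r=r_eff,
                        d=d_eff,
                        direction="up" if np.mean(vb - va) > 0 else "down",
                    )
                    if not math.isnan(d_eff):
                        row["power"] = wilcoxon_power(va.size, alpha, abs(d_eff))
                except ValueError as exc:
                    logger.warning("%s/%s: %s", comp_name, index_name, exc)
            rows.append(row)
    table = pd.DataFrame(rows)
    if holm_family == "per_comparison":
        table["significant"] = False
        for comp_name, _, _ in comparisons:
            mask = table["comparison"] == comp_name
            table.loc[mask, "significant"] = holm_bonferroni(
                table.loc[mask, "p"].to_numpy(), alpha
            )
    elif holm_family == "all":
        table["significant"] = holm_bonferroni(table["p"].to_numpy(), alpha)
    else:
        raise ValueError(f"unknown holm_family {holm_family!r}")
    return table
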
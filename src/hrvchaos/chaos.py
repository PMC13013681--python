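"""Chaos/complexity HRV indices.

This module implements six nonlinear descriptors of an interval series:

* approximate entropy (ApEn) and sample entropy (SampEn) — template
  regularity statistics with embedding length m and tolerance r = 0.2 sigma
  under the Chebyshev (max-norm) distance;
* the Higuchi fractal dimension — slope of log curve-length against
  log(1/k);
* the Poincare descriptors SD1, SD2 and their ratio — dispersions of the
  lag-1 return map along the axes rotated 45 degrees from (u_n, u_{n+1});
* the entropic chaos degree (CD) — the conditional Shannon entropy (nats)
  of cell-to-cell transitions over an equal partition of
  I = [mu - 2 sigma, mu + 2 sigma];
* the improved chaos degree (ICD) — CD minus the mean information
  -ln q(i,j) carried by the subcell occupancy of each transition, a
  data-only estimate of the Lyapunov exponent.

CD rests on the transition statistics of consecutive pairs (x_n, x_{n+1})
falling inside I: with p(i) the occupancy of cell A_i, p(i,j) the joint
occupancy and p(j|i) = p(i,j)/p(i),

    CD  = - sum_i p(i) sum_j p(j|i) ln p(j|i).

ICD subtracts the partition-resolution information: each destination cell
A_j is split into Q equal subcells, q(i,j) is the fraction of those
subcells reached from A_i, and

    ICD = - sum_i p(i) sum_j p(j|i) [ ln p(j|i) - ln q(i,j) ].

Since q(i,j) <= 1, ICD <= CD always; when every occupied transition lands
in a single subcell, ICD = CD - ln Q exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import RRISeries

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class EntropyParams:
    """Embedding length m and tolerance multiplier for ApEn/SampEn."""

    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")


@dataclass(frozen=True)
class ChaosConfig:
    """Defaults of the full chaos/complexity block.

    The partition interval is I = [mu - s*sigma, mu + s*sigma] with
    s = ``partition_sigma_mult``; CD uses ``cd_cells`` cells, ICD uses
    ``icd_cells`` cells each split into ``icd_subcells`` subcells.
    Consecutive pairs with either endpoint outside I are dropped from the
    transition counts (``out_of_range_policy="clip"`` clips them to the
    boundary cells instead).
    """

    entropy: EntropyParams = field(default_factory=EntropyParams)
    cd_cells: int = 20
    icd_cells: int = 10
    icd_subcells: int = 4
    partition_sigma_mult: float = 2.0
    higuchi_kmax: int = 10
    out_of_range_policy: str = "drop"


# --------------------------------------------------------------------------
# entropies


def _chebyshev_matches(x: np.ndarray, m: int, r: float) -> np.ndarray:
    """Boolean matrix of m-length templates within Chebyshev distance r."""
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    dist = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
    return dist <= r


def approximate_entropy(
    series: np.ndarray | RRISeries, params: EntropyParams = EntropyParams()
) -> float:
    """Approximate entropy with self-matches included (Pincus convention).

    ApEn = Phi^m - Phi^{m+1} with Phi^m the mean log fraction of m-templates
    within r = r_factor * sigma (Chebyshev distance).  A constant series has
    sigma = 0 and returns 0 (perfect regularity) with a warning.  Because r
    tracks sigma, the statistic is invariant under positive affine
    transforms of the data.
    """
    x = series.intervals if isinstance(series, RRISeries) else np.asarray(series, float)
    m = params.m
    if x.size < m + 2:
        raise ValueError(f"series too short for ApEn: need at least {m + 2} points")
    sigma = float(np.std(x, ddof=1))
    if sigma == 0:
        logger.warning("constant series: ApEn set to 0 by convention")
        return 0.0
    r = params.r_factor * sigma

    def phi(mm: int) -> float:
        match = _chebyshev_matches(x, mm, r)
        n_templates = x.size - mm + 1
        return float(np.mean(np.log(match.sum(axis=1) / n_templates)))

    return phi(m) - phi(m + 1)


def sample_entropy(
    series: np.ndarray | RRISeries, params: EntropyParams = EntropyParams()
) -> float:
    """Sample entropy, -ln(A/B), self-matches excluded (Richman convention).

    B counts ordered pairs of distinct m-templates within r, A the same for
    (m+1)-templates; both use the first n-m templates.  Returns 0 with a
    warning for a constant series, NaN (logged) when A or B is zero.
    """
    x = series.intervals if isinstance(series, RRISeries) else np.asarray(series, float)
    m = params.m
    if x.size < m + 2:
        raise ValueError(f"series too short for SampEn: need at least {m + 2} points")
    sigma = float(np.std(x, ddof=1))
    if sigma == 0:
        logger.warning("constant series: SampEn set to 0 by convention")
        return 0.0
    r = params.r_factor * sigma
    nt = x.size - m  # both template lengths use the first n-m start points

    match_m = _chebyshev_matches(x, m, r)[:nt, :nt]
    np.fill_diagonal(match_m, False)
    b = int(match_m.sum())
    match_m1 = _chebyshev_matches(x, m + 1, r)
    np.fill_diagonal(match_m1, False)
    a = int(match_m1.sum())
    if a == 0 or b == 0:
        logger.warning("SampEn undefined: no template matches (A=%d, B=%d)", a, b)
        return math.nan
    return -math.log(a / b)


# --------------------------------------------------------------------------
# Higuchi fractal dimension


def higuchi_fd(series: np.ndarray | RRISeries, k_max: int = 10) -> float:
    """Higuchi fractal dimension from curve lengths at lags 1..k_max.

    For each lag k and offset m the normalised curve length
    L_m(k) = [(sum |x_{m+ik} - x_{m+(i-1)k}|) * (n-1)/(floor((n-m)/k) k)] / k
    is averaged over offsets; the FD is the least-squares slope of
    ln L(k) against ln(1/k).  A constant series returns 1 by convention.
    Values outside [1, 2] are possible for non-physiological inputs and are
    logged, not clipped.
    """
    x = series.intervals if isinstance(series, RRISeries) else np.asarray(series, float)
    n = x.size
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n < 2 * k_max:
        raise ValueError(f"series too short for Higuchi FD with k_max={k_max}")
    lengths = []
    for k in range(1, k_max + 1):
        lm = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lm.append(dist * norm / k)
        lengths.append(np.mean(lm))
    lengths = np.asarray(lengths)
    if np.all(lengths == 0):  # constant series: zero curve length at every lag
        return 1.0
    ks = np.arange(1, k_max + 1)
    slope = np.polyfit(np.log(1.0 / ks), np.log(lengths), 1)[0]
    if not (1.0 <= slope <= 2.0):
        logger.info("Higuchi FD %.3f outside [1, 2]", slope)
    return float(slope)


# --------------------------------------------------------------------------
# Poincare descriptors


def poincare_descriptors(
    series: np.ndarray | RRISeries,
) -> tuple[float, float, float]:
    """SD1, SD2 and SD1/SD2 of the lag-1 Poincare plot.

    SD1 (SD2) is the population standard deviation of the plot projected
    onto the minor (major) axis, i.e. of (u_{n+1} -+ u_n)/sqrt(2).  The
    ratio is NaN (logged) when SD2 = 0.
    """
    x = series.intervals if isinstance(series, RRISeries) else np.asarray(series, float)
    if x.size < 3:
        raise ValueError("series too short for Poincare descriptors")
    if np.ptp(x) == 0:  # constant series: avoid rounding-noise dispersion
        logger.warning("SD2 = 0: SD1/SD2 undefined")
        return 0.0, 0.0, math.nan
    u, v = x[:-1], x[1:]
    sd1 = float(np.std((v - u) / math.sqrt(2.0), ddof=0))
    sd2 = float(np.std((v + u) / math.sqrt(2.0), ddof=0))
    if sd2 == 0:
        logger.warning("SD2 = 0: SD1/SD2 undefined")
        return sd1, sd2, math.nan
    return sd1, sd2, sd1 / sd2


# --------------------------------------------------------------------------
# partition and transition statistics for CD / ICD


@dataclass(frozen=True)
class PartitionSpec:
    """Equal partition of I = [a, b] into ``n_cells`` half-open cells.

    Cells are [a + i*w, a + (i+1)*w) with w = (b-a)/N, except the last
    which is closed so that b belongs to cell N-1.  Each cell is further
    split into ``q_subcells`` equal subcells with the same convention.
    """

    a: float
    b: float
    n_cells: int
    q_subcells: int = 1

    def __post_init__(self) -> None:
        if not (self.b > self.a):
            raise ValueError("degenerate partition: need b > a")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        if self.q_subcells < 1:
            raise ValueError("q_subcells must be >= 1")

    @property
    def cell_width(self) -> float:
        return (self.b - self.a) / self.n_cells

    def cell_index(self, values: np.ndarray) -> np.ndarray:
        """Cell index of each value; -1 marks values outside [a, b]."""
        x = np.asarray(values, float)
        idx = np.floor((x - self.a) / self.cell_width).astype(int)
        idx = np.minimum(idx, self.n_cells - 1)  # x == b -> last cell
        idx[(x < self.a) | (x > self.b)] = -1
        return idx

    def subcell_index(self, values: np.ndarray) -> np.ndarray:
        """Subcell index within the containing cell (0..Q-1); -1 outside."""
        x = np.asarray(values, float)
        w = self.cell_width / self.q_subcells
        total = np.floor((x - self.a) / w).astype(int)
        total = np.minimum(total, self.n_cells * self.q_subcells - 1)
        sub = total % self.q_subcells
        sub[(x < self.a) | (x > self.b)] = -1
        return sub


def build_partition(
    series: np.ndarray | RRISeries,
    n_cells: int,
    q_subcells: int = 1,
    sigma_mult: float = 2.0,
) -> PartitionSpec:
    """Data-driven partition over I = [mu - s*sigma, mu + s*sigma]."""
    x = series.intervals if isinstance(series, RRISeries) else np.asarray(series, float)
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    if sigma == 0:
        raise ValueError("degenerate partition: series has zero variance")
    return PartitionSpec(
        a=mu - sigma_mult * sigma,
        b=mu + sigma_mult * sigma,
        n_cells=n_cells,
        q_subcells=q_subcells,
    )


@dataclass(frozen=True)
class TransitionModel:
    """Empirical occupancy/transition statistics over a partition.

    ``m_transitions`` is the number of consecutive pairs counted (both
    endpoints inside I).  ``p_i`` sums to 1 over the first elements of
    counted pairs, ``p_ij`` over the pairs; ``q_ij`` is the fraction of the
    Q subcells of the destination cell that receive at least one transition
    from the source cell.
    """

    m_transitions: int
    p_i: np.ndarray
    p_ij: np.ndarray
    p_j_given_i: np.ndarray
    q_ij: np.ndarray
    n_cells: int
    q_subcells: int


def transition_statistics(
    series: np.ndarray | RRISeries,
    part: PartitionSpec,
    out_of_range_policy: str = "drop",
) -> TransitionModel:
    """Count cell-to-cell transitions of consecutive pairs.

    With the default ``drop`` policy, pairs with either endpoint outside I
    are excluded; ``clip`` assigns out-of-range values to the nearest
    boundary cell.
    """
    x = series.intervals if isinstance(series, RRISeries) else np.asarray(series, float)
    if x.size < 2:
        raise ValueError("insufficient data: need at least one consecutive pair")
    cells = part.cell_index(x)
    subs = part.subcell_index(x)
    if out_of_range_policy == "clip":
        clipped = np.clip(x, part.a, part.b)
        cells = part.cell_index(clipped)
        subs = part.subcell_index(clipped)
    elif out_of_range_policy != "drop":
        raise ValueError(f"unknown out_of_range_policy {out_of_range_policy!r}")

    src, dst, dst_sub = cells[:-1], cells[1:], subs[1:]
    ok = (src >= 0) & (dst >= 0)
    src, dst, dst_sub = src[ok], dst[ok], dst_sub[ok]
    m = src.size
    if m == 0:
        raise ValueError("insufficient in-range data: no counted pairs")

    n, q = part.n_cells, part.q_subcells
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (src, dst), 1)
    occupied = np.zeros((n, n, q), dtype=bool)
    occupied[src, dst, dst_sub] = True

    p_ij = counts / m
    p_i = p_ij.sum(axis=1)  # occupancy of first pair elements; sums to 1
    with np.errstate(divide="ignore", invalid="ignore"):
        p_j_given_i = np.where(p_i[:, None] > 0, p_ij / p_i[:, None], 0.0)
    q_ij = occupied.sum(axis=2) / q
    return TransitionModel(
        m_transitions=m,
        p_i=p_i,
        p_ij=p_ij,
        p_j_given_i=p_j_given_i,
        q_ij=q_ij,
        n_cells=n,
        q_subcells=q,
    )


def chaos_degree(model: TransitionModel) -> float:
    """Entropic chaos degree: conditional transition entropy in nats.

    CD = -sum_ij p(i,j) ln p(j|i), with 0 ln 0 = 0.  Bounded by ln N.
    """
    mask = model.p_ij > 0
    return float(-np.sum(model.p_ij[mask] * np.log(model.p_j_given_i[mask])))


def improved_chaos_degree(
    series: np.ndarray | RRISeries,
    part: PartitionSpec,
    out_of_range_policy: str = "drop",
) -> float:
    """Improved chaos degree: CD minus the subcell-occupancy information.

    ICD = -sum_ij p(i,j) [ln p(j|i) - ln q(i,j)] in nats.  Whenever
    p(i,j) > 0 the destination cell has at least one occupied subcell, so
    q(i,j) >= 1/Q and every logarithm is finite.  ICD <= CD; it estimates
    the Lyapunov exponent of the generating dynamics.
    """
    if part.q_subcells < 2:
        raise ValueError("ICD needs q_subcells >= 2")
    model = transition_statistics(series, part, out_of_range_policy)
    mask = model.p_ij > 0
    terms = np.log(model.p_j_given_i[mask]) - np.log(model.q_ij[mask])
    return float(-np.sum(model.p_ij[mask] * terms))


def chaos_indicator_ratio(cci_rest: float, cci_task: float) -> float:
    """Chaos indicator ratio gamma = CCI_task / CCI_rest.

    gamma > 1 marks a mental-task-like increase of the chaos/complexity
    index, gamma < 1 a physical-task-like decrease.
    """
    if cci_rest == 0:
        raise ValueError("undefined ratio: rest-condition index is zero")
    return cci_task / cci_rest


# --------------------------------------------------------------------------
# full index block


@dataclass
class ChaosIndices:
    """The six chaos/complexity index values for one recording.

    ``flags`` maps an index name to an error message when that index could
    not be computed (the corresponding value is NaN); a partial failure
    never aborts the batch.
    """

    apen: float
    sampen: float
    fractal_dimension: float
    sd1: float
    sd2: float
    sd1_sd2: float
    cd: float
    icd: float
    flags: dict = field(default_factory=dict)


def compute_chaos_indices(
    series: RRISeries | np.ndarray, config: ChaosConfig = ChaosConfig()
) -> ChaosIndices:
    """Compute all six chaos/complexity indices of a windowed recording.

    Component failures (e.g. the degenerate partition of a constant series)
    are recorded per index in ``flags`` with NaN values.
    """
    x = series.intervals if isinstance(series, RRISeries) else np.asarray(series, float)
    out = dict.fromkeys(
        ("apen", "sampen", "fractal_dimension", "sd1", "sd2", "sd1_sd2", "cd", "icd"),
        math.nan,
    )
    flags: dict[str, str] = {}

    def attempt(name: str, fn):
        try:
            out[name] = fn()
        except ValueError as exc:
            flags[name] = str(exc)
            logger.warning("%s failed: %s", name, exc)

    attempt("apen", lambda: approximate_entropy(x, config.entropy))
    attempt("sampen", lambda: sample_entropy(x, config.entropy))
    attempt("fractal_dimension", lambda: higuchi_fd(x, config.higuchi_kmax))

    try:
        sd1, sd2, ratio = poincare_descriptors(x)
        out["sd1"], out["sd2"], out["sd1_sd2"] = sd1, sd2, ratio
        if math.isnan(ratio):
            flags["sd1_sd2"] = "SD2 = 0: ratio undefined"
    except ValueError as exc:
        flags["sd1_sd2"] = str(exc)

    def cd_value():
        part = build_partition(x, config.cd_cells, 1, config.partition_sigma_mult)
        return chaos_degree(
            transition_statistics(x, part, config.out_of_range_policy)
        )

    def icd_value():
        part = build_partition(
            x, config.icd_cells, config.icd_subcells, config.partition_sigma_mult
        )
        return improved_chaos_degree(x, part, config.out_of_range_policy)

    attempt("cd", cd_value)
    attempt("icd", icd_value)
    if math.isnan(out["sampen"]) and "sampen" not in flags:
        flags["sampen"] = "no template matches"
    return ChaosIndices(**out, flags=flags)
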
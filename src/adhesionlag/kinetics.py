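"""Half-rise times, recruitment lags, and nonparametric summaries.

The recruitment lag of a tracked cluster is defined from its averaged
per-channel intensity traces: each trace is min–max rescaled to [0, 1],
smoothed with a centred moving average, and the time of the first upward
crossing of 0.5 is linearly interpolated (t½).  The lag is
Δt½ = t½(green/query) − t½(red/reference); it is positive when the query
protein arrives later than the reference.

Per-cell statistics follow the nonparametric reporting conventions of
single-cell adhesion studies: the median lag over a cell's clusters with a
distribution-free 95% confidence interval from exact binomial order
statistics and a one-sided signed-rank test of median > 0; across cells,
the mean of per-cell medians with its standard error.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CellSummary, HalfRiseResult, PopulationSummary


# ---------------------------------------------------------------------------
# trace conditioning and half-rise interpolation


def condition_trace(trace: np.ndarray, window_frames: int = 3) -> tuple[np.ndarray, bool, str]:
    """Min–max rescale to [0, 1], then centred moving average.

    The smoothing window must be odd; at the trace edges the window shrinks
    to the available samples, so no padding values are invented.  A constant
    (or non-finite) trace cannot be rescaled and is flagged invalid rather
    than raising.

    Returns ``(conditioned, valid, reason)``.
    """
    trace = np.asarray(trace, dtype=float)
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window_frames}")
    if trace.size < window_frames:
        raise ValueError("trace shorter than the smoothing window")
    if not np.all(np.isfinite(trace)):
        return np.full_like(trace, np.nan), False, "non-finite"
    lo, hi = trace.min(), trace.max()
    if hi == lo:
        return np.full_like(trace, np.nan), False, "constant trace"
    rescaled = (trace - lo) / (hi - lo)
    if window_frames == 1:
        return rescaled, True, ""
    kernel = np.ones(window_frames)
    smoothed = np.convolve(rescaled, kernel, mode="same") / np.convolve(
        np.ones_like(rescaled), kernel, mode="same"
    )
    return smoothed, True, ""


def half_rise_time(trace: np.ndarray, times_s: np.ndarray) -> tuple[float, bool, str]:
    """Interpolated time of the first upward crossing of 0.5.

    ``trace`` must already be conditioned to [0, 1].  Returns
    ``(t_half_s, valid, reason)``; invalid when the trace starts at or above
    0.5 (the rise is not captured) or never reaches 0.5.
    """
    trace = np.asarray(trace, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if trace.shape != times_s.shape:
        raise ValueError("trace and time axis must have equal length")
    if not np.all(np.isfinite(trace)):
        return np.nan, False, "non-finite"
    if trace[0] >= 0.5:
        return np.nan, False, "starts above 0.5"
    below = trace < 0.5
    crossing = np.nonzero(below[:-1] & ~below[1:])[0]
    if crossing.size == 0:
        return np.nan, False, "never reaches 0.5"
    i = int(crossing[0])
    frac = (0.5 - trace[i]) / (trace[i + 1] - trace[i])
    return float(times_s[i] + frac * (times_s[i + 1] - times_s[i])), True, ""


def half_rise_result(
    cluster_id: int,
    trace_red: np.ndarray,
    trace_green: np.ndarray,
    times_s: np.ndarray,
    window_frames: int = 3,
) -> HalfRiseResult:
    """Condition both channel traces and compute t½ per channel and Δt½."""
    out = HalfRiseResult(cluster_id=cluster_id)
    for name, trace in (("red", trace_red), ("green", trace_green)):
        conditioned, ok, reason = condition_trace(trace, window_frames)
        if ok:
            t_half, ok, reason = half_rise_time(conditioned, times_s)
        else:
            t_half = np.nan
        setattr(out, f"t_half_{name}_s", t_half)
        setattr(out, f"valid_{name}", ok)
        setattr(out, f"reason_{name}", reason)
    return out


def delta_t_half(result: HalfRiseResult) -> float:
    """Δt½ = t½(green) − t½(red); NaN when either channel is invalid."""
    return result.delta_t_half_s


# ---------------------------------------------------------------------------
# per-cell and population summaries


def median_ci(
    values: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, bool]:
    """Distribution-free CI for the median from binomial order statistics.

    Picks the smallest symmetric pair of order statistics (x_(j), x_(n+1-j))
    whose exact binomial coverage 1 − 2·P(Bin(n, ½) < j) reaches the target;
    for n < 6 no such pair exists and the full sample range is returned,
    flagged degenerate.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("need at least one value")
    if n == 1:
        return x[0], x[0], True
    best_j = 0
    for j in range(1, n // 2 + 1):
        coverage = 1.0 - 2.0 * stats.binom.cdf(j - 1, n, 0.5)
        if coverage >= confidence:
            best_j = j
        else:
            break
    if best_j == 0:
        return x[0], x[-1], True
    return float(x[best_j - 1]), float(x[n - best_j]), False


def cell_summary(
    deltas: Sequence[float],
    cell_id: object = 0,
    test: str = "signed-rank",
) -> CellSummary:
    """Summarise one cell's valid cluster lags.

    Reports the median Δt½, its exact 95% order-statistic CI, and a
    one-sided test of median > 0 (Wilcoxon signed-rank by default, sign test
    optionally).
    """
    deltas = np.asarray([d for d in deltas if np.isfinite(d)], dtype=float)
    if deltas.size < 1:
        raise ValueError("need at least one valid delta")
    median = float(np.median(deltas))
    lo, hi, degenerate = median_ci(deltas)
    nonzero = deltas[deltas != 0]
    if nonzero.size == 0:
        p = 1.0
    elif test == "signed-rank":
        p = float(stats.wilcoxon(nonzero, alternative="greater").pvalue)
    elif test == "sign":
        pos = int(np.sum(nonzero > 0))
        p = float(stats.binomtest(pos, nonzero.size, 0.5, alternative="greater").pvalue)
    else:
        raise ValueError("test must be 'signed-rank' or 'sign'")
    return CellSummary(
        cell_id=cell_id,
        n_valid_clusters=int(deltas.size),
        median_delta_s=median,
        ci95_low_s=lo,
        ci95_high_s=hi,
        p_one_sided=p,
        ci_degenerate=degenerate,
    )


def population_summary(cell_medians: Sequence[float]) -> PopulationSummary:
    """Mean of per-cell medians and its standard error (sd/√n)."""
    medians = np.asarray(cell_medians, dtype=float)
    n = medians.size
    if n < 1:
        raise ValueError("need at least one cell median")
    mean = float(medians.mean())
    sem = float(medians.std(ddof=1) / math.sqrt(n)) if n >= 2 else np.nan
    return PopulationSummary(n_cells=n, mean_of_medians_s=mean, sem_s=sem)


# ---------------------------------------------------------------------------
# group comparisons


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; exact by enumeration for small samples.

    For combined n ≤ ``exact_max_n`` the permutation null of U is enumerated
    exhaustively over all group assignments (midranks handle ties, so the
    exact p remains valid with tied data); larger samples use the
    tie-corrected normal approximation.  Returns ``(U, p)`` with U counted
    for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= exact_max_n:
        mu = n1 * n2 / 2.0
        observed = abs(u1 - mu)
        count = 0
        total = 0
        rank_sum_offset = n1 * (n1 + 1) / 2.0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - rank_sum_offset
            if abs(u - mu) >= observed - 1e-9:
                count += 1
            total += 1
        return u1, count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u1, float(res.pvalue)


@dataclass
class GroupComparison:
    """Report of a nonparametric group comparison."""

    test: str  # "mann-whitney" or "kruskal-wallis+dunn"
    statistic: float
    p_value: float
    pairwise: Optional[list[tuple[int, int, float, float]]] = None  # (i, j, z, p_adj)


def dunn_pairwise(
    groups: Sequence[Sequence[float]], adjust: str = "holm"
) -> list[tuple[int, int, float, float]]:
    """Dunn's rank-based post-hoc comparisons with multiplicity adjustment.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the
    standard tie correction T = Σ(t³ − t) / (12(N − 1)); two-sided normal
    p-values, Holm-adjusted by default.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    combined = np.concatenate(arrays)
    n_total = combined.size
    ranks = _midranks(combined)
    mean_ranks = []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = []
    raw_p = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = math.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        pairs.append((i, j, z))
        raw_p.append(2.0 * stats.norm.sf(abs(z)))
    adjusted = multipletests(raw_p, method=adjust)[1] if raw_p else []
    return [(i, j, z, float(p)) for (i, j, z), p in zip(pairs, adjusted)]


def group_compare(groups: Sequence[Sequence[float]], adjust: str = "holm") -> GroupComparison:
    """Compare ≥2 groups of per-cell medians.

    Two groups: two-sided Mann–Whitney U (exact for combined n ≤ 20).
    Three or more: Kruskal–Wallis followed by Dunn's pairwise tests with
    Holm adjustment.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if len(groups) == 2:
        u, p = mann_whitney_u(groups[0], groups[1])
        return GroupComparison(test="mann-whitney", statistic=u, p_value=p)
    h, p = stats.kruskal(*groups)
    return GroupComparison(
        test="kruskal-wallis+dunn",
        statistic=float(h),
        p_value=float(p),
        pairwise=dunn_pairwise(groups, adjust=adjust),
    )
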
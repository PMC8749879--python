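"""Small-sample nonparametric statistics for repeated-measures monitoring.

The whole battery is implemented from first principles because the study
design (n = 8 athletes, 4 weeks) lives exactly where asymptotic
approximations are weakest:

* one-sample Kolmogorov–Smirnov normality check with a Monte-Carlo
  (Lilliefors) p-value, since the normal parameters are estimated;
* Wilcoxon signed-rank for paired pre/post contrasts, with the exact null
  distribution by full enumeration of the 2^n sign assignments at small n;
* Friedman rank test across weeks, chi-square reference with tie correction;
* Bonferroni-corrected pairwise signed-rank post hoc comparisons;
* Cliff's delta effect size, the coefficient of quartile variation (CQV)
  and pre/post normalized variation as descriptive measures.

Quartiles follow the linear order-statistic interpolation at position
(n-1)*p + 1 (numpy's default), fixed once so IQR/CQV values are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "AnalysisConfig",
    "TestResult",
    "EffectSize",
    "ks_normality",
    "wilcoxon_signed_rank",
    "friedman",
    "bonferroni_posthoc",
    "cliffs_delta",
    "cqv",
    "normalized_variation",
    "median_iqr",
    "quartiles",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunables of the statistical battery.

    alpha
        Significance threshold for flagging comparisons.
    exact_max_n
        Largest n for which the Wilcoxon null is enumerated exactly
        (2^n assignments; 12 keeps enumeration below 4096 cases).
    ks_mc_replicates
        Monte-Carlo replicates for the Lilliefors-corrected KS p-value.
    posthoc
        "pairwise-wilcoxon" (default) or "rank-difference" — the
        Friedman-rank critical-difference variant.
    """

    alpha: float = 0.05
    exact_max_n: int = 12
    ks_mc_replicates: int = 10_000
    posthoc: str = "pairwise-wilcoxon"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.posthoc not in ("pairwise-wilcoxon", "rank-difference"):
            raise ValueError(f"unknown posthoc method {self.posthoc!r}")


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: tuple
    exact: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class EffectSize:
    delta: float
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError(f"Cliff's delta {self.delta} outside [-1, 1]")


# ---------------------------------------------------------------------------
# Quartiles and robust descriptives
# ---------------------------------------------------------------------------

def quartiles(sample: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) by linear interpolation at position (n-1)*p + 1."""
    x = np.asarray(sample, dtype=float)
    if x.size < 1:
        raise ValueError("empty sample")
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    return float(q1), float(q2), float(q3)


def median_iqr(sample: Sequence[float]) -> tuple[float, float]:
    """(median, interquartile range Q3 - Q1)."""
    q1, q2, q3 = quartiles(sample)
    return q2, q3 - q1


def cqv(sample: Sequence[float]) -> float:
    """Coefficient of quartile variation, 100*(Q3 - Q1)/(Q3 + Q1), percent."""
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError(f"CQV needs n >= 4, got {x.size}")
    q1, _, q3 = quartiles(x)
    if q1 + q3 <= 0:
        raise ValueError(f"CQV undefined: Q1 + Q3 = {q1 + q3:.6g} <= 0")
    return 100.0 * (q3 - q1) / (q3 + q1)


def normalized_variation(pre: float, post: float) -> float:
    """Percent change of a post-effort value relative to its pre-effort
    baseline, 100*(post - pre)/pre.  Negative values mean performance loss
    for larger-is-better parameters."""
    if pre == 0:
        raise ValueError("pre-effort baseline is zero; variation undefined")
    return 100.0 * (post - pre) / pre


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov normality (Lilliefors Monte-Carlo p)
# ---------------------------------------------------------------------------

def _ks_stat_fitted_normal(x: np.ndarray) -> float:
    """sup |F_n - Phi((x - mean)/sd)| evaluated at the step points."""
    n = x.shape[-1]
    xs = np.sort(x, axis=-1)
    mu = xs.mean(axis=-1, keepdims=True)
    sd = xs.std(axis=-1, ddof=1, keepdims=True)
    cdf = norm.cdf((xs - mu) / sd)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=-1)
    d_minus = (cdf - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def ks_normality(
    sample: Sequence[float],
    cfg: AnalysisConfig = AnalysisConfig(),
    seed: int = 0,
) -> TestResult:
    """One-sample KS test of normality with estimated parameters.

    Because mean and sd are fitted from the data, the classical KS null
    distribution is anticonservative; the p-value is instead computed by
    seeded Monte Carlo over normal samples of the same size (Lilliefors
    correction), p = (1 + #{D_sim >= D_obs}) / (replicates + 1).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError(f"normality check needs n >= 4, got {x.size}")
    if np.std(x) == 0:
        raise ValueError("zero-variance sample: normality test degenerate")
    d_obs = float(_ks_stat_fitted_normal(x))
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((cfg.ks_mc_replicates, x.size))
    d_sim = _ks_stat_fitted_normal(sims)
    p = (1 + int((d_sim >= d_obs).sum())) / (cfg.ks_mc_replicates + 1)
    return TestResult(
        method="ks-lilliefors",
        statistic=d_obs,
        p_value=p,
        n=(x.size,),
        exact=False,
        notes=f"monte-carlo p, {cfg.ks_mc_replicates} replicates, seed={seed}",
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact by enumeration at small n)
# ---------------------------------------------------------------------------

def _signed_rank_prep(pre: np.ndarray, post: np.ndarray):
    d = post - pre
    nonzero = d != 0
    n_zeros = int((~nonzero).sum())
    d = d[nonzero]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))  # mid-ranks for tied magnitudes
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < d.size
    return d, ranks, w_plus, n_zeros, has_ties


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p by full enumeration of all 2^n sign assignments.

    The null distribution of W+ is symmetric about n(n+1)/4 for tie-free
    ranks, so the two-sided p is the doubled smaller tail, clipped at 1.
    """
    n = ranks.size
    # distribution of W+ over all sign patterns via subset-sum counting
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    lo = float((sums <= w_plus + 1e-9).sum()) / sums.size
    hi = float((sums >= w_plus - 1e-9).sum()) / sums.size
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    cfg: AnalysisConfig = AnalysisConfig(),
) -> TestResult:
    """Paired Wilcoxon signed-rank test of post vs pre.

    Zero differences are dropped (Wilcoxon's original treatment, recorded in
    ``notes``); tied magnitudes get mid-ranks.  For n <= ``cfg.exact_max_n``
    with no tied magnitudes, the two-sided p comes from full enumeration of
    the 2^n sign assignments; otherwise from the normal approximation with
    tie correction.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    d, ranks, w_plus, n_zeros, has_ties = _signed_rank_prep(pre, post)
    n = d.size
    if n < 3:
        raise ValueError(f"need >= 3 non-zero differences, got {n}")
    notes = [f"zeros_dropped={n_zeros}"]
    if n <= cfg.exact_max_n and not has_ties:
        p = _exact_two_sided_p(ranks, w_plus)
        exact = True
    else:
        mu = n * (n + 1) / 4.0
        # tie-corrected variance of W+
        tie_term = 0.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((counts**3 - counts) / 48.0).sum())
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mu) / math.sqrt(sigma2)
        p = float(2 * norm.sf(abs(z)))
        exact = False
        notes.append("normal approximation" + (", tie-corrected" if has_ties else ""))
        if has_ties:
            notes.append("ties present: exact enumeration disabled")
    return TestResult(
        method="wilcoxon-signed-rank",
        statistic=w_plus,
        p_value=min(p, 1.0),
        n=(n,),
        exact=exact,
        notes="; ".join(notes),
    )


# ---------------------------------------------------------------------------
# Friedman test and Bonferroni post hoc
# ---------------------------------------------------------------------------

def friedman(block_matrix) -> TestResult:
    """Friedman rank test on a blocks x treatments matrix.

    Rows are blocks (athletes), columns treatments (weeks).  Mid-ranks are
    assigned within each block; the tie-corrected statistic is referred to
    the chi-square distribution with k-1 degrees of freedom.
    """
    x = np.asarray(block_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("block_matrix must be 2-D (blocks x treatments)")
    n, k = x.shape
    if n < 2 or k < 3:
        raise ValueError(f"need >= 2 blocks and >= 3 treatments, got {n}x{k}")
    if np.isnan(x).any():
        raise ValueError(
            "missing cells in the block matrix; aggregate sessions per "
            "(athlete, week) before testing"
        )
    r = rankdata(x, axis=1)
    rj = r.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
    # tie correction: per-block sum of (t^3 - t) over tied groups
    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k * k - 1))
    if correction <= 0:
        # all rows fully tied: no evidence of any treatment effect
        return TestResult("friedman", 0.0, 1.0, (n, k), notes="all blocks fully tied")
    q /= correction
    p = float(chi2.sf(q, k - 1))
    return TestResult("friedman", q, p, (n, k), notes=f"df={k - 1}, tie-corrected")


def bonferroni_posthoc(
    block_matrix,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> list[dict]:
    """All pairwise treatment comparisons with Bonferroni correction.

    Default: a Wilcoxon signed-rank test per column pair with p multiplied
    by the number of comparisons k*(k-1)/2 (clipped at 1).  The
    "rank-difference" variant instead compares Friedman rank-sum differences
    against the Bonferroni-adjusted normal critical difference.
    Returns one dict per pair: {i, j, statistic, p_raw, p_adjusted,
    significant}.  Treatment indices are 1-based.
    """
    x = np.asarray(block_matrix, dtype=float)
    n, k = x.shape
    m = k * (k - 1) // 2
    out = []
    if cfg.posthoc == "rank-difference":
        r = rankdata(x, axis=1)
        rj = r.sum(axis=0)
        se = math.sqrt(n * k * (k + 1) / 6.0)
        for i, j in combinations(range(k), 2):
            diff = abs(rj[i] - rj[j])
            z = diff / se
            p_raw = float(2 * norm.sf(z))
            p_adj = min(1.0, p_raw * m)
            out.append(
                dict(i=i + 1, j=j + 1, statistic=diff, p_raw=p_raw,
                     p_adjusted=p_adj, significant=p_adj < cfg.alpha)
            )
        return out
    for i, j in combinations(range(k), 2):
        if (x[:, i] == x[:, j]).all():
            # identical columns: no difference by construction
            out.append(dict(i=i + 1, j=j + 1, statistic=0.0, p_raw=1.0,
                            p_adjusted=1.0, significant=False))
            continue
        res = wilcoxon_signed_rank(x[:, i], x[:, j], cfg)
        p_adj = min(1.0, res.p_value * m)
        out.append(
            dict(i=i + 1, j=j + 1, statistic=res.statistic, p_raw=res.p_value,
                 p_adjusted=p_adj, significant=p_adj < cfg.alpha)
        )
    return out


# ---------------------------------------------------------------------------
# Cliff's delta
# ---------------------------------------------------------------------------

def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    """Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = xa[:, None] - ya[None, :]
    delta = (int((diff > 0).sum()) - int((diff < 0).sum())) / (xa.size * ya.size)
    return EffectSize(delta=delta, n_x=int(xa.size), n_y=int(ya.size))
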
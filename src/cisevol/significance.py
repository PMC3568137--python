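"""Significance machinery: empirical p-values, Storey q-values, tail analysis.

A foreground CoEvol value CE_F is compared against the CoEvol values of R
shuffle replicates: p = #{CE_S >= CE_F} / R (ties inclusive), so p lives on
the grid {0, 1/R, ..., 1} and a value beating every replicate reports as
"<1/R".  Across many position pairs the p-values are converted to q-values
(positive FDR) with the Storey-Tibshirani estimator.  The right-tail
analysis compares the fraction of foreground values above the 99th
percentile of the Random control (nearest-rank) against the same fraction
in each shuffle replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def empirical_pvalue(observed: float, null_values) -> float:
    """Fraction of null values >= observed (ties count against the observed)."""
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size < 1:
        raise ValueError("need at least one null value")
    return float(np.mean(nulls >= observed))


def format_pvalue(p: float, n_null: int) -> str:
    """Human-readable empirical p; zero is reported as a bound, not as 0."""
    if p == 0.0:
        return f"<{1.0 / n_null:g}"
    return f"{p:g}"


DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 10)


@dataclass
class QValueSet:
    pvalues: np.ndarray
    pi0: float
    qvalues: np.ndarray


def storey_pi0(pvalues: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> float:
    """Estimate the null proportion pi0 by the smoother method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed over the
    grid, smoothed by an inverse-variance-weighted linear fit, and read off
    at the largest lambda; the estimate is capped into (0, 1].  The stiff
    smoother keeps the endpoint estimate stable at moderate m (a flexible
    spline is very noisy at lambda near 1); any upward bias under
    non-uniform alternatives makes the q-values conservative.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    lam = np.asarray(lambda_grid, dtype=float)
    pi0_hat = np.array([np.sum(p > l) / (m * (1.0 - l)) for l in lam])
    if np.allclose(pi0_hat, pi0_hat[0]):
        est = pi0_hat[0]
    else:
        # inverse-variance weights: Var[pi0_hat(l)] is proportional to
        # l / (m (1 - l)) under the uniform null, so the noisy large-l
        # estimates get down-weighted
        w = np.sqrt((1.0 - lam) / lam)
        coeffs = np.polyfit(lam, pi0_hat, deg=1, w=w)
        est = float(np.polyval(coeffs, lam.max()))
    return float(min(1.0, max(est, 1.0 / m)))


def storey_qvalues(
    pvalues, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID
) -> QValueSet:
    """Storey-Tibshirani q-values: q(p_(i)) = min_{j>=i} pi0 * m * p_(j) / j."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = storey_pi0(p, lambda_grid)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]  # step-up enforcement
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return QValueSet(pvalues=p, pi0=pi0, qvalues=q)


def nearest_rank_percentile(values, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    rank = int(np.ceil(percentile / 100.0 * n))
    rank = min(max(rank, 1), n)
    return float(v[rank - 1])


@dataclass
class TailAnalysis:
    """Right-tail comparison of foreground vs shuffle above the Random T99."""

    t99: float
    f_s: dict[int, float]  # per-scope foreground fraction > T99
    s_s: dict[int, list[float]]  # per-scope shuffle-replicate fractions
    tail_p: dict[int, float]  # per-scope fraction of replicates with S^S >= F^S


def tail_analysis(
    foreground_by_scope: dict[int, np.ndarray],
    random_values,
    shuffle_by_scope: dict[int, list[np.ndarray]],
    percentile: float = 99.0,
) -> TailAnalysis:
    """Per-scope F^S, per-replicate S^S and their comparison p-value.

    ``shuffle_by_scope[s]`` holds one array of CoEvol values per shuffle
    replicate.  Fractions use a strict > against the threshold.
    """
    t99 = nearest_rank_percentile(random_values, percentile)
    f_s, s_s, tail_p = {}, {}, {}
    for scope, fg in foreground_by_scope.items():
        fg = np.asarray(fg, dtype=float)
        f = float(np.mean(fg > t99)) if fg.size else float("nan")
        f_s[scope] = f
        reps = [float(np.mean(np.asarray(r) > t99)) for r in shuffle_by_scope.get(scope, [])]
        s_s[scope] = reps
        tail_p[scope] = float(np.mean([r >= f for r in reps])) if reps else float("nan")
    return TailAnalysis(t99=t99, f_s=f_s, s_s=s_s, tail_p=tail_p)
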
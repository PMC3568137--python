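"""Branch-resolved decomposition of co-evolution into nucleotide quadruples.

A quadruple (u, v, x, y) records base u changing to v at position i while x
changes to y at position j, on the same tree branch.  Under a given
ancestral assignment every branch carries exactly one transition per
position, so the assignment machinery yields *propensities*

    Pr(u,v)     = (1/N) sum_k  E[ I_uv(t_k) | data ]        (per branch)
    Pr(u,v,x,y) = the joint analogue under the pair machinery,

each a proper distribution over 16 (resp. 256) outcomes per branch.  The
quadruple-level CoEvol is the log-ratio log[Pr(u,v,x,y)/(Pr(u,v)Pr(x,y))].
Only the 240 quadruples with u != v or x != y are admissible for the
enrichment and reciprocal-rank analyses (both positions silent is not an
evolutionary event); reciprocity (u,v,x,y) <-> (v,u,y,x) is an involution
with 120 orbits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import kendalltau

from .coevol import (
    ConditionalLikelihoodTable,
    JointAssignmentDistribution,
    AssignmentDistribution,
    assignment_distribution,
    joint_distribution,
)
from .controls import shuffle_pairs
from .phylo import PhyloModel, assignment_tuples
from .significance import empirical_pvalue

logger = logging.getLogger(__name__)

N_ADMISSIBLE = 240


def admissible_quadruples() -> list[tuple[int, int, int, int]]:
    """All (u,v,x,y) with u != v or x != y, in lexicographic order (240 total)."""
    return [q for q in product(range(4), repeat=4) if q[0] != q[1] or q[2] != q[3]]


def reciprocal(q: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    u, v, x, y = q
    return (v, u, y, x)


def _responsibilities(table: ConditionalLikelihoodTable, dist: AssignmentDistribution) -> np.ndarray:
    """Per-instance posterior over assignments: rows sum to 1. (N, S)"""
    logr = dist.log_probs[None, :] + table.log_values
    logr = logr - logr.max(axis=1, keepdims=True)
    r = np.exp(logr)
    return r / r.sum(axis=1, keepdims=True)


def transition_propensities(
    table: ConditionalLikelihoodTable,
    dist: AssignmentDistribution,
    model: PhyloModel,
    branch: int,
) -> np.ndarray:
    """Pr(u, v) for one position and one branch (1-based index); shape (4, 4)."""
    tree = model.tree
    b = branch - 1
    if not 0 <= b < tree.n_branches:
        raise ValueError(f"branch index must be in 1..{tree.n_branches}")
    assigns = assignment_tuples(tree.n_internal)
    par = assigns[:, tree.branch_parent[b]]
    r = _responsibilities(table, dist)
    n = table.n
    ci = tree.branch_child_internal[b]
    if ci >= 0:
        cls = par * 4 + assigns[:, ci]
        colsum = r.sum(axis=0)
        pr = np.bincount(cls, weights=colsum, minlength=16).reshape(4, 4) / n
    else:
        row = tree.branch_child_leaf[b]
        obs = table.columns[:, row]
        mass = np.stack([r[:, par == u].sum(axis=1) for u in range(4)], axis=1)  # (N, 4)
        pr = np.zeros((4, 4))
        for v in range(4):
            sel = obs == v
            if np.any(sel):
                pr[:, v] = mass[sel].sum(axis=0)
        pr /= n
    return pr


def joint_transition_propensities(
    table_i: ConditionalLikelihoodTable,
    table_j: ConditionalLikelihoodTable,
    joint: JointAssignmentDistribution,
    model: PhyloModel,
    branch: int,
) -> np.ndarray:
    """Pr(u, v, x, y) for one position pair and branch; shape (4, 4, 4, 4)."""
    tree = model.tree
    b = branch - 1
    if not 0 <= b < tree.n_branches:
        raise ValueError(f"branch index must be in 1..{tree.n_branches}")
    if table_i.n != table_j.n:
        raise ValueError("tables must share N")
    n = table_i.n
    assigns = assignment_tuples(tree.n_internal)
    par = assigns[:, tree.branch_parent[b]]
    ci = tree.branch_child_internal[b]
    internal_child = ci >= 0
    if internal_child:
        cls = par * 4 + assigns[:, ci]  # class = (parent, child) in 0..15
        n_cls = 16
    else:
        cls = par  # class = parent base; child comes from the observation
        n_cls = 4

    # per-instance scaled likelihood vectors (per-k scaling cancels on
    # normalization, so only relative magnitudes within a row matter)
    li = np.exp(table_i.log_values - table_i.log_values.max(axis=1, keepdims=True))
    lj = np.exp(table_j.log_values - table_j.log_values.max(axis=1, keepdims=True))
    p = joint.probs

    idx_by_cls = [np.flatnonzero(cls == c) for c in range(n_cls)]
    t = np.empty((n, n_cls, n_cls))
    for cb in range(n_cls):
        jb = idx_by_cls[cb]
        y_b = lj[:, jb] @ p[:, jb].T  # (N, S): sum over sj in class cb
        for ca in range(n_cls):
            ja = idx_by_cls[ca]
            t[:, ca, cb] = np.einsum("ks,ks->k", li[:, ja], y_b[:, ja])
    z = t.sum(axis=(1, 2), keepdims=True)
    t = t / z

    pr = np.zeros((4, 4, 4, 4))
    if internal_child:
        # class a = u*4+v indexes axes (u, v); class b = x*4+y axes (x, y)
        pr = (t.sum(axis=0) / n).reshape(4, 4, 4, 4)
    else:
        row = tree.branch_child_leaf[b]
        vi = table_i.columns[:, row]
        yj = table_j.columns[:, row]
        for k in range(n):
            pr[:, vi[k], :, yj[k]] += t[k]
        pr /= n
    return pr


def quadruple_coevol(pr_joint: float, pr_uv: float, pr_xy: float) -> float:
    """log[Pr(u,v,x,y) / (Pr(u,v) Pr(x,y))], natural log.

    Returns -inf when the joint propensity is 0 (filtered downstream); a
    zero marginal with positive joint yields +inf and is flagged.
    """
    if pr_joint == 0.0:
        return float("-inf")
    if pr_uv == 0.0 or pr_xy == 0.0:
        logger.warning("quadruple with zero marginal but positive joint propensity")
        return float("inf")
    return float(np.log(pr_joint / (pr_uv * pr_xy)))


@dataclass
class QuadrupleRecord:
    pwm_id: str
    i: int
    j: int
    branch: int
    u: int
    v: int
    x: int
    y: int
    pr_uv: float
    pr_xy: float
    pr_joint: float
    coevol: float
    p_empirical: float | None = None


def _branch_quadruple_coevols(
    table_i: ConditionalLikelihoodTable,
    table_j: ConditionalLikelihoodTable,
    model: PhyloModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """CoEvol tensor (B, 4,4,4,4) plus marginal propensities for all branches."""
    di = assignment_distribution(table_i)
    dj = assignment_distribution(table_j)
    joint = joint_distribution(table_i, table_j)
    nb = model.tree.n_branches
    pr_i = np.stack([transition_propensities(table_i, di, model, b + 1) for b in range(nb)])
    pr_j = np.stack([transition_propensities(table_j, dj, model, b + 1) for b in range(nb)])
    pr4 = np.stack(
        [joint_transition_propensities(table_i, table_j, joint, model, b + 1) for b in range(nb)]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = pr_i[:, :, :, None, None] * pr_j[:, None, None, :, :]
        ce = np.where(pr4 > 0, np.log(np.where(pr4 > 0, pr4, 1.0)) - np.log(np.where(denom > 0, denom, 1.0)), -np.inf)
        ce = np.where((pr4 > 0) & (denom == 0), np.inf, ce)
    return ce, pr_i, pr_j, pr4


def quadruple_analysis(
    table_i: ConditionalLikelihoodTable,
    table_j: ConditionalLikelihoodTable,
    model: PhyloModel,
    *,
    pwm_id: str = "",
    i: int = 0,
    j: int = 1,
    n_shuffles: int = 100,
    seed: int = 0,
) -> list[QuadrupleRecord]:
    """Quadruple CoEvol values with empirical p against shuffle replicates.

    For every branch and every admissible quadruple, the foreground CoEvol
    is compared with the same quantity under ``n_shuffles`` re-pairings of
    the instances (matched per branch and quadruple).
    """
    ce_f, pr_i, pr_j, pr4 = _branch_quadruple_coevols(table_i, table_j, model)
    nb = model.tree.n_branches
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles,) + ce_f.shape)
    for r in range(n_shuffles):
        _, tj_perm, _ = shuffle_pairs(table_i, table_j, rng)
        null[r], _, _, _ = _branch_quadruple_coevols(table_i, tj_perm, model)
    records = []
    quads = admissible_quadruples()
    for b in range(nb):
        for (u, v, x, y) in quads:
            obs = ce_f[b, u, v, x, y]
            nulls = null[:, b, u, v, x, y]
            # -inf (unobserved) compares fine under >=; NaN cannot occur
            p = float(np.mean(nulls >= obs))
            records.append(
                QuadrupleRecord(
                    pwm_id=pwm_id, i=i, j=j, branch=b + 1, u=u, v=v, x=x, y=y,
                    pr_uv=float(pr_i[b, u, v]), pr_xy=float(pr_j[b, x, y]),
                    pr_joint=float(pr4[b, u, v, x, y]),
                    coevol=float(obs), p_empirical=p,
                )
            )
    return records


@dataclass
class EnrichmentResult:
    counts: dict[tuple[int, int, int, int], int]
    n_cases: int
    m_quadruples: int
    threshold: float
    enriched: list[tuple[int, int, int, int]] = field(default_factory=list)


def quadruple_enrichment(
    counts: dict[tuple[int, int, int, int], int],
    n_cases: int | None = None,
    m: int = N_ADMISSIBLE,
) -> EnrichmentResult:
    """Quadruples represented above mean + 2 SD of the uniform expectation.

    With N significant cases spread over M quadruples the null mean is N/M
    and SD sqrt((N/M)(1 - 1/M)); counts strictly greater than mean + 2 SD
    are flagged (nominal p < 0.05 under the normal approximation).
    """
    total = sum(counts.values())
    if n_cases is None:
        n_cases = total
    elif total != n_cases:
        raise ValueError("counts do not sum to n_cases")
    if n_cases == 0:
        return EnrichmentResult(counts=dict(counts), n_cases=0, m_quadruples=m, threshold=float("nan"))
    mean = n_cases / m
    sd = np.sqrt(mean * (1.0 - 1.0 / m))
    threshold = mean + 2.0 * sd
    enriched = sorted(q for q, c in counts.items() if c > threshold)
    return EnrichmentResult(
        counts=dict(counts), n_cases=n_cases, m_quadruples=m, threshold=float(threshold),
        enriched=enriched,
    )


def rank_quadruples(counts: dict[tuple[int, int, int, int], int]) -> list[tuple[int, int, int, int]]:
    """Full ranking of the 240 admissible quadruples by descending count.

    Ties break by quadruple lexicographic order for reproducibility.
    """
    quads = admissible_quadruples()
    return sorted(quads, key=lambda q: (-counts.get(q, 0), q))


@dataclass
class ReciprocalPairRow:
    quadruple: tuple[int, int, int, int]
    reciprocal: tuple[int, int, int, int]
    r: int  # better (smaller) rank
    actual_diff: int
    expected_diff: float
    sd: float
    z: float


@dataclass
class ReciprocalRankResult:
    rows: list[ReciprocalPairRow]
    tau: float
    tau_pvalue: float
    skipped: int = 0


def reciprocal_rank_analysis(ranking: list[tuple[int, int, int, int]]) -> ReciprocalRankResult:
    """Reciprocal-pair rank differences and their z-scores.

    For each of the 120 reciprocal orbits, let r be the better rank; under
    the null the rank difference is discrete-uniform on {1, ..., 240 - r},
    giving expected difference (1 + (240 - r))/2 and variance (m^2 - 1)/12
    with m = 240 - r.  Kendall's tau correlates r with z across pairs.
    """
    m_total = len(ranking)
    rank_of = {q: k + 1 for k, q in enumerate(ranking)}
    if len(rank_of) != m_total:
        raise ValueError("ranking contains duplicates")
    seen = set()
    rows = []
    skipped = 0
    for q in ranking:
        qr = reciprocal(q)
        key = tuple(sorted([q, qr]))
        if key in seen:
            continue
        seen.add(key)
        if qr not in rank_of:
            raise ValueError(f"ranking is missing the reciprocal of {q}")
        r1, r2 = rank_of[q], rank_of[qr]
        r = min(r1, r2)
        m = m_total - r
        if m < 2:
            skipped += 1
            logger.info("reciprocal pair %s/%s skipped (degenerate range m=%d)", q, qr, m)
            continue
        actual = abs(r1 - r2)
        expected = (1.0 + m) / 2.0
        sd = np.sqrt((m * m - 1.0) / 12.0)
        rows.append(
            ReciprocalPairRow(
                quadruple=q, reciprocal=qr, r=r, actual_diff=actual,
                expected_diff=expected, sd=float(sd), z=float((actual - expected) / sd),
            )
        )
    if len(rows) >= 2:
        tau, tau_p = kendalltau([row.r for row in rows], [row.z for row in rows])
    else:
        tau, tau_p = float("nan"), float("nan")
    return ReciprocalRankResult(rows=rows, tau=float(tau), tau_pvalue=float(tau_p), skipped=skipped)
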
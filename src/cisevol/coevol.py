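"""The co-evolution statistic: data-weighted ancestral assignments and CoEvol.

For a single motif position with N aligned binding-site instances, the
likelihood of instance k's column given ancestral assignment s is tabulated
(N x S, log space).  Assignments are then weighted by how well they explain
the whole instance set,

    W(A_s) = sum_k Pr(T_k | A_s),      Pr(A_s) = W(A_s) / sum_p W(A_p),

and the marginal likelihood of each instance is the Pr(A_s)-weighted sum
over assignments.  For a position pair the same construction runs over
S x S assignment pairs, whose joint weight is in general *not* the product
of the marginals -- that deviation is exactly what the statistic measures:

    CoEvol(i,j) = sum_k [ log Pr(T_i^k, T_j^k)
                          - log Pr(T_i^k) - log Pr(T_j^k) ]   (natural log).

A positive CoEvol indicates that the two positions' substitution histories
track each other more than independence predicts.  Everything is a single
pass over the data: weights come from the likelihood tables, then per-site
likelihoods from the weights; there is no EM-style iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .phylo import PhyloModel, assignment_log_likelihoods, encode_columns
from .sites import SiteSet


@dataclass
class ConditionalLikelihoodTable:
    """N x S table of log Pr(T_k | A_s) for one motif position.

    ``columns`` keeps the observed leaf bases (N, n_leaves) so branch-level
    analyses can recover the leaf transitions implied by each assignment.
    """

    log_values: np.ndarray
    columns: np.ndarray

    @property
    def n(self) -> int:
        return self.log_values.shape[0]

    @property
    def n_assignments(self) -> int:
        return self.log_values.shape[1]

    @classmethod
    def from_linear(cls, values: np.ndarray, columns: np.ndarray | None = None) -> "ConditionalLikelihoodTable":
        values = np.asarray(values, dtype=float)
        if np.any(values <= 0):
            raise ValueError("conditional likelihoods must be positive")
        if columns is None:
            columns = np.zeros((values.shape[0], 0), dtype=np.int64)
        return cls(log_values=np.log(values), columns=np.asarray(columns))

    def permuted(self, perm: np.ndarray) -> "ConditionalLikelihoodTable":
        perm = np.asarray(perm)
        return ConditionalLikelihoodTable(
            log_values=self.log_values[perm], columns=self.columns[perm]
        )


@dataclass
class AssignmentDistribution:
    """Data-weighted probabilities over ancestral assignments for one position."""

    log_weights: np.ndarray
    log_probs: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)

    @property
    def total_weight(self) -> float:
        return float(np.exp(logsumexp(self.log_weights)))


@dataclass
class JointAssignmentDistribution:
    """S x S analogue of :class:`AssignmentDistribution` for a position pair."""

    log_weights: np.ndarray
    log_probs: np.ndarray

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)


@dataclass
class CoEvolRecord:
    """One CoEvol evaluation: motif, position pair, scope, statistic value."""

    pwm_id: str
    i: int
    j: int
    value: float
    n: int

    @property
    def scope(self) -> int:
        return self.j - self.i


def conditional_table(siteset: SiteSet, position: int, model: PhyloModel) -> ConditionalLikelihoodTable:
    """Tabulate log Pr(T_k | A_s) for every instance of one motif position."""
    if not 0 <= position < siteset.length:
        raise ValueError(f"position {position} outside motif of length {siteset.length}")
    cols = siteset.columns[:, position, :]  # (N, n_leaves)
    if cols.shape[1] == model.tree.n_leaves and model.tree.n_leaves == 5:
        # cached lookup: only 4**5 distinct columns exist
        table = model.column_log_table()[encode_columns(cols)]
    else:
        table = assignment_log_likelihoods(model, cols)
    return ConditionalLikelihoodTable(log_values=table, columns=cols)


def assignment_distribution(table: ConditionalLikelihoodTable) -> AssignmentDistribution:
    """Aggregate per-instance likelihoods into assignment weights and probabilities."""
    if table.n < 1:
        raise ValueError("need at least one instance")
    log_w = logsumexp(table.log_values, axis=0)
    total = logsumexp(log_w)
    if not np.isfinite(total):
        raise ValueError("all-zero likelihood table: cannot normalize weights")
    return AssignmentDistribution(log_weights=log_w, log_probs=log_w - total)


def marginal_log_likelihoods(
    table: ConditionalLikelihoodTable, dist: AssignmentDistribution
) -> np.ndarray:
    """log Pr(T_k) = log sum_s Pr(A_s) Pr(T_k | A_s), for every instance k."""
    return logsumexp(table.log_values + dist.log_probs[None, :], axis=1)


def _scaled_exp(log_table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row scaled linear table: (exp(log - rowmax), rowmax)."""
    m = log_table.max(axis=1)
    return np.exp(log_table - m[:, None]), m


def joint_distribution(
    table_i: ConditionalLikelihoodTable, table_j: ConditionalLikelihoodTable
) -> JointAssignmentDistribution:
    """Joint assignment weights W(s_i, s_j) = sum_k Pr(T_i^k|s_i) Pr(T_j^k|s_j)."""
    if table_i.n != table_j.n:
        raise ValueError("tables must describe the same instances (N mismatch)")
    ai, mi = _scaled_exp(table_i.log_values)
    aj, mj = _scaled_exp(table_j.log_values)
    c = mi + mj
    cmax = c.max()
    w = (ai * np.exp(c - cmax)[:, None]).T @ aj  # (S, S), scaled by exp(-cmax)
    with np.errstate(divide="ignore"):
        log_w = np.log(w) + cmax
    total = logsumexp(log_w)
    return JointAssignmentDistribution(log_weights=log_w, log_probs=log_w - total)


def joint_marginal_log_likelihoods(
    table_i: ConditionalLikelihoodTable,
    table_j: ConditionalLikelihoodTable,
    joint: JointAssignmentDistribution,
) -> np.ndarray:
    """log Pr(T_i^k, T_j^k) under the joint assignment distribution."""
    ai, mi = _scaled_exp(table_i.log_values)
    aj, mj = _scaled_exp(table_j.log_values)
    p = joint.probs
    inner = np.einsum("ks,st,kt->k", ai, p, aj, optimize=True)
    with np.errstate(divide="ignore"):
        return np.log(inner) + mi + mj


def coevol_score(
    table_i: ConditionalLikelihoodTable,
    table_j: ConditionalLikelihoodTable,
    *,
    pwm_id: str = "",
    i: int = 0,
    j: int = 1,
    aggregate: str = "sum",
) -> CoEvolRecord:
    """CoEvol statistic for a position pair from its two likelihood tables.

    ``aggregate="mean"`` divides by N for cross-motif pooling diagnostics;
    the default sum is what the significance machinery calibrates against
    N-matched controls.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")
    di = assignment_distribution(table_i)
    dj = assignment_distribution(table_j)
    joint = joint_distribution(table_i, table_j)
    log_joint = joint_marginal_log_likelihoods(table_i, table_j, joint)
    log_mi = marginal_log_likelihoods(table_i, di)
    log_mj = marginal_log_likelihoods(table_j, dj)
    value = float(np.sum(log_joint - log_mi - log_mj))
    if aggregate == "mean":
        value /= table_i.n
    return CoEvolRecord(pwm_id=pwm_id, i=i, j=j, value=value, n=table_i.n)


def coevol_for_pair(
    siteset: SiteSet, model: PhyloModel, i: int, j: int, **kwargs
) -> CoEvolRecord:
    """Convenience wrapper: CoEvol(i, j) straight from a SiteSet."""
    if not 0 <= i < j < siteset.length:
        raise ValueError("need 0 <= i < j < L")
    ti = conditional_table(siteset, i, model)
    tj = conditional_table(siteset, j, model)
    return coevol_score(ti, tj, pwm_id=siteset.pwm_id, i=i, j=j, **kwargs)
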
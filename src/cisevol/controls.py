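"""Null constructions for CoEvol calibration: Random, RandomContext, Shuffle.

* *Random*: pseudo-sites assembled from scattered gapless alignment columns
  of a promoter pool -- the baseline expectation.
* *RandomContext*: contiguous gapless L-column slices of promoter
  alignments, capturing context-dependent mutational structure (CpG and
  friends) without TF binding.  Because binding sites are more conserved
  than random promoter positions, RandomContext tree likelihoods are
  left-shifted relative to a Foreground; comparisons therefore match
  per-instance likelihood products into 16 equal bins spanning [-16, 0] on
  a log10 scale before re-scoring.
* *Shuffle*: keep both positions' instance sets but permute the pairing,
  destroying the within-site link while preserving each position's marginal
  composition and evolutionary signature exactly.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coevol import (
    ConditionalLikelihoodTable,
    assignment_distribution,
    coevol_score,
    marginal_log_likelihoods,
)
from .phylo import PhyloModel, assignment_log_likelihoods, encode_columns
from .sites import SiteSet

logger = logging.getLogger(__name__)

LOG10 = np.log(10.0)


@dataclass
class ColumnPool:
    """Gapless 5-species alignment columns tagged with their source offsets."""

    columns: np.ndarray  # (M, n_species)
    source_ids: np.ndarray  # (M,) alignment index
    offsets: np.ndarray  # (M,) column offset within the source alignment

    @classmethod
    def from_alignments(cls, alignments: Sequence[Sequence[str]]) -> "ColumnPool":
        from .alphabet import NUC_INDEX

        cols, sids, offs = [], [], []
        for a_idx, rows in enumerate(alignments):
            lens = {len(r) for r in rows}
            if len(lens) != 1:
                raise ValueError(f"alignment {a_idx}: rows of unequal length")
            for off in range(lens.pop()):
                chars = [r[off].upper() for r in rows]
                if all(c in NUC_INDEX for c in chars):
                    cols.append([NUC_INDEX[c] for c in chars])
                    sids.append(a_idx)
                    offs.append(off)
        if not cols:
            raise ValueError("no gapless columns in the alignments")
        return cls(
            columns=np.array(cols, dtype=np.int64),
            source_ids=np.array(sids, dtype=np.int64),
            offsets=np.array(offs, dtype=np.int64),
        )

    @property
    def size(self) -> int:
        return self.columns.shape[0]


def make_random(
    pool: ColumnPool, n_sites: int, length: int, seed: int, *, replace_across: bool = True
) -> SiteSet:
    """N pseudo-sites of L columns each, drawn from the pool.

    Columns are drawn without replacement within a site; across sites the
    draws are with replacement by default (set ``replace_across=False`` for
    small pools, which partitions a single without-replacement draw).
    """
    if pool.size < length:
        raise ValueError("pool too small for even one pseudo-site")
    rng = np.random.default_rng(seed)
    if replace_across:
        idx = np.stack([rng.choice(pool.size, size=length, replace=False) for _ in range(n_sites)])
    else:
        if pool.size < n_sites * length:
            raise ValueError("pool exhausted: need n_sites*length distinct columns")
        flat = rng.choice(pool.size, size=n_sites * length, replace=False)
        idx = flat.reshape(n_sites, length)
    cols = pool.columns[idx]  # (N, L, n_species)
    sources = [
        ",".join(f"{pool.source_ids[i]}:{pool.offsets[i]}" for i in row) for row in idx
    ]
    return SiteSet(pwm_id="Random", columns=cols, sources=sources)


def gapless_runs(rows: Sequence[str]) -> list[tuple[int, int]]:
    """Maximal gapless intervals [start, end) shared by all rows."""
    length = len(rows[0])
    ok = np.ones(length, dtype=bool)
    for r in rows:
        ok &= np.array([c not in "-." and c.upper() in "ACGT" for c in r])
    runs = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, length))
    return runs


def make_random_context(
    alignments: Sequence[Sequence[str]], n_sites: int, length: int, seed: int
) -> SiteSet:
    """N contiguous gapless L-column slices, uniform over eligible offsets."""
    from .alphabet import encode_sequence

    eligible = []  # (alignment idx, start)
    for a_idx, rows in enumerate(alignments):
        for s, e in gapless_runs(rows):
            for start in range(s, e - length + 1):
                eligible.append((a_idx, start))
    if not eligible:
        raise ValueError(f"no gapless run of length >= {length} in the alignments")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(eligible), size=n_sites)
    cols = np.empty((n_sites, length, len(alignments[0])), dtype=np.int64)
    sources = []
    for k, p in enumerate(picks):
        a_idx, start = eligible[p]
        rows = alignments[a_idx]
        slice_rows = [encode_sequence(r[start : start + length]) for r in rows]
        cols[k] = np.stack(slice_rows, axis=1)
        sources.append(f"{a_idx}:{start}")
    return SiteSet(pwm_id="RandomContext", columns=cols, sources=sources)


def shuffle_pairs(
    table_i: ConditionalLikelihoodTable,
    table_j: ConditionalLikelihoodTable,
    seed: int | np.random.Generator,
) -> tuple[ConditionalLikelihoodTable, ConditionalLikelihoodTable, np.ndarray]:
    """Shuffle control: re-pair instances by permuting position j's rows.

    Per-position assignment distributions are untouched (weight sums are
    row-order invariant); only the instance pairing changes.
    """
    if table_i.n != table_j.n:
        raise ValueError("tables must share N")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(table_j.n)
    return table_i, table_j.permuted(perm), perm


@dataclass(frozen=True)
class LikelihoodBinner:
    """16 equal bins over the log10 per-pair likelihood product range [-16, 0].

    Values below the range clamp (logged) to the lowest bin; 0 falls in the
    top bin.
    """

    low: float = -16.0
    high: float = 0.0
    n_bins: int = 16

    def bin(self, log10_values: np.ndarray) -> np.ndarray:
        v = np.asarray(log10_values, dtype=float)
        n_clamped = int(np.sum(v < self.low))
        if n_clamped:
            logger.info("LikelihoodBinner: %d values below %.1f clamped to lowest bin", n_clamped, self.low)
        width = (self.high - self.low) / self.n_bins
        idx = np.floor((v - self.low) / width).astype(np.int64)
        return np.clip(idx, 0, self.n_bins - 1)


def pair_log10_products(
    table_i: ConditionalLikelihoodTable,
    table_j: ConditionalLikelihoodTable,
    dist_i=None,
    dist_j=None,
) -> np.ndarray:
    """log10 [Pr(T_i^k) * Pr(T_j^k)] per instance, under given (or own) weights."""
    di = dist_i if dist_i is not None else assignment_distribution(table_i)
    dj = dist_j if dist_j is not None else assignment_distribution(table_j)
    return (marginal_log_likelihoods(table_i, di) + marginal_log_likelihoods(table_j, dj)) / LOG10


def match_random_context(
    foreground_log10: np.ndarray,
    candidate_log10: np.ndarray,
    binner: LikelihoodBinner,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each foreground instance, pick one candidate from the same bin.

    Draws are uniform within the bin, with replacement across foreground
    instances.  Empty bins fall back to the nearest non-empty bin (logged).
    Returns candidate indices, one per foreground instance.
    """
    fg_bins = binner.bin(foreground_log10)
    cand_bins = binner.bin(candidate_log10)
    members = [np.flatnonzero(cand_bins == b) for b in range(binner.n_bins)]
    non_empty = [b for b in range(binner.n_bins) if len(members[b])]
    if not non_empty:
        raise ValueError("no candidates at all")
    out = np.empty(len(fg_bins), dtype=np.int64)
    for k, b in enumerate(fg_bins):
        pool = members[b]
        if len(pool) == 0:
            nearest = min(non_empty, key=lambda x: abs(x - b))
            logger.info("match_random_context: bin %d empty, using nearest bin %d", b, nearest)
            pool = members[nearest]
        out[k] = pool[rng.integers(0, len(pool))]
    return out


@dataclass
class RandomContextCandidates:
    """Pre-scored candidate column pairs at one scope, pool-weighted.

    ``table_i``/``table_j`` hold conditional likelihoods for every candidate
    pair; ``log10_products`` are scored under assignment weights estimated
    from the full candidate pool (the default weighting for binning).
    """

    scope: int
    table_i: ConditionalLikelihoodTable
    table_j: ConditionalLikelihoodTable
    log10_products: np.ndarray


def random_context_candidates(
    rc_sites: SiteSet, scope: int, model: PhyloModel
) -> RandomContextCandidates:
    """Pool all position pairs at the given scope across RandomContext sites."""
    if scope < 1 or scope >= rc_sites.length:
        raise ValueError("scope must satisfy 1 <= scope < L")
    ci, cj = [], []
    for a in range(rc_sites.length - scope):
        ci.append(rc_sites.columns[:, a, :])
        cj.append(rc_sites.columns[:, a + scope, :])
    ci = np.concatenate(ci)
    cj = np.concatenate(cj)

    def table_for(cols):
        if cols.shape[1] == model.tree.n_leaves == 5:
            lv = model.column_log_table()[encode_columns(cols)]
        else:
            lv = assignment_log_likelihoods(model, cols)
        return ConditionalLikelihoodTable(log_values=lv, columns=cols)

    ti = table_for(ci)
    tj = table_for(cj)
    return RandomContextCandidates(
        scope=scope, table_i=ti, table_j=tj, log10_products=pair_log10_products(ti, tj)
    )


def matched_random_context_coevol(
    fg_table_i: ConditionalLikelihoodTable,
    fg_table_j: ConditionalLikelihoodTable,
    candidates: RandomContextCandidates,
    seed: int,
    n_reps: int = 100,
    binner: LikelihoodBinner | None = None,
) -> np.ndarray:
    """Likelihood-matched RandomContext CoEvol values for one foreground pair.

    Repeats the bin-matched selection ``n_reps`` times; each selection of N
    candidate pairs is re-scored self-consistently (assignment weights
    re-estimated from the selected instances).
    """
    if binner is None:
        binner = LikelihoodBinner()
    fg_log10 = pair_log10_products(fg_table_i, fg_table_j)
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for r in range(n_reps):
        idx = match_random_context(fg_log10, candidates.log10_products, binner, rng)
        sel_i = candidates.table_i.permuted(idx)
        sel_j = candidates.table_j.permuted(idx)
        out[r] = coevol_score(sel_i, sel_j).value
    return out


def shuffle_null_coevols(
    table_i: ConditionalLikelihoodTable,
    table_j: ConditionalLikelihoodTable,
    n_shuffles: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """CoEvol values of ``n_shuffles`` re-pairings (the Shuffle null sample).

    Equivalent to scoring :func:`shuffle_pairs` output repeatedly, but the
    per-position marginal distributions and likelihoods -- which a
    permutation provably leaves unchanged -- are computed once.
    """
    from .coevol import joint_distribution, joint_marginal_log_likelihoods

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    di = assignment_distribution(table_i)
    dj = assignment_distribution(table_j)
    log_mi = marginal_log_likelihoods(table_i, di)
    log_mj = marginal_log_likelihoods(table_j, dj)
    base = float(np.sum(log_mi) + np.sum(log_mj))
    out = np.empty(n_shuffles)
    for r in range(n_shuffles):
        perm = rng.permutation(table_j.n)
        tj = table_j.permuted(perm)
        joint = joint_distribution(table_i, tj)
        lj = joint_marginal_log_likelihoods(table_i, tj, joint)
        out[r] = float(np.sum(lj)) - base
    return out
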
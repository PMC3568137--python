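"""Synthetic binding-site evolution on the five-taxon tree.

The generator evolves N independent L-column sites along the species tree
under HKY85, with two optional departures from site-independence that mimic
the biological mechanisms the co-evolution statistic is meant to detect or
be confounded by:

* *preferred nucleotide pairs*: a coupled position pair (i, j) carries a set
  of preferred base combinations; any proposed substitution that would move
  the pair out of the preferred set is rejected with probability 1 - lambda
  (lambda = 1: no coupling; lambda = 0: hard constraint);
* *CpG hypermutation*: the C->T rate is multiplied when the C is followed by
  a G, and symmetrically G->A when preceded by a C (the reverse-strand view
  of the same CG dinucleotide).

Each branch is simulated by an event-driven (thinning) scheme over the full
L-mer so the dinucleotide context stays current.  Per-(site, branch) random
streams are split from the master seed with counter-based spawn keys, so
enlarging N never shifts earlier draws.  True ancestral states are returned
for oracle tests only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabet import A, C, G, T, BASE_CLASS
from .phylo import PhyloModel
from .sites import SiteSet


@dataclass(frozen=True)
class Coupling:
    """Preferred-pair coupling between positions i < j.

    ``preferred`` is a set of (base_i, base_j) integer pairs; ``strength``
    is the acceptance probability lambda for proposals leaving the set.
    """

    i: int
    j: int
    preferred: frozenset
    strength: float  # lambda in [0, 1]; 1 = no coupling

    def __post_init__(self):
        object.__setattr__(self, "preferred", frozenset(tuple(map(int, p)) for p in self.preferred))
        if self.i == self.j:
            raise ValueError("coupled positions must be distinct")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength (lambda) must be in [0, 1]")
        if not self.preferred:
            raise ValueError("preferred set must be non-empty")


@dataclass
class SimulationConfig:
    phylo: PhyloModel
    n_sites: int = 237  # average number of retained binding sites per TF
    length: int = 12    # median PWM length in the motif collection
    root_profile: np.ndarray | None = None  # (L, 4); default: stationary pi per column
    couplings: Sequence[Coupling] = field(default_factory=tuple)
    cpg_rate: float = 1.0  # multiplier >= 1 for C->T in CpG context (both strands)
    seed: int = 0

    def __post_init__(self):
        if self.cpg_rate < 1.0:
            raise ValueError("cpg_rate multiplier must be >= 1")
        for c in self.couplings:
            if not (0 <= c.i < self.length and 0 <= c.j < self.length):
                raise ValueError("coupled positions must be < length")


@dataclass
class SimulationResult:
    siteset: SiteSet
    #: (N, n_internal, L) true ancestral bases, internal nodes in post-order
    ancestral: np.ndarray


def _site_rates(seq: np.ndarray, model: PhyloModel, cpg_rate: float) -> np.ndarray:
    """(L, 4) substitution rates out of the current L-mer state."""
    pi = model.hky.pi
    kappa = model.hky.kappa
    mu = 2.0 * kappa * (pi[A] * pi[G] + pi[C] * pi[T]) + 2.0 * (pi[A] + pi[G]) * (pi[C] + pi[T])
    beta = 1.0 / mu
    L = len(seq)
    rates = np.empty((L, 4))
    for b in range(4):
        coef = np.where(BASE_CLASS[seq] == BASE_CLASS[b], kappa, 1.0)
        rates[:, b] = beta * coef * pi[b]
    rates[np.arange(L), seq] = 0.0
    if cpg_rate > 1.0:
        for p in range(L):
            if seq[p] == C and p + 1 < L and seq[p + 1] == G:
                rates[p, T] *= cpg_rate  # CpG: C -> T
            if seq[p] == G and p - 1 >= 0 and seq[p - 1] == C:
                rates[p, A] *= cpg_rate  # CpG on the reverse strand: G -> A
    return rates


def _evolve_branch(
    seq: np.ndarray,
    t: float,
    model: PhyloModel,
    couplings: Sequence[Coupling],
    cpg_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    seq = seq.copy()
    by_pos: dict[int, list[Coupling]] = {}
    for c in couplings:
        by_pos.setdefault(c.i, []).append(c)
        by_pos.setdefault(c.j, []).append(c)
    elapsed = 0.0
    while True:
        rates = _site_rates(seq, model, cpg_rate)
        total = rates.sum()
        if total <= 0:
            break
        elapsed += rng.exponential(1.0 / total)
        if elapsed >= t:
            break
        flat = rates.ravel() / total
        ev = rng.choice(flat.size, p=flat)
        pos, new_base = divmod(ev, 4)
        accept = True
        for c in by_pos.get(pos, ()):  # rejection makes the preferred set sticky
            pair = (new_base, seq[c.j]) if pos == c.i else (seq[c.i], new_base)
            if tuple(map(int, pair)) not in c.preferred and rng.random() > c.strength:
                accept = False
                break
        if accept:
            seq[pos] = new_base
    return seq


def _draw_root(
    profile: np.ndarray, couplings: Sequence[Coupling], rng: np.random.Generator
) -> np.ndarray:
    L = profile.shape[0]
    seq = np.array([rng.choice(4, p=profile[p]) for p in range(L)])
    for c in couplings:
        for _ in range(10_000):
            if (int(seq[c.i]), int(seq[c.j])) in c.preferred or rng.random() < c.strength:
                break
            seq[c.i] = rng.choice(4, p=profile[c.i])
            seq[c.j] = rng.choice(4, p=profile[c.j])
        else:
            raise RuntimeError("could not draw a root sequence satisfying the coupling")
    return seq


def simulate_siteset(config: SimulationConfig) -> SimulationResult:
    """Evolve N sites on the tree; returns the leaf SiteSet plus ancestral truth."""
    model = config.phylo
    tree = model.tree
    L = config.length
    profile = config.root_profile
    if profile is None:
        profile = np.tile(model.hky.pi, (L, 1))
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (L, 4):
        raise ValueError("root_profile must be (L, 4)")
    profile = profile / profile.sum(axis=1, keepdims=True)

    n = config.n_sites
    leaf_cols = np.empty((n, L, tree.n_leaves), dtype=np.int64)
    anc = np.empty((n, tree.n_internal, L), dtype=np.int64)
    for k in range(n):
        root_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(k, 0))
        )
        states: dict[int, np.ndarray] = {}
        states[tree.root_index] = _draw_root(profile, config.couplings, root_rng)
        # branches in pre-order: parent state always available
        for b in range(tree.n_branches):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(k, b + 1))
            )
            parent_state = states[tree.branch_parent[b]]
            child = _evolve_branch(
                parent_state, tree.branch_lengths[b], model, config.couplings, config.cpg_rate, rng
            )
            row = tree.branch_child_leaf[b]
            if row >= 0:
                leaf_cols[k, :, row] = child
            else:
                states[tree.branch_child_internal[b]] = child
        for m in range(tree.n_internal):
            anc[k, m, :] = states[m]
    siteset = SiteSet(pwm_id="sim", columns=leaf_cols)
    return SimulationResult(siteset=siteset, ancestral=anc)


def simulate_promoter_alignments(
    model: PhyloModel,
    n_promoters: int,
    length: int,
    seed: int,
    cpg_rate: float = 1.0,
) -> list[list[str]]:
    """Simulate gapless 5-species promoter alignments (for control pools)."""
    from .alphabet import decode_sequence

    out = []
    for p in range(n_promoters):
        cfg = SimulationConfig(
            phylo=model,
            n_sites=1,
            length=length,
            cpg_rate=cpg_rate,
            seed=int(np.random.SeedSequence(entropy=seed, spawn_key=(p,)).generate_state(1)[0] % (2**31)),
        )
        res = simulate_siteset(cfg)
        cols = res.siteset.columns[0]  # (L, 5)
        out.append([decode_sequence(cols[:, s]) for s in range(cols.shape[1])])
    return out


def null_column_pool(model: PhyloModel, pool_size: int, seed: int) -> SiteSet:
    """Pool of independently evolved single columns (for Random-control draws)."""
    res = simulate_siteset(
        SimulationConfig(phylo=model, n_sites=pool_size, length=1, seed=seed)
    )
    return res.siteset


def null_coevol_sample(
    model: PhyloModel,
    n_pairs: int,
    n_instances: int,
    seed: int,
    pool: SiteSet | None = None,
    pool_size: int = 20_000,
) -> np.ndarray:
    """Random-control CoEvol sample under the null (independent columns).

    ``n_pairs`` pseudo position pairs are assembled by drawing
    ``n_instances`` column pairs each from a pool of independently evolved
    columns (generated here unless supplied) and scored with the full
    CoEvol machinery.  This is the distribution the Random control
    calibrates against (e.g. its 99th-percentile threshold T99).
    """
    from .coevol import ConditionalLikelihoodTable, coevol_score
    from .phylo import encode_columns

    if pool is None:
        pool_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(0,)).generate_state(1)[0] % 2**31
        )
        pool = null_column_pool(model, pool_size, pool_seed)
    cols = pool.columns[:, 0, :]
    pool_codes = encode_columns(cols)
    cll = model.column_log_table()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    out = np.empty(n_pairs)
    m = cols.shape[0]
    for p in range(n_pairs):
        idx = rng.integers(0, m, size=(n_instances, 2))
        ti = ConditionalLikelihoodTable(log_values=cll[pool_codes[idx[:, 0]]], columns=cols[idx[:, 0]])
        tj = ConditionalLikelihoodTable(log_values=cll[pool_codes[idx[:, 1]]], columns=cols[idx[:, 1]])
        out[p] = coevol_score(ti, tj).value
    return out
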
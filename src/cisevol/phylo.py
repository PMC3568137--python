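"""Phylogenetic machinery: HKY85 model, rooted species tree, likelihoods.

The analysis operates on a rooted binary tree for five mammals (human,
chimp, mouse, rat, dog by default) evolving under the HKY85 substitution
model.  The quantity everything downstream is built from is the likelihood
of one gapless alignment column *given a complete ancestral assignment* --
one concrete base at every internal node -- which is simply the root prior
times the product of per-branch transition probabilities.  With K internal
nodes there are 4**K assignments (256 for the five-taxon tree); the engine
below enumerates them generically so that tiny two-taxon toys (4
assignments) are handled by the same code paths as the full tree.

Branches carry a deterministic 1-based index assigned by pre-order
traversal; internal nodes are ordered by post-order traversal, so for the
default topology ``(((human,chimp),(mouse,rat)),dog)`` the assignment tuple
reads (anc(human,chimp), anc(mouse,rat), anc(primates,rodents), root).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import yaml
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alphabet import BASE_CLASS, encode_sequence

DEFAULT_TAXA = ("human", "chimp", "mouse", "rat", "dog")
DEFAULT_NEWICK = "(((human:0.007,chimp:0.008):0.09,(mouse:0.09,rat:0.08):0.27):0.02,dog:0.25);"


@dataclass(frozen=True)
class HKYModel:
    """HKY85 substitution model: transition/transversion ratio and base frequencies.

    ``kappa`` is the transition/transversion rate ratio (dimensionless, > 0)
    and ``pi`` the equilibrium frequencies in A,C,G,T order.  The rate
    matrix is scaled so branch lengths are in expected substitutions/site.
    """

    kappa: float
    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (4,):
            raise ValueError("pi must be a 4-vector")
        if np.any(pi <= 0):
            raise ValueError("all equilibrium frequencies must be positive")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1 within 1e-12")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")

    def rate_matrix(self) -> np.ndarray:
        """Scaled HKY rate matrix Q with mean rate 1 at stationarity."""
        pi = self.pi
        q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                coef = self.kappa if BASE_CLASS[i] == BASE_CLASS[j] else 1.0
                q[i, j] = coef * pi[j]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(pi, np.diag(q))
        return q / mu


def hky_transition_matrix(model: HKYModel, t: float) -> np.ndarray:
    """Closed-form HKY85 transition matrix P(t), row-stochastic.

    P[u, v] = Pr(child = v | parent = u) over a branch of length ``t``
    substitutions/site.  Uses the standard spectral solution rather than a
    generic matrix exponential.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    pi = model.pi
    kappa = model.kappa
    pi_r = pi[0] + pi[2]
    pi_y = pi[1] + pi[3]
    # mean substitution rate of the unscaled matrix; d = beta*t is the
    # rescaled time so that t is in substitutions/site
    mu = 2.0 * kappa * (pi[0] * pi[2] + pi[1] * pi[3]) + 2.0 * pi_r * pi_y
    d = t / mu
    e2 = np.exp(-d)
    p = np.empty((4, 4))
    for j in range(4):
        big = pi_r if BASE_CLASS[j] == 0 else pi_y
        e3 = np.exp(-d * (1.0 + big * (kappa - 1.0)))
        for i in range(4):
            if i == j:
                p[i, j] = pi[j] + pi[j] * (1.0 / big - 1.0) * e2 + ((big - pi[j]) / big) * e3
            elif BASE_CLASS[i] == BASE_CLASS[j]:
                p[i, j] = pi[j] + pi[j] * (1.0 / big - 1.0) * e2 - (pi[j] / big) * e3
            else:
                p[i, j] = pi[j] * (1.0 - e2)
    return np.clip(p, 0.0, 1.0)


class PhyloTree:
    """Rooted tree with labelled leaves, branch lengths, and fixed indexing.

    Leaves map to alignment rows via ``taxa`` (row order); branches get a
    deterministic 1..B index by pre-order traversal and internal nodes a
    post-order position used for ancestral-assignment encoding.
    """

    def __init__(self, newick: str, taxa: Sequence[str] | None = None):
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        self._dtree = dtree
        nodes_pre = list(dtree.preorder_node_iter())
        root = dtree.seed_node
        leaves = [n for n in nodes_pre if n.is_leaf()]
        internal = [n for n in dtree.postorder_internal_node_iter()]
        labels = [lf.taxon.label for lf in leaves]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        if taxa is None:
            taxa = tuple(labels)  # order of appearance in the newick string
        else:
            taxa = tuple(taxa)
            if set(taxa) != set(labels):
                raise ValueError("taxa do not match newick leaf labels")
        self.taxa = taxa
        row_of = {name: i for i, name in enumerate(taxa)}

        self._internal_pos = {id(n): k for k, n in enumerate(internal)}
        self.n_leaves = len(leaves)
        self.n_internal = len(internal)
        self.root_index = self._internal_pos[id(root)]

        # branches indexed 1..B by pre-order, identified by their child node
        branch_children = [n for n in nodes_pre if n is not root]
        self.n_branches = len(branch_children)
        lengths = []
        parent_idx = []
        child_leaf_row = []   # leaf row, or -1 for internal children
        child_internal = []   # internal index, or -1 for leaf children
        for n in branch_children:
            el = n.edge.length
            if el is None:
                el = 0.0
            if el < 0:
                raise ValueError("negative branch length")
            lengths.append(float(el))
            parent_idx.append(self._internal_pos[id(n.parent_node)])
            if n.is_leaf():
                child_leaf_row.append(row_of[n.taxon.label])
                child_internal.append(-1)
            else:
                child_leaf_row.append(-1)
                child_internal.append(self._internal_pos[id(n)])
        self.branch_lengths = np.array(lengths)
        self.branch_parent = np.array(parent_idx, dtype=np.int64)
        self.branch_child_leaf = np.array(child_leaf_row, dtype=np.int64)
        self.branch_child_internal = np.array(child_internal, dtype=np.int64)

    @classmethod
    def default(cls) -> "PhyloTree":
        return cls(DEFAULT_NEWICK, taxa=DEFAULT_TAXA)

    @property
    def n_assignments(self) -> int:
        return 4 ** self.n_internal

    def with_branch_lengths(self, lengths: Sequence[float]) -> "PhyloTree":
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (self.n_branches,):
            raise ValueError("wrong number of branch lengths")
        tree = PhyloTree(self.to_newick(), taxa=self.taxa)
        # pre-order branch order is preserved by to_newick/re-parse
        k = 0
        for n in tree._dtree.preorder_node_iter():
            if n is tree._dtree.seed_node:
                continue
            n.edge.length = float(lengths[k])
            k += 1
        return PhyloTree(tree.to_newick(), taxa=self.taxa)

    def to_newick(self) -> str:
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()


def assignment_tuples(n_internal: int) -> np.ndarray:
    """All 4**K ancestral assignments as a (S, K) base array.

    Index s encodes the tuple big-endian: the first internal node (post-order
    position 0) occupies the most significant base-4 digit.
    """
    k = n_internal
    s = 4 ** k
    idx = np.arange(s)
    out = np.empty((s, k), dtype=np.int64)
    for m in range(k):
        out[:, m] = (idx // 4 ** (k - 1 - m)) % 4
    return out


def assignment_index(bases: Sequence[int]) -> int:
    """Encode an internal-node base tuple as its assignment index."""
    idx = 0
    for b in bases:
        idx = idx * 4 + int(b)
    return idx


def branch_transition_matrices(tree: PhyloTree, model: HKYModel) -> np.ndarray:
    """Per-branch 4x4 transition matrices, stacked in branch-index order."""
    return np.stack([hky_transition_matrix(model, t) for t in tree.branch_lengths])


@dataclass
class PhyloModel:
    """Tree + HKY model with cached per-branch matrices and column tables."""

    tree: PhyloTree
    hky: HKYModel
    _tmats: np.ndarray | None = field(default=None, repr=False)
    _column_table: np.ndarray | None = field(default=None, repr=False)

    @property
    def transition_matrices(self) -> np.ndarray:
        if self._tmats is None:
            self._tmats = branch_transition_matrices(self.tree, self.hky)
        return self._tmats

    def column_log_table(self) -> np.ndarray:
        """Log likelihood of every possible leaf column under every assignment.

        Shape (4**n_leaves, 4**n_internal); columns are encoded big-endian in
        leaf-row order.  Cached: downstream code looks likelihoods up rather
        than recomputing per alignment column.
        """
        if self._column_table is None:
            all_cols = assignment_tuples(self.tree.n_leaves)  # reuse the encoder
            self._column_table = assignment_log_likelihoods(self, all_cols)
        return self._column_table

    def to_config(self) -> str:
        """Serialize (kappa, pi, newick-with-lengths) as a YAML block."""
        return yaml.safe_dump(
            {
                "kappa": float(self.hky.kappa),
                "pi": [float(x) for x in self.hky.pi],
                "tree": self.tree.to_newick(),
                "taxa": list(self.tree.taxa),
            },
            sort_keys=False,
        )

    @classmethod
    def from_config(cls, text: str) -> "PhyloModel":
        doc = yaml.safe_load(text)
        tree = PhyloTree(doc["tree"], taxa=doc.get("taxa"))
        return cls(tree=tree, hky=HKYModel(kappa=doc["kappa"], pi=np.asarray(doc["pi"])))

    @classmethod
    def default(cls, kappa: float = 2.5, pi: Sequence[float] = (0.3, 0.2, 0.2, 0.3)) -> "PhyloModel":
        return cls(tree=PhyloTree.default(), hky=HKYModel(kappa=kappa, pi=np.asarray(pi, dtype=float)))


def encode_columns(columns: np.ndarray) -> np.ndarray:
    """Encode (N, n_leaves) base arrays as integer column codes (big-endian)."""
    columns = np.asarray(columns)
    n_leaves = columns.shape[1]
    weights = 4 ** np.arange(n_leaves - 1, -1, -1)
    return columns @ weights


def tree_log_likelihood_given_assignment(
    model: PhyloModel, column: Sequence[int], assignment: Sequence[int]
) -> float:
    """log Pr(column | assignment): root prior times branch transitions.

    Direct scalar implementation of the product definition; the vectorized
    table builder below is the workhorse.
    """
    tree = model.tree
    column = np.asarray(column)
    assignment = np.asarray(assignment)
    if column.shape != (tree.n_leaves,):
        raise ValueError("column has wrong number of leaves")
    if assignment.shape != (tree.n_internal,):
        raise ValueError("assignment must specify every internal node")
    tmats = model.transition_matrices
    ll = np.log(model.hky.pi[assignment[tree.root_index]])
    for b in range(tree.n_branches):
        parent = assignment[tree.branch_parent[b]]
        if tree.branch_child_leaf[b] >= 0:
            child = column[tree.branch_child_leaf[b]]
        else:
            child = assignment[tree.branch_child_internal[b]]
        ll += np.log(tmats[b, parent, child])
    return float(ll)


def assignment_log_likelihoods(model: PhyloModel, columns: np.ndarray) -> np.ndarray:
    """log Pr(column_k | assignment_s) for all k, s; shape (N, S)."""
    tree = model.tree
    columns = np.asarray(columns)
    if columns.ndim == 1:
        columns = columns[None, :]
    n = columns.shape[0]
    with np.errstate(divide="ignore"):
        logp = np.log(model.transition_matrices)
        logpi = np.log(model.hky.pi)
    assigns = assignment_tuples(tree.n_internal)  # (S, K)
    base = logpi[assigns[:, tree.root_index]]
    for b in range(tree.n_branches):
        par = assigns[:, tree.branch_parent[b]]
        ci = tree.branch_child_internal[b]
        if ci >= 0:
            base = base + logp[b, par, assigns[:, ci]]
    out = np.broadcast_to(base, (n, base.shape[0])).copy()
    for b in range(tree.n_branches):
        row = tree.branch_child_leaf[b]
        if row < 0:
            continue
        par = assigns[:, tree.branch_parent[b]]
        m = logp[b, par, :]  # (S, 4)
        out += m[:, columns[:, row]].T
    return out


def pruning_log_likelihood(model: PhyloModel, columns: np.ndarray) -> np.ndarray:
    """Column log likelihoods by Felsenstein pruning (root prior = pi).

    Mathematically equal to logsumexp over all ancestral assignments of
    ``assignment_log_likelihoods``; used for parameter estimation and as the
    independent cross-check of the enumeration path.
    """
    tree = model.tree
    columns = np.asarray(columns)
    if columns.ndim == 1:
        columns = columns[None, :]
    n = columns.shape[0]
    tmats = model.transition_matrices
    # children of each internal node, in branch terms
    partial = [None] * tree.n_internal  # (N, 4) conditional likelihood, scaled
    scale = [None] * tree.n_internal    # (N,) log scaling factors
    for m in range(tree.n_internal):    # post-order: children come first
        p = np.ones((n, 4))
        s = np.zeros(n)
        for b in range(tree.n_branches):
            if tree.branch_parent[b] != m:
                continue
            row = tree.branch_child_leaf[b]
            if row >= 0:
                like = tmats[b][:, columns[:, row]].T  # (N, 4)
            else:
                ci = tree.branch_child_internal[b]
                like = partial[ci] @ tmats[b].T
                s = s + scale[ci]
            p = p * like
            mx = p.max(axis=1)
            mx[mx == 0] = 1.0
            p = p / mx[:, None]
            s = s + np.log(mx)
        partial[m] = p
        scale[m] = s
    root = tree.root_index
    return np.log(partial[root] @ model.hky.pi) + scale[root]


@dataclass
class PhyloFit:
    model: PhyloModel
    log_likelihood: float
    n_columns: int


def alignment_to_columns(sequences: Sequence[str]) -> np.ndarray:
    """Convert equal-length gapless sequences (rows) to an (N, n_rows) array."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    rows = [encode_sequence(s) for s in sequences]
    return np.stack(rows, axis=1)


def estimate_phylo_params(
    sequences: Sequence[str],
    topology: PhyloTree | None = None,
    *,
    kappa_bounds: tuple[float, float] = (0.1, 100.0),
    length_bounds: tuple[float, float] = (1e-6, 10.0),
    initial_kappa: float = 2.0,
    initial_length: float = 0.1,
) -> PhyloFit:
    """ML estimate of kappa and branch lengths from a concatenated alignment.

    pi is taken from observed base frequencies; kappa and the branch lengths
    maximize the summed pruning log likelihood via bounded L-BFGS-B on log
    parameters.  Unique column patterns are collapsed first, so cost is
    bounded by 4**n_leaves patterns regardless of alignment length.
    """
    if topology is None:
        topology = PhyloTree.default()
    columns = alignment_to_columns(sequences)
    if columns.shape[0] < 2 or len(np.unique(encode_columns(columns))) < 2:
        import warnings

        warnings.warn("fewer than 2 distinct columns; branch lengths may collapse to 0")
    # add-half smoothing keeps pi strictly positive on degenerate alignments
    counts_pi = np.bincount(columns.ravel(), minlength=4).astype(float) + 0.5
    pi = counts_pi / counts_pi.sum()
    patterns, counts = np.unique(columns, axis=0, return_counts=True)

    nb = topology.n_branches
    lo = np.concatenate([[np.log(kappa_bounds[0])], np.full(nb, np.log(length_bounds[0]))])
    hi = np.concatenate([[np.log(kappa_bounds[1])], np.full(nb, np.log(length_bounds[1]))])
    x0 = np.concatenate([[np.log(initial_kappa)], np.full(nb, np.log(initial_length))])

    def negloglik(x):
        kappa = np.exp(x[0])
        lengths = np.exp(x[1:])
        model = PhyloModel(tree=topology.with_branch_lengths(lengths), hky=HKYModel(kappa, pi))
        ll = pruning_log_likelihood(model, patterns)
        return -float(counts @ ll)

    res = minimize(negloglik, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
    kappa = float(np.exp(res.x[0]))
    lengths = np.exp(res.x[1:])
    model = PhyloModel(tree=topology.with_branch_lengths(lengths), hky=HKYModel(kappa, pi))
    return PhyloFit(model=model, log_likelihood=-float(res.fun), n_columns=int(columns.shape[0]))


def read_fasta_alignment(path_or_handle, taxa: Sequence[str] = DEFAULT_TAXA) -> list[str]:
    """Read a FASTA alignment and return sequences in the given taxon order."""
    from Bio import SeqIO

    handle = path_or_handle
    if isinstance(path_or_handle, (str, bytes)):
        handle = open(path_or_handle)
    try:
        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(handle, "fasta")}
    finally:
        if handle is not path_or_handle:
            handle.close()
    missing = [t for t in taxa if t not in records]
    if missing:
        raise ValueError(f"alignment is missing taxa: {missing}")
    return [records[t] for t in taxa]
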
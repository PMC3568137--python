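"""Binding-site inputs: PWMs, alignment archives, and motif scanning.

A *site archive* stores one binding site per block of exactly five
equal-length gapless sequence lines (human, chimp, mouse, rat, dog order),
blocks separated by blank lines.  ``pwm_scan`` finds motif matches with an
exact tail p-value computed by dynamic programming over the discretized
log-odds score distribution under the background model -- needed because
the match threshold (1e-9 by default downstream) is far beyond what
sampling could resolve.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .alphabet import NUCLEOTIDES, decode_sequence, encode_sequence, reverse_complement

N_SPECIES = 5
SPECIES = ("human", "chimp", "mouse", "rat", "dog")


@dataclass
class PWM:
    """A 4 x L base-preference matrix (counts or probabilities) with an id."""

    id: str
    matrix: np.ndarray  # (4, L), rows in A,C,G,T order

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"PWM {self.id}: matrix must be 4 x L")
        if self.matrix.shape[1] < 1:
            raise ValueError(f"PWM {self.id}: L must be >= 1")
        if np.any(self.matrix < 0):
            raise ValueError(f"PWM {self.id}: negative entries")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def probabilities(self, pseudocount_fraction: float = 0.01) -> np.ndarray:
        """Column-normalized probabilities after pseudocount smoothing.

        Zero counts are smoothed by adding ``pseudocount_fraction`` of each
        column total (split evenly across the 4 bases) before normalizing.
        """
        m = self.matrix.copy()
        totals = m.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError(f"PWM {self.id}: empty column")
        m = m + pseudocount_fraction * totals / 4.0
        return m / m.sum(axis=0)

    def log_odds(self, background: np.ndarray | None = None, **kwargs) -> np.ndarray:
        if background is None:
            background = np.full(4, 0.25)
        p = self.probabilities(**kwargs)
        return np.log(p / np.asarray(background)[:, None])


def read_jaspar(handle) -> list[PWM]:
    """Parse a JASPAR flat file (or minimal 4-row numeric format) into PWMs."""
    if isinstance(handle, str):
        handle = io.StringIO(handle)
    text = handle.read()
    try:
        records = bio_motifs.parse(io.StringIO(text), "jaspar")
        out = []
        for m in records:
            counts = np.array([m.counts[b] for b in NUCLEOTIDES], dtype=float)
            name = m.matrix_id or m.name
            out.append(PWM(id=name, matrix=counts))
        if out:
            return out
    except Exception:
        pass
    # minimal format: optional '>id' header then 4 whitespace-separated rows
    out = []
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    idx = 0
    counter = 0
    while idx < len(lines):
        if lines[idx].startswith(">"):
            name = lines[idx][1:].split()[0]
            idx += 1
        else:
            counter += 1
            name = f"motif{counter}"
        rows = []
        for r in range(4):
            if idx >= len(lines) or lines[idx].startswith(">"):
                raise ValueError(f"PWM {name}: expected 4 numeric rows")
            toks = lines[idx].replace(",", " ").replace("[", " ").replace("]", " ").split()
            if toks and toks[0].upper() in NUCLEOTIDES:
                toks = toks[1:]
            try:
                rows.append([float(x) for x in toks])
            except ValueError:
                raise ValueError(f"PWM {name}: non-numeric row {lines[idx]!r}") from None
            idx += 1
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"PWM {name}: row-length mismatch {sorted(widths)}")
        out.append(PWM(id=name, matrix=np.array(rows)))
    return out


def write_jaspar(pwms: Iterable[PWM], handle) -> None:
    for pwm in pwms:
        handle.write(f">{pwm.id}\n")
        for r, base in enumerate(NUCLEOTIDES):
            vals = " ".join(repr(float(v)) for v in pwm.matrix[r])
            handle.write(f"{base} [ {vals} ]\n")


@dataclass
class SiteSet:
    """N gapless 5-species alignment instances of an L-column binding site.

    ``columns`` has shape (N, L, n_species) with integer base codes; row
    order within each column follows :data:`SPECIES`.  Reverse-strand
    matches are stored already reverse-complemented into motif orientation.
    """

    pwm_id: str
    columns: np.ndarray
    strands: list[str] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=np.int64)
        if self.columns.ndim != 2 + 1:
            raise ValueError("columns must be (N, L, n_species)")
        n = self.columns.shape[0]
        if not self.strands:
            self.strands = ["+"] * n
        if not self.sources:
            self.sources = [""] * n

    @property
    def n(self) -> int:
        return self.columns.shape[0]

    @property
    def length(self) -> int:
        return self.columns.shape[1]

    @property
    def n_species(self) -> int:
        return self.columns.shape[2]

    def instance(self, k: int) -> list[str]:
        """The k-th site as species-ordered sequence strings."""
        return [decode_sequence(self.columns[k, :, s]) for s in range(self.n_species)]

    def subset(self, idx) -> "SiteSet":
        idx = np.asarray(idx)
        return SiteSet(
            pwm_id=self.pwm_id,
            columns=self.columns[idx],
            strands=[self.strands[int(i)] for i in idx],
            sources=[self.sources[int(i)] for i in idx],
        )


def read_site_archive(handle, pwm_id: str = "") -> SiteSet:
    """Read blank-line-separated blocks of 5 aligned sequences into a SiteSet."""
    if isinstance(handle, str):
        handle = io.StringIO(handle)
    blocks: list[list[str]] = []
    current: list[str] = []
    for raw in handle:
        line = raw.strip()
        if not line:
            if current:
                blocks.append(current)
                current = []
            continue
        current.append(line)
    if current:
        blocks.append(current)
    if not blocks:
        raise ValueError("empty site archive")
    sites = []
    length = None
    for bi, block in enumerate(blocks, start=1):
        if len(block) != N_SPECIES:
            raise ValueError(f"block {bi}: expected {N_SPECIES} sequence lines, got {len(block)}")
        if any("-" in s or "." in s for s in block):
            raise ValueError(f"block {bi}: gap characters are not allowed")
        lens = {len(s) for s in block}
        if len(lens) != 1:
            raise ValueError(f"block {bi}: unequal sequence lengths {sorted(lens)}")
        l = lens.pop()
        if length is None:
            length = l
        elif l != length:
            raise ValueError(f"block {bi}: length {l} differs from earlier blocks ({length})")
        try:
            rows = [encode_sequence(s) for s in block]
        except ValueError as e:
            raise ValueError(f"block {bi}: {e}") from None
        sites.append(np.stack(rows, axis=1))  # (L, n_species)
    return SiteSet(pwm_id=pwm_id, columns=np.stack(sites))


def write_site_archive(siteset: SiteSet, handle) -> None:
    for k in range(siteset.n):
        for row in siteset.instance(k):
            handle.write(row + "\n")
        handle.write("\n")


@dataclass
class PwmMatch:
    """One PWM hit: 0-based offset, strand, log-odds score, exact p-value."""

    position: int
    strand: str
    score: float
    pvalue: float


class ScoreDistribution:
    """Exact PWM score distribution under a background, on an integer lattice.

    Log-odds scores are rounded to multiples of ``resolution`` and the full
    distribution of the L-column sum under the i.i.d. background is built by
    dynamic programming (convolution per column); p-values are survival
    probabilities of the lattice distribution.
    """

    def __init__(self, pwm: PWM, background: np.ndarray | None = None, resolution: float = 1e-3):
        if background is None:
            background = np.full(4, 0.25)
        self.background = np.asarray(background, dtype=float)
        self.resolution = float(resolution)
        lodds = pwm.log_odds(self.background)
        self.int_scores = np.round(lodds / self.resolution).astype(np.int64)  # (4, L)
        lo = int(self.int_scores.min(axis=0).sum())
        hi = int(self.int_scores.max(axis=0).sum())
        probs = np.zeros(hi - lo + 1)
        offset = 0  # current distribution covers [cur_lo, ...]
        cur = np.array([1.0])
        cur_lo = 0
        for col in range(pwm.length):
            col_scores = self.int_scores[:, col]
            new_lo = cur_lo + int(col_scores.min())
            new_hi = cur_lo + len(cur) - 1 + int(col_scores.max())
            new = np.zeros(new_hi - new_lo + 1)
            for b in range(4):
                shift = cur_lo + int(col_scores[b]) - new_lo
                new[shift : shift + len(cur)] += self.background[b] * cur
            cur = new
            cur_lo = new_lo
        self.lattice_lo = cur_lo
        self.probs = cur
        # survival: P(score >= s)
        self.survival = np.cumsum(cur[::-1])[::-1]

    def pvalue(self, score: float) -> float:
        """P(lattice score >= round(score/resolution)) under the background."""
        s = int(np.round(score / self.resolution))
        idx = s - self.lattice_lo
        if idx <= 0:
            return 1.0
        if idx >= len(self.survival):
            return 0.0
        return float(min(1.0, self.survival[idx]))


def pwm_scan(
    sequence: str,
    pwm: PWM,
    background: np.ndarray | None = None,
    p_threshold: float = 1e-9,
    resolution: float = 1e-3,
) -> list[PwmMatch]:
    """Scan both strands of ``sequence`` for PWM matches with p <= threshold.

    Returns matches sorted by ascending p-value (ties by position, strand);
    positions are 0-based offsets of the match start on the forward strand.
    """
    codes = encode_sequence(sequence)
    L = pwm.length
    if len(codes) < L:
        return []
    dist = ScoreDistribution(pwm, background, resolution)
    lattice = dist.int_scores  # (4, L)
    res = dist.resolution
    matches = []
    for strand in "+-":
        strand_codes = codes if strand == "+" else reverse_complement(codes)
        windows = np.lib.stride_tricks.sliding_window_view(strand_codes, L)
        scores = lattice[windows, np.arange(L)].sum(axis=1)
        for w, s_int in enumerate(scores):
            p = dist.pvalue(s_int * res)
            if p <= p_threshold:
                pos = w if strand == "+" else len(codes) - L - w
                matches.append(
                    PwmMatch(position=int(pos), strand=strand, score=float(s_int * res), pvalue=p)
                )
    matches.sort(key=lambda m: (m.pvalue, m.position, m.strand))
    return matches


def select_sites(
    matches_with_slices: Sequence[tuple[PwmMatch, Sequence[str]]],
    pwm_id: str = "",
    max_n: int = 1000,
) -> SiteSet | None:
    """Apply the site-selection filters to scored matches.

    Each match carries its 5-species alignment slice (sequence strings, motif
    length, species order).  Matches spanning a gap in any species are
    dropped; the survivors are ranked by (p-value, position, strand) and
    truncated to ``max_n``.  Reverse-strand slices are reverse-complemented
    into motif orientation.  Returns None (with a warning) if nothing
    survives.
    """
    kept = []
    for match, rows in matches_with_slices:
        if len(rows) != N_SPECIES:
            raise ValueError("each slice must have 5 species rows")
        if any("-" in r or "." in r for r in rows):
            continue
        cols = np.stack([encode_sequence(r) for r in rows], axis=1)  # (L, 5)
        if match.strand == "-":
            cols = np.stack(
                [reverse_complement(cols[:, s]) for s in range(N_SPECIES)], axis=1
            )
        kept.append((match, cols))
    if not kept:
        import warnings

        warnings.warn(f"PWM {pwm_id}: no gapless matches survive site selection")
        return None
    kept.sort(key=lambda t: (t[0].pvalue, t[0].position, t[0].strand))
    kept = kept[:max_n]
    return SiteSet(
        pwm_id=pwm_id,
        columns=np.stack([c for _, c in kept]),
        strands=[m.strand for m, _ in kept],
        sources=[f"pos={m.position}" for m, _ in kept],
    )


def scan_alignment(
    alignment: Sequence[str],
    pwm: PWM,
    background: np.ndarray | None = None,
    p_threshold: float = 1e-9,
    resolution: float = 1e-3,
) -> list[tuple[PwmMatch, list[str]]]:
    """Scan the (gapped) human row of a 5-species alignment; slice matches.

    The human sequence is degapped for scanning, match coordinates are
    mapped back to alignment columns, and a match is returned with its
    5-species slice only when the slice is contiguous in the alignment;
    gap-containing slices are still returned (select_sites drops them) so
    callers can count the filtering.
    """
    if len(alignment) != N_SPECIES:
        raise ValueError("alignment must have 5 rows")
    human = alignment[0]
    col_of = [i for i, ch in enumerate(human) if ch not in "-."]
    seq = "".join(human[i] for i in col_of)
    out = []
    for match in pwm_scan(seq, pwm, background, p_threshold, resolution):
        cols = col_of[match.position : match.position + pwm.length]
        if cols[-1] - cols[0] + 1 != pwm.length:
            continue  # human row itself spans a gap column
        rows = [r[cols[0] : cols[-1] + 1] for r in alignment]
        out.append((match, rows))
    return out


def write_match_table(matches: Sequence[PwmMatch], pwm_id: str, handle) -> None:
    handle.write("pwm\tposition\tstrand\tscore\tpvalue\n")
    for m in matches:
        handle.write(f"{pwm_id}\t{m.position}\t{m.strand}\t{m.score:.6g}\t{m.pvalue:.6g}\n")
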
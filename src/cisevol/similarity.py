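"""Cross-motif comparison of dependency maps, and column mutual information.

A *dependency map* is the set of significant (i, j) position pairs for one
PWM.  Two maps are compared with a Jaccard-like index J: a pair in either
map is *matched* when the other map holds a pair with the same scope whose
begin position differs by at most d; J is the number of matched pairs
(counted on each side) over the total number of pairs in both maps, so
identical maps score 1.  Mutual information between two motif columns is
the standard plug-in estimate on the empirical joint base distribution of
the binding-site instances (human row by default), in bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .sites import SiteSet, SPECIES

logger = logging.getLogger(__name__)


@dataclass
class DependencyMap:
    """Significant position pairs (0-based, i < j) of one PWM."""

    pwm_id: str
    pairs: set = field(default_factory=set)
    length: int | None = None

    def __post_init__(self):
        self.pairs = {(int(i), int(j)) for i, j in self.pairs}
        for i, j in self.pairs:
            if i >= j or i < 0:
                raise ValueError(f"pairs must satisfy 0 <= i < j, got ({i}, {j})")
            if self.length is not None and j >= self.length:
                raise ValueError(f"pair ({i}, {j}) outside PWM of length {self.length}")


@dataclass
class SimilarityScore:
    pwm_a: str
    pwm_b: str
    d: int
    j_value: float


def _matched(pair, other_pairs, d: int) -> bool:
    i, j = pair
    scope = j - i
    return any(j2 - i2 == scope and abs(i2 - i) <= d for i2, j2 in other_pairs)


def dependency_similarity(map1: DependencyMap, map2: DependencyMap, d: int = 0,
                          one_sided: bool = False) -> SimilarityScore:
    """Jaccard-like similarity of two dependency maps with shift tolerance d.

    Default counts matches on both sides over |P1| + |P2| (identical maps
    give J = 1); ``one_sided=True`` counts each match once, over the same
    denominator.  Empty maps score 0 by convention.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    total = len(map1.pairs) + len(map2.pairs)
    if total == 0:
        return SimilarityScore(map1.pwm_id, map2.pwm_id, d, 0.0)
    m1 = sum(_matched(p, map2.pairs, d) for p in map1.pairs)
    m2 = sum(_matched(p, map1.pairs, d) for p in map2.pairs)
    matched = min(m1, m2) if one_sided else m1 + m2
    return SimilarityScore(map1.pwm_id, map2.pwm_id, d, matched / total)


def column_mutual_information(
    siteset: SiteSet, i: int, j: int, species: str | None = "human", pool_species: bool = False
) -> float:
    """Mutual information (bits) between motif columns i and j.

    Estimated from the empirical joint distribution of (base_i, base_j)
    over the N instances, using the chosen species row (default human) or
    pooling all rows; zero-count cells contribute 0.
    """
    if siteset.n < 2:
        raise ValueError("need at least 2 instances")
    if not (0 <= i < siteset.length and 0 <= j < siteset.length):
        raise ValueError("positions outside motif")
    if pool_species:
        bi = siteset.columns[:, i, :].ravel()
        bj = siteset.columns[:, j, :].ravel()
    else:
        row = SPECIES.index(species) if species in SPECIES else 0
        bi = siteset.columns[:, i, row]
        bj = siteset.columns[:, j, row]
    joint = np.zeros((4, 4))
    np.add.at(joint, (bi, bj), 1.0)
    joint /= joint.sum()
    pi_ = joint.sum(axis=1)
    pj_ = joint.sum(axis=0)
    mask = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / np.outer(pi_, pj_))
    return float(terms[mask].sum())


@dataclass
class FamilyComparison:
    d: int
    within: list[float]
    cross: list[float]
    pvalue: float | None  # one-sided Mann-Whitney (within > cross); None if skipped


def family_similarity_test(
    scores: list[SimilarityScore], family_map: dict[str, str]
) -> FamilyComparison | list[FamilyComparison]:
    """Compare within-family vs cross-family J values by rank-sum test.

    ``scores`` may mix several d values; one comparison is returned per d.
    Families with a single PWM contribute no within pairs (logged).  When
    either side is empty the test is skipped (pvalue None).
    """
    by_d: dict[int, tuple[list[float], list[float]]] = {}
    for s in scores:
        fa = family_map.get(s.pwm_a)
        fb = family_map.get(s.pwm_b)
        if fa is None or fb is None:
            logger.info("PWM without family label skipped: %s / %s", s.pwm_a, s.pwm_b)
            continue
        w, c = by_d.setdefault(s.d, ([], []))
        (w if fa == fb else c).append(s.j_value)
    out = []
    for d in sorted(by_d):
        within, cross = by_d[d]
        if not within or not cross:
            logger.info("family test skipped at d=%d (within=%d, cross=%d)", d, len(within), len(cross))
            out.append(FamilyComparison(d=d, within=within, cross=cross, pvalue=None))
            continue
        stat = mannwhitneyu(within, cross, alternative="greater")
        out.append(FamilyComparison(d=d, within=within, cross=cross, pvalue=float(stat.pvalue)))
    return out[0] if len(out) == 1 else out


def read_family_map(handle) -> dict[str, str]:
    """Two-column TSV (pwm_id <tab> family) into a dict."""
    import io

    if isinstance(handle, str):
        handle = io.StringIO(handle)
    out = {}
    for ln in handle:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed family-map line: {ln!r}")
        out[parts[0]] = parts[1]
    return out


def render_dependency_map(dep: DependencyMap, length: int, max_length: int | None = None) -> str:
    """Text rendering of a dependency map, one row per significant pair.

    Endpoints print as '#', the intervening link as '=', other positions
    within the PWM as '.', and columns beyond the PWM as spaces.
    """
    if max_length is None:
        max_length = length
    lines = [f"# {dep.pwm_id} (L={length}, {len(dep.pairs)} significant pairs)"]
    for i, j in sorted(dep.pairs, key=lambda p: (p[1] - p[0], p[0])):
        row = []
        for pos in range(max_length):
            if pos >= length:
                row.append(" ")
            elif pos == i or pos == j:
                row.append("#")
            elif i < pos < j:
                row.append("=")
            else:
                row.append(".")
        lines.append("".join(row))
    return "\n".join(lines)
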
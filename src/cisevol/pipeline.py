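"""End-to-end orchestration: CoEvol over all pairs, controls, significance,
quadruples, similarity, and TSV/text reports.

``run_all`` is deterministic: every random stage derives its generator from
the master seed and fixed stage keys, results are emitted in sorted PWM /
pair order regardless of computation order, and a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .controls import (
    ColumnPool,
    LikelihoodBinner,
    make_random,
    make_random_context,
    matched_random_context_coevol,
    random_context_candidates,
    shuffle_pairs,
)
from .coevol import conditional_table, coevol_score
from .phylo import PhyloModel
from .quadruples import (
    quadruple_analysis,
    quadruple_enrichment,
    rank_quadruples,
    reciprocal_rank_analysis,
)
from .significance import empirical_pvalue, format_pvalue, storey_qvalues, tail_analysis
from .similarity import (
    DependencyMap,
    dependency_similarity,
    family_similarity_test,
    render_dependency_map,
)
from .sites import SiteSet
from .alphabet import NUCLEOTIDES

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    sitesets: dict[str, SiteSet]
    phylo: PhyloModel
    promoter_alignments: Sequence[Sequence[str]] | None = None
    scope_max: int = 8
    n_shuffles: int = 100
    fdr: float = 0.05
    quadruple_p: float = 0.01
    quadruple_pairs: str = "significant"  # or "all"
    n_random_context_sites: int = 0  # 0 disables the RandomContext stage
    n_random_context_reps: int = 100
    similarity_shifts: tuple[int, ...] = (0, 1, 2)
    family_map: dict[str, str] | None = None
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self):
        if self.scope_max < 1:
            raise ValueError("scope_max must be >= 1")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")

    def digest(self) -> str:
        keys = (
            sorted(self.sitesets), self.scope_max, self.n_shuffles, self.fdr,
            self.quadruple_p, self.quadruple_pairs, self.n_random_context_sites,
            self.n_random_context_reps, self.similarity_shifts, self.seed,
        )
        return hashlib.sha256(repr(keys).encode()).hexdigest()[:12]


@dataclass
class RunResult:
    coevol: pd.DataFrame
    tail: pd.DataFrame | None
    quadruples: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    reciprocal: pd.DataFrame | None
    similarity: pd.DataFrame | None
    random_context: pd.DataFrame | None
    dependency_maps: dict[str, DependencyMap]
    t99: float | None = None


def _pair_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=tuple(key))


def run_all(config: RunConfig) -> RunResult:
    model = config.phylo
    pwm_ids = sorted(config.sitesets)
    if not pwm_ids:
        raise ValueError("no site sets supplied")

    # --- CoEvol over all pairs + shuffle significance -----------------------
    rows = []
    shuffle_values: dict[tuple[str, int, int], np.ndarray] = {}
    tables_cache: dict[str, list] = {}
    for p_idx, pwm_id in enumerate(pwm_ids):
        ss = config.sitesets[pwm_id]
        try:
            tables = [conditional_table(ss, pos, model) for pos in range(ss.length)]
        except Exception as e:
            raise RuntimeError(f"stage coevol failed for PWM {pwm_id}: {e}") from e
        tables_cache[pwm_id] = tables
        for i in range(ss.length):
            for j in range(i + 1, min(ss.length, i + config.scope_max + 1)):
                fg = coevol_score(tables[i], tables[j], pwm_id=pwm_id, i=i, j=j)
                rng = np.random.default_rng(_pair_seed(config.seed, 1, p_idx, i, j))
                nulls = np.empty(config.n_shuffles)
                for r in range(config.n_shuffles):
                    _, tj_perm, _ = shuffle_pairs(tables[i], tables[j], rng)
                    nulls[r] = coevol_score(tables[i], tj_perm).value
                shuffle_values[(pwm_id, i, j)] = nulls
                p = empirical_pvalue(fg.value, nulls)
                rows.append(
                    dict(pwm=pwm_id, i=i, j=j, scope=j - i, coevol=fg.value, n=fg.n,
                         p_empirical=p, p_display=format_pvalue(p, config.n_shuffles))
                )
    coevol_df = pd.DataFrame(rows)
    qset = storey_qvalues(coevol_df["p_empirical"].to_numpy())
    coevol_df["q"] = qset.qvalues
    coevol_df["significant"] = coevol_df["q"] <= config.fdr

    # --- Random control + right-tail analysis -------------------------------
    tail_df = None
    t99 = None
    if config.promoter_alignments is not None:
        pool = ColumnPool.from_alignments(config.promoter_alignments)
        random_vals = []
        for p_idx, pwm_id in enumerate(pwm_ids):
            ss = config.sitesets[pwm_id]
            seed = int(_pair_seed(config.seed, 2, p_idx).generate_state(1)[0] % 2**31)
            rnd = make_random(pool, ss.n, ss.length, seed)
            rtabs = [conditional_table(rnd, pos, model) for pos in range(rnd.length)]
            for i in range(rnd.length):
                for j in range(i + 1, min(rnd.length, i + config.scope_max + 1)):
                    random_vals.append(coevol_score(rtabs[i], rtabs[j]).value)
        fg_by_scope = {
            s: g["coevol"].to_numpy() for s, g in coevol_df.groupby("scope")
        }
        shuf_by_scope = {}
        for s in fg_by_scope:
            reps = []
            sel = coevol_df[coevol_df["scope"] == s]
            for r in range(config.n_shuffles):
                reps.append(
                    np.array([
                        shuffle_values[(row.pwm, row.i, row.j)][r] for row in sel.itertuples()
                    ])
                )
            shuf_by_scope[s] = reps
        ta = tail_analysis(fg_by_scope, np.array(random_vals), shuf_by_scope)
        t99 = ta.t99
        tail_df = pd.DataFrame(
            [dict(scope=s, f_s=ta.f_s[s], t99=ta.t99,
                  s_s_mean=float(np.mean(ta.s_s[s])) if ta.s_s[s] else float("nan"),
                  tail_p=ta.tail_p[s]) for s in sorted(ta.f_s)]
        )

    # --- RandomContext (likelihood-matched), optional ------------------------
    rc_df = None
    if config.promoter_alignments is not None and config.n_random_context_sites > 0:
        max_len = max(config.sitesets[p].length for p in pwm_ids)
        rc_seed = int(_pair_seed(config.seed, 3).generate_state(1)[0] % 2**31)
        rc_sites = make_random_context(
            config.promoter_alignments, config.n_random_context_sites, max_len, rc_seed
        )
        binner = LikelihoodBinner()
        cand_cache: dict[int, object] = {}
        rc_rows = []
        for p_idx, pwm_id in enumerate(pwm_ids):
            tables = tables_cache[pwm_id]
            sel = coevol_df[coevol_df["pwm"] == pwm_id]
            for row in sel.itertuples():
                scope = row.scope
                if scope not in cand_cache:
                    cand_cache[scope] = random_context_candidates(rc_sites, scope, model)
                seed = int(_pair_seed(config.seed, 4, p_idx, row.i, row.j).generate_state(1)[0] % 2**31)
                vals = matched_random_context_coevol(
                    tables[row.i], tables[row.j], cand_cache[scope], seed,
                    n_reps=config.n_random_context_reps, binner=binner,
                )
                rc_rows.append(
                    dict(pwm=pwm_id, i=row.i, j=row.j, scope=scope,
                         coevol_fg=row.coevol, rc_mean=float(vals.mean()),
                         rc_sd=float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                         p_vs_rc=empirical_pvalue(row.coevol, vals))
                )
        rc_df = pd.DataFrame(rc_rows)

    # --- Quadruples ----------------------------------------------------------
    quad_df = None
    enr_df = None
    rec_df = None
    if config.quadruple_pairs == "all":
        quad_targets = coevol_df
    else:
        quad_targets = coevol_df[coevol_df["significant"]]
    qrows = []
    for p_idx, pwm_id in enumerate(pwm_ids):
        tables = tables_cache[pwm_id]
        sel = quad_targets[quad_targets["pwm"] == pwm_id]
        for row in sel.itertuples():
            seed = int(_pair_seed(config.seed, 5, p_idx, row.i, row.j).generate_state(1)[0] % 2**31)
            recs = quadruple_analysis(
                tables[row.i], tables[row.j], model,
                pwm_id=pwm_id, i=row.i, j=row.j,
                n_shuffles=config.n_shuffles, seed=seed,
            )
            for rec in recs:
                qrows.append(
                    dict(pwm=rec.pwm_id, i=rec.i, j=rec.j, scope=rec.j - rec.i,
                         branch=rec.branch,
                         u=NUCLEOTIDES[rec.u], v=NUCLEOTIDES[rec.v],
                         x=NUCLEOTIDES[rec.x], y=NUCLEOTIDES[rec.y],
                         pr_uv=rec.pr_uv, pr_xy=rec.pr_xy, pr_joint=rec.pr_joint,
                         coevol=rec.coevol, p_empirical=rec.p_empirical)
                )
    if qrows:
        quad_df = pd.DataFrame(qrows)
        sig = quad_df[(quad_df["p_empirical"] < config.quadruple_p) & np.isfinite(quad_df["coevol"])]
        counts: dict[tuple[int, int, int, int], int] = {}
        for r in sig.itertuples():
            q = tuple(NUCLEOTIDES.index(c) for c in (r.u, r.v, r.x, r.y))
            counts[q] = counts.get(q, 0) + 1
        enr = quadruple_enrichment(counts)
        enr_df = pd.DataFrame(
            [dict(quadruple="".join(NUCLEOTIDES[c] for c in q),
                  count=enr.counts.get(q, 0),
                  enriched=q in enr.enriched)
             for q in rank_quadruples(counts)]
        )
        enr_df.attrs["threshold"] = enr.threshold
        enr_df.attrs["n_cases"] = enr.n_cases
        rr = reciprocal_rank_analysis(rank_quadruples(counts))
        rec_df = pd.DataFrame(
            [dict(quadruple="".join(NUCLEOTIDES[c] for c in row.quadruple),
                  reciprocal="".join(NUCLEOTIDES[c] for c in row.reciprocal),
                  r=row.r, actual_diff=row.actual_diff,
                  expected_diff=row.expected_diff, sd=row.sd, z=row.z)
             for row in rr.rows]
        )
        rec_df.attrs["kendall_tau"] = rr.tau
        rec_df.attrs["kendall_tau_p"] = rr.tau_pvalue

    # --- Dependency maps & similarity ----------------------------------------
    dep_maps = {}
    for pwm_id in pwm_ids:
        sel = coevol_df[(coevol_df["pwm"] == pwm_id) & coevol_df["significant"]]
        dep_maps[pwm_id] = DependencyMap(
            pwm_id=pwm_id,
            pairs={(r.i, r.j) for r in sel.itertuples()},
            length=config.sitesets[pwm_id].length,
        )
    sim_df = None
    if len(pwm_ids) >= 2:
        srows = []
        scores = []
        for a_idx, a in enumerate(pwm_ids):
            for b in pwm_ids[a_idx + 1:]:
                for d in config.similarity_shifts:
                    s = dependency_similarity(dep_maps[a], dep_maps[b], d)
                    scores.append(s)
                    srows.append(dict(pwm_a=a, pwm_b=b, d=d, j=s.j_value))
        sim_df = pd.DataFrame(srows)
        if config.family_map:
            comps = family_similarity_test(scores, config.family_map)
            if not isinstance(comps, list):
                comps = [comps]
            sim_df.attrs["family_test"] = {
                c.d: c.pvalue for c in comps
            }

    result = RunResult(
        coevol=coevol_df, tail=tail_df, quadruples=quad_df, enrichment=enr_df,
        reciprocal=rec_df, similarity=sim_df, random_context=rc_df,
        dependency_maps=dep_maps, t99=t99,
    )
    if config.out_dir is not None:
        _write_reports(config, result)
    return result


def _header(config: RunConfig) -> str:
    return (f"# cisevol {__version__} config={config.digest()} seed={config.seed} "
            f"n_shuffles={config.n_shuffles} scope_max={config.scope_max}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _write_reports(config: RunConfig, result: RunResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.coevol, out / "coevol.tsv", config)
    if result.tail is not None:
        _write_tsv(result.tail, out / "tail.tsv", config)
    if result.quadruples is not None:
        _write_tsv(result.quadruples, out / "quadruples.tsv", config)
    if result.enrichment is not None:
        _write_tsv(result.enrichment, out / "quadruple_enrichment.tsv", config)
    if result.reciprocal is not None:
        _write_tsv(result.reciprocal, out / "reciprocal_ranks.tsv", config)
    if result.similarity is not None:
        _write_tsv(result.similarity, out / "similarity.tsv", config)
    if result.random_context is not None:
        _write_tsv(result.random_context, out / "random_context.tsv", config)
    with open(out / "dependency_maps.txt", "w") as fh:
        fh.write(_header(config))
        max_len = max(config.sitesets[p].length for p in sorted(config.sitesets))
        for pwm_id in sorted(result.dependency_maps):
            dep = result.dependency_maps[pwm_id]
            fh.write(render_dependency_map(dep, config.sitesets[pwm_id].length, max_len))
            fh.write("\n\n")
    with open(out / "run.log", "w") as fh:
        fh.write(_header(config))
        fh.write(f"pwms={sorted(config.sitesets)}\n")
        if result.t99 is not None:
            fh.write(f"t99={result.t99:.6g}\n")
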
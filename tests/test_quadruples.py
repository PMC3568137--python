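import numpy as np
import pytest

from cisevol.coevol import (
    ConditionalLikelihoodTable,
    assignment_distribution,
    conditional_table,
    joint_distribution,
)
from cisevol.phylo import PhyloModel, PhyloTree, assignment_log_likelihoods
from cisevol.quadruples import (
    admissible_quadruples,
    joint_transition_propensities,
    quadruple_analysis,
    quadruple_coevol,
    quadruple_enrichment,
    rank_quadruples,
    reciprocal,
    reciprocal_rank_analysis,
    transition_propensities,
)
from cisevol.simulate import Coupling, SimulationConfig, simulate_siteset
from cisevol.sites import SiteSet


class TestCombinatorics:
    def test_admissible_count_and_reciprocal_involution(self):
        quads = admissible_quadruples()
        assert len(quads) == 240
        assert all(reciprocal(reciprocal(q)) == q for q in quads)
        orbits = {tuple(sorted([q, reciprocal(q)])) for q in quads}
        assert len(orbits) == 120
        assert all(q[0] != q[1] or q[2] != q[3] for q in quads)


class TestTransitionPropensities:
    def test_sum_to_one_on_every_branch(self, model):
        ss = simulate_siteset(SimulationConfig(phylo=model, n_sites=25, length=2, seed=51)).siteset
        t = conditional_table(ss, 0, model)
        d = assignment_distribution(t)
        for b in range(1, 9):
            pr = transition_propensities(t, d, model, b)
            assert abs(pr.sum() - 1.0) < 1e-9
            assert pr.min() >= 0

    def test_invariant_column_short_branches_silent(self):
        tree = PhyloTree.default().with_branch_lengths(np.full(8, 1e-4))
        model = PhyloModel(tree=tree, hky=PhyloModel.default().hky)
        cols = np.zeros((10, 1, 5), dtype=int)  # all-A everywhere
        ss = SiteSet(pwm_id="t", columns=cols)
        t = conditional_table(ss, 0, model)
        d = assignment_distribution(t)
        for b in (1, 5, 8):
            pr = transition_propensities(t, d, model, b)
            assert pr[0, 0] > 0.999
            assert pr.sum() - pr[0, 0] < 1e-3

    def test_two_taxon_enumeration_oracle(self, model):
        toy = PhyloModel(tree=PhyloTree("(a:0.2,b:0.3);"), hky=model.hky)
        rng = np.random.default_rng(53)
        cols = rng.integers(0, 4, (5, 2))
        t = ConditionalLikelihoodTable(assignment_log_likelihoods(toy, cols), cols)
        d = assignment_distribution(t)
        li = np.exp(t.log_values)
        probs = d.probs
        for branch, leaf in ((1, 0), (2, 1)):
            hand = np.zeros((4, 4))
            for k in range(5):
                denom = float(probs @ li[k])
                for s in range(4):  # root base = parent of both leaf branches
                    hand[s, cols[k, leaf]] += probs[s] * li[k, s] / denom
            hand /= 5
            got = transition_propensities(t, d, toy, branch)
            assert np.abs(got - hand).max() < 1e-12


class TestJointPropensities:
    def test_sum_to_one_per_branch(self, model, pool_tables):
        rng = np.random.default_rng(55)
        ti = pool_tables(20, rng)
        tj = pool_tables(20, rng)
        joint = joint_distribution(ti, tj)
        for b in range(1, 9):
            pr4 = joint_transition_propensities(ti, tj, joint, model, b)
            assert abs(pr4.sum() - 1.0) < 1e-9

    def test_invariant_partner_factorizes(self, model):
        ss = simulate_siteset(SimulationConfig(phylo=model, n_sites=15, length=2, seed=57)).siteset
        cols = ss.columns.copy()
        cols[:, 1, :] = 1  # all-C at position 1
        ss = SiteSet(pwm_id="t", columns=cols)
        ti = conditional_table(ss, 0, model)
        tj = conditional_table(ss, 1, model)
        joint = joint_distribution(ti, tj)
        di = assignment_distribution(ti)
        dj = assignment_distribution(tj)
        for b in (3, 8):
            pr4 = joint_transition_propensities(ti, tj, joint, model, b)
            pri = transition_propensities(ti, di, model, b)
            prj = transition_propensities(tj, dj, model, b)
            # identical rows at j make the joint factorize exactly
            assert np.abs(pr4 - np.einsum("uv,xy->uvxy", pri, prj)).max() < 1e-9
        # with near-zero branch lengths the silent C->C class takes all of
        # j's mass, so Pr(u,v,C,C) collapses onto Pr(u,v)
        short = PhyloModel(
            tree=model.tree.with_branch_lengths(np.full(8, 1e-5)), hky=model.hky
        )
        ti_s = conditional_table(ss, 0, short)
        tj_s = conditional_table(ss, 1, short)
        joint_s = joint_distribution(ti_s, tj_s)
        di_s = assignment_distribution(ti_s)
        pr4 = joint_transition_propensities(ti_s, tj_s, joint_s, short, 3)
        pri = transition_propensities(ti_s, di_s, short, 3)
        assert np.abs(pr4[:, :, 1, 1] - pri).max() < 1e-4

    def test_mirrored_substitutions_dominate(self, model):
        # perfectly mirrored histories: duplicate an A/G-rooted column at
        # both positions, so every substitution at i recurs at j
        profile = np.array([[0.5, 0.0, 0.5, 0.0]])
        sim = simulate_siteset(
            SimulationConfig(phylo=model, n_sites=120, length=1, seed=59,
                             root_profile=profile)
        ).siteset
        cols = np.concatenate([sim.columns, sim.columns], axis=1)  # (N, 2, 5)
        ss = SiteSet(pwm_id="t", columns=cols)
        ti = conditional_table(ss, 0, model)
        tj = conditional_table(ss, 1, model)
        joint = joint_distribution(ti, tj)
        # pool over branches: co-occurring A->G must far exceed one-sided A->G
        ag_ag = sum(
            joint_transition_propensities(ti, tj, joint, model, b)[0, 2, 0, 2]
            for b in range(1, 9)
        )
        ag_aa = sum(
            joint_transition_propensities(ti, tj, joint, model, b)[0, 2, 0, 0]
            for b in range(1, 9)
        )
        assert ag_ag > 10 * ag_aa


class TestQuadrupleCoevol:
    def test_arithmetic(self):
        assert np.isclose(quadruple_coevol(0.5, 0.5, 0.5), np.log(2.0))
        assert quadruple_coevol(0.0, 0.1, 0.1) == float("-inf")
        assert quadruple_coevol(0.1, 0.0, 0.1) == float("inf")

    def test_independent_positions_near_zero(self, model, pool_tables):
        rng = np.random.default_rng(61)
        ti = pool_tables(200, rng)
        tj = pool_tables(200, rng)
        joint = joint_distribution(ti, tj)
        di = assignment_distribution(ti)
        dj = assignment_distribution(tj)
        b = 6
        pr4 = joint_transition_propensities(ti, tj, joint, model, b)
        pri = transition_propensities(ti, di, model, b)
        prj = transition_propensities(tj, dj, model, b)
        # the dominant (frequent) quadruples should show |log-ratio| near 0
        for u, v, x, y in ((0, 0, 0, 0), (3, 3, 1, 1), (2, 2, 3, 3)):
            val = quadruple_coevol(pr4[u, v, x, y], pri[u, v], prj[x, y])
            assert abs(val) < 0.35


class TestEnrichment:
    def test_threshold_matches_printed_formula(self):
        counts = {q: 1 for q in admissible_quadruples()}
        res = quadruple_enrichment(counts)
        assert res.n_cases == 240
        assert np.isclose(res.threshold, 1 + 2 * np.sqrt(239 / 240))
        assert res.enriched == []  # all counts equal the mean

    def test_counts_of_three_exceed_threshold_at_n240(self):
        quads = admissible_quadruples()
        counts = {q: 1 for q in quads}
        counts[quads[0]] += 2
        counts[quads[1]] -= 2
        res = quadruple_enrichment(counts)
        assert quads[0] in res.enriched and len(res.enriched) == 1

    def test_single_dominant_quadruple(self):
        quads = admissible_quadruples()
        counts = {quads[5]: 1000}
        res = quadruple_enrichment(counts)
        assert res.enriched == [quads[5]]

    def test_empty(self):
        res = quadruple_enrichment({})
        assert res.n_cases == 0 and res.enriched == []


class TestReciprocalRanks:
    def test_near_bottom_pair_z(self):
        # construct a ranking where a reciprocal pair sits at ranks 238/239
        quads = admissible_quadruples()
        q = (0, 1, 2, 3)
        qr = reciprocal(q)
        rest = [x for x in quads if x not in (q, qr)]
        ranking = rest[:237] + [q, qr] + rest[237:]
        res = reciprocal_rank_analysis(ranking)
        row = next(r for r in res.rows if r.r == 238)
        assert row.actual_diff == 1
        assert row.expected_diff == 1.5
        assert row.sd == 0.5
        assert row.z == -1.0

    def test_adjacent_pairs_have_unit_difference(self):
        quads = admissible_quadruples()
        seen, ranking = set(), []
        for q in quads:
            if q in seen:
                continue
            qr = reciprocal(q)
            seen.update({q, qr})
            ranking.append(q)
            if qr != q:
                ranking.append(qr)
        res = reciprocal_rank_analysis(ranking)
        assert all(r.actual_diff == 1 for r in res.rows)
        zs = {r.r: r.z for r in res.rows}
        rs = sorted(zs)
        assert all(zs[a] <= zs[b] for a, b in zip(rs, rs[1:]))  # z rises with r

    def test_random_rankings_have_null_tau(self):
        rng = np.random.default_rng(67)
        quads = admissible_quadruples()
        taus = []
        for _ in range(300):
            perm = list(rng.permutation(len(quads)))
            ranking = [quads[i] for i in perm]
            res = reciprocal_rank_analysis(ranking)
            taus.append(res.tau)
        taus = np.array(taus)
        se = taus.std(ddof=1) / np.sqrt(len(taus))
        assert abs(taus.mean()) < 3 * se

    def test_rank_ties_break_lexicographically(self):
        counts = {}
        ranking = rank_quadruples(counts)
        assert ranking == sorted(admissible_quadruples())


class TestQuadrupleAnalysis:
    def test_coupled_quadruple_recovery(self, model):
        """Hard A<->G coupling: the programmed quadruple and its reciprocal
        are the top-ranked significant quadruples."""
        ss = simulate_siteset(
            SimulationConfig(
                phylo=model, n_sites=100, length=2, seed=71,
                couplings=[Coupling(0, 1, frozenset({(0, 0), (2, 2)}), 0.0)],
            )
        ).siteset
        ti = conditional_table(ss, 0, model)
        tj = conditional_table(ss, 1, model)
        records = quadruple_analysis(ti, tj, model, n_shuffles=100, seed=73)
        counts = {}
        for rec in records:
            if rec.p_empirical < 0.01 and np.isfinite(rec.coevol):
                q = (rec.u, rec.v, rec.x, rec.y)
                counts[q] = counts.get(q, 0) + 1
        ranking = rank_quadruples(counts)
        top5 = set(ranking[:5])
        assert (0, 2, 0, 2) in top5 or (2, 0, 2, 0) in top5
        assert counts.get((0, 2, 0, 2), 0) + counts.get((2, 0, 2, 0), 0) >= 2
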
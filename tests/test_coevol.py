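import numpy as np
import pytest
from scipy.special import logsumexp

from cisevol.coevol import (
    ConditionalLikelihoodTable,
    assignment_distribution,
    coevol_score,
    conditional_table,
    coevol_for_pair,
    joint_distribution,
    joint_marginal_log_likelihoods,
    marginal_log_likelihoods,
)
from cisevol.controls import shuffle_null_coevols
from cisevol.phylo import PhyloModel, PhyloTree, assignment_log_likelihoods
from cisevol.simulate import Coupling, SimulationConfig, simulate_siteset
from cisevol.sites import SiteSet

# the worked single-position example: 5 sites, 2 species, 4 root assignments
# (rows A, T, G, C as printed; columns are sites 1..5)
WORKED_EXAMPLE = {
    "A": [0.001, 0.05, 0.0003, 0.003, 0.01],
    "T": [0.01, 0.0007, 0.009, 0.08, 0.1],
    "G": [0.00008, 0.003, 0.006, 0.004, 0.0009],
    "C": [0.023, 0.018, 0.065, 0.3, 0.087],
}


def worked_table() -> ConditionalLikelihoodTable:
    values = np.array([WORKED_EXAMPLE[a] for a in "ATGC"]).T  # (5 sites, 4 assignments)
    return ConditionalLikelihoodTable.from_linear(values)


class TestAssignmentDistribution:
    def test_worked_example_weights(self):
        d = assignment_distribution(worked_table())
        w = dict(zip("ATGC", d.weights))
        assert np.isclose(w["T"], 0.1997, atol=5e-5)
        assert np.isclose(d.total_weight, 0.77098, atol=5e-6)

    def test_worked_example_probabilities(self):
        d = assignment_distribution(worked_table())
        p = dict(zip("ATGC", d.probs))
        assert np.isclose(p["T"], 0.259021, atol=5e-7)
        assert np.isclose(p["C"], 0.639446, atol=5e-7)
        assert np.isclose(p["G"], 0.018133, atol=5e-7)
        assert np.isclose(p["A"], 0.0834, atol=5e-5)
        assert p["C"] == max(p.values())

    def test_single_instance_normalizes_its_row(self):
        t = ConditionalLikelihoodTable.from_linear(np.array([[0.2, 0.1, 0.6, 0.1]]))
        d = assignment_distribution(t)
        assert np.allclose(d.probs, [0.2, 0.1, 0.6, 0.1])

    def test_probs_normalized(self, model):
        rng = np.random.default_rng(0)
        cols = rng.integers(0, 4, (7, 5))
        t = ConditionalLikelihoodTable(assignment_log_likelihoods(model, cols), cols)
        d = assignment_distribution(t)
        assert np.isclose(d.probs.sum(), 1.0, atol=1e-12)


class TestMarginalLikelihoods:
    def test_worked_example_site1_weighted_sum(self):
        t = worked_table()
        d = assignment_distribution(t)
        got = np.exp(marginal_log_likelihoods(t, d))[0]
        p = dict(zip("ATGC", d.probs))
        expected = (
            p["A"] * 0.001 + p["T"] * 0.01 + p["G"] * 0.00008 + p["C"] * 0.023
        )
        assert np.isclose(got, expected, rtol=1e-12)

    def test_point_mass_distribution_selects_column(self):
        t = worked_table()
        d = assignment_distribution(t)
        with np.errstate(divide="ignore"):
            point = type(d)(
                log_weights=np.log([0.0, 1.0, 0.0, 0.0]),
                log_probs=np.log([0.0, 1.0, 0.0, 0.0]),
            )
        got = np.exp(marginal_log_likelihoods(t, point))
        assert np.allclose(got, np.exp(t.log_values[:, 1]))

    def test_uniform_distribution_gives_row_means(self):
        t = worked_table()
        d = assignment_distribution(t)
        uniform = type(d)(
            log_weights=np.zeros(4), log_probs=np.log(np.full(4, 0.25))
        )
        got = np.exp(marginal_log_likelihoods(t, uniform))
        assert np.allclose(got, np.exp(t.log_values).mean(axis=1))


def _tables_for(ss, model, i, j):
    return conditional_table(ss, i, model), conditional_table(ss, j, model)


class TestJointDistribution:
    def test_constant_second_table_factorizes(self, model):
        rng = np.random.default_rng(4)
        cols_i = rng.integers(0, 4, (6, 5))
        cols_j = np.tile(rng.integers(0, 4, (1, 5)), (6, 1))
        ti = ConditionalLikelihoodTable(assignment_log_likelihoods(model, cols_i), cols_i)
        tj = ConditionalLikelihoodTable(assignment_log_likelihoods(model, cols_j), cols_j)
        joint = joint_distribution(ti, tj)
        pi_ = assignment_distribution(ti).probs
        pj_ = assignment_distribution(tj).probs
        assert np.abs(joint.probs - np.outer(pi_, pj_)).max() < 1e-12

    def test_n1_joint_is_outer_product(self, model):
        rng = np.random.default_rng(5)
        cols = rng.integers(0, 4, (1, 5))
        ti = ConditionalLikelihoodTable(assignment_log_likelihoods(model, cols), cols)
        cols2 = rng.integers(0, 4, (1, 5))
        tj = ConditionalLikelihoodTable(assignment_log_likelihoods(model, cols2), cols2)
        joint = joint_distribution(ti, tj)
        outer = np.outer(assignment_distribution(ti).probs, assignment_distribution(tj).probs)
        assert np.abs(joint.probs - outer).max() < 1e-12

    def test_identical_varying_tables_concentrate_diagonal(self):
        # three instances preferring three different assignments
        vals = np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]])
        t = ConditionalLikelihoodTable.from_linear(vals)
        joint = joint_distribution(t, t)
        outer = np.outer(assignment_distribution(t).probs, assignment_distribution(t).probs)
        assert np.trace(joint.probs) > np.trace(outer)

    def test_normalized_and_mismatch_rejected(self, model):
        rng = np.random.default_rng(6)
        cols = rng.integers(0, 4, (4, 5))
        t = ConditionalLikelihoodTable(assignment_log_likelihoods(model, cols), cols)
        joint = joint_distribution(t, t)
        assert np.isclose(joint.probs.sum(), 1.0, atol=1e-12)
        short = t.permuted(np.arange(3))
        with pytest.raises(ValueError):
            joint_distribution(t, short)


class TestCoEvolScore:
    def test_invariant_second_position_scores_zero(self, model):
        ss = simulate_siteset(SimulationConfig(phylo=model, n_sites=40, length=2, seed=7)).siteset
        cols = ss.columns.copy()
        cols[:, 1, :] = 2  # all-G column at position 1, every instance
        ss = SiteSet(pwm_id="t", columns=cols)
        rec = coevol_for_pair(ss, model, 0, 1)
        assert abs(rec.value) < 1e-9

    def test_instance_order_invariance(self, model):
        ss = simulate_siteset(SimulationConfig(phylo=model, n_sites=30, length=2, seed=8)).siteset
        ti, tj = _tables_for(ss, model, 0, 1)
        base = coevol_score(ti, tj).value
        perm = np.random.default_rng(1).permutation(30)
        assert np.isclose(coevol_score(ti.permuted(perm), tj.permuted(perm)).value, base, atol=1e-9)

    def test_mean_aggregate_divides_by_n(self, model):
        ss = simulate_siteset(SimulationConfig(phylo=model, n_sites=25, length=2, seed=9)).siteset
        ti, tj = _tables_for(ss, model, 0, 1)
        s = coevol_score(ti, tj, aggregate="sum").value
        m = coevol_score(ti, tj, aggregate="mean").value
        assert np.isclose(m, s / 25)

    def test_two_taxon_toy_matches_hand_computation(self):
        hky = PhyloModel.default().hky
        toy = PhyloModel(tree=PhyloTree("(a:0.2,b:0.3);"), hky=hky)
        rng = np.random.default_rng(10)
        cols_i = rng.integers(0, 4, (3, 2))
        cols_j = rng.integers(0, 4, (3, 2))
        ti = ConditionalLikelihoodTable(assignment_log_likelihoods(toy, cols_i), cols_i)
        tj = ConditionalLikelihoodTable(assignment_log_likelihoods(toy, cols_j), cols_j)
        li = np.exp(ti.log_values)  # (3, 4)
        lj = np.exp(tj.log_values)
        wi = li.sum(axis=0); pi_ = wi / wi.sum()
        wj = lj.sum(axis=0); pj_ = wj / wj.sum()
        wij = li.T @ lj; pij = wij / wij.sum()
        hand = 0.0
        for k in range(3):
            joint_k = float(li[k] @ pij @ lj[k])
            hand += np.log(joint_k) - np.log(li[k] @ pi_) - np.log(lj[k] @ pj_)
        got = coevol_score(ti, tj).value
        assert np.isclose(got, hand, rtol=1e-12)

    def test_null_centered_against_shuffle(self, model, pool_tables):
        """Independent positions: CoEvol is exchangeable with its shuffle
        nulls, so the shuffle-centred statistic has mean zero (the raw
        statistic carries a positive plug-in bias)."""
        rng = np.random.default_rng(123)
        centred = []
        for _ in range(120):
            ti = pool_tables(40, rng)
            tj = pool_tables(40, rng)
            fg = coevol_score(ti, tj).value
            nulls = shuffle_null_coevols(ti, tj, 24, rng)
            centred.append(fg - nulls.mean())
        centred = np.array(centred)
        se = centred.std(ddof=1) / np.sqrt(len(centred))
        assert abs(centred.mean()) < 3 * se

    def test_coupled_positions_score_positive(self, model):
        hits = 0
        for rep in range(40):
            ss = simulate_siteset(
                SimulationConfig(
                    phylo=model, n_sites=40, length=2, seed=1000 + rep,
                    couplings=[Coupling(0, 1, frozenset({(0, 0), (2, 2)}), 0.0)],
                )
            ).siteset
            if coevol_for_pair(ss, model, 0, 1).value > 0:
                hits += 1
        assert hits >= 38  # >= 95% of replicates
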
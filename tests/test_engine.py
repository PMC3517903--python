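"""Rate-matrix construction, beta discretization, transition
probabilities, and the pruning likelihood against enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from codonsel.engine import (
    CodonModelSpec,
    beta_plus_class,
    build_generator,
    discretize_beta,
    log_likelihood,
    transition_probabilities,
    tree_log_likelihood,
)
from codonsel.genetics import STANDARD_CODE, is_transition
from codonsel.phylo import read_newick
from codonsel.seqdata import CodonFrequencies

from conftest import make_alignment

UNIF = np.full(61, 1.0 / 61)


class TestGenerator:
    def test_rows_sum_to_zero(self, uniform_pi):
        Q = build_generator(2.0, 0.5, uniform_pi).Q
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_unit_mean_rate(self, uniform_pi):
        Q = build_generator(3.0, 0.2, uniform_pi).Q
        assert abs(-np.dot(uniform_pi, np.diag(Q)) - 1.0) < 1e-12

    def test_detailed_balance(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61))
        Q = build_generator(2.5, 0.3, pi).Q
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_omega_zero_kills_nonsynonymous_rates(self, uniform_pi):
        Q = build_generator(2.0, 0.0, uniform_pi).Q
        code = STANDARD_CODE
        for i in range(61):
            for j in range(61):
                if i != j and code.single_difference(i, j) and not code.is_synonymous(i, j):
                    assert Q[i, j] == 0.0

    def test_kappa_omega_ratio_by_brute_scan(self, uniform_pi):
        # under equal frequencies q(syn transition) / q(nonsyn
        # transversion) = kappa / omega for every qualifying pair
        kappa, omega = 2.0, 0.5
        Q = build_generator(kappa, omega, uniform_pi).Q
        code = STANDARD_CODE
        syn_ts, nonsyn_tv = [], []
        for i in range(61):
            for j in range(61):
                if i == j:
                    continue
                d = code.single_difference(i, j)
                if d is None:
                    continue
                _, a, b = d
                if code.is_synonymous(i, j) and is_transition(a, b):
                    syn_ts.append(Q[i, j])
                if not code.is_synonymous(i, j) and not is_transition(a, b):
                    nonsyn_tv.append(Q[i, j])
        ratios = np.array(syn_ts)[:, None] / np.array(nonsyn_tv)[None, :]
        np.testing.assert_allclose(ratios, kappa / omega, rtol=1e-12)

    def test_zero_frequency_rejected(self):
        pi = np.full(61, 1.0 / 60)
        pi[0] = 0.0
        with pytest.raises(ValueError, match="reversibility"):
            build_generator(2.0, 0.5, pi)


class TestBetaDiscretization:
    def test_uniform_interval_means(self):
        d = discretize_beta(1.0, 1.0, 10)
        np.testing.assert_allclose(d.omegas, np.arange(0.05, 1.0, 0.1), atol=1e-12)
        np.testing.assert_allclose(d.weights, 0.1)

    @pytest.mark.parametrize("p,q", [(0.01, 2.86), (0.47, 0.96), (6.3, 99.0), (2.0, 2.0)])
    def test_means_match_quadrature_oracle(self, p, q):
        # oracle: adaptive quadrature of x * pdf over each quantile
        # interval, divided by the interval mass 1/ncat
        ncat = 10
        d = discretize_beta(p, q, ncat)
        edges = beta_dist.ppf(np.linspace(0, 1, ncat + 1), p, q)
        for c in range(ncat):
            val, _ = quad(
                lambda x: x * beta_dist.pdf(x, p, q), edges[c], edges[c + 1],
                limit=200,
            )
            assert abs(d.omegas[c] - val * ncat) < 1e-6

    @settings(max_examples=40, deadline=None)
    @given(
        st.floats(0.05, 20.0), st.floats(0.05, 20.0), st.integers(2, 12)
    )
    def test_weights_sum_and_means_increase(self, p, q, ncat):
        d = discretize_beta(p, q, ncat)
        assert abs(d.weights.sum() - 1.0) < 1e-12
        assert np.all(np.diff(d.omegas) > 0)
        assert np.all((d.omegas > 0) & (d.omegas < 1))

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            discretize_beta(float("nan"), 1.0, 10)

    def test_beta_plus_class_weights(self):
        d = beta_plus_class(0.5, 1.5, p_ad=0.2, omega_ad=3.0)
        assert abs(d.weights.sum() - 1.0) < 1e-12
        assert d.omegas[-1] == 3.0
        assert abs(d.weights[-1] - 0.2) < 1e-12
        np.testing.assert_allclose(d.weights[:-1], 0.08)


class TestTransitionProbabilities:
    def test_identity_at_zero(self, uniform_pi):
        Q = build_generator(2.0, 0.5, uniform_pi)
        np.testing.assert_allclose(
            transition_probabilities(Q, 0.0), np.eye(61), atol=1e-12
        )

    def test_rows_stochastic(self, uniform_pi):
        Q = build_generator(2.0, 0.5, uniform_pi)
        P = transition_probabilities(Q, 0.7)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0.0 and P.max() <= 1.0 + 1e-12

    def test_ergodic_limit_is_pi(self):
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.full(61, 5.0))
        Q = build_generator(2.0, 0.5, pi)
        P = transition_probabilities(Q, 500.0)
        assert np.abs(P - pi[None, :]).max() < 1e-8

    def test_chapman_kolmogorov(self, uniform_pi):
        Q = build_generator(1.7, 0.4, uniform_pi)
        P_st = transition_probabilities(Q, 0.9)
        prod = transition_probabilities(Q, 0.3) @ transition_probabilities(Q, 0.6)
        assert np.abs(P_st - prod).max() < 1e-10

    def test_negative_time_rejected(self, uniform_pi):
        Q = build_generator(2.0, 0.5, uniform_pi)
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1)


def brute_force_loglik(tree, taxa, codons, pi, kappa, omega):
    """Independent oracle: sum the joint probability over every
    assignment of internal-node states, site by site."""
    Q = build_generator(kappa, omega, pi)
    P = {e: Q.probabilities(float(tree.edge_length[e])) for e in tree.edges}
    internal = [v for v in tree.postorder if tree.children[v]]
    tip_state = {tree.tip_ids[t]: codons[i] for i, t in enumerate(taxa)}
    total = 0.0
    n_sites = codons.shape[1]
    for s in range(n_sites):
        lik = 0.0
        grids = np.meshgrid(*[range(61)] * len(internal), indexing="ij")
        flat = [g.ravel() for g in grids]
        for assign in zip(*flat):
            states = dict(zip(internal, assign))
            states.update({v: tip_state[v][s] for v in tip_state})
            p = pi[states[tree.root]]
            for e in tree.edges:
                p *= P[e][states[tree.parent[e]], states[e]]
            lik += p
        total += np.log(lik)
    return total


class TestPruningLikelihood:
    def test_two_tip_closed_form(self, uniform_pi):
        tree = read_newick("(A:0.1,B:0.2);")
        codons = np.array([[5], [7]], dtype=np.int16)
        total, _ = tree_log_likelihood(
            codons, ["A", "B"], tree, uniform_pi, 2.0,
            np.array([1.0]), np.full((1, tree.n_nodes), 0.5),
        )
        P = build_generator(2.0, 0.5, uniform_pi).probabilities(0.3)
        assert abs(total - np.log(uniform_pi[5] * P[5, 7])) < 1e-10

    def test_three_tip_exhaustive_enumeration(self, uniform_pi):
        # derooted 3-tip tree: one internal node, 61 assignments
        tree = read_newick("(A:0.1,B:0.2,C:0.15);")
        rng = np.random.default_rng(4)
        codons = rng.integers(0, 61, (3, 2)).astype(np.int16)
        total, _ = tree_log_likelihood(
            codons, ["A", "B", "C"], tree, uniform_pi, 2.0,
            np.array([1.0]), np.full((1, tree.n_nodes), 0.4),
        )
        oracle = brute_force_loglik(tree, ["A", "B", "C"], codons, uniform_pi, 2.0, 0.4)
        assert abs(total - oracle) < 1e-10

    def test_four_tip_two_internal_nodes_enumeration(self, uniform_pi):
        # 61^2 internal-state assignments
        tree = read_newick("((A:0.1,B:0.2):0.12,C:0.15,D:0.3);")
        rng = np.random.default_rng(5)
        codons = rng.integers(0, 61, (4, 2)).astype(np.int16)
        total, _ = tree_log_likelihood(
            codons, ["A", "B", "C", "D"], tree, uniform_pi, 1.5,
            np.array([1.0]), np.full((1, tree.n_nodes), 0.25),
        )
        oracle = brute_force_loglik(
            tree, ["A", "B", "C", "D"], codons, uniform_pi, 1.5, 0.25
        )
        assert abs(total - oracle) < 1e-10

    def test_root_placement_invariance(self, uniform_pi):
        rng = np.random.default_rng(6)
        codons = rng.integers(0, 61, (4, 5)).astype(np.int16)
        taxa = ["A", "B", "C", "D"]
        args = (uniform_pi, 2.0, np.array([1.0]))
        t1 = read_newick("((A:0.1,B:0.2):0.12,C:0.15,D:0.3);")
        l1, _ = tree_log_likelihood(
            codons, taxa, t1, *args, np.full((1, t1.n_nodes), 0.4)
        )
        # same unrooted shape written with a different basal arrangement
        t3 = read_newick("((A:0.1,B:0.2):0.06,(C:0.15,D:0.3):0.06);")
        l3, _ = tree_log_likelihood(
            codons, taxa, t3, *args, np.full((1, t3.n_nodes), 0.4)
        )
        assert abs(l1 - l3) < 1e-9

    def test_pattern_duplication_doubles_loglik(self, uniform_pi):
        tree = read_newick("(A:0.1,B:0.2,C:0.15);")
        rng = np.random.default_rng(7)
        codons = rng.integers(0, 61, (3, 6)).astype(np.int16)
        doubled = np.hstack([codons, codons])
        kw = dict(
            pi=uniform_pi, kappa=2.0, weights=np.array([1.0]),
            omega_edges=np.full((1, tree.n_nodes), 0.3),
        )
        l1, _ = tree_log_likelihood(codons, ["A", "B", "C"], tree, **kw)
        l2, _ = tree_log_likelihood(doubled, ["A", "B", "C"], tree, **kw)
        assert abs(l2 - 2 * l1) < 1e-9

    def test_missing_column_contributes_zero(self, uniform_pi):
        tree = read_newick("(A:0.1,B:0.2,C:0.15);")
        codons = np.array([[3, -1], [9, -1], [20, -1]], dtype=np.int16)
        kw = dict(
            pi=uniform_pi, kappa=2.0, weights=np.array([1.0]),
            omega_edges=np.full((1, tree.n_nodes), 0.3),
        )
        l_both, _ = tree_log_likelihood(codons, ["A", "B", "C"], tree, **kw)
        l_one, _ = tree_log_likelihood(codons[:, :1], ["A", "B", "C"], tree, **kw)
        assert abs(l_both - l_one) < 1e-12

    def test_m8_at_boundary_equals_m8a(self):
        aln = make_alignment({"A": "ATGAAACCCTGG", "B": "ATGCAACCATGG", "C": "ATGAAACCATGC"})
        tree = read_newick("(A:0.1,B:0.2,C:0.15);")
        pi = CodonFrequencies("equal", UNIF)
        shared = dict(p=0.4, q=1.2, p_ad=0.15, kappa=2.0)
        m8a = CodonModelSpec(family="M8A")
        m8 = CodonModelSpec(family="M8")
        l_null, _ = log_likelihood(aln, tree, m8a, shared, pi)
        l_alt, _ = log_likelihood(aln, tree, m8, {**shared, "omega_ad": 1.0}, pi)
        assert abs(l_null - l_alt) < 1e-12

    def test_invariant_site_at_zero_length(self, uniform_pi):
        # all branch lengths zero: an invariant site has probability
        # pi(state), a variable site probability zero
        tree = read_newick("(A:0.0,B:0.0,C:0.0);")
        codons = np.array([[10, 10], [10, 11], [10, 12]], dtype=np.int16)
        total, table = tree_log_likelihood(
            codons, ["A", "B", "C"], tree, uniform_pi, 2.0,
            np.array([1.0]), np.full((1, tree.n_nodes), 0.3),
        )
        assert abs(table[0, 0] - np.log(uniform_pi[10])) < 1e-9
        # a variable site is (numerically) impossible at zero length
        assert table[1, 0] < -25
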
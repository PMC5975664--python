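"""Tests of the collapsed variational bound and its optimiser."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from branchgp.inference import (
    AssignmentPrior,
    NoiseModel,
    OptimiserConfig,
    VariationalState,
    _full_core,
    build_assignment_prior,
    collapsed_bound,
    kl_assignment,
    optimise,
    sparse_collapsed_bound,
    update_assignments,
)
from branchgp.kernel import AugmentedInput, BranchingKernelSpec, branching_covariance
from branchgp.model import GlobalBranching
from conftest import random_instance


def exact_log_marginal(y, t, pi, spec, noise_variance):
    """Brute-force log p(Y) by enumerating every assignment Z.

    Independent oracle: sums p(Z) N(Y | 0, Z K Z' + s2 I) over the support
    of the categorical prior, using the full augmented covariance directly.
    """
    n = len(t)
    kmat = branching_covariance(spec, AugmentedInput.expand(t))
    free = np.flatnonzero((pi > 0).sum(axis=1) > 1)
    fixed = np.argmax(pi, axis=1)
    supports = [np.flatnonzero(pi[i] > 0) for i in free]
    terms = []
    for combo in itertools.product(*supports) if free.size else [()]:
        m = fixed.copy()
        for j, i in enumerate(free):
            m[i] = combo[j]
        idx = m * n + np.arange(n)
        cov = kmat[np.ix_(idx, idx)] + noise_variance * np.eye(n)
        logp_z = float(np.sum(np.log([pi[i, m[i]] for i in range(n)])))
        terms.append(logp_z + multivariate_normal.logpdf(y, np.zeros(n), cov))
    return logsumexp(terms)


class TestAssignmentPrior:
    def test_strong_prior_row(self, small_branching):
        pi = build_assignment_prior(small_branching, 0.3, 0.99).pi
        i = np.flatnonzero(small_branching.pseudotime >= 0.3)[0]
        expect = (0.0, 0.99, 0.01) if small_branching.label_codes[i] == 1 else (0.0, 0.01, 0.99)
        assert pi[i] == pytest.approx(expect)

    def test_cells_before_candidate_are_trunk_only(self, small_branching):
        pi = build_assignment_prior(small_branching, 0.5, 0.8).pi
        pre = small_branching.pseudotime < 0.5
        assert np.all(pi[pre] == [1.0, 0.0, 0.0])

    def test_simulation_study_confidence(self, small_branching):
        pi = build_assignment_prior(small_branching, 0.3, 0.80).pi
        post = small_branching.pseudotime >= 0.3
        assert np.allclose(np.sort(pi[post], axis=1)[:, 1:], [0.2, 0.8])

    def test_unlabelled_window_is_uninformative(self, small_branching):
        # candidate earlier than the global branching time
        pi = build_assignment_prior(small_branching, 0.1, 0.9).pi
        window = (small_branching.pseudotime >= 0.1) & (small_branching.pseudotime < 0.3)
        assert window.any()
        assert np.all(pi[window] == [0.0, 0.5, 0.5])

    @pytest.mark.parametrize("conf", [0.4, 1.0, 1.5])
    def test_confidence_out_of_range(self, small_branching, conf):
        with pytest.raises(ValueError):
            build_assignment_prior(small_branching, 0.3, conf)


class TestKL:
    def test_identity_is_zero(self):
        pi = np.tile([0.2, 0.3, 0.5], (4, 1))
        assert kl_assignment(VariationalState(pi), AssignmentPrior(pi)) == pytest.approx(0.0)

    def test_point_mass_against_even_prior(self):
        phi = np.array([[0.0, 1.0, 0.0]])
        pi = np.array([[0.0, 0.5, 0.5]])
        assert kl_assignment(VariationalState(phi), AssignmentPrior(pi)) == pytest.approx(np.log(2))

    def test_matches_double_sum_oracle(self, rng):
        phi = rng.dirichlet(np.ones(3), size=5)
        pi = rng.dirichlet(np.ones(3), size=5)
        expected = sum(
            phi[n, m] * np.log(phi[n, m] / pi[n, m]) for n in range(5) for m in range(3) if phi[n, m] > 0
        )
        got = kl_assignment(VariationalState(phi), AssignmentPrior(pi))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got >= 0.0

    def test_unsupported_mass_is_an_error(self):
        phi = np.array([[0.5, 0.5, 0.0]])
        pi = np.array([[1.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            kl_assignment(VariationalState(phi), AssignmentPrior(pi))


class TestCollapsedBound:
    def test_trunk_only_equals_gp_log_marginal(self, rng):
        # with all mass on the trunk the mixture collapses to GP regression
        n = 8
        t = np.sort(rng.uniform(0, 1, n))
        y = rng.normal(size=n)
        spec = BranchingKernelSpec(1.5, 0.7, 0.4)
        pi = np.zeros((n, 3))
        pi[:, 0] = 1.0
        state, prior = VariationalState(pi), AssignmentPrior(pi)
        got = collapsed_bound(y, t, state, spec, NoiseModel(0.3), prior)
        kff = branching_covariance(spec, AugmentedInput(t, np.ones(n, dtype=int)))
        expect = multivariate_normal.logpdf(y, np.zeros(n), kff + 0.3 * np.eye(n))
        assert got == pytest.approx(expect, rel=1e-10)

    def test_never_exceeds_enumeration_oracle(self, rng):
        # bound property on >= 50 random small instances, optimised over phi
        for _ in range(50):
            n = int(rng.integers(4, 7))
            y, gb = random_instance(rng, n=n)
            tb = float(np.quantile(gb.pseudotime, 0.3))
            spec = BranchingKernelSpec(float(rng.uniform(0.5, 3)), float(rng.uniform(0.3, 2)), tb)
            nv = float(rng.uniform(0.05, 0.5))
            prior = build_assignment_prior(gb, tb, 0.8)
            exact = exact_log_marginal(y, gb.pseudotime, prior.pi, spec, nv)
            phi = prior.pi.copy()
            for _ in range(30):
                _, aux = _full_core(
                    y, gb.pseudotime, VariationalState(phi).expanded_weights,
                    spec.signal_variance, spec.lengthscale, nv, tb, 1e-6, want_estep=True,
                )
                phi = update_assignments(y, prior, aux["mu"], aux["sdiag"], nv)
            bound = collapsed_bound(y, gb.pseudotime, VariationalState(phi), spec, NoiseModel(nv), prior)
            assert bound <= exact + 1e-8

    def test_gap_shrinks_with_well_separated_branches(self, rng):
        # low noise + separated branches: assignments become certain and
        # the bound approaches the exact marginal
        t = np.array([0.1, 0.2, 0.6, 0.7, 0.8, 0.9])
        labels = ["trunk", "trunk", "1", "2", "1", "2"]
        gb = GlobalBranching(t, labels, 0.5, "truth")
        y = np.array([0.0, 0.0, 1.0, -1.0, 1.5, -1.5])
        spec = BranchingKernelSpec(2.0, 0.8, 0.5)
        prior = build_assignment_prior(gb, 0.5, 0.8)
        gaps = []
        for nv in (0.5, 0.01):
            exact = exact_log_marginal(y, t, prior.pi, spec, nv)
            phi = prior.pi.copy()
            for _ in range(50):
                _, aux = _full_core(
                    y, t, VariationalState(phi).expanded_weights,
                    spec.signal_variance, spec.lengthscale, nv, 0.5, 1e-6, want_estep=True,
                )
                phi = update_assignments(y, prior, aux["mu"], aux["sdiag"], nv)
            bound = collapsed_bound(y, t, VariationalState(phi), spec, NoiseModel(nv), prior)
            assert bound <= exact + 1e-8
            gaps.append(exact - bound)
        assert gaps[1] < gaps[0]

    def test_zero_data_noise_doubling_matches_determinant_change(self):
        # with Y = 0 only the log-determinant terms move when s2 doubles
        n = 6
        t = np.linspace(0, 1, n)
        y = np.zeros(n)
        spec = BranchingKernelSpec(2.0, 1.0, 0.5)
        pi = np.zeros((n, 3))
        pi[:, 0] = 1.0
        state, prior = VariationalState(pi), AssignmentPrior(pi)
        kff = branching_covariance(spec, AugmentedInput(t, np.ones(n, dtype=int)))
        vals = {}
        for nv in (0.2, 0.4):
            vals[nv] = collapsed_bound(y, t, state, spec, NoiseModel(nv), prior)
        expected_change = -0.5 * (
            np.linalg.slogdet(kff + 0.4 * np.eye(n))[1] - np.linalg.slogdet(kff + 0.2 * np.eye(n))[1]
        )
        assert vals[0.4] - vals[0.2] == pytest.approx(expected_change, rel=1e-9)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 9))
            y, gb = random_instance(rng, n=n)
            tb = float(np.quantile(gb.pseudotime, 0.4))
            prior = build_assignment_prior(gb, tb, 0.8)
            w = VariationalState(prior.pi).expanded_weights
            theta = np.log([rng.uniform(0.5, 3), rng.uniform(0.3, 2), rng.uniform(0.05, 0.5)])
            _, aux = _full_core(y, gb.pseudotime, w, *np.exp(theta), tb, 1e-6, want_grad=True)
            fd = np.zeros(3)
            eps = 1e-5
            for i in range(3):
                up, dn = theta.copy(), theta.copy()
                up[i] += eps
                dn[i] -= eps
                fu, _ = _full_core(y, gb.pseudotime, w, *np.exp(up), tb, 1e-6)
                fdn, _ = _full_core(y, gb.pseudotime, w, *np.exp(dn), tb, 1e-6)
                fd[i] = (fu - fdn) / (2 * eps)
            assert np.allclose(aux["grad"], fd, rtol=1e-5, atol=1e-7)


class TestSparseBound:
    def _instance(self, rng, n=12):
        y, gb = random_instance(rng, n=n)
        tb = float(np.quantile(gb.pseudotime, 0.4))
        spec = BranchingKernelSpec(float(rng.uniform(0.5, 3)), float(rng.uniform(0.3, 2)), tb)
        noise = NoiseModel(float(rng.uniform(0.05, 0.5)))
        prior = build_assignment_prior(gb, tb, 0.8)
        state = VariationalState(prior.pi.copy())
        return y, gb.pseudotime, state, spec, noise, prior

    def test_full_inducing_set_recovers_full_bound(self, rng):
        for _ in range(20):
            y, t, state, spec, noise, prior = self._instance(rng)
            full = collapsed_bound(y, t, state, spec, noise, prior)
            sparse = sparse_collapsed_bound(y, t, state, spec, noise, prior, inducing=t)
            assert sparse == pytest.approx(full, rel=1e-6)

    def test_subset_never_exceeds_full_bound(self, rng):
        for _ in range(50):
            y, t, state, spec, noise, prior = self._instance(rng)
            full = collapsed_bound(y, t, state, spec, noise, prior)
            k = int(rng.integers(2, len(t) - 1))
            u = np.quantile(t, (np.arange(k) + 0.5) / k)
            sparse = sparse_collapsed_bound(y, t, state, spec, noise, prior, inducing=u)
            assert sparse <= full + 1e-8


class TestOptimise:
    def test_bound_trace_is_monotone(self, rng):
        y, gb = random_instance(rng, n=20)
        tb = float(np.quantile(gb.pseudotime, 0.5))
        res = optimise(y, gb, tb, OptimiserConfig(prior_confidence=0.8, n_inducing=0, max_outer=5))
        trace = np.array(res.trace)
        assert np.all(np.diff(trace) >= -1e-6 * (1 + np.abs(trace[:-1])))

    def test_recovers_well_separated_assignments(self):
        # two clearly separated branches at low noise: cells far from the
        # branch point are assigned to the generating branch with > 0.95
        t = np.linspace(0, 1, 40)
        tb = 0.3
        rng = np.random.default_rng(0)
        branch = np.where(t < tb, 0, 1 + (np.arange(40) % 2))
        f = np.where(branch == 1, 2.0 * (t - tb), -2.0 * (t - tb))
        f = np.where(branch == 0, 0.0, f)
        y = f + 0.03 * rng.standard_normal(40)
        labels = np.where(branch == 0, "trunk", branch.astype(str))
        gb = GlobalBranching(t, labels, tb, "truth")
        res = optimise(y, gb, tb, OptimiserConfig(prior_confidence=0.8, n_inducing=0, max_outer=6))
        far = t > tb + 0.2
        phi_true = res.state.phi[np.arange(40), branch]
        assert np.all(phi_true[far] > 0.95)

    def test_equidistant_cells_have_half_half_assignment(self):
        # a cell sitting exactly between the two branches is maximally
        # uncertain (0.5) under a symmetric prior
        t = np.concatenate([np.linspace(0, 0.28, 6), np.linspace(0.35, 1, 12), [0.995]])
        tb = 0.3
        branch = np.concatenate([np.zeros(6, int), 1 + (np.arange(12) % 2), [0]])
        f = np.where(branch == 1, 3.0 * (t - tb), -3.0 * (t - tb))
        f = np.where(branch == 0, 0.0, f)
        y = f.copy()
        y[-1] = 0.0  # equidistant from both branches
        labels = np.where(t < tb, "trunk", np.where(np.arange(19) % 2 == 0, "1", "2"))
        gb = GlobalBranching(t, labels, tb, "truth")
        res = optimise(y, gb, tb, OptimiserConfig(prior_confidence=0.5, n_inducing=0, max_outer=6))
        assert res.state.phi[-1, 1] == pytest.approx(0.5, abs=0.1)
        assert res.state.phi[-1, 2] == pytest.approx(0.5, abs=0.1)

    def test_pure_noise_gene_matches_iid_gaussian_fit(self, rng):
        # no structure: optimised signal variance is small and the bound is
        # close to the closed-form iid Gaussian log likelihood
        n = 40
        y, gb = random_instance(rng, n=n)
        res = optimise(y, gb, np.inf, OptimiserConfig(n_inducing=0, max_outer=3, lbfgs_maxiter_first=50))
        assert res.spec.signal_variance < 0.5 * np.var(y)
        sig2 = np.var(y)
        iid = -0.5 * n * np.log(2 * np.pi * sig2) - 0.5 * n
        assert res.bound == pytest.approx(iid, abs=0.15 * abs(iid))
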
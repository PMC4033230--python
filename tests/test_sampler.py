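import numpy as np
import pytest
import scipy.optimize
import scipy.stats

from mycoloop.model import compile_problem, evaluate_feasibility
from mycoloop.sampler import (InfeasibleProblemError, SamplerConfig,
                              compare_index_ensembles, initial_point,
                              null_space_decomposition, sample_polytope,
                              summarize_ensemble)
from mycoloop.synth import SynthConfig, generate_problem
from conftest import make_model


def interval_model(cap=1.0):
    """gpp-a = a-res with gpp-a <= cap: a one-dimensional box [0, cap]."""
    return compile_problem(make_model(
        "interval", [("a", "autotroph")], ["gpp-a", "a-res"],
        constraints=[("cap", "gpp-a", None, str(cap))]))


def simplex_model():
    """gpp-a + gpp-b = 1 with nonnegativity: the unit simplex."""
    return compile_problem(make_model(
        "simplex", [("a", "autotroph"), ("b", "autotroph")],
        ["gpp-a", "gpp-b", "a-res", "b-res"],
        equalities=[("total", "GPP", 1.0)]))


class TestInitialPoint:
    def test_fully_determined_system(self):
        problem = compile_problem(make_model(
            "pinned", [("a", "autotroph")], ["gpp-a", "a-res"],
            equalities=[("x", "gpp-a", 3.0)]))
        x = initial_point(problem)
        assert x == pytest.approx([3.0, 3.0])

    def test_box_interior(self):
        x = initial_point(interval_model())
        assert 0 < x[0] < 1

    def test_pavin_interior_point(self, pavin):
        problem, _ = pavin
        x = initial_point(problem)
        resid = np.abs(problem.E @ x - problem.f).max()
        assert resid <= 1e-6 * max(1.0, np.abs(problem.f).max())
        assert (problem.G @ x - problem.h).min() > 0

    def test_empty_polytope_raises(self):
        problem = compile_problem(make_model(
            "empty", [("a", "autotroph")], ["gpp-a", "a-res"],
            equalities=[("x", "gpp-a", 3.0)],
            constraints=[("cap", "gpp-a", None, "1")]))
        with pytest.raises(InfeasibleProblemError):
            initial_point(problem)


class TestMirrorWalk:
    def test_interval_uniform(self):
        ens = sample_polytope(interval_model(),
                              SamplerConfig(n_iterations=50_000, jump=0.4,
                                            seed=11, burn_in=1000, thinning=25))
        x = ens.column("gpp-a")
        se = (1 / 12) ** 0.5 / len(x) ** 0.5
        assert abs(x.mean() - 0.5) < 3 * se
        assert scipy.stats.kstest(x, "uniform").pvalue > 0.01

    def test_simplex_symmetry(self):
        ens = sample_polytope(simplex_model(),
                              SamplerConfig(n_iterations=30_000, jump=0.4, seed=7))
        means = ens.samples.mean(axis=0)
        se = 0.5 / (12 * 100) ** 0.5  # generous: effective n >= 100
        assert means[0] == pytest.approx(0.5, abs=3 * se)
        assert means[1] == pytest.approx(0.5, abs=3 * se)

    def test_seed_determinism(self, pavin):
        problem, _ = pavin
        cfg = SamplerConfig(n_iterations=500, seed=42)
        a = sample_polytope(problem, cfg)
        b = sample_polytope(problem, cfg)
        assert np.array_equal(a.samples, b.samples)
        c = sample_polytope(problem, SamplerConfig(n_iterations=500, seed=43))
        assert not np.array_equal(a.samples, c.samples)

    def test_feasibility_closure(self, pavin):
        problem, _ = pavin
        ens = sample_polytope(problem, SamplerConfig(n_iterations=2000, seed=5))
        assert ens.feasible.all()

    def test_rejection_oracle_on_synthetic_polytope(self):
        """Marginal flow means match uniform rejection sampling on a
        low-dimensional generated problem."""
        sp = generate_problem(SynthConfig(n_compartments=3, n_imports=1,
                                          with_detritus=False, window=0.4,
                                          edge_density=0.0, seed=3))
        problem = sp.problem
        x0, N = null_space_decomposition(problem)
        k = N.shape[1]
        assert k <= 4, "oracle needs a low-dimensional polytope"
        A = problem.G @ N
        b = problem.h - problem.G @ x0
        lo, hi = [], []
        for d in range(k):
            c = np.zeros(k)
            c[d] = 1.0
            r1 = scipy.optimize.linprog(c, A_ub=-A, b_ub=-b,
                                        bounds=[(None, None)] * k, method="highs")
            r2 = scipy.optimize.linprog(-c, A_ub=-A, b_ub=-b,
                                        bounds=[(None, None)] * k, method="highs")
            lo.append(r1.fun)
            hi.append(-r2.fun)
        rng = np.random.default_rng(17)
        pts = rng.uniform(lo, hi, size=(400_000, k))
        inside = pts[(pts @ A.T >= b - 1e-12).all(axis=1)]
        assert len(inside) > 1000
        oracle = x0[None, :] + inside @ N.T
        ens = sample_polytope(problem, SamplerConfig(
            n_iterations=60_000, jump=np.ptp(oracle, axis=0).max() / 3,
            seed=23, burn_in=1000, thinning=10))
        for j, fid in enumerate(problem.flow_ids):
            se_o = oracle[:, j].std() / len(inside) ** 0.5
            se_m = ens.samples[:, j].std() / (len(ens.samples) / 5) ** 0.5
            tol = 3 * np.hypot(se_o, se_m)
            assert ens.samples[:, j].mean() == pytest.approx(
                oracle[:, j].mean(), abs=max(tol, 1e-9)), fid


class TestSummaries:
    def test_identical_rows(self):
        problem = interval_model()
        ens = sample_polytope(problem, SamplerConfig(n_iterations=3, seed=1))
        ens.samples = np.tile(ens.samples[0], (5, 1))
        s = summarize_ensemble(ens)
        assert s.sd == pytest.approx([0.0, 0.0])
        assert s.mean == pytest.approx(ens.samples[0])

    def test_interval_quantiles(self):
        ens = sample_polytope(interval_model(),
                              SamplerConfig(n_iterations=50_000, jump=0.4, seed=2))
        s = summarize_ensemble(ens)
        assert s.q025[0] == pytest.approx(0.025, abs=0.02)
        assert s.q975[0] == pytest.approx(0.975, abs=0.02)

    def test_mean_is_feasible_and_in_envelope(self, pavin):
        """Convexity: the ensemble mean lies inside the polytope and inside
        the per-flow min-max envelope."""
        problem, _ = pavin
        ens = sample_polytope(problem, SamplerConfig(n_iterations=3000, seed=9))
        s = summarize_ensemble(ens, problem)
        assert s.mean_feasible
        assert (s.min <= s.mean + 1e-12).all()
        assert (s.mean <= s.max + 1e-12).all()


class TestTTest:
    def test_identical_samples(self):
        t, p = compare_index_ensembles([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(5, 1, 10_000)
        _, p = compare_index_ensembles(a, b)
        assert p < 1e-4

    def test_degenerate_zero_variance(self):
        assert compare_index_ensembles([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
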
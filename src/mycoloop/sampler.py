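"""Uniform sampling of the feasible flow polytope by a mirror random walk.

The equality system ``E x = f`` confines solutions to an affine subspace
``x = x0 + N q`` with ``N`` an orthonormal null-space basis.  Inequalities map
to half-spaces ``A q >= b`` in the reduced coordinates.  The walk proposes
Gaussian steps scaled by the *jump* parameter and, whenever a proposal leaves
the polytope, reflects it across the hyperplane of the (most) violated
constraint until it is inside again — the "mirror technique".  Because the
proposal is symmetric and reflection is an isometry, the chain's stationary
distribution is uniform over the polytope.

The defaults (jump 10 mgC m⁻² d⁻¹, 100,000 iterations, no burn-in, no
thinning) are the study conditions the built-in lake models were solved
under.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats

from .model import LIMProblem

__all__ = ["SamplerConfig", "FlowEnsemble", "FlowSummary", "InfeasibleProblemError",
           "initial_point", "sample_polytope", "summarize_ensemble",
           "compare_index_ensembles", "null_space_decomposition"]

_RANK_RTOL = 1e-10  # relative to the largest singular value


class InfeasibleProblemError(RuntimeError):
    """The constraint polytope is empty (or has no interior point)."""

    def __init__(self, message: str, violated: list[str] | None = None):
        super().__init__(message)
        self.violated = violated or []


@dataclass(frozen=True)
class SamplerConfig:
    """Mirror-walk settings.

    ``jump`` is the per-coordinate standard deviation of the Gaussian
    proposal, in flow units; ``n_iterations`` counts proposals after the
    start point.
    """

    n_iterations: int = 100_000
    jump: float = 10.0
    seed: int = 0
    burn_in: int = 0
    thinning: int = 1
    max_reflections: int = 1000
    tol_eq: float = 1e-6     # relative equality residual for feasibility flags
    tol_ineq: float = 1e-7   # absolute slack tolerance for feasibility flags

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.jump <= 0:
            raise ValueError("jump must be > 0")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must lie in [0, n_iterations)")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class FlowEnsemble:
    """Retained MCMC samples (rows) over the problem's flow index (columns)."""

    flow_ids: list[str]
    samples: np.ndarray
    config: SamplerConfig
    feasible: np.ndarray                 # per-row flag at config tolerances
    n_rejected: int = 0                  # moves that exceeded the reflection cap
    total_reflections: int = 0

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def column(self, fid: str) -> np.ndarray:
        return self.samples[:, self.flow_ids.index(fid)]


@dataclass
class FlowSummary:
    """Component-wise statistics of an ensemble."""

    flow_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    mean_feasible: bool = True

    def as_frame(self):
        import pandas as pd
        return pd.DataFrame({"mean": self.mean, "sd": self.sd, "min": self.min,
                             "max": self.max, "q025": self.q025, "q975": self.q975},
                            index=self.flow_ids)

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.flow_ids, self.mean.tolist()))


def null_space_decomposition(problem: LIMProblem) -> tuple[np.ndarray, np.ndarray]:
    """Particular solution and orthonormal null-space basis of ``E x = f``."""
    E, f = problem.E, problem.f
    if E.size == 0:
        return np.zeros(problem.n_flows), np.eye(problem.n_flows)
    x0, *_ = np.linalg.lstsq(E, f, rcond=None)
    if not np.allclose(E @ x0, f, atol=1e-8 * max(1.0, np.abs(f).max())):
        raise InfeasibleProblemError("equality system is inconsistent",
                                     violated=[lab for lab, r in
                                               zip(problem.eq_labels, E @ x0 - f)
                                               if abs(r) > 1e-8])
    N = scipy.linalg.null_space(E, rcond=_RANK_RTOL)
    return x0, N


def initial_point(problem: LIMProblem, method: str = "interior") -> np.ndarray:
    """A strictly feasible flow vector, or an explicit infeasibility error.

    ``interior`` (default) maximises the minimum inequality slack subject to
    the equalities — a slack-maximising linear program that lands well inside
    the polytope.  ``least_squares`` returns the minimum-norm solution of the
    equalities provided it satisfies the inequalities.
    """
    E, f, G, h = problem.E, problem.f, problem.G, problem.h
    n = problem.n_flows
    if method == "least_squares":
        x0, _ = null_space_decomposition(problem)
        slack = G @ x0 - h
        if slack.min() < 0:
            raise InfeasibleProblemError(
                "least-squares equality solution violates inequalities",
                violated=[problem.ineq_labels[i] for i in np.argsort(slack)[:5]])
        return x0
    if method != "interior":
        raise ValueError(f"unknown initial-point method {method!r}")
    # variables: x (n flows) and the common slack s; maximize s
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub = np.hstack([-G, np.ones((G.shape[0], 1))])
    b_ub = -h
    A_eq = np.hstack([E, np.zeros((E.shape[0], 1))]) if E.size else None
    b_eq = f if E.size else None
    scale = max(1.0, np.abs(h).max(), np.abs(f).max() if f.size else 0.0)
    bounds = [(None, None)] * n + [(None, 1e6 * scale)]
    res = scipy.optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                                 bounds=bounds, method="highs")
    if not res.success:
        raise InfeasibleProblemError(f"feasibility LP failed: {res.message}")
    x, s = res.x[:n], res.x[-1]
    if s <= 0:
        slack = G @ x - h
        raise InfeasibleProblemError(
            f"polytope has no interior point (best common slack {s:.3g})",
            violated=[problem.ineq_labels[i] for i in np.argsort(slack)[:5]])
    return x


def sample_polytope(problem: LIMProblem, config: SamplerConfig,
                    start: np.ndarray | None = None) -> FlowEnsemble:
    """Run the mirror walk and return the retained ensemble.

    Deterministic for a fixed ``(problem, config)``; every retained sample
    satisfies the inequalities up to the configured tolerances by
    construction (a proposal still outside the polytope after
    ``max_reflections`` reflections is rejected and the chain stays put).
    """
    x_start = initial_point(problem) if start is None else np.asarray(start, float)
    x0, N = null_space_decomposition(problem)
    k = N.shape[1]
    if k == 0:
        samples = np.tile(x_start, (1, 1))
        return FlowEnsemble(list(problem.flow_ids), samples, config,
                            feasible=np.array([True]))
    # reduced inequalities A q >= b
    A = problem.G @ N
    b = problem.h - problem.G @ x0
    norms = np.linalg.norm(A, axis=1)
    live = norms > 1e-12
    if np.any(~live & (b > 1e-9)):
        bad = [problem.ineq_labels[i] for i in np.nonzero(~live & (b > 1e-9))[0]]
        raise InfeasibleProblemError("constraints unsatisfiable on the equality "
                                     "subspace", violated=bad)
    A, b, norms = A[live], b[live], norms[live]
    An = A / norms[:, None]            # unit normals
    bn = b / norms
    q = N.T @ (x_start - x0)
    if np.min(An @ q - bn) < -1e-6:
        raise InfeasibleProblemError("start point is outside the polytope")
    rng = np.random.default_rng(config.seed)
    kept: list[np.ndarray] = []
    n_rejected = 0
    total_reflections = 0
    for it in range(config.n_iterations):
        prop = q + rng.normal(0.0, config.jump, size=k)
        ok = True
        for _ in range(config.max_reflections):
            viol = An @ prop - bn
            i = int(np.argmin(viol))
            if viol[i] >= 0:
                break
            prop = prop - 2.0 * viol[i] * An[i]
            total_reflections += 1
        else:
            ok = False
            n_rejected += 1
        if ok:
            q = prop
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            kept.append(q.copy())
    Q = np.array(kept)
    X = x0[None, :] + Q @ N.T
    slack_min = (X @ problem.G.T - problem.h).min(axis=1)
    scale = max(1.0, float(np.abs(problem.f).max()) if problem.f.size else 1.0)
    eq_res = (np.abs(X @ problem.E.T - problem.f).max(axis=1) / scale
              if problem.E.size else np.zeros(len(X)))
    feas = (slack_min >= -config.tol_ineq * max(1.0, scale)) & (eq_res <= config.tol_eq)
    return FlowEnsemble(list(problem.flow_ids), X, config, feasible=feas,
                        n_rejected=n_rejected, total_reflections=total_reflections)


def summarize_ensemble(ensemble: FlowEnsemble,
                       problem: LIMProblem | None = None) -> FlowSummary:
    """Per-flow mean, spread and central 95% interval of an ensemble."""
    S = ensemble.samples
    if S.size == 0:
        raise ValueError("empty ensemble")
    summary = FlowSummary(
        flow_ids=list(ensemble.flow_ids),
        mean=S.mean(axis=0), sd=S.std(axis=0, ddof=1) if len(S) > 1 else np.zeros(S.shape[1]),
        min=S.min(axis=0), max=S.max(axis=0),
        q025=np.quantile(S, 0.025, axis=0), q975=np.quantile(S, 0.975, axis=0))
    if problem is not None:
        from .model import evaluate_feasibility
        summary.mean_feasible = evaluate_feasibility(
            problem, summary.mean, tol_eq=1e-6, tol_ineq=1e-6).feasible
    return summary


def compare_index_ensembles(a, b) -> tuple[float, float]:
    """Classical two-sample two-tailed t test between two index ensembles.

    Returns ``(t, p)``.  Two degenerate equal-mean zero-variance samples give
    ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each ensemble needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
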
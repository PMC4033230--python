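"""Synthetic linear inverse food-web problems with known true flows.

The generator emulates the structural assumptions of the lake bloom models
rather than arbitrary digraphs: exogenous input enters only as gross primary
production into producer compartments, every living compartment respires,
some compartments export (sinking/loss), and the web is a feed-forward
grazing chain (optionally with a detrital pool).  The "true" flow vector is
built by routing the imports through random per-compartment output
proportions, so every mass balance holds exactly by construction; equality
and two-sided interval constraints are then placed around the truth with the
truth strictly interior.  This makes every generated problem a ground-truthed
test case for the sampler and the index suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (CompartmentSpec, ConstraintSpec, EqualitySpec, FlowSpec,
                    LIMProblem, ModelConfig, compile_problem)

__all__ = ["SynthConfig", "SynthProblem", "generate_problem",
           "generate_bloom_like", "fixture_networks", "fixture_problem"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``window`` is the half-width, relative to the true value, of the interval
    constraints placed around true flow ratios (0.3 → ±30%).
    """

    n_compartments: int = 5
    edge_density: float = 0.5        # probability of each allowed grazing arc
    n_imports: int = 2
    magnitude: float = 100.0         # total import, mgC m⁻² d⁻¹
    window: float = 0.3
    with_detritus: bool = True
    n_pinned_flows: int = 1          # individual flows fixed by equalities
    seed: int = 0

    def __post_init__(self):
        if self.n_compartments < 2:
            raise ValueError("need at least two compartments")
        if not 0 < self.window:
            raise ValueError("window must be positive")
        if not 1 <= self.n_imports <= self.n_compartments:
            raise ValueError("n_imports out of range")


@dataclass
class SynthProblem:
    """A compiled problem plus the strictly feasible truth it was built from."""

    problem: LIMProblem
    truth: dict[str, float]
    config: SynthConfig

    @property
    def truth_vector(self) -> np.ndarray:
        return self.problem.vector(self.truth)


def _make_topology(cfg: SynthConfig, rng: np.random.Generator) -> ModelConfig:
    n = cfg.n_compartments
    names = [f"c{i}" for i in range(n)]
    comps = [CompartmentSpec(id=c, name=f"synthetic compartment {c}",
                             kind="living",
                             tags=frozenset({"autotroph"} if i < cfg.n_imports
                                            else {"heterotroph"}))
             for i, c in enumerate(names)]
    flows: list[str] = [f"gpp-{c}" for c in names[:cfg.n_imports]]
    flows += [f"{c}-res" for c in names]
    # feed-forward grazing arcs; guarantee connectivity via a spine
    for j in range(1, n):
        prey = names[rng.integers(0, j)]
        flows.append(f"{prey}-{names[j]}")
    for i in range(n):
        for j in range(i + 1, n):
            fid = f"{names[i]}-{names[j]}"
            if fid not in flows and rng.random() < cfg.edge_density:
                flows.append(fid)
    if cfg.with_detritus:
        comps.append(CompartmentSpec(id="det", name="synthetic detrital pool",
                                     kind="nonliving", tags=frozenset({"detrital"})))
        for c in rng.choice(names, size=max(1, n // 2), replace=False):
            flows.append(f"{c}-det")
        flows.append("det-los")
    # terminal compartments must export
    for j, c in enumerate(names):
        preys_on = any(f.startswith(f"{c}-") and not f.endswith(("-res", "-det", "-los"))
                       for f in flows)
        if not preys_on or rng.random() < 0.5:
            flows.append(f"{c}-los")
    return ModelConfig(name=f"synthetic_{cfg.seed}", compartments=comps,
                       flows=[FlowSpec.from_id(f) for f in dict.fromkeys(flows)])


def _route_truth(config: ModelConfig, cfg: SynthConfig,
                 rng: np.random.Generator) -> dict[str, float]:
    """Propagate imports through random output proportions (exact balance)."""
    comp_ids = [c.id for c in config.compartments]
    imports = {f.target: 0.0 for f in config.flows if f.is_import}
    weights = rng.dirichlet(np.ones(len(imports)))
    for w, c in zip(weights, imports):
        imports[c] = cfg.magnitude * float(w)
    truth = {f"gpp-{c}": v for c, v in imports.items()}
    inputs = dict.fromkeys(comp_ids, 0.0)
    for c, v in imports.items():
        inputs[c] += v
    # compartments are topologically ordered by construction (det last)
    for c in comp_ids:
        outs = [f for f in config.flows if f.source == c]
        shares = rng.dirichlet(np.ones(len(outs)) * 2.0)
        for f, s in zip(outs, shares):
            v = inputs[c] * float(s)
            truth[f.id] = v
            if f.is_internal:
                inputs[f.target] += v
    return truth


def generate_problem(config: SynthConfig) -> SynthProblem:
    """Generate a random feasible LIM problem with its known truth."""
    rng = np.random.default_rng(config.seed)
    for attempt in range(10):
        topo = _make_topology(config, rng)
        truth = _route_truth(topo, config, rng)
        eqs = [EqualitySpec(label="total import", expr="GPP",
                            value=sum(v for f, v in truth.items()
                                      if f.startswith("gpp-")))]
        internal = [f.id for f in topo.flows if f.is_internal]
        pinnable = [f for f in internal if truth[f] > 1e-9]
        rng.shuffle(pinnable)
        for fid in pinnable[:config.n_pinned_flows]:
            eqs.append(EqualitySpec(label=f"measured flow {fid}", expr=fid,
                                    value=truth[fid]))
        cons = []
        w = config.window
        for fl in topo.flows:
            if fl.is_import or truth[fl.id] <= 1e-9:
                continue
            lo, hi = (1 - w) * truth[fl.id], (1 + w) * truth[fl.id]
            cons.append(ConstraintSpec(label=f"window {fl.id}", expr=fl.id,
                                       min=f"{lo:.12g}", max=f"{hi:.12g}"))
        model = ModelConfig(name=topo.name, compartments=topo.compartments,
                            flows=topo.flows, equalities=eqs, constraints=cons)
        problem = compile_problem(model)
        x = problem.vector(truth)
        slack = problem.G @ x - problem.h
        resid = np.abs(problem.E @ x - problem.f).max()
        # truth must be interior to every window (zero-valued flows sit on
        # their nonnegativity bound, which the walk never needs to cross)
        if resid < 1e-8:
            return SynthProblem(problem=problem, truth=truth, config=config)
    raise RuntimeError("could not generate an interior-feasible problem; "
                       "widen the constraint window")


def generate_bloom_like(base: ModelConfig, gpp_scale: float,
                        seed: int | None = None) -> ModelConfig:
    """A bloom-intensity variant of a built-in model.

    Scales every equality constant and every biomass by ``gpp_scale``;
    topology and relative constraint windows are unchanged.  ``seed`` is
    accepted for interface symmetry with the generator (the transform itself
    is deterministic).
    """
    if gpp_scale <= 0:
        raise ValueError("gpp_scale must be positive")
    comps = [CompartmentSpec(id=c.id, name=c.name, kind=c.kind,
                             biomass=None if c.biomass is None else c.biomass * gpp_scale,
                             tags=c.tags)
             for c in base.compartments]
    eqs = [EqualitySpec(label=e.label, expr=e.expr, value=e.value * gpp_scale)
           for e in base.equalities]
    name = base.name if gpp_scale == 1 else f"{base.name}_x{gpp_scale:g}"
    return ModelConfig(name=name, compartments=comps, flows=list(base.flows),
                       equalities=eqs, constraints=list(base.constraints))


def fixture_problem(name: str):
    """Compiled built-in model plus its packaged mean-flow vector."""
    from .model import builtin_models
    from .io import fixture_flow_table, flow_table_to_mapping

    config = builtin_models()[name]
    problem = compile_problem(config)
    flows = flow_table_to_mapping(fixture_flow_table(name))
    return problem, flows


def fixture_networks():
    """The packaged mean-flow networks, keyed by model name."""
    from .model import builtin_models
    from .network import to_flow_network

    out = {}
    for name in builtin_models():
        problem, flows = fixture_problem(name)
        out[name] = to_flow_network(flows, problem)
    return out
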
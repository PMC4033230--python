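"""Declarative steady-state carbon-flow food web models.

A model is declared as compartments plus flows named ``src-dst`` (imports
``gpp-<c>``, dissipations ``<c>-res``, exports ``<c>-los``), together with
measured-flow equalities and ecological inequality constraints.  Compilation
produces a linear inverse problem (LIM): an underdetermined equality system
``E x = f`` (one mass balance per compartment plus the measured flows) and an
inequality system ``G x >= h`` (ecological bounds plus nonnegativity) over the
flow vector ``x`` in mgC m⁻² d⁻¹.  The feasible set is a convex polytope which
the mirror sampler explores.

Built-in models cover the two lake bloom food webs shipped with the package:
a spring diatom bloom in a deep oligo-mesotrophic lake and an autumn
cyanobacteria bloom in a shallow eutrophic lake, both with chytrid parasite
compartments (host-attached sporangia ``spg`` and free-living zoospores
``zsp``) grafted onto the classical plankton web.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .expressions import ExpressionError, LinearExpression, parse_expression

__all__ = [
    "EXTERNAL", "DISSIPATION",
    "CompartmentSpec", "FlowSpec", "EqualitySpec", "ConstraintSpec",
    "ModelConfig", "LIMProblem", "FeasibilityReport",
    "ConfigurationError", "build_topology", "assemble_equalities",
    "assemble_inequalities", "compile_problem", "evaluate_feasibility",
    "builtin_models",
]

logger = logging.getLogger(__name__)

EXTERNAL = "EXTERNAL"
DISSIPATION = "DISSIPATION"

_KINDS = {"living", "nonliving"}
_TAGS = {"autotroph", "heterotroph", "parasite-sporangia", "parasite-zoospore", "detrital"}


class ConfigurationError(ValueError):
    """A model declaration is internally inconsistent."""


@dataclass(frozen=True)
class CompartmentSpec:
    """One model compartment (carbon pool)."""

    id: str
    name: str = ""
    kind: str = "living"
    biomass: float | None = None  # mgC m⁻², used only by biomass-linked bounds
    tags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigurationError(f"compartment {self.id!r}: kind must be living|nonliving")
        if self.biomass is not None and self.biomass < 0:
            raise ConfigurationError(f"compartment {self.id!r}: negative biomass")
        bad = set(self.tags) - _TAGS
        if bad:
            raise ConfigurationError(f"compartment {self.id!r}: unknown tags {sorted(bad)}")


@dataclass(frozen=True)
class FlowSpec:
    """One carbon flow, identified by its canonical ``src-dst`` code."""

    id: str
    source: str
    target: str

    @classmethod
    def from_id(cls, fid: str) -> "FlowSpec":
        parts = fid.split("-")
        if len(parts) != 2 or not all(parts):
            raise ConfigurationError(f"flow id {fid!r} is not of the form 'src-dst'")
        src, dst = parts
        source = EXTERNAL if src == "gpp" else src
        target = DISSIPATION if dst == "res" else (EXTERNAL if dst == "los" else dst)
        return cls(fid, source, target)

    @property
    def is_import(self) -> bool:
        return self.source == EXTERNAL

    @property
    def is_export(self) -> bool:
        return self.target == EXTERNAL

    @property
    def is_dissipation(self) -> bool:
        return self.target == DISSIPATION

    @property
    def is_internal(self) -> bool:
        return not (self.is_import or self.is_export or self.is_dissipation)


@dataclass(frozen=True)
class EqualitySpec:
    """A measured-flow equality ``expr = value`` (mgC m⁻² d⁻¹)."""

    label: str
    expr: str
    value: float

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ConfigurationError(f"equality {self.label!r}: value not finite")


@dataclass(frozen=True)
class ConstraintSpec:
    """A one- or two-sided bound on a linear expression.

    ``min`` and ``max`` are themselves expression strings (so bounds can be
    proportional to aggregates such as ``0.6 * GPP``).  Two-sided bounds are
    compiled to two one-sided rows ``expr - min >= 0`` and ``max - expr >= 0``.
    """

    label: str
    expr: str
    min: str | None = None
    max: str | None = None
    provenance: str = ""

    def __post_init__(self):
        if self.min is None and self.max is None:
            raise ConfigurationError(f"constraint {self.label!r} has no bound")


@dataclass
class ModelConfig:
    """A declarative food-web model (pre-compilation)."""

    name: str
    compartments: list[CompartmentSpec]
    flows: list[FlowSpec]
    equalities: list[EqualitySpec] = field(default_factory=list)
    constraints: list[ConstraintSpec] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for c in self.compartments:
            if c.id in seen:
                raise ConfigurationError(f"duplicate compartment id {c.id!r}")
            seen.add(c.id)
        fseen = set()
        comp_ids = {c.id for c in self.compartments}
        for fl in self.flows:
            if fl.id in fseen:
                raise ConfigurationError(f"duplicate flow id {fl.id!r}")
            fseen.add(fl.id)
            for end, role in ((fl.source, "source"), (fl.target, "target")):
                if end not in (EXTERNAL, DISSIPATION) and end not in comp_ids:
                    raise ConfigurationError(
                        f"flow {fl.id!r}: unknown {role} compartment {end!r}")

    # -- convenience lookups ----------------------------------------------
    def compartment(self, cid: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def flow_ids(self) -> list[str]:
        return [f.id for f in self.flows]

    def autotroph_ids(self) -> list[str]:
        return [c.id for c in self.compartments if "autotroph" in c.tags]

    # -- named aggregates --------------------------------------------------
    def resolve_aggregate(self, name: str, arg: str | None) -> LinearExpression:
        """Resolve a named linear aggregate used in constraint expressions."""
        flows = self.flows

        def total(pred) -> LinearExpression:
            return LinearExpression({f.id: 1.0 for f in flows if pred(f)})

        if name == "GPP" and arg is None:
            return total(lambda f: f.is_import)
        if name == "NPP" and arg is None:
            expr = total(lambda f: f.is_import)
            for aid in self.autotroph_ids():
                rid = f"{aid}-res"
                if rid in {f.id for f in flows}:
                    expr = expr - LinearExpression({rid: 1.0})
            return expr
        if name == "NPP" and arg is not None:
            ids = {f.id for f in flows}
            gid, rid = f"gpp-{arg}", f"{arg}-res"
            if gid not in ids or rid not in ids:
                raise ExpressionError(f"NPP({arg}): flows {gid}/{rid} not declared")
            return LinearExpression({gid: 1.0, rid: -1.0})
        if name == "Ing" and arg is not None:
            expr = total(lambda f: f.is_internal and f.target == arg)
            if not expr.terms:
                raise ExpressionError(f"Ing({arg}): no ingestion flows declared")
            return expr
        if name == "Det_total" and arg is None:
            return total(lambda f: f.target == "det")
        if name == "Los_total" and arg is None:
            return total(lambda f: f.is_export)
        if name == "BP" and arg is None:
            return LinearExpression({"doc-bac": 1.0, "bac-res": -1.0})
        if name == "Biom" and arg is not None:
            comp = self.compartment(arg)
            if comp.biomass is None:
                raise _MissingBiomass(arg)
            return LinearExpression(constant=comp.biomass)
        raise ExpressionError(f"unknown aggregate {name!r}")

    def parse(self, text: str) -> LinearExpression:
        return parse_expression(text, {f.id for f in self.flows}, self.resolve_aggregate)


class _MissingBiomass(ExpressionError):
    def __init__(self, cid: str):
        super().__init__(f"biomass of compartment {cid!r} is not supplied")
        self.compartment = cid


@dataclass
class LIMProblem:
    """A compiled linear inverse problem ``E x = f``, ``G x >= h``."""

    config: ModelConfig
    flow_ids: list[str]
    E: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    f: np.ndarray = field(default_factory=lambda: np.zeros(0))
    G: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    h: np.ndarray = field(default_factory=lambda: np.zeros(0))
    eq_labels: list[str] = field(default_factory=list)
    ineq_labels: list[str] = field(default_factory=list)
    n_mass_balance: int = 0
    n_nonneg: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_flows(self) -> int:
        return len(self.flow_ids)

    @property
    def flow_index(self) -> dict[str, int]:
        return {fid: i for i, fid in enumerate(self.flow_ids)}

    def vector(self, flows: Mapping[str, float]) -> np.ndarray:
        """Order a flow mapping into the problem's flow vector."""
        try:
            return np.array([flows[fid] for fid in self.flow_ids], dtype=float)
        except KeyError as exc:
            raise ValueError(f"flow vector missing {exc.args[0]!r}") from exc

    def mapping(self, x: Sequence[float]) -> dict[str, float]:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_flows,):
            raise ValueError(f"flow vector has shape {x.shape}, expected ({self.n_flows},)")
        return dict(zip(self.flow_ids, x.tolist()))


def build_topology(config: ModelConfig) -> LIMProblem:
    """Build the LIM skeleton: ordered flow index plus nonnegativity rows."""
    if not config.compartments:
        raise ConfigurationError("model declares no compartments")
    if not config.flows:
        raise ConfigurationError("model declares no flows")
    n = len(config.flows)
    problem = LIMProblem(config=config, flow_ids=[f.id for f in config.flows])
    problem.G = np.eye(n)
    problem.h = np.zeros(n)
    problem.ineq_labels = [f"nonnegativity: {fid} >= 0" for fid in problem.flow_ids]
    problem.n_nonneg = n
    return problem


def assemble_equalities(problem: LIMProblem, config: ModelConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Install mass-balance rows (one per compartment) and measured equalities."""
    config = config or problem.config
    n = problem.n_flows
    idx = problem.flow_index
    rows, rhs, labels = [], [], []
    for comp in config.compartments:
        row = np.zeros(n)
        for fl in config.flows:
            if fl.target == comp.id:
                row[idx[fl.id]] += 1.0
            if fl.source == comp.id:
                row[idx[fl.id]] -= 1.0
        rows.append(row)
        rhs.append(0.0)
        labels.append(f"mass balance: {comp.id}")
    problem.n_mass_balance = len(config.compartments)
    for eq in config.equalities:
        try:
            expr = config.parse(eq.expr)
        except ExpressionError as exc:
            raise ConfigurationError(f"equality {eq.label!r}: {exc}") from exc
        rows.append(expr.row(idx, n))
        rhs.append(eq.value - expr.constant)
        labels.append(eq.label)
    problem.E = np.array(rows)
    problem.f = np.array(rhs)
    problem.eq_labels = labels
    return problem.E, problem.f


def assemble_inequalities(problem: LIMProblem, config: ModelConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Compile ecological constraints to one-sided rows ``G x >= h``.

    A constraint whose bound needs a biomass that the config does not supply
    is skipped with a logged warning (recorded on the problem), mirroring how
    unquantified biomass-linked bounds are handled in practice.
    """
    config = config or problem.config
    n = problem.n_flows
    idx = problem.flow_index
    rows = [np.eye(n)[i] for i in range(n)]
    rhs = [0.0] * n
    labels = [f"nonnegativity: {fid} >= 0" for fid in problem.flow_ids]
    for con in config.constraints:
        try:
            expr = config.parse(con.expr)
            bounds = []
            if con.min is not None:
                bounds.append((config.parse(con.min), "lower"))
            if con.max is not None:
                bounds.append((config.parse(con.max), "upper"))
        except _MissingBiomass as exc:
            msg = (f"constraint {con.label!r} skipped: biomass of "
                   f"{exc.compartment!r} not supplied")
            logger.warning(msg)
            problem.warnings.append(msg)
            continue
        except ExpressionError as exc:
            raise ConfigurationError(f"constraint {con.label!r}: {exc}") from exc
        for bexpr, side in bounds:
            diff = expr - bexpr if side == "lower" else bexpr - expr
            rows.append(diff.row(idx, n))
            rhs.append(-diff.constant)
            labels.append(f"{con.label} [{side}]")
    problem.G = np.array(rows)
    problem.h = np.array(rhs)
    problem.ineq_labels = labels
    problem.n_nonneg = n
    return problem.G, problem.h


def compile_problem(config: ModelConfig) -> LIMProblem:
    """Topology, equalities and inequalities in one call."""
    problem = build_topology(config)
    assemble_equalities(problem, config)
    assemble_inequalities(problem, config)
    return problem


# ---------------------------------------------------------------------------
# feasibility checking


@dataclass
class FeasibilityReport:
    """Row-by-row residuals and slacks of a flow vector against a LIM."""

    eq_labels: list[str]
    eq_residuals: np.ndarray         # signed, mgC m⁻² d⁻¹
    eq_relative: np.ndarray          # |residual| / row scale
    ineq_labels: list[str]
    ineq_slacks: np.ndarray          # G x - h, >= 0 when satisfied
    tol_eq: float
    tol_ineq: float

    @property
    def violated_equalities(self) -> list[str]:
        return [lab for lab, rel in zip(self.eq_labels, self.eq_relative)
                if rel > self.tol_eq]

    @property
    def violated_inequalities(self) -> list[str]:
        return [lab for lab, s in zip(self.ineq_labels, self.ineq_slacks)
                if s < -self.tol_ineq]

    @property
    def feasible(self) -> bool:
        return not self.violated_equalities and not self.violated_inequalities

    def summary(self) -> str:
        lines = [f"feasible: {self.feasible} "
                 f"(tol_eq={self.tol_eq:g} rel, tol_ineq={self.tol_ineq:g} abs)"]
        for lab in self.violated_equalities:
            i = self.eq_labels.index(lab)
            lines.append(f"  EQ  {lab}: residual {self.eq_residuals[i]:+.4f} "
                         f"({100 * self.eq_relative[i]:.2f}% of row scale)")
        for lab in self.violated_inequalities:
            i = self.ineq_labels.index(lab)
            lines.append(f"  INEQ {lab}: slack {self.ineq_slacks[i]:+.4f}")
        return "\n".join(lines)


def evaluate_feasibility(problem: LIMProblem, flows: Mapping[str, float] | Sequence[float],
                         tol_eq: float = 0.01, tol_ineq: float = 0.5) -> FeasibilityReport:
    """Check a flow vector against every compiled row.

    Equality residuals are compared relative to a per-row scale — for a mass
    balance, the compartment's gross throughput; for a measured equality, the
    measured value — so that a vector transcribed from a table rounded to two
    decimals is not rejected for accumulated rounding.  Inequality slacks are
    compared absolutely (mgC m⁻² d⁻¹).
    """
    x = flows if isinstance(flows, np.ndarray) else (
        problem.vector(flows) if isinstance(flows, Mapping) else np.asarray(flows, float))
    if x.shape != (problem.n_flows,):
        raise ValueError(f"flow vector has shape {x.shape}, expected ({problem.n_flows},)")
    resid = problem.E @ x - problem.f
    pos = np.clip(problem.E, 0, None) @ np.abs(x)
    neg = np.clip(-problem.E, 0, None) @ np.abs(x)
    scale = np.maximum.reduce([pos, neg, np.abs(problem.f), np.full_like(resid, 1e-9)])
    slacks = problem.G @ x - problem.h
    return FeasibilityReport(
        eq_labels=list(problem.eq_labels), eq_residuals=resid,
        eq_relative=np.abs(resid) / scale,
        ineq_labels=list(problem.ineq_labels), ineq_slacks=slacks,
        tol_eq=tol_eq, tol_ineq=tol_ineq)


def with_swapped_bacterivory(config: ModelConfig) -> ModelConfig:
    """Variant of a model with the two measured bacterivory values exchanged.

    The autumn-bloom model pins bacterivory by nanoflagellates (bac-hnf) and
    by microzooplankton (bac-mic); the default assignment follows the
    realized flow table.  This toggle returns the alternative reading in
    which the two measured values are attributed the other way round.
    """
    swaps = {"bac-hnf": "bac-mic", "bac-mic": "bac-hnf"}
    eqs = []
    by_expr = {e.expr.strip(): e for e in config.equalities}
    for eq in config.equalities:
        other = swaps.get(eq.expr.strip())
        if other and other in by_expr:
            eqs.append(EqualitySpec(label=eq.label, expr=eq.expr,
                                    value=by_expr[other].value))
        else:
            eqs.append(eq)
    return ModelConfig(name=f"{config.name}_swapped_bacterivory",
                       compartments=list(config.compartments),
                       flows=list(config.flows), equalities=eqs,
                       constraints=list(config.constraints))


def builtin_models() -> dict[str, ModelConfig]:
    """The packaged lake bloom models, keyed by name.

    Returns at least ``pavin_spring_bloom`` (diatom bloom, 53 flows) and
    ``aydat_autumn_bloom`` (cyanobacteria bloom, 54 flows; the
    microzooplankton additionally consumes detritus, flow ``det-mic``).
    """
    from . import io as _io
    from importlib import resources

    out: dict[str, ModelConfig] = {}
    data = resources.files("mycoloop") / "data"
    for entry in sorted(data.iterdir()):
        if entry.name.endswith(".yaml"):
            cfg = _io.read_model(entry)
            out[cfg.name] = cfg
    return out
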
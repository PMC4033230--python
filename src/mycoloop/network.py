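"""Ecological network analysis of a realized flow network.

A :class:`FlowNetwork` partitions a feasible flow vector into imports ``Z``
(gross primary production), internal compartment-to-compartment transfers
``T``, exports ``E`` (sinking and losses to higher trophic levels) and
dissipations ``R`` (respiration).  All indices are computed from this
partition.

Conventions (validated against the built-in lake fixtures; see
docs/methods.md):

* ``TST`` is the sum over *all* flows: imports + internal + exports +
  dissipations.
* Information indices are computed on the extended flow matrix — the
  compartments plus one import source node, one export sink and one
  dissipation sink.  ``AMI`` uses base-2 logarithms (bits).
* The development capacity is the throughput-diversity form
  ``DC = TST * H(node output throughputs)`` (import node included); its
  internal counterpart ``DCi`` drops the import node's entropy term.
  ``Ai`` is the internal-transfer part of the ascendency sum and
  ``Ri = DCi - Ai``, so ``Ai + Ri = DCi`` by construction.
* Effective connectance is ``2**(Hc/2)`` with ``Hc`` the flow-weighted
  conditional entropy, on (a) all transfers, (b) internal transfers, and
  (c) transfers among living compartments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import LIMProblem

__all__ = ["FlowNetwork", "ENAReport", "DietTable", "to_flow_network",
           "total_system_throughput", "average_path_length",
           "information_indices", "connectance_indices", "diet_composition",
           "contribution_shares", "detritivory_herbivory", "mycoloop_metrics",
           "ena_report"]

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)


@dataclass
class FlowNetwork:
    """Realized flows partitioned by boundary role."""

    compartments: list[str]
    living: dict[str, bool]
    imports: dict[str, float]                    # compartment -> Z
    internal: dict[tuple[str, str], float]       # (src, dst) -> T
    exports: dict[str, float]                    # compartment -> E
    dissipations: dict[str, float]               # compartment -> R

    def __post_init__(self):
        for group in (self.imports, self.exports, self.dissipations):
            for c, v in group.items():
                if v < 0:
                    raise ValueError(f"negative boundary flow at {c!r}: {v}")
        for (a, b), v in self.internal.items():
            if v < 0:
                raise ValueError(f"negative internal flow {a}-{b}: {v}")

    # -- totals ------------------------------------------------------------
    @property
    def total_import(self) -> float:
        return sum(self.imports.values())

    def input_throughput(self, c: str) -> float:
        """Total carbon input of one compartment (imports + internal inflows)."""
        return (self.imports.get(c, 0.0)
                + sum(v for (a, b), v in self.internal.items() if b == c))

    def output_throughput(self, c: str) -> float:
        return (self.exports.get(c, 0.0) + self.dissipations.get(c, 0.0)
                + sum(v for (a, b), v in self.internal.items() if a == c))

    def compartment_throughputs(self) -> dict[str, float]:
        return {c: self.input_throughput(c) for c in self.compartments}

    def extended_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Flows on compartments + [import source, export sink, dissipation sink]."""
        n = len(self.compartments)
        idx = {c: i for i, c in enumerate(self.compartments)}
        T = np.zeros((n + 3, n + 3))
        for c, v in self.imports.items():
            T[n, idx[c]] = v
        for (a, b), v in self.internal.items():
            T[idx[a], idx[b]] = v
        for c, v in self.exports.items():
            T[idx[c], n + 1] = v
        for c, v in self.dissipations.items():
            T[idx[c], n + 2] = v
        return T, self.compartments + ["<import>", "<export>", "<dissipation>"]

    def internal_matrix(self) -> np.ndarray:
        n = len(self.compartments)
        idx = {c: i for i, c in enumerate(self.compartments)}
        T = np.zeros((n, n))
        for (a, b), v in self.internal.items():
            T[idx[a], idx[b]] = v
        return T

    def scaled(self, k: float) -> "FlowNetwork":
        return FlowNetwork(
            list(self.compartments), dict(self.living),
            {c: k * v for c, v in self.imports.items()},
            {e: k * v for e, v in self.internal.items()},
            {c: k * v for c, v in self.exports.items()},
            {c: k * v for c, v in self.dissipations.items()})


@dataclass
class DietTable:
    """Prey fractions of one consumer's total ingestion."""

    consumer: str
    fractions: dict[str, float] = field(default_factory=dict)
    total_ingestion: float = 0.0


@dataclass
class ENAReport:
    """The topological index bundle for one realized network."""

    tst: float
    apl: float
    ami: float
    h_flow: float
    ascendency: float
    capacity: float
    overhead: float
    redundancy: float
    internal_ascendency: float
    internal_capacity: float
    internal_redundancy: float
    connectance_overall: float
    connectance_intercompartmental: float
    connectance_foodweb: float
    compartment_throughput: dict[str, float]

    @property
    def relative_ascendency(self) -> float:
        return self.ascendency / self.capacity

    @property
    def relative_redundancy(self) -> float:
        return self.redundancy / self.capacity

    @property
    def internal_relative_ascendency(self) -> float:
        return self.internal_ascendency / self.internal_capacity

    @property
    def internal_relative_redundancy(self) -> float:
        return self.internal_redundancy / self.internal_capacity

    def as_dict(self) -> dict[str, float]:
        return {
            "TST": self.tst, "APL": self.apl, "AMI": self.ami, "H": self.h_flow,
            "A": self.ascendency, "DC": self.capacity, "overhead": self.overhead,
            "R": self.redundancy, "A/DC": self.relative_ascendency,
            "R/DC": self.relative_redundancy,
            "Ai": self.internal_ascendency, "DCi": self.internal_capacity,
            "Ri": self.internal_redundancy,
            "Ai/DCi": self.internal_relative_ascendency,
            "Ri/DCi": self.internal_relative_redundancy,
            "connectance_overall": self.connectance_overall,
            "connectance_intercompartmental": self.connectance_intercompartmental,
            "connectance_foodweb": self.connectance_foodweb,
        }


def to_flow_network(flows: Mapping[str, float] | Sequence[float],
                    problem: LIMProblem) -> FlowNetwork:
    """Partition a flow vector into a :class:`FlowNetwork`.

    ``gpp-*`` flows become imports, ``*-res`` dissipations, ``*-los``
    exports; everything else is an internal transfer.
    """
    mapping = (problem.mapping(flows) if not isinstance(flows, Mapping)
               else dict(flows))
    config = problem.config
    net = FlowNetwork(
        compartments=[c.id for c in config.compartments],
        living={c.id: c.kind == "living" for c in config.compartments},
        imports={}, internal={}, exports={}, dissipations={})
    for spec in config.flows:
        v = float(mapping[spec.id])
        if v < 0:
            raise ValueError(f"negative flow value for {spec.id!r}: {v}")
        if spec.is_import:
            net.imports[spec.target] = net.imports.get(spec.target, 0.0) + v
        elif spec.is_dissipation:
            net.dissipations[spec.source] = net.dissipations.get(spec.source, 0.0) + v
        elif spec.is_export:
            net.exports[spec.source] = net.exports.get(spec.source, 0.0) + v
        else:
            net.internal[(spec.source, spec.target)] = v
    return net


def total_system_throughput(net: FlowNetwork) -> float:
    """Sum of all flows: imports + internal + exports + dissipations."""
    return (sum(net.imports.values()) + sum(net.internal.values())
            + sum(net.exports.values()) + sum(net.dissipations.values()))


def average_path_length(net: FlowNetwork) -> float:
    """Mean number of compartments crossed per unit of carbon: (TST - Z)/Z."""
    z = net.total_import
    if z <= 0:
        raise ValueError("average path length undefined: no exogenous input")
    return (total_system_throughput(net) - z) / z


def _entropy_terms(T: np.ndarray):
    tot = T.sum()
    ti = T.sum(axis=1)
    tj = T.sum(axis=0)
    i, j = np.nonzero(T > 0)
    t = T[i, j]
    p = t / tot
    ami_terms = p * np.log2(t * tot / (ti[i] * tj[j]))
    h_terms = -p * np.log2(p)
    return i, j, ami_terms, h_terms, tot


def information_indices(net: FlowNetwork) -> ENAReport:
    """AMI, ascendency, capacity, redundancy and internal variants."""
    T, _names = net.extended_matrix()
    n = len(net.compartments)
    i, j, ami_terms, h_terms, tot = _entropy_terms(T)
    if tot <= 0:
        raise ValueError("empty network")
    ami = float(ami_terms.sum())
    h_flow = float(h_terms.sum())
    ascendency = tot * ami
    internal_mask = (i < n) & (j < n)
    ai = float(tot * ami_terms[internal_mask].sum())
    # throughput-diversity capacity over node outputs (import node included)
    ti = T.sum(axis=1)
    pos = ti > 0
    p = ti[pos] / tot
    node_terms = -p * np.log2(p)
    dc = float(tot * node_terms.sum())
    comp_mask = np.nonzero(pos)[0] < n
    dci = float(tot * node_terms[comp_mask].sum())
    ri = dci - ai
    conn = connectance_indices(net)
    return ENAReport(
        tst=float(tot), apl=average_path_length(net), ami=ami, h_flow=h_flow,
        ascendency=ascendency, capacity=dc, overhead=dc - ascendency,
        redundancy=ri, internal_ascendency=ai, internal_capacity=dci,
        internal_redundancy=ri,
        connectance_overall=conn["overall"],
        connectance_intercompartmental=conn["intercompartmental"],
        connectance_foodweb=conn["foodweb"],
        compartment_throughput=net.compartment_throughputs())


def _effective_connectance(T: np.ndarray) -> float:
    tot = T.sum()
    if tot <= 0:
        return 0.0
    ti = T.sum(axis=1)
    tj = T.sum(axis=0)
    i, j = np.nonzero(T > 0)
    t = T[i, j]
    hc = float(np.sum(-(t / tot) * np.log2(t * t / (ti[i] * tj[j]))))
    return float(2.0 ** (hc / 2.0))


def connectance_indices(net: FlowNetwork) -> dict[str, float]:
    """Effective links per node from flow-weighted conditional entropy.

    ``overall`` uses all transfers (extended matrix), ``intercompartmental``
    internal transfers only, ``foodweb`` transfers among living compartments.
    """
    T, _ = net.extended_matrix()
    Tint = net.internal_matrix()
    liv = [k for k, c in enumerate(net.compartments) if net.living[c]]
    Tfw = Tint[np.ix_(liv, liv)]
    return {"overall": _effective_connectance(T),
            "intercompartmental": _effective_connectance(Tint),
            "foodweb": _effective_connectance(Tfw)}


def diet_composition(net: FlowNetwork, consumer: str) -> DietTable:
    """Prey shares of a consumer's total ingestion (internal inflows)."""
    if consumer not in net.compartments:
        raise KeyError(f"unknown compartment {consumer!r}")
    inflows = {a: v for (a, b), v in net.internal.items() if b == consumer}
    total = sum(inflows.values())
    if total <= 0:
        logger.warning("compartment %r has zero total ingestion", consumer)
        return DietTable(consumer=consumer)
    return DietTable(consumer=consumer,
                     fractions={a: v / total for a, v in inflows.items()},
                     total_ingestion=total)


def contribution_shares(net: FlowNetwork) -> dict[str, dict[str, float]]:
    """Per-compartment share (%) of total export and of detritus input."""
    total_loss = sum(net.exports.values())
    det_in = {a: v for (a, b), v in net.internal.items() if b == "det"}
    total_det = sum(det_in.values())
    out: dict[str, dict[str, float]] = {}
    for c in net.compartments:
        out[c] = {
            "loss_share_pct": 100.0 * net.exports.get(c, 0.0) / total_loss
            if total_loss > 0 else 0.0,
            "detritus_share_pct": 100.0 * det_in.get(c, 0.0) / total_det
            if total_det > 0 else 0.0,
        }
    return out


def detritivory_herbivory(net: FlowNetwork,
                          autotrophs: Sequence[str] | None = None,
                          pools: Sequence[str] | None = None) -> tuple[float, float]:
    """(D, H): consumption of non-living pools vs of living autotrophs.

    By default autotrophs are the import recipients (primary producers) and
    pools are the non-living compartments.  Parasitism on autotrophs counts
    as herbivory; pool-to-pool transfers (detritus dissolution) count as
    neither.
    """
    if autotrophs is None:
        autotrophs = [c for c in net.compartments
                      if net.living[c] and net.imports.get(c, 0.0) > 0]
    if pools is None:
        pools = [c for c in net.compartments if not net.living[c]]
    d = sum(v for (a, b), v in net.internal.items()
            if a in pools and b not in pools)
    h = sum(v for (a, b), v in net.internal.items()
            if a in autotrophs and b not in pools)
    return d, h


def mycoloop_metrics(net: FlowNetwork) -> dict[str, float]:
    """Parasite-pathway metrics: how much primary production the chytrids
    divert from the inedible bloom algae to zooplankton grazers."""
    required = {"spg", "zsp"}
    missing = required - set(net.compartments)
    if missing:
        raise KeyError(f"network lacks parasite compartments: {sorted(missing)}")
    get = lambda a, b: net.internal.get((a, b), 0.0)
    gpp_ph3 = net.imports.get("ph3", 0.0)
    spg_in = net.input_throughput("spg")
    zsp_thru = net.input_throughput("zsp")
    mic_thru = net.input_throughput("mic")
    mes_thru = net.input_throughput("mes")
    d, h = detritivory_herbivory(net)
    out = {
        "parasitism_fraction": get("ph3", "spg") / gpp_ph3 if gpp_ph3 else np.nan,
        "sporangia_to_zoospore_fraction": get("spg", "zsp") / spg_in if spg_in else np.nan,
        "zoospore_to_mic_fraction": get("zsp", "mic") / zsp_thru if zsp_thru else np.nan,
        "zoospore_to_mes_fraction": get("zsp", "mes") / zsp_thru if zsp_thru else np.nan,
        "sporangia_loss_fraction": net.exports.get("spg", 0.0) / spg_in if spg_in else np.nan,
        "indirect_transfer_to_grazers":
            (get("zsp", "mic") + get("zsp", "mes")) / gpp_ph3 if gpp_ph3 else np.nan,
        "detritivory": d,
        "herbivory": h,
        "detritivory_herbivory_ratio": d / h if h else np.nan,
        "microzooplankton_efficiency": get("mic", "mes") / mic_thru if mic_thru else np.nan,
        "microbial_link":
            (get("mic", "mes") + get("bac", "mes")) / mes_thru if mes_thru else np.nan,
    }
    return out


def ena_report(net: FlowNetwork) -> dict:
    """Full index report (information, connectance, shares, mycoloop)."""
    report = information_indices(net).as_dict()
    report["contribution_shares"] = contribution_shares(net)
    report["diets"] = {
        c: diet_composition(net, c).fractions
        for c in net.compartments
        if any(b == c for (_, b) in net.internal)}
    if {"spg", "zsp"} <= set(net.compartments):
        report["mycoloop"] = mycoloop_metrics(net)
    return report
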
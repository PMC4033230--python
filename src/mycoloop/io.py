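"""File formats: model declarations (YAML), flow tables and ensembles
(delimited text), reports and manifests (JSON).

A model declaration is one YAML document with sections ``compartments``,
``flows``, ``equalities`` and ``constraints``; constraint bounds may use the
named aggregates documented in :mod:`mycoloop.expressions`/:mod:`.model`
(``GPP``, ``NPP``, ``NPP(ph3)``, ``Ing(mes)``, ``Det_total``, ``Los_total``,
``BP``, ``Biom(zsp)``).  Reading and then writing a model yields an identical
compiled problem.

Flow tables are UTF-8 TSV with columns ``flow_id``, ``description``,
``value_mgC_m2_d`` (period decimal separator).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .model import (CompartmentSpec, ConfigurationError, ConstraintSpec,
                    EqualitySpec, FlowSpec, ModelConfig)

__all__ = ["read_model", "write_model", "read_flow_table", "write_flow_table",
           "write_ensemble", "read_ensemble", "write_report", "fixture_flow_table"]


def _as_constraint(entry: Mapping[str, Any]) -> ConstraintSpec:
    return ConstraintSpec(
        label=str(entry["label"]), expr=str(entry["expr"]),
        min=None if entry.get("min") is None else str(entry["min"]),
        max=None if entry.get("max") is None else str(entry["max"]),
        provenance=str(entry.get("provenance", "")))


def read_model(path) -> ModelConfig:
    """Read a model declaration file into a :class:`ModelConfig`."""
    text = Path(path).read_text() if not hasattr(path, "read_text") else path.read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"model file {path} is not a mapping document")
    try:
        comps = [CompartmentSpec(
            id=str(c["id"]), name=str(c.get("name", "")),
            kind=str(c.get("kind", "living")),
            biomass=None if c.get("biomass") is None else float(c["biomass"]),
            tags=frozenset(c.get("tags", ())))
            for c in doc.get("compartments", ())]
        flows = [FlowSpec.from_id(str(fid)) for fid in doc.get("flows", ())]
        eqs = [EqualitySpec(label=str(e["label"]), expr=str(e["expr"]),
                            value=float(e["value"]))
               for e in doc.get("equalities", ())]
        cons = [_as_constraint(c) for c in doc.get("constraints", ())]
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"model file {path}: {exc!r}") from exc
    return ModelConfig(name=str(doc.get("name", Path(str(path)).stem)),
                       compartments=comps, flows=flows,
                       equalities=eqs, constraints=cons)


def write_model(config: ModelConfig, path) -> None:
    """Serialize a :class:`ModelConfig` to the declaration format."""
    doc: dict[str, Any] = {
        "name": config.name,
        "compartments": [
            {k: v for k, v in (("id", c.id), ("name", c.name), ("kind", c.kind),
                               ("biomass", c.biomass), ("tags", sorted(c.tags)))
             if v not in (None, "", [])}
            for c in config.compartments],
        "flows": [f.id for f in config.flows],
        "equalities": [{"label": e.label, "expr": e.expr, "value": e.value}
                       for e in config.equalities],
        "constraints": [
            {k: v for k, v in (("label", c.label), ("expr", c.expr),
                               ("min", c.min), ("max", c.max))
             if v is not None}
            for c in config.constraints],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, width=120))


def read_flow_table(path) -> pd.DataFrame:
    """Read a flow table (``flow_id``, ``description``, ``value_mgC_m2_d``)."""
    src = path if hasattr(path, "open") and not isinstance(path, (str, Path)) else Path(path)
    with (src.open("r") if hasattr(src, "open") else open(src)) as fh:
        df = pd.read_csv(fh, sep="\t")
    missing = {"flow_id", "value_mgC_m2_d"} - set(df.columns)
    if missing:
        raise ValueError(f"flow table {path} lacks columns {sorted(missing)}")
    if df["flow_id"].duplicated().any():
        raise ValueError(f"flow table {path} has duplicate flow ids")
    return df


def write_flow_table(flows: Mapping[str, float], path,
                     descriptions: Mapping[str, str] | None = None) -> None:
    df = pd.DataFrame({
        "flow_id": list(flows),
        "description": [(descriptions or {}).get(f, "") for f in flows],
        "value_mgC_m2_d": [flows[f] for f in flows]})
    df.to_csv(path, sep="\t", index=False)


def flow_table_to_mapping(df: pd.DataFrame) -> dict[str, float]:
    return dict(zip(df["flow_id"].astype(str), df["value_mgC_m2_d"].astype(float)))


def fixture_flow_table(model_name: str) -> pd.DataFrame:
    """The packaged mean-flow table for a built-in model."""
    from importlib import resources

    entry = resources.files("mycoloop") / "data" / f"{model_name}_flows.tsv"
    if not entry.is_file():
        raise KeyError(f"no packaged flow table for model {model_name!r}")
    return read_flow_table(entry)


def write_ensemble(samples: np.ndarray, flow_ids: list[str], path) -> None:
    pd.DataFrame(samples, columns=flow_ids).to_csv(path, sep="\t", index=False)


def read_ensemble(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(report: Mapping[str, Any], path) -> None:
    """JSON report writer tolerant of numpy scalars/arrays."""

    def default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default) + "\n")
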
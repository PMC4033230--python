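"""Linear expressions over flow variables.

Every constraint in a linear inverse food-web model is an affine function of
the flow vector.  :class:`LinearExpression` is the shared currency between the
model declaration layer (where constraints are written with named aggregates
such as ``GPP`` or ``Ing(mes)``) and the compiled matrix form.

The expression grammar accepted by :func:`parse_expression` is deliberately
small::

    expr      := term (("+" | "-") term)*
    term      := [number "*"] atom
    atom      := flow-id | aggregate | number
    aggregate := NAME | NAME "(" arg ")"

Tokens are whitespace separated, so the hyphen inside a flow id such as
``gpp-ph3`` is never confused with subtraction (which must be surrounded by
spaces): ``"gpp-ph1 + gpp-ph2"`` parses, ``"gpp-ph1+gpp-ph2"`` does not.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping

__all__ = ["LinearExpression", "ExpressionError", "parse_expression"]


class ExpressionError(ValueError):
    """Raised for malformed expressions or unknown symbols."""


@dataclass
class LinearExpression:
    """An affine function ``sum(coef * flow) + constant`` of the flow vector.

    Parameters
    ----------
    terms
        Mapping from flow id to dimensionless coefficient.
    constant
        Additive constant, in the flow units (mgC m⁻² d⁻¹).
    """

    terms: dict[str, float] = field(default_factory=dict)
    constant: float = 0.0

    def evaluate(self, flows: Mapping[str, float]) -> float:
        try:
            return sum(c * flows[f] for f, c in self.terms.items()) + self.constant
        except KeyError as exc:  # pragma: no cover - guarded upstream
            raise ExpressionError(f"flow {exc.args[0]!r} missing from flow vector") from exc

    def row(self, flow_index: Mapping[str, int], n: int) -> "np.ndarray":
        """Dense coefficient row aligned with an ordered flow index."""
        import numpy as np

        out = np.zeros(n)
        for fid, coef in self.terms.items():
            try:
                out[flow_index[fid]] = coef
            except KeyError:
                raise ExpressionError(f"expression references undeclared flow {fid!r}")
        return out

    # -- algebra ----------------------------------------------------------
    def __add__(self, other: "LinearExpression | float") -> "LinearExpression":
        if isinstance(other, (int, float)):
            return LinearExpression(dict(self.terms), self.constant + other)
        terms = dict(self.terms)
        for fid, coef in other.terms.items():
            terms[fid] = terms.get(fid, 0.0) + coef
        return LinearExpression(terms, self.constant + other.constant)

    def __sub__(self, other: "LinearExpression | float") -> "LinearExpression":
        return self + (other * -1.0 if isinstance(other, LinearExpression) else -other)

    def __mul__(self, scalar: float) -> "LinearExpression":
        return LinearExpression({f: c * scalar for f, c in self.terms.items()},
                                self.constant * scalar)

    __rmul__ = __mul__

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"{c:+g}*{f}" for f, c in self.terms.items()]
        if self.constant:
            parts.append(f"{self.constant:+g}")
        return "LinearExpression(" + " ".join(parts) + ")"


_AGG_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)(?:\(([^)]*)\))?$")
_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")

AggregateResolver = Callable[[str, str | None], LinearExpression]


def parse_expression(text: str, flow_ids: set[str],
                     resolve_aggregate: AggregateResolver | None = None) -> LinearExpression:
    """Parse an expression string into a :class:`LinearExpression`.

    ``resolve_aggregate(name, arg)`` is consulted for atoms that are not flow
    ids or numbers; it must return a :class:`LinearExpression` or raise
    :class:`ExpressionError`.
    """
    tokens = text.split()
    if not tokens:
        raise ExpressionError("empty expression")
    result = LinearExpression()
    sign = 1.0
    expect_term = True
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok in {"+", "-"}:
            if expect_term:
                raise ExpressionError(f"unexpected operator {tok!r} in {text!r}")
            sign = 1.0 if tok == "+" else -1.0
            expect_term = True
            i += 1
            continue
        if not expect_term:
            raise ExpressionError(f"missing operator before {tok!r} in {text!r}")
        coef = 1.0
        # optional "number *" prefix
        if _NUM_RE.match(tok) and i + 2 < len(tokens) + 1 and i + 1 < len(tokens) and tokens[i + 1] == "*":
            coef = float(tok)
            i += 2
            if i >= len(tokens):
                raise ExpressionError(f"dangling '*' in {text!r}")
            tok = tokens[i]
        result = result + sign * coef * _atom(tok, text, flow_ids, resolve_aggregate)
        sign = 1.0
        expect_term = False
        i += 1
    if expect_term:
        raise ExpressionError(f"expression {text!r} ends with an operator")
    return result


def _atom(tok: str, text: str, flow_ids: set[str],
          resolve_aggregate: AggregateResolver | None) -> LinearExpression:
    if tok in flow_ids:
        return LinearExpression({tok: 1.0})
    if _NUM_RE.match(tok):
        return LinearExpression(constant=float(tok))
    m = _AGG_RE.match(tok)
    if m and resolve_aggregate is not None:
        return resolve_aggregate(m.group(1), m.group(2))
    raise ExpressionError(f"unknown symbol {tok!r} in expression {text!r}")
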
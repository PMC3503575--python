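"""ISO-style propagation of standard measurement uncertainties.

The combined standard uncertainty of a scalar output ``e = f(k_1, ..., k_m)``
computed from independent measured inputs is

    U_e^2 = sum_i (de/dk_i)^2 * U_ki^2

where ``U_ki`` is the standard (1-sigma) uncertainty of input ``k_i``.  This
module evaluates that quadrature for an arbitrary Python callable, returns the
full per-input *uncertainty budget* (partials, variance terms, contribution
fractions), and provides an independent Monte Carlo oracle that samples the
inputs as independent Gaussians — useful to verify the linearization on any
concrete expression.

Inputs are treated as uncorrelated throughout; uncertainties are standard
uncertainties, never expanded/coverage-factor ones.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Measurement",
    "BudgetTerm",
    "UncertaintyBudget",
    "UncertaintyError",
    "DuplicateInputError",
    "EvaluationError",
    "propagate",
    "mc_oracle",
    "rank_contributions",
]


class UncertaintyError(ValueError):
    """Base class for propagation errors."""


class DuplicateInputError(UncertaintyError):
    """Two inputs share a name."""


class EvaluationError(UncertaintyError):
    """The expression (or one of its partials) evaluated non-finite."""


@dataclass(frozen=True)
class Measurement:
    """A named measured value with a standard (1-sigma) uncertainty.

    Parameters
    ----------
    name : str
        Identifier; must match a keyword argument of any expression the
        measurement is propagated through.
    value : float
        Measured value, in ``units``.
    std_uncertainty : float
        Standard uncertainty, same units as ``value``; must be >= 0.
    units : str
        Free-text unit label (informational).
    """

    name: str
    value: float
    std_uncertainty: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise UncertaintyError("measurement needs a non-empty name")
        if not math.isfinite(self.value):
            raise UncertaintyError(f"{self.name}: value must be finite")
        if not math.isfinite(self.std_uncertainty) or self.std_uncertainty < 0:
            raise UncertaintyError(
                f"{self.name}: std_uncertainty must be finite and >= 0"
            )

    @property
    def relative_uncertainty(self) -> float:
        """u_r = U / |value| (inf when value == 0 and U > 0)."""
        if self.value == 0:
            return math.inf if self.std_uncertainty > 0 else 0.0
        return self.std_uncertainty / abs(self.value)


@dataclass(frozen=True)
class BudgetTerm:
    """One input's contribution to a combined uncertainty.

    ``term = (partial * std_uncertainty)^2`` and ``fraction = term / U_e^2``.
    """

    name: str
    partial: float
    term: float
    fraction: float


@dataclass
class UncertaintyBudget:
    """Output value, combined standard uncertainty and its decomposition."""

    output_name: str
    value: float
    combined_uncertainty: float
    terms: list[BudgetTerm]
    flags: list[str] = field(default_factory=list)

    def fraction(self, name: str) -> float:
        for t in self.terms:
            if t.name == name:
                return t.fraction
        raise KeyError(name)

    def as_measurement(self, units: str = "") -> Measurement:
        """Re-use the propagated output as a derived-quantity input."""
        return Measurement(
            self.output_name, self.value, self.combined_uncertainty, units
        )

    def to_dict(self) -> dict:
        return {
            "output_name": self.output_name,
            "value": self.value,
            "combined_uncertainty": self.combined_uncertainty,
            "terms": [
                {
                    "name": t.name,
                    "partial": t.partial,
                    "term": t.term,
                    "fraction": t.fraction,
                }
                for t in self.terms
            ],
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UncertaintyBudget":
        return cls(
            output_name=d["output_name"],
            value=d["value"],
            combined_uncertainty=d["combined_uncertainty"],
            terms=[
                BudgetTerm(t["name"], t["partial"], t["term"], t["fraction"])
                for t in d["terms"]
            ],
            flags=list(d.get("flags", [])),
        )


def _check_names(inputs: Sequence[Measurement]) -> list[str]:
    names = [m.name for m in inputs]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise DuplicateInputError(f"duplicate input name: {n!r}")
        seen.add(n)
    return names


def _eval(expr: Callable[..., float], values: dict[str, float], what: str) -> float:
    y = float(expr(**values))
    if not math.isfinite(y):
        raise EvaluationError(f"expression non-finite while evaluating {what}")
    return y


def propagate(
    expr: Callable[..., float],
    inputs: Sequence[Measurement],
    output_name: str = "output",
    rel_step: float = 1e-6,
    abs_step: float = 1e-12,
) -> UncertaintyBudget:
    """Propagate standard uncertainties of ``inputs`` through ``expr``.

    ``expr`` is any callable taking the input names as keyword arguments and
    returning a finite scalar.  Partial derivatives are taken by central
    finite differences with relative step ``rel_step`` (absolute floor
    ``abs_step``); if the expression object exposes a
    ``gradient(values: dict) -> dict`` attribute, those exact derivatives are
    used instead.

    Returns an :class:`UncertaintyBudget` whose variance terms sum exactly to
    ``combined_uncertainty**2`` and whose contribution fractions sum to 1
    whenever the combined uncertainty is positive.
    """
    names = _check_names(inputs)
    values = {m.name: float(m.value) for m in inputs}
    e0 = _eval(expr, values, "the base point")

    if hasattr(expr, "gradient"):
        grad = expr.gradient(dict(values))
        partials = {n: float(grad[n]) for n in names}
        for n, g in partials.items():
            if not math.isfinite(g):
                raise EvaluationError(f"non-finite exact partial for input {n!r}")
    else:
        partials = {}
        for n in names:
            h = max(abs(values[n]) * rel_step, abs_step)
            hi = dict(values, **{n: values[n] + h})
            lo = dict(values, **{n: values[n] - h})
            try:
                f_hi = _eval(expr, hi, f"the partial for input {n!r}")
                f_lo = _eval(expr, lo, f"the partial for input {n!r}")
            except EvaluationError:
                raise
            partials[n] = (f_hi - f_lo) / (2.0 * h)

    terms_sq = {n: (partials[n] * m.std_uncertainty) ** 2
                for n, m in zip(names, inputs)}
    var = sum(terms_sq.values())
    u = math.sqrt(var)
    terms = [
        BudgetTerm(
            name=n,
            partial=partials[n],
            term=terms_sq[n],
            fraction=(terms_sq[n] / var) if var > 0 else 0.0,
        )
        for n in names
    ]
    return UncertaintyBudget(output_name, e0, u, terms)


def mc_oracle(
    expr: Callable[..., float],
    inputs: Sequence[Measurement],
    n: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte Carlo check of :func:`propagate` in its linearization regime.

    Samples each input independently as ``Normal(value, std_uncertainty)``
    and returns the sample mean and sample standard deviation (ddof=1) of the
    expression over ``n`` draws.  Deterministic for a given ``seed``.
    """
    if n < 1000:
        raise UncertaintyError("mc_oracle needs n >= 1000")
    _check_names(inputs)
    rng = np.random.default_rng(seed)
    draws = {
        m.name: rng.normal(m.value, m.std_uncertainty, size=n) for m in inputs
    }
    out = None
    try:
        cand = np.asarray(expr(**draws), dtype=float)
        if cand.shape == (n,):
            out = cand
    except Exception:
        out = None
    if out is None:
        # expression is not vectorizable; evaluate draw by draw
        out = np.empty(n)
        for i in range(n):
            out[i] = expr(**{k: v[i] for k, v in draws.items()})
    bad = np.flatnonzero(~np.isfinite(out))
    if bad.size:
        raise EvaluationError(f"expression non-finite on draw {int(bad[0])}")
    sd = float(out.std(ddof=1)) if n > 1 else 0.0
    return float(out.mean()), sd


def rank_contributions(budget: UncertaintyBudget) -> list[tuple[str, float]]:
    """Contribution fractions in descending order (name breaks ties)."""
    return [
        (t.name, t.fraction)
        for t in sorted(budget.terms, key=lambda t: (-t.fraction, t.name))
    ]
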
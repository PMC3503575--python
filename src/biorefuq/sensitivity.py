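"""Normalized (log-log) sensitivity of MESP to process-model variables.

The normalized sensitivity of an output M to a variable X is the elasticity

    S = (dM/M) / (dX/X) = d ln M / d ln X,

estimated here as the least-squares slope of ln(M) against ln(X) over a set
of log-spaced evaluation points.  A sensitivity of -1.5 means a 1 % increase
in X lowers M by 1.5 %.

Perturbation ranges default to +/-15 % of the base value, but are tightened
where a group of competing reactions shares a substrate: the perturbed yield
must never push the group total past 100 % (or past a per-reaction cap such
as a maximum attainable conversion).  When the remaining headroom is
negligible the upper bound collapses to zero and only downward perturbations
are explored.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .surrogate import (
    DEFAULT_COMPOSITION,
    CompositionProfile,
    EconConfig,
    SAMPLED_YIELD_NAMES,
    compute_mesp,
    simulate_plant,
)

__all__ = [
    "SensitivityResult",
    "SensitivityError",
    "normalized_sensitivity",
    "constrained_range",
    "mesp_sensitivities",
]


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class SensitivityResult:
    """Elasticity of the model output with respect to one variable."""

    variable: str
    sensitivity: float      # d ln(output) / d ln(variable)
    lo: float               # perturbation range used, fraction of base
    hi: float
    r_squared: float        # goodness of the log-log line fit

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise SensitivityError("perturbation range must have lo < hi")
        if not math.isfinite(self.sensitivity):
            raise SensitivityError("sensitivity must be finite")


def normalized_sensitivity(
    model: Callable[[float], float],
    base: float,
    prange: tuple[float, float] = (-0.15, 0.15),
    variable: str = "X",
    n_points: int = 7,
) -> SensitivityResult:
    """Least-squares log-log slope of ``model`` around ``base``.

    ``model`` is evaluated at ``n_points`` log-spaced values spanning
    ``[base*(1+lo), base*(1+hi)]``; the model must be strictly positive over
    the range.
    """
    lo, hi = prange
    if base <= 0:
        raise SensitivityError("base must be > 0")
    if not lo < hi:
        raise SensitivityError("need lo < hi")
    if base * (1.0 + lo) <= 0:
        raise SensitivityError("lower range endpoint is non-positive")
    xs = np.geomspace(base * (1.0 + lo), base * (1.0 + hi), n_points)
    ys = np.array([float(model(x)) for x in xs])
    if np.any(ys <= 0) or not np.all(np.isfinite(ys)):
        raise SensitivityError(
            f"model must be positive and finite over the range for {variable}"
        )
    lx, ly = np.log(xs), np.log(ys)
    slope, intercept = np.polyfit(lx, ly, 1)
    fitted = slope * lx + intercept
    ss_res = float(np.sum((ly - fitted) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return SensitivityResult(variable, float(slope), lo, hi, r2)


def constrained_range(
    base: float,
    group_total: float | None = None,
    cap: float = 100.0,
    default: float = 0.15,
    headroom_tol: float = 0.01,
) -> tuple[float, float]:
    """Perturbation range for a yield (percent scale), honoring mass closure.

    The default range is ``(-default, +default)`` as fractions of ``base``.
    The upper bound is reduced so the perturbed yield never exceeds
    ``min(cap, 100 - (group_total - base))``, where ``group_total`` is the
    summed yield of all reactions competing for the same substrate.  Upper
    bounds below ``headroom_tol`` (relative) collapse to 0 — a group already
    at ~100 % total conversion is only perturbed downward.
    """
    if not (0.0 < base <= 100.0):
        raise SensitivityError("base must be in (0, 100]")
    if base > cap:
        raise SensitivityError(f"base {base} exceeds cap {cap}")
    if group_total is None:
        group_total = base
    if group_total < base:
        raise SensitivityError("group_total cannot be below base")
    allowed_max = min(cap, 100.0 - (group_total - base))
    hi = min(default, allowed_max / base - 1.0)
    if hi < headroom_tol:
        hi = 0.0
    return (-default, hi)


def mesp_sensitivities(
    composition: CompositionProfile = DEFAULT_COMPOSITION,
    yields: Mapping[str, float] | None = None,
    econ: EconConfig | None = None,
    feed_rate: float = 83_333.0,
    variables: Sequence[str] = SAMPLED_YIELD_NAMES + ("glucan", "xylan", "lignin"),
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> list[SensitivityResult]:
    """Normalized MESP sensitivities for yield and composition variables.

    Composition variables perturb the named dry-basis mass fraction with the
    extractives component absorbing closure; yield variables perturb the
    named slate reaction.  ``ranges`` overrides the default +/-15 % range per
    variable (use :func:`constrained_range` to respect yield caps).
    """
    econ = econ or EconConfig()
    base_yields = dict(yields or {})
    comp_fields = set(CompositionProfile._FIELDS)
    ranges = dict(ranges or {})
    results = []
    for var in variables:
        if var in comp_fields:
            base = getattr(composition, var)

            def model(x, var=var):
                comp = composition.with_updates(**{var: x})
                plant = simulate_plant(comp, base_yields, feed_rate=feed_rate)
                return compute_mesp(plant, econ).mesp

        else:
            base = base_yields.get(var)
            if base is None:
                base = _default_yield(var)

            def model(x, var=var):
                plant = simulate_plant(
                    composition, dict(base_yields, **{var: x}),
                    feed_rate=feed_rate,
                )
                return compute_mesp(plant, econ).mesp

        if var in ranges:
            prange = ranges[var]
        elif var in comp_fields:
            prange = (-0.15, 0.15)
        else:
            group_total = base + _competing_yield(var)
            prange = constrained_range(base * 100.0, group_total * 100.0)
        results.append(
            normalized_sensitivity(model, base, prange, variable=var)
        )
    return results


def _slate_groups() -> list[list]:
    from .surrogate import (
        enzymatic_hydrolysis_slates,
        fermentation_slate,
        pretreatment_slate,
    )

    s1, s2 = enzymatic_hydrolysis_slates()
    return [pretreatment_slate(), s1, s2, fermentation_slate()]


def _find_reaction(name: str):
    for slate in _slate_groups():
        for r in slate:
            if r.name == name:
                return r, slate
    raise SensitivityError(f"unknown variable {name!r}")


def _default_yield(name: str) -> float:
    return _find_reaction(name)[0].fyield


def _competing_yield(name: str) -> float:
    """Summed default yields competing for the same substrate.

    Fermentation sink reactions adapt to the ethanol yield (they share the
    residual), so an ethanol yield faces no fixed competitors there — only
    the 100 % cap applies.
    """
    rxn, slate = _find_reaction(name)
    ferm_sugars = ("glucose", "xylose", "arabinose", "galactose", "mannose")
    if rxn.reactant in ferm_sugars:
        return 0.0
    return sum(
        r.fyield for r in slate if r.reactant == rxn.reactant and r.name != name
    )
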
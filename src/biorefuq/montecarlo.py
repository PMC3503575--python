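"""Constrained Monte Carlo simulation of MESP uncertainty.

Key input parameters (feedstock composition fractions and unit-operation
yields, all on the percent scale) are sampled from independent normal
distributions truncated to +/- two standard deviations and, for yields,
additionally capped at a maximum attainable value and at 100 %.  Each
sampled input vector is pushed through the calibrated plant surrogate; the
resulting MESP distribution is summarized (mode via kernel density, mean,
equal-tailed 95 % probability interval) and its variance is apportioned
across the unit-operation groups by a standardized linear-regression
variance decomposition.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .surrogate import (
    DEFAULT_COMPOSITION,
    CompositionProfile,
    EconConfig,
    compute_mesp,
    simulate_plant,
)

__all__ = [
    "MCInputSpec",
    "MCResult",
    "MCError",
    "table1_specs",
    "sample_inputs",
    "mesp_model",
    "run_mc",
    "summarize",
    "apportion_uncertainty",
]

logger = logging.getLogger(__name__)

GROUPS = ("feedstock", "pretreatment", "enzymatic hydrolysis", "fermentation")


class MCError(ValueError):
    pass


@dataclass(frozen=True)
class MCInputSpec:
    """One sampled input: base and max value, uncertainty, group (percent scale)."""

    name: str
    base: float
    uncertainty: float
    group: str
    max_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise MCError(f"{self.name}: uncertainty must be >= 0")
        if self.max_value is not None and self.base > self.max_value:
            raise MCError(f"{self.name}: base exceeds max value")

    def bounds(self, n_sigma: float | None = 2.0) -> tuple[float, float]:
        """Truncation interval [base - 2u, min(base + 2u, max, 100)]."""
        if n_sigma is None:
            return (-math.inf, math.inf)
        lo = self.base - n_sigma * self.uncertainty
        hi = self.base + n_sigma * self.uncertainty
        if self.max_value is not None:
            hi = min(hi, self.max_value)
        hi = min(hi, 100.0)
        return lo, hi


def table1_specs() -> list[MCInputSpec]:
    """The standard eight-row Monte Carlo input table.

    Feedstock composition fractions (glucan/xylan/lignin) and the five key
    conversion yields, with base values, maximum attainable yields, and
    standard uncertainties in percentage points.
    """
    return [
        MCInputSpec("glucan", 35.1, 0.53, "feedstock"),
        MCInputSpec("xylan", 19.5, 0.34, "feedstock"),
        MCInputSpec("lignin", 15.8, 0.17, "feedstock"),
        MCInputSpec("xylan_to_xylose", 90.0, 2.7, "pretreatment", 95.0),
        MCInputSpec("arabinan_to_arabinose", 90.0, 7.6, "pretreatment", 95.0),
        MCInputSpec("cellulose_to_glucose", 90.0, 5.2, "enzymatic hydrolysis",
                    95.0),
        MCInputSpec("glucose_to_ethanol", 95.0, 3.00, "fermentation", 100.0),
        MCInputSpec("xylose_to_ethanol", 85.0, 3.00, "fermentation", 95.0),
    ]


def sample_inputs(
    specs: Sequence[MCInputSpec],
    n: int,
    seed: int,
    n_sigma: float | None = 2.0,
) -> np.ndarray:
    """Sample an (n, m) matrix of truncated-normal inputs.

    Each column is sampled independently as ``Normal(base, uncertainty)``
    with out-of-bounds draws rejected (never clipped — clipping would place
    point masses at the bounds).  ``n_sigma=None`` disables truncation.
    Deterministic for a given seed.
    """
    if n < 1:
        raise MCError("need n >= 1")
    rng = np.random.default_rng(seed)
    cols = []
    for spec in specs:
        lo, hi = spec.bounds(n_sigma)
        if spec.uncertainty == 0:
            cols.append(np.full(n, spec.base))
            continue
        if lo > hi:
            raise MCError(f"{spec.name}: empty truncation interval")
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(spec.base, spec.uncertainty, size=n - filled)
            ok = draw[(draw >= lo) & (draw <= hi)]
            out[filled:filled + ok.size] = ok
            filled += ok.size
        cols.append(out)
    return np.column_stack(cols)


def mesp_model(
    composition: CompositionProfile = DEFAULT_COMPOSITION,
    econ: EconConfig | None = None,
    feed_rate: float = 83_333.0,
    base_yields: Mapping[str, float] | None = None,
) -> Callable[[Mapping[str, float]], float]:
    """Build a MESP callable over percent-scale named inputs.

    Composition names (glucan/xylan/lignin) update the feedstock profile
    with the extractives component absorbing closure; all other names are
    reaction-yield overrides.  Non-sampled inputs stay at their base values.
    """
    econ = econ or EconConfig()
    base_yields = dict(base_yields or {})
    comp_fields = set(CompositionProfile._FIELDS)

    def model(inputs: Mapping[str, float]) -> float:
        comp_updates = {
            k: v / 100.0 for k, v in inputs.items() if k in comp_fields
        }
        yield_updates = {
            k: v / 100.0 for k, v in inputs.items() if k not in comp_fields
        }
        comp = (composition.with_updates(**comp_updates)
                if comp_updates else composition)
        plant = simulate_plant(comp, dict(base_yields, **yield_updates),
                               feed_rate=feed_rate)
        return compute_mesp(plant, econ).mesp

    return model


@dataclass
class MCResult:
    """Sampled inputs, MESP distribution and its summaries."""

    input_names: list[str]
    samples: np.ndarray          # (n, m) input sample matrix, percent scale
    mesp: np.ndarray             # (n,) $/gal
    mode: float
    mean: float
    p95: tuple[float, float]     # equal-tailed (2.5th, 97.5th) percentiles
    half_width: float            # (hi - lo) / 2
    apportionment: dict[str, float]
    seed: int

    def summary_dict(self) -> dict:
        return {
            "n": int(self.mesp.size),
            "seed": self.seed,
            "mode": self.mode,
            "mean": self.mean,
            "p95_lo": self.p95[0],
            "p95_hi": self.p95[1],
            "half_width": self.half_width,
            "apportionment": dict(self.apportionment),
        }


def run_mc(
    model: Callable[[Mapping[str, float]], float],
    specs: Sequence[MCInputSpec],
    n: int = 5000,
    seed: int = 0,
    n_sigma: float | None = 2.0,
) -> MCResult:
    """Evaluate ``model`` on ``n`` constrained input samples and summarize.

    Deterministic for a given seed.  A model failure is re-raised with the
    offending sample index and values.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise MCError("duplicate spec names")
    X = sample_inputs(specs, n, seed, n_sigma=n_sigma)
    y = np.empty(n)
    for i in range(n):
        row = dict(zip(names, X[i]))
        try:
            y[i] = model(row)
        except Exception as exc:
            raise MCError(f"model failed on sample {i}: {row}") from exc
    mode, mean, p95, half_width = summarize(y)
    groups = {s.name: s.group for s in specs}
    apportionment = apportion_uncertainty(X, y, [groups[n_] for n_ in names])
    if mean <= mode:
        logger.info(
            "MESP distribution not positively skewed (mean %.4f <= mode %.4f)",
            mean, mode,
        )
    return MCResult(names, X, y, mode, mean, p95, half_width, apportionment,
                    seed)


def summarize(samples: np.ndarray) -> tuple[float, float, tuple[float, float], float]:
    """(mode, mean, equal-tailed 95 % interval, half-width) of a sample.

    The mode is the argmax of a Gaussian kernel density estimate with
    Silverman bandwidth, located on a 512-point grid over the sample range.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 100:
        raise MCError("summarize needs at least 100 samples")
    mean = float(samples.mean())
    lo, hi = np.percentile(samples, [2.5, 97.5])
    if np.ptp(samples) == 0:
        mode = float(samples[0])
    else:
        kde = gaussian_kde(samples, bw_method="silverman")
        grid = np.linspace(samples.min(), samples.max(), 512)
        mode = float(grid[np.argmax(kde(grid))])
    return mode, mean, (float(lo), float(hi)), float((hi - lo) / 2.0)


def apportion_uncertainty(
    samples: np.ndarray,
    outputs: np.ndarray,
    groups: Sequence[str],
) -> dict[str, float]:
    """Apportion output variance across input groups.

    The output is regressed on standardized inputs by least squares; each
    input's contribution is its squared standardized coefficient (its
    explained variance under independence), and group shares are the
    normalized sums over group members.  Inputs with zero variance are
    dropped with a warning.  Shares are >= 0 and sum to 1.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(outputs, dtype=float)
    n, m = X.shape
    if len(groups) != m:
        raise MCError("one group label per input column required")
    if n <= m:
        raise MCError("need more samples than inputs")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    for j in np.flatnonzero(~keep):
        logger.warning("dropping constant input column %d from apportionment", j)
    if not keep.any():
        raise MCError("all inputs constant; cannot apportion")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    design = np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    contrib = beta[1:] ** 2
    total = contrib.sum()
    shares: dict[str, float] = {}
    kept_groups = [g for g, k in zip(groups, keep) if k]
    for g, c in zip(kept_groups, contrib):
        shares[g] = shares.get(g, 0.0) + (c / total if total > 0 else 0.0)
    if total == 0:
        # constant model: spread evenly so shares still sum to 1
        ng = len(set(kept_groups))
        shares = {g: 1.0 / ng for g in set(kept_groups)}
    return shares
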
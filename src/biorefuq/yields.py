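"""Experimental yield calculations with full uncertainty budgets.

Three headline conversions of a dilute-acid corn-stover-to-ethanol process
are computed from primary measurements:

* **xylose from xylan** in pretreatment (batch, or continuous pilot runs
  where the slurry flow may itself be a derived quantity),
* **glucose from cellulose** in enzymatic hydrolysis,
* **ethanol from xylose** in co-fermentation, under an assumed hexose
  (glucose + fructose) ethanol yield.

Each function returns an :class:`~biorefuq.uncertainty.UncertaintyBudget`
propagated over *all* primary measurements, including measurements that only
enter through derived quantities such as the slurry mass flow.

Unit conventions: masses in kg, flows in kg/h, concentrations in g/L,
densities in kg/L.  Yields are dimensionless fractions internally; the
percent conversion happens only at the I/O boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .uncertainty import Measurement, UncertaintyBudget, propagate

__all__ = [
    "MolecularWeights",
    "DEFAULT_MW",
    "PretreatmentRun",
    "EnzymaticHydrolysisRun",
    "FermentationRun",
    "YieldError",
    "UndefinedYieldError",
    "InvalidFractionError",
    "BalanceError",
    "xylose_yield",
    "derived_slurry_flow",
    "glucose_yield",
    "ethanol_yield_from_xylose",
]

G_PER_KG = 1000.0


def _bind(m: Measurement, role: str) -> Measurement:
    """Re-key a measurement to the formula symbol it plays in a yield."""
    if m.name == role:
        return m
    return Measurement(role, m.value, m.std_uncertainty, m.units)


class YieldError(ValueError):
    """Base class for yield-computation errors."""


class UndefinedYieldError(YieldError):
    """Denominator of a yield expression is zero (no substrate)."""


class InvalidFractionError(YieldError):
    """A mass fraction lies outside its physical range."""


class BalanceError(YieldError):
    """A derived mass balance is infeasible (negative net flow)."""


@dataclass(frozen=True)
class MolecularWeights:
    """Molecular weights and stoichiometric constants used in yield formulas.

    The anhydro corrections 132/150 (xylan/xylose) and 162/180
    (anhydroglucose/glucose) account for the water added on hydrolysis;
    0.511 g/g is the stoichiometric mass yield of ethanol from either a
    hexose or a pentose sugar.
    """

    xylose: float = 150.0
    xylan: float = 132.0
    glucose: float = 180.0
    cellulose: float = 162.0  # anhydroglucose unit
    ethanol_mass_yield: float = 0.511

    def __post_init__(self) -> None:
        for name in ("xylose", "xylan", "glucose", "cellulose",
                     "ethanol_mass_yield"):
            if getattr(self, name) <= 0:
                raise YieldError(f"{name} must be > 0")

    @property
    def xylan_anhydro(self) -> float:
        """xylan/xylose mass ratio (0.88 at default weights)."""
        return self.xylan / self.xylose

    @property
    def cellulose_anhydro(self) -> float:
        """cellulose/glucose mass ratio (0.90 at default weights)."""
        return self.cellulose / self.glucose


DEFAULT_MW = MolecularWeights()


def _require_fraction(m: Measurement, strict_upper: bool = False) -> None:
    hi_ok = m.value < 1.0 if strict_upper else m.value <= 1.0
    if not (0.0 <= m.value and hi_ok):
        raise InvalidFractionError(
            f"{m.name} = {m.value} is not a valid mass fraction"
        )


def _require_positive(m: Measurement) -> None:
    if m.value <= 0:
        raise YieldError(f"{m.name} must be > 0 (got {m.value})")


@dataclass
class PretreatmentRun:
    """Primary measurements of one pretreatment experiment.

    ``mode`` selects the yield form: ``"batch"`` uses final slurry mass
    ``m_f`` and initial dry biomass mass ``m_i``; ``"continuous"`` uses
    steady-state mass flows, where the slurry flow is either measured
    (``slurry_flow``) or, when ``slurry_flow`` is None, derived from the feed,
    water and acid flows minus a configured flash-loss fraction.

    Shared measurements: ``f_IS`` (fraction insoluble solids of the
    pretreated slurry), ``rho_L`` (liquor density, kg/L), ``C_X`` (xylose
    concentration in the liquor, g/L) and ``x_X`` (xylan mass fraction of the
    dry feedstock).
    """

    mode: str
    f_IS: Measurement
    rho_L: Measurement
    C_X: Measurement
    x_X: Measurement
    # batch
    m_f: Optional[Measurement] = None
    m_i: Optional[Measurement] = None
    # continuous
    feed_dry_flow: Optional[Measurement] = None
    feed_moisture: Optional[Measurement] = None
    water_flow: Optional[Measurement] = None
    acid_flow: Optional[Measurement] = None
    slurry_flow: Optional[Measurement] = None
    flash_loss: float = 0.0
    x_G: Optional[Measurement] = None  # informational, not in the yield form

    def __post_init__(self) -> None:
        if self.mode not in ("batch", "continuous"):
            raise YieldError(f"unknown mode {self.mode!r}")
        _require_fraction(self.f_IS, strict_upper=True)
        _require_fraction(self.x_X)
        _require_positive(self.rho_L)
        if self.C_X.value < 0:
            raise YieldError("C_X must be >= 0")
        if self.mode == "batch":
            if self.m_f is None or self.m_i is None:
                raise YieldError("batch mode needs m_f and m_i")
            _require_positive(self.m_f)
            _require_positive(self.m_i)
        else:
            if self.feed_dry_flow is None:
                raise YieldError("continuous mode needs feed_dry_flow")
            _require_positive(self.feed_dry_flow)
            if self.slurry_flow is None:
                missing = [
                    n for n in ("feed_moisture", "water_flow", "acid_flow")
                    if getattr(self, n) is None
                ]
                if missing:
                    raise YieldError(
                        "continuous mode without a measured slurry flow "
                        f"needs {', '.join(missing)}"
                    )
                _require_fraction(self.feed_moisture, strict_upper=True)
            else:
                _require_positive(self.slurry_flow)
        if not (0.0 <= self.flash_loss < 1.0):
            raise InvalidFractionError("flash_loss must be in [0, 1)")


def _slurry_flow_value(feed_dry_flow, feed_moisture, water_flow, acid_flow,
                       flash_loss):
    wet_feed = feed_dry_flow / (1.0 - feed_moisture)
    return (wet_feed + water_flow + acid_flow) * (1.0 - flash_loss)


def derived_slurry_flow(
    feed_dry_flow: Measurement,
    feed_moisture: Measurement,
    water_flow: Measurement,
    acid_flow: Measurement,
    flash_loss: float = 0.0,
) -> UncertaintyBudget:
    """Slurry mass flow derived from the reactor inlet mass balance.

    slurry = (feed_dry/(1 - moisture) + water + acid) * (1 - flash_loss)

    The result is a derived quantity: its budget can be fed back into
    :func:`xylose_yield` as a measurement with the propagated uncertainty
    intact (``budget.as_measurement()``).
    """
    for m in (feed_dry_flow, water_flow, acid_flow):
        if m.value < 0:
            raise BalanceError(f"{m.name} must be >= 0")
    _require_fraction(feed_moisture, strict_upper=True)

    def expr(feed_dry_flow, feed_moisture, water_flow, acid_flow):
        return _slurry_flow_value(feed_dry_flow, feed_moisture, water_flow,
                                  acid_flow, flash_loss)

    budget = propagate(
        expr,
        [_bind(feed_dry_flow, "feed_dry_flow"),
         _bind(feed_moisture, "feed_moisture"),
         _bind(water_flow, "water_flow"), _bind(acid_flow, "acid_flow")],
        output_name="slurry_flow",
    )
    if budget.value < 0:
        raise BalanceError("derived slurry flow is negative")
    return budget


def xylose_yield(run: PretreatmentRun,
                 mw: MolecularWeights = DEFAULT_MW) -> UncertaintyBudget:
    """Yield of monomeric xylose from feedstock xylan, with its budget.

    Batch form::

        Y_X = [m_f (1 - f_IS) / rho_L * C_X] / (m_i * x_X) * (MW_xylan/MW_xylose)

    Continuous form replaces ``m_f`` by the slurry mass flow and ``m_i`` by
    the feed dry-mass flow; when the slurry flow is derived rather than
    measured, the underlying primary flow measurements appear individually in
    the budget.
    """
    if run.x_X.value == 0:
        raise UndefinedYieldError("x_X is zero: no xylan in the feed")
    anhydro = mw.xylan_anhydro

    common = [("f_IS", run.f_IS), ("rho_L", run.rho_L), ("C_X", run.C_X),
              ("x_X", run.x_X)]
    if run.mode == "batch":

        def expr(m_f, f_IS, rho_L, C_X, m_i, x_X):
            liquor_g = m_f * (1.0 - f_IS) / rho_L * C_X
            return liquor_g / (m_i * x_X * G_PER_KG) * anhydro

        bound = [("m_f", run.m_f), *common, ("m_i", run.m_i)]
    elif run.slurry_flow is not None:

        def expr(slurry_flow, f_IS, rho_L, C_X, feed_dry_flow, x_X):
            liquor_g = slurry_flow * (1.0 - f_IS) / rho_L * C_X
            return liquor_g / (feed_dry_flow * x_X * G_PER_KG) * anhydro

        bound = [("slurry_flow", run.slurry_flow), *common,
                 ("feed_dry_flow", run.feed_dry_flow)]
    else:
        flash = run.flash_loss

        def expr(feed_dry_flow, feed_moisture, water_flow, acid_flow,
                 f_IS, rho_L, C_X, x_X):
            slurry = _slurry_flow_value(feed_dry_flow, feed_moisture,
                                        water_flow, acid_flow, flash)
            liquor_g = slurry * (1.0 - f_IS) / rho_L * C_X
            return liquor_g / (feed_dry_flow * x_X * G_PER_KG) * anhydro

        bound = [("feed_dry_flow", run.feed_dry_flow),
                 ("feed_moisture", run.feed_moisture),
                 ("water_flow", run.water_flow),
                 ("acid_flow", run.acid_flow), *common]
    inputs = [_bind(m, role) for role, m in bound]

    budget = propagate(expr, inputs, output_name="xylose_yield")
    _flag_range(budget)
    return budget


@dataclass
class EnzymaticHydrolysisRun:
    """Primary measurements of one batch enzymatic-hydrolysis experiment.

    The initial cellulose charge is ``m_slurry_0 * f_IS_0 * x_C`` (slurry
    mass times initial fraction insoluble solids times cellulose fraction of
    those solids); released glucose is measured in the final liquor.  The two
    f_IS measurements enter the budget as separate inputs.
    """

    m_slurry_0: Measurement
    f_IS_0: Measurement
    x_C: Measurement
    m_slurry_f: Measurement
    f_IS_f: Measurement
    rho_L: Measurement
    C_G: Measurement

    def __post_init__(self) -> None:
        _require_positive(self.m_slurry_0)
        _require_positive(self.m_slurry_f)
        _require_positive(self.rho_L)
        _require_fraction(self.f_IS_0)
        _require_fraction(self.f_IS_f, strict_upper=True)
        _require_fraction(self.x_C)
        if self.C_G.value < 0:
            raise YieldError("C_G must be >= 0")


def glucose_yield(run: EnzymaticHydrolysisRun,
                  mw: MolecularWeights = DEFAULT_MW) -> UncertaintyBudget:
    """Yield of monomeric glucose from cellulose in enzymatic hydrolysis.

    Y_G = [m_slurry_f (1 - f_IS_f) / rho_L * C_G]
          / (m_slurry_0 * f_IS_0 * x_C) * (MW_cellulose / MW_glucose)
    """
    if run.f_IS_0.value == 0 or run.x_C.value == 0:
        raise UndefinedYieldError("initial cellulose charge is zero")
    anhydro = mw.cellulose_anhydro

    def expr(m_slurry_f, f_IS_f, rho_L, C_G, m_slurry_0, f_IS_0, x_C):
        glucose_g = m_slurry_f * (1.0 - f_IS_f) / rho_L * C_G
        cellulose_g = m_slurry_0 * f_IS_0 * x_C * G_PER_KG
        return glucose_g / cellulose_g * anhydro

    bound = [("m_slurry_f", run.m_slurry_f), ("f_IS_f", run.f_IS_f),
             ("rho_L", run.rho_L), ("C_G", run.C_G),
             ("m_slurry_0", run.m_slurry_0), ("f_IS_0", run.f_IS_0),
             ("x_C", run.x_C)]
    budget = propagate(
        expr,
        [_bind(m, role) for role, m in bound],
        output_name="glucose_yield",
    )
    _flag_range(budget)
    return budget


@dataclass
class FermentationRun:
    """Primary measurements of one batch co-fermentation experiment.

    Sugar and ethanol masses are concentration deltas times the liquor
    volume of the matching slurry state, ``V = m_slurry (1 - f_IS) / rho_L``.
    Two f_IS measurements (initial and final broth) are required, mirroring
    how batch yields are bookkept at the bench.  ``assumed_hexose_yield`` is
    the assumed fractional ethanol yield from glucose and fructose (a
    constant carrying no uncertainty).
    """

    m_slurry_0: Measurement
    f_IS_0: Measurement
    m_slurry_f: Measurement
    f_IS_f: Measurement
    rho_L: Measurement
    c_glc_0: Measurement
    c_glc_f: Measurement
    c_fru_0: Measurement
    c_fru_f: Measurement
    c_xyl_0: Measurement
    c_xyl_f: Measurement
    c_etoh_0: Measurement
    c_etoh_f: Measurement
    assumed_hexose_yield: float = 0.95

    def __post_init__(self) -> None:
        _require_positive(self.m_slurry_0)
        _require_positive(self.m_slurry_f)
        _require_positive(self.rho_L)
        _require_fraction(self.f_IS_0, strict_upper=True)
        _require_fraction(self.f_IS_f, strict_upper=True)
        for c in (self.c_glc_0, self.c_glc_f, self.c_fru_0, self.c_fru_f,
                  self.c_xyl_0, self.c_xyl_f, self.c_etoh_0, self.c_etoh_f):
            if c.value < 0:
                raise YieldError(f"{c.name} must be >= 0")
        if not (0.0 < self.assumed_hexose_yield <= 1.0):
            raise YieldError("assumed_hexose_yield must be in (0, 1]")
        v0, vf = self._volumes()
        if self.c_etoh_f.value * vf < self.c_etoh_0.value * v0:
            raise YieldError("final ethanol mass below initial ethanol mass")

    def _volumes(self) -> tuple[float, float]:
        v0 = self.m_slurry_0.value * (1 - self.f_IS_0.value) / self.rho_L.value
        vf = self.m_slurry_f.value * (1 - self.f_IS_f.value) / self.rho_L.value
        return v0, vf

    def consumed(self, sugar: str) -> float:
        """Consumed mass (g) of 'glc', 'fru' or 'xyl' at the measured values."""
        v0, vf = self._volumes()
        c0 = getattr(self, f"c_{sugar}_0").value
        cf = getattr(self, f"c_{sugar}_f").value
        return c0 * v0 - cf * vf


def ethanol_yield_from_xylose(
    run: FermentationRun, mw: MolecularWeights = DEFAULT_MW
) -> UncertaintyBudget:
    """Fractional ethanol yield from xylose in co-fermentation.

    With consumed sugar masses and produced ethanol mass from state-matched
    liquor volumes, and an assumed hexose ethanol yield ``a``:

        Y = [dEtOH - a * 0.511 * (dGlc + dFru)] / (0.511 * dXyl)

    A negative numerator (more hexose-attributed ethanol than measured) is
    flagged on the budget, not silenced.
    """
    for sugar in ("glc", "fru", "xyl"):
        if run.consumed(sugar) < 0:
            raise YieldError(f"consumed {sugar} is negative at measured values")
    if run.consumed("xyl") == 0:
        raise UndefinedYieldError("no xylose consumed")
    a = run.assumed_hexose_yield
    f511 = mw.ethanol_mass_yield

    def expr(m_slurry_0, f_IS_0, m_slurry_f, f_IS_f, rho_L,
             c_glc_0, c_glc_f, c_fru_0, c_fru_f,
             c_xyl_0, c_xyl_f, c_etoh_0, c_etoh_f):
        v0 = m_slurry_0 * (1.0 - f_IS_0) / rho_L
        vf = m_slurry_f * (1.0 - f_IS_f) / rho_L
        d_etoh = c_etoh_f * vf - c_etoh_0 * v0
        d_glc = c_glc_0 * v0 - c_glc_f * vf
        d_fru = c_fru_0 * v0 - c_fru_f * vf
        d_xyl = c_xyl_0 * v0 - c_xyl_f * vf
        return (d_etoh - a * f511 * (d_glc + d_fru)) / (f511 * d_xyl)

    roles = ("m_slurry_0", "f_IS_0", "m_slurry_f", "f_IS_f", "rho_L",
             "c_glc_0", "c_glc_f", "c_fru_0", "c_fru_f",
             "c_xyl_0", "c_xyl_f", "c_etoh_0", "c_etoh_f")
    budget = propagate(
        expr,
        [_bind(getattr(run, r), r) for r in roles],
        output_name="ethanol_yield_from_xylose",
    )
    v0, vf = run._volumes()
    d_etoh = run.c_etoh_f.value * vf - run.c_etoh_0.value * v0
    if d_etoh - a * f511 * (run.consumed("glc") + run.consumed("fru")) < 0:
        budget.flags.append("negative_numerator")
    _flag_range(budget)
    return budget


def _flag_range(budget: UncertaintyBudget) -> None:
    # diagnostic only: out-of-range yields are reported, never clipped
    if not (0.0 <= budget.value <= 1.0):
        budget.flags.append("yield_out_of_range")
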
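"""Transparent stoichiometric plant surrogate and MESP economics.

A corn-stover-to-ethanol biochemical conversion train is represented as
three unit operations — dilute-acid pretreatment, enzymatic hydrolysis and
co-fermentation — each applying a *reaction slate* (idealized conversions
with fractional yields) to a component mass-flow stream.  Mass balances
close exactly: every reaction satisfies ``reactant + water = products``,
with water an explicit stream component so anhydro/hydration bookkeeping is
conservative to machine precision.

Economics are a deliberately simple levelized-cost model: annualized
capital, fixed and variable operating costs, feedstock cost, minus a power
credit on the lignin-rich boiler stream, divided by annual ethanol gallons.
The minimum ethanol selling price (MESP) is the plant-gate price at which
ethanol revenue balances this production cost.  A single calibration scalar
pins the base case to a declared target (the standard published base case
is $2.15/gal); absolute cost fidelity to a full discounted-cash-flow design
model is not claimed — what the surrogate preserves is the *relative*
response of MESP to compositions and yields, which is what sensitivity and
Monte Carlo analyses consume.

The default slate yields are documented placeholders: the full design-report
yield sets are not public.  Each unit carries its canonical reaction count
(21 pretreatment, 8 enzymatic hydrolysis, 31 fermentation) so every slate
position is nameable and overridable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "CompositionProfile",
    "DEFAULT_COMPOSITION",
    "Reaction",
    "Stream",
    "SurrogateError",
    "MassClosureError",
    "apply_reactions",
    "pretreatment_slate",
    "enzymatic_hydrolysis_slates",
    "fermentation_slate",
    "known_reaction_names",
    "PlantState",
    "simulate_plant",
    "EconConfig",
    "TEResult",
    "compute_mesp",
    "calibrate_economics",
    "SAMPLED_YIELD_NAMES",
]

_TOL = 1e-9

#: the five reaction yields carried through sensitivity and Monte Carlo
SAMPLED_YIELD_NAMES = (
    "xylan_to_xylose",
    "arabinan_to_arabinose",
    "cellulose_to_glucose",
    "glucose_to_ethanol",
    "xylose_to_ethanol",
)


class SurrogateError(ValueError):
    """Base class for surrogate-model errors."""


class MassClosureError(SurrogateError):
    """Competing fractional yields on one reactant exceed unity."""


@dataclass(frozen=True)
class CompositionProfile:
    """Dry-basis mass fractions of the feedstock.

    Fractions must sum to 1 within 1e-6; the ``extractives`` component
    absorbs closure when individual fractions are perturbed.
    """

    glucan: float = 0.351
    xylan: float = 0.195
    arabinan: float = 0.024
    galactan: float = 0.014
    mannan: float = 0.006
    lignin: float = 0.158
    ash: float = 0.049
    protein: float = 0.031
    soluble_sugars: float = 0.008
    extractives: float = 0.164

    _FIELDS = ("glucan", "xylan", "arabinan", "galactan", "mannan", "lignin",
               "ash", "protein", "soluble_sugars", "extractives")

    def __post_init__(self) -> None:
        for name in self._FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SurrogateError(f"{name} = {v} outside [0, 1]")
        if abs(self.total - 1.0) > 1e-6:
            raise SurrogateError(f"fractions sum to {self.total}, not 1")

    @property
    def total(self) -> float:
        return sum(getattr(self, n) for n in self._FIELDS)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in self._FIELDS}

    def with_updates(self, **fracs: float) -> "CompositionProfile":
        """Return a copy with some fractions replaced, closure preserved.

        The ``extractives`` fraction is adjusted so the total stays 1;
        a negative adjusted extractives fraction is an error.
        """
        unknown = set(fracs) - set(self._FIELDS)
        if unknown:
            raise SurrogateError(f"unknown components: {sorted(unknown)}")
        if "extractives" in fracs:
            raise SurrogateError("extractives absorbs closure; set the others")
        new = dict(self.as_dict(), **fracs)
        new["extractives"] = 0.0
        new["extractives"] = 1.0 - sum(new.values())
        if new["extractives"] < -1e-12:
            raise SurrogateError(
                "composition update leaves no room for extractives"
            )
        new["extractives"] = max(new["extractives"], 0.0)
        return CompositionProfile(**new)


DEFAULT_COMPOSITION = CompositionProfile()


@dataclass(frozen=True)
class Reaction:
    """A lumped stoichiometric conversion with a fractional yield.

    ``mass_factor`` is product mass per unit reactant mass (e.g. 150/132 for
    xylan -> xylose); ``coproducts`` lists secondary product masses per unit
    reactant (e.g. CO2 from fermentation).  ``water_term`` is water consumed
    per unit reactant (negative = released) and, if not given, is set from
    the conservation identity ``1 + water = mass_factor + sum(coproducts)``.
    """

    name: str
    reactant: str
    product: str
    mass_factor: float
    fyield: float
    coproducts: tuple[tuple[str, float], ...] = ()
    water_term: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mass_factor <= 0:
            raise SurrogateError(f"{self.name}: mass_factor must be > 0")
        if not (0.0 <= self.fyield <= 1.0):
            raise SurrogateError(f"{self.name}: yield {self.fyield} not in [0,1]")
        needed = self.mass_factor + sum(m for _, m in self.coproducts) - 1.0
        if self.water_term is None:
            object.__setattr__(self, "water_term", needed)
        elif abs(self.water_term - needed) > _TOL:
            raise SurrogateError(
                f"{self.name}: mass not conserved "
                f"(water_term {self.water_term} vs required {needed})"
            )


class Stream(dict):
    """Component mass flows in kg/h.  Absent components read as 0."""

    def __missing__(self, key: str) -> float:
        return 0.0

    @property
    def total(self) -> float:
        return sum(self.values())

    def validated(self) -> "Stream":
        for k, v in self.items():
            if v < -1e-9:
                raise SurrogateError(f"negative flow for {k}: {v}")
        return self


def apply_reactions(stream: Stream, slate: Iterable[Reaction]) -> Stream:
    """Apply a reaction slate to a stream; total mass is conserved.

    Each reaction converts ``fyield * available_reactant``; yields of
    competing reactions on the same reactant must sum to <= 1.  Water is
    debited (or credited) per the reaction's water term; all conversions use
    the *inlet* availability, so reaction order within a slate is irrelevant.
    """
    slate = list(slate)
    by_reactant: dict[str, float] = {}
    for r in slate:
        by_reactant[r.reactant] = by_reactant.get(r.reactant, 0.0) + r.fyield
    for reactant, total_y in by_reactant.items():
        if total_y > 1.0 + _TOL:
            raise MassClosureError(
                f"competing yields on {reactant!r} sum to {total_y:.6g} > 1"
            )
    out = Stream(stream)
    for r in slate:
        avail = stream[r.reactant]
        converted = r.fyield * avail
        if converted == 0.0:
            continue
        out[r.reactant] -= converted
        out[r.product] = out[r.product] + converted * r.mass_factor
        for comp, m in r.coproducts:
            out[comp] = out[comp] + converted * m
        out["water"] = out["water"] - converted * r.water_term
    if out["water"] < -1e-9:
        raise SurrogateError("insufficient water in stream for hydrolysis")
    return out.validated()


# -- stoichiometric constants ------------------------------------------------
_PENTOSE = 150.0 / 132.0     # pentosan -> pentose
_HEXOSE = 180.0 / 162.0      # hexosan -> hexose
_FURFURAL = 96.0 / 132.0     # pentosan -> furfural + 2 H2O
_HMF = 126.0 / 162.0         # hexosan -> HMF + 2 H2O
_CELLOBIOSE = 342.0 / 324.0  # 2 anhydroglucose -> cellobiose
_CB_GLUCOSE = 360.0 / 342.0  # cellobiose -> 2 glucose
_SUCROSE_INV = 360.0 / 342.0
_ETOH = 0.511                # g ethanol / g sugar (hexose or pentose)
_CO2 = 1.0 - _ETOH


def _r(name, reactant, product, factor, y, coproducts=()):
    return Reaction(name, reactant, product, factor, y, tuple(coproducts))


def pretreatment_slate(overrides: Mapping[str, float] | None = None) -> list[Reaction]:
    """The 21-reaction dilute-acid pretreatment slate.

    Default yields are placeholders except the two sampled reactions
    (``xylan_to_xylose`` 0.90, ``arabinan_to_arabinose`` 0.90).
    """
    y = _YieldLookup(overrides)
    return [
        _r("pt_glucan_to_glucose", "glucan", "glucose", _HEXOSE,
           y("pt_glucan_to_glucose", 0.099)),
        _r("pt_glucan_to_glucose_oligomer", "glucan", "glucose_oligomer", 1.0,
           y("pt_glucan_to_glucose_oligomer", 0.003)),
        _r("pt_glucan_to_hmf", "glucan", "hmf", _HMF,
           y("pt_glucan_to_hmf", 0.003)),
        _r("pt_glucan_to_degradation", "glucan", "degradation_products", 1.0,
           y("pt_glucan_to_degradation", 0.003)),
        _r("xylan_to_xylose", "xylan", "xylose", _PENTOSE,
           y("xylan_to_xylose", 0.90)),
        _r("pt_xylan_to_xylose_secondary", "xylan", "xylose", _PENTOSE,
           y("pt_xylan_to_xylose_secondary", 0.0)),
        _r("pt_xylan_to_xylose_oligomer", "xylan", "xylose_oligomer", 1.0,
           y("pt_xylan_to_xylose_oligomer", 0.02)),
        _r("pt_xylan_to_furfural", "xylan", "furfural", _FURFURAL,
           y("pt_xylan_to_furfural", 0.02)),
        _r("pt_xylan_to_tar", "xylan", "tar", 1.0,
           y("pt_xylan_to_tar", 0.01)),
        _r("arabinan_to_arabinose", "arabinan", "arabinose", _PENTOSE,
           y("arabinan_to_arabinose", 0.90)),
        _r("pt_arabinan_to_arabinose_oligomer", "arabinan",
           "arabinose_oligomer", 1.0,
           y("pt_arabinan_to_arabinose_oligomer", 0.02)),
        _r("pt_arabinan_to_furfural", "arabinan", "furfural", _FURFURAL,
           y("pt_arabinan_to_furfural", 0.02)),
        _r("pt_galactan_to_galactose", "galactan", "galactose", _HEXOSE,
           y("pt_galactan_to_galactose", 0.60)),
        _r("pt_galactan_to_galactose_oligomer", "galactan",
           "galactose_oligomer", 1.0,
           y("pt_galactan_to_galactose_oligomer", 0.04)),
        _r("pt_galactan_to_hmf", "galactan", "hmf", _HMF,
           y("pt_galactan_to_hmf", 0.01)),
        _r("pt_mannan_to_mannose", "mannan", "mannose", _HEXOSE,
           y("pt_mannan_to_mannose", 0.60)),
        _r("pt_mannan_to_mannose_oligomer", "mannan", "mannose_oligomer", 1.0,
           y("pt_mannan_to_mannose_oligomer", 0.04)),
        _r("pt_mannan_to_hmf", "mannan", "hmf", _HMF,
           y("pt_mannan_to_hmf", 0.01)),
        _r("pt_sucrose_to_glucose", "soluble_sugars", "glucose", _SUCROSE_INV,
           y("pt_sucrose_to_glucose", 0.50)),
        _r("pt_extractives_to_acetic_acid", "extractives", "acetic_acid", 1.0,
           y("pt_extractives_to_acetic_acid", 0.10)),
        _r("pt_lignin_solubilization", "lignin", "soluble_lignin", 1.0,
           y("pt_lignin_solubilization", 0.05)),
    ]


def enzymatic_hydrolysis_slates(
    overrides: Mapping[str, float] | None = None,
) -> tuple[list[Reaction], list[Reaction]]:
    """The 8-reaction enzymatic-hydrolysis slate, split over two stages.

    Residual glucan after pretreatment is the cellulose substrate; the
    sampled reaction is ``cellulose_to_glucose`` (default 0.90).  Stage-two
    positions are zero-yield placeholders apart from cellobiose hydrolysis.
    """
    y = _YieldLookup(overrides)
    stage1 = [
        _r("cellulose_to_glucose", "glucan", "glucose", _HEXOSE,
           y("cellulose_to_glucose", 0.90)),
        _r("eh_cellulose_to_cellobiose", "glucan", "cellobiose", _CELLOBIOSE,
           y("eh_cellulose_to_cellobiose", 0.03)),
        _r("eh_cellulose_to_glucose_oligomer", "glucan", "glucose_oligomer",
           1.0, y("eh_cellulose_to_glucose_oligomer", 0.01)),
        _r("eh_cellulose_to_cellobiose_slow", "glucan", "cellobiose",
           _CELLOBIOSE, y("eh_cellulose_to_cellobiose_slow", 0.0)),
    ]
    stage2 = [
        _r("eh_cellobiose_to_glucose", "cellobiose", "glucose", _CB_GLUCOSE,
           y("eh_cellobiose_to_glucose", 0.95)),
        _r("eh_cellulose_to_glucose_residual", "glucan", "glucose", _HEXOSE,
           y("eh_cellulose_to_glucose_residual", 0.0)),
        _r("eh_cellulose_to_cellobiose_residual", "glucan", "cellobiose",
           _CELLOBIOSE, y("eh_cellulose_to_cellobiose_residual", 0.0)),
        _r("eh_cellobiose_to_glucose_oligomer", "cellobiose",
           "glucose_oligomer", 1.0,
           y("eh_cellobiose_to_glucose_oligomer", 0.0)),
    ]
    return stage1, stage2


_FERM_SUGARS = ("glucose", "xylose", "arabinose", "galactose", "mannose")
_ETOH_DEFAULTS = {
    "glucose": 0.95,
    "xylose": 0.85,
    "arabinose": 0.85,
    "galactose": 0.85,
    "mannose": 0.85,
}
_ETOH_NAME = {
    "glucose": "glucose_to_ethanol",
    "xylose": "xylose_to_ethanol",
    "arabinose": "ferm_arabinose_to_ethanol",
    "galactose": "ferm_galactose_to_ethanol",
    "mannose": "ferm_mannose_to_ethanol",
}
# relative weights splitting the non-ethanol sugar residual
_SINK_WEIGHTS = (
    ("cell_mass", 0.50),
    ("lactic_acid", 0.15),
    ("succinic_acid", 0.10),
    ("glycerol", 0.10),
    ("byproduct", 0.15),
)


def fermentation_slate(overrides: Mapping[str, float] | None = None) -> list[Reaction]:
    """The 31-reaction co-fermentation slate over five sugars.

    Each sugar has an ethanol reaction (CO2 coproduct, 0.511/0.489 split) and
    residual-sink reactions (cell mass, organic acids, glycerol, lumped
    byproduct; xylose additionally xylitol).  Sink yields are derived so each
    sugar's total conversion is exactly 1: they share the residual
    ``1 - y_ethanol`` by fixed weights, preserving mass closure for any
    sampled ethanol yield up to 100 %.
    """
    y = _YieldLookup(overrides)
    slate: list[Reaction] = []
    for sugar in _FERM_SUGARS:
        y_eth = y(_ETOH_NAME[sugar], _ETOH_DEFAULTS[sugar])
        slate.append(
            _r(_ETOH_NAME[sugar], sugar, "ethanol", _ETOH, y_eth,
               coproducts=(("co2", _CO2),))
        )
        residual = 1.0 - y_eth
        sinks = list(_SINK_WEIGHTS)
        if sugar == "xylose":
            sinks = [(p, w * 0.9) for p, w in sinks] + [("xylitol", 0.1)]
        for product, w in sinks:
            cop = (("co2", 0.55),) if product == "cell_mass" else ()
            factor = 0.45 if product == "cell_mass" else 1.0
            slate.append(
                _r(f"ferm_{sugar}_to_{product}", sugar, product, factor,
                   residual * w, coproducts=cop)
            )
    assert len(slate) == 31
    return slate


class _YieldLookup:
    """Tracks which override names a slate builder consumed."""

    def __init__(self, overrides: Mapping[str, float] | None):
        self.overrides = dict(overrides or {})
        self.used: set[str] = set()

    def __call__(self, name: str, default: float) -> float:
        if name in self.overrides:
            self.used.add(name)
            v = float(self.overrides[name])
            if not (0.0 <= v <= 1.0):
                raise SurrogateError(f"override {name} = {v} not in [0, 1]")
            return v
        return default


def known_reaction_names() -> set[str]:
    """All overridable reaction names across the three slates."""
    names = {r.name for r in pretreatment_slate()}
    s1, s2 = enzymatic_hydrolysis_slates()
    names |= {r.name for r in s1} | {r.name for r in s2}
    names |= {r.name for r in fermentation_slate()}
    return names


@dataclass
class PlantState:
    """Steady-state plant mass balance at the fermentation outlet."""

    feed_rate: float              # kg dry feedstock / h
    ethanol: float                # kg/h
    boiler_fuel: float            # kg/h lignin + unconverted solids + cells
    outlet: Stream
    byproducts: dict[str, float]


_BOILER_COMPONENTS = (
    "lignin", "soluble_lignin", "glucan", "xylan", "arabinan", "galactan",
    "mannan", "cellobiose", "tar", "degradation_products", "cell_mass",
)


def simulate_plant(
    composition: CompositionProfile = DEFAULT_COMPOSITION,
    yields: Mapping[str, float] | None = None,
    feed_rate: float = 83_333.0,
    water_ratio: float = 2.5,
) -> PlantState:
    """Chain the three unit-operation slates over a dry-feed stream.

    ``yields`` maps reaction names (see :func:`known_reaction_names`) to
    fractional-yield overrides; unknown names raise.  ``feed_rate`` is the
    dry feedstock rate in kg/h (default approximates a 2000 Mg/day plant);
    ``water_ratio`` kg water per kg dry feed is added ahead of pretreatment
    so hydrolysis water demand is always covered.
    """
    if feed_rate <= 0:
        raise SurrogateError("feed_rate must be > 0")
    overrides = dict(yields or {})
    unknown = set(overrides) - known_reaction_names()
    if unknown:
        raise SurrogateError(f"unknown yield overrides: {sorted(unknown)}")

    feed = Stream({c: f * feed_rate for c, f in composition.as_dict().items()})
    feed["water"] = water_ratio * feed_rate

    pretreated = apply_reactions(feed, pretreatment_slate(overrides))
    s1, s2 = enzymatic_hydrolysis_slates(overrides)
    hydrolyzed = apply_reactions(apply_reactions(pretreated, s1), s2)
    broth = apply_reactions(hydrolyzed, fermentation_slate(overrides))

    boiler = sum(broth[c] for c in _BOILER_COMPONENTS)
    byproducts = {
        c: broth[c]
        for c in ("co2", "furfural", "hmf", "lactic_acid", "succinic_acid",
                  "glycerol", "xylitol", "acetic_acid", "byproduct",
                  "glucose_oligomer", "xylose_oligomer")
        if broth[c] > 0
    }
    return PlantState(
        feed_rate=feed_rate,
        ethanol=broth["ethanol"],
        boiler_fuel=boiler,
        outlet=broth,
        byproducts=byproducts,
    )


KG_PER_DRY_TON = 907.185  # US short ton


@dataclass(frozen=True)
class EconConfig:
    """Levelized-cost parameters of the MESP surrogate.

    All cost terms are annual; ``scale_factor`` is the single calibration
    scalar pinning the base case to a published MESP (see
    :func:`calibrate_economics`).
    """

    annualized_capital: float = 60e6      # $/yr
    fixed_operating: float = 15e6         # $/yr
    feedstock_price: float = 58.5         # $/dry US ton
    variable_cost_per_kg_feed: float = 0.04   # $/kg dry feed (enzymes, chemicals)
    power_price: float = 0.06             # $/kWh
    boiler_kwh_per_kg: float = 2.0        # net kWh electricity per kg boiler fuel
    operating_hours: float = 8410.0       # h/yr
    ethanol_kg_per_gal: float = 2.988     # 0.789 kg/L * 3.785 L/gal
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("annualized_capital", "fixed_operating",
                     "feedstock_price", "variable_cost_per_kg_feed",
                     "power_price", "boiler_kwh_per_kg", "operating_hours",
                     "ethanol_kg_per_gal", "scale_factor"):
            if getattr(self, name) < 0:
                raise SurrogateError(f"{name} must be >= 0")
        if self.operating_hours > 8766:
            raise SurrogateError("operating_hours exceeds hours in a year")
        if self.ethanol_kg_per_gal <= 0:
            raise SurrogateError("ethanol_kg_per_gal must be > 0")


@dataclass
class TEResult:
    """MESP and its levelized cost breakdown."""

    mesp: float                  # $/gal
    annual_ethanol_gal: float    # gal/yr
    breakdown: dict[str, float]  # $/yr by category (credit negative)


def compute_mesp(plant: PlantState, econ: EconConfig) -> TEResult:
    """Levelized MESP = scale * (annual costs - power credit) / annual gallons."""
    annual_kg = plant.ethanol * econ.operating_hours
    if annual_kg <= 0:
        raise SurrogateError("no ethanol produced: MESP undefined")
    annual_gal = annual_kg / econ.ethanol_kg_per_gal
    annual_feed_kg = plant.feed_rate * econ.operating_hours
    breakdown = {
        "annualized_capital": econ.annualized_capital,
        "fixed_operating": econ.fixed_operating,
        "feedstock": econ.feedstock_price * annual_feed_kg / KG_PER_DRY_TON,
        "variable_operating": econ.variable_cost_per_kg_feed * annual_feed_kg,
        "power_credit": -(plant.boiler_fuel * econ.operating_hours
                          * econ.boiler_kwh_per_kg * econ.power_price),
    }
    net = sum(breakdown.values())
    return TEResult(
        mesp=econ.scale_factor * net / annual_gal,
        annual_ethanol_gal=annual_gal,
        breakdown=breakdown,
    )


def calibrate_economics(
    composition: CompositionProfile = DEFAULT_COMPOSITION,
    yields: Mapping[str, float] | None = None,
    target_mesp: float = 2.15,
    econ: EconConfig | None = None,
    feed_rate: float = 83_333.0,
) -> EconConfig:
    """Set the calibration scalar so the base case hits ``target_mesp`` exactly.

    Idempotent: re-calibrating a calibrated config to a new target works the
    same way, because the scalar is recomputed from scale-factor 1.
    """
    if target_mesp <= 0:
        raise SurrogateError("target MESP must be > 0")
    econ = econ or EconConfig()
    base = replace(econ, scale_factor=1.0)
    plant = simulate_plant(composition, yields, feed_rate=feed_rate)
    raw = compute_mesp(plant, base).mesp
    if raw == 0:
        raise SurrogateError("base-case MESP is zero; cannot calibrate")
    return replace(econ, scale_factor=target_mesp / raw)
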
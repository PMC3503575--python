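"""Synthetic primary-measurement runs with known ground truth.

No public dataset of the underlying pilot/laboratory measurements exists,
so end-to-end testing of the yield + propagation pipeline relies on
generated runs: a continuous pilot-scale pretreatment experiment
(flow-based measurements) and batch bench-scale enzymatic-hydrolysis and
fermentation experiments (mass/concentration-based measurements).

Each generator starts from a *true* process state (true yield, composition,
operating scale), inverts the corresponding yield formula to obtain the
noiseless measurement set (e.g. solves for the liquor sugar concentration
implied by the true yield), then perturbs every measurement with
independent Gaussian noise at its stated standard uncertainty.  With noise
disabled the yield functions recover the true yields to machine precision,
which pins the algebra; with noise enabled the propagated uncertainty can
be validated by coverage statistics over replicates.

Instrument-class standard uncertainties (defaults): fraction insoluble
solids 1.0 % *absolute* (i.e. +/-0.01 on the fraction — the convention used
throughout this package, flagged because "1 %" on an f_IS of ~20 % is
ambiguous); flows 2 % relative; laboratory masses 0.2 % relative;
concentrations 1 % relative; liquor density 0.5 % relative; feedstock
composition absolute per the standard compositional-analysis
uncertainties (glucan 0.53, xylan 0.34, lignin 0.17 percentage points).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .surrogate import DEFAULT_COMPOSITION, CompositionProfile
from .uncertainty import Measurement
from .yields import (
    DEFAULT_MW,
    EnzymaticHydrolysisRun,
    FermentationRun,
    MolecularWeights,
    PretreatmentRun,
)

__all__ = ["TrueProcessSpec", "GenerationError", "generate_pretreatment_run",
           "generate_eh_run", "generate_fermentation_run"]

G_PER_KG = 1000.0


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class TrueProcessSpec:
    """Ground-truth process state and instrument uncertainty settings.

    True yields default to the headline experimental values of the emulated
    campaign (xylose from pretreatment 56.4 %, glucose from enzymatic
    hydrolysis 77.8 %, ethanol from xylose 86.2 %).  The pretreatment scale
    approximates a 1-Mg-per-day continuous reactor; hydrolysis and
    fermentation are 1-kg bench batches.
    """

    # true conversions (fractions)
    true_xylose_yield: float = 0.564
    true_glucose_yield: float = 0.778
    true_ethanol_from_xylose: float = 0.862
    assumed_hexose_yield: float = 0.95

    composition: CompositionProfile = DEFAULT_COMPOSITION

    # continuous pretreatment operating point (kg/h unless noted)
    feed_dry_flow: float = 42.0
    feed_moisture: float = 0.10
    water_flow: float = 90.0
    acid_flow: float = 3.0
    flash_loss: float = 0.05
    pt_f_IS: float = 0.20
    pt_rho_L: float = 1.05            # kg/L

    # batch enzymatic hydrolysis operating point
    eh_slurry_mass: float = 1.0       # kg
    eh_f_IS_0: float = 0.20
    eh_x_C: float = 0.60              # cellulose fraction of insoluble solids
    eh_rho_L: float = 1.03

    # batch fermentation operating point
    ferm_m_0: float = 1.0
    ferm_f_IS_0: float = 0.10
    ferm_m_f: float = 0.97
    ferm_f_IS_f: float = 0.08
    ferm_rho_L: float = 1.01
    ferm_c_glc_0: float = 100.0       # g/L
    ferm_c_glc_f: float = 1.0
    ferm_c_fru_0: float = 8.0
    ferm_c_fru_f: float = 0.5
    ferm_c_xyl_0: float = 45.0
    ferm_c_xyl_f: float = 4.0
    ferm_c_etoh_0: float = 0.5

    # instrument-class standard uncertainties
    u_f_IS_abs: float = 0.01
    u_flow_rel: float = 0.02
    u_mass_rel: float = 0.002
    u_conc_rel: float = 0.01
    u_rho_rel: float = 0.005
    u_moisture_abs: float = 0.005
    u_glucan_abs: float = 0.0053
    u_xylan_abs: float = 0.0034
    u_lignin_abs: float = 0.0017
    u_solids_comp_rel: float = 0.015

    def __post_init__(self) -> None:
        for name in ("true_xylose_yield", "true_glucose_yield",
                     "true_ethanol_from_xylose", "assumed_hexose_yield"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise GenerationError(f"{name} must be in [0, 1]")
        for name in ("u_f_IS_abs", "u_flow_rel", "u_mass_rel", "u_conc_rel",
                     "u_rho_rel", "u_moisture_abs", "u_glucan_abs",
                     "u_xylan_abs", "u_lignin_abs", "u_solids_comp_rel"):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")

    def scaled_uncertainties(self, factor: float) -> "TrueProcessSpec":
        """Copy with every instrument uncertainty multiplied by ``factor``."""
        ufields = {n: getattr(self, n) * factor for n in (
            "u_f_IS_abs", "u_flow_rel", "u_mass_rel", "u_conc_rel",
            "u_rho_rel", "u_moisture_abs", "u_glucan_abs", "u_xylan_abs",
            "u_lignin_abs", "u_solids_comp_rel")}
        return replace(self, **ufields)


def _measure(rng, name: str, true: float, u: float, units: str,
             noise: bool) -> Measurement:
    value = true + rng.normal(0.0, u) if (noise and u > 0) else true
    return Measurement(name, value, u, units)


def generate_pretreatment_run(
    spec: TrueProcessSpec = TrueProcessSpec(),
    seed: int = 0,
    noise: bool = True,
    mw: MolecularWeights = DEFAULT_MW,
) -> tuple[PretreatmentRun, dict]:
    """Continuous pretreatment run with a derived slurry flow.

    The liquor xylose concentration is solved from the true yield at the
    true flows/solids, then every primary measurement is noised.  Returns
    the run and a truth sidecar (true yield + true measurement values).
    """
    s = spec
    wet_feed = s.feed_dry_flow / (1.0 - s.feed_moisture)
    slurry = (wet_feed + s.water_flow + s.acid_flow) * (1.0 - s.flash_loss)
    x_X = s.composition.xylan
    liquor_vol = slurry * (1.0 - s.pt_f_IS) / s.pt_rho_L       # L/h
    xylan_in_g = s.feed_dry_flow * x_X * G_PER_KG
    c_x = s.true_xylose_yield * xylan_in_g / (mw.xylan_anhydro * liquor_vol)
    if c_x <= 0 or not np.isfinite(c_x):
        raise GenerationError(f"infeasible true state: implied C_X = {c_x}")

    rng = np.random.default_rng(seed)
    truth = {
        "unit": "pretreatment",
        "true_yield": s.true_xylose_yield,
        "true_values": {
            "feed_dry_flow": s.feed_dry_flow, "feed_moisture": s.feed_moisture,
            "water_flow": s.water_flow, "acid_flow": s.acid_flow,
            "f_IS": s.pt_f_IS, "rho_L": s.pt_rho_L, "C_X": c_x, "x_X": x_X,
            "flash_loss": s.flash_loss,
        },
        "seed": seed,
    }
    run = PretreatmentRun(
        mode="continuous",
        feed_dry_flow=_measure(rng, "feed_dry_flow", s.feed_dry_flow,
                               s.u_flow_rel * s.feed_dry_flow, "kg/h", noise),
        feed_moisture=_measure(rng, "feed_moisture", s.feed_moisture,
                               s.u_moisture_abs, "fraction", noise),
        water_flow=_measure(rng, "water_flow", s.water_flow,
                            s.u_flow_rel * s.water_flow, "kg/h", noise),
        acid_flow=_measure(rng, "acid_flow", s.acid_flow,
                           s.u_flow_rel * s.acid_flow, "kg/h", noise),
        flash_loss=s.flash_loss,
        f_IS=_measure(rng, "f_IS", s.pt_f_IS, s.u_f_IS_abs, "fraction", noise),
        rho_L=_measure(rng, "rho_L", s.pt_rho_L, s.u_rho_rel * s.pt_rho_L,
                       "kg/L", noise),
        C_X=_measure(rng, "C_X", c_x, s.u_conc_rel * c_x, "g/L", noise),
        x_X=_measure(rng, "x_X", x_X, s.u_xylan_abs, "fraction", noise),
    )
    return run, truth


def generate_eh_run(
    spec: TrueProcessSpec = TrueProcessSpec(),
    seed: int = 0,
    noise: bool = True,
    mw: MolecularWeights = DEFAULT_MW,
) -> tuple[EnzymaticHydrolysisRun, dict]:
    """Batch enzymatic-hydrolysis run, self-consistent solids balance.

    The final fraction insoluble solids follows from the cellulose actually
    hydrolyzed at the true yield (slurry mass unchanged in the closed
    vessel); the liquor glucose concentration is then solved from the true
    yield.
    """
    s = spec
    m0 = s.eh_slurry_mass
    cellulose0 = m0 * s.eh_f_IS_0 * s.eh_x_C                   # kg
    consumed = s.true_glucose_yield * cellulose0
    glucose_g = consumed / mw.cellulose_anhydro * G_PER_KG
    mf = m0
    solids_f = m0 * s.eh_f_IS_0 - consumed
    f_f = solids_f / mf
    if not (0.0 <= f_f < 1.0):
        raise GenerationError(f"infeasible final f_IS = {f_f}")
    liquor_vol = mf * (1.0 - f_f) / s.eh_rho_L
    c_g = glucose_g / liquor_vol
    if c_g <= 0:
        raise GenerationError("implied C_G <= 0")

    rng = np.random.default_rng(seed)
    truth = {
        "unit": "enzymatic_hydrolysis",
        "true_yield": s.true_glucose_yield,
        "true_values": {
            "m_slurry_0": m0, "f_IS_0": s.eh_f_IS_0, "x_C": s.eh_x_C,
            "m_slurry_f": mf, "f_IS_f": f_f, "rho_L": s.eh_rho_L, "C_G": c_g,
        },
        "seed": seed,
    }
    run = EnzymaticHydrolysisRun(
        m_slurry_0=_measure(rng, "m_slurry_0", m0, s.u_mass_rel * m0, "kg",
                            noise),
        f_IS_0=_measure(rng, "f_IS_0", s.eh_f_IS_0, s.u_f_IS_abs, "fraction",
                        noise),
        x_C=_measure(rng, "x_C", s.eh_x_C, s.u_solids_comp_rel * s.eh_x_C,
                     "fraction", noise),
        m_slurry_f=_measure(rng, "m_slurry_f", mf, s.u_mass_rel * mf, "kg",
                            noise),
        f_IS_f=_measure(rng, "f_IS_f", f_f, s.u_f_IS_abs, "fraction", noise),
        rho_L=_measure(rng, "rho_L", s.eh_rho_L, s.u_rho_rel * s.eh_rho_L,
                       "kg/L", noise),
        C_G=_measure(rng, "C_G", c_g, s.u_conc_rel * c_g, "g/L", noise),
    )
    return run, truth


def generate_fermentation_run(
    spec: TrueProcessSpec = TrueProcessSpec(),
    seed: int = 0,
    noise: bool = True,
    mw: MolecularWeights = DEFAULT_MW,
) -> tuple[FermentationRun, dict]:
    """Batch co-fermentation run honoring the assumed hexose ethanol yield.

    The final ethanol concentration is constructed so that, at the true
    measurement values, the xylose-to-ethanol yield equals the spec's true
    value given the assumed glucose/fructose ethanol yield.
    """
    s = spec
    a = s.assumed_hexose_yield
    v0 = s.ferm_m_0 * (1.0 - s.ferm_f_IS_0) / s.ferm_rho_L
    vf = s.ferm_m_f * (1.0 - s.ferm_f_IS_f) / s.ferm_rho_L
    d_glc = s.ferm_c_glc_0 * v0 - s.ferm_c_glc_f * vf
    d_fru = s.ferm_c_fru_0 * v0 - s.ferm_c_fru_f * vf
    d_xyl = s.ferm_c_xyl_0 * v0 - s.ferm_c_xyl_f * vf
    if min(d_glc, d_fru, d_xyl) <= 0:
        raise GenerationError("true state has non-positive sugar consumption")
    f511 = mw.ethanol_mass_yield
    d_etoh = (s.true_ethanol_from_xylose * f511 * d_xyl
              + a * f511 * (d_glc + d_fru))
    c_etoh_f = (d_etoh + s.ferm_c_etoh_0 * v0) / vf
    if c_etoh_f <= s.ferm_c_etoh_0:
        raise GenerationError("implied final ethanol below initial")

    rng = np.random.default_rng(seed)
    truth = {
        "unit": "fermentation",
        "true_yield": s.true_ethanol_from_xylose,
        "assumed_hexose_yield": a,
        "true_values": {
            "m_slurry_0": s.ferm_m_0, "f_IS_0": s.ferm_f_IS_0,
            "m_slurry_f": s.ferm_m_f, "f_IS_f": s.ferm_f_IS_f,
            "rho_L": s.ferm_rho_L,
            "c_glc_0": s.ferm_c_glc_0, "c_glc_f": s.ferm_c_glc_f,
            "c_fru_0": s.ferm_c_fru_0, "c_fru_f": s.ferm_c_fru_f,
            "c_xyl_0": s.ferm_c_xyl_0, "c_xyl_f": s.ferm_c_xyl_f,
            "c_etoh_0": s.ferm_c_etoh_0, "c_etoh_f": c_etoh_f,
        },
        "seed": seed,
    }

    def conc(name, true):
        return _measure(rng, name, true, s.u_conc_rel * true, "g/L", noise)

    run = FermentationRun(
        m_slurry_0=_measure(rng, "m_slurry_0", s.ferm_m_0,
                            s.u_mass_rel * s.ferm_m_0, "kg", noise),
        f_IS_0=_measure(rng, "f_IS_0", s.ferm_f_IS_0, s.u_f_IS_abs,
                        "fraction", noise),
        m_slurry_f=_measure(rng, "m_slurry_f", s.ferm_m_f,
                            s.u_mass_rel * s.ferm_m_f, "kg", noise),
        f_IS_f=_measure(rng, "f_IS_f", s.ferm_f_IS_f, s.u_f_IS_abs,
                        "fraction", noise),
        rho_L=_measure(rng, "rho_L", s.ferm_rho_L,
                       s.u_rho_rel * s.ferm_rho_L, "kg/L", noise),
        c_glc_0=conc("c_glc_0", s.ferm_c_glc_0),
        c_glc_f=conc("c_glc_f", s.ferm_c_glc_f),
        c_fru_0=conc("c_fru_0", s.ferm_c_fru_0),
        c_fru_f=conc("c_fru_f", s.ferm_c_fru_f),
        c_xyl_0=conc("c_xyl_0", s.ferm_c_xyl_0),
        c_xyl_f=conc("c_xyl_f", s.ferm_c_xyl_f),
        c_etoh_0=conc("c_etoh_0", s.ferm_c_etoh_0),
        c_etoh_f=conc("c_etoh_f", c_etoh_f),
        assumed_hexose_yield=a,
    )
    return run, truth
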
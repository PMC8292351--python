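"""Energy and mass budgets linking electron transport to carbon metabolism.

The photosynthetic electron transport chain exports reduced ferredoxin (Fd),
NADPH and ATP to the photosynthetic carbon reduction (PCR, Calvin) and carbon
oxidation (PCO, photorespiration) cycles.  In steady state the three budgets
must close simultaneously.  This module holds the fixed stoichiometric
coefficients of those budgets, the proton bookkeeping behind the composite
coupling efficiencies ``n_L`` (ATP per electron in linear flow) and ``n_C``
(ATP per electron in cyclic flow around PS I), and the Rubisco kinetics that
set the demand side (specificity, CO2 compensation point).

Unit conventions
----------------
Areal fluxes are µmol m⁻² s⁻¹ throughout.  Chloroplast CO2 partial pressure
``C`` and the compensation point ``Γ*`` are stored in µbar, O2 in mbar;
conversion to a common pressure unit happens *inside* operations, never at
call sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Environment",
    "RubiscoKinetics",
    "CouplingScenario",
    "CouplingEfficiencies",
    "MetabolicFluxes",
    "DEFAULT_KINETICS",
    "DEFAULT_COUPLING",
    "rubisco_specificity",
    "co2_compensation",
    "coupling_efficiencies",
    "eta",
    "cef1_fraction",
    "electron_requirements",
    "demand_fluxes",
    "supply_fluxes",
    "assimilation",
]

#: mbar -> µbar
_MBAR_TO_UBAR = 1000.0


@dataclass(frozen=True)
class Environment:
    """Driving conditions at the chloroplast.

    Parameters
    ----------
    q : float
        Incident photosynthetically active radiation (µmol PPFD m⁻² s⁻¹).
    t_leaf : float
        Leaf temperature (°C).  All kinetic constants are referenced to
        25 °C; no temperature scaling is applied.
    c : float
        Chloroplast CO2 partial pressure (µbar).
    o : float
        Chloroplast O2 partial pressure (mbar).
    p : float
        Air pressure (bar).
    """

    q: float = 0.0
    t_leaf: float = 25.0
    c: float = 200.0
    o: float = 209.0
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("PPFD q must be >= 0")
        if self.c <= 0:
            raise ValueError("chloroplast CO2 c must be > 0")
        if self.o < 0:
            raise ValueError("chloroplast O2 o must be >= 0")
        if self.p <= 0:
            raise ValueError("air pressure p must be > 0")


@dataclass(frozen=True)
class RubiscoKinetics:
    """Rubisco catalytic and Michaelis constants at 25 °C.

    ``k_c``/``k_o`` are catalytic constants (mol CO2 or O2 mol⁻¹ sites s⁻¹),
    ``km_c`` the Michaelis constant for CO2 (µbar) and ``km_o`` for O2 (mbar).
    """

    k_c: float = 3.6
    k_o: float = 0.9
    km_c: float = 260.0
    km_o: float = 179.0

    def __post_init__(self) -> None:
        if min(self.k_c, self.k_o, self.km_c, self.km_o) <= 0:
            raise ValueError("Rubisco kinetic constants must be strictly positive")


@dataclass(frozen=True)
class CouplingScenario:
    """Assumptions feeding the proton ledger of the coupling efficiencies.

    ``q_cycle_on``
        Cytochrome b6f runs a constitutive Q-cycle (2 H⁺/e⁻ instead of 1).
    ``ndh_pump_on``
        CEF1 electrons return to the PQ pool via the proton-pumping NDH
        complex (2 extra H⁺/e⁻) rather than a non-pumping route.
    ``h_per_atp``
        ATP synthase stoichiometry: 4 (thermodynamic) or 14/3 (structural,
        from the c14 ring).
    """

    q_cycle_on: bool = True
    ndh_pump_on: bool = True
    h_per_atp: float = 4.0

    def __post_init__(self) -> None:
        if not (
            np.isclose(self.h_per_atp, 4.0) or np.isclose(self.h_per_atp, 14.0 / 3.0)
        ):
            raise ValueError("h_per_atp must be 4 or 14/3")


@dataclass(frozen=True)
class CouplingEfficiencies:
    """ATP produced per electron in linear (``n_l``) and cyclic (``n_c``) flow."""

    n_l: float = 0.75
    n_c: float = 1.00

    def __post_init__(self) -> None:
        if self.n_l <= 0 or self.n_c <= 0:
            raise ValueError("coupling efficiencies must be positive")


@dataclass(frozen=True)
class MetabolicFluxes:
    """Consumption rates of reductant and ATP by the PCR + PCO cycles."""

    v_c: float
    v_o: float
    j_nadph: float
    j_fd: float
    j_atp: float


DEFAULT_KINETICS = RubiscoKinetics()
DEFAULT_COUPLING = CouplingEfficiencies()


def rubisco_specificity(kin: RubiscoKinetics = DEFAULT_KINETICS) -> float:
    """Rubisco CO2/O2 specificity S = (k_c/K_c)·(K_o/k_o), dimensionless.

    ``K_c`` (µbar) and ``K_o`` (mbar) are converted to a common pressure unit
    internally.
    """
    return (kin.k_c / kin.km_c) * (kin.km_o * _MBAR_TO_UBAR / kin.k_o)


def co2_compensation(s_spec: float, o: float) -> float:
    """CO2 compensation point Γ* = O/(2·S) in µbar, for ``o`` in mbar.

    Γ* is the chloroplast pCO2 at which carboxylase CO2 uptake balances the
    CO2 released by oxygenase (photorespiratory) activity.
    """
    s_spec = np.asarray(s_spec, dtype=float)
    if np.any(s_spec <= 0):
        raise ValueError("specificity must be positive")
    return float(0.5 * o * _MBAR_TO_UBAR / s_spec)


def coupling_efficiencies(scenario: CouplingScenario) -> CouplingEfficiencies:
    """Proton bookkeeping for the composite coupling efficiencies.

    Per electron, linear flow deposits one lumen proton at water oxidation
    plus one (or two, with the Q-cycle) at PQH2 oxidation by b6f.  Cyclic
    flow deposits the b6f protons plus, when the NDH pump carries the
    Fd→PQ step, two more.  Dividing by the H⁺/ATP ratio of the synthase
    gives ATP per electron.
    """
    h_b6f = 2.0 if scenario.q_cycle_on else 1.0
    h_lef = 1.0 + h_b6f
    h_cef = h_b6f + (2.0 if scenario.ndh_pump_on else 0.0)
    return CouplingEfficiencies(
        n_l=h_lef / scenario.h_per_atp, n_c=h_cef / scenario.h_per_atp
    )


def eta(n: CouplingEfficiencies, gamma_star: float, c):
    """PS I : PS II electron-flux ratio closing the Fd/NADPH/ATP budgets.

    η = 1 − n_L/n_C + (3 + 7·Γ*/C) / ((4 + 8·Γ*/C)·n_C).  The CEF1 share of
    total PS I electron flow is 1 − 1/η.
    """
    if n.n_c == 0:
        raise ValueError("n_c must be nonzero")
    x = gamma_star / np.asarray(c, dtype=float)
    out = 1.0 - n.n_l / n.n_c + (3.0 + 7.0 * x) / ((4.0 + 8.0 * x) * n.n_c)
    return out if out.ndim else float(out)


def cef1_fraction(eta_value) -> float:
    """Fraction of total PS I electron flow that is cyclic: 1 − 1/η."""
    return 1.0 - 1.0 / np.asarray(eta_value, dtype=float) if np.ndim(eta_value) else float(
        1.0 - 1.0 / eta_value
    )


def electron_requirements(a, r_d: float, c, gamma_star: float, eta_value):
    """PS II and PS I electron fluxes required to support assimilation ``a``.

    J_P680 = (A + R_d)·(4 + 8·Γ*/C)/(1 − Γ*/C) and J_P700 = η·J_P680.
    Requires C > Γ* (above the compensation point).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= gamma_star):
        raise ValueError("chloroplast CO2 is at or below the compensation point")
    x = gamma_star / c
    j_p680 = (np.asarray(a, dtype=float) + r_d) * (4.0 + 8.0 * x) / (1.0 - x)
    j_p700 = j_p680 * eta_value
    if j_p680.ndim:
        return j_p680, j_p700
    return float(j_p680), float(j_p700)


def demand_fluxes(v_c: float, v_o: float) -> MetabolicFluxes:
    """Reductant and ATP demand of carboxylation ``v_c`` and oxygenation ``v_o``.

    J_NADPH = 2·V_c + 1.5·V_o, J_Fd = V_o, J_ATP = 3·V_c + 3.5·V_o — the PCR
    cycle consumes 6 NADPH and 9 ATP per 3 CO2; the PCO cycle 9 NADPH, 6 Fd
    and 21 ATP per 6 O2.
    """
    if v_c < 0 or v_o < 0:
        raise ValueError("rates must be non-negative")
    return MetabolicFluxes(
        v_c=v_c,
        v_o=v_o,
        j_nadph=2.0 * v_c + 1.5 * v_o,
        j_fd=v_o,
        j_atp=3.0 * v_c + 3.5 * v_o,
    )


def supply_fluxes(
    j_p680: float, j_p700: float, n: CouplingEfficiencies = DEFAULT_COUPLING
) -> tuple[float, float]:
    """Reductant (electron) and ATP supply of the electron transport chain.

    Linear flow delivers ``j_p680`` electrons to Fd/NADPH; ATP supply is
    J_P680·n_L + (J_P700 − J_P680)·n_C, the second term being CEF1.
    """
    if j_p700 < j_p680:
        raise ValueError("j_p700 < j_p680 would imply negative cyclic flow")
    if j_p680 < 0:
        raise ValueError("fluxes must be non-negative")
    return j_p680, j_p680 * n.n_l + (j_p700 - j_p680) * n.n_c


def assimilation(v_c: float, v_o: float, r_d: float = 0.0) -> tuple[float, float]:
    """Gross and net CO2 assimilation: A_g = V_c − 0.5·V_o, A = A_g − R_d."""
    if v_c < 0 or v_o < 0:
        raise ValueError("rates must be non-negative")
    a_g = v_c - 0.5 * v_o
    return a_g, a_g - r_d
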
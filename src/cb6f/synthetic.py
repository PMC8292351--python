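"""Protocol-faithful synthetic datasets and the published simulation cases.

The generator emulates the sine-wave greenhouse protocol: light rises and
falls as Q(t) = Q_peak·sin(π·t/8 h) over an 8-hour day, sampled every 8
minutes (61 samples; the first and last are in darkness and provide the
dark-adapted F_m/F_o references).  At each sample the steady state is solved
at a fixed chloroplast CO2, the forward fluorescence operator produces the
PAM levels, and gas-exchange columns (C_a, E, g_tc) are synthesized
consistently with the leaf's mesophyll conductance so that the diffusion
path inverts exactly.  Multiplicative lognormal noise with configurable CV
emulates instrument error.

``case_fixture`` returns the twelve published simulation configurations:
Cases 1–4 explore the b6f-limited ("potential") state, Cases 5–8 the
regulatory modes that bridge to the Rubisco-limited state, and Cases 9–12
connectivity, state transitions and the balance of maximum activities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SCHEMA, Dataset
from .fluorescence import DetectorModel, fluorescence_levels
from .light_reactions import DEFAULT_CONSTANTS, PhotochemicalConstants
from .solver import (
    DEFAULT_LEAF,
    LeafParameters,
    aj,
    solve_cross_sections,
    solve_steady_state,
)
from .stoichiometry import (
    DEFAULT_COUPLING,
    DEFAULT_KINETICS,
    CouplingScenario,
    Environment,
    co2_compensation,
    coupling_efficiencies,
    eta,
    rubisco_specificity,
)

__all__ = [
    "Protocol",
    "NoiseModel",
    "LAKE_KU2",
    "sine_wave_protocol",
    "generate_dataset",
    "case_fixture",
    "simulate_case",
    "DEFAULT_Q_GRID",
]

#: light-response evaluation grid used by the simulations (µmol m⁻² s⁻¹)
DEFAULT_Q_GRID = np.arange(0.0, 2401.0, 25.0)

#: numerical stand-in for lake-type (fully connected) PS II antennae
LAKE_KU2 = 1000.0


@dataclass(frozen=True)
class Protocol:
    """Light protocol: sine wave (default), constant, or a custom sequence."""

    peak_q: float = 2400.0
    duration_h: float = 8.0
    interval_min: float = 8.0
    waveform: str = "sine"

    def __post_init__(self) -> None:
        if self.peak_q < 0:
            raise ValueError("peak_q must be >= 0")
        n = self.duration_h * 60.0 / self.interval_min
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling interval must divide the duration")
        if self.waveform not in ("sine", "constant"):
            raise ValueError("waveform must be 'sine' or 'constant'")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise (unit mean) with per-stream CVs."""

    cv_fluor: float = 0.0
    cv_gas: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_fluor < 0 or self.cv_gas < 0:
            raise ValueError("coefficients of variation must be >= 0")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size if size is not None else ())
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def sine_wave_protocol(
    peak_q: float, duration_h: float = 8.0, interval_min: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sampling times (s) and light levels for the sine-wave day.

    Q(t) = peak·sin(π t/duration), clipped at zero; first and last samples
    are dark.
    """
    proto = Protocol(peak_q=peak_q, duration_h=duration_h, interval_min=interval_min)
    n = int(round(proto.duration_h * 60.0 / proto.interval_min)) + 1
    t_s = np.arange(n) * proto.interval_min * 60.0
    q = proto.peak_q * np.sin(np.pi * t_s / (proto.duration_h * 3600.0))
    q = np.clip(q, 0.0, None)
    q[np.abs(q) < 1e-6] = 0.0  # endpoints are true darkness
    return t_s, q


def generate_dataset(
    leaf: LeafParameters = DEFAULT_LEAF,
    env_base: Environment | None = None,
    protocol: Protocol = Protocol(),
    noise: NoiseModel = NoiseModel(),
    detector: DetectorModel = DetectorModel(eps_f2=1.0, eps_f1=2.0),
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
    g_tc: float = 0.08,
    e_mmol: float = 1.5,
) -> Dataset:
    """Simulate one protocol run into the standard dataset schema.

    Chloroplast CO2 is held at ``env_base.c`` across light levels (the
    simulations' convention); cuvette CO2 is synthesized backwards through
    the mesophyll and stomatal/boundary-layer path so the diffusion
    equations invert exactly.  Samples with Q = 0 become dark records
    carrying F_m/F_o.  Fixed seed gives identical output bytes.
    """
    env_base = env_base or Environment()
    if protocol.waveform == "constant":
        n = int(round(protocol.duration_h * 60.0 / protocol.interval_min)) + 1
        t_s = np.arange(n) * protocol.interval_min * 60.0
        q_seq = np.full(n, protocol.peak_q)
    else:
        t_s, q_seq = sine_wave_protocol(
            protocol.peak_q, protocol.duration_h, protocol.interval_min
        )
    rng = np.random.default_rng(noise.seed)
    e_mol = e_mmol / 1000.0

    rows = []
    for t, qv in zip(t_s, q_seq):
        try:
            state = solve_steady_state(float(qv), leaf, env_base, k)
        except ValueError:
            continue  # unsolvable sample dropped
        dark = qv <= 0.0
        levels = fluorescence_levels(
            state, k, detector, alpha_dark=(leaf.alpha_1, leaf.alpha_2)
        )
        a_true = state.a
        c_i = env_base.c + a_true / leaf.g_m
        c_a = (c_i * (g_tc + e_mol / 2.0) + a_true) / (g_tc - e_mol / 2.0)
        a_obs = a_true * _lognormal_factor(rng, noise.cv_gas, None)
        nf = _lognormal_factor(rng, noise.cv_fluor, 3)
        if dark:
            f_s, f_mx, f_ox = np.nan, levels.f_m * nf[1], levels.f_o * nf[2]
        else:
            f_s = levels.f_s * nf[0]
            f_mx = levels.f_m_prime * nf[1]
            f_ox = levels.f_o_prime * nf[2]
        rows.append(
            {
                "time_s": float(t),
                "record_type": "dark" if dark else "light",
                "Q": float(qv),
                "T_leaf": env_base.t_leaf,
                "C_a": float(c_a),
                "O_mbar": env_base.o,
                "P_bar": env_base.p,
                "A": float(a_obs),
                "E_mmol": e_mmol,
                "g_tc": g_tc,
                "F_s": float(f_s) if f_s == f_s else np.nan,
                "F_m_or_Fm_prime": float(f_mx),
                "F_o_or_Fo_prime": float(f_ox),
            }
        )
    return Dataset(pd.DataFrame(rows, columns=SCHEMA))


def _balanced_leaf(base: LeafParameters, **kw) -> LeafParameters:
    """Leaf with the cross-section split balanced for the base environment."""
    env = Environment()
    gamma = co2_compensation(rubisco_specificity(DEFAULT_KINETICS), env.o)
    e = eta(DEFAULT_COUPLING, gamma, env.c)
    k0 = PhotochemicalConstants(k_u2=0.0)
    _, a2 = solve_cross_sections(e, 0.0, k0, base.alpha_total)
    return base.with_(alpha_2=a2, **kw)


def case_fixture(case_id: int) -> dict:
    """Exact configuration of one of the twelve published simulation cases.

    Returns ``{"case", "description", "mode", "variants"}`` where ``mode``
    is ``"potential"`` (b6f-limited response only, Cases 1–4) or ``"full"``
    (minimum-rule solve, Cases 5–12) and each variant carries a label, a
    ``LeafParameters``, an ``Environment``, a ``PhotochemicalConstants`` and
    a ``CouplingEfficiencies``.
    """
    base = DEFAULT_LEAF
    env = Environment()
    k0 = DEFAULT_CONSTANTS
    n0 = DEFAULT_COUPLING

    def var(label, leaf=base, e=env, k=k0, n=n0):
        return {"label": label, "leaf": leaf, "env": e, "k": k, "coupling": n}

    if case_id == 1:
        variants = [
            var(
                f"alpha={a:.2f}",
                base.with_(
                    alpha_total=a,
                    alpha_2=base.alpha_2 * a / base.alpha_total,
                    alpha_1=base.alpha_1 * a / base.alpha_total,
                ),
            )
            for a in (0.50, 0.70, 0.85)
        ]
        return _case(1, "leaf absorptance sweep, constant partitioning",
                     "potential", variants)
    if case_id == 2:
        variants = [
            var(f"v_b6f={v:g}", base.with_(v_max_cb6f=v)) for v in (175.0, 350.0, 700.0)
        ]
        return _case(2, "maximum Cyt b6f activity sweep", "potential", variants)
    if case_id == 3:
        scenarios = {
            "reference": CouplingScenario(True, True, 4.0),
            "no_ndh": CouplingScenario(True, False, 4.0),
            "structural_atp": CouplingScenario(True, True, 14.0 / 3.0),
            "no_q_cycle": CouplingScenario(False, True, 4.0),
            "all_relaxed": CouplingScenario(False, False, 14.0 / 3.0),
        }
        variants = [
            var(label, n=coupling_efficiencies(s)) for label, s in scenarios.items()
        ]
        return _case(3, "electron transport / ATP coupling scenarios",
                     "potential", variants)
    if case_id == 4:
        variants = [
            var(f"C={c:g}", e=Environment(c=c))
            for c in (100.0, 200.0, 500.0, 1000.0, 2000.0, 5000.0)
        ]
        return _case(4, "chloroplast CO2 sweep", "potential", variants)
    if case_id == 5:
        leaf = _balanced_leaf(base, npq_enabled=False)
        return _case(5, "photosynthetic control via Cyt b6f alone (no NPQ)",
                     "full", [var("b6f_only", leaf)])
    if case_id == 6:
        leaf = _balanced_leaf(base, b6f_control=False)
        return _case(6, "photosynthetic control via NPQ alone", "full",
                     [var("npq_only", leaf)])
    if case_id == 7:
        leaf = _balanced_leaf(base)
        return _case(7, "NPQ + Cyt b6f feedback, minimal CEF1", "full",
                     [var("npq_b6f", leaf)])
    if case_id == 8:
        leaf = _balanced_leaf(base, cef_mode="regulatory")
        return _case(8, "NPQ + regulatory CEF1 (k* stays maximal)", "full",
                     [var("npq_cef", leaf)])
    if case_id in (9, 10):
        st = case_id == 10
        variants = [
            var(
                f"k_u2={u:g}",
                base.with_(state_transitions=st),
                k=PhotochemicalConstants(k_u2=u),
            )
            for u in (0.0, 2.0, LAKE_KU2)
        ]
        title = "PS II connectivity sweep" + (
            " with state transitions" if st else ", fixed cross sections"
        )
        return _case(case_id, title, "full", variants)
    if case_id == 11:
        variants = [
            var(
                f"v_b6f={v:g}",
                base.with_(v_max_cb6f=v, state_transitions=True),
                k=PhotochemicalConstants(k_u2=2.0),
            )
            for v in (175.0, 350.0, 700.0)
        ]
        return _case(11, "Cyt b6f over/under-expression, K_U2=2, state transitions",
                     "full", variants)
    if case_id == 12:
        variants = [
            var(
                f"scale={s:g}",
                base.with_(
                    v_max_cb6f=350.0 * s,
                    v_max_rubc=100.0 * s,
                    state_transitions=True,
                ),
                k=PhotochemicalConstants(k_u2=2.0),
            )
            for s in (0.5, 1.0, 2.0)
        ]
        return _case(12, "joint V_max scaling at fixed ratio 3.5", "full", variants)
    raise ValueError(f"unknown case id {case_id!r} (expected 1..12)")


def _case(case_id, description, mode, variants):
    return {
        "case": case_id,
        "description": description,
        "mode": mode,
        "variants": variants,
    }


def simulate_case(case_id: int, q_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Light-response table for one simulation case.

    Columns: variant label, Q, LEF (J_P680), CEF1, total PS I flux, gross
    assimilation, absorbed quantum yield of gross CO2 fixation, K_N2, NPQ,
    open fractions of PS II and PS I, PQ-pool poise fb, k*/k_q, steady-state
    PS II fluorescence yield, net A and the regime label.  Cases 1–4 report
    the *potential* (b6f-limited) response; Cases 5–12 apply the minimum
    rule.
    """
    cfg = case_fixture(case_id)
    q_grid = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    rows = []
    for variant in cfg["variants"]:
        leaf, env, k, n = (
            variant["leaf"], variant["env"], variant["k"], variant["coupling"]
        )
        gamma = co2_compensation(rubisco_specificity(DEFAULT_KINETICS), env.o)
        x = gamma / env.c
        e = eta(n, gamma, env.c)
        if cfg["mode"] == "potential":
            for qv in q_grid:
                _, jp680, jp700 = aj(float(qv), leaf, env, k, n=n)
                a_g = jp680 * (1.0 - x) / (4.0 + 8.0 * x)
                rows.append(
                    {
                        "label": variant["label"],
                        "Q": qv,
                        "LEF": jp680,
                        "CEF1": jp700 - jp680,
                        "J_P700": jp700,
                        "A_g": a_g,
                        "phi_co2": a_g / (qv * leaf.alpha_total) if qv > 0 else np.nan,
                        "cef1_fraction": 1.0 - 1.0 / e,
                    }
                )
        else:
            for qv in q_grid:
                st = solve_steady_state(float(qv), leaf, env, k, n=n)
                levels = fluorescence_levels(
                    st, k, DetectorModel(), (leaf.alpha_1, leaf.alpha_2)
                )
                a_g = st.a + leaf.r_d
                rows.append(
                    {
                        "label": variant["label"],
                        "Q": qv,
                        "LEF": st.j_p680,
                        "CEF1": st.cef1,
                        "J_P700": st.j_p700,
                        "A_g": a_g,
                        "phi_co2": a_g / (qv * leaf.alpha_total) if qv > 0 else np.nan,
                        "K_N2": st.k_n2,
                        "NPQ": levels.f_m / levels.f_m_prime - 1.0,
                        "f_open_psii": 1.0 - st.f2,
                        "f_open_psi": 1.0 - st.f1,
                        "fb": st.fb,
                        "k_star_over_kq": st.k_star_over_kq,
                        "phi_f2": st.psii.big_phi_f2,
                        "A": st.a,
                        "regime": st.regime,
                    }
                )
    return pd.DataFrame(rows)
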
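"""Steady-state solution under the minimum rule A = min(A_j, A_c).

Two regimes exist.  In the *b6f-limited* (light-limited) regime the PQ pool,
the b6f Q_p site and the PS I donor side share one closure fraction
f = Q/(V_max/a + Q), PQH2 is oxidized at the maximum turnover constant
(k* = k_q), and PS I flux follows a rectangular hyperbola of light with
asymptote V_max(CB6F).  In the *Rubisco-limited* (light-saturated) regime the
PS II flux is pinned by Rubisco kinetics and the excess capacity of the light
reactions is absorbed by regulation: NPQ (K_N2) balances PS II excitation,
and either photosynthetic control of b6f (k* < k_q, minimal CEF1) or a
regulatory CEF1 flux (k* = k_q, J_CB6F held at its light-limited value)
controls intersystem transport.

Two regulatory switches select how the split of absorbed light adapts:
``state_transitions`` lets the PS II/PS I cross sections re-balance under
limiting light (with the split frozen at its light-saturation value above),
and ``cef_mode`` chooses minimal versus regulatory CEF1.  ``npq_enabled`` and
``b6f_control`` expose the single-mechanism scenarios used in simulations.

All closures, fluxes and back-solved quantities are closed-form; the NPQ
rate constant is the unique non-negative root of a quadratic in K_N2, which
makes the whole solve vectorizable across light gradients and parameter
populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .light_reactions import (
    DEFAULT_CONSTANTS,
    PhotochemicalConstants,
    PsiYields,
    PsiiYields,
    _phi_p2,
    psi_yields,
    psii_yields,
)
from .stoichiometry import (
    DEFAULT_COUPLING,
    DEFAULT_KINETICS,
    CouplingEfficiencies,
    Environment,
    RubiscoKinetics,
    co2_compensation,
    eta as _eta,
    rubisco_specificity,
)

__all__ = [
    "LeafParameters",
    "SteadyState",
    "DEFAULT_LEAF",
    "aj",
    "ac",
    "solve_npq",
    "solve_cross_sections",
    "light_saturation_point",
    "solve_steady_state",
]

# flag bits in the array path
FLAG_PSII_LIMITED = 1
FLAG_NEVER_SATURATES = 2


@dataclass(frozen=True)
class LeafParameters:
    """Leaf biochemistry driving the steady-state solution.

    ``alpha_total`` is leaf PAR absorbance, split into the PS I and PS II
    cross sections ``alpha_1``/``alpha_2`` (α1 + α2 = α_total enforced; pass
    ``alpha_1=None`` to derive it).  ``v_max_cb6f`` is in µmol e⁻ m⁻² s⁻¹,
    ``v_max_rubc`` in µmol CO2 m⁻² s⁻¹.  Day respiration defaults to
    0.01·V_max(RUBC).  ``g_m`` is mesophyll conductance
    (mol CO2 m⁻² s⁻¹ bar⁻¹), used only on the gas-exchange path.
    """

    alpha_total: float = 0.85
    alpha_2: float = 0.44
    alpha_1: float | None = 0.41
    v_max_cb6f: float = 350.0
    v_max_rubc: float = 100.0
    r_d: float | None = None
    g_m: float = 0.084
    state_transitions: bool = False
    cef_mode: str = "minimal"
    npq_enabled: bool = True
    b6f_control: bool = True

    def __post_init__(self) -> None:
        if self.alpha_1 is None:
            object.__setattr__(self, "alpha_1", self.alpha_total - self.alpha_2)
        if self.r_d is None:
            object.__setattr__(self, "r_d", 0.01 * self.v_max_rubc)
        if abs(self.alpha_1 + self.alpha_2 - self.alpha_total) > 1e-9:
            raise ValueError("alpha_1 + alpha_2 must equal alpha_total")
        if min(self.alpha_1, self.alpha_2) <= 0:
            raise ValueError("cross sections must be positive")
        if self.v_max_cb6f <= 0 or self.v_max_rubc <= 0 or self.g_m <= 0:
            raise ValueError("activities and conductances must be positive")
        if self.cef_mode not in ("minimal", "regulatory"):
            raise ValueError("cef_mode must be 'minimal' or 'regulatory'")

    def with_(self, **kw) -> "LeafParameters":
        """Return a copy with fields replaced (alpha_1/r_d re-derived unless given)."""
        if "alpha_2" in kw and "alpha_1" not in kw:
            kw["alpha_1"] = None
        if "v_max_rubc" in kw and "r_d" not in kw:
            kw["r_d"] = None
        return replace(self, **kw)


DEFAULT_LEAF = LeafParameters()


@dataclass(frozen=True)
class SteadyState:
    """A solved operating point of the coupled system."""

    q: float
    regime: str                  # "b6f_limited" | "rubisco_limited"
    a: float
    a_j: float
    a_c: float
    v_c: float
    v_o: float
    j_p680: float
    j_p700: float
    j_cb6f: float
    cef1: float
    f1: float
    f2: float
    fb: float
    k_star_over_kq: float
    k_n2: float
    alpha_1_eff: float
    alpha_2_eff: float
    eta: float
    gamma_star: float
    psii: PsiiYields
    psi: PsiYields
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# closed-form kernels
# ---------------------------------------------------------------------------

def _kn2_root(target, q, alpha_2, f2, k: PhotochemicalConstants, k_u2):
    """Unique K_N2 >= 0 with Q·α2·Φ_P2(f2, K_N2) = target (may return nan).

    Substituting the sharing-corrected yield and clearing denominators gives
    n² + (b − W/T)·n + (c0 − W(d+u)/T) = 0 with W = Q·α2·(1−f2)·K_P2; the
    larger root is the physical one because Φ_P2 is strictly decreasing in n.
    """
    p, d, u = k.k_p2, k.k_d2 + k.k_f2, k_u2
    w = q * alpha_2 * (1.0 - f2) * p
    b = p + 2.0 * d + u
    c0 = (1.0 - f2) * (p + d) * (d + u) + f2 * d * (p + d + u)
    with np.errstate(divide="ignore", invalid="ignore"):
        bq = b - w / target
        cq = c0 - w * (d + u) / target
        disc = bq * bq - 4.0 * cq
        return 0.5 * (-bq + np.sqrt(disc))


def _f2_self_consistent(q, alpha_2, v_max, eta_value, k: PhotochemicalConstants, k_u2):
    """Closure solving Q·α2·Φ_P2(f, 0) = f·V_max/η (no-NPQ b6f-limited branch)."""
    p, d, u = k.k_p2, k.k_d2 + k.k_f2, k_u2
    big_a = (p + d) * (d + u)
    big_b = d * (p + d + u)
    ell = q * alpha_2 * p * (d + u) * eta_value / v_max
    aq = big_b - big_a          # = -p*u  (<= 0)
    bq = big_a + ell
    with np.errstate(divide="ignore", invalid="ignore"):
        lin = ell / bq          # exact when u == 0
        disc = bq * bq - 4.0 * aq * (-ell)
        quad = (-bq + np.sqrt(disc)) / (2.0 * aq)
    return np.where(np.asarray(k_u2) > 0, quad, lin)


def _f2_at_fixed_target(target, q, alpha_2, k: PhotochemicalConstants, k_u2):
    """Closure solving Q·α2·Φ_P2(f, 0) = target (linear in f)."""
    p, d, u = k.k_p2, k.k_d2 + k.k_f2, k_u2
    big_a = (p + d) * (d + u)
    w = q * alpha_2 * p * (d + u)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (w - target * big_a) / (w - target * p * u)


def _split_ratio(f, eta_value, k: PhotochemicalConstants, k_u2):
    """Balanced cross-section ratio α2/α1 at shared closure f (K_N2 = 0)."""
    return ((1.0 - f) * k.phi_p1_max / eta_value) / _phi_p2(f, 0.0, k, k_u2)


def _balanced_alpha2(f, eta_value, alpha_total, k: PhotochemicalConstants, k_u2):
    r = _split_ratio(f, eta_value, k, k_u2)
    return alpha_total * r / (1.0 + r)


# ---------------------------------------------------------------------------
# vectorized core
# ---------------------------------------------------------------------------

def _solve_arrays(
    q,
    c,
    *,
    o=209.0,
    alpha_total=0.85,
    alpha_1=0.41,
    alpha_2=0.44,
    v_b6f=350.0,
    v_rub=100.0,
    r_d=1.0,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
    k_u2=None,
    kin: RubiscoKinetics = DEFAULT_KINETICS,
    n: CouplingEfficiencies = DEFAULT_COUPLING,
    state_transitions=False,
    npq_enabled=True,
    b6f_control=True,
    regulatory=False,
    st_tol=1e-10,
    st_max_iter=400,
):
    """Broadcasting steady-state solve; returns a dict of arrays.

    All inputs broadcast against each other (e.g. a population of parameter
    vectors against a light/CO2 record grid).  ``k_u2`` overrides the value
    in ``k`` and may be an array.
    """
    q = np.asarray(q, dtype=float)
    c = np.asarray(c, dtype=float)
    u = np.asarray(k.k_u2 if k_u2 is None else k_u2, dtype=float)
    alpha_2 = np.asarray(alpha_2, dtype=float)
    alpha_1 = np.asarray(alpha_1, dtype=float)
    v_b6f = np.asarray(v_b6f, dtype=float)
    v_rub = np.asarray(v_rub, dtype=float)
    r_d = np.asarray(r_d, dtype=float)

    gamma_star = co2_compensation(rubisco_specificity(kin), o)
    x = gamma_star / c
    e = _eta(n, gamma_star, c)
    c1 = k.phi_p1_max

    # Rubisco-limited demand
    vc_m = v_rub * c / (kin.km_c * (1.0 + o / kin.km_o) + c)
    a_c = vc_m * (1.0 - x) - r_d
    jp680_rub = vc_m * (4.0 + 8.0 * x)

    shape = np.broadcast_shapes(
        q.shape, c.shape, u.shape, alpha_2.shape, alpha_1.shape,
        v_b6f.shape, v_rub.shape, np.shape(e),
    )
    flags = np.zeros(shape, dtype=np.int64)

    if state_transitions:
        # light-limited branch: damped fixed point between the closure and
        # the balanced cross-section split (ratio depends on f when K_U2>0)
        a2_lim = np.broadcast_to(
            _balanced_alpha2(0.0, e, alpha_total, k, u), shape
        ).copy()
        f_lim = np.zeros(shape)
        for _ in range(st_max_iter):
            aa = (alpha_total - a2_lim) * c1
            f_lim = q / (v_b6f / aa + q)
            a2_new = _balanced_alpha2(f_lim, e, alpha_total, k, u)
            step = 0.5 * (a2_new - a2_lim)
            a2_lim = a2_lim + step
            if float(np.max(np.abs(step), initial=0.0)) < st_tol:
                break
        a1_lim = alpha_total - a2_lim
        # frozen split at the light-saturation closure f_sat = η·J_rub/V
        f_sat = e * jp680_rub / v_b6f
        never_sat = f_sat >= 1.0
        flags |= np.where(never_sat, FLAG_NEVER_SATURATES, 0)
        f_sat = np.clip(f_sat, 0.0, 1.0 - 1e-12)
        a2_sat = _balanced_alpha2(f_sat, e, alpha_total, k, u)
        a1_sat = alpha_total - a2_sat

        jp680_lim = f_lim * v_b6f / e
        b6f_regime = (jp680_lim <= jp680_rub) | never_sat
        a1_eff = np.where(b6f_regime, a1_lim, a1_sat)
        a2_eff = np.where(b6f_regime, a2_lim, a2_sat)
    else:
        a1_eff = np.broadcast_to(alpha_1, shape).astype(float)
        a2_eff = np.broadcast_to(alpha_2, shape).astype(float)

    # Eq-34 poise with the effective PS I cross section
    a_slope = a1_eff * c1
    f_poise = q / (v_b6f / a_slope + q)
    jp700_pot = f_poise * v_b6f
    jp680_pot = jp700_pot / e

    # ---------------- b6f-limited branch ----------------
    if npq_enabled:
        f2_b = f_poise
        target_b = jp680_pot
        supply0 = q * a2_eff * _phi_p2(f2_b, 0.0, k, u)
        feasible = supply0 >= target_b * (1.0 - 1e-6)
        kn2_b = np.where(
            target_b > 1e-12, _kn2_root(target_b, q, a2_eff, f2_b, k, u), 0.0
        )
        kn2_b = np.where(np.isfinite(kn2_b), kn2_b, 0.0)
        kn2_b = np.maximum(kn2_b, 0.0)
        # infeasible PS II balance: fall back to the self-consistent closure
        f2_fb = np.clip(_f2_self_consistent(q, a2_eff, v_b6f, e, k, u), 0.0, 1.0)
        f2_b = np.where(feasible, f2_b, f2_fb)
        kn2_b = np.where(feasible, kn2_b, 0.0)
        flags |= np.where(~feasible & (q > 0), FLAG_PSII_LIMITED, 0)
    else:
        f2_b = np.clip(_f2_self_consistent(q, a2_eff, v_b6f, e, k, u), 0.0, 1.0)
        kn2_b = np.zeros(shape)
        feasible = np.ones(shape, dtype=bool)
    fb_b = f2_b
    jcb6f_b = fb_b * v_b6f
    jp700_b = jcb6f_b
    jp680_b = jcb6f_b / e
    kstar_b = np.ones(shape)

    # ---------------- Rubisco-limited branch ----------------
    target_r = jp680_rub
    if not npq_enabled:
        f2_r = np.clip(_f2_at_fixed_target(target_r, q, a2_eff, k, u), 0.0, 1.0)
        kn2_r = np.zeros(shape)
        fb_r = f2_r
    elif not b6f_control and not regulatory:
        fb_r = np.clip(e * target_r / v_b6f, 0.0, 1.0)
        f2_r = fb_r
        kn2_r = np.maximum(
            np.nan_to_num(_kn2_root(target_r, q, a2_eff, f2_r, k, u)), 0.0
        )
    else:
        fb_r = f_poise
        f2_r = f_poise
        kn2_r = np.maximum(
            np.nan_to_num(_kn2_root(target_r, q, a2_eff, f2_r, k, u)), 0.0
        )
    if regulatory:
        jcb6f_r = fb_r * v_b6f
        kstar_r = np.ones(shape)
    else:
        jcb6f_r = e * target_r
        with np.errstate(divide="ignore", invalid="ignore"):
            kstar_r = np.where(fb_r > 0, jcb6f_r / (fb_r * v_b6f), 1.0)
    jp700_r = jcb6f_r
    jp680_r = target_r

    # ---------------- regime selection ----------------
    if state_transitions:
        pass  # b6f_regime computed above
    else:
        b6f_regime = jp680_b <= jp680_rub

    j_p680 = np.where(b6f_regime, jp680_b, jp680_r)
    j_p700 = np.where(b6f_regime, jp700_b, jp700_r)
    j_cb6f = np.where(b6f_regime, jcb6f_b, jcb6f_r)
    f2 = np.where(b6f_regime, f2_b, f2_r)
    fb = np.where(b6f_regime, fb_b, fb_r)
    k_n2 = np.where(b6f_regime, kn2_b, kn2_r)
    kstar = np.where(b6f_regime, kstar_b, kstar_r)

    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(q > 0, 1.0 - j_p700 / (q * a1_eff * c1), 0.0)
    f1 = np.clip(f1, 0.0, 1.0)

    v_c = j_p680 / (4.0 * (1.0 + 2.0 * x))
    v_o = 2.0 * x * v_c
    a_j_arr = jp680_b * (1.0 - x) / (4.0 + 8.0 * x) - r_d
    a_net = np.where(b6f_regime, a_j_arr, a_c)

    return {
        "b6f_limited": np.broadcast_to(b6f_regime, shape),
        "a": np.broadcast_to(a_net, shape),
        "a_j": np.broadcast_to(a_j_arr, shape),
        "a_c": np.broadcast_to(a_c, shape),
        "v_c": np.broadcast_to(v_c, shape),
        "v_o": np.broadcast_to(v_o, shape),
        "j_p680": np.broadcast_to(j_p680, shape),
        "j_p700": np.broadcast_to(j_p700, shape),
        "j_cb6f": np.broadcast_to(j_cb6f, shape),
        "cef1": np.broadcast_to(j_p700 - j_p680, shape),
        "f1": np.broadcast_to(f1, shape),
        "f2": np.broadcast_to(f2, shape),
        "fb": np.broadcast_to(fb, shape),
        "k_star_over_kq": np.broadcast_to(kstar, shape),
        "k_n2": np.broadcast_to(k_n2, shape),
        "alpha_1_eff": np.broadcast_to(a1_eff, shape),
        "alpha_2_eff": np.broadcast_to(a2_eff, shape),
        "eta": np.broadcast_to(e, shape),
        "gamma_star": gamma_star,
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def ac(
    leaf: LeafParameters,
    env: Environment | None = None,
    kin: RubiscoKinetics = DEFAULT_KINETICS,
) -> tuple[float, float]:
    """Rubisco-limited net assimilation A_c and the Michaelis carboxylation V_c."""
    env = env or Environment()
    gamma_star = co2_compensation(rubisco_specificity(kin), env.o)
    v_c = leaf.v_max_rubc * env.c / (kin.km_c * (1.0 + env.o / kin.km_o) + env.c)
    return v_c * (1.0 - gamma_star / env.c) - leaf.r_d, v_c


def aj(
    q: float,
    leaf: LeafParameters,
    env: Environment | None = None,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
    kin: RubiscoKinetics = DEFAULT_KINETICS,
    n: CouplingEfficiencies = DEFAULT_COUPLING,
) -> tuple[float, float, float]:
    """b6f-limited net assimilation A_j and the potential fluxes (J'_P680, J'_P700)."""
    env = env or Environment()
    gamma_star = co2_compensation(rubisco_specificity(kin), env.o)
    if env.c <= gamma_star:
        raise ValueError("chloroplast CO2 is at or below the compensation point")
    x = gamma_star / env.c
    e = _eta(n, gamma_star, env.c)
    a_slope = leaf.alpha_1 * k.phi_p1_max
    jp700 = leaf.v_max_cb6f * q / (leaf.v_max_cb6f / a_slope + q)
    jp680 = jp700 / e
    return jp680 * (1.0 - x) / (4.0 + 8.0 * x) - leaf.r_d, jp680, jp700


def solve_npq(
    j_p680_target: float,
    q: float,
    alpha_2: float,
    f2: float,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
) -> tuple[float, bool]:
    """Back-solve the NPQ rate constant K_N2 for a PS II flux target.

    Returns ``(k_n2, psii_limited)``.  When the target exceeds the PS II
    supply at K_N2 = 0 no non-negative root exists; K_N2 = 0 is returned with
    the PS II-limited flag set.
    """
    if j_p680_target <= 1e-12:
        return 0.0, False
    supply0 = q * alpha_2 * _phi_p2(f2, 0.0, k, k.k_u2)
    if supply0 < j_p680_target * (1.0 - 1e-9):
        return 0.0, True
    root = float(_kn2_root(j_p680_target, q, alpha_2, f2, k, k.k_u2))
    if not math.isfinite(root):
        return 0.0, True
    return max(root, 0.0), False


def solve_cross_sections(
    eta_value: float,
    f: float,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
    alpha_total: float = 0.85,
) -> tuple[float, float]:
    """Cross-section split (α1, α2) balancing PS II supply to PS I demand.

    At shared closure ``f`` with K_N2 = 0 the balance Q·α2·Φ_P2 = Q·α1·Φ_P1/η
    fixes α2/α1; the split is independent of ``f`` when K_U2 = 0.
    """
    alpha_2 = float(_balanced_alpha2(f, eta_value, alpha_total, k, k.k_u2))
    return alpha_total - alpha_2, alpha_2


def light_saturation_point(
    leaf: LeafParameters = DEFAULT_LEAF,
    env: Environment | None = None,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
    kin: RubiscoKinetics = DEFAULT_KINETICS,
    n: CouplingEfficiencies = DEFAULT_COUPLING,
) -> float:
    """Light intensity where A_j crosses A_c (closed-form hyperbola inversion).

    Returns ``inf`` when Rubisco capacity exceeds the b6f asymptote (the leaf
    never light-saturates).  Under state transitions the PS I cross section
    at the saturation closure f_sat = η·J_P680(rubisco)/V_max is used.
    """
    env = env or Environment()
    gamma_star = co2_compensation(rubisco_specificity(kin), env.o)
    x = gamma_star / env.c
    e = _eta(n, gamma_star, env.c)
    a_c_val, _ = ac(leaf, env, kin)
    j_req = e * (a_c_val + leaf.r_d) * (4.0 + 8.0 * x) / (1.0 - x)
    if j_req >= leaf.v_max_cb6f:
        return math.inf
    if leaf.state_transitions:
        f_sat = j_req / leaf.v_max_cb6f
        alpha_1, _ = solve_cross_sections(e, f_sat, k, leaf.alpha_total)
    else:
        alpha_1 = leaf.alpha_1
    a_slope = alpha_1 * k.phi_p1_max
    return float(j_req * (leaf.v_max_cb6f / a_slope) / (leaf.v_max_cb6f - j_req))


def solve_steady_state(
    q: float,
    leaf: LeafParameters = DEFAULT_LEAF,
    env: Environment | None = None,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
    kin: RubiscoKinetics = DEFAULT_KINETICS,
    n: CouplingEfficiencies = DEFAULT_COUPLING,
) -> SteadyState:
    """Solve the operating point at light ``q`` and conditions ``env``."""
    env = env or Environment()
    if q < 0:
        raise ValueError("q must be >= 0")
    gamma_star = co2_compensation(rubisco_specificity(kin), env.o)
    if env.c <= gamma_star:
        raise ValueError("chloroplast CO2 is at or below the compensation point")
    res = _solve_arrays(
        q,
        env.c,
        o=env.o,
        alpha_total=leaf.alpha_total,
        alpha_1=leaf.alpha_1,
        alpha_2=leaf.alpha_2,
        v_b6f=leaf.v_max_cb6f,
        v_rub=leaf.v_max_rubc,
        r_d=leaf.r_d,
        k=k,
        kin=kin,
        n=n,
        state_transitions=leaf.state_transitions,
        npq_enabled=leaf.npq_enabled,
        b6f_control=leaf.b6f_control,
        regulatory=leaf.cef_mode == "regulatory",
    )
    g = {key: np.asarray(val).item() for key, val in res.items() if key != "flags"}
    flag_bits = int(np.asarray(res["flags"]).item())
    flags = []
    if flag_bits & FLAG_PSII_LIMITED:
        flags.append("psii_limited")
    if flag_bits & FLAG_NEVER_SATURATES:
        flags.append("never_saturates")
    return SteadyState(
        q=q,
        regime="b6f_limited" if g["b6f_limited"] else "rubisco_limited",
        a=g["a"],
        a_j=g["a_j"],
        a_c=g["a_c"],
        v_c=g["v_c"],
        v_o=g["v_o"],
        j_p680=g["j_p680"],
        j_p700=g["j_p700"],
        j_cb6f=g["j_cb6f"],
        cef1=g["cef1"],
        f1=g["f1"],
        f2=g["f2"],
        fb=g["fb"],
        k_star_over_kq=g["k_star_over_kq"],
        k_n2=g["k_n2"],
        alpha_1_eff=g["alpha_1_eff"],
        alpha_2_eff=g["alpha_2_eff"],
        eta=g["eta"],
        gamma_star=g["gamma_star"],
        psii=psii_yields(min(max(g["f2"], 0.0), 1.0), k, g["k_n2"]),
        psi=psi_yields(min(max(g["f1"], 0.0), 1.0), k),
        flags=tuple(flags),
    )
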
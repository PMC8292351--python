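"""Rate equations for cytochrome b6f, PS I and PS II.

Each photosystem is a two-state bed of photosynthetic units: reaction centers
are either *open* (able to perform photochemistry) or *closed*.  PS II closes
on the acceptor side (reduced Q_A, tracked as the fraction ``f2``), PS I on
the donor side (oxidized P700, fraction ``f1``), and both closures are
consequences of the kinetic bottleneck at cytochrome b6f, whose PQH2 site
occupancy is the fraction ``fb``.

Excitation reaching a unit is partitioned among de-excitation pathways in
proportion to first-order rate constants (ns⁻¹): photochemistry (K_P),
constitutive heat loss (K_D), fluorescence (K_F), regulated heat loss
(K_N2, the pH/zeaxanthin forms of NPQ — a *variable*, passed per call), and
inter-unit exciton sharing within the PS II bed (K_U2).  Sharing is a random
walk, so overall PS II yields are the internal yields amplified by the
geometric series 1/(1 − φ_U2).

Absolute complex concentrations never appear: all rate laws are written in
ratio form, with the b6f maximum activity V_max(CB6F) (µmol e⁻ m⁻² s⁻¹)
carrying the only absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhotochemicalConstants",
    "ClosureState",
    "CytB6F",
    "PsiYields",
    "PsiiYields",
    "DEFAULT_CONSTANTS",
    "psi_yields",
    "psii_yields",
    "cytb6f_flux",
    "potential_psi_rate",
    "closure_at_light",
    "psii_flux",
    "psi_flux",
]


@dataclass(frozen=True)
class PhotochemicalConstants:
    """First-order de-excitation rate constants (ns⁻¹) for PS I and PS II.

    Defaults reproduce fluorescence-lifetime observations in higher plants:
    maximum photochemical yields of 96 % (PS I) and 88 % (PS II), and PS II
    fluorescence yields of 1 % (all open) to 8 % (all closed).  ``k_x1``
    (heat loss at closed PS I centers) is numerically equal to ``k_p1`` so
    that closed PS I centers quench as efficiently as open ones; it defaults
    accordingly.
    """

    k_p1: float = 14.5
    k_d1: float = 0.55
    k_f1: float = 0.05
    k_x1: float = field(default=14.5)
    k_p2: float = 4.5
    k_d2: float = 0.55
    k_f2: float = 0.05
    k_u2: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.k_p1, self.k_d1, self.k_f1, self.k_x1,
                self.k_p2, self.k_d2, self.k_f2, self.k_u2)
        if any(v < 0 for v in vals):
            raise ValueError("rate constants must be non-negative")

    # -- PS I sums -----------------------------------------------------
    @property
    def sigma_p700_open(self) -> float:
        return self.k_p1 + self.k_d1 + self.k_f1

    @property
    def sigma_p700_closed(self) -> float:
        return self.k_x1 + self.k_d1 + self.k_f1

    @property
    def phi_p1_max(self) -> float:
        """Maximum (all-open) PS I photochemical yield."""
        return self.k_p1 / self.sigma_p700_open

    @property
    def phi_p2_max(self) -> float:
        """Maximum PS II photochemical yield, no NPQ and no sharing."""
        return self.k_p2 / (self.k_p2 + self.k_d2 + self.k_f2)


DEFAULT_CONSTANTS = PhotochemicalConstants()


@dataclass(frozen=True)
class ClosureState:
    """Closure fractions: f2 (PS II), fb (b6f PQH2 occupancy), f1 (PS I)."""

    f2: float
    fb: float
    f1: float

    def __post_init__(self) -> None:
        for v in (self.f2, self.fb, self.f1):
            if not 0.0 <= v <= 1.0:
                raise ValueError("closure fractions must lie in [0, 1]")


@dataclass(frozen=True)
class CytB6F:
    """Cytochrome b6f capacity and turnover state.

    ``v_max`` is the maximum activity (µmol e⁻ m⁻² s⁻¹); ``k_q`` the maximum
    and ``k_star`` the current turnover constant of PQH2 oxidation.  Only the
    ratio ``k_star/k_q`` enters the flux law.
    """

    v_max: float = 350.0
    k_q: float = 300.0
    k_star: float = 300.0

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.k_q <= 0:
            raise ValueError("v_max and k_q must be positive")
        if not 0.0 <= self.k_star <= self.k_q:
            raise ValueError("k_star must lie in [0, k_q]")


@dataclass(frozen=True)
class PsiYields:
    """Overall PS I yields (mol dissipated per mol absorbed); sum to 1."""

    phi_p1: float
    phi_x1: float
    phi_d1: float
    phi_f1: float


@dataclass(frozen=True)
class PsiiYields:
    """Internal (unit-level) and overall (bed-level) PS II yields.

    The five internal yields sum to 1; the four overall yields are the
    internal ones divided by (1 − φ_U2) and also sum to 1.
    """

    phi_p2: float
    phi_n2: float
    phi_d2: float
    phi_f2: float
    phi_u2: float
    big_phi_p2: float
    big_phi_n2: float
    big_phi_d2: float
    big_phi_f2: float


# ---------------------------------------------------------------------------
# array kernels (used by the solver and the vectorized inversion path)
# ---------------------------------------------------------------------------

def _psii_internal(f2, k_n2, k: PhotochemicalConstants, k_u2=None):
    """Internal PS II yields (phi_P2, phi_N2, phi_D2, phi_F2, phi_U2)."""
    u = k.k_u2 if k_u2 is None else k_u2
    s_open = k.k_p2 + k_n2 + k.k_d2 + k.k_f2 + u
    s_closed = k_n2 + k.k_d2 + k.k_f2 + u
    w_open = (1.0 - f2) / s_open
    w_closed = f2 / s_closed
    return (
        (1.0 - f2) * k.k_p2 / s_open,
        k_n2 * (w_open + w_closed),
        k.k_d2 * (w_open + w_closed),
        k.k_f2 * (w_open + w_closed),
        u * (w_open + w_closed),
    )


def _phi_p2(f2, k_n2, k: PhotochemicalConstants, k_u2=None):
    """Overall PS II photochemical yield Φ_P2 = φ_P2/(1 − φ_U2)."""
    p, _, _, _, u = _psii_internal(f2, k_n2, k, k_u2)
    return p / (1.0 - u)


def _phi_f2(f2, k_n2, k: PhotochemicalConstants, k_u2=None):
    """Overall PS II fluorescence yield."""
    _, _, _, f, u = _psii_internal(f2, k_n2, k, k_u2)
    return f / (1.0 - u)


def _phi_f1(f1, k: PhotochemicalConstants):
    """Overall PS I fluorescence yield (independent of f1 when K_X1 = K_P1)."""
    return k.k_f1 * ((1.0 - f1) / k.sigma_p700_open + f1 / k.sigma_p700_closed)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def psi_yields(f1: float, k: PhotochemicalConstants = DEFAULT_CONSTANTS) -> PsiYields:
    """Overall PS I yields at closed-center fraction ``f1``."""
    if not 0.0 <= f1 <= 1.0:
        raise ValueError("f1 must lie in [0, 1]")
    so, sc = k.sigma_p700_open, k.sigma_p700_closed
    return PsiYields(
        phi_p1=(1.0 - f1) * k.k_p1 / so,
        phi_x1=f1 * k.k_x1 / sc,
        phi_d1=k.k_d1 * ((1.0 - f1) / so + f1 / sc),
        phi_f1=k.k_f1 * ((1.0 - f1) / so + f1 / sc),
    )


def psii_yields(
    f2: float, k: PhotochemicalConstants = DEFAULT_CONSTANTS, k_n2: float = 0.0
) -> PsiiYields:
    """Internal and overall PS II yields at closure ``f2`` and NPQ ``k_n2``."""
    if not 0.0 <= f2 <= 1.0:
        raise ValueError("f2 must lie in [0, 1]")
    if k_n2 < 0:
        raise ValueError("k_n2 must be non-negative")
    p, n, d, f, u = _psii_internal(f2, k_n2, k)
    if u >= 1.0:
        raise ValueError("exciton-sharing yield phi_U2 must be < 1")
    g = 1.0 / (1.0 - u)
    return PsiiYields(
        phi_p2=p, phi_n2=n, phi_d2=d, phi_f2=f, phi_u2=u,
        big_phi_p2=p * g, big_phi_n2=n * g, big_phi_d2=d * g, big_phi_f2=f * g,
    )


def cytb6f_flux(fb: float, b6f: CytB6F) -> float:
    """Electron flux through b6f: J = fb · V_max · (k*/k_q)."""
    if not 0.0 <= fb <= 1.0:
        raise ValueError("fb must lie in [0, 1]")
    return fb * b6f.v_max * (b6f.k_star / b6f.k_q)


def potential_psi_rate(q, alpha_1: float, k: PhotochemicalConstants, v_max_cb6f: float):
    """Light-limited PS I electron flux (rectangular hyperbola in Q).

    J'_P700 = V_max·Q / (V_max/a + Q) with initial slope
    a = α1·K_P1/ΣK⁰_P700; the asymptote is the b6f maximum activity.
    """
    q = np.asarray(q, dtype=float)
    a = alpha_1 * k.phi_p1_max
    out = v_max_cb6f * q / (v_max_cb6f / a + q)
    return out if out.ndim else float(out)


def closure_at_light(q, alpha_1: float, k: PhotochemicalConstants, v_max_cb6f: float):
    """Shared closure fraction f = Q/(V_max/a + Q) of the b6f-limited poise.

    Identical for PS II closure, b6f PQH2 occupancy and PS I closure when the
    system is b6f-limited; note J'_P700 = f·V_max.
    """
    q = np.asarray(q, dtype=float)
    a = alpha_1 * k.phi_p1_max
    out = q / (v_max_cb6f / a + q)
    return out if out.ndim else float(out)


def psii_flux(
    f2: float, q, alpha_2: float,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS, k_n2: float = 0.0,
):
    """PS II electron flux J_P680 = Q·α2·Φ_P2(f2, K_N2)."""
    if not 0.0 <= f2 <= 1.0:
        raise ValueError("f2 must lie in [0, 1]")
    out = np.asarray(q, dtype=float) * alpha_2 * _phi_p2(f2, k_n2, k)
    return out if out.ndim else float(out)


def psi_flux(f1: float, q, alpha_1: float, k: PhotochemicalConstants = DEFAULT_CONSTANTS):
    """PS I electron flux J_P700 = Q·α1·Φ_P1(f1)."""
    if not 0.0 <= f1 <= 1.0:
        raise ValueError("f1 must lie in [0, 1]")
    out = np.asarray(q, dtype=float) * alpha_1 * (1.0 - f1) * k.phi_p1_max
    return out if out.ndim else float(out)
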
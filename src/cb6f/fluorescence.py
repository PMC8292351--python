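"""Forward operator from a solved steady state to PAM fluorescence.

The signal reaching a PAM detector is a weighted sum of PS II and PS I
fluorescence fluxes,

    F/S = α2·Φ_F2·ε_F2 + α1·Φ_F1·ε_F1,

where ε_F2 and ε_F1 fold together emission spectra, escape ratios and the
detector's spectral response.  The classical convention assumes ε_F1 = 0
(all signal from PS II); a nonzero ε_F1/ε_F2 lets the model quantify the
PS I contamination of every derived index.

The extreme levels use the conventional rate-constant sums: F_m/F_m' with
all centers closed (dark/light-adapted K_N2), F_o/F_o' with all centers
open.  Exciton sharing (K_U2) enters the steady-state yield but is omitted
from the extreme-state sums, matching the convention of the level
definitions (the open/closed extremes are defined per unit, not per bed).

From the five levels every standard PAM index is derived, including the
lake- and puddle-model b6f conductance diagnostics k_Lake = LEF/(1 − qL)
and k_Puddle = LEF/(1 − qP) used to estimate V_max(CB6F) in vivo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .light_reactions import DEFAULT_CONSTANTS, PhotochemicalConstants, _phi_f1, _phi_f2
from .solver import SteadyState

__all__ = [
    "DetectorModel",
    "FluorescenceLevels",
    "PamIndices",
    "fluorescence_levels",
    "pam_indices",
    "estimate_vmax_b6f",
]

#: the experimenter's convention for apparent LEF: half of 0.85 absorbance
ALPHA2_ASSUMED = 0.85 * 0.5


@dataclass(frozen=True)
class DetectorModel:
    """Detector sensitivity and PS II / PS I emission weighting factors."""

    s_det: float = 1.0
    eps_f2: float = 1.0
    eps_f1: float = 0.0

    def __post_init__(self) -> None:
        if self.s_det <= 0:
            raise ValueError("detector sensitivity must be positive")
        if self.eps_f2 < 0 or self.eps_f1 < 0:
            raise ValueError("weighting factors must be non-negative")

    @property
    def eps_ratio(self) -> float:
        return self.eps_f1 / self.eps_f2


@dataclass(frozen=True)
class FluorescenceLevels:
    """Detector-space fluorescence levels (arbitrary but common scale)."""

    f_s: float
    f_m: float
    f_m_prime: float
    f_o: float
    f_o_prime: float


@dataclass(frozen=True)
class PamIndices:
    """Every index an experimenter derives from the five PAM levels.

    ``phi_p2_app`` = 1 − Fs/Fm', ``phi_n2_app`` = Fs·(1/Fm' − 1/Fm) and
    ``phi_df2_app`` = Fs/Fm partition absorbed excitation (they sum to 1);
    ``npq`` = Fm/Fm' − 1; ``qp``/``ql`` are the puddle- and lake-model
    openness indices; ``lef_app`` = Q·α2_assumed·Φ_P2_app; ``k_lake`` and
    ``k_puddle`` extrapolate LEF to a fully reduced PQ pool.  Degenerate
    levels yield ``nan`` entries rather than exceptions.
    """

    phi_p2_app: float
    phi_n2_app: float
    phi_df2_app: float
    npq: float
    qp: float
    ql: float
    lef_app: float
    k_lake: float
    k_puddle: float


# ---------------------------------------------------------------------------
# array kernel shared with the inversion
# ---------------------------------------------------------------------------

def _levels_arrays(
    f2, k_n2, alpha_1, alpha_2, eps_ratio, k: PhotochemicalConstants, k_u2=None,
    f1=None,
):
    """(F_s, F_m', F_o') in units of S·ε_F2 for light-adapted states."""
    u = k.k_u2 if k_u2 is None else k_u2
    if f1 is None:
        f1 = f2
    phi_f1 = _phi_f1(f1, k)
    f_s = alpha_2 * _phi_f2(f2, k_n2, k, u) + alpha_1 * phi_f1 * eps_ratio
    f_mp = (
        alpha_2 * k.k_f2 / (k_n2 + k.k_d2 + k.k_f2)
        + alpha_1 * (k.k_f1 / k.sigma_p700_closed) * eps_ratio
    )
    f_op = (
        alpha_2 * k.k_f2 / (k.k_p2 + k_n2 + k.k_d2 + k.k_f2)
        + alpha_1 * (k.k_f1 / k.sigma_p700_open) * eps_ratio
    )
    return f_s, f_mp, f_op


def _dark_levels_arrays(alpha_1, alpha_2, eps_ratio, k: PhotochemicalConstants):
    """(F_m, F_o) in units of S·ε_F2 for a dark-adapted leaf (K_N2 = 0)."""
    f_m = (
        alpha_2 * k.k_f2 / (k.k_d2 + k.k_f2)
        + alpha_1 * (k.k_f1 / k.sigma_p700_closed) * eps_ratio
    )
    f_o = (
        alpha_2 * k.k_f2 / (k.k_p2 + k.k_d2 + k.k_f2)
        + alpha_1 * (k.k_f1 / k.sigma_p700_open) * eps_ratio
    )
    return f_m, f_o


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fluorescence_levels(
    state: SteadyState,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
    detector: DetectorModel = DetectorModel(),
    alpha_dark: tuple[float, float] | None = None,
) -> FluorescenceLevels:
    """Five PAM levels for a solved state.

    ``alpha_dark`` optionally supplies the dark-adapted (α1, α2) used for
    F_m and F_o — relevant under state transitions, where the light-adapted
    split differs from the dark one; defaults to the state's effective split.
    """
    scale = detector.s_det * detector.eps_f2
    r = detector.eps_ratio
    a1d, a2d = alpha_dark if alpha_dark is not None else (
        state.alpha_1_eff, state.alpha_2_eff
    )
    f_s, f_mp, f_op = _levels_arrays(
        state.f2, state.k_n2, state.alpha_1_eff, state.alpha_2_eff, r, k, k.k_u2,
        f1=state.f1,
    )
    f_m, f_o = _dark_levels_arrays(a1d, a2d, r, k)
    return FluorescenceLevels(
        f_s=float(f_s) * scale,
        f_m=float(f_m) * scale,
        f_m_prime=float(f_mp) * scale,
        f_o=float(f_o) * scale,
        f_o_prime=float(f_op) * scale,
    )


def pam_indices(
    levels: FluorescenceLevels,
    q: float,
    alpha_2_assumed: float = ALPHA2_ASSUMED,
) -> PamIndices:
    """Derive the full index set from measured or modeled levels."""
    fs, fm, fmp, fop = levels.f_s, levels.f_m, levels.f_m_prime, levels.f_o_prime
    phi_p2 = 1.0 - fs / fmp if fmp > 0 else math.nan
    phi_n2 = fs * (1.0 / fmp - 1.0 / fm) if fmp > 0 and fm > 0 else math.nan
    phi_df2 = fs / fm if fm > 0 else math.nan
    npq = fm / fmp - 1.0 if fmp > 0 else math.nan
    if fmp > fop:
        qp = (fmp - fs) / (fmp - fop)
        ql = qp * fop / fs if fs > 0 else math.nan
    else:
        qp = math.nan
        ql = math.nan
    lef = q * alpha_2_assumed * phi_p2
    k_lake = lef / (1.0 - ql) if ql == ql and ql < 1.0 else math.nan
    k_puddle = lef / (1.0 - qp) if qp == qp and qp < 1.0 else math.nan
    return PamIndices(
        phi_p2_app=phi_p2,
        phi_n2_app=phi_n2,
        phi_df2_app=phi_df2,
        npq=npq,
        qp=qp,
        ql=ql,
        lef_app=lef,
        k_lake=k_lake,
        k_puddle=k_puddle,
    )


def estimate_vmax_b6f(
    records: Sequence[PamIndices],
    limiting_light_mask: Iterable[bool] | None = None,
) -> float:
    """Estimate V_max(CB6F) from PAM records under limiting light.

    Each record extrapolates its apparent LEF through the apparent PQ-pool
    reduction 1 − qL to complete reduction (k_Lake); the masked records are
    aggregated robustly with a median.  Valid when b6f turns over at its
    maximum rate, i.e. below light saturation.
    """
    records = list(records)
    if limiting_light_mask is None:
        mask = [True] * len(records)
    else:
        mask = list(limiting_light_mask)
    vals = [
        r.k_lake
        for r, m in zip(records, mask)
        if m and r.k_lake == r.k_lake and r.ql < 1.0
    ]
    if not vals:
        raise ValueError("no usable records under the mask")
    return float(np.median(vals))
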
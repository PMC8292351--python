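"""CO2 diffusion path from cuvette air to the chloroplast stroma.

Two serial resistances separate the measured cuvette CO2 partial pressure
from the one that drives Rubisco: the combined boundary-layer + stomatal
conductance ``g_tc`` (with the standard ternary correction for the
transpiration stream) gives the intercellular partial pressure C_i, and a
lumped mesophyll conductance ``g_m`` gives the chloroplast value
C_c = C_i − A/g_m.  No leaf energy balance is computed; leaf temperature is
a measured input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GasExchangeRecord", "intercellular_co2", "chloroplast_co2"]


@dataclass(frozen=True)
class GasExchangeRecord:
    """One gas-exchange observation in LI-6800-like units.

    ``a`` µmol CO2 m⁻² s⁻¹, ``e_mmol`` mmol H2O m⁻² s⁻¹, ``g_tc`` mol CO2
    m⁻² s⁻¹, ``c_a`` µbar, ``t_leaf`` °C, ``p`` bar.
    """

    a: float
    e_mmol: float
    g_tc: float
    c_a: float
    t_leaf: float = 25.0
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.g_tc <= 0:
            raise ValueError("g_tc must be positive")
        if self.e_mmol < 0:
            raise ValueError("transpiration must be non-negative")


def intercellular_co2(rec: GasExchangeRecord) -> float:
    """Ternary-corrected intercellular CO2: ((g_tc − E/2)·C_a − A)/(g_tc + E/2)."""
    e = rec.e_mmol / 1000.0  # mol m-2 s-1
    if rec.g_tc <= e / 2.0:
        raise ValueError("g_tc must exceed E/2 for a defined C_i")
    return ((rec.g_tc - e / 2.0) * rec.c_a - rec.a) / (rec.g_tc + e / 2.0)


def chloroplast_co2(c_i, a, g_m: float):
    """Chloroplast CO2: C_c = C_i − A/g_m (µbar for A in µmol, g_m per bar)."""
    if g_m <= 0:
        raise ValueError("g_m must be positive")
    out = np.asarray(c_i, dtype=float) - np.asarray(a, dtype=float) / g_m
    return out if out.ndim else float(out)
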
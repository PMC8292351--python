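"""TOML run configuration, validated with pydantic.

Sections mirror the model's parameter tables: ``env`` (driving conditions),
``leaf`` (biochemistry and regulatory switches), ``photochemical_constants``,
``biochemical_constants`` (coupling efficiencies + Rubisco kinetics),
``detector`` and ``ga``.  Unknown keys are rejected with the offending field
path; every default is the reference simulation value.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from .fluorescence import DetectorModel
from .light_reactions import PhotochemicalConstants
from .solver import LeafParameters
from .stoichiometry import CouplingEfficiencies, Environment, RubiscoKinetics

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnvSection(_Strict):
    t_leaf: float = 25.0
    c: float = 200.0
    o: float = 209.0
    p: float = 1.0


class LeafSection(_Strict):
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


class PhotochemSection(_Strict):
    k_p1: float = 14.5
    k_d1: float = 0.55
    k_f1: float = 0.05
    k_x1: float = 14.5
    k_p2: float = 4.5
    k_d2: float = 0.55
    k_f2: float = 0.05
    k_u2: float = 0.0


class BiochemSection(_Strict):
    k_q: float = 300.0
    n_l: float = 0.75
    n_c: float = 1.00
    k_c: float = 3.6
    k_o: float = 0.9
    km_c: float = 260.0
    km_o: float = 179.0


class DetectorSection(_Strict):
    s_det: float = 1.0
    eps_f2: float = 1.0
    eps_f1: float = 0.0


class GASection(_Strict):
    population: int = 200
    generations: int = 300
    seed: int = 0


class RunConfig(_Strict):
    env: EnvSection = EnvSection()
    leaf: LeafSection = LeafSection()
    photochemical_constants: PhotochemSection = PhotochemSection()
    biochemical_constants: BiochemSection = BiochemSection()
    detector: DetectorSection = DetectorSection()
    ga: GASection = GASection()

    # -- adapters to domain objects -----------------------------------
    def environment(self, q: float = 0.0) -> Environment:
        e = self.env
        return Environment(q=q, t_leaf=e.t_leaf, c=e.c, o=e.o, p=e.p)

    def leaf_parameters(self) -> LeafParameters:
        return LeafParameters(**self.leaf.model_dump())

    def photochemistry(self) -> PhotochemicalConstants:
        return PhotochemicalConstants(**self.photochemical_constants.model_dump())

    def rubisco(self) -> RubiscoKinetics:
        b = self.biochemical_constants
        return RubiscoKinetics(k_c=b.k_c, k_o=b.k_o, km_c=b.km_c, km_o=b.km_o)

    def coupling(self) -> CouplingEfficiencies:
        b = self.biochemical_constants
        return CouplingEfficiencies(n_l=b.n_l, n_c=b.n_c)

    def detector_model(self) -> DetectorModel:
        d = self.detector
        return DetectorModel(s_det=d.s_det, eps_f2=d.eps_f2, eps_f1=d.eps_f1)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a TOML config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return RunConfig(**raw)
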
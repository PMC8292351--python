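"""Multiobjective inversion of the model against paired PAM + gas-exchange data.

Six parameters are free: the dark-adapted PS II cross section α2 (with
α1 = α_total − α2), the PS II exciton-sharing rate constant K_U2, the
maximum activities of cytochrome b6f and Rubisco, the mesophyll conductance
g_m, and the PS I/PS II detector weighting ε_F1/ε_F2.  Everything else is
pinned by measurements or literature constants.

Two objectives are minimized simultaneously with an NSGA-II genetic
algorithm: a fluorescence misfit over {F_s, F_m', F_o', dark F_m, dark F_o}
and a gas-exchange misfit over A.  The unknown detector scale S·ε_F2 is
profiled out of the fluorescence objective by a closed-form least-squares
normalization, so the fit is invariant to rescaling all fluorescence
observations by a common factor.  The model is driven at each record's
chloroplast CO2 (derived from the gas-exchange columns through the
candidate's g_m), with state transitions permitted under limiting light and
the pigment distribution held constant under saturating light.

The result is a population of equivalent solutions on a Pareto front,
summarized as per-parameter medians and interquartile ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nsga2 import nsga2
from .data import Dataset
from .fluorescence import DetectorModel, _dark_levels_arrays, _levels_arrays
from .light_reactions import DEFAULT_CONSTANTS, PhotochemicalConstants
from .solver import LeafParameters, _solve_arrays
from .stoichiometry import (
    DEFAULT_COUPLING,
    DEFAULT_KINETICS,
    CouplingEfficiencies,
    RubiscoKinetics,
    co2_compensation,
    rubisco_specificity,
)

__all__ = [
    "FreeParameters",
    "ParetoFront",
    "FitReport",
    "DEFAULT_BOUNDS",
    "PARAM_NAMES",
    "objectives",
    "fit",
    "recovery_test",
    "fit_report",
    "predict",
    "ModelInversion",
]

PARAM_NAMES = ("alpha_2", "k_u2", "v_max_cb6f", "v_max_rubc", "g_m", "eps_ratio")


@dataclass(frozen=True)
class FreeParameters:
    """The six free variables of the inversion."""

    alpha_2: float
    k_u2: float
    v_max_cb6f: float
    v_max_rubc: float
    g_m: float
    eps_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "FreeParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))


def default_bounds(alpha_total: float = 0.85) -> dict[str, tuple[float, float]]:
    return {
        "alpha_2": (0.2 * alpha_total, 0.7 * alpha_total),
        "k_u2": (0.0, 10.0),
        "v_max_cb6f": (50.0, 1000.0),
        "v_max_rubc": (20.0, 300.0),
        "g_m": (0.01, 0.5),
        "eps_ratio": (0.0, 10.0),
    }


DEFAULT_BOUNDS = default_bounds()

_PENALTY = 1e12


@dataclass(frozen=True)
class ParetoFront:
    """Non-dominated population with its objective vectors."""

    params: np.ndarray          # (m, 6)
    objective_values: np.ndarray  # (m, 2)
    names: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self) -> None:
        if len(self.params) == 0:
            raise ValueError("empty Pareto front")

    def summary(self) -> pd.DataFrame:
        """Per-parameter 50th (25th, 75th) percentiles."""
        q = np.percentile(self.params, [50, 25, 75], axis=0)
        return pd.DataFrame(
            {"median": q[0], "q25": q[1], "q75": q[2]}, index=list(self.names)
        )

    def median_params(self) -> FreeParameters:
        return FreeParameters.from_array(np.median(self.params, axis=0))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.params, columns=list(self.names))
        out["loss_fluor"] = self.objective_values[:, 0]
        out["loss_gas"] = self.objective_values[:, 1]
        return out


@dataclass(frozen=True)
class FitReport:
    """Type I regression statistics of modeled on measured, per observable."""

    table: pd.DataFrame  # index: observable; columns r2, rmse, beta0, beta1, n


@dataclass
class _Prepared:
    q: np.ndarray
    c_i: np.ndarray
    a_obs: np.ndarray
    f_s: np.ndarray
    f_mp: np.ndarray
    f_op: np.ndarray
    a_dark: np.ndarray
    f_m: np.ndarray
    f_o: np.ndarray
    o: float
    sigma: dict[str, float] = field(default_factory=dict)


def _sigma(values: np.ndarray, frac: float = 0.02) -> float:
    """Misfit normalizer: ``frac`` of the observable's dynamic range."""
    if values.size == 0:
        return 1.0
    span = float(np.nanmax(values) - np.nanmin(values))
    if span <= 0:
        span = max(float(np.nanmax(np.abs(values))), 1.0)
    return frac * span


def _prepare(dataset: Dataset, ascending: bool, sigma_frac: float) -> _Prepared:
    ds = dataset.ascending() if ascending else dataset
    light = ds.light
    dark = ds.dark
    gl = light[["A", "E_mmol", "g_tc", "C_a"]].to_numpy(dtype=float)
    e_mol = gl[:, 1] / 1000.0
    c_i = ((gl[:, 2] - e_mol / 2.0) * gl[:, 3] - gl[:, 0]) / (gl[:, 2] + e_mol / 2.0)
    prep = _Prepared(
        q=light["Q"].to_numpy(dtype=float),
        c_i=c_i,
        a_obs=gl[:, 0],
        f_s=light["F_s"].to_numpy(dtype=float),
        f_mp=light["F_m_or_Fm_prime"].to_numpy(dtype=float),
        f_op=light["F_o_or_Fo_prime"].to_numpy(dtype=float),
        a_dark=dark["A"].to_numpy(dtype=float),
        f_m=dark["F_m_or_Fm_prime"].to_numpy(dtype=float),
        f_o=dark["F_o_or_Fo_prime"].to_numpy(dtype=float),
        o=float(np.nanmedian(ds.frame["O_mbar"].to_numpy(dtype=float))),
    )
    prep.sigma = {
        "A": _sigma(np.concatenate([prep.a_obs, prep.a_dark]), sigma_frac),
        "F_s": _sigma(prep.f_s, sigma_frac),
        "F_mp": _sigma(prep.f_mp, sigma_frac),
        "F_op": _sigma(prep.f_op, sigma_frac),
        "F_m": _sigma(prep.f_m, sigma_frac),
        "F_o": _sigma(prep.f_o, sigma_frac),
    }
    return prep


def _forward_batch(
    x: np.ndarray,
    prep: _Prepared,
    alpha_total: float,
    k: PhotochemicalConstants,
    kin: RubiscoKinetics,
    coupling: CouplingEfficiencies,
):
    """Modeled observables for a population ``x`` of parameter vectors.

    Returns (a_mod (n,R), fluor dict of modeled arrays, bad mask (n,)).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    a2d = x[:, 0:1]
    k_u2 = x[:, 1:2]
    v_b6f = x[:, 2:3]
    v_rub = x[:, 3:4]
    g_m = x[:, 4:5]
    eps = x[:, 5:6]
    r_d = 0.01 * v_rub

    gamma = co2_compensation(rubisco_specificity(kin), prep.o)
    c_c = prep.c_i[None, :] - prep.a_obs[None, :] / g_m
    bad = np.any(c_c <= gamma * 1.05, axis=1)
    c_c = np.maximum(c_c, gamma * 1.05 + 1e-9)

    res = _solve_arrays(
        prep.q[None, :],
        c_c,
        o=prep.o,
        alpha_total=alpha_total,
        alpha_1=alpha_total - a2d,
        alpha_2=a2d,
        v_b6f=v_b6f,
        v_rub=v_rub,
        r_d=r_d,
        k=k,
        k_u2=k_u2,
        kin=kin,
        n=coupling,
        state_transitions=True,
    )
    f_s, f_mp, f_op = _levels_arrays(
        res["f2"], res["k_n2"], res["alpha_1_eff"], res["alpha_2_eff"],
        eps, k, k_u2, f1=res["f1"],
    )
    f_m, f_o = _dark_levels_arrays(alpha_total - a2d, a2d, eps, k)
    n_dark = len(prep.f_m)
    fluor = {
        "F_s": (f_s, prep.f_s, prep.sigma["F_s"]),
        "F_mp": (f_mp, prep.f_mp, prep.sigma["F_mp"]),
        "F_op": (f_op, prep.f_op, prep.sigma["F_op"]),
        "F_m": (np.repeat(f_m, n_dark, axis=1), prep.f_m, prep.sigma["F_m"]),
        "F_o": (np.repeat(f_o, n_dark, axis=1), prep.f_o, prep.sigma["F_o"]),
    }
    a_mod = res["a"]
    return a_mod, fluor, bad, np.broadcast_to(-r_d, (x.shape[0], n_dark))


def _batch_objectives(
    x: np.ndarray,
    prep: _Prepared,
    alpha_total: float,
    k: PhotochemicalConstants,
    kin: RubiscoKinetics,
    coupling: CouplingEfficiencies,
) -> np.ndarray:
    a_mod, fluor, bad, a_mod_dark = _forward_batch(
        x, prep, alpha_total, k, kin, coupling
    )
    # profile out the detector scale by weighted least squares
    num = 0.0
    den = 0.0
    for m, obs, sig in fluor.values():
        w = 1.0 / sig**2
        num = num + w * np.sum(m * obs[None, :], axis=1)
        den = den + w * np.sum(m * m, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(den > 0, num / den, 0.0)[:, None]
    loss_f = 0.0
    for m, obs, sig in fluor.values():
        loss_f = loss_f + np.sum(((scale * m - obs[None, :]) / sig) ** 2, axis=1)
    loss_g = np.sum(((a_mod - prep.a_obs[None, :]) / prep.sigma["A"]) ** 2, axis=1)
    loss_g = loss_g + np.sum(
        ((a_mod_dark - prep.a_dark[None, :]) / prep.sigma["A"]) ** 2, axis=1
    )
    out = np.stack([loss_f, loss_g], axis=1)
    invalid = bad | ~np.isfinite(out).all(axis=1)
    out[invalid] = _PENALTY
    return out


def objectives(
    params: FreeParameters,
    dataset: Dataset,
    alpha_total: float = 0.85,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
    kin: RubiscoKinetics = DEFAULT_KINETICS,
    coupling: CouplingEfficiencies = DEFAULT_COUPLING,
    ascending: bool = True,
    sigma_frac: float = 0.02,
) -> tuple[float, float]:
    """(fluorescence, gas-exchange) misfit of one parameter vector."""
    prep = _prepare(dataset, ascending, sigma_frac)
    f = _batch_objectives(
        params.as_array()[None, :], prep, alpha_total, k, kin, coupling
    )
    return float(f[0, 0]), float(f[0, 1])


def fit(
    dataset: Dataset,
    bounds: dict[str, tuple[float, float]] | None = None,
    population: int = 200,
    generations: int = 300,
    seed: int = 0,
    alpha_total: float = 0.85,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
    kin: RubiscoKinetics = DEFAULT_KINETICS,
    coupling: CouplingEfficiencies = DEFAULT_COUPLING,
    ascending: bool = True,
    sigma_frac: float = 0.02,
) -> ParetoFront:
    """Run the NSGA-II inversion and return the Pareto front."""
    bounds = bounds or default_bounds(alpha_total)
    b = np.array([bounds[name] for name in PARAM_NAMES], dtype=float)
    prep = _prepare(dataset, ascending, sigma_frac)

    def evaluate(x: np.ndarray) -> np.ndarray:
        return _batch_objectives(x, prep, alpha_total, k, kin, coupling)

    x_front, f_front = nsga2(
        evaluate, b, population=population, generations=generations, seed=seed
    )
    if len(x_front) == 0:
        raise RuntimeError("inversion produced an empty feasible set")
    _, uniq = np.unique(x_front, axis=0, return_index=True)
    uniq = np.sort(uniq)
    return ParetoFront(params=x_front[uniq], objective_values=f_front[uniq])


def predict(
    params: FreeParameters,
    dataset: Dataset,
    alpha_total: float = 0.85,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
    kin: RubiscoKinetics = DEFAULT_KINETICS,
    coupling: CouplingEfficiencies = DEFAULT_COUPLING,
    ascending: bool = True,
    sigma_frac: float = 0.02,
) -> dict[str, pd.DataFrame]:
    """Modeled observables (detector scale fitted) next to the measured ones."""
    prep = _prepare(dataset, ascending, sigma_frac)
    a_mod, fluor, _, a_mod_dark = _forward_batch(
        params.as_array()[None, :], prep, alpha_total, k, kin, coupling
    )
    num = sum(
        np.sum(m * obs[None, :], axis=1) / sig**2 for m, obs, sig in fluor.values()
    )
    den = sum(np.sum(m * m, axis=1) / sig**2 for m, _, sig in fluor.values())
    den_val = float(np.asarray(den).item())
    scale = float(np.asarray(num).item()) / den_val if den_val > 0 else 0.0
    out = {
        "A": pd.DataFrame(
            {"measured": prep.a_obs, "modeled": a_mod[0]},
        ),
        "A_dark": pd.DataFrame(
            {"measured": prep.a_dark, "modeled": a_mod_dark[0]},
        ),
    }
    for name, (m, obs, _) in fluor.items():
        out[name] = pd.DataFrame({"measured": obs, "modeled": scale * m[0]})
    return out


def fit_report(
    front: ParetoFront,
    dataset: Dataset,
    alpha_total: float = 0.85,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
    kin: RubiscoKinetics = DEFAULT_KINETICS,
    coupling: CouplingEfficiencies = DEFAULT_COUPLING,
    ascending: bool = True,
    outlier_masks: dict[str, np.ndarray] | None = None,
) -> FitReport:
    """Type I regressions of the median model against the measurements.

    ``outlier_masks`` maps observable name to a boolean keep-mask, exposing
    the outlier exclusion rule used when summarizing fit quality.
    """
    pred = predict(
        front.median_params(), dataset, alpha_total, k, kin, coupling, ascending
    )
    rows = {}
    for name, frame in pred.items():
        y = frame["modeled"].to_numpy()
        xm = frame["measured"].to_numpy()
        if outlier_masks and name in outlier_masks:
            keep = np.asarray(outlier_masks[name], dtype=bool)
            y, xm = y[keep], xm[keep]
        ok = np.isfinite(y) & np.isfinite(xm)
        y, xm = y[ok], xm[ok]
        if len(y) < 2 or np.ptp(xm) == 0:
            continue
        beta1, beta0 = np.polyfit(xm, y, 1)
        resid = y - xm
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((xm - xm.mean()) ** 2))
        rows[name] = {
            "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
            "rmse": float(np.sqrt(np.mean(resid**2))),
            "beta0": float(beta0),
            "beta1": float(beta1),
            "n": len(y),
        }
    return FitReport(table=pd.DataFrame(rows).T)


def recovery_test(
    true_params: FreeParameters,
    protocol=None,
    noise_level: float = 0.0,
    population: int = 200,
    generations: int = 300,
    seed: int = 0,
    alpha_total: float = 0.85,
    k: PhotochemicalConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Synthetic closed-loop recovery: generate → invert → compare medians.

    Returns per-parameter relative errors (%) of the Pareto-front medians
    against the truth and their maximum.
    """
    from .synthetic import NoiseModel, Protocol, generate_dataset

    protocol = protocol or Protocol()
    leaf = LeafParameters(
        alpha_total=alpha_total,
        alpha_2=true_params.alpha_2,
        alpha_1=None,
        v_max_cb6f=true_params.v_max_cb6f,
        v_max_rubc=true_params.v_max_rubc,
        g_m=true_params.g_m,
        state_transitions=True,
    )
    k_true = PhotochemicalConstants(
        k_p1=k.k_p1, k_d1=k.k_d1, k_f1=k.k_f1, k_x1=k.k_x1,
        k_p2=k.k_p2, k_d2=k.k_d2, k_f2=k.k_f2, k_u2=true_params.k_u2,
    )
    detector = DetectorModel(s_det=1000.0, eps_f2=1.0, eps_f1=true_params.eps_ratio)
    dataset = generate_dataset(
        leaf,
        protocol=protocol,
        noise=NoiseModel(cv_fluor=noise_level, cv_gas=noise_level, seed=seed),
        detector=detector,
        k=k_true,
    )
    front = fit(
        dataset,
        population=population,
        generations=generations,
        seed=seed,
        alpha_total=alpha_total,
        k=k,
    )
    truth = true_params.as_array()
    med = np.median(front.params, axis=0)
    denom = np.where(np.abs(truth) > 0, np.abs(truth), 1.0)
    rel = 100.0 * np.abs(med - truth) / denom
    return {
        "max_rel_error_pct": float(np.max(rel)),
        "per_parameter": dict(zip(PARAM_NAMES, map(float, rel))),
        "medians": dict(zip(PARAM_NAMES, map(float, med))),
        "front": front,
    }


class ModelInversion:
    """Estimator-style wrapper: configure, ``fit`` a dataset, inspect results.

    Fitted attributes (trailing underscore): ``front_`` (ParetoFront),
    ``summary_`` (percentile table), ``best_params_`` (median
    ``FreeParameters``), ``report_`` (FitReport).
    """

    def __init__(
        self,
        population: int = 200,
        generations: int = 300,
        seed: int = 0,
        alpha_total: float = 0.85,
        ascending: bool = True,
        bounds: dict | None = None,
    ):
        self.population = population
        self.generations = generations
        self.seed = seed
        self.alpha_total = alpha_total
        self.ascending = ascending
        self.bounds = bounds

    def get_params(self) -> dict:
        return {
            "population": self.population,
            "generations": self.generations,
            "seed": self.seed,
            "alpha_total": self.alpha_total,
            "ascending": self.ascending,
            "bounds": self.bounds,
        }

    def set_params(self, **kw) -> "ModelInversion":
        for key, val in kw.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(self, dataset: Dataset) -> "ModelInversion":
        self.front_ = fit(
            dataset,
            bounds=self.bounds,
            population=self.population,
            generations=self.generations,
            seed=self.seed,
            alpha_total=self.alpha_total,
            ascending=self.ascending,
        )
        self.summary_ = self.front_.summary()
        self.best_params_ = self.front_.median_params()
        self.report_ = fit_report(
            self.front_, dataset, alpha_total=self.alpha_total,
            ascending=self.ascending,
        )
        return self

    def predict(self, dataset: Dataset) -> dict[str, pd.DataFrame]:
        if not hasattr(self, "front_"):
            raise RuntimeError("call fit() first")
        return predict(
            self.best_params_, dataset, alpha_total=self.alpha_total,
            ascending=self.ascending,
        )
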
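"""Synthetic PAM-fluorometry and gas-exchange tables from known parameters.

The generator emulates the measurement design of the pea dataset: four blue
actinic-light intensities, ambient / low / saturating CO2 levels, seven
replicate leaves, a 70-s pulse train for the damage stage and a temperature
series for the activity fits.  Observables carry multiplicative Gaussian
noise with a configurable coefficient of variation; stomatal conductance
varies leaf-to-leaf.  With the noise CV at zero the tables are exact fixed
points of the estimation pipeline.

Deliberate idealizations (see docs/methods.md): saturating-CO2 assimilation
rows encode the infinite-Cc calibration relation ``Ahv = J/4`` exactly, and
all parameterization rows are generated at activity factors of 1, so that
the fitted Jmax and Vcmax are reference-condition values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import steady_state
from .errors import ParameterError
from .estimate import PipelineResult
from .kernels import electron_flow_potential
from .params import KineticParameters, TemperatureResponse

__all__ = [
    "SyntheticSpec",
    "generate_pam_table",
    "generate_gas_exchange_table",
    "generate_temperature_activity_table",
    "recovery_report",
    "RECOVERY_TOLERANCES",
]

#: Documented recovery tolerances under the default 2% noise design:
#: (tolerance, "relative" | "absolute").
RECOVERY_TOLERANCES = {
    "Jmax": (0.05, "relative"),
    "theta": (0.05, "relative"),
    "Vcmax": (0.10, "relative"),
    "kd0": (0.10, "relative"),
    "alpha": (0.20, "relative"),
    "t_opt_rubisco": (2.0, "absolute"),
    "t_opt_etc": (2.0, "absolute"),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth plus measurement design of a synthetic experiment."""

    params: KineticParameters = field(default_factory=KineticParameters)
    tr_c: TemperatureResponse = field(default_factory=TemperatureResponse.rubisco_default)
    tr_j: TemperatureResponse = field(default_factory=TemperatureResponse.etc_default)
    light_levels: Sequence[float] = (108.0, 239.0, 425.0, 758.0)
    co2_levels: Sequence[float] = (100.0, 360.0, 2000.0)
    temperatures: Sequence[float] = (10.0, 15.0, 23.0, 30.0, 37.0, 41.0, 42.0)
    replicates: int = 7
    noise_cv: float = 0.02
    gs_spread: float = 0.06
    pulse_duration: float = 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")

    @property
    def meas_co2(self) -> float:
        """The ambient measurement CO2: the level closest to the model's Co."""
        levels = np.asarray(self.co2_levels, dtype=float)
        return float(levels[np.argmin(np.abs(levels - self.params.Co))])

    @property
    def ref_co2(self) -> float:
        """The saturating (calibration) CO2 level."""
        return float(max(self.co2_levels))

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one output stream, derived from the seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _replicate_gs(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-leaf stomatal conductance; exact at zero noise."""
    if spec.noise_cv == 0:
        return np.full(spec.replicates, spec.params.gs)
    gs = rng.normal(spec.params.gs, spec.gs_spread, size=spec.replicates)
    return np.clip(gs, 0.02, None)


def _noisy(rng: np.random.Generator, value: float, cv: float) -> float:
    return float(value) * (1.0 + cv * rng.standard_normal()) if cv > 0 else float(value)


def generate_pam_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Dual-PAM-style table: yield rows plus damage pulse trains.

    Yield rows (block == "yield"): PSII/PSI quantum yields per light level at
    the ambient and saturating CO2, with Y(II) consistent with the truth
    light response (``Y(II) = J/(beta'*PAR)``) and Y(I) = Y(II) so that the
    PSII fraction equals the 0.5 reference.  Pulse rows (block == "pulse"):
    dark-relaxed qN before each of the 70-s pulses of increasing intensity,
    the increment over pulse i being the photodamage accrued at that light
    (one forward step of the damage law per pulse), plus a closing row after
    the last pulse.
    """
    p = spec.params
    rng = spec.rng(1)
    gs_leaf = _replicate_gs(spec, spec.rng(0))
    rows = []

    for co2 in (spec.meas_co2, spec.ref_co2):
        for par in spec.light_levels:
            j_true = electron_flow_potential(par, p)
            y_true = j_true / (p.beta_prime * par)
            for rep in range(spec.replicates):
                y_ii = np.clip(_noisy(rng, y_true, spec.noise_cv), 1e-6, 1.0)
                y_i = np.clip(_noisy(rng, y_true, spec.noise_cv), 1e-6, 1.0)
                rows.append({
                    "block": "yield", "par": par, "co2": co2, "replicate": rep,
                    "y_i": y_i, "y_ii": y_ii, "qn": 0.0,
                    "pulse_index": 0, "pulse_duration_s": 0.0,
                })

    for rep in range(spec.replicates):
        p_rep = p.replace(gs=gs_leaf[rep])
        aj = 1.0
        for i, par in enumerate(spec.light_levels):
            j_true = electron_flow_potential(par, p)
            y_true = np.clip(j_true / (p.beta_prime * par), 1e-6, 1.0)
            rows.append({
                "block": "pulse", "par": par, "co2": spec.meas_co2,
                "replicate": rep, "y_i": y_true, "y_ii": y_true,
                "qn": min(1.0 - aj, 0.99),
                "pulse_index": i, "pulse_duration_s": spec.pulse_duration,
            })
            st = steady_state(par, p_rep, aj=aj, co2=spec.meas_co2)
            kd = p.kd0 * (p.alpha * st.rates.Wj + (st.rates.Wj - st.rates.W))
            dq = _noisy(rng, kd * aj * spec.pulse_duration, spec.noise_cv)
            aj = float(np.clip(aj - dq, 0.01, 1.0))
        last = spec.light_levels[-1]
        rows.append({
            "block": "pulse", "par": last, "co2": spec.meas_co2, "replicate": rep,
            "y_i": 0.5, "y_ii": 0.5, "qn": min(1.0 - aj, 0.99),
            "pulse_index": len(spec.light_levels),
            "pulse_duration_s": spec.pulse_duration,
        })
    return pd.DataFrame(rows)


def generate_gas_exchange_table(spec: SyntheticSpec) -> pd.DataFrame:
    """GFS-3000-style table: net assimilation and CO2 diffusion per condition.

    Ambient and low-CO2 rows come from the forward model's quasi-steady
    state at the truth parameters (per-leaf stomatal conductance); the
    saturating-CO2 rows report the calibration relation ``Ahv = J/4``.
    """
    p = spec.params
    rng = spec.rng(2)
    gs_leaf = _replicate_gs(spec, spec.rng(0))
    rows = []
    for co2 in spec.co2_levels:
        for par in spec.light_levels:
            for rep in range(spec.replicates):
                p_rep = p.replace(gs=gs_leaf[rep])
                st = steady_state(par, p_rep, co2=co2)
                if co2 == spec.ref_co2:
                    a_hv = electron_flow_potential(par, p) / 4.0
                else:
                    a_hv = st.rates.A_hv
                rows.append({
                    "par": par, "co2": co2, "replicate": rep,
                    "a_hv": _noisy(rng, a_hv, spec.noise_cv),
                    "ci": st.Ci, "gs": gs_leaf[rep], "rd": p.Rd,
                    "temperature": 23.0,
                })
    return pd.DataFrame(rows)


def generate_temperature_activity_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Normalized temperature-activity observations for both processes.

    Emits the asymmetric-Gaussian activities of Rubisco and of the ETC at
    the design temperatures with multiplicative noise — the normalized form
    in which temperature series are fitted.
    """
    from .kernels import temperature_activity

    rng = spec.rng(3)
    rows = []
    for process, tr in (("rubisco", spec.tr_c), ("etc", spec.tr_j)):
        for t in spec.temperatures:
            act = temperature_activity(t, tr)
            for rep in range(spec.replicates):
                rows.append({
                    "process": process, "temperature": t, "replicate": rep,
                    "activity": max(_noisy(rng, act, spec.noise_cv), 1e-9),
                })
    return pd.DataFrame(rows)


def recovery_report(spec: SyntheticSpec, result: Optional[PipelineResult]) -> pd.DataFrame:
    """Truth vs. estimate per parameter, with documented-tolerance flags.

    Parameters without a completed fit are reported with a missing estimate;
    parameters without a documented tolerance carry a null ``passed`` flag.
    """
    p = spec.params
    truth = {
        "beta_prime": p.beta_prime, "Jmax": p.Jmax, "theta": p.theta,
        "Vcmax": p.Vcmax, "gd": p.gd, "dg_max": p.dg_max,
        "hill_n": p.hill_n, "hill_K": p.hill_K,
        "kd0": p.kd0, "alpha": p.alpha,
        "t_opt_rubisco": spec.tr_c.t_opt, "sigma_rubisco": spec.tr_c.sigma_lo,
        "t_opt_etc": spec.tr_j.t_opt,
        "sigma_lo_etc": spec.tr_j.sigma_lo, "sigma_hi_etc": spec.tr_j.sigma_hi,
    }
    est: dict = {}
    if result is not None:
        fits = result.fits
        est["beta_prime"] = result.beta
        for stage, keys in (
            ("light_response", {"Jmax": "Jmax", "theta": "theta"}),
            ("vcmax", {"Vcmax": "Vcmax"}),
            ("gm_light_response", {"gd": "gd", "dg_max": "dg_max",
                                   "hill_n": "hill_n", "hill_K": "hill_K"}),
            ("damage", {"kd0": "kd0", "alpha": "alpha"}),
            ("temperature_rubisco", {"t_opt_rubisco": "t_opt",
                                     "sigma_rubisco": "sigma_lo"}),
            ("temperature_etc", {"t_opt_etc": "t_opt", "sigma_lo_etc": "sigma_lo",
                                 "sigma_hi_etc": "sigma_hi"}),
        ):
            if stage in fits:
                for name, key in keys.items():
                    est[name] = fits[stage].estimates[key]

    rows = []
    for name, tv in truth.items():
        ev = est.get(name)
        tol_kind = RECOVERY_TOLERANCES.get(name)
        if ev is None:
            rows.append({"parameter": name, "truth": tv, "estimate": np.nan,
                         "error": np.nan, "tolerance": np.nan, "kind": None,
                         "passed": None})
            continue
        if tol_kind is not None and tol_kind[1] == "absolute":
            err = abs(ev - tv)
        else:
            err = abs(ev - tv) / abs(tv)
        row = {"parameter": name, "truth": tv, "estimate": ev, "error": err}
        if tol_kind is None:
            row.update({"tolerance": np.nan, "kind": None, "passed": None})
        else:
            row.update({"tolerance": tol_kind[0], "kind": tol_kind[1],
                        "passed": bool(err <= tol_kind[0])})
        rows.append(row)
    return pd.DataFrame(rows)
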
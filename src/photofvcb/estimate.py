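"""Parameter estimation from PAM fluorometry and gas-exchange measurements.

The pipeline mirrors the staged field protocol:

1. the absorbed-light coefficient ``beta`` from saturating-CO2 gas exchange
   and PSII yields, and the reference PSII fraction ``dII`` from the two
   photosystem yields;
2. linear electron flow ``J`` per light level from PSII yields, then the
   light-response parameters (Jmax, theta);
3. chloroplast CO2 by inverting the ETC-limited assimilation at the
   reference light, mesophyll conductance gm, Vcmax from a low-CO2
   (Rubisco-limited) point, then the Hill-type gm light response;
4. damage rate constants from dark-relaxed non-photochemical quenching of
   successive light pulses, fitted to the photodamage rate law (kd0, alpha);
5. asymmetric-Gaussian temperature responses of each process.

All nonlinear fits are bounded least squares with a deterministic
multi-start grid.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dynamics import steady_state
from .errors import DomainError, FitError
from .kernels import electron_flow_potential, mesophyll_conductance, temperature_activity
from .params import KineticParameters, TemperatureResponse

__all__ = [
    "PAMRecord",
    "GasExchangeRecord",
    "FitResult",
    "beta_from_saturating_co2",
    "psii_fraction",
    "electron_flow_from_pam",
    "electron_flow_from_yields",
    "cc_from_electron_transport",
    "cc_from_rubisco",
    "gm_from_gas_exchange",
    "cc_from_ci",
    "cc_from_gas_exchange",
    "vcmax_from_point",
    "fit_light_response",
    "fit_gm_light_response",
    "damage_rates_from_qn",
    "fit_damage_constants",
    "fit_temperature_response",
    "run_pipeline",
    "PipelineResult",
]


@dataclass(frozen=True)
class PAMRecord:
    """One PAM-fluorometry observation (yields and quenching per pulse)."""

    par: float
    y_i: float
    y_ii: float
    qn: float = 0.0
    pulse_index: int = 0
    pulse_duration: float = 70.0
    co2: float = 360.0
    replicate: int = 0

    def __post_init__(self) -> None:
        for name in ("y_i", "y_ii", "qn"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class GasExchangeRecord:
    """One gas-exchange observation (net assimilation and CO2 diffusion)."""

    par: float
    co2: float
    a_hv: float
    ci: float
    gs: float
    rd: float
    temperature: float = 23.0
    replicate: int = 0

    def __post_init__(self) -> None:
        if not self.gs > 0:
            raise DomainError("gs must be > 0")
        if self.a_hv > 0 and self.ci > self.co2:
            raise DomainError("Ci must not exceed ambient CO2 at positive assimilation")


@dataclass
class FitResult:
    """Estimates plus goodness of fit of one least-squares stage."""

    estimates: dict
    r_squared: float
    residuals: np.ndarray
    warnings: list = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.estimates[key]


def _r_squared(obs: np.ndarray, residuals: np.ndarray) -> float:
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum(residuals**2)) / ss_tot


def _multistart(residual_fn, starts, lower, upper):
    """Bounded least squares from a deterministic grid of starts; best cost wins."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lower + 1e-12, upper - 1e-12)
        try:
            res = least_squares(
                residual_fn, x0, bounds=(lower, upper),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("all least-squares starts failed")
    return best


# ---------------------------------------------------------------------------
# algebraic estimators
# ---------------------------------------------------------------------------

def beta_from_saturating_co2(a_hv, par, y_ii):
    """Absorbed-light coefficient ``beta = 4*Ahv / (PAR*Y(II))``.

    Valid at saturating CO2, where every transported electron is consumed by
    carboxylation and photorespiration vanishes (Cc -> infinity limit).
    """
    par = np.asarray(par, dtype=float)
    y_ii = np.asarray(y_ii, dtype=float)
    if np.any(par * y_ii <= 0):
        raise DomainError("PAR * Y(II) must be > 0")
    beta = 4.0 * np.asarray(a_hv, dtype=float) / (par * y_ii)
    return beta if beta.ndim else float(beta)


def psii_fraction(y_i, y_ii):
    """Fraction of absorbed light directed to PSII: ``1 / (Y(II)/Y(I) + 1)``."""
    y_i = np.asarray(y_i, dtype=float)
    if np.any(y_i <= 0):
        raise DomainError("Y(I) must be > 0")
    d = 1.0 / (np.asarray(y_ii, dtype=float) / y_i + 1.0)
    return d if d.ndim else float(d)


def electron_flow_from_yields(par, y_ii, y_i, beta, dii_ref: Optional[float] = None):
    """Linear electron flow ``J = beta * (dII'/dII_ref) * PAR * Y(II)``.

    ``dII'`` is the PSII fraction of this observation; without a reference
    fraction the ratio defaults to 1 (with a warning).
    """
    dii = psii_fraction(y_i, y_ii)
    if dii_ref is None:
        _warnings.warn("no reference PSII fraction given; using dII'/dII_ref = 1")
        ratio = 1.0
    else:
        if dii_ref <= 0:
            raise DomainError("dII_ref must be > 0")
        ratio = np.asarray(dii, dtype=float) / dii_ref
    j = beta * ratio * np.asarray(par, dtype=float) * np.asarray(y_ii, dtype=float)
    return j if np.ndim(j) else float(j)


def electron_flow_from_pam(record: PAMRecord, beta: float, dii_ref: Optional[float] = None):
    """Electron flow of one PAM record (see :func:`electron_flow_from_yields`)."""
    return electron_flow_from_yields(record.par, record.y_ii, record.y_i, beta, dii_ref)


def cc_from_electron_transport(a_hv, j, gamma_star: float = 38.6):
    """Chloroplast CO2 from an ETC-limited gas-exchange point.

    Inverts ``Ahv = [J/(4 + 8*Gamma_star/Cc)] * (Cc - Gamma_star)/Cc`` to
    ``Cc = Gamma_star * (8*Ahv + J) / (J - 4*Ahv)``; requires ``J > 4*Ahv``.
    """
    a_hv = np.asarray(a_hv, dtype=float)
    j = np.asarray(j, dtype=float)
    if np.any(j - 4.0 * a_hv <= 0):
        raise DomainError("ETC-limited inversion needs J > 4*Ahv")
    cc = gamma_star * (8.0 * a_hv + j) / (j - 4.0 * a_hv)
    return cc if cc.ndim else float(cc)


def cc_from_rubisco(a_hv, vcmax, p: KineticParameters):
    """Chloroplast CO2 from a Rubisco-limited point: inverse of the Wc branch."""
    a_hv = np.asarray(a_hv, dtype=float)
    if np.any(vcmax - a_hv <= 0):
        raise DomainError("Rubisco-limited inversion needs Ahv < Vcmax")
    cc = (a_hv * p.kc_eff + vcmax * p.Gamma_star) / (vcmax - a_hv)
    return cc if cc.ndim else float(cc)


def gm_from_gas_exchange(rec, cc):
    """Mesophyll conductance ``gm = (Ahv - Rd) / (Ci - Cc)``.

    A negative result (CO2 apparently flowing against its gradient) is
    returned as-is with a validity warning.
    """
    ci = np.asarray(rec.ci, dtype=float)
    cc = np.asarray(cc, dtype=float)
    if np.any(ci == cc):
        raise DomainError("Ci = Cc leaves gm undefined")
    gm = (np.asarray(rec.a_hv, dtype=float) - np.asarray(rec.rd, dtype=float)) / (ci - cc)
    if np.any(gm < 0):
        _warnings.warn("negative mesophyll conductance: check Cc estimate")
    return gm if gm.ndim else float(gm)


def cc_from_ci(rec, gm):
    """Chloroplast CO2 ``Cc = Ci - Ahv/gm``.

    Neglects respiration: exact inverse of :func:`gm_from_gas_exchange` only
    at Rd = 0 (see :func:`cc_from_gas_exchange` for the Rd-corrected form).
    """
    gm = np.asarray(gm, dtype=float)
    if np.any(gm <= 0):
        raise DomainError("gm must be > 0")
    cc = np.asarray(rec.ci, dtype=float) - np.asarray(rec.a_hv, dtype=float) / gm
    return cc if cc.ndim else float(cc)


def cc_from_gas_exchange(rec, gm):
    """Chloroplast CO2 ``Cc = Ci - (Ahv - Rd)/gm`` (inverse of the gm estimator)."""
    gm = np.asarray(gm, dtype=float)
    if np.any(gm <= 0):
        raise DomainError("gm must be > 0")
    cc = (
        np.asarray(rec.ci, dtype=float)
        - (np.asarray(rec.a_hv, dtype=float) - np.asarray(rec.rd, dtype=float)) / gm
    )
    return cc if cc.ndim else float(cc)


def vcmax_from_point(a_hv, cc, p: KineticParameters):
    """Vcmax from a Rubisco-limited point: ``Ahv*(Cc + Kc*(1+O/Ko))/(Cc - Gamma_star)``."""
    cc = np.asarray(cc, dtype=float)
    if np.any(cc <= p.Gamma_star):
        raise DomainError("Rubisco-limited inversion needs Cc > Gamma_star")
    v = np.asarray(a_hv, dtype=float) * (cc + p.kc_eff) / (cc - p.Gamma_star)
    return v if v.ndim else float(v)


# ---------------------------------------------------------------------------
# least-squares fits
# ---------------------------------------------------------------------------

def fit_light_response(pars, js, beta_prime: float) -> FitResult:
    """Fit (Jmax, theta) of the non-rectangular hyperbola to J(PAR) data."""
    pars = np.asarray(pars, dtype=float)
    js = np.asarray(js, dtype=float)
    if len(np.unique(pars)) < 3:
        raise FitError("light-response fit needs >= 3 distinct light levels")

    def resid(x):
        p = KineticParameters(Jmax=x[0], theta=min(x[1], 1.0), beta_prime=beta_prime)
        return electron_flow_potential(pars, p) - js

    m = max(float(js.max()), 1e-6)
    starts = [(1.2 * m, 0.5), (1.5 * m, 0.25), (3.0 * m, 0.75),
              (1.05 * m, 0.9), (2.0 * m, 0.1)]
    best = _multistart(resid, starts, lower=(1e-6, 1e-6), upper=(1000.0, 1.0))
    est = {"Jmax": float(best.x[0]), "theta": float(best.x[1])}
    return FitResult(est, _r_squared(js, best.fun), best.fun)


def fit_gm_light_response(pars, gms, fixed: Optional[dict] = None) -> FitResult:
    """Fit the Hill-type gm light response (gd, dg_max, hill_n, hill_K).

    Parameters listed in ``fixed`` are held at the given values.  A flat
    input yields dg_max = 0 with a degeneracy warning instead of a fit.
    """
    pars = np.asarray(pars, dtype=float)
    gms = np.asarray(gms, dtype=float)
    fixed = dict(fixed or {})
    names = [n for n in ("gd", "dg_max", "hill_n", "hill_K") if n not in fixed]
    if len(np.unique(pars)) < len(names):
        raise FitError(
            f"gm fit with {len(names)} free parameters needs >= {len(names)} "
            "distinct light levels"
        )
    if np.ptp(gms) == 0.0:
        est = dict(fixed)
        est.setdefault("gd", float(gms.mean()))
        est.setdefault("dg_max", 0.0)
        est.setdefault("hill_n", 2.0)
        est.setdefault("hill_K", 1000.0)
        resid = np.full_like(gms, 0.0)
        return FitResult(est, float("nan"), resid,
                         warnings=["flat gm input: light response unidentifiable"])

    bounds = {"gd": (1e-6, 1.0), "dg_max": (1e-6, 5.0),
              "hill_n": (1.0, 4.0), "hill_K": (1.0, 1e5)}
    defaults = {"gd": float(gms.min()), "dg_max": float(max(np.ptp(gms), 1e-3)),
                "hill_n": 2.0, "hill_K": float(np.median(pars))}

    def resid(x):
        kw = dict(fixed)
        kw.update(zip(names, x))
        p = KineticParameters(gd=kw["gd"], dg_max=kw["dg_max"],
                              hill_n=kw["hill_n"], hill_K=kw["hill_K"])
        return mesophyll_conductance(pars, p) - gms

    k_grid = [defaults["hill_K"], 2 * defaults["hill_K"], 5 * defaults["hill_K"],
              0.5 * defaults["hill_K"], 1000.0]
    starts = []
    for i, k0 in enumerate(k_grid):
        s = dict(defaults)
        s["hill_K"] = k0
        s["hill_n"] = [2.0, 1.5, 3.0, 2.0, 2.0][i]
        starts.append([s[n] for n in names])
    best = _multistart(
        resid, starts,
        lower=[bounds[n][0] for n in names],
        upper=[bounds[n][1] for n in names],
    )
    est = dict(fixed)
    est.update({n: float(v) for n, v in zip(names, best.x)})
    return FitResult(est, _r_squared(gms, best.fun), best.fun)


def damage_rates_from_qn(records: Iterable) -> pd.DataFrame:
    """Per-interval damage rates from a pulse train of dark-relaxed qN values.

    For successive pulses i and i+1 (ordered by ``pulse_index``):
    ``Vd_i = (qN_{i+1} - qN_i) / dt`` and ``kd_i = Vd_i / (1 - qN_i)``,
    with ``dt`` the duration of pulse i and ``1 - qN_i`` the undamaged
    fraction at the interval start.  Negative rates (qN decreasing) are
    passed through with a warning; they are excluded from fitting by default.
    """
    rows = list(records)
    if len(rows) < 2:
        raise DomainError("damage-rate estimation needs at least two pulses")
    rows.sort(key=lambda r: r.pulse_index)
    out = []
    for a, b in zip(rows[:-1], rows[1:]):
        if a.qn >= 1.0:
            raise DomainError("qN = 1 leaves the damage rate undefined")
        if not a.pulse_duration > 0:
            raise DomainError("pulse duration must be > 0")
        vd = (b.qn - a.qn) / a.pulse_duration
        kd = vd / (1.0 - a.qn)
        out.append({"par": a.par, "pulse_index": a.pulse_index,
                    "vd": vd, "kd": kd, "aj": 1.0 - a.qn})
    df = pd.DataFrame(out)
    if (df["kd"] < 0).any():
        _warnings.warn("negative per-interval damage rates (qN decreased)")
    return df


def fit_damage_constants(
    kds,
    pars,
    p: KineticParameters,
    tr_c: Optional[TemperatureResponse] = None,
    tr_j: Optional[TemperatureResponse] = None,
    temperature: Optional[float] = None,
    ajs=None,
    gss=None,
    include_negative: bool = False,
) -> FitResult:
    """Fit (kd0, alpha) of the damage law to observed rate constants.

    For each observation the model rates Wj and W are computed at the quasi-
    steady state for that light level (undamaged fraction ``ajs``, default 1;
    per-observation stomatal conductance ``gss`` when the leaves differ;
    activities from ``temperature`` via the temperature responses, or 1 when
    no temperature is given), then ``kd = kd0*(alpha*Wj + Wj - W)`` is fitted
    by bounded least squares.
    """
    kds = np.asarray(kds, dtype=float)
    pars = np.asarray(pars, dtype=float)
    ajs = np.ones_like(pars) if ajs is None else np.asarray(ajs, dtype=float)
    gss = np.full_like(pars, p.gs) if gss is None else np.asarray(gss, dtype=float)
    if len(np.unique(pars)) < 2:
        raise FitError("damage fit needs >= 2 light levels")
    if not include_negative:
        keep = kds >= 0
        kds, pars, ajs, gss = kds[keep], pars[keep], ajs[keep], gss[keep]
        if len(np.unique(pars)) < 2:
            raise FitError("damage fit needs >= 2 light levels with kd >= 0")

    wj = np.empty_like(pars)
    w = np.empty_like(pars)
    for i, (par, aj, gs) in enumerate(zip(pars, ajs, gss)):
        st = steady_state(par, p.replace(gs=gs), tr_c=tr_c, tr_j=tr_j,
                          temperature=temperature, aj=aj)
        wj[i], w[i] = st.rates.Wj, st.rates.W

    warn = []
    excess = wj - w
    if np.max(excess) <= 1e-9 * max(np.max(wj), 1e-12):
        warn.append(
            "Wj = W at every light level: alpha and kd0 are only jointly "
            "identifiable (their product is constrained)"
        )

    def resid(x):
        kd0, alpha = x
        return kd0 * (alpha * wj + excess) - kds

    starts = [(8e-5, 0.1), (1e-4, 0.5), (1e-5, 0.05), (1e-3, 0.2), (1e-6, 0.9)]
    best = _multistart(resid, starts, lower=(1e-12, 1e-9), upper=(1.0, 1.0))
    est = {"kd0": float(best.x[0]), "alpha": float(best.x[1])}
    return FitResult(est, _r_squared(kds, best.fun), best.fun, warnings=warn)


def fit_temperature_response(temps, activities, symmetric: bool = False) -> FitResult:
    """Fit the asymmetric-Gaussian temperature response (t_opt, sigma_lo, sigma_hi).

    ``symmetric=True`` constrains the two e-folding widths to be equal.
    Activities are expected on the normalized (max = 1) scale.
    """
    temps = np.asarray(temps, dtype=float)
    acts = np.asarray(activities, dtype=float)
    nfree = 2 if symmetric else 3
    if len(np.unique(temps)) < max(3, nfree):
        raise FitError("temperature-response fit needs >= 3 distinct temperatures")

    def resid(x):
        if symmetric:
            tr = TemperatureResponse(x[0], x[1], x[1])
        else:
            tr = TemperatureResponse(x[0], x[1], x[2])
        return temperature_activity(temps, tr) - acts

    tmin, tmax = float(temps.min()), float(temps.max())
    span = max(tmax - tmin, 1.0)
    t_center = float(temps[np.argmax(acts)])
    t_starts = [t_center, tmin + 0.25 * span, tmin + 0.5 * span,
                tmin + 0.75 * span, t_center + 5.0]
    if symmetric:
        starts = [(t0, s0) for t0, s0 in zip(t_starts, (20.0, 15.0, 30.0, 10.0, 25.0))]
        lower, upper = (tmin - 30.0, 0.5), (tmax + 30.0, 300.0)
    else:
        starts = [(t0, s0, s1) for t0, s0, s1 in
                  zip(t_starts, (30.0, 20.0, 15.0, 40.0, 25.0),
                      (15.0, 20.0, 30.0, 10.0, 25.0))]
        lower, upper = (tmin - 30.0, 0.5, 0.5), (tmax + 30.0, 300.0, 300.0)
    best = _multistart(resid, starts, lower, upper)
    warn = []
    if not tmin <= best.x[0] <= tmax:
        warn.append("fitted optimum lies outside the sampled temperature range")
    if symmetric:
        est = {"t_opt": float(best.x[0]), "sigma_lo": float(best.x[1]),
               "sigma_hi": float(best.x[1])}
    else:
        est = {"t_opt": float(best.x[0]), "sigma_lo": float(best.x[1]),
               "sigma_hi": float(best.x[2])}
    return FitResult(est, _r_squared(acts, best.fun), best.fun, warnings=warn)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Outputs of the staged estimation pipeline."""

    fits: dict                  # stage name -> FitResult
    beta: float
    dii_ref: float
    gm_points: pd.DataFrame     # per-row (par, gm) estimates
    params: KineticParameters   # constants with the fitted values substituted


def run_pipeline(
    pam: pd.DataFrame,
    gas: pd.DataFrame,
    activity: Optional[pd.DataFrame] = None,
    constants: Optional[KineticParameters] = None,
    ref_co2: Optional[float] = None,
    low_co2: Optional[float] = None,
    meas_co2: Optional[float] = None,
    etc_reference_par: float = 239.0,
) -> PipelineResult:
    """Run the full staged estimation on PAM and gas-exchange tables.

    ``pam`` needs columns par, co2, replicate, y_i, y_ii plus (for the damage
    stage) block == "pulse" rows with qn, pulse_index, pulse_duration_s;
    ``gas`` needs par, co2, replicate, a_hv, ci, gs, rd.  ``activity`` is an
    optional normalized temperature-activity table with columns temperature,
    process ("rubisco" / "etc"), activity.  ``constants`` supplies the fixed
    FvCB constants (Gamma_star, Kc, O/Ko ratio); fitted fields are ignored.
    """
    constants = constants or KineticParameters()
    fits: dict = {}

    co2_levels = sorted(gas["co2"].unique())
    ref_co2 = ref_co2 if ref_co2 is not None else co2_levels[-1]
    low_co2 = low_co2 if low_co2 is not None else co2_levels[0]
    if meas_co2 is None:
        mids = [c for c in co2_levels if c not in (ref_co2, low_co2)]
        meas_co2 = mids[0] if mids else ref_co2

    if "block" in pam.columns:
        yields = pam[pam["block"] == "yield"]
        pulses = pam[pam["block"] == "pulse"]
    else:
        yields, pulses = pam, pam.iloc[0:0]

    rd = float(gas["rd"].mean())

    # -- stage 1: beta at saturating CO2, reference PSII fraction -----------
    y_ref = yields[yields["co2"] == ref_co2]
    g_ref = gas[gas["co2"] == ref_co2]
    merged = pd.merge(g_ref, y_ref, on=["par", "replicate"], suffixes=("", "_pam"))
    if merged.empty:
        raise FitError(f"no matched saturating-CO2 rows at {ref_co2} ppm")
    beta = float(np.mean(beta_from_saturating_co2(
        merged["a_hv"].to_numpy(), merged["par"].to_numpy(), merged["y_ii"].to_numpy()
    )))
    dii_ref = float(np.mean(psii_fraction(
        y_ref["y_i"].to_numpy(), y_ref["y_ii"].to_numpy()
    )))

    # -- stage 2: J per observation, light-response fit ---------------------
    y_meas = yields[yields["co2"] == meas_co2].copy()
    y_meas["j"] = electron_flow_from_yields(
        y_meas["par"].to_numpy(), y_meas["y_ii"].to_numpy(),
        y_meas["y_i"].to_numpy(), beta, dii_ref,
    )
    fits["light_response"] = fit_light_response(
        y_meas["par"].to_numpy(), y_meas["j"].to_numpy(), beta
    )

    # -- stage 3: Cc at the reference light, gm, Vcmax ----------------------
    # The reference-light chloroplast CO2 is the larger of the two branch
    # inversions (the final-Cc max rule); since the Rubisco inversion needs
    # Vcmax, (gm, Vcmax) are solved self-consistently by fixed-point
    # iteration (one pass suffices when the reference light is ETC-limited).
    g_meas = gas[gas["co2"] == meas_co2]
    j_by = y_meas.groupby(["par", "replicate"])["j"].mean()
    g_etc = g_meas[g_meas["par"] == etc_reference_par]
    if g_etc.empty:
        raise FitError(f"no gas-exchange rows at the reference light {etc_reference_par}")
    j_etc = np.array([j_by.get((r.par, r.replicate), np.nan) for r in g_etc.itertuples()])
    if np.isnan(j_etc).any():
        raise FitError("could not match PAM electron flow to reference-light rows")
    g_low = gas[(gas["co2"] == low_co2) & (gas["par"] == etc_reference_par)]
    if g_low.empty:
        raise FitError(f"no low-CO2 rows at {low_co2} ppm for the Vcmax stage")

    def _cc_candidates(a_hv, j, vcmax):
        cands = [cc_from_electron_transport(a_hv, j, constants.Gamma_star)
                 if np.isfinite(j) and j > 4.0 * a_hv else -np.inf]
        if vcmax is not None and vcmax > a_hv:
            cands.append(float(cc_from_rubisco(a_hv, vcmax, constants)))
        return max(cands)

    vcmax: Optional[float] = None
    gm_ref = np.nan
    cc_ref = np.full(len(g_etc), np.nan)
    cc_low = np.full(len(g_low), np.nan)
    for _ in range(200):
        cc_ref = np.array([_cc_candidates(r.a_hv, j_r, vcmax)
                           for r, j_r in zip(g_etc.itertuples(), j_etc)])
        gm_ref = float(np.mean(
            (g_etc["a_hv"].to_numpy() - g_etc["rd"].to_numpy())
            / (g_etc["ci"].to_numpy() - cc_ref)
        ))
        cc_low = (
            g_low["ci"].to_numpy()
            - (g_low["a_hv"].to_numpy() - g_low["rd"].to_numpy()) / gm_ref
        )
        new = float(np.mean(vcmax_from_point(g_low["a_hv"].to_numpy(), cc_low, constants)))
        if vcmax is not None and abs(new - vcmax) < 1e-12:
            vcmax = new
            break
        vcmax = new
    fits["vcmax"] = FitResult({"Vcmax": vcmax, "gm_ref": gm_ref,
                               "cc_ref": float(np.mean(cc_ref)),
                               "cc_low": float(np.mean(cc_low))},
                              float("nan"), np.array([]))

    # -- stage 4: per-light gm, Hill light response -------------------------
    gm_rows = []
    for r in g_meas.itertuples():
        j_r = j_by.get((r.par, r.replicate), np.nan)
        cc = _cc_candidates(r.a_hv, j_r, vcmax)
        if not np.isfinite(cc):
            continue
        gm_rows.append({"par": r.par, "replicate": r.replicate,
                        "gm": (r.a_hv - r.rd) / (r.ci - cc)})
    gm_points = pd.DataFrame(gm_rows)
    fits["gm_light_response"] = fit_gm_light_response(
        gm_points["par"].to_numpy(), gm_points["gm"].to_numpy()
    )

    # -- stage 5: damage constants from qN pulse trains ---------------------
    if not pulses.empty:
        jmax = fits["light_response"]["Jmax"]
        theta = fits["light_response"]["theta"]
        g = fits["gm_light_response"].estimates
        p_hat = constants.replace(
            Jmax=jmax, theta=theta, beta_prime=min(beta, 0.99), Vcmax=vcmax,
            Rd=rd, gs=float(gas["gs"].mean()),
            gd=g["gd"], dg_max=max(g["dg_max"], 1e-6),
            hill_n=g["hill_n"], hill_K=g["hill_K"],
        )
        gs_by_rep = gas.groupby("replicate")["gs"].mean()
        kd_frames = []
        for rep, grp in pulses.groupby("replicate"):
            recs = [
                PAMRecord(par=r.par, y_i=r.y_i, y_ii=r.y_ii, qn=r.qn,
                          pulse_index=int(r.pulse_index),
                          pulse_duration=r.pulse_duration_s,
                          co2=r.co2, replicate=int(rep))
                for r in grp.itertuples()
            ]
            frame = damage_rates_from_qn(recs)
            frame["gs"] = gs_by_rep.get(rep, float(gas["gs"].mean()))
            kd_frames.append(frame)
        kd_df = pd.concat(kd_frames, ignore_index=True)
        fits["damage"] = fit_damage_constants(
            kd_df["kd"].to_numpy(), kd_df["par"].to_numpy(), p_hat,
            ajs=kd_df["aj"].to_numpy(), gss=kd_df["gs"].to_numpy(),
        )
    else:
        p_hat = constants

    # -- stage 6: temperature responses -------------------------------------
    if activity is not None and not activity.empty:
        for process, symmetric, key in (("rubisco", True, "temperature_rubisco"),
                                        ("etc", False, "temperature_etc")):
            sub = activity[activity["process"] == process]
            if not sub.empty:
                fits[key] = fit_temperature_response(
                    sub["temperature"].to_numpy(), sub["activity"].to_numpy(),
                    symmetric=symmetric,
                )

    final = p_hat
    if "damage" in fits:
        final = final.replace(kd0=fits["damage"]["kd0"], alpha=fits["damage"]["alpha"])
    return PipelineResult(fits=fits, beta=beta, dii_ref=dii_ref,
                          gm_points=gm_points, params=final)
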
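"""Pointwise algebraic kernels of the photodamage-extended FvCB model.

All functions are pure, accept scalars or numpy arrays, and broadcast.
"""

from __future__ import annotations

import numpy as np

from .errors import ConsistencyError, DomainError, ParameterError
from .params import KineticParameters, RateBundle, TemperatureResponse

__all__ = [
    "electron_flow_potential",
    "mesophyll_conductance",
    "temperature_activity",
    "carboxylation_rates",
    "net_assimilation",
    "damage_rate",
]


def electron_flow_potential(par, p: KineticParameters):
    """Potential linear electron flow J at light intensity ``par``.

    J is the smaller root of the non-rectangular hyperbola
    ``theta*J**2 - (I2 + Jmax)*J + I2*Jmax = 0`` with ``I2 = beta_prime*par``
    the PAR absorbed by PSII.  Satisfies ``0 <= J <= min(I2, Jmax)`` and
    saturates at Jmax for large I2.
    """
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise DomainError("PAR must be non-negative")
    i2 = p.beta_prime * par
    s = i2 + p.Jmax
    disc = s * s - 4.0 * p.theta * i2 * p.Jmax
    j = (s - np.sqrt(disc)) / (2.0 * p.theta)
    return j if j.ndim else float(j)


def mesophyll_conductance(par, p: KineticParameters):
    """Hill-type light response of mesophyll conductance to CO2.

    ``gm = dg_max * par**n / (K**n + par**n) + gd``: equals the dark
    conductance ``gd`` at par = 0 and approaches ``gd + dg_max`` at
    saturating light; monotone non-decreasing in PAR.
    """
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise DomainError("PAR must be non-negative")
    parn = par ** p.hill_n
    gm = p.dg_max * parn / (p.hill_K ** p.hill_n + parn) + p.gd
    return gm if gm.ndim else float(gm)


def temperature_activity(t, tr: TemperatureResponse):
    """Dimensionless activity of a process at leaf temperature ``t`` (°C).

    Asymmetric Gaussian: 1 at ``tr.t_opt``, e-folding widths ``sigma_lo``
    below and ``sigma_hi`` above the optimum; continuous at the optimum.
    """
    if not (tr.sigma_lo > 0 and tr.sigma_hi > 0):  # defensive; dataclass validates
        raise ParameterError("temperature-response widths must be > 0")
    t = np.asarray(t, dtype=float)
    d = t - tr.t_opt
    sigma = np.where(d < 0, tr.sigma_lo, tr.sigma_hi)
    act = np.exp(-(d * d) / (sigma * sigma))
    return act if act.ndim else float(act)


def carboxylation_rates(cc, j_eff, p: KineticParameters, act_c=1.0, act_j=1.0) -> RateBundle:
    """Limitation-specific and realized carboxylation rates at chloroplast CO2 ``cc``.

    ``Wj = act_j * J_eff / (4 + 8*Gamma_star/Cc)`` (ETC-limited),
    ``Wc = act_c * Cc * Vcmax / (Cc + Kc*(1 + O/Ko))`` (Rubisco-limited),
    ``W = min(Wj, Wc)``.  ``j_eff`` is the (possibly damage-scaled) electron
    flow; the temperature activities ``act_c``/``act_j`` multiply the
    respective limits.
    """
    cc = np.asarray(cc, dtype=float)
    if np.any(cc <= 0):
        raise DomainError("chloroplast CO2 must be > 0")
    act_c = np.asarray(act_c, dtype=float)
    act_j = np.asarray(act_j, dtype=float)
    if np.any((act_c < 0) | (act_c > 1)) or np.any((act_j < 0) | (act_j > 1)):
        raise DomainError("activities must lie in [0, 1]")
    j_eff = np.asarray(j_eff, dtype=float)
    wj = act_j * j_eff / (4.0 + 8.0 * p.Gamma_star / cc)
    wc = act_c * cc * p.Vcmax / (cc + p.kc_eff)
    w = np.minimum(wj, wc)
    a_hv = w * (cc - p.Gamma_star) / cc
    scalar = wj.ndim == 0 and wc.ndim == 0
    if scalar:
        wj, wc, w, a_hv = float(wj), float(wc), float(w), float(a_hv)
    return RateBundle(
        J_potential=np.nan, J_eff=j_eff if j_eff.ndim else float(j_eff),
        Wj=wj, Wc=wc, W=w, A_hv=a_hv,
    )


def net_assimilation(w, cc, p: KineticParameters):
    """Net CO2 assimilation ``A_hv = W * (Cc - Gamma_star) / Cc``.

    Positive above the compensation point, zero at ``Cc = Gamma_star`` and
    approaches W as Cc grows large.
    """
    cc = np.asarray(cc, dtype=float)
    if np.any(cc <= 0):
        raise DomainError("chloroplast CO2 must be > 0")
    a = np.asarray(w, dtype=float) * (cc - p.Gamma_star) / cc
    return a if a.ndim else float(a)


def damage_rate(wj, w, aj, p: KineticParameters):
    """Photodamage rate dAj/dt = -kd0 * (alpha*Wj + Wj - W) * Aj  (s⁻¹).

    Damage is proportional to the remaining undamaged fraction Aj and to the
    electron flow entering the chain, with the excess Wj - W (electrons not
    consumed by carboxylation) damaging at the full rate and the balanced
    flow Wj = W damaging at the reduced rate alpha * kd0.  Always <= 0.
    """
    wj = np.asarray(wj, dtype=float)
    w = np.asarray(w, dtype=float)
    aj = np.asarray(aj, dtype=float)
    if np.any((aj < 0) | (aj > 1)):
        raise DomainError("Aj must lie in [0, 1]")
    # tiny negative excess from floating point is tolerated
    if np.any(w - wj > 1e-9 * np.maximum(1.0, np.abs(wj))):
        raise ConsistencyError("W > Wj violates W = min(Wj, Wc)")
    rate = -p.kd0 * (p.alpha * wj + np.maximum(wj - w, 0.0)) * aj
    return rate if rate.ndim else float(rate)
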
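"""Quasi-steady CO2 balance, Euler photodamage stepping, protocols and sweeps.

The only dynamical variable is the undamaged ETC fraction ``Aj``: the CO2
pools equilibrate much faster than damage accrues, so at every Euler step the
two limitation-specific chloroplast CO2 steady states are solved, the final
``Cc`` is taken as their maximum (which selects the limiting, i.e. slower,
carboxylation branch) and ``Aj`` is advanced with the photodamage rate law.

Clearing the steady-state CO2 balances of denominators turns each of them
into a quadratic in ``Cc`` with exactly one positive root, which always lies
in ``[Gamma_star, Co + Rd/g_tot]`` (``g_tot`` the series stomatal-mesophyll
conductance); the solvers return that root in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, SolverError
from .kernels import (
    electron_flow_potential,
    mesophyll_conductance,
    temperature_activity,
)
from .params import KineticParameters, RateBundle, TemperatureResponse

__all__ = [
    "Segment",
    "Protocol",
    "SystemState",
    "Timecourse",
    "standard_protocol",
    "steady_ci",
    "steady_cc_rubisco",
    "steady_cc_etc",
    "cc_residual_rubisco",
    "cc_residual_etc",
    "select_final_cc",
    "steady_state",
    "step_euler",
    "run_protocol",
    "sweep_act_heatmap",
    "sweep_temperature",
]

#: Default leaf temperature of the favorable protocol phases (°C) — the
#: cultivation and measurement temperature of the pea dataset.
BASE_TEMPERATURE = 23.0

#: Duration of each phase of the standard favorable/stress/favorable protocol.
PHASE_DURATION_S = 1200.0


# ---------------------------------------------------------------------------
# protocol containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One piecewise-constant driver segment.

    ``temperature`` sets the activities of both processes through their
    temperature responses; ``act_j``/``act_c`` are direct overrides that
    bypass the temperature block for the corresponding process.  Driver
    fields may be numpy arrays of a common shape, in which case an ensemble
    of protocols is integrated in lockstep (used by the sweep generators).
    """

    duration: float
    par: object
    temperature: object = BASE_TEMPERATURE
    act_j: object = None
    act_c: object = None
    co2: object = None
    gs_scale: object = 1.0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ParameterError("segment duration must be > 0")
        if np.any(np.asarray(self.par, dtype=float) < 0):
            raise ParameterError("PAR must be non-negative")
        gsc = np.asarray(self.gs_scale, dtype=float)
        if np.any((gsc <= 0) | (gsc > 1)):
            raise ParameterError("gs_scale must lie in (0, 1]")
        for name in ("act_j", "act_c"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any((v < 0) | (v > 1)):
                    raise ParameterError(f"{name} override must lie in [0, 1]")
        if self.temperature is None and (self.act_j is None or self.act_c is None):
            raise ParameterError(
                "a segment needs a temperature unless both activities are overridden"
            )
        if self.co2 is not None and np.any(np.asarray(self.co2, dtype=float) <= 0):
            raise ParameterError("co2 must be > 0")


@dataclass(frozen=True)
class Protocol:
    """Ordered driver segments plus integration and recording steps."""

    segments: tuple
    dt: float = 0.1
    record_every: float = 10.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ParameterError("protocol needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.dt > 0:
            raise ParameterError("dt must be > 0")
        if self.dt > min(s.duration for s in self.segments):
            raise ParameterError("dt must not exceed the shortest segment")
        if self.record_every < self.dt:
            raise ParameterError("record_every must be >= dt")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))


def standard_protocol(
    par: float,
    stress_temperature: Optional[float] = None,
    stress_act_j: Optional[float] = None,
    stress_act_c: Optional[float] = None,
    base_temperature: float = BASE_TEMPERATURE,
    co2: Optional[float] = None,
    gs_scale: float = 1.0,
    phase_duration: float = PHASE_DURATION_S,
    dt: float = 0.1,
    record_every: float = 10.0,
) -> Protocol:
    """The standard 20/20/20-min favorable / stress / favorable protocol.

    Favorable phases run at ``base_temperature`` (or, when the stress phase
    uses direct activity overrides, at activities fixed to exactly 1); the
    middle phase either holds ``stress_temperature`` or applies the
    ``stress_act_j``/``stress_act_c`` overrides.
    """
    overrides = stress_act_j is not None or stress_act_c is not None
    if overrides and stress_temperature is not None:
        raise ParameterError("give either a stress temperature or activity overrides")
    if overrides:
        fav = Segment(phase_duration, par, temperature=None, act_j=1.0, act_c=1.0,
                      co2=co2, gs_scale=gs_scale)
        stress = Segment(
            phase_duration, par, temperature=None,
            act_j=1.0 if stress_act_j is None else stress_act_j,
            act_c=1.0 if stress_act_c is None else stress_act_c,
            co2=co2, gs_scale=gs_scale,
        )
    else:
        fav = Segment(phase_duration, par, temperature=base_temperature,
                      co2=co2, gs_scale=gs_scale)
        t_stress = base_temperature if stress_temperature is None else stress_temperature
        stress = Segment(phase_duration, par, temperature=t_stress,
                         co2=co2, gs_scale=gs_scale)
    return Protocol(segments=(fav, stress, fav), dt=dt, record_every=record_every)


# ---------------------------------------------------------------------------
# steady-state CO2 balance
# ---------------------------------------------------------------------------

def steady_ci(cc, co, gs, gm):
    """Steady intercellular CO2: ``Ci = (gs*Co + gm*Cc) / (gs + gm)``.

    Lies between Cc and Co; equals Co when Cc = Co or when gm vanishes.
    """
    gs = np.asarray(gs, dtype=float)
    gm = np.asarray(gm, dtype=float)
    if np.any(gs + gm <= 0):
        raise DomainError("gs + gm must be > 0")
    ci = (gs * np.asarray(co, dtype=float) + gm * np.asarray(cc, dtype=float)) / (gs + gm)
    return ci if ci.ndim else float(ci)


def _series_conductance(gs_eff, gm):
    return gs_eff * gm / (gs_eff + gm)


def _positive_root(a, b, c):
    """Positive root of ``a x^2 + b x + c = 0`` with a > 0 and c <= 0."""
    disc = b * b - 4.0 * a * c
    if np.any(disc < 0):
        raise SolverError("steady-state CO2 balance has no real root")
    return (-b + np.sqrt(disc)) / (2.0 * a)


def steady_cc_rubisco(p: KineticParameters, gm, act_c=1.0, gs_eff=None, co2=None):
    """Steady chloroplast CO2 under the Rubisco limitation.

    Root of ``g_tot*(Co - Cc) - (Cc - Gamma_star)*act_c*Vcmax/(Cc + Km) + Rd = 0``
    with ``Km = Kc*(1 + O/Ko)``; at ``act_c = 0`` this reduces to the
    zero-consumption equilibrium ``Co + Rd*(gs+gm)/(gs*gm)``.
    """
    gs_eff = p.gs if gs_eff is None else gs_eff
    co2 = p.Co if co2 is None else co2
    if np.any(np.asarray(act_c, dtype=float) < 0):
        raise DomainError("act_c must be >= 0")
    g_tot = _series_conductance(np.asarray(gs_eff, dtype=float), np.asarray(gm, dtype=float))
    b0 = g_tot * np.asarray(co2, dtype=float) + p.Rd
    vn = np.asarray(act_c, dtype=float) * p.Vcmax
    km = p.kc_eff
    cc = _positive_root(g_tot, g_tot * km + vn - b0, -(b0 * km + vn * p.Gamma_star))
    return cc if cc.ndim else float(cc)


def steady_cc_etc(p: KineticParameters, gm, j_eff, act_j=1.0, gs_eff=None, co2=None):
    """Steady chloroplast CO2 under the electron-transport limitation.

    Root of ``g_tot*(Co - Cc) - (Cc - Gamma_star)*Jn/(4*Cc + 8*Gamma_star) + Rd = 0``
    with ``Jn = act_j * J_eff``; at ``Jn = 0`` this reduces to the
    zero-consumption equilibrium ``Co + Rd*(gs+gm)/(gs*gm)``.
    """
    gs_eff = p.gs if gs_eff is None else gs_eff
    co2 = p.Co if co2 is None else co2
    if np.any(np.asarray(j_eff, dtype=float) < 0):
        raise DomainError("J_eff must be >= 0")
    g_tot = _series_conductance(np.asarray(gs_eff, dtype=float), np.asarray(gm, dtype=float))
    b0 = g_tot * np.asarray(co2, dtype=float) + p.Rd
    jn = np.asarray(act_j, dtype=float) * np.asarray(j_eff, dtype=float)
    g = p.Gamma_star
    cc = _positive_root(4.0 * g_tot, jn + 8.0 * g * g_tot - 4.0 * b0, -g * (8.0 * b0 + jn))
    return cc if cc.ndim else float(cc)


def cc_residual_rubisco(cc, p: KineticParameters, gm, act_c=1.0, gs_eff=None, co2=None):
    """CO2-balance residual of the Rubisco branch at ``cc`` (ppm·s⁻¹ scale)."""
    gs_eff = p.gs if gs_eff is None else gs_eff
    co2 = p.Co if co2 is None else co2
    g_tot = _series_conductance(gs_eff, gm)
    return (
        g_tot * (co2 - cc)
        - (cc - p.Gamma_star) * act_c * p.Vcmax / (cc + p.kc_eff)
        + p.Rd
    )


def cc_residual_etc(cc, p: KineticParameters, gm, j_eff, act_j=1.0, gs_eff=None, co2=None):
    """CO2-balance residual of the ETC branch at ``cc``."""
    gs_eff = p.gs if gs_eff is None else gs_eff
    co2 = p.Co if co2 is None else co2
    g_tot = _series_conductance(gs_eff, gm)
    jn = act_j * j_eff
    return (
        g_tot * (co2 - cc)
        - (cc - p.Gamma_star) * jn / (4.0 * cc + 8.0 * p.Gamma_star)
        + p.Rd
    )


def select_final_cc(ccc, ccj):
    """Final chloroplast CO2: the larger of the two limitation-specific values.

    The branch with the higher steady CO2 is the one consuming CO2 more
    slowly, i.e. the limiting branch of ``W = min(Wj, Wc)``.
    """
    ccc = np.asarray(ccc, dtype=float)
    ccj = np.asarray(ccj, dtype=float)
    if np.any(ccc <= 0) or np.any(ccj <= 0):
        raise DomainError("limitation-specific Cc values must be > 0")
    cc = np.maximum(ccc, ccj)
    return cc if cc.ndim else float(cc)


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemState:
    """Instantaneous model state along a trajectory."""

    time: float
    Aj: float
    Cc: float
    Ci: float
    limitation: str          # "ETC" if Wj <= Wc else "Rubisco"
    rates: RateBundle
    gm: float
    act_j: float
    act_c: float


@dataclass
class Timecourse:
    """Recorded trajectory of a protocol run."""

    states: list = field(default_factory=list)

    @property
    def final_Aj(self) -> float:
        return self.states[-1].Aj

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    def to_dataframe(self) -> pd.DataFrame:
        r = self.states
        return pd.DataFrame(
            {
                "time_s": [s.time for s in r],
                "Aj": [s.Aj for s in r],
                "Cc_ppm": [s.Cc for s in r],
                "Ci_ppm": [s.Ci for s in r],
                "W": [s.rates.W for s in r],
                "Wj": [s.rates.Wj for s in r],
                "Wc": [s.rates.Wc for s in r],
                "Ahv": [s.rates.A_hv for s in r],
                "gm": [s.gm for s in r],
                "limitation": [s.limitation for s in r],
            }
        )


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

class _SegmentConstants:
    """Driver-derived quantities constant within one segment."""

    __slots__ = ("n_steps", "par", "gm", "gs_eff", "g_tot", "co2", "b0",
                 "j_pot", "act_j", "act_c", "vn", "ccc", "jc")

    def __init__(self, seg: Segment, p: KineticParameters,
                 tr_c: TemperatureResponse, tr_j: TemperatureResponse, dt: float):
        self.n_steps = max(1, int(round(seg.duration / dt)))
        self.par = np.asarray(seg.par, dtype=float)
        if seg.act_j is not None:
            self.act_j = np.asarray(seg.act_j, dtype=float)
        else:
            self.act_j = np.asarray(temperature_activity(seg.temperature, tr_j))
        if seg.act_c is not None:
            self.act_c = np.asarray(seg.act_c, dtype=float)
        else:
            self.act_c = np.asarray(temperature_activity(seg.temperature, tr_c))
        self.gm = np.asarray(mesophyll_conductance(self.par, p))
        self.gs_eff = p.gs * np.asarray(seg.gs_scale, dtype=float)
        self.g_tot = _series_conductance(self.gs_eff, self.gm)
        self.co2 = np.asarray(p.Co if seg.co2 is None else seg.co2, dtype=float)
        self.b0 = self.g_tot * self.co2 + p.Rd
        self.j_pot = np.asarray(electron_flow_potential(self.par, p))
        self.jc = self.act_j * self.j_pot          # Jn = jc * Aj
        self.vn = self.act_c * p.Vcmax
        # the Rubisco branch does not depend on Aj: solve it once per segment
        self.ccc = np.asarray(
            steady_cc_rubisco(p, self.gm, self.act_c, self.gs_eff, self.co2)
        )


def _advance_aj(aj, c: _SegmentConstants, p: KineticParameters, dt: float):
    """One explicit-Euler update of the undamaged fraction Aj."""
    g = p.Gamma_star
    jn = c.jc * aj
    bq = jn + 8.0 * g * c.g_tot - 4.0 * c.b0
    cq = -g * (8.0 * c.b0 + jn)
    aq = 4.0 * c.g_tot
    ccj = (-bq + np.sqrt(bq * bq - 4.0 * aq * cq)) / (2.0 * aq)
    cc = np.maximum(c.ccc, ccj)
    wj = jn * cc / (4.0 * cc + 8.0 * g)
    wc = c.vn * cc / (cc + p.kc_eff)
    w = np.minimum(wj, wc)
    aj = aj - dt * p.kd0 * (p.alpha * wj + (wj - w)) * aj
    return np.clip(aj, 0.0, 1.0)


def _state_at(aj, time, c: _SegmentConstants, p: KineticParameters) -> SystemState:
    g = p.Gamma_star
    jn = float(c.jc * aj)
    ccj = steady_cc_etc(p, float(c.gm), float(c.j_pot) * float(aj),
                        float(c.act_j), float(c.gs_eff), float(c.co2))
    ccc = float(c.ccc)
    cc = max(ccc, ccj)
    ci = steady_ci(cc, float(c.co2), float(c.gs_eff), float(c.gm))
    wj = jn * cc / (4.0 * cc + 8.0 * g)
    wc = float(c.vn) * cc / (cc + p.kc_eff)
    w = min(wj, wc)
    a_hv = w * (cc - g) / cc
    bundle = RateBundle(
        J_potential=float(c.j_pot),
        J_eff=float(aj) * float(c.j_pot),
        Wj=wj, Wc=wc, W=w, A_hv=a_hv,
    )
    return SystemState(
        time=float(time), Aj=float(aj), Cc=cc, Ci=ci,
        limitation="ETC" if wj <= wc else "Rubisco",
        rates=bundle, gm=float(c.gm),
        act_j=float(c.act_j), act_c=float(c.act_c),
    )


def steady_state(
    par: float,
    p: Optional[KineticParameters] = None,
    tr_c: Optional[TemperatureResponse] = None,
    tr_j: Optional[TemperatureResponse] = None,
    temperature: Optional[float] = None,
    act_j: Optional[float] = None,
    act_c: Optional[float] = None,
    aj: float = 1.0,
    co2: Optional[float] = None,
    gs_scale: float = 1.0,
) -> SystemState:
    """Quasi-steady model state at fixed drivers and undamaged fraction ``aj``.

    Activities come from ``temperature`` through the temperature responses,
    from the direct overrides, or default to exactly 1 when neither is given.
    """
    p = p or KineticParameters()
    tr_c = tr_c or TemperatureResponse.rubisco_default()
    tr_j = tr_j or TemperatureResponse.etc_default()
    if temperature is None:
        act_j = 1.0 if act_j is None else act_j
        act_c = 1.0 if act_c is None else act_c
    seg = Segment(1.0, par, temperature=temperature, act_j=act_j, act_c=act_c,
                  co2=co2, gs_scale=gs_scale)
    c = _SegmentConstants(seg, p, tr_c, tr_j, 1.0)
    return _state_at(float(aj), 0.0, c, p)


def step_euler(
    state: SystemState,
    segment: Segment,
    p: KineticParameters,
    tr_c: TemperatureResponse,
    tr_j: TemperatureResponse,
    dt: float,
) -> SystemState:
    """Advance one Euler step under the segment's drivers and re-solve the state."""
    if not dt > 0:
        raise ParameterError("dt must be > 0")
    c = _SegmentConstants(segment, p, tr_c, tr_j, dt)
    aj = _advance_aj(np.asarray(state.Aj, dtype=float), c, p, dt)
    return _state_at(float(aj), state.time + dt, c, p)


def run_protocol(
    protocol: Protocol,
    p: Optional[KineticParameters] = None,
    tr_c: Optional[TemperatureResponse] = None,
    tr_j: Optional[TemperatureResponse] = None,
    aj0: float = 1.0,
) -> Timecourse:
    """Integrate a full protocol, recording the state every ``record_every`` s.

    Returns a :class:`Timecourse` whose first state is the initial condition
    and whose last state is the final one (always recorded).
    """
    p = p or KineticParameters()
    tr_c = tr_c or TemperatureResponse.rubisco_default()
    tr_j = tr_j or TemperatureResponse.etc_default()
    dt = protocol.dt
    record_stride = max(1, int(round(protocol.record_every / dt)))

    tc = Timecourse()
    aj = np.asarray(float(aj0), dtype=float)
    time = 0.0
    step_count = 0
    for seg in protocol.segments:
        c = _SegmentConstants(seg, p, tr_c, tr_j, dt)
        if not tc.states:
            tc.states.append(_state_at(float(aj), time, c, p))
        for _ in range(c.n_steps):
            aj = _advance_aj(aj, c, p, dt)
            time += dt
            step_count += 1
            if step_count % record_stride == 0:
                tc.states.append(_state_at(float(aj), time, c, p))
        if step_count % record_stride != 0:
            tc.states.append(_state_at(float(aj), time, c, p))
    return tc


def _integrate_final_aj(segments, p, tr_c, tr_j, dt, aj0=1.0):
    """Final Aj of an ensemble of protocols integrated in lockstep."""
    shape = np.broadcast_shapes(
        *[np.shape(getattr(s, f)) for s in segments
          for f in ("par", "act_j", "act_c", "temperature", "gs_scale", "co2")
          if getattr(s, f) is not None]
    )
    aj = np.full(shape, float(aj0)) if shape else np.asarray(float(aj0))
    for seg in segments:
        c = _SegmentConstants(seg, p, tr_c, tr_j, dt)
        for _ in range(c.n_steps):
            aj = _advance_aj(aj, c, p, dt)
    return aj


# ---------------------------------------------------------------------------
# sweep generators
# ---------------------------------------------------------------------------

def sweep_act_heatmap(
    grid_j: Sequence[float],
    grid_c: Sequence[float],
    par: float,
    p: Optional[KineticParameters] = None,
    tr_c: Optional[TemperatureResponse] = None,
    tr_j: Optional[TemperatureResponse] = None,
    dt: float = 0.1,
    phase_duration: float = PHASE_DURATION_S,
) -> np.ndarray:
    """Final Aj over a grid of stress-phase activity overrides.

    Entry ``[i, j]`` is the final Aj of the standard protocol with direct
    overrides ``act_j = grid_j[i]``, ``act_c = grid_c[j]`` during the stress
    phase (favorable phases at activities exactly 1).
    """
    p = p or KineticParameters()
    tr_c = tr_c or TemperatureResponse.rubisco_default()
    tr_j = tr_j or TemperatureResponse.etc_default()
    gj = np.asarray(grid_j, dtype=float)
    gc = np.asarray(grid_c, dtype=float)
    if np.any((gj < 0) | (gj > 1)) or np.any((gc < 0) | (gc > 1)):
        raise ParameterError("activity grids must lie in [0, 1]")
    aj_grid, ac_grid = np.meshgrid(gj, gc, indexing="ij")
    fav = Segment(phase_duration, par, temperature=None, act_j=1.0, act_c=1.0)
    stress = Segment(phase_duration, par, temperature=None,
                     act_j=aj_grid, act_c=ac_grid)
    return _integrate_final_aj((fav, stress, fav), p, tr_c, tr_j, dt)


def sweep_temperature(
    temps: Sequence[float],
    pars: Sequence[float],
    p: Optional[KineticParameters] = None,
    tr_c: Optional[TemperatureResponse] = None,
    tr_j: Optional[TemperatureResponse] = None,
    gs_scale: float = 1.0,
    base_temperature: float = BASE_TEMPERATURE,
    dt: float = 0.1,
    phase_duration: float = PHASE_DURATION_S,
) -> pd.DataFrame:
    """Final Aj for every (stress temperature, light intensity) pair.

    The stress phase holds the test temperature; the favorable phases run at
    ``base_temperature``.  Returns a long-format frame with columns
    ``temperature``, ``par``, ``final_aj``.
    """
    p = p or KineticParameters()
    tr_c = tr_c or TemperatureResponse.rubisco_default()
    tr_j = tr_j or TemperatureResponse.etc_default()
    t_grid, par_grid = np.meshgrid(
        np.asarray(temps, dtype=float), np.asarray(pars, dtype=float), indexing="ij"
    )
    fav = Segment(phase_duration, par_grid, temperature=base_temperature,
                  gs_scale=gs_scale)
    stress = Segment(phase_duration, par_grid, temperature=t_grid,
                     gs_scale=gs_scale)
    final = _integrate_final_aj((fav, stress, fav), p, tr_c, tr_j, dt)
    return pd.DataFrame(
        {
            "temperature": t_grid.ravel(),
            "par": par_grid.ravel(),
            "final_aj": final.ravel(),
        }
    )
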
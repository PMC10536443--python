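"""Parameter containers for the photodamage-extended FvCB model.

The defaults are the pea (*Pisum sativum*) parameterization: light response of
linear electron flow (Jmax, theta), Rubisco kinetics (Vcmax, Kc, the folded
O/Ko oxygenation ratio, Gamma_star), CO2 diffusion (gs, the Hill-type light
response of mesophyll conductance), and the photodamage rate law (kd0, alpha).
Two asymmetric-Gaussian temperature responses (one for Rubisco, one for the
electron transport chain) scale the corresponding carboxylation limits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ParameterError

#: Dimensionless O/Ko oxygenation ratio. O = 200,000 ppm O2 with Ko read in the
#: standard FvCB mbar convention (Ko = 179) gives O/Ko = 200/179; the effective
#: Michaelis denominator is then Kc * (1 + Ko_ratio) ~ 550.5 ppm. Reading Ko in
#: ppm instead would make Rubisco-limited carboxylation vanishingly small; the
#: ratio is a plain config value so either reading can be forced.
DEFAULT_KO_RATIO = 200000.0 / 179000.0


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and conductances of the model.

    Units: fluxes in µmol·m⁻²·s⁻¹, conductances in mol·m⁻²·s⁻¹, CO2 in ppm,
    light in µmol·m⁻²·s⁻¹ PAR, kd0 in s⁻¹.

    Attributes
    ----------
    Jmax : maximum electron transport rate through the ETC.
    theta : empirical curvature factor of the light response (0, 1].
    beta_prime : fraction of incident PAR absorbed and delivered to PSII.
        Never reported directly for this dataset; the default 0.23 is the
        value implied by the reported chloroplast CO2 concentrations at the
        standard 239 µmol·m⁻²·s⁻¹ light (which put the electron flow there
        near 29 µmol·m⁻²·s⁻¹) and reproduces the ETC limitation at low
        light together with the multi-phase temperature dependence of the
        final damage (see docs/methods.md).
    Vcmax : maximum Rubisco carboxylation rate.
    Gamma_star : CO2 compensation point in the absence of respiration.
    Kc : Michaelis constant of carboxylation.
    Ko_ratio : dimensionless O/Ko term in the oxygenation denominator.
    Rd : mitochondrial respiration rate (not reported; default 1.0).
    gs : stomatal conductance to CO2.
    gd : dark mesophyll conductance.
    dg_max : light-induced increment of mesophyll conductance.
    hill_n : Hill coefficient of the gm light response.
    hill_K : PAR giving half of the light-induced gm increment.
    kd0 : photodamage rate constant.
    alpha : ratio of the damage rate at Wj = W to that at Wj > W, in (0, 1).
    Co : ambient CO2.
    """

    Jmax: float = 55.0
    theta: float = 0.25
    beta_prime: float = 0.23
    Vcmax: float = 18.2
    Gamma_star: float = 38.6
    Kc: float = 260.0
    Ko_ratio: float = DEFAULT_KO_RATIO
    Rd: float = 1.0
    gs: float = 0.17
    gd: float = 0.018
    dg_max: float = 0.25
    hill_n: float = 2.0
    hill_K: float = 1000.0
    kd0: float = 0.00008
    alpha: float = 0.09
    Co: float = 360.0

    def __post_init__(self) -> None:
        for name in (
            "Jmax", "Vcmax", "Gamma_star", "Kc", "Ko_ratio", "Rd", "gs",
            "gd", "dg_max", "hill_n", "hill_K", "kd0", "Co",
        ):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.theta <= 1:
            raise ParameterError(f"theta must be in (0, 1], got {self.theta}")
        if not 0 < self.beta_prime < 1:
            raise ParameterError(
                f"beta_prime must be in (0, 1), got {self.beta_prime}"
            )
        if not self.Gamma_star < self.Co:
            raise ParameterError("Gamma_star must be below ambient CO2 Co")

    @property
    def kc_eff(self) -> float:
        """Effective Michaelis denominator Kc * (1 + O/Ko), ppm."""
        return self.Kc * (1.0 + self.Ko_ratio)

    def replace(self, **changes: float) -> "KineticParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TemperatureResponse:
    """Asymmetric-Gaussian temperature activity of one process.

    The activity equals 1 at ``t_opt`` and falls to e⁻¹ at
    ``t_opt - sigma_lo`` and ``t_opt + sigma_hi``.
    """

    t_opt: float
    sigma_lo: float
    sigma_hi: float

    def __post_init__(self) -> None:
        if not self.sigma_lo > 0 or not self.sigma_hi > 0:
            raise ParameterError("temperature-response widths must be > 0")

    @classmethod
    def rubisco_default(cls) -> "TemperatureResponse":
        """Fitted pea Rubisco response: optimum 25 °C, symmetric 22 °C widths."""
        return cls(t_opt=25.0, sigma_lo=22.0, sigma_hi=22.0)

    @classmethod
    def etc_default(cls) -> "TemperatureResponse":
        """Fitted pea ETC response: optimum 31 °C, widths 36 / 15.5 °C."""
        return cls(t_opt=31.0, sigma_lo=36.0, sigma_hi=15.5)

    def replace(self, **changes: float) -> "TemperatureResponse":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class RateBundle:
    """Instantaneous fluxes at one model state (all µmol·m⁻²·s⁻¹).

    ``J_potential`` is the undamaged light-limited electron flow,
    ``J_eff`` the damage- and temperature-scaled flow actually entering the
    ETC-limited carboxylation rate ``Wj``; ``Wc`` is the Rubisco-limited rate,
    ``W = min(Wj, Wc)`` the realized rate and ``A_hv`` net CO2 assimilation.
    """

    J_potential: float
    J_eff: float
    Wj: float
    Wc: float
    W: float
    A_hv: float
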
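"""Closed-form two-state models of protein folding stability.

Every quantity in this module follows one unit convention:

* energies (``dG``, ``dH``, amplitudes of ``T dS``) in kJ mol⁻¹,
* heat capacities and entropies in kJ mol⁻¹ K⁻¹,
* temperatures in Kelvin (Celsius appears only at I/O boundaries),
* denaturant concentrations in mol L⁻¹ (M),
* rates in s⁻¹,
* spectroscopic signals in arbitrary linear units (CD millidegrees,
  mean residue ellipticity, ... — all results are invariant to affine
  rescaling of the signal axis).

The sign convention is that a positive unfolding free energy ``dG``
means the native state is the stable one, so the unfolding equilibrium
constant is ``K = exp(-dG / (R T))`` and the unfolded fraction is 0.5
exactly where ``dG = 0`` (at the denaturation midpoint ``Cm`` or the
melting temperature ``Tm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

#: Gas constant in kJ mol^-1 K^-1.
R = 8.3145e-3

#: Offset between the Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_celsius):
    """Convert a temperature (scalar or array) from Celsius to Kelvin."""
    return np.asarray(t_celsius, dtype=float) + CELSIUS_OFFSET if np.ndim(t_celsius) else float(t_celsius) + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin):
    """Convert a temperature (scalar or array) from Kelvin to Celsius."""
    return np.asarray(t_kelvin, dtype=float) - CELSIUS_OFFSET if np.ndim(t_kelvin) else float(t_kelvin) - CELSIUS_OFFSET


def _check_nonneg(x, name):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be non-negative")
    return x


def _check_pos(x, name):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError(f"{name} must be positive")
    return x


@dataclass(frozen=True)
class TwoStateEqParams:
    """Parameters of one equilibrium denaturant titration at one temperature.

    The observed signal is a population-weighted mixture of two linear
    baselines; the populations follow the linear extrapolation model
    ``dG([D]) = dG(H2O) - m [D]``.

    Attributes
    ----------
    dg_h2o : float
        Unfolding free energy extrapolated to zero denaturant, kJ mol⁻¹.
    m_value : float
        Slope of ``dG`` versus denaturant concentration, kJ mol⁻¹ M⁻¹.
        Must be positive (denaturant destabilises).
    temperature : float
        Temperature of the titration, K.
    bn0, bu0 : float
        Native / unfolded baseline intercepts (signal units).
    an, au : float
        Native / unfolded baseline slopes (signal M⁻¹).
    """

    dg_h2o: float
    m_value: float
    temperature: float
    bn0: float = 0.0
    bu0: float = -10.0
    an: float = 0.0
    au: float = 0.0

    def __post_init__(self):
        if self.m_value <= 0:
            raise ValueError("m_value must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")

    @property
    def cm(self) -> float:
        """Midpoint denaturant concentration ``Cm = dG(H2O) / m``, M."""
        return self.dg_h2o / self.m_value


@dataclass(frozen=True)
class StabilityCurveParams:
    """Gibbs-Helmholtz description of the protein stability curve.

    ``dG(T) = dH(T0) - T dS(T0) + dCp (T - T0 - T ln(T/T0))``

    When ``anchored`` is true the entropy is constrained to
    ``dS(T0) = dH(T0) / T0`` so the curve crosses zero exactly at the
    reference temperature — the natural choice when ``T0`` is the
    melting temperature ``Tm``.
    """

    dh_t0: float
    ds_t0: float
    dcp: float
    t0: float
    anchored: bool = False

    def __post_init__(self):
        if self.t0 <= 0:
            raise ValueError("t0 must be positive (Kelvin)")
        if self.dcp < 0:
            raise ValueError("dcp must be non-negative")
        if self.anchored and abs(self.dh_t0 - self.t0 * self.ds_t0) > 1e-9:
            raise ValueError("anchored parameters require dS(T0) = dH(T0)/T0")

    @classmethod
    def anchored_at(cls, dh_tm: float, dcp: float, tm: float) -> "StabilityCurveParams":
        """Build an anchored curve from ``dH(Tm)``, ``dCp`` and ``Tm`` (K)."""
        return cls(dh_t0=dh_tm, ds_t0=dh_tm / tm, dcp=dcp, t0=tm, anchored=True)


@dataclass(frozen=True)
class ThermalMeltParams:
    """Van't Hoff two-state description of a heat-induced melt.

    ``K(T) = exp(-(dHm/R) (1/T - 1/Tm))`` with linear native/unfolded
    baselines in temperature.  ``dHm`` is the van't Hoff enthalpy at the
    transition midpoint ``Tm`` (K); no heat-capacity term is included.
    """

    tm: float
    dhm: float
    bn: float = 0.0
    bu: float = -10.0
    an: float = 0.0
    au: float = 0.0

    def __post_init__(self):
        if self.tm <= 0:
            raise ValueError("tm must be positive (Kelvin)")
        if self.dhm <= 0:
            raise ValueError("dhm must be positive for an observable transition")

    @property
    def tm_celsius(self) -> float:
        return self.tm - CELSIUS_OFFSET


@dataclass(frozen=True)
class KineticParams:
    """Single-exponential kinetic trace ``A(t) = A(inf) + A exp(-k t)``."""

    k_app: float
    amplitude: float
    a_inf: float

    def __post_init__(self):
        if self.k_app <= 0:
            raise ValueError("k_app must be positive")


@dataclass(frozen=True)
class ChevronParams:
    """Unfolding limb of a chevron plot: ``ln k_u([D]) = ln k_u(H2O) + m_u [D]``."""

    ln_ku_h2o: float
    mu: float

    @property
    def ku_h2o(self) -> float:
        """Back-transformed unfolding rate in water, s⁻¹."""
        return float(np.exp(self.ln_ku_h2o))


# ---------------------------------------------------------------------------
# forward models


def equilibrium_free_energy(p: TwoStateEqParams, denaturant):
    """Unfolding free energy at denaturant concentration ``[D]`` (kJ mol⁻¹).

    Linear extrapolation model: ``dG = dG(H2O) - m [D]``; zero at
    ``[D] = Cm`` by construction.
    """
    d = _check_nonneg(denaturant, "denaturant concentration")
    return p.dg_h2o - p.m_value * d


def equilibrium_fraction_unfolded(p: TwoStateEqParams, denaturant):
    """Unfolded population at ``[D]``; in [0, 1], exactly 0.5 at ``Cm``."""
    dg = equilibrium_free_energy(p, denaturant)
    return expit(-dg / (R * p.temperature))


def equilibrium_signal(p: TwoStateEqParams, denaturant):
    """Observed signal: baseline mixture weighted by the two-state populations."""
    d = _check_nonneg(denaturant, "denaturant concentration")
    fu = equilibrium_fraction_unfolded(p, d)
    native = p.bn0 + p.an * d
    unfolded = p.bu0 + p.au * d
    return (1.0 - fu) * native + fu * unfolded


def stability_curve_dg(c: StabilityCurveParams, temperature):
    """Gibbs-Helmholtz free energy of unfolding at temperature ``T`` (kJ mol⁻¹)."""
    t = _check_pos(temperature, "temperature")
    return c.dh_t0 - t * c.ds_t0 + c.dcp * (t - c.t0 - t * np.log(t / c.t0))


def temperature_of_max_stability(c: StabilityCurveParams) -> float:
    """Temperature ``Ts`` at which ``dG(T)`` is maximal (K).

    The stationary point of the Gibbs-Helmholtz curve solves
    ``-dS(T0) - dCp ln(T/T0) = 0``, i.e. ``Ts = T0 exp(-dS(T0)/dCp)``.
    Requires ``dCp > 0`` (otherwise the curve has no interior maximum).
    """
    if c.dcp <= 0:
        raise ValueError("no interior stability maximum when dCp <= 0")
    return float(c.t0 * np.exp(-c.ds_t0 / c.dcp))


def thermal_fraction_unfolded(p: ThermalMeltParams, temperature):
    """Unfolded population in a thermal melt; exactly 0.5 at ``Tm``."""
    t = _check_pos(temperature, "temperature")
    return expit(-(p.dhm / R) * (1.0 / t - 1.0 / p.tm))


def thermal_signal(p: ThermalMeltParams, temperature):
    """Observed melt signal: van't Hoff populations mixing linear baselines."""
    t = _check_pos(temperature, "temperature")
    fu = thermal_fraction_unfolded(p, t)
    native = p.bn + p.an * t
    unfolded = p.bu + p.au * t
    return (1.0 - fu) * native + fu * unfolded


def kinetic_signal(p: KineticParams, time):
    """Single-exponential decay toward the unfolded end point ``A(inf)``."""
    t = _check_nonneg(time, "time")
    return p.a_inf + p.amplitude * np.exp(-p.k_app * t)


def chevron_ln_k(c: ChevronParams, denaturant):
    """``ln k_u`` at denaturant concentration ``[D]`` (linear in ``[D]``)."""
    d = _check_nonneg(denaturant, "denaturant concentration")
    return c.ln_ku_h2o + c.mu * d
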
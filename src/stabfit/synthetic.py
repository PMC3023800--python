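"""Seeded synthetic denaturation data with the study's statistical structure.

The generator emulates CD-monitored unfolding experiments: equilibrium
GdnHCl titrations at several temperatures, single-jump kinetic unfolding
traces at several final denaturant concentrations, and heat-induced
melts scanned in 1 °C steps — each with 2–3 replicates per condition,
i.i.d. Gaussian instrument noise on the signal, and sloping linear
native/unfolded baselines.

Named presets carry the measured thermodynamic and kinetic parameters
of the proteins studied (Sto-RNase HI and its C58/145A and ΔC6
variants, plus the tag-fusion chimera pairs for So-RNase HI, Ec-RNase
HI and Sto-esterase).  Quantities no experiment reports — baseline
coefficients, equilibrium m-values, kinetic m-values for most proteins
— are documented package defaults; each preset records per-field
provenance (``"measured"`` vs ``"default"``).

Randomness is drawn from one root seed with a per-(protein, condition,
replicate) derived substream, so adding a condition never shifts the
noise of the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    CELSIUS_OFFSET,
    ChevronParams,
    KineticParams,
    StabilityCurveParams,
    ThermalMeltParams,
    TwoStateEqParams,
    celsius_to_kelvin,
    chevron_ln_k,
    equilibrium_signal,
    kinetic_signal,
    stability_curve_dg,
    thermal_signal,
)

__all__ = [
    "NoiseModel",
    "Preset",
    "PRESET_NAMES",
    "preset",
    "simulate_equilibrium_curve",
    "simulate_thermal_melt",
    "simulate_kinetic_trace",
    "StudyDesign",
    "simulate_study",
]

#: default baseline coefficients (signal units / per-x slopes)
DEFAULT_BN0, DEFAULT_BU0 = 0.0, -10.0
DEFAULT_AN, DEFAULT_AU = 0.05, -0.1

#: default equilibrium m-value for a small globular protein, kJ mol^-1 M^-1
DEFAULT_M_VALUE = 10.0

#: default kinetic m-value, M^-1
DEFAULT_MU = 2.0

#: default van't Hoff enthalpy when none is reported, kJ mol^-1
DEFAULT_DHM = 400.0

#: default noise, as a fraction of the baseline separation |bu0 - bn0|
DEFAULT_NOISE_FRACTION = 0.02


@dataclass(frozen=True)
class NoiseModel:
    """I.i.d. Gaussian noise of standard deviation ``sd`` (signal units)."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")


def _substream(noise: NoiseModel, key: str) -> np.random.Generator:
    """Deterministic per-condition RNG derived from the root seed."""
    child = zlib.crc32(key.encode("utf-8")) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(noise.seed) % (2**31), child]))


@dataclass(frozen=True)
class Preset:
    """Ground-truth parameter set for one protein.

    ``tm_c`` and ``dh_tm`` anchor the Gibbs-Helmholtz stability curve
    (``dh_tm`` doubles as the van't Hoff melt enthalpy ``dHm``);
    ``provenance`` maps each numeric field to ``"measured"`` or
    ``"default"``.
    """

    protein_id: str
    tm_c: float
    dh_tm: float
    dcp: Optional[float] = None
    ku_h2o: Optional[float] = None
    mu: float = DEFAULT_MU
    m_value: float = DEFAULT_M_VALUE
    bn0: float = DEFAULT_BN0
    bu0: float = DEFAULT_BU0
    an: float = DEFAULT_AN
    au: float = DEFAULT_AU
    provenance: dict = field(default_factory=dict)

    @property
    def tm_k(self) -> float:
        return self.tm_c + CELSIUS_OFFSET

    def stability_params(self) -> StabilityCurveParams:
        """Anchored stability curve through (Tm, 0); requires a dCp."""
        if self.dcp is None:
            raise ValueError(f"preset {self.protein_id} has no heat-capacity change")
        return StabilityCurveParams.anchored_at(self.dh_tm, self.dcp, self.tm_k)

    def thermal_params(self) -> ThermalMeltParams:
        """Van't Hoff melt parameters (baseline slopes are per Kelvin)."""
        return ThermalMeltParams(tm=self.tm_k, dhm=self.dh_tm, bn=self.bn0,
                                 bu=self.bu0, an=self.an, au=self.au)

    def equilibrium_params(self, temperature_k: float) -> TwoStateEqParams:
        """Titration parameters at one temperature.

        ``dG(H2O)`` is taken from the preset's anchored stability curve,
        so simulated profiles lie exactly on that curve.
        """
        dg = float(stability_curve_dg(self.stability_params(), temperature_k))
        if dg <= 0:
            raise ValueError(
                f"{self.protein_id} is unstable at {temperature_k:.2f} K; "
                "no equilibrium transition to titrate"
            )
        return TwoStateEqParams(dg_h2o=dg, m_value=self.m_value,
                                temperature=temperature_k, bn0=self.bn0,
                                bu0=self.bu0, an=self.an, au=self.au)

    def chevron_params(self) -> ChevronParams:
        if self.ku_h2o is None:
            raise ValueError(f"preset {self.protein_id} has no unfolding rate")
        return ChevronParams(ln_ku_h2o=float(np.log(self.ku_h2o)), mu=self.mu)

    def noise_sd(self, fraction: float = DEFAULT_NOISE_FRACTION) -> float:
        """Noise sd as a fraction of the baseline separation."""
        return fraction * abs(self.bu0 - self.bn0)


def _measured(*names):
    prov = {n: "measured" for n in names}
    for n in ("mu", "m_value", "bn0", "bu0", "an", "au"):
        prov.setdefault(n, "default")
    return prov


_PRESETS = {
    "Sto_WT": Preset("Sto_WT", tm_c=102.0, dh_tm=890.0, dcp=12.8, ku_h2o=5.7e-11,
                     provenance=_measured("tm_c", "dh_tm", "dcp", "ku_h2o")),
    "Sto_C58_145A": Preset("Sto_C58_145A", tm_c=87.3, dh_tm=827.0, dcp=11.0,
                           ku_h2o=1.0e-6,
                           provenance=_measured("tm_c", "dh_tm", "dcp", "ku_h2o")),
    "Sto_dC6": Preset("Sto_dC6", tm_c=79.1, dh_tm=508.0, dcp=7.9, ku_h2o=1.7e-5,
                      provenance=_measured("tm_c", "dh_tm", "dcp", "ku_h2o")),
    "So_chimera": Preset("So_chimera", tm_c=49.1, dh_tm=DEFAULT_DHM,
                         provenance=_measured("tm_c")),
    "So_WT": Preset("So_WT", tm_c=30.4, dh_tm=DEFAULT_DHM,
                    provenance=_measured("tm_c")),
    "Ec_chimera": Preset("Ec_chimera", tm_c=52.2, dh_tm=DEFAULT_DHM,
                         provenance=_measured("tm_c")),
    "Ec_WT": Preset("Ec_WT", tm_c=49.9, dh_tm=DEFAULT_DHM,
                    provenance=_measured("tm_c")),
    "StoEst_chimera": Preset("StoEst_chimera", tm_c=72.4, dh_tm=DEFAULT_DHM,
                             provenance=_measured("tm_c")),
    "StoEst_WT": Preset("StoEst_WT", tm_c=67.9, dh_tm=DEFAULT_DHM,
                        provenance=_measured("tm_c")),
}

PRESET_NAMES = tuple(_PRESETS)

#: chimera/wild-type pairing used by the tag-fusion comparison
CHIMERA_PAIRS = {
    "So-RNase HI": ("So_chimera", "So_WT"),
    "Ec-RNase HI": ("Ec_chimera", "Ec_WT"),
    "Sto-esterase": ("StoEst_chimera", "StoEst_WT"),
}


def preset(name: str) -> Preset:
    """Look up a named protein preset; raises ``KeyError`` for unknown names."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# record emission

_COLUMNS = ["record_type", "protein_id", "temperature_C", "denaturant_M",
            "time_s", "signal", "replicate"]


def _records(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_COLUMNS)


def simulate_equilibrium_curve(
    p: TwoStateEqParams,
    d_grid: Sequence[float],
    noise: NoiseModel = NoiseModel(),
    replicates: int = 2,
    protein_id: str = "protein",
) -> pd.DataFrame:
    """Replicate-tagged equilibrium titration records at one temperature."""
    d = np.asarray(d_grid, dtype=float)
    if d.size == 0:
        raise ValueError("empty denaturant grid")
    if np.any(d < 0):
        raise ValueError("negative denaturant concentrations")
    if replicates not in (1, 2, 3):
        raise ValueError("replicates must be 1, 2 or 3")
    temp_c = p.temperature - CELSIUS_OFFSET
    clean = equilibrium_signal(p, d)
    rows = []
    for rep in range(1, replicates + 1):
        rng = _substream(noise, f"{protein_id}|eq|{temp_c:.4f}|{rep}")
        y = clean + rng.normal(0.0, noise.sd, size=d.size) if noise.sd > 0 else clean
        for di, yi in zip(d, y):
            rows.append(("equilibrium", protein_id, temp_c, di, np.nan, yi, rep))
    return _records(rows)


def default_melt_grid(tm_k: float, half_span_c: float = 25.0, step_c: float = 1.0):
    """Default thermal scan: Tm ± ``half_span_c`` in ``step_c`` steps (Kelvin)."""
    n = int(round(2 * half_span_c / step_c)) + 1
    return tm_k + np.linspace(-half_span_c, half_span_c, n)


def simulate_thermal_melt(
    p: ThermalMeltParams,
    t_grid: Optional[Sequence[float]] = None,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 2,
    protein_id: str = "protein",
) -> pd.DataFrame:
    """Thermal melt records; default grid spans Tm ± 25 °C in 1 °C steps."""
    t = default_melt_grid(p.tm) if t_grid is None else np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty temperature grid")
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive (Kelvin)")
    if replicates not in (1, 2, 3):
        raise ValueError("replicates must be 1, 2 or 3")
    clean = thermal_signal(p, t)
    rows = []
    for rep in range(1, replicates + 1):
        rng = _substream(noise, f"{protein_id}|melt|{rep}")
        y = clean + rng.normal(0.0, noise.sd, size=t.size) if noise.sd > 0 else clean
        for ti, yi in zip(t, y):
            rows.append(("thermal", protein_id, ti - CELSIUS_OFFSET, np.nan, np.nan, yi, rep))
    return _records(rows)


def default_kinetic_grid(k_app: float, n_points: int = 60, n_halflives: float = 7.0):
    """Default time grid covering ``n_halflives``/k (≥ 5/k) from zero."""
    if k_app <= 0:
        raise ValueError("k_app must be positive")
    return np.linspace(0.0, n_halflives / k_app, n_points)


def simulate_kinetic_trace(
    p: KineticParams,
    t_grid: Optional[Sequence[float]] = None,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 2,
    protein_id: str = "protein",
    denaturant_m: float = 0.0,
) -> pd.DataFrame:
    """Kinetic unfolding trace records at one final denaturant concentration."""
    t = default_kinetic_grid(p.k_app) if t_grid is None else np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(t < 0):
        raise ValueError("negative times")
    if replicates not in (1, 2, 3):
        raise ValueError("replicates must be 1, 2 or 3")
    clean = kinetic_signal(p, t)
    rows = []
    for rep in range(1, replicates + 1):
        rng = _substream(noise, f"{protein_id}|kin|{denaturant_m:.4f}|{rep}")
        y = clean + rng.normal(0.0, noise.sd, size=t.size) if noise.sd > 0 else clean
        for ti, yi in zip(t, y):
            rows.append(("kinetic", protein_id, 25.0, denaturant_m, ti, yi, rep))
    return _records(rows)


# ---------------------------------------------------------------------------
# whole-study simulation


@dataclass(frozen=True)
class StudyDesign:
    """Experimental design of a simulated study.

    Defaults mirror the measured study layout: equilibrium titrations at
    five temperatures with 15 concentrations and 2 replicates each,
    kinetic jumps at three final GdnHCl concentrations, and a thermal
    melt scanned over Tm ± 25 °C in 1 °C steps.
    """

    eq_temperatures_c: tuple = (10.0, 20.0, 30.0, 40.0, 50.0)
    eq_n_concentrations: int = 15
    kinetic_concentrations_m: tuple = (4.0, 5.0, 6.0)
    kinetic_n_points: int = 60
    replicates: int = 2
    noise_fraction: float = DEFAULT_NOISE_FRACTION
    melt_half_span_c: float = 25.0
    melt_step_c: float = 1.0

    def eq_grid(self, cm: float) -> np.ndarray:
        """Concentration grid for one titration, bracketing the midpoint.

        Mimics how denaturant titrations are laid out on the bench:
        roughly half the points sample the transition region (Cm ± 1.5 M,
        where ``m`` and ``Cm`` are determined) and the rest define the
        native and unfolded baselines on either side.
        """
        n = self.eq_n_concentrations
        n_trans = n - 2 * (n // 4)
        n_edge = n // 4
        lo = max(cm - 1.5, 0.0)
        hi = cm + 1.5
        native = np.linspace(0.0, max(lo - 0.3, 0.0), n_edge, endpoint=True)
        transition = np.linspace(lo, hi, n_trans)
        unfolded = np.linspace(hi + 0.3, hi + 2.5, n_edge)
        return np.concatenate([native, transition, unfolded])


def simulate_study(
    preset_names: Sequence[str],
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
):
    """Simulate a full study for the named presets.

    Returns ``(records, truth)``: one flat DataFrame in the curve-record
    format exercising every pipeline stage, and a JSON-serialisable
    ground-truth dict (per-protein parameters actually used, including
    defaulted values and their provenance).
    """
    frames, truth = [], {}
    for name in preset_names:
        pre = preset(name)
        noise = NoiseModel(sd=pre.noise_sd(design.noise_fraction), seed=seed)
        entry = {
            "preset": name,
            "tm_C": pre.tm_c,
            "dh_tm_kJ_mol": pre.dh_tm,
            "dcp_kJ_mol_K": pre.dcp,
            "ku_h2o_per_s": pre.ku_h2o,
            "mu_per_M": pre.mu,
            "m_value_kJ_mol_M": pre.m_value,
            "baselines": {"bn0": pre.bn0, "bu0": pre.bu0, "an": pre.an, "au": pre.au},
            "noise_sd": noise.sd,
            "provenance": dict(pre.provenance),
            "equilibrium": {},
        }
        if pre.dcp is not None:
            for tc in design.eq_temperatures_c:
                tk = celsius_to_kelvin(tc)
                try:
                    ep = pre.equilibrium_params(tk)
                except ValueError:
                    continue
                frames.append(simulate_equilibrium_curve(
                    ep, design.eq_grid(ep.cm), noise, design.replicates, name))
                entry["equilibrium"][f"{tc:g}"] = {"dg_h2o": ep.dg_h2o, "cm": ep.cm}
        frames.append(simulate_thermal_melt(
            pre.thermal_params(),
            default_melt_grid(pre.tm_k, design.melt_half_span_c, design.melt_step_c),
            noise, design.replicates, name))
        if pre.ku_h2o is not None:
            ch = pre.chevron_params()
            for dm in design.kinetic_concentrations_m:
                k = float(np.exp(chevron_ln_k(ch, dm)))
                kp = KineticParams(k_app=k, amplitude=pre.bn0 - pre.bu0, a_inf=pre.bu0)
                frames.append(simulate_kinetic_trace(
                    kp, default_kinetic_grid(k, design.kinetic_n_points),
                    noise, design.replicates, name, denaturant_m=dm))
        truth[name] = entry
    records = pd.concat(frames, ignore_index=True) if frames else _records([])
    return records, truth


def write_study(path, records: pd.DataFrame, truth: dict) -> None:
    """Write study records as CSV plus a ``<path>.truth.json`` sidecar."""
    records.to_csv(path, index=False)
    with open(f"{path}.truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
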
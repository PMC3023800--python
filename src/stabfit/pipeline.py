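"""Composite analysis workflows.

Three workflows mirror how a stability study of a tagged or mutated
protein is actually analysed:

* :func:`build_stability_profile` — fit each equilibrium titration,
  collect the per-temperature ``dG(H2O)`` values into a stability
  profile, and fit the Gibbs-Helmholtz curve anchored at the melting
  temperature (``dG = 0`` at ``Tm``; the anchor comes from calorimetry
  or a thermal melt and is never re-fitted here).
* :func:`run_unfolding_kinetics` — fit every kinetic trace to a single
  exponential, combine replicate rates at one concentration as the mean
  of ``ln k_app``, and extrapolate ``ln k_u`` linearly to zero
  denaturant to obtain ``k_u(H2O)``.
* :func:`compare_thermal_stability` — pair chimera and wild-type
  melting temperatures (fitted or literature-injected) and report
  ``ΔTm`` at 0.1 °C precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import fitting
from .models import (
    CELSIUS_OFFSET,
    ThermalMeltParams,
    TwoStateEqParams,
    equilibrium_fraction_unfolded,
    thermal_fraction_unfolded,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityPoint",
    "ChimeraRecord",
    "StudyReport",
    "build_stability_profile",
    "run_unfolding_kinetics",
    "compare_thermal_stability",
    "apparent_fraction_unfolded",
]


@dataclass(frozen=True)
class StabilityPoint:
    """One (temperature, dG(H2O)) entry of a stability profile.

    ``source`` is ``"equilibrium-fit"`` for points estimated from a
    denaturant titration and ``"anchor"`` for the ``(Tm, 0)`` point
    supplied externally.
    """

    temperature: float  # K
    dg_h2o: float  # kJ mol^-1
    stderr: float  # kJ mol^-1
    source: str = "equilibrium-fit"

    def __post_init__(self):
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")
        if self.source == "anchor" and self.dg_h2o != 0.0:
            raise ValueError("anchor points have dG(H2O) = 0 by definition")


def _tenths(x: float) -> int:
    """Round a Celsius temperature half-up to integer tenths of a degree."""
    import decimal

    return int(decimal.Decimal(repr(float(x))).scaleb(1)
               .quantize(decimal.Decimal(1), rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ChimeraRecord:
    """Melting-temperature comparison for one chimera/wild-type pair.

    Temperatures are carried as integer tenths of a degree internally so
    ``dTm = Tm(chimera) - Tm(wild-type)`` is exact at 0.1 °C precision.
    """

    protein_id: str
    tm_chimera_c: float
    tm_wildtype_c: float

    @property
    def dtm_c(self) -> float:
        return (_tenths(self.tm_chimera_c) - _tenths(self.tm_wildtype_c)) / 10.0


@dataclass
class StudyReport:
    """Aggregated per-protein results with provenance.

    ``proteins`` maps protein id to a dict of stage results (stability
    curve parameters, chevron parameters, melt parameters, diagnostics);
    ``chimera_records`` holds the ΔTm comparison; ``provenance`` records
    inputs, seed and configuration so a rerun is reproducible.
    """

    proteins: dict = field(default_factory=dict)
    chimera_records: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stability profile


def build_stability_profile(
    titrations: Union[Mapping[float, tuple], Sequence[tuple]],
    anchor_tm: float,
    weights_from_stderr: bool = False,
) -> tuple:
    """Build an anchored stability profile from equilibrium titrations.

    Parameters
    ----------
    titrations
        Mapping ``temperature_K -> (denaturant, signal)`` or a sequence
        of ``(temperature_K, denaturant, signal)`` tuples (replicates
        pooled into the arrays).
    anchor_tm
        Melting temperature in Kelvin; the Gibbs-Helmholtz fit is
        constrained through ``(anchor_tm, 0)``.

    Returns ``(points, curve_fit)`` where ``points`` contains one
    :class:`StabilityPoint` per successfully fitted temperature plus the
    anchor point, and ``curve_fit`` is the anchored Gibbs-Helmholtz
    :class:`~stabfit.fitting.FitResult`.  Temperatures whose titration
    fit fails are excluded and logged (and listed in
    ``curve_fit.extra['excluded_temperatures']``).
    """
    if isinstance(titrations, Mapping):
        items = [(t, d, y) for t, (d, y) in titrations.items()]
    else:
        items = [(t, d, y) for t, d, y in titrations]
    points, excluded = [], []
    for temp_k, d, y in sorted(items, key=lambda it: it[0]):
        try:
            res = fitting.fit_equilibrium_curve(d, y, temperature=temp_k)
        except (fitting.FitError, ValueError) as exc:
            logger.warning("excluding titration at %.2f K: %s", temp_k, exc)
            excluded.append(float(temp_k))
            continue
        points.append(StabilityPoint(
            temperature=float(temp_k),
            dg_h2o=res.params.dg_h2o,
            stderr=res.stderr["dg_h2o"],
        ))
    if len(points) < 3:
        raise fitting.FitError(
            f"only {len(points)} usable equilibrium fits; need at least 3"
        )
    temps = [p.temperature for p in points]
    if min(temps) <= anchor_tm <= max(temps):
        warnings.warn(
            "anchor Tm lies inside the sampled temperature range; the anchored "
            "fit normally extrapolates to Tm",
            stacklevel=2,
        )
    w = None
    if weights_from_stderr:
        w = np.array([1.0 / p.stderr if p.stderr > 0 else 0.0 for p in points])
    curve_fit = fitting.fit_stability_curve(points, anchor_tm=anchor_tm, weights=w)
    curve_fit.extra["excluded_temperatures"] = excluded
    points = points + [StabilityPoint(float(anchor_tm), 0.0, 0.0, source="anchor")]
    return points, curve_fit


# ---------------------------------------------------------------------------
# unfolding kinetics


def run_unfolding_kinetics(traces: Sequence[tuple]) -> tuple:
    """Fit kinetic traces and extrapolate ``ln k_u`` to zero denaturant.

    ``traces`` is a sequence of ``(denaturant_M, time, signal)`` tuples;
    several entries may share a concentration (replicates), in which
    case their rates are combined as the mean of ``ln k_app`` — the
    space in which the extrapolation is linear — before the chevron fit.

    Returns ``(trace_table, chevron_fit)``: a DataFrame with one row per
    trace (``denaturant_M``, ``k_app``, ``k_app_stderr``, ``converged``)
    and the :class:`~stabfit.fitting.FitResult` of the unfolding-limb
    line, whose ``extra['ku_h2o']`` is the rate in water.
    """
    rows = []
    for dm, t, y in traces:
        try:
            res = fitting.fit_kinetic_trace(t, y)
        except fitting.FitError as exc:
            logger.warning("dropping trace at %.3g M: %s", dm, exc)
            continue
        rows.append({
            "denaturant_M": float(dm),
            "k_app": res.params.k_app,
            "k_app_stderr": res.stderr["k_app"],
            "converged": res.converged,
        })
    table = pd.DataFrame(rows)
    usable = table[table["converged"]] if len(table) else table
    if len(usable) == 0 or usable["denaturant_M"].nunique() < 3:
        raise fitting.FitError(
            "need converged traces at >= 3 distinct denaturant concentrations"
        )
    pooled = (
        usable.assign(ln_k=np.log(usable["k_app"]))
        .groupby("denaturant_M")["ln_k"].mean()
    )
    chevron_fit = fitting.fit_chevron(pooled.index.to_numpy(),
                                      np.exp(pooled.to_numpy()))
    return table, chevron_fit


# ---------------------------------------------------------------------------
# chimera comparison


def compare_thermal_stability(
    pairs: Mapping[str, tuple],
    expected_dtm: Optional[Mapping[str, float]] = None,
) -> list:
    """Compute ΔTm for chimera/wild-type pairs.

    ``pairs`` maps a protein label to ``(tm_chimera, tm_wildtype)`` in
    °C — either plain floats (e.g. literature values) or fitted
    :class:`~stabfit.models.ThermalMeltParams`.  If ``expected_dtm``
    supplies an externally reported ΔTm, a mismatch with the computed
    difference raises a validation warning rather than an error.
    """

    def tm_c(v):
        if isinstance(v, ThermalMeltParams):
            return v.tm_celsius
        return float(v)

    records = []
    for protein_id, pair in pairs.items():
        if pair is None or len(pair) != 2 or pair[0] is None or pair[1] is None:
            raise ValueError(f"missing counterpart Tm for {protein_id}")
        rec = ChimeraRecord(protein_id, tm_c(pair[0]), tm_c(pair[1]))
        if expected_dtm and protein_id in expected_dtm:
            if abs(rec.dtm_c - float(expected_dtm[protein_id])) > 0.05:
                warnings.warn(
                    f"{protein_id}: reported dTm {expected_dtm[protein_id]:+.1f} C "
                    f"differs from the Tm pair difference {rec.dtm_c:+.1f} C",
                    stacklevel=2,
                )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# display transform


def apparent_fraction_unfolded(x, y, params, noise_sd: float = 0.0):
    """Baseline-normalise a measured curve to an apparent unfolded fraction.

    ``f_app(x) = (y - native(x)) / (unfolded(x) - native(x))`` with the
    fitted baselines of ``params`` (equilibrium: lines in denaturant;
    thermal: lines in Kelvin).  Noiseless two-state data map exactly
    onto the model's unfolded fraction; noisy data may slightly exceed
    [0, 1] and are flagged with a warning, never clipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if isinstance(params, TwoStateEqParams):
        native = params.bn0 + params.an * x
        unfolded = params.bu0 + params.au * x
    elif isinstance(params, ThermalMeltParams):
        native = params.bn + params.an * x
        unfolded = params.bu + params.au * x
    else:
        raise TypeError("params must be TwoStateEqParams or ThermalMeltParams")
    denom = unfolded - native
    floor = max(10.0 * noise_sd, 1e-12 * max(1.0, float(np.max(np.abs(y)))))
    if np.any(np.abs(denom) < floor):
        raise ValueError("baseline collapse: native and unfolded baselines coincide")
    f = (y - native) / denom
    if np.any((f < -1e-9) | (f > 1 + 1e-9)):
        warnings.warn("apparent fraction exceeds [0, 1]; values left unclipped",
                      stacklevel=2)
    return f
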
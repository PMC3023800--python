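"""Least-squares estimators for the two-state folding models.

Nonlinear fits (equilibrium titration, stability curve, kinetic trace,
thermal melt) run Levenberg-Marquardt through :mod:`lmfit`, seeded by
deterministic data-driven initial guesses.  The chevron extrapolation is
ordinary least squares of ``ln k_app`` on denaturant concentration,
solved in closed form.  Standard errors come from the linearised
covariance at the optimum (J'J scaled by the residual variance), which
is what standard fitting packages report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np

from .models import (
    R,
    ChevronParams,
    KineticParams,
    StabilityCurveParams,
    ThermalMeltParams,
    TwoStateEqParams,
    equilibrium_fraction_unfolded,
    equilibrium_signal,
    kinetic_signal,
    stability_curve_dg,
    thermal_fraction_unfolded,
    thermal_signal,
)

__all__ = [
    "FitError",
    "NoTransitionError",
    "FitResult",
    "guess_equilibrium_init",
    "fit_equilibrium_curve",
    "fit_stability_curve",
    "fit_kinetic_trace",
    "fit_chevron",
    "fit_thermal_melt",
]

#: relative convergence tolerance passed to the optimizer
FIT_TOL = 1e-12

_MAX_NFEV = 20000


class FitError(RuntimeError):
    """A fit could not be performed or did not converge."""


class NoTransitionError(FitError):
    """The data contain no resolvable folding transition."""


@dataclass
class FitResult:
    """Outcome of one least-squares fit.

    ``params`` holds the fitted parameter object (one of the core model
    types), ``stderr`` the per-parameter standard errors in the same
    units (plus derived quantities such as ``cm`` or ``ku_h2o``), and
    ``extra`` derived scalars.
    """

    params: object
    stderr: dict
    residual_ss: float
    n_points: int
    converged: bool
    n_iter: int
    extra: dict = field(default_factory=dict)


def _as_xy(x, y, weights=None):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if weights is not None:
        weights = np.asarray(weights, dtype=float).ravel()
        if weights.shape != x.shape:
            raise ValueError("weights must match the data length")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
    return x, y, weights


def _run_lmfit(residual, params, n_free):
    result = lmfit.minimize(
        residual,
        params,
        method="leastsq",
        xtol=FIT_TOL,
        ftol=FIT_TOL,
        max_nfev=_MAX_NFEV,
    )
    return result


def _stderr_of(result, name):
    p = result.params[name]
    if p.stderr is None or not np.isfinite(p.stderr):
        return float("nan")
    return float(p.stderr)


def _covar_entry(result, a, b):
    if result.covar is None:
        return float("nan")
    names = [n for n in result.params if result.params[n].vary]
    try:
        i, j = names.index(a), names.index(b)
    except ValueError:
        return float("nan")
    return float(result.covar[i, j])


# ---------------------------------------------------------------------------
# equilibrium denaturant titration


def _baseline_lines(x, y, n_edge=3):
    """Least-squares lines through the first/last ``n_edge`` points (by x)."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    slope_n, icpt_n = np.polyfit(xs[:n_edge], ys[:n_edge], 1)
    slope_u, icpt_u = np.polyfit(xs[-n_edge:], ys[-n_edge:], 1)
    return (icpt_n, slope_n), (icpt_u, slope_u), xs, ys


def _crossings(xs, f, level):
    """x positions where the piecewise-linear curve f(xs) crosses ``level``."""
    out = []
    for i in range(len(xs) - 1):
        f0, f1 = f[i] - level, f[i + 1] - level
        if f0 == 0.0:
            out.append(xs[i])
        elif f0 * f1 < 0:
            out.append(xs[i] + (xs[i + 1] - xs[i]) * f0 / (f0 - f1))
    if len(f) and f[-1] == level:
        out.append(xs[-1])
    return out


def guess_equilibrium_init(denaturant, signal, temperature: float) -> TwoStateEqParams:
    """Data-driven starting values for an equilibrium titration fit.

    Baselines are lines through the three lowest- and three highest-
    concentration points; ``Cm`` is where the baseline-normalised signal
    crosses 0.5 (the crossing closest to the median concentration when
    there are several); the m-value comes from the 0.2->0.8 transition
    width via ``m ~ 4 R T / width``; and ``dG(H2O) = m Cm``.
    """
    d, y, _ = _as_xy(denaturant, signal)
    if d.size < 9:
        raise ValueError("need at least 9 points to initialise an equilibrium fit")
    (bn0, an), (bu0, au), xs, ys = _baseline_lines(d, y)
    native = bn0 + an * xs
    unfolded = bu0 + au * xs
    denom = unfolded - native
    span = np.max(np.abs(denom))
    if span < 1e-12 * max(1.0, np.max(np.abs(ys))) or np.ptp(ys) == 0:
        raise NoTransitionError("no transition detected: baselines coincide")
    f = (ys - native) / np.where(np.abs(denom) < 1e-300, np.nan, denom)
    f = np.nan_to_num(f, nan=0.0)
    mids = _crossings(xs, f, 0.5)
    if not mids:
        raise NoTransitionError("no transition detected: signal never crosses the midpoint")
    med = float(np.median(xs))
    cm = min(mids, key=lambda c: abs(c - med))
    lo = _crossings(xs, f, 0.2)
    hi = _crossings(xs, f, 0.8)
    if lo and hi:
        width = abs(min(hi, key=lambda c: abs(c - cm)) - min(lo, key=lambda c: abs(c - cm)))
    else:
        width = 0.0
    if width <= 0:
        width = max(np.ptp(xs) / 10.0, 1e-3)
    m = 4.0 * R * temperature / width
    return TwoStateEqParams(
        dg_h2o=m * cm,
        m_value=m,
        temperature=temperature,
        bn0=float(bn0),
        bu0=float(bu0),
        an=float(an),
        au=float(au),
    )


def fit_equilibrium_curve(
    denaturant,
    signal,
    temperature: float,
    init: Optional[TwoStateEqParams] = None,
    weights=None,
    n_starts: int = 1,
) -> FitResult:
    """Fit a two-state equilibrium titration (6 free parameters).

    Returns ``dG(H2O)``, the m-value and the four baseline coefficients
    with standard errors; the derived midpoint ``Cm = dG(H2O)/m`` and
    its delta-method standard error are in ``extra`` / ``stderr``.
    Raises :class:`NoTransitionError` if the fitted midpoint falls
    outside the sampled concentration range.
    """
    d, y, w = _as_xy(denaturant, signal, weights)
    if d.size < 9:
        raise ValueError("need at least 9 points for an equilibrium fit")
    if init is None:
        init = guess_equilibrium_init(d, y, temperature)

    def residual(pars):
        p = TwoStateEqParams(
            dg_h2o=pars["dg_h2o"].value,
            m_value=pars["m_value"].value,
            temperature=temperature,
            bn0=pars["bn0"].value,
            bu0=pars["bu0"].value,
            an=pars["an"].value,
            au=pars["au"].value,
        )
        r = equilibrium_signal(p, d) - y
        return r * w if w is not None else r

    def make_params(g: TwoStateEqParams):
        pars = lmfit.Parameters()
        pars.add("dg_h2o", value=g.dg_h2o)
        pars.add("m_value", value=g.m_value, min=1e-6)
        pars.add("bn0", value=g.bn0)
        pars.add("bu0", value=g.bu0)
        pars.add("an", value=g.an)
        pars.add("au", value=g.au)
        return pars

    best = _run_lmfit(residual, make_params(init), 6)
    if n_starts > 1:
        rng = np.random.default_rng(0)
        for _ in range(n_starts - 1):
            jitter = rng.normal(1.0, 0.2, size=2)
            try:
                g = TwoStateEqParams(
                    dg_h2o=init.dg_h2o * jitter[0],
                    m_value=max(init.m_value * jitter[1], 1e-3),
                    temperature=temperature,
                    bn0=init.bn0,
                    bu0=init.bu0,
                    an=init.an,
                    au=init.au,
                )
            except ValueError:
                continue
            trial = _run_lmfit(residual, make_params(g), 6)
            if trial.chisqr < best.chisqr:
                best = trial

    v = {k: best.params[k].value for k in best.params}
    fitted = TwoStateEqParams(
        dg_h2o=v["dg_h2o"], m_value=v["m_value"], temperature=temperature,
        bn0=v["bn0"], bu0=v["bu0"], an=v["an"], au=v["au"],
    )
    if not (d.min() <= fitted.cm <= d.max()):
        raise NoTransitionError(
            f"no transition detected: fitted Cm={fitted.cm:.3g} M lies outside "
            f"the sampled range [{d.min():.3g}, {d.max():.3g}] M"
        )
    # the transition must be resolved by the data: a fitted sigmoid squeezed
    # between two adjacent grid points is baseline curvature, not unfolding
    fu_hat = equilibrium_fraction_unfolded(fitted, d)
    if np.count_nonzero((fu_hat > 0.05) & (fu_hat < 0.95)) < 2:
        raise NoTransitionError(
            "no transition detected: fewer than 2 points fall inside the "
            "fitted transition region"
        )
    sd_dg = _stderr_of(best, "dg_h2o")
    sd_m = _stderr_of(best, "m_value")
    cov_dg_m = _covar_entry(best, "dg_h2o", "m_value")
    # delta method for Cm = dG/m
    g = np.array([1.0 / v["m_value"], -v["dg_h2o"] / v["m_value"] ** 2])
    var_cm = (
        g[0] ** 2 * sd_dg**2 + g[1] ** 2 * sd_m**2 + 2 * g[0] * g[1] * cov_dg_m
    )
    stderr = {
        "dg_h2o": sd_dg,
        "m_value": sd_m,
        "bn0": _stderr_of(best, "bn0"),
        "bu0": _stderr_of(best, "bu0"),
        "an": _stderr_of(best, "an"),
        "au": _stderr_of(best, "au"),
        "cm": float(np.sqrt(var_cm)) if var_cm >= 0 else float("nan"),
    }
    resid = equilibrium_signal(fitted, d) - y
    return FitResult(
        params=fitted,
        stderr=stderr,
        residual_ss=float(np.sum(resid**2)),
        n_points=int(d.size),
        converged=bool(best.success),
        n_iter=int(best.nfev),
        extra={"cm": fitted.cm},
    )


# ---------------------------------------------------------------------------
# Gibbs-Helmholtz stability curve


def fit_stability_curve(
    points: Sequence,
    anchor_tm: Optional[float] = None,
    t0: Optional[float] = None,
    weights=None,
) -> FitResult:
    """Fit the Gibbs-Helmholtz stability curve to (T, dG) points.

    Parameters
    ----------
    points : sequence
        ``(temperature_K, dG)`` or ``(temperature_K, dG, stderr)`` tuples,
        or objects with ``temperature`` / ``dg_h2o`` attributes.
    anchor_tm : float, optional
        Melting temperature in Kelvin.  When given, the reference
        temperature is fixed at ``Tm`` and the entropy is constrained to
        ``dS(Tm) = dH(Tm)/Tm`` so the curve passes through ``(Tm, 0)``
        exactly, leaving ``dH(Tm)`` and ``dCp`` free (2 parameters).
    t0 : float, optional
        Reference temperature for the unanchored 3-parameter fit
        (default: mean of the data temperatures).
    """
    ts, dgs = [], []
    for pt in points:
        if hasattr(pt, "temperature"):
            ts.append(float(pt.temperature))
            dgs.append(float(pt.dg_h2o))
        else:
            ts.append(float(pt[0]))
            dgs.append(float(pt[1]))
    t = np.asarray(ts)
    dg = np.asarray(dgs)
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive (Kelvin)")
    anchored = anchor_tm is not None
    n_free = 2 if anchored else 3
    if t.size < n_free + 2:
        raise ValueError(
            f"need at least {n_free + 2} stability points for a "
            f"{'anchored' if anchored else 'free'} Gibbs-Helmholtz fit"
        )
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    ref = float(anchor_tm) if anchored else float(t0 if t0 is not None else t.mean())

    pars = lmfit.Parameters()
    pars.add("dh_t0", value=float(dg.max() * 6) if dg.max() > 0 else 500.0)
    pars.add("dcp", value=5.0, min=0.0)
    if not anchored:
        pars.add("ds_t0", value=pars["dh_t0"].value / ref)

    def residual(p):
        ds = p["dh_t0"].value / ref if anchored else p["ds_t0"].value
        c = StabilityCurveParams(
            dh_t0=p["dh_t0"].value, ds_t0=ds, dcp=max(p["dcp"].value, 0.0),
            t0=ref, anchored=False,
        )
        r = stability_curve_dg(c, t) - dg
        return r * w if w is not None else r

    result = _run_lmfit(residual, pars, n_free)
    dh = result.params["dh_t0"].value
    dcp = max(result.params["dcp"].value, 0.0)
    ds = dh / ref if anchored else result.params["ds_t0"].value
    fitted = StabilityCurveParams(dh_t0=dh, ds_t0=ds, dcp=dcp, t0=ref, anchored=anchored)
    stderr = {
        "dh_t0": _stderr_of(result, "dh_t0"),
        "dcp": _stderr_of(result, "dcp"),
        "ds_t0": _stderr_of(result, "dh_t0") / ref if anchored else _stderr_of(result, "ds_t0"),
    }
    resid = stability_curve_dg(fitted, t) - dg
    return FitResult(
        params=fitted,
        stderr=stderr,
        residual_ss=float(np.sum(resid**2)),
        n_points=int(t.size),
        converged=bool(result.success),
        n_iter=int(result.nfev),
        extra={
            "t_max_stability": (
                float(ref * np.exp(-ds / dcp))
                if dcp > 0 and abs(ds / dcp) < 50 else None
            )
        },
    )


# ---------------------------------------------------------------------------
# kinetic trace


def fit_kinetic_trace(
    time,
    signal,
    init: Optional[KineticParams] = None,
    weights=None,
) -> FitResult:
    """Fit a single-exponential unfolding trace ``A(t) = A(inf) + A exp(-k t)``.

    The fit is flagged non-converged when the observed time span is
    shorter than ``1/k`` for the fitted rate (the plateau is then not
    constrained by the data).
    """
    t, y, w = _as_xy(time, signal, weights)
    if t.size < 6:
        raise ValueError("need at least 6 points for a kinetic fit")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    order = np.argsort(t, kind="stable")
    ts, ys = t[order], y[order]
    if init is None:
        n_tail = max(3, t.size // 10)
        a_inf = float(np.mean(ys[-n_tail:]))
        amp = float(ys[0] - a_inf)
        if abs(amp) < 1e-12 * max(1.0, np.max(np.abs(ys))) or np.ptp(ys) == 0:
            raise FitError("constant signal: rate constant is undefined")
        # time at which the decay has fallen to 1/e of its initial amplitude
        target = a_inf + amp / math.e
        below = np.nonzero((ys - target) * np.sign(amp) <= 0)[0]
        t_e = float(ts[below[0]]) if below.size and ts[below[0]] > 0 else float(ts[-1]) / 3.0
        k0 = 1.0 / max(t_e, 1e-12)
    else:
        a_inf, amp, k0 = init.a_inf, init.amplitude, init.k_app

    pars = lmfit.Parameters()
    pars.add("k_app", value=k0, min=1e-15)
    pars.add("amplitude", value=amp)
    pars.add("a_inf", value=a_inf)

    def residual(p):
        kp = KineticParams(k_app=p["k_app"].value, amplitude=p["amplitude"].value,
                           a_inf=p["a_inf"].value)
        r = kinetic_signal(kp, t) - y
        return r * w if w is not None else r

    result = _run_lmfit(residual, pars, 3)
    k = result.params["k_app"].value
    if k <= 0:
        raise FitError("invalid trace: fitted rate constant is non-positive")
    fitted = KineticParams(
        k_app=k,
        amplitude=result.params["amplitude"].value,
        a_inf=result.params["a_inf"].value,
    )
    span_ok = (ts[-1] - ts[0]) >= 1.0 / k
    resid = kinetic_signal(fitted, t) - y
    return FitResult(
        params=fitted,
        stderr={
            "k_app": _stderr_of(result, "k_app"),
            "amplitude": _stderr_of(result, "amplitude"),
            "a_inf": _stderr_of(result, "a_inf"),
        },
        residual_ss=float(np.sum(resid**2)),
        n_points=int(t.size),
        converged=bool(result.success) and span_ok,
        n_iter=int(result.nfev),
    )


# ---------------------------------------------------------------------------
# chevron (unfolding limb) extrapolation


def fit_chevron(denaturant, k_app) -> FitResult:
    """Ordinary least squares of ``ln k_app`` on denaturant concentration.

    Closed-form OLS; the intercept is ``ln k_u(H2O)`` and the slope the
    kinetic m-value ``m_u``.  The back-transformed rate ``k_u(H2O)`` is
    reported in ``extra`` together with its log-scale standard error.
    """
    d = np.asarray(denaturant, dtype=float).ravel()
    k = np.asarray(k_app, dtype=float).ravel()
    if d.shape != k.shape:
        raise ValueError("denaturant and k_app must have the same length")
    if np.unique(d).size < 3:
        raise ValueError("need at least 3 distinct denaturant concentrations")
    if np.any(k <= 0):
        raise ValueError("all rate constants must be positive")
    lnk = np.log(k)
    n = d.size
    xbar = d.mean()
    sxx = float(np.sum((d - xbar) ** 2))
    slope = float(np.sum((d - xbar) * (lnk - lnk.mean())) / sxx)
    intercept = float(lnk.mean() - slope * xbar)
    resid = lnk - (intercept + slope * d)
    ssr = float(np.sum(resid**2))
    if n > 2:
        s2 = ssr / (n - 2)
        sd_slope = math.sqrt(s2 / sxx)
        sd_icpt = math.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    else:
        sd_slope = sd_icpt = float("nan")
    fitted = ChevronParams(ln_ku_h2o=intercept, mu=slope)
    return FitResult(
        params=fitted,
        stderr={"ln_ku_h2o": sd_icpt, "mu": sd_slope},
        residual_ss=ssr,
        n_points=int(n),
        converged=True,
        n_iter=1,
        extra={"ku_h2o": fitted.ku_h2o},
    )


# ---------------------------------------------------------------------------
# thermal melt


def guess_thermal_init(temperature, signal) -> ThermalMeltParams:
    """Data-driven starting values for a thermal melt fit.

    Same strategy as the equilibrium guess but in temperature: edge
    baselines, midpoint from the 0.5 crossing of the normalised signal,
    and a van't Hoff enthalpy from the 0.2->0.8 transition width
    (``dHm ~ 2.4 R Tm^2 / width``, the logistic slope relation).
    """
    t, y, _ = _as_xy(temperature, signal)
    if t.size < 9:
        raise ValueError("need at least 9 points to initialise a melt fit")
    (bn, an), (bu, au), xs, ys = _baseline_lines(t, y)
    native = bn + an * xs
    unfolded = bu + au * xs
    denom = unfolded - native
    if np.max(np.abs(denom)) < 1e-12 * max(1.0, np.max(np.abs(ys))) or np.ptp(ys) == 0:
        raise NoTransitionError("no transition detected: baselines coincide")
    f = (ys - native) / np.where(np.abs(denom) < 1e-300, np.nan, denom)
    f = np.nan_to_num(f, nan=0.0)
    mids = _crossings(xs, f, 0.5)
    if not mids:
        raise NoTransitionError("no transition detected in the scanned range")
    med = float(np.median(xs))
    tm = min(mids, key=lambda c: abs(c - med))
    lo, hi = _crossings(xs, f, 0.2), _crossings(xs, f, 0.8)
    width = 0.0
    if lo and hi:
        width = abs(min(hi, key=lambda c: abs(c - tm)) - min(lo, key=lambda c: abs(c - tm)))
    if width <= 0:
        width = max(np.ptp(xs) / 10.0, 0.5)
    dhm = 2.4 * R * tm**2 / width
    return ThermalMeltParams(tm=float(tm), dhm=float(dhm), bn=float(bn),
                             bu=float(bu), an=float(an), au=float(au))


def fit_thermal_melt(
    temperature,
    signal,
    init: Optional[ThermalMeltParams] = None,
    weights=None,
) -> FitResult:
    """Fit a van't Hoff thermal melt (6 free parameters: Tm, dHm, baselines).

    ``temperature`` is in Kelvin; the fitted ``Tm`` in Celsius is in
    ``extra['tm_celsius']``.  Raises :class:`NoTransitionError` when the
    fitted midpoint lies outside the scanned range.
    """
    t, y, w = _as_xy(temperature, signal, weights)
    if t.size < 9:
        raise ValueError("need at least 9 points for a thermal melt fit")
    if init is None:
        init = guess_thermal_init(t, y)

    pars = lmfit.Parameters()
    pars.add("tm", value=init.tm, min=1.0)
    pars.add("dhm", value=init.dhm, min=1e-6)
    pars.add("bn", value=init.bn)
    pars.add("bu", value=init.bu)
    pars.add("an", value=init.an)
    pars.add("au", value=init.au)

    def residual(p):
        mp = ThermalMeltParams(tm=p["tm"].value, dhm=p["dhm"].value,
                               bn=p["bn"].value, bu=p["bu"].value,
                               an=p["an"].value, au=p["au"].value)
        r = thermal_signal(mp, t) - y
        return r * w if w is not None else r

    result = _run_lmfit(residual, pars, 6)
    v = {k: result.params[k].value for k in result.params}
    fitted = ThermalMeltParams(tm=v["tm"], dhm=v["dhm"], bn=v["bn"],
                               bu=v["bu"], an=v["an"], au=v["au"])
    if not (t.min() <= fitted.tm <= t.max()):
        raise NoTransitionError(
            f"no transition in scanned range: fitted Tm={fitted.tm:.2f} K outside "
            f"[{t.min():.2f}, {t.max():.2f}] K"
        )
    fu_hat = thermal_fraction_unfolded(fitted, t)
    if np.count_nonzero((fu_hat > 0.05) & (fu_hat < 0.95)) < 2:
        raise NoTransitionError(
            "no transition in scanned range: the fitted transition is narrower "
            "than the scan step"
        )
    resid = thermal_signal(fitted, t) - y
    return FitResult(
        params=fitted,
        stderr={
            "tm": _stderr_of(result, "tm"),
            "dhm": _stderr_of(result, "dhm"),
            "bn": _stderr_of(result, "bn"),
            "bu": _stderr_of(result, "bu"),
            "an": _stderr_of(result, "an"),
            "au": _stderr_of(result, "au"),
        },
        residual_ss=float(np.sum(resid**2)),
        n_points=int(t.size),
        converged=bool(result.success),
        n_iter=int(result.nfev),
        extra={"tm_celsius": fitted.tm_celsius},
    )
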
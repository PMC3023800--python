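# Methods

## Models

All analyses assume a reversible two-state equilibrium N ⇌ U with no
populated intermediates, and a linear spectroscopic probe so the
observed signal is the population-weighted mixture of two state
baselines. The sign convention is ΔG > 0 for a stable native state;
the unfolding equilibrium constant is `K = exp(−ΔG/RT)`, so the
unfolded fraction is exactly ½ wherever ΔG = 0 (at `Cm` and at `Tm`).

**Equilibrium titration.** The linear extrapolation model
`ΔG([D]) = ΔG(H₂O) − m·[D]` with linear baselines `bn⁰ + an·[D]` and
`bu⁰ + au·[D]`. The raw signal is fitted directly (six free
parameters), never pre-normalised, so baseline uncertainty propagates
into ΔG(H₂O). The apparent-fraction-unfolded transform used for
display divides out the fitted baselines after the fact; it is never
part of the estimation.

**Stability curve.** Gibbs–Helmholtz with temperature-independent
ΔCp: `ΔG(T) = ΔH(T₀) − T·ΔS(T₀) + ΔCp·(T − T₀ − T·ln(T/T₀))`. The
anchored fit sets T₀ to a caller-supplied melting temperature and
constrains ΔS(T₀) = ΔH(T₀)/T₀, so the curve passes through (Tm, 0)
exactly and only (ΔH(Tm), ΔCp) are estimated. The anchor is an input
(typically from calorimetry) and is never re-fitted. The curve's
stationary point `Ts = T₀·exp(−ΔS(T₀)/ΔCp)` is reported as the
temperature of maximal stability.

**Thermal melt.** Pure van't Hoff two-state,
`K(T) = exp(−(ΔHm/R)(1/T − 1/Tm))`, with linear baselines in T. No
ΔCp term is included in the melt model: it is the minimal form
consistent with reporting only (Tm, ΔHm), and over the ±25 °C span of
a scan the ΔCp correction is far below the instrument noise modelled
here. Consequently ΔHm from a melt and ΔH(Tm) from a stability curve
need not coincide on real data.

**Kinetics.** Single-exponential traces
`A(t) = A(∞) + A·e^(−kt)` (all traces in scope are single-phase), and
the unfolding limb of the chevron: ordinary least squares of
`ln k_app` on [D], intercept `ln k_u(H₂O)`, slope `m_u`. The
extrapolation spans many orders of magnitude (for the
hyperthermostable wild type, from ~10⁻⁷ s⁻¹ at 4 M GdnHCl down to
~10⁻¹¹ s⁻¹ in water), so it inherits the usual caveat that linearity
in [D] is assumed, not tested, below the measured range.

## Fitting

Nonlinear fits use Levenberg–Marquardt (lmfit) with ftol/xtol 10⁻¹²
and a generous evaluation cap (2×10⁴; a tight iteration cap falsely
flags non-convergence on the six-parameter melt fit). Initial values
are data-driven and deterministic: baselines from least-squares lines
through the three points at each end of the sorted abscissa, midpoint
from the 0.5-crossing of the baseline-normalised signal (the crossing
closest to the median abscissa when noise creates several), slope
parameters from the 0.2→0.8 transition width (`m ≈ 4RT/width`;
`ΔHm ≈ 2.4·R·Tm²/width`). An optional multistart perturbs the
equilibrium guess. Residuals are unweighted by default; per-point
weights (e.g. from replicate standard deviations) are accepted
everywhere. Replicates are fitted as pooled points by default.

Standard errors are the linearised (J'J)⁻¹ covariance scaled by the
residual variance; derived quantities (`Cm = ΔG/m`, `k_u(H₂O) =
exp(intercept)`) get delta-method errors. Monte-Carlo tests in the
suite verify ~99.7 % nominal (3σ) intervals achieve ≥ 90 % coverage
under the generator's noise model.

Degenerate inputs: a fit whose midpoint falls outside the sampled
range, or whose fitted transition contains fewer than two interior
data points (the 5–95 % unfolded band), raises "no transition
detected" — the latter guard exists because baseline-only data can
otherwise be fitted by an absurdly sharp sigmoid squeezed between two
grid points. Kinetic fits whose time span is shorter than 1/k are
flagged non-converged rather than rejected. Ties in the midpoint
guess break toward the median abscissa.

ΔTm comparisons carry temperatures as integer tenths of a degree, so
chimera-minus-wild-type differences are exact at the 0.1 °C precision
at which melting temperatures are reported (default uncertainty
±0.3 °C). When an externally reported ΔTm disagrees with the
difference of the supplied Tm pair, the package computes from the pair
and emits a validation warning rather than silently choosing a side.

## Synthetic data

The generator emulates the study design, not any particular
instrument: i.i.d. Gaussian noise on the signal (default sd = 2 % of
the native–unfolded baseline separation, a typical CD noise floor),
2–3 replicates per condition with independent noise streams,
equilibrium titrations at five temperatures, kinetic jumps at three
final GdnHCl concentrations, and thermal scans over Tm ± 25 °C in
1 °C steps. Randomness derives from one root seed through
per-(protein, condition, replicate) substreams, so adding a condition
never shifts the noise of existing ones and regeneration is
byte-identical under the same seed.

Each preset's titration ΔG(H₂O)(T) values lie exactly on its anchored
Gibbs–Helmholtz curve. Parameters no experiment reports are
documented defaults, recorded per-field in the preset provenance and
in the truth sidecar: equilibrium m-value 10 kJ mol⁻¹ M⁻¹
(representative of small globular proteins), kinetic m_u 2.0 M⁻¹,
van't Hoff enthalpy 400 kJ mol⁻¹ for the non-Sto proteins, baselines
0/−10 signal units with slopes 0.05/−0.1. The default titration grid
brackets the predicted midpoint the way a bench titration does —
about half the points across Cm ± 1.5 M where m and Cm are
determined, the rest defining the two baselines — rather than
spreading points uniformly, which would leave the ~0.6 M transition
essentially unsampled.

What the generator does **not** emulate: slow equilibration and
scan-rate hysteresis, aggregation, three-state behaviour, baseline
curvature, correlated (drift-like) noise, and denaturant-dependent
noise. Passing recovery tests therefore demonstrate the estimators
are correct and well-calibrated under the stated noise model; they do
not certify robustness to those real-data pathologies. For the
hyperthermostable wild-type preset the simulated titrations extend to
denaturant concentrations above the solubility of aqueous GdnHCl
(~8 M); they exercise the analysis chain, not an executable bench
protocol.

Problem sizes in the shipped tests and acceptance script: 15-point
titrations ×2 replicates ×5 temperatures, 51-point melts ×2
replicates, 60-point kinetic traces, 6-point noiseless stability
profiles; Monte-Carlo properties use 50–200 seeded replicates.

## Known limitations

* Two-state only; no global multi-curve fitting with shared m-values,
  no Bayesian posteriors, no robust losses.
* The anchored stability-curve fit trusts the external Tm completely;
  an erroneous anchor biases ΔH(Tm) and ΔCp with no diagnostic beyond
  the residuals.
* Chevron analysis covers the unfolding limb only (no refolding limb,
  no rollover).
* Melt buffers containing denaturant (e.g. 1 M GdnHCl) are carried as
  row metadata, not modelled.
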
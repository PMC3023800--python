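# stabfit

Two-state analysis of protein conformational stability from
spectroscopic denaturation data — the standard measurement chain used
to ask "did this mutation, truncation or fusion tag stabilise my
protein, and by how much?"

It is written for protein scientists who monitor unfolding by circular
dichroism (or any linear spectroscopic probe) and need to turn raw
curves into thermodynamic and kinetic parameters:

* **Equilibrium denaturant titrations** (GdnHCl/urea) fitted to the
  two-state linear extrapolation model,
  `ΔG([D]) = ΔG(H₂O) − m·[D]`, with linear native/unfolded baselines
  folded into a single direct fit of the observed signal
  (Santoro–Bolen style); yields ΔG(H₂O), the m-value and the midpoint
  `Cm = ΔG(H₂O)/m`.
* **Stability curves**: per-temperature ΔG(H₂O) values fitted to the
  Gibbs–Helmholtz equation
  `ΔG(T) = ΔH(T₀) − T·ΔS(T₀) + ΔCp·(T − T₀ − T·ln(T/T₀))`,
  anchored through `(Tm, 0)` with an externally supplied melting
  temperature (e.g. from DSC), giving ΔH(Tm) and ΔCp.
* **Unfolding kinetics**: single-exponential trace fits
  `A(t) = A(∞) + A·e^(−k·t)` and linear extrapolation of `ln k_app`
  versus [D] to the unfolding rate in water, `k_u(H₂O)` (the unfolding
  limb of a chevron plot, slope `m_u`).
* **Thermal melts**: van't Hoff two-state fits
  `K(T) = exp(−(ΔHm/R)(1/T − 1/Tm))` with sloping baselines, and ΔTm
  comparison of tag-fusion chimeras against their wild types at
  0.1 °C precision.
* **Synthetic data**: a seeded generator that emulates the study
  design (2–3 replicates per condition, Gaussian instrument noise,
  sloping baselines, titrations at several temperatures, 1 °C-step
  thermal scans) plus named presets carrying the measured parameters
  of Sto-RNase HI, its C58/145A and ΔC6 variants, and the
  IGCIILT-tagged chimera pairs — so the whole chain runs with no
  external data.

All energies are kJ mol⁻¹, temperatures Kelvin internally and Celsius
in every file and CLI surface, `R = 8.3145 J mol⁻¹ K⁻¹`. Every
thermodynamic estimate is invariant to affine rescaling of the signal.

## Worked example

Simulate the ΔC6 truncation variant study and re-analyse it:

```
$ stabfit simulate --preset Sto_dC6 --seed 1 --out dc6.csv
wrote 612 records for 1 preset(s) to dc6.csv

$ stabfit profile dc6.csv --protein Sto_dC6 --anchor-tm 79.1
Sto_dC6: dH(Tm) = 488.9 kJ/mol, dCp = 7.54 kJ/mol/K (anchor 79.1 C)

$ stabfit chevron dc6.csv --protein Sto_dC6
Sto_dC6: k_u(H2O) = 1.8e-05 /s, m_u = 1.991 /M

$ stabfit fit-melt dc6.csv --protein Sto_dC6
Sto_dC6: Tm = 79.1 C, dHm = 509 kJ/mol

$ stabfit compare-tm --tm So_chimera=49.1 --tm-wt So_WT=30.4
So_chimera/So_WT: dTm = +18.7 C
```

The simulated ground truth for this preset is ΔH(Tm) = 508 kJ/mol,
ΔCp = 7.9 kJ/mol/K, Tm = 79.1 °C, k_u(H₂O) = 1.7×10⁻⁵ s⁻¹ and
m_u = 2.0 M⁻¹ (written alongside the CSV in `dc6.csv.truth.json`), so
the re-analysis recovers the profile parameters to a few percent under
the default 2 %-of-amplitude noise, the melt Tm to well under 0.1 °C,
and the chimera/wild-type ΔTm exactly. Every subcommand accepts
`--out file.json` for machine-readable results, and `stabfit report`
merges those fragments into one study report with provenance.

The same analyses are available as library functions
(`stabfit.fit_equilibrium_curve`, `stabfit.build_stability_profile`,
`stabfit.run_unfolding_kinetics`, ...) operating on plain arrays and
returning parameter objects with standard errors.

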
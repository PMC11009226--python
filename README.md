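# chex2dir

Analysis toolkit for two-state amide–water hydrogen-bond exchange, the
kind of problem posed by a small peptide-model amide (e.g. an
*N*-alkyl amide) in water: the backbone C=O can hold **two strong**
hydrogen bonds to solvent water (SHB state) or **one strong plus one
weak/absent** bond (WHB state), and the two states interconvert on a
sub-picosecond timescale.  The package turns the three measurements that
expose this equilibrium into thermodynamic and kinetic constants:

1. **FTIR** — the amide-I band splits into two Voigt sub-bands
   (≈ 1607.8 and 1620.9 cm⁻¹ at 23 °C).  Second-derivative analysis
   provides the evidence, a two-Voigt fit the per-temperature areas, and
   the centers drift linearly with temperature (≈ 0.07 cm⁻¹/°C for the
   low-frequency band).
2. **Van't Hoff thermodynamics** — integrated areas weight populations by
   the squared transition dipole, so

   K_eq = C₍WHB₎/C₍SHB₎ = (A₍WHB₎ · |μ|²₍SHB₎) / (A₍SHB₎ · |μ|²₍WHB₎),

   and a linear fit of ln K_eq against 1/T yields ΔH (slope = −ΔH/R) and
   ΔS (intercept = ΔS/R); ΔG(T) = ΔH − TΔS.
3. **Chemical-exchange 2D IR** — cross peaks between the two diagonal
   bands grow with the waiting time T_w.  The protocol normalizes each
   spectrum by the magnitude of a diagonal 1→2 window, subtracts the
   T_w = 0 spectrum, integrates a small cross-peak window, and fits
   m(T_w) = A·(1 − e^(−T_w/τ)); k₁ = 1/τ is the forward (SHB→WHB)
   exchange rate.  Arrhenius analysis of k₁(T) gives the activation
   energy, and detailed balance k₁ = k₋₁·e^(−ΔG/RT) the reverse rate.
4. **Hydration-shell statistics** — on labeled trajectories: radial
   distribution functions (minimum image, cubic box), shell coordination
   numbers, geometric hydrogen-bond counts (donor–acceptor distance
   < 3.5 Å, angle < 40°), nearest/second-nearest water-hydrogen
   distances to the carbonyl O, and SHB/WHB frame classification.

Because no instrument or MD engine is attached, a first-class
synthetic-data module generates all three inputs with the statistical
structure the analysis assumes, so every stage is testable end to end.

## Worked example

```python
from chex2dir import (FTIRGenParams, ExchangeGenParams, SpectralWindow,
                      fit_ftir_series, simulate_ftir, simulate_2dir_series,
                      thermo_from_fits, extract_forward_kinetics)

# FTIR temperature series -> two-Voigt fits -> van't Hoff
params = FTIRGenParams()                      # 1607.8 / 1620.9 cm^-1 bands
spectra = simulate_ftir(params, [23, 33, 43, 53, 63, 73, 85])
fits = fit_ftir_series(spectra)
thermo = thermo_from_fits(fits, mu_shb=0.344, mu_whb=0.321)
print(f"dH = {thermo.dH:.2f} kJ/mol, dS = {thermo.dS:.2f} J/(mol K)")

# 2D IR waiting-time series -> cross-peak kinetics
series = simulate_2dir_series(ExchangeGenParams(tau_forward=0.53))
series.temperature = 23.0
kin = extract_forward_kinetics(
    series,
    norm_window=SpectralWindow(1605, 1610, 1592, 1597),
    cross_window=SpectralWindow.centered(1607.8, 1620.9, 5.0),
    dG=thermo.dG[0])
print(f"tau_forward = {kin.tau_forward:.3f} ps, "
      f"tau_reverse = {kin.tau_reverse:.3f} ps")
```

prints

```
dH = 6.22 kJ/mol, dS = 15.34 J/(mol K)
tau_forward = 0.530 ps, tau_reverse = 0.268 ps
```

i.e. the WHB state lies ΔG(23 °C) ≈ 1.68 kJ/mol above SHB, the forward
exchange takes ~0.53 ps and the reverse ~0.27 ps — the water molecule
rebinds about twice as fast as it leaves.

The full pipeline (simulate → fit → van't Hoff → exchange → Arrhenius)
is one call or one command:

```bash
chex2dir run --out out/          # writes out/report.json + run manifest
```

Other subcommands: `chex2dir simulate ftir|2dir|traj`, `fit-ftir`,
`vant-hoff`, `exchange-fit`, `arrhenius`, `hbond-stats`, `rdf`.

## Layout

```
src/chex2dir/
  constants.py    # R, Celsius->Kelvin convention
  types.py        # Spectrum1D, Spectrum2DSeries, Trajectory, results
  synthetic.py    # FTIR / 2D IR / trajectory generators
  ftir.py         # second derivative, Voigt profile, two-Voigt fit
  thermo.py       # K_eq, van't Hoff, Gibbs, dipole sensitivity
  exchange.py     # normalization, subtraction, cross-peak trace, fits
  hydration.py    # RDF, coordination, H-bonds, r1/r2, classification
  io.py           # text formats: spectra, 2D series, extended XYZ
  pipeline.py     # end-to-end orchestration + run manifest
  cli.py          # `chex2dir` command group
docs/methods.md   # model, conventions, parameter choices, limitations
```
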
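# Methods

## The two-state hydration model

A peptide-model amide carbonyl in water is treated as a two-state
system: SHB (two strong C=O···H–O water bonds) and WHB (one strong bond
plus one weak or broken second bond).  The states are spectroscopically
distinct amide-I oscillators — SHB at lower frequency (stronger
H-bonding red-shifts the C=O stretch), WHB ~13 cm⁻¹ higher — and they
interconvert:

    SHB  ⇌  WHB,    k₁ forward, k₋₁ reverse.

Three observables constrain the model:

* **Populations** (FTIR): each state contributes a Voigt sub-band whose
  integrated area is ∝ concentration × |μ|², with μ the amide-I
  transition dipole of that state.  Hence
  K_eq = (A_WHB·μ_SHB²)/(A_SHB·μ_WHB²).
* **Thermodynamics** (van't Hoff): ln K_eq = −ΔH/(RT) + ΔS/R, fitted by
  unweighted ordinary least squares on ln K_eq (a weighted option exists
  behind a flag but the default analysis carries no per-point errors).
  ΔG(T) = ΔH − TΔS; its standard error propagates the ΔH and ΔS SEs
  without their covariance unless a covariance is supplied.
* **Kinetics** (2D IR): cross peaks between the two diagonal bands grow
  during the waiting time; their growth rate, after the normalization
  protocol below, is assigned to k₁.  Detailed balance
  k₁ = k₋₁·e^(−ΔG/RT) supplies k₋₁.

All Boltzmann-type factors use the molar gas constant
R = 8.314462618 J mol⁻¹ K⁻¹ with molar energies (kJ/mol for ΔH and ΔG,
J/(mol·K) for ΔS); temperatures convert as K = °C + 273.15.  This
convention is pinned by a unit test: with ΔG(23 °C) = 1.68 kJ/mol and
τ_forward = 0.53 ps it reproduces a reverse time constant of 0.27 ps.

## FTIR stage

**Second derivative.** Savitzky–Golay local-polynomial filter, default
window 11 points and order 3 at 1 cm⁻¹ sampling.  Two local minima are
the evidence for two sub-bands and seed the fit initialization.  Edge
regions (half a window) are flagged in metadata and excluded from
minima detection.

**Two-Voigt fit.** Voigt profiles are evaluated through the Faddeeva
function (scipy), never a pseudo-Voigt approximation; profiles are
area-normalized so the fitted `area` parameter *is* the integrated
absorbance.  A constant baseline is fitted jointly (linear term behind a
flag).  Bounds: centers within ±10 cm⁻¹ of initialization, widths in
(0.1, 30) cm⁻¹ — this prevents component swapping and collapse.
Components are relabeled after every fit so SHB is always the
lower-frequency one.  Standard errors come from the least-squares
covariance.  A relative RMS residual above 2% of the peak absorbance
warns but does not fail.

**Temperature series.** The coolest spectrum is fitted with automatic
(second-derivative) initialization; each warmer spectrum is seeded with
the previous result.  This matters because the low-frequency band drifts
at ~0.07 cm⁻¹/°C while the high-frequency band moves more slowly, so the
split narrows from 13.1 cm⁻¹ at 23 °C to ~10 cm⁻¹ at 85 °C, below what
the second derivative resolves at these widths.

## 2D IR stage

**Generator.** Each population pathway i→j contributes a positive 2D
Gaussian at (ω_i(0→1), ω_j(0→1)) and a negative one displaced down the
probe axis by the anharmonicity Δ_anh (default 13 cm⁻¹, inferred from
the separation between the 0→1 position of the low-frequency band and
its 1→2 detection window; configurable).  With the default geometry the
SHB→WHB cross peak's 1→2 partner overlaps the WHB diagonal region —
deliberately not separated, since the extraction integrates windows.
Peak amplitudes are initial population × pathway weight × lifetime
damping.

*Pathway weights.* Two modes:

* **phenomenological** (default): diagonal weights stay at 1, cross
  weights grow as 1 − e^(−T_w/τ) with the forward (SHB→WHB) or reverse
  time constant.  This is the construction under which the extraction
  protocol's single-exponential fit recovers exactly the forward time
  constant — i.e. it encodes the standard assignment of the cross-peak
  growth rate to k₁.
* **master_equation**: weights are conditional probabilities
  P(j|i) = [e^(K·T_w)]_{ji} of the two-state rate matrix
  K = [[−k_f, k_r], [k_f, −k_r]] (closed form; columns sum to 1).  Its
  cross-peak growth eigenvalue is k_f + k_r, not k_f, so a
  single-exponential fit of this mode reads out the *relaxation* rate —
  the two modes intentionally diverge, and the rigorous mode exists to
  quantify that divergence.

*Lifetime damping.* e^(−T_w/T1) with the lifetime of the **pumped**
state (defaults T1 = 0.67 ps SHB, 0.72 ps WHB; orientational relaxation
is lumped into these single decays).  The pumped-state convention is
what the normalization step is built to cancel: the normalization
window shares its pumped state with the cross peak, so population decay
divides out of the normalized trace exactly, making the extracted
kinetics independent of the T1 values (a tested invariant).

*Lineshapes.* Separable Gaussians, σ = 3 cm⁻¹ on both axes (the source
measurements do not state 2D linewidths; this repository's choice keeps
the 5-cm⁻¹ integration windows single-pathway — at σ = 6 cm⁻¹
diagonal-tail leakage biases the fitted τ by ~7%).  An optional
diagonal-correlation parameter decaying with T_w models spectral
diffusion for the diagonal peaks; it is off by default because the
protocol integrates fixed windows, which preserves peak volume.

**Extraction protocol.** (1) divide each matrix by |∫ window| over a
diagonal 1→2 window of the low-frequency state (defaults
ω_τ 1605–1610, ω_t 1592–1597 cm⁻¹; fully configurable per temperature);
(2) subtract the T_w = 0 matrix; (3) integrate a 5×5 cm⁻¹ window
(≈25 cm⁻² area) centered at (pump = SHB 0→1, probe = WHB 0→1) — the
SHB→WHB pathway — with *signed* trapezoidal integration, while the
normalization uses the absolute magnitude; (4) fit
m(T_w) = A·(1 − e^(−T_w/τ)).  The default waiting-time grid is 0–3 ps in
0.1 ps steps (a repository choice; the sources do not list their grids).
Degenerate traces (e.g. constant nonzero) drive τ outside the resolvable
range and raise instead of returning a bound-struck value.

**Energetics.** Arrhenius: OLS of ln k against 1/T, Ea = −slope·R.
Reverse rates via detailed balance with ΔG in J/mol internally.  Note a
reproducibility subtlety established while validating: the reverse
activation energy computed from *unrounded* detailed-balance reverse
rates is ≈ Ea(forward) − ΔH ≈ 7.05 kJ/mol, whereas recomputing from the
reverse time constants at the two-decimal precision at which such values
are conventionally reported gives 7.49 kJ/mol — rounding 0.1643 ps to
0.16 ps at the hottest point dominates the difference.  The test suite
checks both chains at their own values.

## Trajectory stage

**Generator.** A single amide (OC, N, HN) at the center of a cubic
periodic box with water molecules (OW, HW, HW; rigid geometry, O–H
0.96 Å, 104.5°).  Atom pairs closer than 0.5 Å are rejected and
resampled.  Three placement modes:

* *uniform*: ideal gas, the g(r) = 1 reference;
* *designed_shell*: n waters each aim one H at the carbonyl O with the
  O···H distance ~ N(1.65, 0.08) Å truncated to (1.35, 2.45) Å — the
  lower cut keeps the molecule's second H outside 2.55 Å, so the shell
  holds *exactly* n hydrogens; bulk water O stays ≥ 3.7 Å out;
* *telegraph_hbond*: one water pinned at 1.65 Å; a tagged second water
  switches between 1.85 Å (bound) and 3.0 Å (unbound) via an exact
  continuous-time telegraph process (exponential holding times, started
  from stationarity, so the per-frame bound probability is exactly
  k_on/(k_on+k_off)).

H and D are treated identically throughout.

**Statistics.** RDF: minimum-image pair histogram normalized by the
ideal-gas shell count ρ·(4π/3)(r_hi³−r_lo³) per center per frame, ρ from
the box volume; cubic boxes only, non-periodic trajectories are rejected
for RDFs (no density).  Coordination number:
n(r_c) = ρ∫₀^{r_c} g(r)·4πr² dr by trapezoid, closed at r = 0.
H-bond criterion: donor–acceptor distance < 3.5 Å and angle < 40°.  The
angle is implemented by default as the deviation between the D→H and
D→A vectors (small = near-linear bond), the common reading of the
geometric criterion; the literal vertex angle at the proton is
selectable (`angle_convention="hydrogen"`), under which a 40° threshold
keeps only strongly bent geometries — published phrasings of this
criterion are ambiguous, so both are exposed.  Water hydrogens are
assigned to their donor oxygen by nearest-OW search, which also works on
externally supplied trajectories with arbitrary atom order.
SHB/WHB classification: a frame is SHB when the second-nearest water-H
distance r₂ < 2.55 Å (the first RDF valley, preferred over the midpoint
of the 1.85/3.0 Å modes because it is the physically meaningful shell
boundary); the SHB fraction carries a binomial standard error, which is
only valid when frames are sampled sparsely relative to the switching
correlation time 1/(k_on+k_off).

## What the generators do and do not emulate

The generators reproduce the *structure* the analysis assumes: two
Voigt sub-bands with van't Hoff-coupled areas and linear center drift;
2D peak pairs with growing cross peaks, lifetime decay and optional
spectral diffusion; shell-structured or telegraph-switching hydration.
They do **not** emulate: baseline drift and solvent subtraction
artifacts, Fermi resonances, non-Gaussian 2D lineshapes or
rephasing/nonrephasing pathway structure, finite pulse bandwidth,
heat-capacity curvature of the van't Hoff line, or force-field water
structure (the published MD-derived shell numbers — e.g. ~2.06 shell
hydrogens, ~1.39 mean C=O H-bonds, peak/valley at 1.65/2.55 Å — depend
on the simulation engine and are *not* reproduced by the toy
trajectories; the trajectory stage is validated on constructed
geometries instead).  Passing tests therefore demonstrate correctness of
the analysis pipeline, not instrument- or force-field-level realism.

Default FTIR widths are σ = γ = 3.0 cm⁻¹ (Voigt FWHM ≈ 10.8 cm⁻¹).
This is the widest scanned setting at which the second-derivative
evidence behaves cleanly: for FWHM ≳ 12 cm⁻¹ the curvature minimum of
the 2.26× weaker high-frequency band is displaced more than 1 cm⁻¹ from
its true center by overlap with the stronger band, and the two-minima
initialization degrades.  Experimental amide-I sub-bands are broader;
the narrower default trades lineshape realism for a generator whose
derivative-based detection is exact by construction, and all widths are
configurable.

## Numerical choices

* Seeds: a single root seed is split per stage with numpy
  `SeedSequence.spawn`; child seeds are reduced below 2³¹.  Identical
  parameters + seed give bit-identical outputs.
* Text I/O writes floats with 17 significant digits; all round trips
  are bit-exact (CSV parsing uses round-trip float precision).
* Normalization aborts if a window integral falls below 10⁻¹² of the
  matrix maximum, naming the offending waiting time.
* The exponential fit bounds τ to [10⁻⁴, 10²] × the waiting-time span
  and additionally rejects τ below 0.2× the grid resolution (the
  signature of a non-representable trace).
* `ThermoResult` self-checks ΔG = ΔH − TΔS to 10⁻⁹ kJ/mol on
  construction; `exchange_populations` columns sum to 1 at the 10⁻¹²
  level (property-tested).

## Known limitations

* Two components only; a third sub-band (aggregation, Fermi resonance)
  is out of scope and will bias the fit it is forced into.
* The phenomenological/master-equation divergence means a fitted τ from
  real data should be interpreted under an explicit kinetic model; the
  package reports which mode generated synthetic data in all manifests.
* RDFs assume cubic boxes and minimum-image distances; r_max ≤ L/2.
* Van't Hoff SEs are regression-scatter errors and do not include the
  per-temperature area-fit uncertainty (reported separately as area
  SEs).
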
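# Methods

## The kinetic models

`proofkin` models proofreading by T7 DNA polymerase as mass-action
reaction networks over explicit enzyme–DNA species. Concentrations are in
µM and time in s; unimolecular rate constants are s⁻¹ and bimolecular
constants µM⁻¹ s⁻¹ (the dCMP inhibition constant K_I is stored in mM and
converted on use). Three bundled mechanisms share one compiled mass-action
core (`proofkin.core`):

**ssDNA** (`build_ssdna_mechanism`, defaults in `data/table2.json`).
Single-stranded 27-mer DNA binds the exonuclease (exo) site in one
diffusion-limited step (k₁/k₋₁; K_d = k₋₁/k₁ ≈ 40 nM). Bound DNA is
shortened processively: a fast, reversible first chemistry step
(k₂ = 5000 s⁻¹, a locked lower limit; k₋₂) produces a complex that still
holds the excised dNMP, and product release (k₃ for the first base — a
dCMP for this substrate — then k₃,₂, k₃,₃ and a common 500 s⁻¹
afterwards) limits the observable rate of subsequent excisions. Released
dCMP rebinds the product complex (k₋₃) and also binds free enzyme as a
weak competitive inhibitor (on-rate locked at 100 µM⁻¹ s⁻¹, K_I in mM).
Digestion stops at a configurable minimum length (default 19 nt, the
shortest band the gel analysis tracks).

**3′-terminal mismatch duplex** (`build_mm3_mechanism`, `data/table3.json`).
The mismatched duplex binds the enzyme at three parallel sites — pol
(k₃/k₋₃), a partially melted intermediate (k₂/k₋₂), and exo (k₁/k₋₁) —
with the intermediate exchanging with the exo site (k₅/k₋₅). Without
dNTPs there is no pol→intermediate transfer; with dNTPs it opens at
k₄,act and the intermediate→exo step accelerates to k₅,act. Hydrolysis
(k₆, locked lower limit 5000 s⁻¹) removes the mismatched nucleotide, the
trimmed 26-mer returns to the pol site at k₇, and with dNTPs it is
extended by two bases at ≥300 s⁻¹ per nucleotide.

**Buried mismatch duplex** (`build_bmm_mechanism`, `data/table4.json`).
Same three-site binding topology, but pol↔intermediate transfer operates
without dNTPs (k₄/k₋₄, equilibrium ≈ 2). After the first excision the
dNMP stays in the exo site: release is rate-limiting and modeled as a
first-order opening of the product complex (k₈/k₋₈; k₈,act with dNTPs).
From the open state the complex either re-closes (k₋₈, 16,200 s⁻¹),
hydrolyzes the now-terminal mismatch (k₆) — the dominant outcome, at a
net rate k₈·k₆/(k₋₈+k₆) ≈ 1.2 s⁻¹ without dNTPs and ≈ 10 s⁻¹ with —
returns the 26-mer to the pol site (k₁₂, locked 60 s⁻¹), or dissociates
(k₉). Dissociated 26-mer is a 3′-mismatch substrate and rebinds with the
3′-mismatch association constants and the locked dissociation values
k₉/k₁₀/k₁₄. The second excision releases its dNMP fast (k₁₁, a lower
limit), the 25-mer returns to the pol site at k₇, and with dNTPs is
extended to 30 nt. 25-mer complexes are otherwise terminal: the gel data
pause at 25 nt, so no further excision of correctly paired bases is
modeled.

### Committed structural choices

Several aspects of the buried-mismatch scheme are not machine-readable
from the source diagrams and were committed here:

- **k₋₈ as a first-order re-closing.** The tabulated k₋₈ is in s⁻¹, so
  the k₈ step is an isomerization between a closed and an open product
  complex rather than bimolecular dNMP rebinding. To keep every reaction
  balanced in nucleotide units, the open complex still counts the
  displaced dNMP in its composition; free dNMP is emitted by whichever
  step exits the open state.
- **k₁₂ acts on the open complex.** Placing the 26-mer return on the
  dNMP-bound closed complex instead would cut the flux reaching the
  second excision to a few percent, contradicting the near-complete
  single-turnover double excision seen with a trap and dNTPs, and would
  leave k₇ essentially unconstrained by any experiment in the suite.
- **Site map.** k₁↔exo, k₂↔intermediate, k₃↔pol for both duplex tables:
  this is the unique assignment that reproduces the published 12/47/40 %
  association-flux shares from the tabulated on-rates.
- **dNTP "activation"** switches rate-constant values on existing steps
  (k₄,act, k₅,act, k₈,act) rather than adding explicit dNTP-binding
  species; the experiments used saturating (100 µM) dNTPs and no
  concentration dependence is modeled.
- **Mg²⁺ is not a species.** "+Mg²⁺" and "−Mg²⁺" are distinct mechanism
  variants (hydrolysis present/absent); no Mg-binding constants exist to
  model it explicitly. Phosphorothioate (hydrolysis-resistant) substrates
  use the hydrolysis-free variant with rate constants linked by symbol.

## Numerical integration

Networks compile once into index arrays driving a generic
numba-compiled mass-action right-hand side and analytic Jacobian;
`scipy.integrate.solve_ivp` (LSODA) integrates them. Rate constants span
~0.05 to 16,200 s⁻¹ (and the inhibitor off-rate reaches ~5×10⁵ s⁻¹), so
the system is stiff; reference tolerances are rtol 10⁻⁸ / atol 10⁻¹² µM,
relaxed to 10⁻⁶/10⁻¹⁰ inside fitting loops (self-convergence of reported
concentrations is verified at <10⁻⁶ relative). Concentrations in
(−10⁻¹⁰, 0) µM (or −100·atol if looser) are clipped to zero; anything
more negative raises. Enzyme, DNA, and nucleotide totals are conserved by
construction and checked to 10⁻⁶ relative along trajectories; primer
extension steps draw on the implicit saturating dNTP pool and are
explicitly exempted from the nucleotide total.

## Observables

- **Fluorescence (melting signal):** signal = a·Σ b_class·[species] over
  labeled DNA, with brightness classes free / low (pol-bound duplex) /
  mid (partially melted intermediate) / high (exo-bound, melted);
  b_high > b_mid > b_low is enforced. Default generator brightnesses are
  1.0/1.3/1.8/2.6 (the fluorescent cytosine analog brightens as its
  environment becomes single-stranded; the ssDNA substrate uses
  free = 1.0, bound = 2.6 for its FRET-type signal).
- **Anisotropy:** r(t) = (r_free·[free] + r_bound·[bound])/[total],
  assuming equal brightness of free and bound DNA (no quantum-yield data
  exist to weight them); defaults r_free = 0.05, r_bound = 0.15.
- **Primer-length tables:** per-length totals of free plus bound labeled
  DNA (quench gels cannot distinguish binding state), aggregated into the
  band series each protocol declares. Unlabeled trap DNA is invisible to
  all observables.

In every fit the scaling coefficients (a·b_class per fluorescence class,
or r_free/r_bound) are linear nuisance parameters and are profiled out
exactly by weighted linear least squares inside each residual evaluation
(variable projection). This is the joint optimum the optimizer would
reach anyway, with none of the extra nonlinear dimensions.

## Synthetic experiments

`proofkin.protocols` bundles 26 protocol files mirroring the study's
experiment classes at their reported final concentrations: stopped-flow
anisotropy binding (enzyme 100–400 nM vs 25–50 nM DNA), trap off-rate
(preincubated complex vs 10–20× unlabeled competitor), stirred-cuvette
equilibrium titrations, rapid-quench excision time courses (mixing or
Mg²⁺-start), and excision–extension experiments with trap and dNTPs.
Conventions:

- **Time grids.** Stopped-flow binding uses linear grids over ~5
  relaxation times; melting traces and quench experiments use log-spaced
  grids (from 1.5 ms and 1–2 ms respectively), the split/log timebase
  stopped-flow and quench instruments actually record — a linear 50 ms
  grid cannot see the ~60 s⁻¹ return-step relaxation that helps pin k₇.
- **Titrations** follow the stirred-cuvette protocol: 24 additions
  totalling 20.5 µl of titrant into 280 µl, cumulative dilution tracked
  per point. Because the titrant (enzyme) is the FRET donor, the raw
  signal carries an inverse-inner-filter inflation
  (1−10^(ε·E))/(−ln10·ε·E) with ε = 0.805 µM⁻¹; generation applies it and
  analysis divides it out. The bundled Kd fits (hyperbola, tight-binding
  quadratic) additionally undo the dilution; the global fit instead uses
  the exact per-point totals, which avoids the small depletion
  approximation entirely.
- **"+Mg²⁺-start" initialization** places bound DNA at the reported
  no-Mg²⁺ site occupancies (pol/int/exo = 34/57/8 % for the 3′ mismatch,
  27/64/9 % for the buried mismatch), remainder free. The tabulated
  (with-Mg²⁺) constants demonstrably do not reproduce those occupancies,
  so the reported numbers are taken as the initialization convention
  rather than re-derived.
- **Trap DNA** is an explicit unlabeled species competing for free
  enzyme with the substrate's own binding constants (binding only).
- **Noise:** i.i.d. Gaussian, 2 % of the trace's dynamic range for
  optical signals (titrations: 2 % of the raw range, applied on the raw
  scale) and 3 % of total DNA (absolute µM) for quench tables; seeded
  and bit-reproducible.

The generator emulates signal shapes and noise magnitude only. It does
not emulate instrument dead time (the first sample is simply 1.5–2 ms),
photobleaching or lamp drift, gel-quantification error structure
(correlated, signal-dependent), or pipetting errors in concentrations.
Passing recovery tests therefore demonstrate identifiability of the
mechanism under idealized data of realistic size and noise — not
robustness to systematic instrument artifacts.

## Global fitting

`GlobalFitProblem` minimizes χ² = Σ((y−ŷ)/σ)² across heterogeneous
datasets, σ per dataset as above (divided by √weight; multiplying all
weights by a constant provably leaves the argmin unchanged). Kinetic
parameters are optimized in log₁₀ space with box bounds
(`scipy.optimize.least_squares`, TRF, finite-difference step 10⁻³ in
log₁₀ to stay above integration noise). Status flags from the parameter
tables are respected: `locked` and `lower-limit` entries never move
(chemistry rates k₂/k₆ = 5000 s⁻¹ are lower limits and stay locked, as do
the tabulated locked dissociations), `upper-limit` entries float below
their bound (buried-mismatch k₃ ≤ 6.66 µM⁻¹ s⁻¹). Parameters not
referenced by any dataset's mechanism are excluded from the fit rather
than left to drift. Near-zero-curvature directions are reported on the
result (`unidentifiable`), and integration failures during a trial step
return a large finite residual instead of crashing the optimizer.

Recovery experiments (`recovery_experiment`) generate a full suite per
seed, start each fit from the truth jittered uniformly by up to ±0.15
decades per parameter (≈ ×/÷1.4), and record every fit, converged or
not. Known identifiability limits under the committed topology: the
buried-mismatch pair k₈/k₋₈ is a near-ridge (the data pin the
combination k₈·k₆/(k₋₈+k₆)), and k₁₃ carries almost no flux, so those
entries scatter widely across seeds while the graded constants (k₁, k₋₁,
k₃ for ssDNA; k₇ for both duplexes) recover to within a few percent in
the median.

## Confidence contours and flux shares

Profiles clamp one parameter on a log-spaced grid (15 points per side
over ±0.5 decade by default, expanded until the threshold is crossed or
bounds are hit) and re-minimize all remaining free parameters from the
best fit. The 95 % threshold on the χ²-ratio is
1 + p/(n−p)·F⁻¹(0.95; p, n−p). Threshold crossings are interpolated with
a local quadratic in log₁₀(value): the profile is locally parabolic, and
a straight chord between coarse grid points systematically narrows the
interval. Intervals are one-sided when no crossing exists within the
parameter's bounds — the ssDNA chemistry rate k₂, profiled with its
linked partners floating, shows exactly this lower-limit-only behavior.

Binding-flux shares integrate the gross (one-way) forward association
flux k_site·[E][D] of each tagged binding step from mixing until 99.9 %
of the DNA has bound or reacted, then normalize. Gross—not net—flux is
the metric that reproduces the published 12/47/40 % partition for the 3′
mismatch; shares are invariant to enzyme concentration in the
excess-enzyme regime and always sum to 1. For the buried mismatch the
same identity gives ≈0.7/71/28 % (pol/int/exo), which does not match the
published 2/64/34 % for that substrate; the discrepancy is documented
rather than patched, and no buried-mismatch flux number is asserted.

## Known limitations

- The simulated Mg²⁺-start melting relaxation of the preincubated
  3′-mismatch complex has a dominant-phase rate of ≈6.0 s⁻¹ under the
  tabulated constants, not the 7.24 s⁻¹ obtained by equation-based
  fitting of the original instrument data. The difference is structural:
  with ~60 nM free enzyme, DNA dissociating from the intermediate site
  (k₋₂ = 2.44 s⁻¹) rebinds within ~20 ms and ~48 % re-enters the
  intermediate pool, slowing the apparent transfer-limited decay below
  k₅+k₋₂ = 7.31 s⁻¹; deleting rebinding raises the simulated fast phase
  to ≈7.7 s⁻¹. The same constants reproduce the published off-rate
  biexponential exactly (1.15/0.23 s⁻¹ with 65 % fast amplitude), so the
  constants and site map are implemented as tabulated; the residual gap
  between the published conventional fit and the model-generated trace
  is inherited, not introduced.
- Exponential, quadratic and hyperbolic fits are descriptive tools;
  multi-exponential fits of multi-step kinetics are biased when phases
  overlap, which is precisely why the package's primary estimator is the
  global fit.
- Problem sizes: suites use 2 binding traces (40 points), one off-rate
  and one or two melting traces (50–60 points), a 24-point titration and
  2–3 quench tables (13–14 times × 2–4 bands); recoveries use 10 seeds.
  These match the information content of the original experiments while
  keeping a full three-suite recovery run in a few minutes on one core.
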
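# Methods

## Models and assumptions

### Steady-state rate laws

All kinetic analysis assumes single-substrate Michaelis-Menten kinetics in
the initial-rate regime with rapid-equilibrium reversible inhibition:

- competitive: v = Vmax·S / (Km(1 + I/Ki) + S)
- noncompetitive: v = Vmax·S / ((Km + S)(1 + I/Ki))
- uncompetitive: v = Vmax·S / (Km + S(1 + I/Ki))
- mixed: v = Vmax·S / (Km(1 + I/Ki) + S(1 + I/(αKi)))

Noncompetitive is the α = 1 special case of mixed and competitive the
α → ∞ limit, so the 4-parameter mixed law nests every 3-parameter law.
Progress curves are treated as linear over the 20-min read (no substrate
depletion); velocity scales linearly with enzyme load relative to the
0.02 unit/mL reference.

### Slow binding

Preincubation decay follows the single-step slow-binding model with no
steady-state plateau: v/v₀ = exp(−K_obs·t), K_obs = k₄(1 + [I]/K_iᵃᵖᵖ),
K_iᵃᵖᵖ = k₄/k₃. K_obs is fitted per inhibitor level by nonlinear least
squares constrained to K_obs ≥ 0; k₄ and k₃ are the intercept and slope of
the K_obs-vs-[I] line (weighted by 1/SE² when K_obs standard errors are
available, OLS otherwise), and K_iᵃᵖᵖ is derived as k₄/k₃ so the three
reported constants are mutually consistent by construction rather than
fitted independently.

All slow-binding computation uses minutes (k₃ in µM⁻¹·min⁻¹, k₄ in min⁻¹).
Published tables sometimes label the slope constant in s⁻¹ while the
intercept is min⁻¹; the ratio k₄/k₃ is only a concentration if both share a
time unit, so results carry an explicit unit note instead of silently
rescaling.

### Quenching

Titration spectra are reduced to peak intensities (scan maximum). The
Stern-Volmer constant is the through-origin slope of (F₀/F − 1) vs [Q]; the
double-log regression of log₁₀[(F₀−F)/F] on log₁₀[Q] gives log₁₀K_A
(intercept) and n (slope). Base-10 logarithms are fixed and documented
because intercept and slope are only jointly base-invariant. Free quencher
is approximated by total quencher: the enzyme is at trace concentration
(0.02 unit/mL), so ligand depletion by binding is negligible. K_A's formal
unit is µM⁻ⁿ; the 10⁶ µM⁻¹ → L·mol⁻¹ factor is applied as if n = 1 for the
conventional reporting scale, and the result objects say so.

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| Km | µM | 100 | MUNANA under the standard assay conditions |
| read schedule | min | 0–20 by 1 | plate-reader kinetic mode |
| substrate levels | ×Km | 0.5, 1, 2 | double-reciprocal design |
| inhibitor levels | ×IC50 | 0, 0.5, 1, 2 | Dixon design plus control |
| enzyme levels | unit/mL | 0.01, 0.02, 0.04 | reversibility dilution series |
| preincubation | min | 0–10 by 2 | slow-binding K_obs series |
| quencher levels | µM | 0, 0.2 … 3.2 doublings | emission titration |
| noise cv | — | 0.02 | typical plate-reader repeatability |
| replicates | — | 3 | triplicate measurement convention |
| linearity r² | — | 0.98 | velocity-window acceptance |
| mode score margin | AICc units | 2 | "substantial support" convention |
| mixed-law F-test α | — | 0.01 | see below |
| intercept z threshold | — | 2 | reversibility verdict |

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design faithfully — linear progress
curves with the mode-specific inhibited rate, logistic dose-response,
velocity-vs-enzyme lines through the origin, exponential preincubation
decay, and Gaussian emission bands (centre 340 nm, width 18 nm) whose peak
follows the chosen quenching model — with multiplicative Gaussian noise of
stated CV and one seed governing all draws (identical inputs give
bit-identical output).

It does **not** emulate: substrate depletion or product inhibition
(progress curves never curve), pipetting-level systematic errors or plate
edge effects, inner-filter effects or background fluorescence in the
quench spectra, or tight-binding depletion of free inhibitor. Passing
recovery tests therefore demonstrate estimator correctness under the
stated noise model, not robustness to every artifact of real plate data.
The Stern-Volmer and double-log quenching models coincide only at n = 1, so
a single synthetic titration is generated from one model at a time and can
only be expected to recover that model's parameters.

## Numerical choices

- **Model selection.** Candidate rate laws are compared by AICc computed
  from the (weighted) residual sum of squares. RSS below numerical
  precision (relative 1e-8 of the response RMS) is floored so that exact
  fits of nested laws tie and the parameter penalty decides. Candidates
  within 2 AICc of the best are resolved by the fewest-assumption order
  competitive > noncompetitive > uncompetitive > mixed.
- **Mixed-law guard.** Because mixed nests all three simpler laws, AICc
  alone accepts it too often on small grids: on the 3×4 design at 2% CV it
  misclassified noncompetitive data as mixed in ~8% of replicates. A mixed
  verdict is therefore retained only when it beats the best 3-parameter law
  by an extra-sum-of-squares F-test at α = 0.01; otherwise the nested law
  is reported. With the guard, all four generating mechanisms are
  recovered in ≥ 98% of noisy replicates while noiseless behaviour is
  unchanged.
- **Reciprocal-space weights.** Under constant-CV noise, sd(1/v) ∝ 1/v, so
  Lineweaver-Burk and Dixon regressions weight points by v² (an unweighted
  option is retained). Noiseless geometry is unaffected.
- **Dixon Ki.** Ki = −median of all pairwise line-intersection
  x-coordinates; pairs with indistinguishable slopes are skipped and a
  fully parallel family (the uncompetitive signature) raises an error
  directing to the global fit.
- **Degenerate inputs.** A grid whose inhibited velocities equal the
  control at every substrate level is flagged `mode="none"` with Ki = ∞
  rather than fitted. A flat v/v₀ series returns K_obs = 0; an increasing
  one is flagged with K_obs = 0 instead of a negative rate. Exact-fit
  regressions report r² = 1 and, in the reversibility test, an intercept
  with zero residual error is scored z = 0 when it is numerically zero and
  z = ∞ otherwise.
- **IC50 fitting.** The logistic is fitted on log₁₀ concentration for
  stability; zero-concentration wells are controls, never fit points;
  replicates are averaged to means first (pooled fitting is an option);
  data not bracketing 50% inhibition raise an unreliable-fit error. The
  confidence interval comes from the covariance of log₁₀IC50.

## Problem sizes

Stochastic recovery checks use 200 seeded repetitions of the study design
(triplicate, cv = 0.02); the test suite uses 50–100 repetitions for the
slower checks and the acceptance script the full 200. These sizes put the
median-recovery Monte-Carlo error well below the 10% acceptance bands.

## Known limitations

- Tight-binding inhibitors (Ki comparable to enzyme concentration) need the
  Morrison quadratic, which is out of scope; Ki estimates assume free ≈
  total inhibitor.
- The slow-binding model is single-step; a two-step induced-fit mechanism
  (hyperbolic K_obs vs [I]) would be misread as a poor linear fit.
- Dose-response is the two-parameter logistic only: partial or biphasic
  inhibition is not modelled.
- The quenching analysis does not separate static from dynamic quenching
  (no temperature series) and applies no inner-filter correction.
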
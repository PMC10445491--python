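# bnakinetics

Analysis toolkit for characterizing enzyme inhibitors from fluorometric
plate-reader assays, built around the workflow used to profile bacterial
neuraminidase (BNA, EC 3.2.1.18) inhibitors with the fluorogenic substrate
MUNANA: dose-response potency, inhibition mechanism, reversibility,
slow-binding kinetics, and binding affinity by intrinsic-fluorescence
quenching. A synthetic assay generator with known ground truth makes every
estimator verifiable by parameter recovery, so the whole pipeline is tested
without any external data.

## What it computes

**Initial velocities.** Each well's progress curve (RFU vs time, 1-min
reads over 20 min) is reduced to an ordinary-least-squares slope over its
linear window; the window shrinks from the end until r² ≥ 0.98.

**IC50.** Fractional inhibition is (v₀ − vᵢ)/v₀ against the uninhibited
control, fitted with a two-parameter logistic on log concentration,

  inhibition(c) = cʰ / (cʰ + IC50ʰ),

bottom and top fixed at 0 and 1 (the ratio is already normalized).

**Inhibition mode and Ki.** Velocities on a substrate × inhibitor grid
(0.5×/1×/2× Km by 0/0.5×/1×/2× IC50) are fitted globally with the four
classical rate laws — competitive, noncompetitive, uncompetitive, mixed —
and the mechanism is selected by small-sample-corrected AIC with an
extra-sum-of-squares F-test guard against overfitting the mixed law.
Lineweaver-Burk (1/v vs 1/[S]) and Dixon (1/v vs [I]) geometry are reported
as cross-checks; the Dixon intersection abscissa gives −Ki.

**Reversibility.** Velocity vs enzyme concentration at each inhibitor
level: straight lines through the origin indicate a reversible inhibitor;
intercepts are tested against zero (|z| < 2).

**Slow binding.** Preincubating enzyme with inhibitor depletes activity as
v/v₀ = exp(−K_obs·t); K_obs is linear in inhibitor, K_obs = k₄(1 +
[I]/K_iᵃᵖᵖ), so the K_obs-vs-[I] line yields k₄ (intercept), k₃ (slope) and
K_iᵃᵖᵖ = k₄/k₃.

**Binding affinity.** Quenching of the enzyme's tryptophan emission (peak
near 340 nm) is analyzed by Stern-Volmer, F₀/F = 1 + K_SV[Q], and by the
double-log form log[(F₀−F)/F] = log K_A + n·log[Q], giving the affinity
constant K_A and binding-site number n.

All concentrations are µM internally; 1 µM⁻¹ = 10⁶ L·mol⁻¹ for reporting.

## Worked example

Simulate a two-compound study (a potent competitive slow-binder and a
weaker noncompetitive inhibitor) and analyze it end to end:

```sh
bnakin simulate --cv 0 --replicates 1 --seed 3 --out-dir sim
bnakin report --kinetics sim/kinetics.csv --quench sim/quench.csv --out-dir res
```

`res/ic50.csv`:

```
compound,ic50_uM,ic50_ci_low,ic50_ci_high,hill,r2,n_points
cpdA,0.38,0.38,0.38,1,1,8
cpdB,3.8,3.8,3.8,1,1,8
```

`res/mode.csv` (abridged): `cpdA,competitive,0.17,...` and
`cpdB,noncompetitive,4.2,...` — the generating mechanism and Ki (µM) are
recovered exactly from noiseless data, and the Dixon cross-check column
`ki_dixon_uM` agrees.

`res/slow_binding.csv` reports `k3_per_uM_min=0.141`, `k4_per_min=0.0203`
and `ki_app_uM=0.1439716312` for cpdA: the association and dissociation
rate constants of the enzyme-inhibitor complex and their ratio k₄/k₃, the
apparent inhibition constant.

`res/quenching.csv` reports `ka_1e6_L_per_mol=0.24434` and `n=1.2897` for
cpdA: a strong binder with slightly more than one site, versus
`0.05545`/`0.7819` for cpdB — affinity tracks inhibitory potency.

With `--cv 0.02 --replicates 3` (the default triplicate noise model) the
same run recovers each truth to within a few percent.

The same analyses are available per stage (`bnakin ic50`, `bnakin mode`,
`bnakin slowbind`, `bnakin quench`, each with optional plots) and as plain
library calls (`fit_ic50`, `fit_global_inhibition`, `analyze_preincubation`,
`analyze_quenching`, ...). Input CSV columns are frozen as
`experiment_id, replicate, time_min, rfu, substrate_uM, inhibitor_uM,
enzyme_u_per_mL, preincubation_min` (kinetics, with experiment ids
`<compound>:<stage>` for stages dose/grid/reversibility/slowbinding) and
`compound, quencher_uM, wavelength_nm, replicate, intensity` (spectra).

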
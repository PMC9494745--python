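# Methods

## Equilibrium speciation model

The speciation problem is posed as a classical tableau: seven components —
Hg²⁺, CH₃Hg⁺, H⁺, Cl⁻, HS⁻, DOM thiolate (RS⁻) and H₂O — and 24 species
formed from them by mass action (`log c = log K + Σ ν log a`). H⁺, Cl⁻ and
H₂O are *fixed* components (pH 7.3, 90 mM free Cl⁻, unit water activity by
default, brackish Baltic conditions); Hg²⁺, CH₃Hg⁺, total S(−II) carried on
HS⁻, and thiol sites carried on RS⁻ are *total* components whose mass
balances must close. Thiol-site concentration is estimated from DOC as
0.15 % of carbon on a molar basis (0.0015 × DOC / 12.011 g mol⁻¹). Activity
coefficients are unity: the shipped constants are taken as conditioned to
the model's ionic strength; an ionic-strength correction would be a
config-level change to the tableau, not code.

Assumptions: equilibrium is attained at each depth (no redox or
precipitation kinetics); nanoparticulate HgS clusters and adsorption to
Fe(III)-oxyhydroxide particles are outside the model; inorganic Hg(II) is
computed upstream as HgT − MeHg.

### Shipped constants

`data/tableau_baltic_v1.yaml` is the versioned source of truth. It is this
package's transcription of the published Hg/MeHg–sulfide–thiol–chloride
equilibrium model family for sulfidic natural waters. Three anchors pin the
behaviour that matters here:

* Hg(SH)₂ log β = 37.71 (literature value);
* the deprotonation steps within the dissolved Hg–sulfide triplet are set
  at pKa₁ = 6.37 and pKa₂ = 8.71, the values implied by the 86.5/10.1/3.4 %
  (HgS₂H⁻/Hg(SH)₂/HgS₂²⁻) distribution of that pool at pH 7.3 reported for
  the source model — since all three species bind two sulfides, their
  relative shares depend only on pH, so this distribution identifies the
  two constants exactly;
* metacinnabar log K = 36.60 and Hg(SR)₂ log β = 41.20, within literature
  ranges, chosen so the dominance sequence thiol-bound → HgS(s) →
  dissolved-sulfide switches near 0.003 and 0.25 μM H₂S for picomolar
  Hg(II) and ~4 mg C/L DOC, the regime structure the source model reports.

MeHg, chloride, hydroxide and minor-species constants are standard
literature values; they shape the MeHg ledger and the trace pools but not
the availability metric. Any deviation from a specific published table is
owned by this file.

### Solver numerics

Newton iteration on log₁₀ free concentrations of the active total-mode
components, with an analytic Jacobian, a 3-log-unit step clip, and a
halving backtracking line search on the residual max-norm. Convergence at
max relative mass-balance residual < 1e-11 (comfortably inside the 1e-8
contract); at most 200 iterations; a deterministic multi-start (free/total
dilutions 1e-6, 1e-2, 1e-10) before a solve is declared non-converged — a
non-converged result is returned flagged, never raised or silently used.
Log-space iteration is what makes the ~12-order span between fM Hg and mM
Cl⁻ tractable.

The solid is handled in two stages: solve aqueous-only; if the metacinnabar
saturation index (log IAP/K) is positive, re-solve with the solid's amount
as an extra unknown and its saturation index pinned at zero; if the solved
amount is negative the solid is dropped. Either the solid is present at
saturation or absent and undersaturated (complementarity, tested).

Degenerate inputs: a zero total removes that component and zeroes every
species formed from it (an all-zero Hg input is a valid result with empty
Hg fractions); zero total Hg(II) makes the dissolved-sulfide fraction 0 by
convention. Regime dominance is the largest summed pool fraction;
crossovers are located by log-linear interpolation between bracketing grid
points (linear when the bracket starts at zero H₂S).

## Tracer kinetics

`k_meth` is the unweighted OLS slope of Me¹⁹⁹Hg (fM) versus time divided by
the ¹⁹⁹Hg(II) spike (pM → fM) — division by the spike is the only
unit-consistent reading of a slope reported in h⁻¹. `k_demeth` is minus the
OLS slope of ln(Me²⁰¹Hg/Me²⁰¹Hg₀) versus time. Both regressions keep a free
intercept (forcing zero is not assumed), and a rate is *detectable* only if
the slope's two-tailed t-test gives p < 0.05; perfectly flat series get
p = 1 by convention. No correction is applied for simultaneous
demethylation of freshly formed Me¹⁹⁹Hg during the 24 h incubation.

Detection limits: the typical `k_meth` limit is 3 × SD of the t = 0
Me¹⁹⁹Hg replicates over (spike × t_max), i.e. the smallest slope
resolvable above the noise floor across the incubation (≈ 0.016 × 10⁻³ h⁻¹
for a ~33 fM SD, 260 pM spike, 24 h). The `k_demeth` limit uses the
first-order form −ln(1 − f)/T for a fractional decrease f over duration T
(0.10 over 24 h → 4.39 × 10⁻³, i.e. 4 × 10⁻³ at one significant figure);
the linear form f/T rounds to the same figure, and the first-order form is
the one consistent with the estimator.

A precision caveat worth stating: at k_demeth ≈ 5 × 10⁻³ h⁻¹ the tracer
only decays ~12 % in 24 h, so with 4 % point noise the analytic OLS
slope SE puts the median relative error near 30 % — the estimator is
unbiased but individual estimates at such slow decays are coarse. The test
suite asserts the analytically predicted precision rather than an
unattainable one, and asserts < 10 % median error where the design resolves
the decay (k_meth at 1.47 × 10⁻³, or fast demethylation).

Blank handling: HgT is corrected by the field-minus-lab blank difference
(0.36 − 0.25 = 0.11 pM) and MeHg by half the 49 fM LOD, both floored at
zero. The pipeline applies these only on request
(`apply_blank_correction=True`): synthetic profiles emulate already
blank-corrected (reported) concentrations.

## Coverage normalization and expression categories

Normalized abundance is coverage (reads/bp) divided by the mean coverage of
all gyrB-annotated sequences in the *same sample and molecule pool* — genes
and transcripts are normalized separately, since metagenome and
metatranscriptome sequencing depths are unrelated, and a per-sample (not
global) mean is used so the statistic is self-contained per sample. Samples
lacking gyrB are flagged undefined rather than set to 0 or ∞. Per-MAG
expression is categorized against gyrB with an absolute coverage-difference
threshold of 0.005: |Δ| < 0.005 similar, Δ ≥ 0.005 higher, Δ ≤ −0.005
lower.

## Statistics

Spearman's ρ uses average ranks on ties and a two-tailed t-approximation
(n > 3); ρ² is reported alongside ρ. Constant vectors give a flagged
undefined result. PLS models use one component (only two predictors) with
mean-centering and unit-variance scaling, the standard practice; the
extraction is NIPALS (via scikit-learn), and with a single response the
first weight vector is proportional to Xᵀy, which is what the independent
eigen-oracle in the tests exploits. q² is computed by explicit leave-one-out
refits; TSS is about the full-sample mean, so q² ≤ r² and can be negative.

Non-detect k_meth values are substituted at half the typical detection
limit (0.008 × 10⁻³ h⁻¹) before rank statistics and PLS: ranks are
insensitive to the exact value provided it lies below every detect, which
the tests verify, and the substitution is explicit, never silent. No
multiple-testing correction is applied across the battery.

## Synthetic stations

Two presets mirror the contrast between a sharp redoxcline (BY32-like:
chemocline ~72 m, sigmoid width 1.8 m, H₂S to 35 μM at 204 m, 11 depths)
and an extended one (BY15-like: width 22 m, euxinia from ~150 m, H₂S to
100 μM at 240 m, 12 depths). O₂ declines as a logistic sigmoid; H₂S rises
below its onset as a square-root ramp; zones follow the O₂/H₂S rule above.
Per-zone draws keep HgT in 300–640 fM (normoxic) rising to the
1400–2600 fM range (euxinic), MeHg from 20–48 fM to 1000–1300 fM, and
MeHg/HgT in the <17 %, 21–60 %, 50–90 % zone bands. In the euxinic zone
HgT is derived as MeHg/ratio because the three band constraints are not
jointly satisfiable as independent draws; the ~4× normoxic→euxinic HgT
increase is preserved. True rate-constant profiles default to the
deep-basin study conditions (k_meth from below detection in normoxic water
to 1.47 × 10⁻³ h⁻¹ at the BY32-like bottom; 1.20 × 10⁻³ h⁻¹ only at the
deepest BY15-like depth; k_demeth 7.6 and 5.1 × 10⁻³ h⁻¹ there).

Incubation noise is multiplicative at 4 % RSD (the field-replicate figure
for MeHg); the t = 0 Me¹⁹⁹Hg noise floor has SD 33.3 fM at that default and
scales linearly with the RSD so noise-free configs are exactly
linear/exponential and estimators recover truth to machine precision.
Coverage tables carry three gyrB sequences per sample/pool, hgcA/hgcB
abundance scaling ~0.004/0.12/0.5 (normalized units) across
normoxic/transition/euxinic with lognormal noise, ten MAG bins in euxinic
samples carrying 44 % (hgcA) and 59 % (hgcB) of transcript abundance, and
metabolic-capacity transcripts for expression profiling. All draws are
governed by the config seed (station name folded into the entropy so
stations sharing a seed stay independent); identical configs regenerate
bit-identical datasets.

What the generator does *not* emulate: hydrodynamic intrusions and mixing,
DOM compositional variation, sampling/analytical bias structure beyond the
single RSD, taxon-level ecological dynamics, or blank contamination
offsets. Passing end-to-end tests therefore demonstrates internal
consistency of the method chain under the stated noise model, not field
validity of any particular correlation strength.

## Problem sizes

Unit and property tests run toy tableaus with closed-form/bracketing
oracles, 60–1000 random speciation inputs (~10 ms per solve), 200–1000
Monte-Carlo seeds for estimator properties, and two-station end-to-end runs
(23 depths, 12 molecular samples). The acceptance script uses 200 replicate
incubations per deep-water rate constant and a 60-point H₂S grid for the
regime scan; a full run takes a few seconds on one core.

## Known limitations

* The tableau's minor-species constants are literature-typical but not
  tied to a specific supplementary table; the availability metric is
  robust to them, the absolute MeHg speciation less so.
* The joint statistics on n = 12 synthetic molecular samples have wide
  sampling variability in r²/q²; they demonstrate the machinery, not
  effect sizes.
* One solid phase is supported (metacinnabar); multi-solid assemblages
  would need a generalization of the two-stage algorithm.
* Rank-based handling of non-detects assumes all non-detects are genuinely
  below every detect; heavily censored datasets would warrant survival
  methods instead.
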
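# Methods

This note documents the models implemented in `dielpond`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the package's numerical conventions.

## Light attenuation

The diffuse attenuation coefficient K_d (cm⁻¹) is estimated from a
depth-resolved PAR profile by ordinary least squares on the linearised
Beer–Lambert law, ln E_d(z) = ln E_d(0) − K_d·z. Log-space OLS is the
standard estimator for short profiles: it is closed-form, stable, and
unbiased under multiplicative (lognormal) sensor noise, which is the noise
model appropriate for irradiance sensors. A nonlinear least-squares refit
of the exponential form is available (`fit_kd(..., nonlinear=True)`) for
profiles with additive error; on clean data the two agree to numerical
precision.

Units are centimetres throughout: in a 15–20 cm pond with K_d of order
0.3 cm⁻¹, metre-based conventions would put all the action in the third
decimal place. The surface reference is the reading just below the water
surface, treated as z = 0. Non-positive irradiance readings are dropped
with a warning before fitting; a fit requires at least three surviving
points (a package choice — with fewer points the standard error is
undefined). A perfectly constant profile is reported as K_d = 0 with
r² = 1 (zero-slope model fits exactly; the conventional r² is 0/0 there).

## PAM indices and the diel summary

Yield II = (F_m′ − F)/F_m′, F_v/F_m = (F_m − F_o)/F_m, and
rETR = Yield II × incident E-PAR with no absorptance factor (the "relative"
convention; absolute ETR would need the mat's absorptance, which is not
measured). Records where instrument noise produces F > F_m′ would yield
negative quantum yields; they are retained in the table with
`qc_valid = False` and excluded from all summaries, so one bad saturating
pulse cannot corrupt a diel statistic.

The diel summary uses a noon window of 11:00–15:00 local time by default
(configurable), the interval in which midday minima are expected at this
latitude. Midday depression is 1 − min(F_v/F_m in window)/max(F_v/F_m
before window); recovery is the last afternoon value over the pre-noon
maximum. If no dark-adapted readings exist the summary falls back to
Yield II and flags that it did.

## Gas solubility, headspace inversion, saturation, fluxes

Solubilities (mol L⁻¹ atm⁻¹) use the standard oceanographic ln-polynomial
in T and S: Weiss (1974) for CO₂, Weiss & Price (1980) for N₂O, and the
Wiesenburg & Guinasso (1979) Bunsen coefficient divided by 22.414 L mol⁻¹
for CH₄. The implementation is checked in the tests against an independent
re-evaluation of the published coefficients and against the qualitative
constraints (solubility falls with temperature and salinity). Inputs
outside T ∈ [−2, 40] °C or S ∈ [0, 40] are flagged as extrapolations.

The headspace inversion is a two-compartment mass balance at equilibration
temperature: moles in the headspace by the ideal gas law at the measured
mole fraction and vial pressure, plus residual dissolved moles by Henry's
law, referenced to the original water volume (vial − headspace). It is
exactly linear in the measured mole fraction, and the forward partitioning
used by the generator is its algebraic inverse (round-trip tested to 1e−6
relative across the full T/S/headspace-fraction grid).

Percent saturation compares the dissolved concentration with
K(T,S) · x_atm · P_ambient. **The ambient pressure default is 0.64 atm**,
appropriate for >3800 m a.s.l.; at 1 atm every equilibrium concentration
would be overstated by ~56%, flipping N₂O's classification. Whether a given
field study applied this correction is often unstated, so the parameter is
explicit and prominent. Atmospheric mole fractions default to modern global
means (CO₂ 420 ppm, CH₄ 1.9 ppm, N₂O 0.335 ppm), configurable.

A caveat for CO₂: at pond pH above 9, dissolved CO₂ is a small and
pH-sensitive fraction of the carbonate system; the package reports CO₂ as
measured without carbonate speciation, so CO₂ saturation should be
interpreted cautiously.

Chamber fluxes are the OLS slope of mole fraction vs time converted with
the ideal-gas molar density P/(RT), chamber volume and area, to
µmol m⁻² h⁻¹ (positive = emission). Classification is by the slope's
t-test at α = 0.05: 'no-trend' when the slope is indistinguishable from
zero, otherwise 'accumulation'/'loss' by sign. An exactly constant series
(zero residual variance) is defined as no-trend. Exponential saturation
fitting of long deployments is out of scope; the deployments this targets
are 80-minute, 5-point series where linearity is adequate.

## Nitrification partitioning and its uncertainty

Endpoint rates are (final − initial)/duration; no intermediate timepoints
are assumed. The partition subtracts the uninhibited control from each
inhibitor combination: azide+GC7 (archaea suppressed) estimates the AOB
contribution, azide+ATU (bacteria suppressed) the AOA contribution, and
azide alone the azide-sensitive "other processes" term, which may be
negative (net nitrite consumption) and is reported as-is.

These difference equations are *operational* definitions, not the output of
a mechanistic mass-balance: no "sum of surviving processes" model makes all
three differences simultaneously equal the underlying process rates (azide
alone, for instance, would expose nitrification as well as block sinks).
The synthetic generator therefore adopts the design's own operating
assumption explicitly: each inhibitor combination reveals one rate
component on top of the control baseline,

    R(T) = R_control + M[T, aob]·r_aob + M[T, aoa]·r_aoa + M[T, other]·r_other

with the ideal reveal matrix M mapping azide+GC7→AOB, azide+ATU→AOA,
azide→other. Efficacy parameters perturb M mechanistically: e.g. partial
ATU cross-inhibition of archaea (e_atu_aoa > 0) shrinks the AOA signal of
the azide+ATU flasks, quantifying how imperfect inhibition biases the
partition. Under ideal efficacies and zero noise the partition recovers the
configured truth exactly — the identity the design assumes. Inhibitor doses
(ATU 84 mM, GC7 0.4 µM, azide 34 µM) are carried as metadata only.

Uncertainty convention: the per-treatment spread is the replicate SD for
n > 2 and the half-range for duplicates (which equals the standard error of
a duplicate mean); differences combine the two operand spreads in
quadrature into `se`. Because a ±1·se band around a duplicate-based
difference covers the truth only ~55–60% of the time regardless of the
noise level, the package also reports `u95`, a 95% expanded uncertainty
using a Welch–Satterthwaite t multiplier on the quadrature SE. `u95` is the
package's stated uncertainty for a partitioned rate; Monte-Carlo checks in
the test suite confirm its coverage (~95–96% per component at the default
duplicate design).

## Statistics

`compare_groups` runs Shapiro–Wilk on pooled within-group residuals
(centring removes group-mean differences that would otherwise masquerade as
non-normality) and median-centred Levene (Brown–Forsythe, the robust
variant); both must pass at α = 0.05 for the ANOVA path, otherwise
Kruskal–Wallis. Constant data make the assumption tests undefined and fall
through to the nonparametric path with a flag; fully identical data report
p = 1. Note that duplicate-sized groups (n = 2 per group) make
median-centred Levene degenerate (within-group deviations have zero
variance), so tiny incubation designs route to Kruskal–Wallis — the
conservative branch. The composite procedure's type-I error on Gaussian
nulls is verified at ~0.05 by simulation in the tests. No multiple-testing
correction is applied by default (matching single-screen field usage);
Benjamini–Hochberg is available as a flag on the correlation screen.

`spearman_matrix` uses average ranks for ties and pairwise-complete
observations; entries with fewer than 4 complete pairs are reported missing
with a flag rather than as unstable numbers.

## The synthetic generator

`SyntheticTruth` defaults encode the observed study conditions: half-sine
radiation peaking at 1100 µmol m⁻² s⁻¹ PAR, 165 W m⁻² UVA, 58 W m⁻² UVB
over a 07:00–19:00 photoperiod; temperature sinusoid −5→18 °C peaking at
14:00; wind ramping 1→6 m s⁻¹ at noon; K_d 0.32 cm⁻¹; Yield II baseline
0.75 with a linear irradiance coupling dropping it to 0.6 at peak light;
F_v/F_m 0.80 baseline with a Gaussian-bump midday depression to 0.75 and
full afternoon recovery; mean dissolved CO₂/CH₄/N₂O of 23.4 µM, 163.1 nM,
7.3 nM with ±10% diel sinusoids (CH₄ peaking in the afternoon, the others
in the morning); an afternoon chamber deployment with a positive CH₄
slope, a negative CO₂ slope and no N₂O trend; and morning incubation rate
components (AOB 0.25, AOA 0.15, other −0.05 µM h⁻¹ over a 0.30 control)
exceeding the afternoon ones (0.05, 0.08, −0.02 over 0.10) — net treatment
rates fall in the 0.2–0.6 µM h⁻¹ range typical of such assays. Water-side
gas conditions are 10 °C, salinity 1, 0.64 atm, chosen once as realistic
for a cold brackish pond at altitude; under them the default means give
CH₄/CO₂ supersaturation and N₂O subsaturation.

Noise models: multiplicative lognormal for irradiance (σ = 0.01 on forcing,
0 by default on profiles), additive Gaussian on quantum yields (σ = 0.005),
multiplicative 1% on dissolved concentrations, additive Gaussian on chamber
mole fractions (per-gas ppm scales), and additive Gaussian σ = 0.05 µM on
incubation endpoint concentrations. The field campaign reports no error
model, so these magnitudes are assumptions, recorded in `truth.json`.

Randomness: one `SeedSequence` per bundle, spawned into named sub-streams
in a fixed order, so the same seed gives bit-identical bundles and changing
one table's parameters does not shift another table's draws.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sensor drift and autocorrelated noise, cloud
events breaking the half-sine, vertical structure in the water column,
carbonate-system buffering of CO₂, non-instantaneous dark adaptation,
inhibitor carry-over or incomplete mixing in flasks, and any coupling
between stages beyond the shared forcing (e.g. wind does not actually drive
the gas field). Parameter-recovery results demonstrate the estimators are
correct under the stated error models, not that those models describe any
particular pond.

## Problem sizes

The test suite and the acceptance script use the default campaign sizes:
6-point light profiles (×3), 7 two-hourly PAM timepoints, 3 gas sampling
hours × 3 replicates × 3 gases, 5-point chamber series, and duplicate
flasks × 4 treatments × 2 sessions. Monte-Carlo checks use 200–2000
replicates, chosen to make the relevant standard errors a few times smaller
than the tolerances they guard.

## Known limitations

* Endpoint rates assume linearity over the 5–6 h incubation; substrate
  depletion or lag would bias them.
* The partition inherits every limitation of the inhibitor design itself;
  the reveal-matrix model quantifies but cannot remove them.
* Saturation status depends on the assumed ambient pressure and atmospheric
  mole fractions; both are configuration, not measurements.
* The decision tree is implemented for two groups (morning/afternoon);
  k > 2 works but is untested beyond k = 2.
* No wind-based (k600) flux model and no UV attenuation in water.
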
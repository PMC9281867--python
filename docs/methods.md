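# Methods

## Kinetic model

The simulator integrates a closed mass-action description of the
tissue-factor pathway with 34 species and 42 reactions (41 distinct rate
constants; the two intrinsic-tenase decay reactions share one). The
network follows the Hockin–Mann (2002) stoichiometric scheme: TF:VIIa
initiation with TFPI and antithrombin regulation, FIX/FX activation,
intrinsic tenase (IXa:VIIIa) and prothrombinase (Xa:Va) assembly,
meizothrombin as the intermediate of prothrombin activation, and FVIIIa
A2-domain dissociation (VIIIa1-L + VIIIa2) as the tenase decay route. The
pathway deliberately excludes FXI, FXII, fibrinogen, protein C, platelets
and flow; what the model predicts is the plasma thrombin-generation
potential of a donor's factor composition, not clot formation in vivo.

Everything kinetic ships as data
(`src/thrombosim/data/mass_action_scheme.yaml`): species, per-species
lineage composition, reactions, rate constants with units, reference
concentrations and drug defaults. Schemes are validated on load (unknown
species, missing rate constants, malformed entries are reported by name)
and audited reaction-by-reaction for lineage conservation: for each of the
nine zymogen/inhibitor lineages (II, V, VII, VIII, IX, X, TF, TFPI, AT)
the lineage-weighted stoichiometry must balance across every reaction.
A network passing this audit conserves each lineage total exactly along
trajectories, which turns conservation drift into a direct measure of
integrator error — the test suite holds it below 1e-6 relative on random
donor profiles.

## Donor inputs

Measured panels carry FII, FV, FVII, FVIII, FIX, FX and AT as percent of a
reference plasma, TF activity in pM and TFPI activity in U/mL. Conversion
to molar initial conditions is linear: `level/100 × reference` for percent
factors, pM taken directly as the model's TF concentration (no calibration
factor), and `U/mL × reference-TFPI` with 1 U/mL defined as the reference
TFPI concentration. The reference table (FII 1.4 µM, FV 20 nM, FVII 10 nM,
FVIII 0.7 nM, FIX 90 nM, FX 160 nM, TFPI 2.5 nM, AT 3.4 µM) uses standard
mean normal-plasma values from the source kinetic literature and is
editable in the parameter file. Trace circulating FVIIa is initialised at
1 % of the donor's FVII (configurable); without it the pathway cannot
initiate at low TF. The conversion is exactly invertible on the measured
subspace, which the tests exploit as a round-trip property.

## Numerics

The system is stiff: concentrations span pM (TF) to µM (FII, AT) and
binding steps are orders of magnitude faster than depletion. Integration
uses LSODA (via `scipy.integrate.odeint`) with an analytic Jacobian; the
generic mass-action right-hand side and Jacobian are compiled with numba
from the reaction arrays, and a pure-NumPy implementation of the
derivative is kept as the public reference and cross-checked against the
compiled path in the tests. Defaults: horizon 1200 s (the slowest factors
deplete over ~15–20 min), output grid 1 s, rtol 1e-8, atol 1e-16 M.
The absolute tolerance sits four orders below the pM TF scale because
lineage conservation to 1e-6 relative must hold for the *smallest*
lineage; at atol 1e-14 the TF lineage drifts by ~1e-4 relative. Negative
excursions smaller than 1e-15 M are clipped to zero after integration;
anything larger would indicate solver failure and is left visible.
Tightening both tolerances tenfold moves peak thrombin and time-to-peak by
~1e-5 relative, comfortably within the 0.1 % convergence requirement the
tests assert.

## Summary predictions

Each trajectory reduces to a scalar panel: peak free thrombin (FIIa), time
to peak, thrombin AUC (trapezoidal), peak total thrombin activity, and the
nineteen depletion/generation summaries — per measured factor (9) the time
to fall below θ = 0.10 of the initial level (first linearly interpolated
crossing; absent if never crossed) and the fraction consumed by the
horizon, and per activated species/complex (10: FIIa, mIIa, FVIIa, FIXa,
FXa, FVIIIa, FVa, TF:VIIa, tenase, prothrombinase) the peak and its time.
Peaks are refined by the parabola through the three grid points around the
maximum, making them invariant to grid refinement well within 0.5 %.
Thrombin is reported two ways because plotted "thrombin" in the literature
sometimes includes meizothrombin's partial activity: free FIIa (the
headline) and total activity FIIa + 1.2·mIIa. θ and the summary-list
membership are configuration, not code.

## Anticoagulants

Warfarin is modelled at equilibrium only: the vitamin-K-dependent factors
(FII, FVII and its FVIIa trace, FIX, FX) are scaled to 33 % of their
measured level (fraction configurable); no pharmacokinetics. The direct
FXa inhibitor (rivaroxaban-like, default dose 6 nM) and direct thrombin
inhibitor (dabigatran-like, default 0.3 µM) are added to the network as a
new conserved species D with reversible 1:1 binding, target + D ⇌
target:D. The main text of the underlying study gives doses but not
kinetics, so defaults use a diffusion-limited on-rate of 1e8 M⁻¹s⁻¹ with
off-rates implied by published equilibrium affinities (rivaroxaban
Ki ≈ 0.4 nM → 0.04 s⁻¹; dabigatran Ki ≈ 4.5 nM → 0.45 s⁻¹); these are
explicit parameter-file entries meant to be replaced when better kinetics
are available. Whether the inhibitor also binds the complex-bound target
(prothrombinase-bound FXa; meizothrombin) is a toggle, default off. Drug
effects are reported per donor as percent peak reduction and percent
time-to-peak change against the undrugged simulation; a donor with zero
undrugged peak is flagged undefined rather than divided by zero.

Known limitation: with these default kinetics the FXa inhibitor at 6 nM is
at least as potent as warfarin at 33 %, so the potency ordering across the
three drug classes reported with the original (unpublished) inhibitor
schemes is not guaranteed to be reproduced; directions and monotone
dose-response are, and are what the tests assert.

## Driver analysis

A "typical" donor of a cohort subset is the arithmetic mean panel in assay
units (averaging what was measured, not molarities). One-at-a-time
contributions replace a single factor of the typical case with the typical
control value and record the change in peak thrombin and time-to-peak;
because the cascade is nonlinear these contributions need not sum to the
total gap and are read as directions and rankings. Sequential adjustment
replaces factors cumulatively in a given order — the shipped defaults are
FVIII, TF, TFPI, FIX for males and FII, FIX, FVIII for females, with an
automatic order ranked by |Δpeak| (ties by |Δtime-to-peak|, then name) —
and after all nine substitutions reproduces the typical-control summary
exactly (to solver tolerance), which the tests assert to < 0.5 %.
Sex-pooled and sex-stratified reference means are both supported.

## Cohort statistics and stratification

Normal ranges are control-group mean ± 2 sample SD. Group comparisons use
the unpaired t-test (pooled-variance default, matching the convention of
the emulated study era; Welch optional), with a summary-statistic variant
for printed tables; categorical comparisons use Pearson chi-squared
(continuity correction off by default); associations between measured
factor levels and predicted drug effects use Pearson correlation with
two-sided p. All are thin wrappers over scipy.stats, validated in the
tests against brute-force, permutation and closed-form oracles.
Stratification assigns rank-based tertiles of predicted peak thrombin
(configurable to AUC): donors sorted by value then donor_id, sizes
differing by at most one with the remainder to the lower tertiles — a
deterministic rule, chosen because ties and remainders are otherwise
unspecified. The heatmap export is data, not a rendering: per-donor factor
tertiles plus sex, group and per-drug effect columns, rows sorted by
(tertile, key, donor_id).

## Synthetic cohorts

The generator emulates the structure of the emulated study population:
162 cases / 186 controls with 86 %/87 % male (sex counts by floor, giving
139/23 and 161/25 male/female donors), TF and FVIII lognormal (right-
skewed in real plasma), the rest truncated normal; case multipliers
TF 1.25, FVIII 1.2, FIX 1.15, FX 1.1, TFPI 0.9; female FVIII ×1.15 in both
groups with FII ×1.1 and FIX ×1.15 additionally in female cases; 2 %
minor-allele frequency for the prothrombin-20210 variant under
Hardy–Weinberg (carriage just under 4 %) with FII ×1.25 in carriers.
Factor levels are drawn independently — real inter-factor correlations are
unreported and no copula is fitted — and the multipliers are modest
synthetic effects encoding the reported directions, not estimates of any
cohort's effect sizes. Passing end-to-end tests therefore demonstrates
that the pipeline recovers known structure planted in its inputs
(case-enriched high-thrombin tertile, multiplier recovery at large n,
seed determinism), not that it reproduces any clinical cohort's numbers.

## Problem sizes

The test suite and acceptance script run the conservation check on 50
random profiles, convergence on 20, drug directionality on a 50-donor
cohort, and the end-to-end recovery on twenty independent 348-donor
cohorts plus a 20,000-donor draw for generator calibration — sizes chosen
to match the emulated study's scale while keeping a full run around a
minute on a single core (one simulation ≈ 4 ms after JIT warm-up).
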
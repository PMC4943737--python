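# Methods

This note documents the statistical models behind `baltind`, the choices
made where the underlying methodology leaves the design open, and what
the synthetic-data experiments do and do not demonstrate.

## Indicators

Nine annual summer (June–September) community metrics are computed per
dataset (see `baltind.indicators` for units): total zooplankton
abundance (TZA, 10³ ind m⁻³) and biomass (TZB, mg WW m⁻³), copepod
biomass absolute and as a share of TZB (CB, CB%), microphagous
mesozooplankton biomass absolute and relative (MMB, MMB%), community
mean individual wet mass (MeanSize = TZB/TZA, µg ind⁻¹), and the two
biomass ratios Cla/Cop and RotCla/Cop with calanoid biomass in the
denominator.

Accounting rules:

* Predatory cladocerans (*Cercopagis*, *Bythotrephes*, *Leptodora*)
  are excluded from every pool — total, cladoceran and microphagous.
* The microphagous set is trait-driven (rotifers, tintinnids,
  appendicularians, small ctenophores, pelagic harpacticoids) plus
  herbivorous cladocerans; a `nauplii_microphagous` switch optionally
  adds copepod nauplius-stage records, because the narrative definition
  of microphagous feeders includes nauplii while the calculation rules
  omit them.  Default: off (the calculation-rule reading).
* CB counts *all* copepods (including pelagic harpacticoids), the two
  ratios use *calanoid* biomass only.  Both literal definitions are kept
  rather than harmonised.
* Zero-denominator ratios become missing values (later imputed), never
  zeros or infinities.

**Station averaging.** Monitoring datasets have unequal station and
visit counts.  Annual values default to mean-over-dates within station,
then mean-over-stations, so a heavily sampled station cannot dominate;
a `grand` mode averages all events directly.  A taxon absent from a
sampling event counts as density zero in that event.

## Transformation, imputation, baselining

Indicator series are strongly right-skewed, so each series is Box-Cox
transformed before all downstream analysis.  The exponent is the MLE
found by bounded scalar optimisation on λ ∈ [−2, 3] (tolerance 1e-4);
series containing zeros (ratios can be exactly zero) are shifted by half
the smallest positive value first, and the fitted shift and λ are
retained so the transform inverts to 1e-8.  Normality is checked with
the Kolmogorov–Smirnov statistic using the Lilliefors correction for
estimated parameters (the plain KS p-value is anti-conservative here);
series shorter than 12 years are reported ineligible rather than tested.

Missing years in the transformed years × indicators matrix are filled by
eigenvector filtering: gaps start at column means, the standardised
matrix is reconstructed from its leading principal axes (the smallest
number explaining ≥ 80 % of variance, capped at 3 and at n_columns − 1),
gap cells are replaced and the loop iterates to a 1e-6 relative change
(at most 500 iterations).  Observed cells are never modified; imputed
cells are flagged.  Order of operations: transform → impute →
standardise.  An entirely missing year converges to the column means
(z = 0), which is the least-informative completion.

z-scores are computed as z = (x − μ)/σ with μ, σ (sample SD, n−1) from
either the whole series or a user-supplied reference window (chlorophyll-
or fish-condition-based year ranges); windows need ≥ 5 years with data.
Window-based σ is the window SD, not a pooled estimate.

## Control charts

The Shewhart chart flags single years beyond ±3 z-units for
reference-window baselines; for entire-series baselines the limit is the
two-sided 99 % normal quantile (±2.576) applied per observation — a
confidence interval of the *mean* would shrink with series length and
flag nearly every year.  The decision-interval CuSum accumulates

    S⁺ᵢ = max(0, S⁺ᵢ₋₁ + zᵢ − k),   S⁻ᵢ = min(0, S⁻ᵢ₋₁ + zᵢ + k),  S₀ = 0

with allowance k = 0.5 (tuned for detecting a 1σ mean shift) and
decision interval h = 5; a year violates when S⁺ > h or S⁻ < −h (a tie
at the limit is not a violation).  The statistic is not reset after an
alarm, so excursions persist until the process genuinely returns.
Missing z after imputation should not occur; if present the statistic is
carried forward and the year logged as unflaggable.  Simulated
calibration of this scheme gives an in-control average run length of
≈ 460 years and a mean 1σ-shift detection delay of ≈ 10 years
(`run_lengths_to_alarm`), matching standard CuSum tables.

Out-of-control *periods* are maximal same-direction violation runs of at
least 4 years ("more than 3 consecutive years").  A year is labelled
out-of-control for a reference state when *any* of the nine indicators
violates its CuSum limits that year.

## Trends and breakpoints

Mann–Kendall is implemented directly (no suitable dependency is
pre-installed): score S, tie-corrected tau-b, tie-corrected variance
with continuity correction for n ≥ 10 and the exact inversion-count null
distribution for shorter tie-free series; it is cross-checked against
`scipy.stats.kendalltau` in the tests.

Chronological clustering partitions the years × indicators z-score
matrix (entire-period baseline) into homogeneous eras.  Starting from
singleton years, the pair of temporally adjacent groups with the
smallest proportional-link distance (the `connectedness` quantile of
inter-group Euclidean distances; 0.5 = median link) merges when a
permutation test cannot reject the homogeneity of the pooled block at
sensitivity α; a rejected boundary is retested only when one of its
groups changes.  The test statistic is the **maximum** between/within
dispersion ratio over all contiguous splits of the block, for the
observed ordering and the permuted ones alike: because candidate
boundaries are data-selected, a fixed-split statistic is
anti-conservative and leaves a ≈ 12 % family-wise false-breakpoint rate
on homogeneous 20-year series at α = 0.01, while the max-split form
keeps it at ≈ 0–2 % with no loss of power against a 3σ shift (100 %
recovery within ±1 year in simulation).  Permutation streams are seeded
deterministically from (seed, block year span) so the same block sees
the same permutations at every α, making partitions comparable (and in
practice nested) across sensitivity levels.  Singleton groups are
allowed and flagged.  Variance shifts around a split year use the
post/pre sample-variance F-ratio with (n_post−1, n_pre−1) degrees of
freedom, one-sided for an increase by default.

## GES models and MSTS

Year labels (1 = in-control, 0 = out-of-control, from the chart
classification against a reference window) are modelled by binomial
regression (statsmodels IRLS) on the indicator z-scores, optionally with
a reference-coded dataset factor.  Wald χ² per coefficient, AIC,
deviance and Pearson χ² are reported; complete separation is flagged on
the result rather than silently returned.  Model search is exhaustive
over predictor subsets of size ≤ 3, screening out subsets with any VIF ≥ 3,
ranked by AIC, with a parsimony rule: a simpler nested model within
ΔAIC ≤ 2 of the best wins when the likelihood-ratio test between them is
non-significant (p > 0.05).  "Similar AIC" is operationalised as
ΔAIC ≤ 2, the standard convention.  Accuracy is in-sample
percent-correct at a 0.5 cutoff (no cross-validation is attempted — a
documented limitation), plus a 2×2 confusion-table odds ratio and
per-predictor exp(β); no single "model log-odds-ratio" is defined here
because that summary has no unambiguous definition.

MSTS combines the MeanSize z-score with a stock z-score (TZA or TZB)
against a reference baseline: both ≥ threshold (default 0, the baseline
mean; configurable) is green / in-GES, both below is red, and one
failing is orange, with the enum naming the *adequate* component
(`orange_size_only` = size adequate, stock failing).  The threshold-0
reading of "adequate" is a convention, flagged to users.

## Synthetic data

The generator emulates the statistical structure of multi-decadal summer
monitoring series, not plankton dynamics.  Defaults (the study
conditions): 35 years from 1980, months 6–9, 2 stations, 1 sample per
month, six functional groups with Baltic-plausible summer biomass means
(mg WW m⁻³: calanoids 60, other copepods 15, herbivorous cladocerans 25,
predatory cladocerans 3, rotifers 8, appendicularians 5) and fixed
individual masses (µg: 8, 4, 10, 150, 0.2, 5).  Observations are
mean-preserving lognormal draws (CV 0.35) around the trend- and
shift-adjusted group mean times a fixed per-station lognormal factor
(CV 0.20); abundance is derived exactly from biomass and individual
mass.  Lognormal noise is deliberate: it makes the Box-Cox stage
non-trivial.  Missing years drop all samples for that year, exercising
the imputation path.  The composite regime-shift preset (copepods
×0.85, herbivorous cladocerans ×1.2, rotifers ×1.25) displaces the
responsive indicators by ≈ 2 interannual SDs under these conditions
(measured: MeanSize −2.0, MMB +2.1, TZA +1.8, Cla/Cop +2.0).

What passing tests show — and don't.  The generator's noise is
exchangeable between years; real series carry autocorrelation, gear and
analyst changes, and slowly drifting baselines that the charts would
partly absorb into σ.  Recovery rates measured here (e.g. ≥ 90 %
out-of-control label agreement five years after a 2σ shift) therefore
bound the method's behaviour under its own assumptions, not its field
performance.  Individual masses are fixed per taxon, so within-group
size change is invisible to MeanSize in synthetic data; in real data
MeanSize also responds to stage and species composition within groups.

## Problem sizes

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the tested bands: 2000 runs for chart run lengths, 5000 null
series for Mann–Kendall calibration, 200 seeds for breakpoint and
predictor recovery, 100 seeds for the end-to-end label recovery, with
999 permutations per clustering test.

## Known limitations

* Years are treated as exchangeable under the baseline; no
  autocorrelation or seasonal modelling.
* Chronological clustering reconstructs the published algorithm family
  (constrained agglomeration, proportional-link linkage, permutation
  gate); it is not a bit-for-bit reimplementation of any proprietary
  package.
* Logistic model evaluation is in-sample only.
* No taxonomic name resolution or portal connectors; inputs are local
  CSV files.
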
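# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions behind `thermsol`.

## Dose-response model and evidence

A protein's response to a ligand dose series is modeled by the
four-parameter logistic in x = log10(dose in molar),

    mu_H1(x) = c + (d - c) / (1 + exp(b (x - e))),

against the intercept null mu_H0 = mean(y), whose least-squares optimum is
closed-form.  The evidence statistic is the relative residual reduction
F = (RSS_H0 - RSS_H1)/RSS_H1, floored at zero (an alternative fit worse
than the intercept carries no evidence).  A perfect alternative fit with
nonzero null residuals yields F = +inf; before replicate medians are
taken, infinite components are replaced by the largest finite component in
the dataset so a single interpolating fit cannot dominate.

Sign convention: with x in log10 molar, the inflection e equals log10 EC50
and the reported affinity is pEC50 = -e.  The model is symmetric under
(b, c, d, e) -> (-b, d, c, e); both representations are accepted and e is
unchanged, so affinities are invariant to the representation found.

### Vehicle handling

The vehicle (dose 0) has, physically, no ligand: the model value there is
the no-ligand asymptote (c for rising curves, d for falling ones), reached
only as x -> -inf.  The common practical workaround — placing the vehicle
at a finite pseudo-dose some decades below the lowest tested dose — makes
the model evaluate partway up the curve at the vehicle whenever the EC50
approaches the bottom of the dose range.  On noise-free generator output
this biases the fitted inflection by more than +0.3 log10 units for
pEC50 >= 5 on the standard 2 mM-top grid, approaching +1 at pEC50 6.
The pipelines therefore default to `vehicle_mode="asymptote"`: the vehicle
point enters the residuals at the exact dose-0 limit of the model
(implemented as a sentinel x large enough that the clipped logistic
saturates exactly in float64), which makes noise-free recovery exact at
every affinity.  `vehicle_mode="pseudo_dose"` restores the two-decades-
below-the-lowest-dose convention, which remains the default of the
low-level `to_dose_series` helper for compatibility with standard
dose-response practice.

### Fitting

Four-parameter logistic fits on 5–30 points are multimodal, and the
permutation FDR requires refitting every protein-window for each of ~100
permuted datasets, so fitting is vectorized over all series of a window at
once and is fully deterministic:

1. **Grid initialization with variable projection.**  For a grid of slopes
   (±0.3 … ±30) and inflections (each observed dose, midpoints, median),
   the conditionally linear pair (c, d) is profiled out by ordinary least
   squares; the best grid point per series seeds stage 2.  Because the
   constant function lies in the span of the profiled basis, every grid
   candidate already has RSS <= the null RSS.
2. **Projected Levenberg–Marquardt** on all four parameters with analytic
   Jacobians, run simultaneously for every series with per-series damping;
   box constraints (c, d in [0, 10 max y], |b| <= 50, e within the observed
   dose range ±2 decades) prevent runaway extrapolation on monotone but
   unsaturated data.  Convergence: relative RSS improvement below 1e-10, an
   exact fit, or a rejected step from an already conservative trust region;
   at most 60 iterations.

Series whose optimization fails to beat the intercept are returned as
null-equivalent and flagged unconverged (F component 0).  A degenerate
dose axis (all x equal) is null-equivalent by construction.  Recovery is
exact (inflection error < 1e-10) on noise-free data whenever the
transition is actually sampled by the dose grid; with EC50 more than
about a decade outside the sampled range plus slope steep enough that no
dose falls on the transition, the parameters are fundamentally
unidentifiable (an RSS-0 manifold), which no optimizer can resolve.

## 2D screen

Preprocessing forms fold changes against the vehicle of the same
temperature, plex and replicate, then centers log2 fold changes so each
TMT channel has median zero (assumes a mostly-unaffected proteome), and
re-pins vehicles to exactly 1.  Windows span two adjacent temperatures
(configurable); the two temperatures' dose series are pooled into one fit
per replicate, the per-replicate F components are combined by their
median, and the per-protein score sums ln F over gated windows.

Gating: a window enters the sum when its most extreme fold change passes
h = 1.5 (gains) or 1/h (losses).  "Most extreme" is measured on the log
scale (max |log2 phi|), because a literal arithmetic maximum can never
fall below 1/h in the presence of near-1 values, which would make
destabilization undetectable.  ln F terms below zero are excluded by
default (`allow_negative_log_terms` restores the literal sum): a window
whose fit barely beats the intercept carries no evidence and would
otherwise cancel real signal in other windows.  When both gates fire for
one protein, the direction of the extreme with the largest |log2| wins.

Permutations shuffle all non-vehicle fold changes jointly across proteins,
doses and replicates within (temperature x qupm-bin) strata — qupm, the
quantified-peptide count capped at the category "5 or more", stratifies
because quantification noise depends on it.  Vehicle values are never
moved, and per-stratum multisets are exactly preserved.  Permutation b
uses a child seed derived from the master seed by counter, so results are
independent of execution order.  The FDR at threshold theta averages
2 v_b/(r + v_b) over permutations (ties counted as permuted hits —
conservative); the reported per-threshold FDR is the minimum raw estimate
over all thresholds at or below theta, clipped to [0, 1], which is
non-increasing in stringency.  Hits require FDR <= 1% and a nonzero score.

pEC50 assignment: the lowest temperature at which the direction's gate
fold change is reached at any dose in at least two replicates anchors the
estimate; the median of the per-replicate inflections from the windows
containing that temperature is reported, clipped to [pEC50 of the highest
dose - 1, pEC50 of the vehicle pseudo-dose].  Inflection estimates pinned
at the optimizer's box edge are runaway solutions and are excluded, as
are fits with no positive evidence; pooling both windows containing the
anchor temperature roughly doubles the estimates entering the median,
which matters because per-replicate inflections at gate-level amplitude
are heavy-tailed.

## Solubility screen

The SDS-extracted vehicle channel measures a protein's total abundance,
the NP40 channels its soluble pool.  The insoluble-proteome flag uses the
replicate median of per-replicate, within-plex SDS/NP40 vehicle ratios
computed on raw reporter intensities: both channels sit in the same TMT
plex and are directly comparable, and this form is exactly invariant to
rescaling whole replicates.  The boundary is inclusive (ratio >= 1.5 is
insoluble); an NP40 vehicle of zero yields an infinite ratio, flagged
insoluble.

Dose fold changes use calibrated intensities: each sample is affinely
calibrated against the per-protein median reference of its calibration
group by least trimmed squares, then passed through a generalized log2
(glog) and its exact inverse.  Two necessities discovered on generator
data: (1) SDS channels are calibrated within their own group — scaling
the totals channel against a soluble-pool reference would erase the
insoluble-proteome signal itself; (2) trimming acts on relative residuals
(regression of y/ref on 1/ref), because absolute residuals on intensities
spanning orders of magnitude select low-intensity rather than unchanged
proteins.  With half-trimming the calibration is exact whenever a
majority of proteins is unchanged — the standard normalization
assumption; it is documented as a simplified variance-stabilizing
transform, not a reimplementation of any published normalization.

Candidates for model fitting must first show a replicate-median fold
change beyond h at some dose (the same two-sided log-scale extreme as the
2D gate).  One joint logistic fit pools all replicates; F = (RSS_H0 -
RSS_H1)/RSS_H1.  The permutation FDR reuses the 2D machinery with strata
reduced to qupm bins (a single temperature).  Hits need FDR <= 1% plus the
gate, and report pEC50_s = -e clipped to the tested dose range ±1 decade.

## Melting analysis

Fraction-non-denatured profiles follow the plateau sigmoid in 1/T,
f(T) = (1-p)/(1 + exp(b' - a/T)) + p, the functional family standard for
thermal profiling; Tm solves f(Tm) = 0.5 (defined only for p < 0.5 and
reported only within the measured range ±5 °C).  Fits use
scipy.optimize.least_squares with multi-starts over plateau and slope and
a Tm initialization interpolated from the first 0.5 crossing; validity
requires r² >= 0.8 and plateau < 0.3 (configurable).  Profiles are
normalized to the lowest temperature; when a protein is already partly
melted there, this normalization shifts the apparent 0.5 crossing by up
to about a degree relative to the unnormalized curve — a property of the
convention, not the fitter, which recovers model-family curves to
< 1e-10 °C.

Co-melting distance between two profiles on a shared grid is the average
squared deviation per temperature (a 0.1 uniform offset gives 0.01).  The
printed 0.02 proximity cutoff is dimensionally consistent only with an
averaged quantity on [0, 1]-valued ten-point profiles; a root-sum-square
variant is available for sensitivity analysis.  Note the cutoff's
resolution: Tm separations below ≈5 °C at standard steepness remain under
0.02, so proximity is a statement about near-identical profiles, not
merely similar melting points.  The complex test compares the mean
pairwise distance of >= 3 quantified subunits against the same statistic
for random same-size subsets of all quantified proteins, drawn without
replacement; p = (1 + #{null <= observed})/(1 + n_rand) is valid
(stochastically >= uniform) under the null by the add-one correction.

The heating-solubilization statistic is the maximum fold change versus
the 37 °C reference over all other temperatures (log2 reported), which
peaks at the transition temperature for proteins leaving an insoluble
assembly on heating.  Solubility-corrected melting curves divide treated
raw intensities pointwise by the protein's solubility fold change at the
matching dose *before* normalizing to the lowest temperature, separating
solubility from stability effects; a missing solubility value returns the
uncorrected curve, flagged.  Group comparisons of Tm shifts use the
Wilcoxon signed-rank (paired) or rank-sum (unpaired) test.

## Synthetic data

The generators are pure functions of (config, seed) and emit the real
designs exactly: 2D plexes span two neighboring temperatures x all doses
(TMT10), SPP plexes hold one NP40 vehicle + eight NP40 doses + one SDS
vehicle, TR plexes one full gradient per condition.  Defaults follow the
published designs: 2D doses {0, 0.005, 0.05, 0.5, 2} mM over ten
temperatures 42–60.1 °C with three replicates; SPP doses
{0.1, 0.5, 1, 2, 4, 5, 8, 10} mM; TR gradient 37–66.3 °C with two
replicates.

Thermal truth: vehicle Tm ~ U(46, 56) °C, plateau ~ U(0, 0.15), slope
scale 550 ± 10%; stabilized/destabilized proteins shift Tm by ±U(2, 6) °C
in the TR design.  Dose truth: effects follow the logistic in log10 molar
dose with unit slope (the 1:1-binding default) and pEC50 ~ U(3.5, 6.5)
for the thermal screen.  In the 2D design the dose-effect amplitude at
temperature T is (max_effect - 1) x (1 - vehicle fraction remaining), so
low temperatures show no effect — the physical rationale for the
sliding-window statistic; max_effect defaults to 3 (a saturating 3-fold
stabilization).  Solubility truth obeys mass balance: SDS vehicle carries
the total, NP40 vehicle the soluble share 1 - insoluble_fraction, and a
dose releases release x insoluble_fraction of the total into solution
(or removes a share of the soluble pool).  Defaults: affected proteins
draw insoluble fractions from U(0.4, 0.8) and release from U(0.6, 1.0) —
note a 40%-insoluble protein with 60% release peaks below the 1.5-fold
gate, i.e. the default population deliberately includes effects too small
to detect; pEC50_s ~ U(2.5, 4.5), inside the tested dose window
(0.1–10 mM, tested pEC50 2–4), because a half-maximal concentration
orders of magnitude below the lowest dose saturates every dose and is
unidentifiable by construction.  Noise is multiplicative lognormal with
mean 1 and configurable CV (default 0.1; the ratio-based analysis makes
multiplicative noise the natural model); qupm is assigned independently
of effect class so permutation strata are exchangeable under the null.

What the generator does not emulate: peptide-level quantification and
roll-up, isotope-impurity spillover between TMT channels, missing values
beyond whole-cell NaN handling, correlated (batch) noise, and
ratio-compression from co-isolation.  Passing tests therefore demonstrate
correctness of the statistics under the stated noise model, not
robustness to every artifact of real MS data.

## Test problem sizes

The statistical suite runs null calibration at 200 proteins x 20
simulations with 50 permutations, power and recovery at 200–300 proteins
over 2–3 simulations, and the randomization-test calibration at 200 runs
of 199 draws — sizes chosen so the full suite completes in a few minutes
on one CPU while leaving the binomial noise on measured rates well below
the asserted margins.  `scripts/acceptance.py` uses the same sizes.

## Known limitations

- FDR estimates with very few candidate proteins are coarse; the factor-2
  average-FDR estimator is used as printed in the field and can exceed 1
  (clipped) for small hit counts.
- Affinities at the edge of the tested dose range are reported after
  clipping and are lower-confidence; the package does not currently flag
  interval uncertainty on pEC50.
- The simplified calibration assumes a majority-unchanged proteome per
  sample; designs where most proteins respond require externally supplied
  normalization factors.
- Proteins quantified in only part of the plexes are fitted on whatever
  cells are present (subject to `min_points_per_fit`); no imputation is
  attempted.
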
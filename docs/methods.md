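# Methods notes

This note records the models, conventions and numerical choices behind
`qpa`, the way they are parameterised, and what the synthetic-data tests
do and do not demonstrate about real instrument data.

## Growth rate

In vivo Chl-a fluorescence (RFU) is treated as a biomass proxy. The
maximum specific growth rate is the steepest slope of an ordinary
least-squares regression of ln(RFU) on time over a sliding window of
four *consecutive* readings; series shorter than the window use all
readings, with an absolute minimum of two. Windows never skip gaps, and
slope ties break to the earliest window, so the estimate is
deterministic. r² is reported but never used to select the window.

Taking the maximum over overlapping windows is a selection: under
multiplicative RFU noise the estimator is biased slightly upward, by
roughly the standard error of a single window slope (≈ 0.009 d⁻¹ at
2% CV and daily readings). This matters proportionally more for slow
growers; it is a property of the estimator itself, shared by any
best-window procedure, and is left uncorrected because the same
convention is used on real data.

Interval rates (used to normalise the 24-h silicification incubation)
are ln(F_end/F_start)/Δt with linear interpolation *in log space* when
the endpoints fall between readings — consistent with the exponential
model within a day.

Harvest phase is classified from two thresholds chosen as fractions
rather than absolutes so they transfer across instruments: a well is
"mid-exponential" while the trailing-window slope is ≥ 80% of the
historical maximum slope and the culture has grown ≥ 4-fold from its
first reading; "stationary" once the trailing slope decays to
≤ 0.05 d⁻¹ after growth (max slope ≥ 0.1 d⁻¹) was seen. On a noiseless
logistic curve these defaults raise the flag before the inflection
point (verified analytically in the tests), i.e. within 30–70% of
carrying capacity.

## Cytometry traits

Events are gated by minimum red-fluorescence (Chl-a) and forward-scatter
thresholds; the gate is idempotent and volume-preserving. Thresholds are
per-experiment configuration because they are instrument- and
gain-dependent; the simulator's defaults sit at the 99.5th percentile of
its debris component.

All population statistics are medians, using the lower-median convention
for even counts so that a reported value is always an observed
instrument value and the result is deterministic. A minimum of 200 gated
cells is required for any median-based trait.

Cell size is an equivalent spherical diameter obtained by inverting a
linear bead calibration FSC = slope·size + intercept, least-squares
fitted on beads of known diameter (2–15 μm) with FSC as the response
(scatter, not diameter, carries the measurement error). The calibration
constants of the instrument the assay was developed on
(size = (FSC + 275,549)/83,539) are shipped as `PAPER_CALIBRATION` and
invert exactly in the tests. With ≥ 2 distinct diameters the fit is
well-posed; fewer raise a degenerate-calibration error.

Stain traits are median *deltas*: BODIPY lipid content is post-stain
minus pre-stain green fluorescence; PDMPO silicification is stained
minus unstained UV fluorescence at 24 h divided by the growth rate over
the incubation. The unstained aliquot carries the background, which is
how the "T24 − T0" correction is realised when no stained-T0
acquisition exists. Negative deltas are retained with a quality warning
rather than clipped: clipping would bias comparisons between
populations whose true delta is near zero. Division-related double
peaks in PDMPO fluorescence are deliberately absorbed by the
whole-population median; no peak splitting is attempted.

Cell concentration is gated events per acquired volume; the ROS trait
divides the plate-reader stain delta by the aliquot cell count (from the
same well's cytometry) and then by median cell size. QC-bead
normalisation (trait / bead median, per channel) removes detector-gain
differences between experiments and is exposed as a separate operation
rather than applied implicitly.

## Photophysiology

Rapid light curves (eight irradiance steps, 0–1878 μmol photons
m⁻² s⁻¹) are converted to relative ETR = Y·E·0.5, with the factor 0.5
(equal photon partitioning to PSII) configurable. Absorptance is not
measured in the assay, so ETR is in relative units; consequently α and
ETRmax are defined up to a common scale while Ik = ETRmax/α is
scale-free — the fit-invariance tests check exactly this.

The fitted model is the exponential saturation curve with optional
photoinhibition, ETR(E) = Pₛ(1 − e^(−αE/Pₛ))e^(−βE/Pₛ). Both the β = 0
and β-free submodels are fitted by bounded nonlinear least squares from
a small multi-start grid (α from the first nonzero-step secant; Pₛ from
the observed maximum × {1, 1.5, 3}; β ∈ {~0, 0.05α}); photoinhibition
is kept only when it improves the RSS by more than 1% (relative),
preferring the simpler curve under noise. The returned Ik is computed
as ETRmax/α so the identity holds exactly. Curves flagged as
detector-saturated are rejected before fitting (the bench remedy is a
25% rather than 50% dilution); fit failures mark the three
photophysiology traits missing rather than aborting the well.

## Trait table and pipeline

One row per layout well; traits in a fixed column order with fixed
units; missing values are explicit NaN, never zeros. Orphan results
(no layout well) and duplicate (well, trait) results are
reconciliation errors. Wells whose best window slope is ≤ 0.05 d⁻¹
("no increase over time", within plate-reader noise of zero) are
excluded with a logged reason. Downstream ordination uses complete
cases only, with the dropped-row count available from the table; no
imputation is attempted anywhere.

## Trait-scapes and centroid metrics

Traits are z-scored column-wise (sample SD, n−1) before any ordination,
since the ten traits differ in scale by orders of magnitude. PCA is the
SVD of the centred z-matrix; percentages of variance sum to 100 over
retained components and the sign of each component is fixed by making
its largest-magnitude loading positive, so plots and stored scores are
reproducible. Centroids are arithmetic means of PC1/PC2 scores per
group.

Centroid shifts are Euclidean distances with direction measured in
degrees from the horizontal via the two-argument arctangent, reported
in (−180°, 180°]; a zero-length shift has an explicitly undefined
direction. The quadrant-resolved form is a deliberate divergence from
the one-argument arctangent sometimes written for this metric: the two
agree wherever both are defined in the first quadrant, and only the
two-argument form is unambiguous elsewhere.

Correspondence between two trait-scapes regresses *all* pairwise
centroid distances of one on those of the other (15 distances for six
groups), not only matched pairs; r² = 1 under any similarity transform,
which the tests verify. Trait correlation matrices are pairwise Pearson
r with two-sided t-distribution p-values (n−2 df), masked at p ≥ 0.05
by default; constant columns yield undefined correlations and are
masked with a reason rather than shown as zeros.

## PERMANOVA

Implemented from first principles on Euclidean distances of the
standardised traits (no other distance is offered, because the data are
z-scored). The Gower-centred matrix G = J(−d²/2)J gives SS(model) =
tr(HG) for any design projection H, so the one-way pseudo-F reduces
*exactly* to the classical ANOVA F on univariate input — the suite
asserts this to 1e-9 and cross-checks the statistic against an
independent ecology-statistics implementation. Permutations are free
(no strata), p = (#{F* ≥ F} + 1)/(n_perm + 1), with 999 permutations by
default and a mandatory seed for reproducibility; the smallest
attainable p is therefore 1/(n_perm + 1). Two-factor designs use
sequential (Type I) sums of squares via nested hat matrices and permute
raw observations for every term; a constant second factor collapses to
the one-way analysis, while a factor aliased with the first raises a
design error. Pairwise tests run on each pair's distance submatrix with
per-pair seeds spawned from the master seed; p-values are reported raw
by default with Benjamini-Hochberg adjustment available.

## The synthetic-data generator

The generator emulates the four instrument streams under the assay's
standard study conditions: logistic growth read daily for 8 days from
100 RFU with 2% multiplicative lognormal noise; cytometry acquisitions
of 5,000 events with a 20% low-signal debris fraction and lognormal
channel clouds (shape σ = 0.25) whose medians sit at the configured
truths; stain shifts as per-event uptake with a median-1 lognormal
factor (σ = 0.1); rapid light curves with additive ETR noise at 5% of
ETRmax; and ROS plate readings consistent with the configured per-cell
value. Six default strains span realistic diatom ranges
(μ 0.35–0.9 d⁻¹, ESD 4–12.5 μm) with a built-in size/growth trade-off.
The default carrying capacity (10⁷ RFU) keeps an 8-day run exponential,
matching the assay's mid-exponential harvest rule. A single integer
seed fixes everything end-to-end via spawned per-well substreams; two
runs with one seed write byte-identical bundles.

What the generator does *not* emulate: chain-forming or clumping cells,
doublets, culture crashes (beyond a zero-growth strain), spectral
bleed-through, plate-position effects, and PDMPO double peaks are only
available as a documented option rather than a default. Passing the
recovery tests therefore shows the estimators are correct under the
stated noise model, not that they are robust to every artefact of real
cytometry.

## Tolerances and problem sizes

Recovery tolerances used by the tests are derived from the noise model,
not tuned: μ within 5% median absolute relative error (2% CV, 8 days,
150 curves); size within 2% (10,000 events); light-curve parameters
within 10% median error at 5% ETR noise (50 curves); end-to-end trait
columns within 5–10% except silicification at 20%, because that trait
divides by a two-point 24-h interval rate whose noise propagates as
√2·CV/μ ≈ 6% (1σ) at μ = 0.5 d⁻¹, on top of the stain-delta error.
Null-calibration checks use 500 one-way and 100 two-factor simulations
against binomial bands at α = 0.05. The acceptance script runs a
6-strain × 3-replicate × 2-vessel experiment (36 wells, 5,000 events
per acquisition), sizes chosen to keep the whole recomputation fast on
a laptop while leaving sampling error well inside the tolerances.

## File formats

Everything is plain text: YAML for layouts and configs, delimited
tables (with `#` metadata lines) for fluorescence series, per-event
cytometry tables, light curves, manifests and trait tables (units in a
comment header). Cytometer exports are per-event channel tables with a
config-level map from instrument column names to the canonical
channels {FSC, SSC, FL_RED, FL_GREEN, FL_UV}; a required channel that
cannot be resolved is a channel-mapping error. Binary cytometer
container formats are out of scope. Readers parse floats in
round-trip mode, so write-then-read reproduces values bit-exactly.
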
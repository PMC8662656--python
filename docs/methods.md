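# Methods

This note documents the models implemented in `ventseep`, the defaults
and why they were chosen, the numerical decisions, and the limits of
what the synthetic experiments establish.

## Demographic scenarios and the coalescent engine

Three pure divergence/founder scenarios relate four genetic groups (JR,
OH, KK seeps; OT vent).  Backward in time each scenario is a sequence of
merge events and instantaneous size changes on at most five demes; the
deeper-seep (JR+OH) ancestor is an internal deme.  There is no migration
between branches — contemporary gene flow is the business of the
migration and ocean modules, and mixing it into the scenarios would
confound the founder signatures the model comparison relies on.

* Time scale: continuous-time coalescent, times in generations, diploid
  pair-coalescence rate `k(k-1)/(4N)`.
* Founder events: the daughter branch carries the founder size between
  its founding and establishment times (e.g. `N_KKP` applies on the OT
  branch between `T_2` and `T_3`), then merges into its source.
* Ancestral sizes beyond `T_A`: scenario 1 uses `N_A`; scenario 2 keeps
  the deeper-seep size `N_JR+OH`; scenario 3 keeps `N_KK` — matching
  each scenario's narrative of which lineage is ancestral.
* Founder-size sanity constraint (on by default): a founder propagule
  cannot exceed the size of the branch it founds.

**SNP ascertainment.**  Each locus carries exactly one mutation placed
uniformly on the genealogy's branches below the root, so every locus is
segregating.  Genealogies are *accepted with probability proportional to
their total branch length* before the mutation is placed.  This models
how SNP loci enter a real panel — a locus is observed because a mutation
occurred on it, and mutations land on long genealogies proportionally
more often — and it makes a neutral single-population sample reproduce
the classic `1/i` site-frequency spectrum exactly.  Placing one mutation
on every genealogy regardless of length (the fixed-segregating-sites
scheme of some simulators) yields the subtly different `E[L_i/L]`
spectrum, which a chi-square test against the `1/i` law rejects already
at a few thousand loci.  The acceptance uses exact rejection sampling
with a cap estimated from a 128-genealogy pilot batch per call;
genealogies longer than the cap (tail probability below ~1%) are
accepted outright, a clip far below statistical detectability.  The
engine is a numba-compiled loop with incremental per-deme bookkeeping
(~10 µs per locus for 80 lineages), so a 20,000-row reference table of
500-locus datasets simulates in minutes on one CPU.

**Default priors.**  Uniform: event times on [10, 100,000] generations
with the ordering `T_1 < T_2 < T_3 (< T_4) < T_A` enforced by rejection;
branch sizes on [10, 100,000]; founder sizes on [5, 1,000].  The ceilings
follow from the posterior 95% quantiles of the original analysis
pressing against ~99,600 and ~967.  An optional minor-allele-frequency
conditioning switch (off by default) re-draws loci below a pooled MAF
threshold, mirroring the ascertainment of filtered empirical panels.

## GBS noise and the filtering cascade

The noise generator decorates clean genotypes with read depth DP ~
negative binomial (mean 30, dispersion 5 — overdispersed restriction-site
coverage typical of GBS libraries), genotype quality
`GQ = min(99, round(scale · DP · exp(0.3·Z)))` with `scale` 4 for
homozygotes and 3 for heterozygotes (both alleles of a heterozygote must
be sampled in the reads, so its call is less confident at equal depth),
and independent missingness (default 10%).  DP = 0 forces a missing call.

The cascade applies, in order: (1) biallelic sites only; (2) genotypes
with DP outside [5, 200] masked; (3) genotypes with GQ < 20 masked;
(4) sites called in ≥ 80% of samples kept; (5) minor allele frequency
≥ 0.02 over called genotypes (inclusive threshold); (6) observed
heterozygosity strictly < 0.5 (paralog-collapse guard); (7) scaffolds
retaining more than nine SNPs dropped whole (repetitive or error-prone
loci).  Genotype-level masking precedes the site-level tests, the
semantics of the standard VCF filtering tools; a regression test pins
this order.  "Genomic locus" means scaffold throughout, the only
grouping recoverable for GBS loci mapped to a fragmented survey
assembly.

## Population-genetic statistics

Per-site, complete-case allele frequencies everywhere; sites with fewer
than two called diploids in a group are skipped for that group.  `pi`
uses the unbiased pairwise-difference factor `2n/(2n-1)` while `H_exp`
does not, so `pi` slightly exceeds `H_exp` — the convention of the
standard RAD/GBS statistics software.  `F_IS = 1 - H_obs/H_exp` per site
(0 where `H_exp = 0`), averaged over variant sites; negative values are
reported as computed.  F_ST is Weir & Cockerham's (1984) theta as a
ratio of summed variance components; the permutation p-value is
`(1 + #{theta_perm >= theta_obs}) / (1 + B)`.  An undefined estimate (no
usable segregating site) is NaN, never silently 0.  Nei's (1972)
standard distance is computed per locus; opposite fixation gives an
infinite distance which is excluded from means with a count reported.
PCA imputes missing genotypes to the per-site mean, standardizes by
`2p` and `sqrt(2p(1-p))`, and eigendecomposes the individual covariance;
coordinates are defined up to sign.

Directional relative migration follows the migrant-pool G_ST method:
pool frequencies are the unweighted pair mean, multi-locus G_ST averages
`H_T` and `H_S` over loci before the ratio, `Nm = (1/G_ST - 1)/4`, and
the directional entry *into* a population derives from that population's
own differentiation from the pool (an admixed recipient sits close to
the pool).  G_ST is floored at 1e-12 before inversion so identical
groups produce equal, finite entries that normalize to 1.

## ABC

Forty summary statistics (four per group: proportion of
zero-gene-diversity loci, mean and variance of the nonzero diversities,
mean over all loci; four per pair: mean and variance of nonzero
per-locus theta, proportion of zero Nei distances, mean Nei distance).
"Zero" for per-locus theta means monomorphic in the pooled pair —
negative estimates count as nonzero.  Statistics whose defining set is
empty are encoded 0.  Distances are Euclidean after dividing by each
statistic's standard deviation over the table; zero-variance columns are
dropped.

*Direct* scenario probabilities are category shares among the 500
closest rows with normal-approximation binomial intervals.  The
*logistic* method fits a weighted multinomial logistic regression
(Epanechnikov weights in distance, small ridge for near-separable
subsets) on the closest 1%, implemented in-package with an analytic
Hessian so the delta method yields confidence intervals; probabilities
are clipped into [1e-6, 1-1e-6] and renormalized under separation, and
the method falls back to the direct shares (with a warning) when the
subset contains one scenario.

Parameter estimation logit-transforms each parameter to its prior
bounds, selects the closest 1% of the table among the chosen scenario's
rows, and applies the local-linear regression adjustment with
Epanechnikov weights; summaries are weighted quantiles of the
back-transformed adjusted values.  Three regression feature sets are
available — plain normalized statistics (default), log-transformed
statistics `log(max(s,0) + c)` with `c` half the statistic's scale
(coalescent times and sizes act multiplicatively, so log features
linearize their effect), or both — plus an `"auto"` mode that picks per
parameter by simulation-based calibration on pseudo-observed table rows.
The default remains the plain linear design: the calibration signal
separating the designs is weaker than its own noise, and an unstable
automatic choice is worse than a fixed classical one.  A singular design
falls back to unadjusted rejection quantiles, flagged.

Model checking fits a PCA on pooled prior- and posterior-predictive
statistic vectors (constant columns dropped) and flags the observed
dataset as inside the cloud when its Mahalanobis distance in the first
two PCs is below the simulations' 99th percentile.  Posterior-predictive
draws resample the weighted adjusted particle cloud and reject vectors
violating the scenario's time ordering (a possible side effect of
per-parameter adjustment).

## Synthetic ocean and particle experiments

The domain (118–130°E, 20–32°N, 1/4°) holds an elongated trough (2,200 m
deep) bounded on the south by a ridge whose crest is the 750 m sill,
pierced by three gap channels (floors at 900, 1,100 and 700 m — analogs
of the channel east of Taiwan, the Kerama Gap, and the lanes east of
Okinawa); the ridge wraps the trough's eastern end so the basin is
enclosed, and land lies north and west.  Currents derive from a stream
function — an eastward boundary jet along the ridge's ocean flank, a
gyre recirculating inside the trough (80% of the jet speed), and an
AR(1)-persistent smoothed-noise eddy field (10-day decorrelation,
relative amplitude 0.3) — all scaled by `U(z) = U0·exp(-z/H)` with
`U0 = 1 m/s` and `H = 1000/ln(10) ≈ 434 m` so the speed is 0.1 m/s at
1,000 m.  Central-difference velocities from a stream function are
exactly non-divergent in spherical flux form, and each component is
rescaled so its discrete maximum speed equals its target.  Velocities
are zeroed wherever the seafloor is shallower than the level depth.

Particles are released area-uniformly in a great-circle disk (default
25 km), advect horizontally at their release depth via `solve_ivp`'s
Dormand–Prince RK5(4) (rtol 1e-5) in daily chunks, with bicubic spatial
and linear temporal velocity interpolation and angular rates
`u/(R·cosφ)`, `v/R`.  A particle entering a cell shallower than its
depth, or a land cell, beaches terminally (no documented larval swimming
to escape with); leaving the domain marks it exited; both checks run at
every daily output.  Basin exchange counts particles inside a polygon
whose only true flow boundary is the southern ridge (the other edges sit
on land/ridge rims with a margin so beached particles count as
retained); each particle's first boundary crossing is attributed to the
nearest gate segment within 1°, else "other".

## What the synthetic experiments do and do not show

The generator reproduces the *statistical structure* the analyses
assume: unlinked biallelic loci, Hardy–Weinberg demes, neutral
genealogies, GBS-like noise; the ocean reproduces a depth-decaying
boundary current, a silled basin, and mesoscale variability.  They do
not reproduce linkage, selection, sequencing batch structure, real
bathymetry, tides, or vertical larval behavior — so passing tests
validate the estimators and the pipeline logic, not any empirical claim
about a real species.

Problem sizes are deliberately reduced: the recovery experiment uses 10
diploids per group, 500 loci and a 20,000-row reference table (the
original analysis scale is 121 individuals, 9,838 SNPs, 3,000,000
simulations).  At this scale the posterior for the vent-group size
`N_OT` is genuinely wide — an oracle experiment that varies only `N_OT`
with every other parameter fixed at the truth still yields posterior
medians scattered around 50–80% of the true value — and the
time-parameter posteriors have relative widths of ~30–40%, so
single-replicate medians scatter accordingly.  The published 5–95%
intervals are attainable only with the full-size data; the reduced-scale
experiments test direction and calibration (scenario identification,
interval coverage, bias of the adjustment), not the printed precision.

## Reproducibility

Every random draw flows from a master seed through `SeedSequence`
spawning (pipeline stages derive their seeds by hashing the stage name);
the numba engine is seeded per call; all seeds stay below 2^31.  Fixed
seeds give bit-identical genotype matrices, tables, and trajectories.
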
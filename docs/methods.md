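# Methods

`peachferm` re-implements, as a tested pipeline, the multivariate analysis
chain commonly applied to staged spontaneous fruit-wine fermentations:
alpha diversity and OTU set algebra on genus-level abundance tables, PCA
ordination, odor-activity-value (OAV) scoring of volatiles, thresholded
correlation networks, and a PLS2/VIP-based three-criteria screen that
defines a "core functional microbiota" and its bipartite association
network with volatile compounds. This note records the models, the
parameter choices, and the numerical decisions, including the places where
the published convention leaves the design genuinely open.

## Data model

Abundance tables are samples x taxa matrices (counts or relative
abundances) with per-sample fermentation `stage` (A–F, i.e. days 0, 3, 6,
9, 13, 16) and `replicate` metadata. Volatile tables are stages (or
replicate samples) x compounds concentration matrices in µg/L; a
not-detected entry ("Nd") is missing, not zero, at the container level —
each downstream stage decides its treatment (ordination and correlation
fill 0, i.e. "below detection"; OAV reports it as undefined). Odor
thresholds are intervals `[low, high]` (equal for point values; missing
allowed). The packaged fixture transcribes a full 53-compound fermentation
profile (means and standard deviations of three parallel runs) with
thresholds and printed OAV bands.

## Alpha diversity

Observed richness, bias-corrected Chao1
`S_obs + F1(F1−1)/(2(F2+1))`, Shannon entropy (natural log by default,
base-2 switch), Gini–Simpson `1 − Σ p_i²` (the dominance form `Σ p_i²` is
behind a flag), and Good's coverage `1 − F1/N`. Estimators using
singleton/doubleton structure require integer counts. No rarefaction is
applied by default; a seeded subsampling-without-replacement option exists
because some studies standardise depth before alpha diversity, but no
depth convention is assumed.

## Ordination

PCA is an exact SVD of the processed matrix. Community ordination runs on
stage-mean relative abundances, centered but not variance-scaled (the
variables share a scale by construction); volatile ordination is on
per-compound z-scores, because concentrations span four orders of
magnitude. Both choices are arguments, not constants. Sign
indeterminacy is fixed by making the largest-magnitude entry of each
loading vector positive, so scores are reproducible across runs and
platforms. Variance-explained fractions are reported over all components
and sum to one.

## OAV

OAV = concentration / odor threshold. Bands follow the printed convention
`<0.1`, `0.1–1`, `>1`; the middle band is closed at both ends (the source
tables do not state the closure). Where a threshold is an interval the
default policy takes the low end — the aroma-conservative choice; `high`
and `midpoint` policies are available. The default scoring stage is the
final stage. `oav_band_agreement` compares computed and printed bands and
*reports* disagreements instead of asserting agreement: in the packaged
fixture the ethanol row is printed `>1` although its final-stage
concentration over threshold is ≈0.245, and two compounds carry printed
bands while not detected at the final stage (their bands match the
penultimate stage); these are classed `mismatch` and `undetected_at_stage`
respectively.

## Profile clustering

Per-compound stage profiles (Nd → 0, z-scored across stages) are clustered
by agglomerative hierarchical clustering, Euclidean distance, average
linkage, cut at k = 2 by default; distance and linkage are arguments. On
the fixture this splits the table into a 12-compound class of fruit-derived
early-fermentation volatiles (the C6 aldehydes/alcohols and lactones) and
a 41-compound class of fermentation products.

## Correlation networks

Pearson (default) or Spearman correlation; two-sided p-values from
`t = r·sqrt((n−2)/(1−r²))` with n−2 df. Networks keep edges with |r|
strictly above the magnitude threshold and p strictly below the
significance threshold (0.7/0.9 with 0.01 as the conventional
within-community settings). No multiple-testing correction by default, to
match the convention this mirrors; Benjamini–Hochberg is available.
Taxon–volatile blocks are aligned replicate-to-replicate when both tables
carry replicates (n = 18 in the 6x3 design), otherwise by stage means.
Zero-variance variables are reported and excluded rather than fatal.

## PLS2 and VIP

The NIPALS algorithm is written out in full with deflation of both blocks;
both blocks are autoscaled (the convention of the commercial tools this
mirrors), and the scaling is stored so predictions return to original
units. Variable importance in projection is

VIP_j = sqrt( p · Σ_a ssy_a w_ja² / Σ_a ssy_a ),   ssy_a = (tᵀt)(qᵀq),

whose identity Σ_j VIP_j² = p makes VIP > 1 the natural above-average cut.
Numerical decisions: the inner iteration converges on the relative change
of the score vector (tol 1e-10, cap 5000 iterations); u is initialised
from the first response column, which breaks ties in the dominant
direction deterministically. When the two leading singular values are
nearly tied — mirror-symmetric succession trajectories produce exactly
this — the power iteration contracts with ratio ≈ 1 and the tolerance is
unreachable in any reasonable iteration count; a stagnated iterate
(relative change < 1e-5 at the cap) is then accepted with a warning, since
any vector in the tied subspace is an equally valid component and
deflation recovers its complement next. Genuine non-convergence still
raises, naming the component.

Component count is selected by leave-one-out cross-validation:
Q²(A) = 1 − PRESS(A)/SS(Y), accumulated on the per-column-sd-scaled
response so that one large-baseline compound cannot mask gains on the
others; components are added while the marginal Q² gain exceeds 0.05,
with a minimum of one.

## The three-criteria core screen

Restricted to the top-40 taxa by mean relative abundance, a taxon is
*core* when it (i) is present in at least half the stages (optionally with
a coefficient-of-variation cap — the published criterion "varied
relatively steadily" has no formula, so prevalence plus an optional CV cap
operationalises it and the diagnostics expose the raw values); (ii) has
VIP > 1.0 in the PLS2 fit of the volatile block on the taxon block; and
(iii) has |Pearson r| > 0.6 with at least one volatile. Core volatiles
pass the mirrored gates, with volatile-side VIPs from a second fit with
the blocks swapped (a projection-based alternative from the original fit
is available; neither convention is asserted as canonical). All
comparisons are strict. The bipartite network connects core taxa to core
volatiles with |r| above the screen threshold, annotated with kingdom and
compound class for network viewers.

## Synthetic data

`generate_succession` draws counts around latent per-taxon trajectories
(logistic rising/falling, Gaussian transient, or flat, on the
log-intensity scale) via Dirichlet-multinomial sampling: stage
compositions are the normalised intensities, each replicate draws a
Dirichlet(concentration × composition) realisation and a multinomial at
the sequencing depth, so rows sum to the depth exactly and replicates are
overdispersed. Defaults: 6 stages × 3 replicates (the standard triplicate
staged design), depth 50 000 reads (a typical amplicon sample), Dirichlet
concentration 300 (replicate CV ≈ 0.17 for a 10 % taxon — realistic
biological-replicate scatter). `concentration=inf` is the documented
noiseless limit (rounded expected counts).

`generate_volatiles` makes log-concentrations linear in realised relative
abundances: `log C_ik = baseline_k + Σ_j B_jk · rel_ij + ε`,
ε ~ N(0, σ²). The log-linear form keeps concentrations positive while the
screen operates linearly, which deliberately stresses the screen with mild
curvature; a linear-scale switch provides the worst case. The effect
matrix B is the ground truth; core taxa/compounds are its nonzero
rows/columns.

`make_screening_dataset` is the recovery benchmark: 40 taxa of which 5
planted cores redistribute a constant half of the community among
themselves along well-separated trajectories (two early and two late
logistic switches plus one mid-fermentation transient — the classic
succession picture in which late fermenters replace the initial flora),
while 35 background taxa hold fixed shares of the other half. The
constant core mass matters: if the cores' total share drifted,
compositional closure would make every "stable" background taxon co-vary
with the net core trend, and a background taxon that co-varies with a core
taxon is observationally confounded with it — no correlation-based screen
could separate the two — so the benchmark excludes that degeneracy by
construction. Each core drives two volatiles of a 12-compound panel
(mirroring the size of the major-volatile panel such studies highlight)
with log-scale effects ±3 and measurement noise σ = 0.05; two compounds
are background. A `null_effects` switch zeroes B for false-positive
control runs.

What the generator does *not* emulate: taxon co-variation beyond
compositional closure (mutualisms/exclusions among background flora),
detection limits and zero-inflation in the volatile assay, retention-index
structure, and replicate-correlated measurement error. Passing the
recovery benchmark therefore shows the chain is implemented correctly and
behaves as designed under clean planted signal; it does not certify the
screen against confounded real communities.

## Measured behaviour of the screen (and its limits)

On the benchmark (seeds 1–20, analysis script `07_recovery_benchmark.py`),
the screen recovers the planted cores with mean recall 0.95 and mean
Jaccard 0.74; with all effects zeroed it calls on average 2.15 false core
taxa. Both numbers are properties of the screening *criteria* at this
sample size, not of the implementation:

* criterion (iii) uses |r| > 0.6 at n = 18 with no significance gate;
  a null taxon crosses it for at least one of 12 compounds with
  probability ≈ 1 − (1 − 0.0085)¹² ≈ 0.10, giving ≈ 3.4 chance candidates
  among 35 background taxa per run;
* the PLS weights are built from those same sample correlations, so the
  VIP > 1 gate passes a majority of the chance candidates rather than
  filtering them (measured conditional rate ≈ 0.6);
* with 40 predictors and 18 samples, leave-one-out Q² cannot credit the
  weakest of the three latent signal directions (the noise contribution to
  a new sample's score cancels the held-out gain), so the marginal-gain
  rule occasionally stops at one component and the transient core's VIP
  collapses — per-compound univariate LOO Q² for its volatiles is 0.93,
  and recall is 1.0 when two components are forced.

Larger panels make the chance-candidate count strictly worse (a realistic
53-compound panel roughly triples it). Users applying the screen to real
data should read its output as a candidate ranking, not a controlled
discovery procedure; adding a significance gate to criterion (iii) or a
stability-selection wrapper would be the natural hardening, and both are
easy to express with the library primitives.

## Pipeline

`run_pipeline` executes diversity → ordination → aroma → association →
PLS/VIP → screen on real or synthetic inputs from a single config (YAML)
with one global seed; every stage writes its artifacts plus a
machine-readable report, and identical config + seed gives byte-identical
reports. The conventional thresholds (0.7/0.9/0.01 network; VIP 1.0;
screen r 0.6; top-40) are the named defaults, so the canonical run is the
default run. A stage failure aborts with the stage name, retaining partial
outputs beside a `FAILED` marker.
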
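# Methods

This package models two linked questions about subjective cognitive
decline (SCD): which psychological and cognitive factors explain
self-reported memory complaints, and how hub organization of resting-state
source-space networks differs between people with and without SCD.  No raw
study data are distributed, so a synthetic-data layer generates cohorts
and networks with planted ground truth; every claim the tests make is a
claim about recovering that ground truth, not about any real cohort.

## PLS path modeling

`scdnet.plssem` implements classical partial least squares path modeling
with reflective (mode-A) measurement.  Indicators are standardized with
the sample standard deviation (ddof = 1).  Outer weights start equal
within each block; each iteration forms construct scores, builds inner
proxies from neighbouring scores under the chosen weighting scheme, and
updates each outer weight as the correlation of the indicator with its
block's inner proxy, until the largest absolute change of the (unit-norm)
weight vectors falls below `tol` (default 1e-7, `max_iter` 300).  The
default inner scheme is `path` — predecessor weights from a multiple
regression of the endogenous score on its predecessors, successor weights
as plain correlations — which is the common default for models with a
single endogenous construct; `centroid` and `factorial` are available.

After convergence, path coefficients are ordinary least squares among the
standardized construct scores, loadings are indicator-score correlations,
and the reflective diagnostics follow their closed forms: composite
reliability rho_c = (sum lambda)^2 / [(sum lambda)^2 + sum(1 - lambda^2)]
and AVE = mean(lambda^2).  Conventional thresholds (rho_c >= 0.70,
AVE >= 0.5) are reported, and an indicator is flagged discriminant-valid
when its own-construct loading dominates its cross-loadings in absolute
value.

PLS scores are only determined up to sign.  Signs are anchored so each
construct's largest-|loading| indicator loads positively; for the
memory-complaints target this makes higher composite = more complaints,
since its indicators are complaint scales.

Two properties of PLS estimates matter for interpreting the tests.
First, composites attenuate structural paths by each block's measurement
quality; with 8 indicators at loading 0.85 the attenuation factor is
about 0.95 per path, so planted coefficients are recovered within +-0.05
at n = 2000.  Second, under a null path the adaptive weights capitalize
on sampling correlations, inflating |beta| to roughly 0.04 at n = 2000
(and considerably more at n = 50); recovery tests therefore average over
5 independent cohorts, and small-sample fits in the pipeline are read as
sign patterns, not point estimates.

Inference is resampling-based: percentile bootstrap confidence intervals
with sign-alignment of each bootstrap fit to the original, and a
label-permutation multigroup test that refits both groups per permutation
and compares |beta_A - beta_B|, with the add-one p-value convention
(p is never exactly 0; non-convergent permutations are excluded and
counted).  Missing data are rejected rather than imputed.  The
null calibration in the acceptance suite uses 500 datasets of 30
subjects/group with a 2-construct, 4-indicator model and 200 permutations
— sizes chosen so the whole calibration is a few minutes of compute while
the binomial uncertainty of the rejection rate (SE ~0.01) stays well
inside the accepted band.

## Synthetic cohorts

`scdnet.synthetic_data.cohort` draws mutually orthogonal standard-normal
exogenous latents (a correlation matrix can be supplied; the default
identity keeps the implied-path algebra closed-form), forms the single
endogenous memory-complaints latent as sum(beta * exogenous) plus a
residual scaled to unit within-group variance, and emits reflective
indicators lambda * latent + noise_sd * sqrt(1 - lambda^2) * eps.  The
study-shaped default (`study_cohort_spec`) has 45 + 50 subjects, five
constructs with 10/3/3/5/4 indicators at the reported outer loadings,
planted paths 0.33 (emotional distress, metacognitive beliefs) in the
non-SCD group and 0.35/0.35/-0.38 (adding personality) in the SCD group,
a between-group shift of the target latent (-0.9 vs +0.8, pooled mean
~0), and per-group raw-scale calibration of the CCI-S memory sum score to
16.31 +- 3.41 and 32.34 +- 5.03.  Raw calibration standardizes by the
theoretical within-group moments before the affine map, so it never
alters the latent structure that the recovery tests check.

What the generator does not emulate: measurement non-normality, floor and
ceiling effects of questionnaire sum scores, correlated exogenous
constructs (available but off by default), and item-level structure.
Passing recovery tests therefore show that the estimator chain is
correct, not that real questionnaire batteries satisfy its assumptions.

## Connectivity

`scdnet.connectivity` computes lagged phase synchronization on epoched
ROI signals (defaults: 2-s epochs at 256 Hz, delta = 1-4 Hz and theta =
4-8 Hz).  Per epoch, signals are Hann-tapered and Fourier-transformed;
spectral coefficients are normalized to unit modulus (phase only) and
averaged over epochs into a complex phase coherency rho(f); the lagged
synchronization at f is Im(rho)^2 / (1 - Re(rho)^2), with the degenerate
Re(rho) = +-1 case defined as 0.  The band value is the arithmetic mean
over the DFT bins inside [f_low, f_high] (2-s epochs give 0.5 Hz
resolution, i.e. 7 delta and 9 theta bins), clipped to [0, 1].  All
epochs enter one estimate; no sub-block averaging.  Discarding the real
part makes the measure insensitive to zero-lag (volume-conduction-like)
common signals: a dominant common signal added to an uncoupled pair
produces < 0.02 spurious synchronization.  A strong common admixture
does attenuate an existing lagged coupling — that is a property of the
measure itself, not an implementation artifact.

The oscillator generator (`generate_coupled_sources`) synthesizes
band-limited noise directly in the frequency domain and injects, for
every coupled pair, a shared narrowband source into both ROIs with a
phase offset drawn from [0.3 pi, 0.7 pi] (away from 0 and pi so the
lagged component is visible) and amplitude coupling_gain * weight.  The
gain (2.0) was calibrated once by simulation and frozen.  Coupling is
planted on strictly interior band bins so adjacent bands do not see each
other through the shared 4 Hz edge bin.  Known limitation: when one ROI
participates in many couplings, the pairwise phase coherence of each
single pair is diluted by the others; rank recovery of planted weights
is therefore validated on matching-structured targets (each ROI in one
coupled pair), where the measured-vs-planted Spearman correlation
exceeds 0.95.  Densely coupled mixtures compress all pairwise values
toward the noise floor, which is why the study-flow pipeline defaults to
direct synthetic adjacency for its network stage (the full
signal-to-adjacency route remains available via
`network_mode="simulated_eeg"`).

## Hubs

`scdnet.graph_hubs` maps weights to lengths 1/w (zero weight = no edge;
-log w available by option), counts all-pairs shortest paths with
fractional credit for ties (Brandes' algorithm via networkx), and reports
unnormalized betweenness with endpoints excluded; disconnected pairs
contribute nothing.  Hubs are nodes with BC >= mean + 1.5 SD (ddof = 1),
ties included; a constant BC vector yields an empty hub set with an
explanatory note since the rule cannot single out nodes.  Normalization
of BC is immaterial to the rule (it is invariant under positive affine
transforms of BC, which the property tests assert).  Hub analysis runs
on the group-average adjacency per band, matching a single hub set and
Venn partition per band; hub turnover between groups is the partition
into shared, lost-in-SCD and gained-in-SCD sets.

The shipped 58-ROI atlas covers 29 Brodmann areas bilaterally with
approximate literature centroid coordinates; it is a reconstruction (no
authoritative list is redistributed) and any atlas CSV with the same
columns can be substituted.

## Spatial network similarity

`scdnet.siminet` scores two spatially embedded weighted graphs in [0, 1].
Node stage: nodes within `epsilon` are common (cost 0); remaining cross
pairs are matched greedily nearest-first and substituted at cost equal to
their Euclidean distance normalized by the coordinate-space diameter,
but only when that normalized distance is below the insertion cost
`c_ins` (default 1.0) — otherwise the nodes are deleted/inserted at
`c_ins` each.  Edge stage: the node correspondence maps edges across,
and the cost is the sum of |w1 - w2| over the union (absent edges count
as weight 0).  Both costs are normalized by their empty-overlap maxima
((|V1| + |V2|) * c_ins and sum(w1) + sum(w2)) and mixed with alpha
(default 0.5); the index is 1 minus the mixture.  Identical graphs score
exactly 1; graphs with no common nodes at maximal separation and
disjoint edges score exactly 0.  Ties in the greedy matching break on
sorted node labels, making the index symmetric and deterministic.

On a fixed atlas every network contains all 58 nodes, which would make
the node stage vacuous; adjacency matrices are therefore proportionally
thresholded (strongest 20% of weights kept, configurable) and a node is
present iff its thresholded degree is positive.  This presence rule is a
reconstruction choice and is flagged as such.  The study protocol —
each SCD subject's network against the averaged non-SCD network, mean
+- SD per band — is what the pipeline and analysis scripts compute.

## Pipeline and selection rules

Subjects are grouped by the 12-item memory-complaint sum score at the
inclusive cutoff 20.  Because grouping conditions on an indicator of the
target latent, per-group path estimates at n ~ 40-55 carry both
truncation effects and small-sample spread; the integration tests assert
only the planted sign pattern.  The middle-of-distribution selection
(24 non-SCD / 26 SCD) trims both tails of the within-group composite
ranking symmetrically; when an odd number must go, the tail farther from
the group median loses first, and ties resolve in stable subject-id
order — a documented deterministic convention, since only the intent
(focus on the middle of the distribution) is specified by the design.
The normality gate for descriptive comparisons is Shapiro-Wilk at
alpha = 0.05 per group; both groups normal -> two-sample t-test,
otherwise Mann-Whitney U, always two-tailed; constant-in-both-groups
variables report p = 1 with a degeneracy note.

Every stage is a pure function of (inputs, config, seed); identical
config + seed give byte-identical summary JSON.  Default problem sizes
in the analysis scripts: 95 subjects, 58 ROIs, 24/26 networks per band
with per-subject jitter SD 0.03, 2000 permutations for the multigroup
test, 100 epochs for the connectivity validation subject.  The
permutation count is a scaled-down default of the 10,000 the full
protocol prescribes; it changes nothing structurally and keeps a full
run near one minute.

## Known limitations

- The generator plants orthogonal exogenous constructs by default; real
  questionnaire constructs correlate substantially.
- PLS attenuation and chance capitalization (above) bound what "recovery"
  can mean at small n.
- The oscillator model validates pairwise coupling recovery only on
  sparse (matching-structured) targets; densely coupled mixtures dilute
  pairwise phase coherence by construction.
- The atlas coordinates are approximate centroids; spatial substitution
  costs in the similarity index inherit that approximation.
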
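# Methods

## Overview

`braingraph` implements a complete graph-theoretical analysis chain for
resting-state fMRI functional connectivity at the ROI level, together with a
synthetic cohort generator that gives every downstream stage a recoverable
ground truth.  The chain is: ROI time-series cleaning → Pearson
connectivity → fixed-density binarization across a 10–50% cost sweep →
nodal/global graph measures with degree-preserving null models → hub
detection → covariate-adjusted group statistics with FDR control →
nested-RFE cross-validated classification of ADHD-like vs TD-like subjects,
including a deliberate "circular" mode that quantifies the accuracy
inflation caused by selecting features on all subjects before
cross-validation.

## Synthetic cohort model

Each group receives a Watts–Strogatz group graph on `n_roi = 116` nodes
(AAL-116 labels) with ring-lattice degree `k = 10`; the TD-like group is
rewired with probability 0.2 and the ADHD-like group with 0.02.  Less
rewiring means fewer long-range shortcuts, hence a longer characteristic
path length (Lp) and lower global efficiency in the ADHD-like group — the
topological contrast every recovery experiment targets.  Subject
heterogeneity moves a small fraction (2%) of group-graph edges to random
vacant pairs, preserving the edge count exactly.

Both group graphs are drawn with **common random numbers** (the same
substream, differing only in the rewiring probability).  Two consequences:
a null configuration (equal rewiring) yields *identical* group graphs, so
there is no graph-level cluster effect and subject-level group tests keep
their nominal type-I error; and under the effect configuration the shared
randomness reduces between-cohort simulation noise.  Without this, each
group's shared graph realization acts as a cluster random effect that makes
subject-level tests anti-conservative.

ROI time series are drawn from a zero-mean multivariate normal with
covariance `Σ = I + c·A`, where `A` is the subject's adjacency matrix.  The
population correlation of a connected pair is then exactly `c` and of an
unconnected pair exactly 0, which keeps recovery tests analytic.  Validity
requires `Σ` positive definite, i.e. `c·λ_max(A) < 1`; the configuration
check uses the conservative lattice-degree bound (`c·k < 1`) and every
emitted subject is verified exactly via Cholesky factorization.

**Coupling strength.** The default is `c = 0.09`.  Empirically
`λ_max(A) ≤ 10.4` across hundreds of jittered degree-10 subject graphs, so
0.09 leaves a ~7% spectral margin.  Real functional connectivity is far
stronger (adjacent-region correlations of 0.3–0.6), but the linear-Gaussian
family bounds the attainable correlation at `1/λ_max ≈ 0.096`; "realistic"
within this family therefore means close to the cap.  At 226 time points
the sampling noise of a correlation coefficient is ≈ 1/√226 ≈ 0.067, so the
per-edge signal-to-noise ratio is about 1.35 and the thresholded networks
are noisy but structured — deliberately a hard, not a toy, recovery
problem.

Covariates mirror a two-group developmental cohort: age matched (≈11.5 ±
2 y), all three Wechsler IQs lower in the ADHD-like group (e.g. full IQ
118.2 ± 13.5 vs 103.6 ± 12.6), mean frame-wise displacement ≈ 0.15 mm, and
majority-male groups (44/56 and 49/56).  Motion traces are small-step
random walks with isolated one-volume translation offsets (0.3 mm per axis,
FD = 0.9 mm) at rate 0.05 per volume; spike volumes are recorded in the
ground truth.

What the generator does **not** emulate: hemodynamics (no HRF, no
autocorrelation — series are temporally white), scanner drift or
physiological noise spectra, negative correlations, spatial structure of
parcels, or site effects.  Passing recovery tests therefore demonstrates
that the analysis chain recovers known topology from correlation-level
signal at realistic SNR; it does not certify performance on real BOLD data.

## Preprocessing

Fixed stage order: discard 10 initial volumes → per-column linear detrend →
ideal (rectangular frequency-domain) band-pass 0.01–0.1 Hz → motion
scrubbing → nuisance regression.  Choices:

* **FD** is the Power convention: Σ|Δtranslation| + 50 mm·Σ|Δrotation|,
  with FD(0) = 0.  Subjects with mean FD > 0.3 mm are excluded; volumes
  with FD > 0.5 mm are censored together with 1 preceding and 2 following
  volumes and replaced by per-column linear interpolation between the
  nearest retained neighbours (nearest-value extension at the ends).  The
  two thresholds are independent configuration fields.
* **Band-pass** zeroes DFT coefficients outside [0.01, 0.1] Hz (toolbox-style
  ideal filter) — exactly testable pass/stop behaviour, no filter ringing
  model.
* **Nuisance design** is the Friston-24 expansion (6 parameters, their
  one-lag backward differences, both squared).  White-matter/CSF signals do
  not exist at ROI level; the optional `motion24+global-like` mode adds the
  grand mean over all ROI series as a global-signal proxy.
* The stage order (scrub after filtering, regression last) is fixed and
  logged; each stage is deterministic.

## Network construction

Pearson correlation between all ROI pairs gives a symmetric 116 × 116
matrix (constant series are an error naming the ROI).  Binarization keeps
the top `⌊density·n(n−1)/2⌋` upper-triangle values — 667 edges at 10% and
3335 at 50% for n = 116 — ranking by signed correlation by default
(absolute-value ranking by flag); ties at the cutoff break by (row, column)
order, so the edge sets of a density sweep are nested and deterministic.
Fisher z-transformation is omitted: it is strictly monotone, hence
irrelevant to a rank-based binary network.

## Graph measures

Conventions (all on binary undirected graphs): clustering = triangles over
possible neighbour pairs, 0 for degree < 2; Lp = mean hop distance over
*reachable* pairs only, with the number of excluded pairs reported (10%
density networks are often disconnected); global/nodal efficiency = mean of
1/d with 1/∞ = 0; local efficiency = efficiency of each neighbour-induced
subgraph; betweenness unnormalized (normalization by flag); assortativity =
Newman degree–degree Pearson correlation over edge end points (undefined on
regular graphs); hierarchy = exponent β of C(k) ∝ k^(−β) fitted by least
squares on log–log over nodes with k ≥ 2, C > 0; synchronization = Laplacian
eigenratio λ₂/λ_max (0 when disconnected).

Small-world coefficients γ = Cp/⟨C_rand⟩, λ = Lp/⟨L_rand⟩, σ = γ/λ (the
ratio some texts label δ) are
normalized by an ensemble (default 100) of degree-preserving random
networks generated by double-edge swaps (10 attempted swaps per edge), the
Markov-chain null model.  When the input is disconnected the coefficients
are computed on the largest connected component and the coverage is
reported.  Null ensembles are seeded per subject and density, so results
are reproducible and parallelizable.

A per-density series is summarized over the sweep by its trapezoidal
average (AUC divided by the density range), so a constant series maps to
itself; group statistics and classification features use these AUC
summaries by default.

**A calibration fact worth knowing:** for Watts–Strogatz graphs at
(n = 116, k = 10, p = 0.1) the normalized path length against exact
degree-preserving nulls is λ ≈ 1.23 ± 0.02, not 1.0 — the null ensemble is
well mixed (its mean Lp equals that of a true G(n,m) random graph), the
graph itself simply retains longer paths at this rewiring level.  γ ≈ 7 and
σ ≈ 5.6, so small-worldness (σ > 1) is recovered in every replicate.

## Group statistics

Demographics use pooled-variance t-tests (callable on raw vectors or
summary statistics) and the uncorrected Pearson chi-square for 2 × 2 gender
tables (the Yates-corrected value would be ≈1.01 rather than the reference
1.585 for the template table, so no correction is applied).  Graph-measure
comparisons are OLS ANCOVAs `metric ~ group + age + gender + FD + three
IQs` with Benjamini–Hochberg FDR across metrics; zero-variance covariates
are pruned with a warning, so the test degrades gracefully to a two-sample
t-test.  Direction is reported as ADHD − TD.  Hubs are nodes whose
group-mean centrality (betweenness by default, degree by flag) exceeds the
across-node mean by more than two across-node standard deviations.

## Classification

Features are the 10 global AUC measures plus 6 nodal AUC measures × 116
ROIs (706 columns, named `metric__ROI`).  Undefined values (e.g.
assortativity of a degenerate graph) are median-imputed *within the
training portion only*.  RFE refits the model, ranks features by |w|
(linear SVM) or impurity importance (random forest / gradient boosting) and
drops the lowest 10% per round (0.5 for the tree models in the packaged
experiments, where refit cost dominates) until 12 remain.  Cross-validation
is stratified 9-fold; metrics (accuracy, sensitivity, specificity, PPV,
NPV; ADHD positive) are computed from pooled confusion counts for
determinism.  The circular mode — RFE once on all subjects, then the same
CV — exists solely to measure the inflation it causes; on label-permuted
cohorts nested CV is unbiased at 50% while circular CV is inflated by
~20–30 percentage points at these sample sizes.

## Scaled experiment sizes

The packaged experiments (`braingraph.experiments`, also used by
`scripts/acceptance.py`) run at sizes a single CPU handles in minutes,
chosen as the package's own study scales: recovery/type-I cohorts use the
full 112 subjects and 116 ROIs but a 5-point density grid (10–50% in 10%
steps) and the reduced global metric set {Cp, Lp, global efficiency}
(no null-normalized coefficients, whose per-subject ensembles dominate
runtime; local efficiency likewise omitted there); small-world replicates
use 20-network ensembles; classification audits use a 235-feature reduced
matrix (3 global + nodal degree and nodal efficiency blocks).  Preprocessing
is skipped inside simulation experiments because the generator emits
trend-free, white, spike-free-by-construction series there; the full
pipeline (including preprocessing) is exercised end to end by the CLI and
pipeline tests.

## Known limitations

* The generator's white-noise Gaussian model understates the temporal
  autocorrelation of BOLD, so its effective degrees of freedom are higher
  than real data at equal length; real-data effect sizes will be smaller.
* Only positive coupling is simulated; the signed-vs-absolute thresholding
  distinction matters more on real data with anticorrelations.
* Weighted-graph analysis is out of scope; all measures are binary.
* ANCOVA assumes linear covariate effects and homoscedastic residuals; no
  permutation-based alternative is provided.
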
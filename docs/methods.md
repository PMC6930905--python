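# Methods

`smnet` re-implements, as a tested pipeline over synthetic data, a
graph-theoretic analysis of how repetitive transcranial magnetic
stimulation (rTMS) over left M1 reorganises the resting-state
sensorimotor network (SMN): 29 ROI time series per scan, Pearson
connectivity, sparsity-thresholded binary graphs, efficiency and
centrality metrics normalised against degree-preserving null networks,
and a group x session mixed-design ANOVA with post-hoc t-tests, ALFF
and seed-FC follow-up.

## The synthetic cohort

No scanner data ships with the package; a generative model stands in
for the study cohort so that every stage is verifiable against known
ground truth.

**Design.** Three groups (HF = 3 Hz, LF = 1 Hz, SHAM), 15 subjects per
group, two sessions (pre/post stimulation), 240 volumes at TR = 2 s —
the study's design parameters.

**Ground-truth network.** A 29-node correlation matrix with three
communities derived from the bundled atlas: medial (|x| ≤ 15 mm; SMA,
paracentral lobule, cingulate), left-lateral and right-lateral
sensorimotor cortex. Within-community correlation 0.45, between 0.25,
and four hub nodes (left PCL, right SMA, left postcentral, right
precentral) with cross-community coupling floored at 0.35. These
contrasts were chosen once so that the thresholded networks land in
the small-world regime the study reports (normalized global efficiency
≈ 0.9, normalized local efficiency ≈ 1.7); a stronger contrast
(0.5/0.15) over-clusters (E~loc > 2). The matrix is repaired by
eigenvalue clipping if hub bumps break positive-semidefiniteness.

**Signals.** White multivariate Gaussian draws are coloured by the
Cholesky factor of the covariance, band-pass filtered to 0.01–0.08 Hz
with the same operator used in preprocessing, rescaled to unit
variance, and white measurement noise (sd 0.4 in signal units) is
added. Noise-free signals hold ≥ 80% of their variance in band. No
haemodynamic convolution, spatial structure or realistic motion
artefacts are modelled — so passing tests validate the numerics and
inference of the pipeline, not its robustness to scanner artefacts.

**Planted effects.** Post-session only: the target node's off-diagonal
covariance is scaled by a connectivity-attenuation factor (default
0.5) and its signal amplitude by an amplitude-attenuation factor
(default 0.7). LF targets the left-PCL analog, HF the right-SMA
analog, SHAM nothing — the direction of the study's findings. Each
subject's two factors are raised to a shared "responsiveness" exponent
drawn Uniform(0.5, 1.5); the shared exponent is what makes the
degree-AUC change and ALFF change positively correlated across
subjects, the analog of the reported change-score correlation.
Seeds derive from the cohort seed by a spawn-key (counter) scheme;
cohort generation is bit-reproducible.

## Preprocessing

Temporal stages only (the spatial stages of an fMRI pipeline operate on
images and are out of scope): discard 5 volumes → linear detrend →
band-pass 0.01–0.08 Hz → OLS regression of nuisance signals
(Friston-24 motion expansion, WM, CSF), themselves band-passed with the
same operator. All operators are linear and commute with the weighted
ROI averaging used for node definition, which is why ROI-level
operation is equivalent to voxel-then-average.

The band-pass is a zero-phase *ideal* (frequency-domain) filter: bins
outside the band are zeroed. It is an orthogonal projection, hence
exactly idempotent, removes DC exactly, and is the construction used in
the classic resting-state toolchains; an IIR (Butterworth) alternative
was rejected because its band-edge roll-off changes band-shaped signals
by ~10% RMS on every repeated application. Lag convention for the
Friston-24 expansion: one-timepoint backward shift, first row
zero-padded. Global signal is not regressed.

## Network construction

Pearson correlation between all ROI pairs (zero-variance columns are a
hard error naming the ROI), diagonal stored as zero. Binarisation at
sparsity S keeps the K = round(S·N(N−1)/2) strongest strictly positive
correlations (negative edges are never admitted); if fewer positives
exist, all are kept and the achieved sparsity recorded. Ties at the
cutoff break lexicographically (smaller i, then j), so edge sets are
exactly nested along the grid — which both guarantees monotone global
efficiency and enables the incremental degree-curve fast path
(`degree_sparsity_curve`, proven identical to per-level thresholding).
The sparsity grid is 0.04–0.40 in steps of 0.02 (19 levels,
decimal-safe). Connectedness is not enforced; disconnected graphs are
handled by the efficiency formalism.

## Graph metrics

For a binary graph G with N nodes and K edges, with d_ij the BFS hop
distance and 1/d_ij := 0 for unreachable pairs:

- global efficiency E_glob = (1/(N(N−1))) Σ_{i≠j} 1/d_ij (the
  Latora–Marchiori prefactor; complete graph → 1),
- nodal efficiency E_nodal(i) = (1/(N−1)) Σ_{j≠i} 1/d_ij,
- local efficiency E_loc = (1/N) Σ_i E_glob(G_i) with G_i the subgraph
  induced by i's neighbours (defined 0 when |G_i| < 2),
- degree N_dc(i) = Σ_j a_ij,
- betweenness N_bc(i) = Σ_{j<k} σ_jk(i)/σ_jk, unnormalised, over
  unordered pairs, by Brandes' accumulation.

Null model: double-edge-swap rewiring that rejects self-loops and
multi-edges, preserving the degree sequence and edge count exactly; 10
accepted swaps per edge per null (capped at 20x attempts; graphs with
no valid swap, e.g. a triangle, return unchanged). Normalised
efficiencies divide by the mean over the null ensemble; a zero null
mean yields NaN rather than infinity. A session is classified
small-world when the grid means (NaN-aware, since very sparse
thresholds can have undefined null local efficiency) satisfy
E~loc > 1 and |E~glob − 1| ≤ 0.15.

Each metric is integrated over the sparsity grid by the trapezoidal
rule; these AUCs are the per-subject responses fed to inference.

## Activity and connectivity follow-up

ALFF is the mean, over in-band periodogram bins, of the square root of
power (the original amplitude-spectrum definition; no whole-brain mALFF
rescaling, which has no meaning at ROI scale). It is computed on the
same preprocessed series as the network analysis. Seed FC is Pearson r
to each other node, Fisher-transformed (z = atanh r); |r| = 1 is
carried as missing with a warning.

## Inference

- Demographics: one-way ANOVA from per-group summary statistics and
  Pearson chi-square (no continuity correction).
- Metric AUCs: classical split-plot (mixed-design) ANOVA — group tested
  against subjects-within-groups, session and group x session against
  the session x subjects residual. With two within levels the
  interaction F is algebraically the one-way F on per-subject
  difference scores, and sphericity corrections are vacuous. F ratios
  with a zero denominator are flagged infinite, not silently divided.
- Bonferroni families: m = 29 (nodes) per nodal metric, m = 1 per
  global metric; the family sizes are recorded in the outputs so users
  can re-correct.
- Post-hoc (only where the corrected interaction is significant):
  paired pre-vs-post t-tests within each group and two-sample t-tests
  between groups at each session, Bonferroni over the 9 contrasts run.
- Follow-up FC/ALFF paired t-tests are reported uncorrected (flagged as
  such), and change-score associations use Pearson correlation with
  the t-based p (n−2 df).

## Problem sizes used by tests and the acceptance script

Chosen as the package's own validation budget: metric-oracle
equivalence is exhaustive over every labelled graph on ≤ 6 nodes plus
200 random 12-node graphs; small-world classification runs the full
90-session default cohort with 20 nulls per threshold (the 100-null
study setting is the pipeline default, configurable); the interaction
test's size uses 1000 null-cohort replicates via the nested-degree fast
path on unpreprocessed simulator output (which is already band-limited
and nuisance-free); effect recovery uses 20–25 cohorts analysing the
LF group, whose subjects are the only ones entering those measures.

## Known limitations

- The generator emulates second-order statistics only; non-Gaussian
  BOLD features, motion artefacts and physiological confounds are
  absent, so nuisance regression is exercised on idealised regressors.
- Effect sizes are invented (the study reports none); planted defaults
  give near-ceiling recovery, so recovery rates here are not power
  estimates for real rTMS effects.
- Binary undirected graphs only; weighted/directed variants, community
  metrics and rich-club analysis are out of scope.
- The ideal band-pass assumes stationarity over the scan and has no
  roll-off; filtered series have exactly zero out-of-band energy,
  unlike IIR-filtered real data.
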
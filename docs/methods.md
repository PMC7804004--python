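# Methods

This note documents the model, the statistical procedure, the synthetic
cohort generator, and the numerical and design choices behind `ctnets`.

## The structural covariance network model

A structural covariance network treats each cortical region's mean
thickness as a random variable over subjects and defines connectivity as
the across-subject Pearson correlation between region pairs.  For a
cohort of M subjects and N = 148 Destrieux-style regions the pipeline:

1. **Residualizes covariates.**  At every region, ordinary least squares
   removes age, sex, the age-by-sex interaction and the subject's mean
   cortical thickness (the unweighted mean of the N region values).
   Residual columns are exactly orthogonal to the design; in particular,
   because the mean-CT regressor is itself the column mean, residual
   *row sums are exactly zero*.  This identity matters: it forces the
   average off-diagonal correlation to be negative
   (Σ_{i<j} cov(e_i, e_j) = −½ Σ_i var(e_i)), so roughly half of all
   residual correlations are negative in any data processed this way.
2. **Correlates and clips.**  Pearson correlation across subjects, zero
   diagonal, negative entries set to zero (no physiological
   interpretation attaches to negative structural covariance, and
   negatives are partly an artifact of global-mean removal).
3. **Thresholds over a sparsity sweep.**  Binary graphs keep the
   K = round((1 − s)·N(N−1)/2) strongest positive correlations at each
   sparsity s in 0.5, 0.52, …, 0.9.  *Sparsity here is the fraction of
   absent edges* (density = 1 − s): the sweep spans densities 0.5 down
   to 0.1.  This convention is the only one compatible with meaningful
   community structure at the single modularity-reporting sparsity of
   0.88 and with a binding connectedness constraint at the sparse end;
   the opposite reading is available as a config flag
   (`sparsity_convention: present`).  Ties at the cutoff break by
   ascending (row, column) index so runs are bit-reproducible.
   When K exceeds the number of strictly positive entries — which the
   row-sum identity above makes unavoidable near density 0.5 — the sweep
   keeps every positive edge (the behavior of proportional thresholding
   in the standard brain-connectivity toolboxes); the strict
   `threshold_to_binary` operation errors by default instead.
4. **Bootstraps subjects.**  Nboot resamples with replacement
   (study-scale default 2000; desk-scale runs use 100–200), re-fitting
   the covariate regression within each resample so regression
   uncertainty propagates ("resample-then-residualize"; the alternative
   of residualizing once is not exposed because it only narrows the
   bootstrap distribution).

## Network properties

Seven binary-graph properties are computed at every sparsity for every
bootstrap sample, plus two weighted (threshold-free) properties per
sample:

* **Clustering index** — mean over nodes of the closed-triple fraction
  (nodes of degree < 2 contribute 0).
* **Characteristic path length** — mean shortest-path distance within
  the largest connected component (a harmonic-mean variant is
  available; the LCC convention mirrors the connectedness constraint
  used for the nodal analysis).
* **Global efficiency** — mean of 1/d over all ordered pairs, 0 for
  disconnected pairs.
* **Local efficiency** — mean over nodes of the global efficiency of
  the neighbor-induced subgraph.
* **Normalized betweenness centrality (NBC)** — Brandes betweenness
  (unordered pairs, endpoints excluded) divided by the network-mean
  betweenness, so NBC > 1.5 reads "50% above the average node"; that
  strict threshold defines hubs.
* **Modularity Q** — Newman spectral community detection (recursive
  bisection of the modularity matrix with deterministic Kernighan–Lin
  refinement; the leading eigenvector comes from a fixed-start shifted
  power iteration).  A split is kept only if it increases Q, which also
  decides the module count.
* **Targeted attack** — nodes are removed in order of betweenness until
  half the network is gone, tracking the largest-component size
  relative to the intact node count; the scalar is the trapezoidal area
  under that curve.  The standalone operation recomputes betweenness
  after every removal (the classic adaptive attack).  Inside the
  bootstrap sweep the removal order is fixed from the intact graph's
  betweenness: the adaptive variant costs ~0.5 s per 148-node graph and
  the sweep evaluates tens of thousands of graphs, while the two
  orderings are equally standard in the attack-tolerance literature and
  the group *difference* of the resulting AUC is what the comparison
  uses.  The strategy is a config switch (`attack_strategy`).
* **Global connectivity** (weighted) — mean of the positive-clipped
  correlations over all pairs; **homologous connectivity** — mean
  correlation over the 74 left–right mirror-region pairs.  Both are
  properties of the weighted matrix and enter the comparison as one
  scalar per bootstrap sample, not as sweep AUCs.

AUC summaries integrate each property curve over the *grid index* (unit
spacing): a constant curve c over G points has AUC (G−1)·c.  Integrating
over sparsity units would only rescale every comparison by the constant
step and can never reorder groups.

## Group comparison statistics

For each property, the bootstrap difference distribution
D_b = AUC_A,b − AUC_B,b pairs the two groups' independent bootstrap
streams by index.  Significance is declared when the 95% interval
excludes zero; a two-sided empirical p-value
2·min(#{D ≤ 0}, #{D ≥ 0} + 1)/(B + 1) accompanies each test.

**Interval choice.**  Three flavors are implemented.  The default is a
bootstrap standard-error interval centered on the *full-sample*
difference estimate.  The bias-corrected percentile interval
(`ci_method: bc_percentile`) is the flavor this literature usually
names, but on null simulations it rejects far too often here: for
rank-thresholded graph statistics at cohort sizes of ~120 subjects, the
bootstrap distribution's center regresses toward a mean-field value
(bootstrap resamples carry ~1.26× the correlation noise of the original
sample, making their thresholded graphs systematically more
random-like).  The bias-correction term z₀ misreads that decentering as
estimator bias and shifts the interval outward, producing null
rejection rates up to ~0.45 for the attack and modularity AUCs.  The
plain percentile interval under-rejects for the mirror-image reason.
The SE interval centered on the full-sample estimate uses the bootstrap
only for spread — which does track the sampling variance — with a
t(B−1) quantile because the spread is itself estimated from B draws,
and is approximately calibrated; the acceptance suite verifies type-I
error in [0.02, 0.09] per property on 200 null replicates.  The
modularity AUC is the weakest-calibrated property and sits near the
upper edge of that band: its bootstrap spread underestimates its
sampling spread by roughly 15% in this regime, which is expected —
detected Q is a maximum over partitions, and the classical bootstrap is
known to be unreliable for maximum-type statistics.  Modularity
significance calls from this pipeline deserve extra skepticism.

**Nodal analysis.**  NBC curves are restricted to the sparsity range in
which *every* bootstrap network of both groups is fully connected (the
minimum over samples of the largest sparsity with a connected graph).
Per-region AUCs over that restricted range are compared with the same
paired-bootstrap test, and Benjamini–Hochberg FDR is applied across the
148 regions (via statsmodels; a brute-force step-up oracle guards it in
the tests).  Hubs are regions whose mean NBC across bootstrap samples
and the restricted grid strictly exceeds 1.5.

**Modularity report.**  Community structure is reported per group from
the full-sample correlation matrix thresholded at the single sparsity
0.88, with module sizes and a per-lobe composition table; a
disconnected graph at that sparsity is reported, not an error.

## The synthetic cohort generator

The generator emulates a two-group elderly MCI-like cohort: 126
"carrier" and 127 "non-carrier" subjects, ages uniform on 55–90 y, 63%
male, regional thickness on the FreeSurfer scale (grand mean 2.23 mm,
regional spread 0.13 mm).  Region values are drawn from a latent
Gaussian with a prescribed correlation matrix assembled from four
layers:

* **Modules** — equicorrelated blocks (`rho_within` inside the five
  ground-truth modules of sizes 30/33/39/22/24, `rho_between`
  elsewhere);
* **Diffuse signed structure** — a fixed random-factor layer
  `rho_diffuse · U Uᵀ` with hemisphere-mirrored unit-norm Gaussian
  loadings (8 factors, deterministic internal seed shared by both
  groups).  It gives every pair a distinct latent correlation with both
  signs, emulating the continuous spread of empirical thickness
  covariance.  Two properties of real data that a pure nonnegative
  block model cannot reproduce depend on it: (i) a substantial share of
  correlations survives global-mean removal as positive, because the
  zero-mean loadings are nearly orthogonal to the uniform vector; and
  (ii) thresholds fall on a continuum of values rather than inside a
  band of exact ties, which keeps bootstrap rankings meaningful;
* **Homolog coupling** — mirror pairs are raised (never lowered) to
  `rho_homolog`; the mirrored diffuse loadings add further left–right
  coupling, as in real data;
* **Hubs** — optional regions with elevated diffuse coupling: an
  additive rank-1 factor in which hub regions load 1.0 and all others
  0.4, scaled by `rho_hub` (PSD-safe by construction).  The default
  cohort plants 12 mirrored hubs.  Note a deliberate realism gap: the
  resulting centrality tail is milder than empirical cortex, and after
  averaging NBC over the (mostly dense) connected sweep range no region
  crosses the 1.5 hub rule under the defaults — empirical cohorts do
  report hubs because their sparse-graph centrality spread is far
  larger.  Hub detection is therefore exercised by planted star-like
  test cases rather than by the default cohort.

The assembled matrix is exactly PSD with unit diagonal whenever
`rho_within + rho_diffuse ≤ 1`; the homolog/hub overrides can perturb
that slightly, so a final eigenvalue-clipping projection (deviation
logged, warning above 0.1) guarantees a valid correlation matrix.

Nuisance structure: additive age (−0.004 mm/y), sex (+0.03 mm male) and
age-by-sex (+0.0008 mm/y) effects, a multiplicative subject-level
global-thickness factor (mean 1, sd 0.04) and Gaussian measurement
noise (sd 0.06 mm).  Measurement noise attenuates observed correlations
by sd²/(sd² + noise_sd²) ≈ 0.82 at the defaults; recovery tests use the
projection-corrected oracle corr(PΣP) (P = I − J/N) because mean-CT
regression provably recenters correlations — the latent targets are
recovered exactly only before residualization.

The default carrier/non-carrier contrast weakens the carrier group's
within-module (0.34 vs 0.40), between-module (0.09 vs 0.10) and homolog
(0.44 vs 0.50) coupling — the direction of the disruption the pipeline
is designed to detect (lower clustering, local efficiency, modularity
and homologous connectivity; higher global efficiency in the carrier
group).  The power acceptance test uses a larger, purely within-module
contrast (0.65 vs 0.40) sized from pilot variance estimates so the
weakest property clears 90% detection power with margin at
n = 120/group with N = 40 regions; the study-scale contrast this
emulates was reported with p-values near 1e-5, i.e. comfortably inside
the detectable regime.

What the generator does **not** emulate: vertex-level surfaces, scanner
and site effects, longitudinal change, region-specific variance
profiles, non-Gaussian thickness distributions, and spatial
autocorrelation beyond the module/gradient layers.  Passing tests
demonstrate correctness and calibration of the *pipeline* under a
plausible covariance topology — not that any particular empirical
cohort satisfies the model.

## Problem sizes used by the test suite

Simulation-based checks are sized to run on one CPU in minutes, as is
standard for a test suite: the null-calibration study uses N = 40
regions, 120 subjects/group, 100 bootstrap samples, an 11-point grid
and 200 replicates; the power study uses 20 seeds at the same shape
with 150 bootstrap samples; the end-to-end run uses the full cohort
shape (148 regions, 253 subjects, 21-point grid) with 200 bootstrap
samples.  The study-scale default of Nboot = 2000 remains the config
default for real analyses.

## Numerical choices

* Thresholding ties: lexicographic (row, column) order, making every
  graph, and therefore every downstream file, bit-reproducible.
* Newman detection: fixed-start shifted power iteration (Gershgorin
  shift, tolerance 1e-12, 500-iteration cap) and a deterministic KL
  sweep (best admissible move per step, ties to the lowest node id);
  splits need ΔQ > 1e-10.
* Bootstrap seeds: one master seed; per-group generators come from
  `SeedSequence.spawn`, so group streams are independent but the whole
  run is reproducible from the manifest.
* Degenerate inputs: < 3 distinct subjects in a resample triggers a
  logged redraw (max 100); zero-variance regions, rank-deficient
  designs (e.g. single-sex cohorts) and edgeless graphs raise with
  specific messages.
* The bias-correction proportion in the BC interval uses midranks for
  ties and is clamped to [1/(B+1), B/(B+1)] so degenerate distributions
  yield the degenerate interval rather than ±∞.

## Known limitations

* The SE-interval default trades the literature's named interval for
  calibration; both are available, and on smooth statistics (the two
  weighted connectivities) they agree closely.
* The initial-order attack in the sweep is a different estimand from
  the adaptive attack (it upper-bounds resilience); group differences
  proved insensitive to the choice on pilot runs, but single-network
  attack analyses should use the adaptive default.
* Near density 0.5 the graphs of *any* mean-CT-residualized dataset
  saturate at the positive-edge capacity (~0.43–0.45 here), so the
  first few sweep points can coincide; the AUC then weights that
  capped regime accordingly.
* Pearson correlation only: no partial correlations (the cohort sizes
  in scope cannot support stable 148-dimensional partial correlation
  estimates), no covariance shrinkage, no weighted-graph metrics.
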
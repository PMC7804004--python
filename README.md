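# ctnets — cortical-thickness structural covariance networks

`ctnets` builds group-wise **structural covariance networks** from
regional cortical-thickness tables (FreeSurfer Destrieux-style exports:
one row per subject, one column per region) and tests how a genetic or
clinical factor reshapes their topology.  It was built for the classic
two-group design in neuroimaging genetics — e.g. ApoE4 carriers versus
non-carriers in mild cognitive impairment — where the connectivity of
interest is the *across-subject correlation* of regional thickness, not
any per-subject signal.

## What it computes

For each group with thickness matrix T (M subjects × N regions):

1. residualize age, sex, age×sex and subject mean thickness at every
   region (OLS);
2. form the N×N Pearson correlation matrix R across subjects, zero
   diagonal, negative entries clipped to 0;
3. draw Nboot bootstrap resamples of subjects (re-residualizing each),
   and threshold every matrix into binary graphs over a sparsity sweep
   s = 0.5, 0.52, …, 0.9, keeping the K(s) = round((1−s)·N(N−1)/2)
   strongest positive edges (sparsity = fraction of absent edges);
4. compute, per graph: clustering index C, characteristic path length
   L, global and local efficiency E_glob / E_loc, Newman modularity Q,
   a targeted-attack resilience score, and nodal normalized betweenness
   NBC_i = BC_i / mean(BC); plus two threshold-free properties of R —
   global connectivity (mean positive r) and homologous connectivity
   (mean r over left–right mirror pairs);
5. summarize each property curve by its area under the curve (AUC) over
   the sweep and compare groups through the paired bootstrap difference
   distribution D_b = AUC_A,b − AUC_B,b: significance when the 95% CI
   excludes zero, with an empirical two-sided p-value;
6. for nodal NBC, restrict the sweep to the range where every bootstrap
   network of both groups is connected, compare per region, and control
   the 148 tests with Benjamini–Hochberg FDR; hubs are regions with
   mean NBC > 1.5;
7. report each group's community structure (Newman spectral detection
   with Kernighan–Lin refinement) at sparsity 0.88.

A synthetic-cohort generator (latent-Gaussian covariance with modules,
hemisphere-mirrored diffuse factors, homolog coupling, covariate
effects and measurement noise) stands in for restricted-access cohort
data, so the entire pipeline is testable offline.  See
`docs/methods.md` for the model, conventions and statistical choices.

## Worked example

Simulate the default two-group cohort (148 regions; 126 carrier-like /
127 non-carrier-like subjects, carrier covariance mildly weakened) and
run the comparison with 200 bootstrap samples:

```bash
python analysis/01_simulate_cohort.py --seed 7
python analysis/02_global_network_comparison.py --seed 7 --n-boot 200
python analysis/03_nodal_centrality_and_hubs.py
python analysis/04_modularity_and_attack.py
```

`02_global_network_comparison.py` prints the global comparison
(carrier − non-carrier AUC differences with 95% CIs) and writes
`results/study/global_comparison.csv`, `nodal_comparison.csv`,
`hubs_<group>.csv`, `modules_<group>.csv` and a JSON run manifest that
reproduces the run byte-for-byte.  With the seed above it prints:

```
               property  estimate   ci_low   ci_high  significant
             clustering    -1.553   -2.225   -0.8816         True
            path_length     -1.27   -1.886   -0.6544         True
          target_attack   0.02973 0.001675   0.05779         True
       local_efficiency   -0.7548   -1.089    -0.421         True
      global_efficiency    0.2077   0.1109    0.3045         True
             modularity    -2.074   -3.165   -0.9827         True
    global_connectivity  -0.01111 -0.01647 -0.005751         True
homologous_connectivity  -0.01667 -0.05931   0.02597        False

connected sparsity bound: 0.90
```

Reading: the carrier-like group's covariance networks are less
clustered, less locally efficient, less modular and less globally
correlated, with shorter characteristic paths only in the sense of a
lower path-length AUC and *higher* global efficiency — exactly the
weakened-segregation pattern the generator plants (its carrier spec has
lower within-module, homolog and hub coupling).  A clustering AUC of
~9.1 over the 21-point sweep corresponds to a mean clustering index of
~0.46 per graph; global and homologous connectivity are on the raw
correlation scale (e.g. 0.075 vs 0.085).  `03_…` then lists the
FDR-significant regions and hub overlap, and `04_…` reports the module
decomposition at sparsity 0.88 (five modules per group here) and
adaptive targeted-attack curves.

The same pipeline runs from the command line on any cohort file:

```bash
ctnets run --dataset data/cohort/dataset.tsv --atlas data/cohort/atlas.csv \
    --n-boot 200 --seed 7 --out-dir results/study
ctnets modularity results/correlation.csv --sparsity 0.88
```

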
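# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `sparsemet`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The study the package implements

A breeding program evaluates n testcross lines (doubled-haploid lines
crossed to t testers) in m environments with r replicates. A *sparse
phenotyping design* splits the lines into a full set (FS), phenotyped
everywhere, and one or more equally-sized sparse sets (SS), each phenotyped
in only a subset of environments (possibly none). The masked cells are
predicted by GBLUP. The package evaluates designs by simulating many random
allocations and asking two questions per allocation: how accurate were the
predictions (four accuracy measures, AMs), and how related were FS and
sparse lines (eight relationship measures, RMs)? Correlating AMs with RMs
across allocations, per design and trait, measures whether the relationship
criteria could guide allocation before field testing.

### The 14 designs

Defaults mirror a 304-line, 5-environment trial. SP1–SP7 put 104 lines in
the FS, SP8–SP14 put 154; the (sparse sets, tested environments per set)
rows are (5,4), (10,3), (10,2), (5,1), (1,0) balanced and (5,3), (5,2)
unbalanced. *Balanced* means the untested-environment combinations of the
sparse sets are pairwise distinct with coverage as even as possible: when
the number of sets equals the number of combinations every combination is
used exactly once; when it equals the number of environments a rotated
window leaves each environment untested equally often. *Unbalanced* draws
distinct combinations uniformly with no coverage guarantee. The saved-plot
percentage is exactly 100 · n_sparse · (m − m_tested) / (n · m); the
literal full-set counts (104, 154) are authoritative rather than the
rounded "30%/50%" labels, because only the counts reproduce the published
saved-plot table. Designs with zero tested environments are a single
sparse pool predicted purely through the genomic relationship.

Environment assignments are redrawn per simulation (seeded); whether a real
program would fix them across repetitions is a design-level choice the
simulation deliberately averages over.

## Synthetic data generator

`simulate_marker_matrix` draws per-marker allele frequencies from
Uniform(0.02, 0.98) by default — wide enough that the standard
[0.05, 0.95] frequency filter has work to do — and Bernoulli 0/1 calls
(the lines are fully homozygous, so a dominant marker platform yields
presence/absence). Markers are exchangeable: no linkage disequilibrium,
map, or pedigree structure is simulated, so any conclusion that depends on
LD structure is out of reach of these tests.

`simulate_true_values` draws line-by-environment genetic values U with
cov(vec U) = Σ_E ⊗ G, Σ_E = TT′ + Ψ a one-factor (FA(1)) covariance.
Defaults derive Σ_E from the trait's variance components as the compound
symmetric special case T = √V_L·1, Ψ = V_{L×E}·I; explicit loadings and
specific variances can be supplied. Tester (σ² = 0.25), environment×tester
(σ² = 0.10), line×tester (V_LT) and line×tester×environment (V_LTE)
effects are independent normal; the paper-level source gives no tester
magnitudes, so those two defaults are stated assumptions.

`simulate_trial` lays the lines out in experiments (an even partition,
constant across environments, so each line sits in exactly one experiment),
replicates and blocks (a single blocks-per-replicate count, default 24 —
field-layout fidelity beyond block effects is irrelevant to the statistics
exercised), adds fixed design effects (SD 1.0), block effects
(variance 0.5) and residual noise.

Trait presets target entry-mean heritabilities GY 0.75, EPP 0.64, PH 0.93,
EH 0.91. The non-line components keep the proportions 2.5 : 0.6 : 1.5 : 6.0
(which contribute exactly 1.0 to the entry-mean denominator at
m=5, t=3, r=2, making the GY preset the exact set V_L=3, V_{L×E}=2.5,
V_LT=0.6, V_LTE=1.5, V_R=6) and are scaled jointly so the plug-in H² hits
the target at the *configured* (m, t, r). One trait is simulated per run;
multi-trait grids loop over presets.

Note that when genetic values are drawn with a marker-based G (diagonal
≈ 0.5 under the 0/1 coding, below), the realized genetic variance is scaled
accordingly; correlation-type results are unaffected.

## Genomic relationship machinery

VanRaden construction: Z is the 0/1 call matrix column-centered by the
allele frequency, G = ZZ′ / (2Σpⱼ(1−pⱼ)). Under doubled-haploid 0/1 coding
the variance of a call is p(1−p), not 2p(1−p), so the expected diagonal of
G is exactly 0.5 — the conventional denominator is kept verbatim and the
global factor of two cancels in every correlation and in GBLUP (it is
absorbed by the genetic variance). The frequency filter keeps markers with
p ∈ [0.05, 0.95], inclusive on both boundaries.

Duplicate genotypes (full sibs with identical marker profiles) make G
singular. `condition_and_invert` blends (1−w)G + wI with w = 0.02 by
default before Cholesky inversion; eigenvalue flooring was considered and
rejected as a second code path for no practical difference at these sizes.
PCA scores are eigenvectors scaled by the square root of the (zero-clipped)
eigenvalues, all components by default, so PP′ reconstructs G. The marker
distance matrix is plain Euclidean distance between 0/1 rows.

## Plot-level adjustment model

The plot model treats environment, experiment, environment×experiment and
replicate-within-both as fixed; block, line, tester, line×tester,
env×line, env×tester and env×line×tester as random with scalar variances;
and a homogeneous residual. Adjusted values are observation − fitted design
effects − block BLUP, averaged over replicates to one value per
line×tester×environment cell; the intercept is retained, so adjusted values
keep the trait scale. Rank-deficient fixed codings (inevitable with nested
dummies) are resolved by pivoted-QR column selection; dropped columns are
recorded on the fit.

Heritability components come from a refit with *all* terms random
(`all_random=True`), the parameterization under which V_L, V_{L×E}, V_LT,
V_LTE and V_R are read off; single-level design factors are skipped there
with a warning (they carry no variance). H² uses the entry-mean formula
above and is strictly increasing in m, t and r whenever the non-line
components are positive.

## EM-REML engine

All mixed models are fitted by one engine (`mixedmodel.EmReml`) on the
mixed-model equations. Random terms are integer level codes per record;
the coefficient matrix is accumulated by scatter-adds (incidence matrices
are never formed) and factorized densely. Variance updates are Henderson's
EM-REML: σ²_k ← (û′K⁻¹û + σ²_e tr(K⁻¹C^{kk})) / q_k from the inverse
coefficient-matrix blocks, σ²_e ← y′(y − Xβ̂ − Zû)/(n − p). The restricted
likelihood is evaluated through the determinant identity of the coefficient
matrix and cross-checked in the tests against a direct dense-covariance
evaluation (agreement ~1e−14) and against the closed-form balanced one-way
ANOVA solution.

The FA(1) G×E term u ~ N(0, Σ_E ⊗ G) is updated by an inner one-factor
factor-analysis EM (Rubin–Thayer) applied to the conditional moment matrix
S = (Û′G⁻¹Û + σ²_e·T_c)/n; because the inner step never decreases the
complete-data objective, the whole algorithm is a generalized EM and the
restricted log-likelihood is non-decreasing — asserted in the tests on
every fit. The loading sign is fixed by forcing the first loading ≥ 0;
loadings are initialized from the leading eigenvector of the empirical
between-environment covariance of the cell means. Plain EM is used without
extrapolation/acceleration: monotonicity is an invariant worth keeping, and
the problem sizes used do not warrant a safeguarded accelerator. EM is
slow near zero-variance boundaries; fits expose `require_convergence` so
long pipelines can cap iterations deliberately. Convergence tolerance
defaults: 1e−6 on successive log-likelihoods, 500 (adjustment) / 1000
(GBLUP) iterations.

## GBLUP with G×E

Model: fixed environment means; random tester, environment×tester and
line×tester (iid scalar variances); line-by-environment genetic effects
with covariance (TT′+Ψ) ⊗ G in FA1 mode, or a genomic line main effect
plus an iid-across-environments genomic interaction in RN (reaction-norm)
mode — the record-level Hadamard kernel (Z_g G Z_g′) ∘ (Z_s Z_s′) σ²_LS,
which is the Σ_E = σ²·11′ + σ²_LS·I special case of FA1 (the two modes
agree on compound-symmetric data; tested). The three-way
line×tester×environment term is absorbed into the FA line×environment
effect plus the iid line×tester effect; the residual is a single
homogeneous variance. BLUPs exist for every cell of the full grid, observed
or masked.

Per-line breeding values are the mean over environments of the
line×environment BLUPs plus the mean over testers of the line×tester
BLUPs. OBV comes from the complete-data fit, PBV from the masked fit —
i.e., accuracy is measured against the complete-data GBLUP, not against
simple phenotype means.

**Plug-in prediction.** By default the experiment driver estimates variance
components by REML once per trait on the complete data and *re-solves* the
mixed-model equations at those components for every masked allocation
(`reestimate=True` refits REML per mask). Components estimated from the
complete data are the best available for that data set, allocation masking
does not change the generating process, and a single solve per allocation
is what makes 100-simulation grids practical. One exact consequence:
with nothing masked the plug-in solve reproduces the complete fit, so
PC = 1 and CG = 100 hold to machine precision.

## Relationship measures

With P the PCA score matrix, P_T/P_V its FS/test rows and λ = 1e−5 (the
shrinkage used by the published software interface these criteria follow):

- PEV = P_V (P_T′P_T + λI)⁻¹ P_V′; PEVMEAN/PEVMAX are the mean/max
  diagonal, DOPT = log det(PEV + 1e−12·I), GOPTPEV = λ_max(PEV);
- AOPT = tr((P_T′P_T + λI)⁻¹), the A-optimality of the training
  information matrix (the verbal description "genomic prediction matrix" is
  ambiguous between the information and error matrices; the trace
  criterion belongs to the former, the max-eigenvalue criterion to the
  latter, and both resolutions are logged in output metadata by being
  exactly these formulas);
- CD_i = 1 − λ·PEV_ii/(p_i′p_i + λ) ∈ [0, 1], the standard BLUP
  reliability with λ = σ²_e/σ²_g (a test line identical to a training line
  → CD → 1; orthogonal to the training span → CD → λ/(p′p+λ) ≈ 0);
  CDMEAN/CDMAX are mean and max;
- NDT = −mean over FS×test pairs of the marker distance (pair mean rather
  than per-test minima; negated so that larger = closer, sign-aligned with
  the CD-type criteria).

The test set is the union of all sparse lines (a per-sparse-set averaging
variant exists behind `per_ss_mean`), so the RM vector depends only on the
line partition, not on environment masking. Monotonicity (growing the FS
never hurts any criterion) and exact agreement with naive dense
implementations are asserted in the tests; log-det agreement is only
numerically well-posed when the PEV matrix is positive definite, which
holds in real use because all PCA components are kept (k = n).

## Accuracy measures

PC is the Pearson correlation of OBV and PBV over all lines (FS and
sparse). Selection-based measures use the top 10% (k = ⌊0.10·n⌋, 30 of 304)
selected *by PBV* and evaluated *on OBV* — the decision-relevant reading:
CG = 100·|top_k(OBV) ∩ top_k(PBV)|/k; AR = mean OBV-rank (best = 1) of the
PBV-selected lines; SD = mean OBV of the PBV-selected minus the mean OBV of
all lines. Ties break by line id for determinism. Larger value = better
(grain-yield orientation); use `ascending` in `select_top` for traits where
smaller is better.

## Experiment driver and correlation stage

`run_design` spawns one child seed per (design, simulation) from the base
seed via `numpy` SeedSequence keyed on a design hash and the simulation
index, so any single cell is reproducible in isolation; failures are
logged and tolerated up to 10% per design. OBV is computed once per trait
and shared by all designs. `am_rm_correlations` computes, per
(design, trait) cell, the Pearson r of each of the 4×8 AM–RM pairs across
simulations with a two-sided t-test p-value (n−2 df); cells with a
constant metric report an undefined (NaN) r excluded from significance.
Raw p < 0.05 drives the significance flag (matching the convention of
coloring only raw-significant cells); a Benjamini–Hochberg column is
emitted alongside for users who want error control over the 32-cell grid.
`run_experiment` is deterministic end-to-end: rerunning a configuration
reproduces the output CSVs byte-identically; the manifest records seeds and
configuration, never timestamps.

## Problem sizes used by the test suite

The suite validates at reduced sizes chosen as the package's own
trade-off between statistical resolution and turnaround: the design-ladder
study uses 150 lines × 3 testers × 5 environments (full-set sizes 50 and
75, 20 seeded allocations per design, plug-in components, the grain-yield
H² = 0.75 preset); variance-component recovery uses 50 simulations of a
40-line × 3-tester × 3-environment trial with an identity G (so the
generating components are exactly the model's components); the type-I
study uses 2000 null cells of 100 simulations. Full-scale runs
(304 lines, 14 designs, 100 simulations, 4 traits) use the same code paths
through `ExperimentConfig`.

## Known limitations

- Markers are exchangeable Bernoulli loci: no LD, no population structure
  beyond what G induces, no marker map. RM–AM conclusions on data with
  strong structure may differ.
- FA order is fixed at K = 1; FA(k>1), multi-trait models and Bayesian
  whole-genome regressions are out of scope.
- The residual is homogeneous across environments.
- EM-REML converges slowly near variance boundaries; capped-iteration fits
  report `converged=False` and the caller decides.
- The plot model has no spatial (row–column / AR1×AR1) residual structure;
  block effects are the only field-layout term.
- Masking removes complete line×environment cells only — no partial plot
  loss or missing-at-random phenotypes.
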
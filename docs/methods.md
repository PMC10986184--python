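# Methods

This note documents the models implemented in `tractopo`, the choices made
where the design was genuinely open, what the synthetic cohort does and
does not emulate, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort generator

The generator (`tractopo.simulate`) produces complete cohorts with the
statistical structure the analysis assumes. Its defaults define the study
conditions used throughout the tests and the acceptance script.

**Participants.** Six phenotypes with default counts 45 (CN), 41 (aAD),
32 (lvPPA), 17 (PCA), 10 (bvAD), 8 (CBS). Ages, sex ratios, MMSE and
disease-duration distributions, intracranial volumes, and APOE ε4
copy-number frequencies (including missing genotypes) are drawn per
phenotype from distributions matching published cohort summaries — in
particular, MMSE strongly separates CN (≈29 ± 1) from patients (≈19–24 ± 4),
which matters for the power of covariate-adjusted contrasts (see
*Limitations*). Planted missingness follows the study's bookkeeping: 4 CN
and 2 aAD MMSE values, one lvPPA duration, and 14 patients without
biomarker confirmation.

**Connectivity.** The parcellation has two hemispheric blocks. A sparse
candidate tract set is drawn once (within-hemisphere density 0.085,
between 0.018, ≈600 tracts of the 11,476 possible pairs at 152 regions);
control baseline GFA per tract is uniform on [0.3, 0.7]. Community
structure exists so that spanning-tree/filtration behaviour is
non-trivial. Per-tract presence probability is Beta-distributed with mean
0.805 and SD 0.119, then Bernoulli per participant — reproducing
between-tract variability in coverage. Four designated regions are
"islands" (all tracts lost) in 35% of scans, so the default island rule
excludes exactly them, leaving 148 regions.

**Effects.** A tract's GFA is

    base + β_age (age − 65) + β_sex·male + shift_pheno·σ
         + s_group (g_a + g_b) σ + ε,  ε ~ N(0, σ²),

with σ = 0.04 GFA units (the control SD, so `effect_spec` shifts are in
control-SD units), default age effect −0.0008/yr and sex effect +0.01.
g_r is a latent per-participant, per-region GM deviation (unit SD, group
mean 0 / −1.0 / −1.2 for CN / amnestic / non-amnestic) that also drives
regional GM volume. Writing the tract deviation as s_group (g_a + g_b)
makes the downstream regression of region-mean WM w-scores on GM w-scores
recover s_group directly: within a participant the neighbour average of g
is nearly constant and is absorbed by the random intercept. Default
coupling slopes are 0.03 (CN) and 0.08 (patients). Default disease
effects: −0.5 SD on 40 tracts (amnestic), −0.8 SD on 60 tracts
(non-amnestic), −0.5 SD on 20 further tracts (lvPPA).

**What is not emulated.** No spatial autocorrelation beyond the
hemispheric blocks, no scanner/protocol batch effects, no tract-length or
anatomy structure, no heavy-tailed GFA marginals (the marginal
distribution is an emulation choice; the data's is unknown), and
microstructure scalars are group-shifted noise not mechanistically linked
to the tract weights. Passing tests therefore demonstrate correctness of
the estimators under the generating model, not robustness to every
property of real diffusion data.

## Quality control

Rules are applied in a fixed order — island exclusion (strict >0.25, so a
region at exactly the threshold is retained), coverage (inclusive ≥0.50 in
*every* phenotype of a configurable set), template masking (template value
defined and >0). The coverage phenotype set defaults to
{CN, lvPPA, PCA, bvAD, CBS}; a warning urges users to confirm the absence
of aAD, and the set is configurable. The chain is idempotent and the
coverage rule is monotone in its threshold; both are asserted in tests.

## W-scores

Per-target OLS on CN participants only; residual SD uses df = n − p.
Sex is a single male indicator (two-level factor; fits are identical under
either coding). Truncation percentiles are computed on the pooled
per-modality distribution (all participants × all targets) — per-target
0.1% quantiles would be meaningless at n ≈ 153 — using linear interpolation
between order statistics. Truncation is applied before any downstream
modelling, including the GM means entering the mixed model. The missing→0
convention applies only to the min/max-normalized table used by the
topology branch; statistical contrasts use the unnormalized table with
tract-by-tract exclusion. Degenerate targets (residual SD ≈ 0, or singular
designs such as a single-sex control set) are flagged and dropped with a
warning rather than silently producing infinite w-scores.

## Tractwise contrasts

Per tract, OLS of w on the factor (group or phenotype) plus MMSE; the
factor is tested with a Type II F (factor adjusted for covariate and vice
versa — order-invariant with a single covariate). Benjamini–Hochberg runs
across all tested tracts with stable-sort tie handling. Tukey post-hoc
tests compare estimated marginal means at the grand covariate mean — at
which pairwise level differences reduce to coefficient differences — with
p from the studentized-range distribution at the residual df; the Tukey
family is per-tract. Tracts losing an entire factor level to missingness
are skipped and listed, not imputed. Tracts with complete data share one
design matrix and are tested in a single vectorized batch.

## GM–WM coupling

Mean WM w-score per (participant, region) — each tract counting toward
both endpoint regions, missing values excluded — regressed on GM w-score
with moderator, interaction, and a random intercept per participant
(REML via statsmodels MixedLM). For this model the marginal covariance is
block diagonal, V_i = σ²I + τ²11ᵀ, so X'V⁻¹X, its derivatives in (σ², τ²),
and the REML expected information all reduce to closed per-participant
forms; Satterthwaite denominator df for single contrasts and the
lmerTest-style eigencontrast combination for multi-df F tests are computed
from those. ANOVA contrasts are Type III with treatment coding
(continuous covariates at zero; factors averaged with equal level
weights), matching `lmerTest::anova`; a frozen fixture fitted with R
lmerTest pins coefficients, SEs, dfs, F and p values in the test suite.
Fixed-effects variance explained is the squared correlation between the
fixed-effect fitted values and the observations. Setting
`random_intercept=False` pins the random-intercept variance at zero and
reduces exactly to pooled OLS (asserted to 1e-6). APOE models treat ε4
copy number as a 3-level factor and offer the additive and
full-interaction variants with diagnostic group.

## Topology

Edges are retained at threshold λ iff weight > λ (strict), so zero-weight
(missing) tracts are absent at every λ ≥ 0 and the filtration removes
edges from the smallest weight upward. β₀ uses an incremental union–find
over the weight-sorted edge list (one pass per participant); any correct
component count is equivalent — scipy's connected components and a
BFS/forest construction serve as oracles in tests. β₁ = β₀ − V + E
exactly. The default grid is 100 linear thresholds over the pooled weight
range; "spanning-tree augmentation" adds the union of participants'
maximum-weight spanning-tree edge weights, which are precisely the merge
thresholds of the filtration in this direction (the single-linkage sense
of "minimum spanning tree"; a `literal_minimum` switch preserves the
minimum-weight tree). Both weight sources — untransformed GFA and
normalized w-scores — are first-class.

## Exact inference

The two group-mean Betti curves are modelled as monotone lattice walks
from (0,0) to (q,q), q = V for β₀ and max(1, E_max − V + 1) for β₁ (the
cycle capacity of the densest retained graph). The real-valued KS distance
D is discretized to the integer band b = ⌈D⌉ — the walks live in integer
component/cycle counts — and p = 1 − A_q(b)/C(2q, q) with A_q(b) the
number of walks staying strictly inside |x − y| < b, computed by exact
big-integer dynamic programming (reproducible bit-for-bit across
platforms; validated against exhaustive enumeration for q ≤ 8). Ties in
the argmax threshold break toward the smallest λ.

**Relation to the permutation test.** The lattice-walk null treats the 2q
steps of the two mean curves as exchangeable; the label-permutation test
instead resamples the group assignment of participants. These are
different null distributions: averaging over n participants stabilizes a
mean curve far beyond a single unit-step walk, so the permutation null of
D is much tighter and the combinatorial p is systematically
*conservative* (p_exact ≥ p_perm), converging with the permutation p only
when effects are large enough that both saturate. The test suite asserts
this conservatism property; the permutation test (seeded,
p = (1 + #{D* ≥ D})/(1 + n_perm)) is the sharper tool when calibrated
error rates matter, and the exact p is a fast, deterministic,
distribution-free upper bound.

## Clinical models

One OLS per Betti metric: outcome ~ metric + age + sex, α = 0.05
uncorrected, MMSE models on all participants and duration models on
patients only (duration is undefined for CN). Outcomes stay in natural
units. Pearson correlations with FA/MD/isotropic diffusion are reported
without correction. Outputs use an explicit long format (graph type,
metric, term, coefficient, SE, t, p).

## Pipeline and problem sizes

Stages run in the fixed order qc → wscore → stats → topology → inference →
clinical; a run is deterministic given seed and configuration, outputs
carry a provenance comment (version, config hash, seed), and INFO logging
records counts at every filter. The subset re-analysis drops patients
without biomarker confirmation and anyone with imputed MMSE/duration, then
re-runs QC through the tractwise contrasts and reports shared-tract
F-statistic correlations and significance concordance.

Default problem sizes: 153 participants, 152→148 regions, ≈500 retained
tracts, ≈110 filtration thresholds after augmentation; the FDR-calibration
experiment uses 200 global-null replicates of 497 tracts; the permutation
oracle uses 10,000 relabelings. A full pipeline run takes ≈20 s and the
acceptance script ≈1 min on one CPU.

## Limitations

- Power at the study's sample sizes is modest for per-tract effects below
  ≈1 control SD once MMSE — which is strongly collinear with diagnosis —
  is adjusted for; the effect-detection experiment quantifies this
  directly (`effect_detection_rate_pct` in the acceptance output).
- The Satterthwaite machinery covers the random-intercept model only (no
  random slopes or crossed random effects, which the analysis does not
  use).
- The exact topological p-value is a conservative bound relative to the
  permutation null, as discussed above.
- Betti numbers depend on the parcellation and on the missing→0
  convention; topological results should be read as statements about the
  filtration of the observed graphs, not parcellation-free invariants.
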
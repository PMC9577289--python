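# Methods

## Normalization model

nCounter-style digital counts carry three nuisance layers: lane/platform
efficiency (captured by spiked positive controls), non-specific background
(negative controls), and sample input amount (housekeeping genes).  The
normalizer removes them in that order.  For a control set C the per-sample
factor is `f_s = mean_s'(g_s') / g_s` where `g_s` is the geometric mean of
sample s over C; after scaling, every sample has the same control geometric
mean, and the choice of the arithmetic-mean reference only shifts all log2
values by a common constant.  Background is the per-sample mean of the
negative controls (`mean_plus_2sd` available by configuration), subtracted
from endogenous and housekeeping counts with flooring at zero; flooring is
idempotent.  Housekeeping factors are computed on background-removed counts
over a configurable housekeeping subset (default: all housekeeping probes;
probes at zero in any sample are excluded, at least three must remain).
Finally `log2(x + 1)`: the +1 pseudocount keeps floored zeros finite and is
the dominant convention; it is configurable.  Whether QC thresholding
happens before or after logging is an open choice; here the marker QC
filter operates on the logged matrix with a background-derived default
threshold, `log2(mean negative count + pseudocount)`.

## Cell scores, TILs gate, relatives

Scores are arithmetic means of marker log2 expression, so they live on the
log2 scale and a cell/TILs "ratio" is implemented as score − TILs — exactly
shift-invariant, which the tests exploit.  The TILs composite averages the
cell scores whose Pearson correlation with *PTPRC* across samples exceeds
0.6 (the gate is monotone in the threshold; an empty gate leaves TILs
undefined with a typed warning).  The shipped 13-cell-type / 60-marker
panel and the 6-gene cytotoxic composite are editable configuration, not
biological claims; swap in your own panel files to change the science
without touching code.

## Patient stratification

The 74-gene panel is z-scored per gene (so high expressors do not dominate
the Ward variance) and clustered with a hand-implemented Lance–Williams
Ward agglomeration.  Two variants are exposed: `ward_d` applies the update
`d(k, i∪j) = [(n_i+n_k) d_ki + (n_j+n_k) d_kj − n_k d_ij]/(n_i+n_j+n_k)`
directly to Euclidean distances (classic `ward.D` behaviour, the default),
`ward_d2` to squared distances with square-root heights (scipy/`ward.D2`;
verified against scipy in the tests).  Ties merge the smallest index pair,
making every dendrogram deterministic.  Gene cluster A is the side whose
genes correlate more with the CD8/NK/B-cell seed markers — an anchored
labelling rather than silhouette order, so "adaptive" vs "innate" semantics
never flip.  Patients are split k = 2 on A-genes (higher mean = hot), then
within each temperature stratum k = 2 on B-genes (higher mean = innate+);
a `median` split mode is provided for sensitivity analysis.  Strata with a
single patient are assigned by comparing their innate-block mean to the
overall median, with a warning.

## Differential expression

A deliberately self-contained NB Wald scheme, not a reimplementation of a
full shrinkage estimator: size factors by median-of-ratios (reference =
per-gene geometric means over zero-free genes, with a positive-counts
fallback), per-gene method-of-moments dispersion pooled within groups and
floored at 1e-8 (the Poisson limit), group means of normalized counts with
a 0.5 pseudocount when a group mean is exactly zero, delta-method standard
error `sqrt(Σ_g (1/n_g)(1/μ_g + α))/ln 2`, two-sided normal Wald p, BH-FDR
across tested genes, and the significance gate |log2FC| ≥ 1 ∧ FDR < 0.05.
No dispersion shrinkage across genes, no fold-change moderation, no
independent filtering — the downstream analysis uses only the gate, and the
simplified statistic is fully testable (antisymmetry under group swap is
exact; type-I control under a simulated global null is checked in the
acceptance suite).  The long/short survival contrast uses a 90-day cutoff:
long = survival observed beyond the cutoff (event or not), short = death
before it; patients censored before 90 days are uninformative and are
excluded with a report.  The reporting median OS (107 days) and the DE
grouping cutoff (90 days) are deliberately two distinct constants.

## Survival analysis

Kaplan–Meier, log-rank and Cox estimation are delegated to `lifelines`;
the module pins the cohort conventions: median OS as the smallest time with
S(t) ≤ 0.5; Efron tie handling (day-resolution OS data is heavily tied and
Efron is less biased than Breslow); Wald CIs `exp(β ± 1.96 se)`; age coded
strictly above 70 years; PD-L1 high at ≥ 50% tumour-cell positivity; the
four clusters entered as one ordinal trend covariate (C1+C2 = 0, C3 = 1,
C4 = 2), i.e. a single per-step hazard ratio.  The default multivariable
model contains age, cluster and PD-L1 (the covariates that are univariably
prognostic); the covariate list is configurable.  Collinearity is detected
by the rank of the centred covariate matrix and raises; listwise deletion
of missing covariates happens only inside the fit.  Brute-force oracles
(hand product-limit, hypergeometric log-rank accumulation, golden-section
maximization of an independently coded Efron partial likelihood) pin the
delegated implementations in the test suite.

## Immunomodulator correlations

Pairwise Pearson r over the 68-gene modulator list, two-sided t-distributed
p-values, BH over the upper-triangle family only (n(n−1)/2 tests, diagonal
excluded — the standard choice where the family is not otherwise declared),
masking at FDR ≥ 0.01, display order from Ward/Euclidean clustering of the
r-matrix rows.  Per-cluster profiles are gene-wise means z-scored across
clusters (constant genes map to 0 by a guarded division).

## IHC comparisons

Ratios are plain quotients against CD45 density; a CD45 of zero leaves the
ratio undefined rather than infinite.  Group comparisons follow the routing
rule: all groups must pass Shapiro–Wilk at α = 0.05 for the parametric
branch (t / one-way ANOVA), otherwise rank-based tests (Mann–Whitney with
exact enumeration for groups ≤ 20 without ties, normal approximation with
tie correction above; Kruskal–Wallis beyond two groups).  Groups under
n = 3 force the non-parametric branch.  An optional BH pass over a declared
comparison family is available and off by default.

## Synthetic cohort generator

The generator encodes the study conditions; its defaults are fixed, not
tuning knobs.  Defaults: 83 patients; cluster proportions C1..C4 =
0.25/0.25/0.30/0.20 (an even hot/cold split with C4 smallest); adaptive and
innate log2 shifts 2.0; NB dispersion 0.2; 6 positive / 8 negative / 20
housekeeping probes; lognormal depth sd 0.25 and platform-factor sd 0.15;
Poisson background mean 8; PD-L1 high probability 0.20; age ~ N(70, 12²)
clipped to [29, 93] so P(age > 70) = 0.5; survival log-coefficients
ln(2.513), ln(1.648), ln(3.316) for age/cluster/PD-L1.

Counts: each endogenous gene gets a baseline log2 mean ~ U(5, 8); cluster-A
panel genes gain the adaptive shift in hot patients, cluster-B genes the
innate shift in innate+ patients; modulators co-elevate with the hot
programme except CD274, TNFRSF9, VEGFA, CD276 and KIR2DL3, which elevate in
the cold clusters; RLR/type-I-interferon pathway genes elevate in hot
patients.  Two couplings are derived from the variance budget at the
default dispersion (per-gene log2 noise sd ≈ 0.65): *PTPRC* is offset by
1.8 (hot) and 1.0 (innate+) so the lymphocyte cell scores clear the 0.6
TILs gate with margin, and CD8/cytotoxic genes get a +0.5 extra hot offset
so the hot group shows the higher CD8/TILs relative (a uniform adaptive
shift cancels exactly in score − TILs).  Counts are Gamma–Poisson draws at
mean × depth; positive controls follow a fixed geometric ladder times a
per-sample platform factor; housekeepers scale with depth only.

Survival: exponential proportional hazards
`λ_i = λ0 · exp(β_age·1{age>70} + β_cluster·ordinal + β_pdl1·1{high})`.
λ0 is not a free parameter: it is solved by root-finding so the marginal
median OS over the theoretical covariate mixture equals 107 days.
Censoring is independent uniform over an administrative window, the window
likewise solved so the expected censored fraction matches the target
(default 0.30).  An exponential baseline (rather than Weibull) is all the
Cox stage needs; proportionality holds by construction.  Observed times in
the full cohort are ceiled to whole days (realistic tie structure for the
Efron handling); the lean recovery path (`simulate_ph_cohort`, used by the
acceptance experiments) keeps continuous times and samples its three
covariates independently (age ~ Bern(0.5), ordinal ~ Unif{0,1,2}, PD-L1 ~
Bern(0.2)).

IHC: CD45 density scales as `150 · 2^(1.3·hot + 0.7·innate)` with lognormal
noise; marker densities are CD45 times archetype-consistent fractions (CD8
and CD20 fractions higher in hot, CD68 and MPO in cold/innate-rich
effusions).

What the generator does **not** emulate: PD-L1 IHC status is sampled
independently of CD274 mRNA, so the PD-L1 differential-expression contrast
is null by construction on synthetic data (the pipeline reports honest
zero counts there); no batch/cartridge structure, no probe
cross-hybridization, no M1/M2 or N1/N2 subpopulations, no image-level
simulation.  Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted structure, not
biological validity on real cohorts.

## Problem sizes and numerical choices

The acceptance experiments use n = 3000 patients and 20 replicates per
hazard-ratio recovery, the cluster-recovery check 20 cohorts of n = 83, the
DE null 50 replicates of 100 genes × 30 samples, and the log-rank
uniformity check 200 label permutations of a 60-patient cohort — sizes at
which Monte-Carlo error is comfortably inside the stated tolerances while a
full run stays in the minutes range on one CPU.  Convergence and
tie-breaking: Ward merges break height ties toward the smallest index pair;
the Cox fit inherits lifelines' Newton convergence criteria and surfaces
failures as a typed `ConvergenceError`; BH is order-preserving and
permutation-equivariant (property-tested).  Known limitations: the MoM
dispersion estimator is noisy for small groups (it is floored, never
shrunk), the gene-side partition assumes exactly two expression programmes,
and the hot/cold dendrogram cut can be unstable when archetype shifts
approach the noise floor — the null-configuration tests document that
regime.
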
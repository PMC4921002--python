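# Methods

## The calling problem

A two-channel SNP array reports, per sample and per SNP, a pair of raw
fluorescence intensities *x = (r, g)* — *r* for the A allele, *g* for
the B allele.  Samples at one SNP form up to three clusters in the
(r, g) plane corresponding to the genotypes AA, AB and BB, ordered
along the contrast *y = (r − g)/(r + g)*.  Calling a genotype is
deciding which cluster a sample belongs to; the hard cases are rare
SNPs, where minor clusters hold very few points or are absent and both
the number of clusters and their boundaries are uncertain.  Intensities
are used raw: the models make no assumption about units or upstream
normalisation, only about within-SNP cluster structure.

## Model I — EM Gaussian mixture (common SNPs)

Per SNP, a three-component bivariate Gaussian mixture is fitted by EM.
The E step computes responsibilities
f_k(x_i) = π_k N(x_i | μ_k, Σ_k) / Σ_u π_u N(x_i | μ_u, Σ_u)
in log space (a remote point never yields NaN); the M step updates π as
mean responsibility, μ as the responsibility-weighted mean, and Σ as the
weighted scatter about the *new* mean plus a ridge εI with
ε = 10⁻⁶ × mean data variance (floor 10⁻¹²) to keep tight clusters
invertible.  Convergence is a relative log-likelihood change below
10⁻⁸ or 500 iterations; the log-likelihood trace is non-decreasing.

**Initialisation.**  Points are split at the contrast cutoffs y = ±0.5,
the standard rough genotype boundaries.  When all three regions are
occupied, a deterministic Lloyd refinement sharpens the three means.
When a region is empty, its component is anchored at the centre of that
region (at the SNP's mean total intensity) and the refinement is
skipped; EM then leaves the component empty (mixing weight driven to a
floor of 10⁻¹⁰) instead of splitting an occupied cluster.  This matters:
a monomorphic SNP whose lone cluster is split three ways would acquire a
spurious MAF ≈ 0.3 and be routed as a common SNP.  With anchoring, its
MAF estimate is ~0 and it reaches the reference-assisted path.

**Labels and quality.**  Components are ordered by the contrast of
their means, descending: highest y → AA (r is the A channel), lowest →
BB.  Each sample's Posterior Rate (PR) is the converged responsibility
of its assigned component; a call is withheld (NC) when PR < 0.85
(threshold inclusive: PR = 0.85 is called).  Abnormal intensities are
handled by exactly this filter rather than by an explicit fourth
mixture component.  The per-SNP Average Posterior Rate (APR) is the
mean PR over assigned samples.

## Model II — Dirichlet-process Gaussian mixture (rare SNPs)

When the number of clusters is uncertain, the mixture is given a DP
prior and sampled by Gibbs.  Indicators are resampled from the
collapsed (Chinese-restaurant-process) conditional: an existing cluster
k attracts sample i with weight n₋ᵢ,ₖ/(n−1+α) · N(xᵢ | μₖ, Rₖ); a new
cluster opens with weight α/(n−1+α) times the prior predictive
∫ N(x|μ,R) p(μ,R) dμ dR.  Components carry a conjugate Normal–Wishart
prior — R ~ W(ν, S⁻¹) a *precision* matrix, μ | R ~ N(m, (rR)⁻¹) with
relative precision r — making the predictive a closed-form bivariate
Student-t with ν−1 degrees of freedom, location m and scale
(1+r)/(r(ν−1)) · S.  The precision reading of R (and of rR for μ) is
what makes the prior conjugate; occupied-cluster parameters are redrawn
each sweep from their Normal–Wishart full conditionals via 2×2 Bartlett
decomposition.  The concentration has the prior 1/α ~ Gamma(1, 1)
(unit shape and mean) and is updated by a log-scale random-walk
Metropolis step targeting p(α | K, n) ∝ p(α) αᴷ Γ(α)/Γ(α+n); the
Escobar–West auxiliary-variable update does not apply to this prior
form.

**Hyperparameter defaults** (fixed within a fit): m = data mean,
r = 0.01, ν = 4, and S = ν × the pooled *within-cluster* covariance of
the rough contrast partition (cutoffs ±0.5), falling back to the total
covariance when no rough cluster has two members.  The within-cluster
scaling is deliberate: it makes the prior expect genotype-cluster-sized
components, so the Student-t predictive is diffuse on the cluster scale
rather than the panel scale and a genuinely remote point can win a new
cluster against an established broad one.  Scaling S to the total
covariance instead leaves the predictive so flat that the sampler
rarely escapes its single-cluster initialisation on well-separated
data.

**Initial state and consensus.**  All samples start in one cluster
(parameters drawn from their full conditional given all data) and
α = 1.  Defaults are 2000 sweeps with 500 burn-in; every 5th
post-burn-in partition is saved, and the reported partition is the
saved sample maximising mean pairwise co-assignment agreement with the
whole saved set — a consensus immune to label switching.  Component
estimates (π, μ, Σ) are the Normal–Wishart conditional posterior means
given the consensus partition (the closed-form conditional average, in
place of re-running the chain at a fixed partition); PR and APR are
then computed exactly as in Model I.

**Genotype mapping.**  Every consensus cluster is labelled by the side
of the ±0.5 contrast cutoffs its mean contrast falls on (y ≥ 0.5 → AA,
y < −0.5 → BB, else AB), and clusters may share a label: a split major
cluster, or an outlier micro-cluster sitting inside a genotype region,
is still that genotype.  A positional map (descending contrast →
AA, AB, BB) was rejected after it miscalled an entire SNP — one
spurious high-contrast micro-cluster shifts every other cluster's
label by one.  The side rule assumes genotype clusters sit in their
canonical contrast regions; a SNP whose minor-homozygote cluster drifts
inside |y| < 0.5 would have it merged with the heterozygotes.

## Model III — reference-assisted DP (extremely rare SNPs)

With zero-to-two points in a minor cluster, the CRP's rich-gets-richer
weighting lets the major cluster absorb them.  A reference SNP fixes
this by donating cluster structure:

1. **R1** — SNPs earlier in array order with MAF > 0.15, nearest first,
   capped at 200 candidates.
2. **R2** — R1 candidates whose rough contrast clustering shows all
   three clusters with proportions ≥ 10 % each (boundary inclusive).
3. **R-SNP** — the R2 candidate minimising the cluster distance
   D = Σₖ Σ_{i∈cluster k of T} (x_i − μₖᵈ)ᵀ ((Σₖᵗ + Σₖᵈ)/2)⁻¹ (x_i − μₖᵈ),
   i.e. member-wise quadratic forms under the pooled covariance, summed
   over the target's occupied clusters (clusters empty in the target
   contribute zero, so rare targets are ranked by the clusters they do
   have).  Ties break to the nearest array position, then
   lexicographic id.

The target's rows are stacked with the reference's and the DP mixture of
Model II is fitted to the combined set; only the target rows' calls are
returned.  When no candidate precedes the target the search mirrors to
the SNPs after it; with no candidate at all the SNP falls back to a
plain DP fit (flagged in the summary, model recorded as DP-GMM).  A
failed DP fit yields all-NC for the target rather than aborting a run.

## Routing and the two-pass procedure

Pass 1 fits Model I to every SNP and estimates its MAF by allele
counting over calls at PR ≥ 0.85 — (2·n_minor-hom + n_het)/(2·n_called),
minor allele chosen so MAF ≤ 0.5 — along with per-genotype cluster
sizes.  Each SNP is routed: g1 if MAF ≥ 0.05 (boundary inclusive);
else g2 if at least one *non-empty* cluster count lies in [b₁, b₂) with
b₁ = 3, b₂ = 10; else g3 (including SNPs with no calls at all).  Pass 2
keeps the EM calls for g1, refits g2 with the DP mixture and g3 with
the reference-assisted DP.  MAF is not recomputed after pass 2; routing
is a one-shot decision from the quick EM estimates.  Per-SNP randomness
derives from seeds spawned per SNP index from the run seed, so results
are reproducible and independent of scheduling.

## Evaluation metrics

Call rate = 100 × called/observed cells (missing input cells never enter
the denominator).  Concordance between two call sets counts only cells
called by both; accuracy is concordance against a truth table.  The HWE
test is the 1-df chi-square goodness of fit of genotype counts against
(1−q)², 2q(1−q), q² at the counted allele frequency, run per population;
a SNP fails at p < 10⁻⁴.  Monomorphic counts pass with statistic 0;
populations with fewer than five called samples are skipped with a
warning.  The chi-square form was chosen over the exact test as the
conventional default at these sample sizes; a config switch reserves
room for an exact-test variant.

## Synthetic data generator

The simulator produces exactly the structure the models assume:
genotypes drawn from Hardy–Weinberg proportions at a chosen MAF (B the
minor allele), cluster means placed by (contrast, total-intensity)
geometry — defaults +0.8/0/−0.8 at total 2000, i.e. AA at (1800, 200) —
isotropic per-channel Gaussian noise (default sd 100, putting ~11 noise
units between adjacent clusters), truncation at zero (intensities are
non-negative), and a configurable fraction (default 1 %) of samples
replaced by uniform draws over [0, 1.5·total]² to mimic abnormal
measurements.  `make_rare_snp_fixture` pins the minor-cluster size
exactly (3–9 heterozygotes for the g2 regime, 0–2 for g3, none for
monomorphic).  The standard desk-scale panel is 70 SNPs at MAF 0.30,
20 at 0.03 and 10 at 0.005 over 300 samples, common SNPs first so rare
SNPs always have reference candidates; these sizes run the full
procedure in a few minutes while exercising every routing path.

What the generator does *not* emulate: probe-level replicates, batch or
plate effects, allele-specific cross-talk, intensity-dependent variance,
or linkage between SNPs.  Passing tests therefore demonstrate that the
inference machinery recovers the structure it models — not that real
BeadArray noise is this clean.  Two consequences of the idealisation are
worth noting.  First, at six-noise-unit separations the zero-truncation
becomes material for extreme-contrast clusters (the AA cluster's g
channel sits about one sd from zero), making the data visibly
non-Gaussian; single-cluster model-selection checks therefore use the
interior heterozygote cluster.  Second, box outliers that happen to land
deep inside a cluster's basin are called with high PR by any of the
models — the PR filter rejects ambiguity, not plausibility — so a small
fraction of outlier cells is expected to be called, and called wrongly,
in panel-level accuracy figures.

## Numerical and design notes

- All mixture densities are evaluated through closed 2×2 forms
  (determinant/inverse/Cholesky) in log space; CRP weights are
  normalised after subtracting the maximum.
- The EM empty-component policy freezes the component's parameters and
  floors its weight; the SNP is then routed onward by its honest MAF.
- The predictive constant of the Student-t and the per-sample predictive
  values are precomputed once per DP fit; they depend only on the
  hyperparameters and data.
- `cluster_distance` treats a rough cluster's members as a set of rows
  (the printed single-vector form is undefined for multi-member
  clusters) and sums, rather than averages, their quadratic forms, so
  better-populated targets are matched more stringently.
- Degenerate inputs: r + g = 0 makes the contrast undefined — such
  points are excluded from rough clustering and treated as missing;
  SNPs with fewer than 3 observed samples skip the EM pass and route
  to g3; all points identical is a degenerate-data error contained at
  the per-SNP level.
- Known limitations: no cross-chromosome or multi-reference search; a
  single reference SNP is assumed sufficient to populate all three
  clusters; hyperparameters of the DP are fixed within a fit
  (no hyperpriors); the HWE exact-test option is not yet implemented.
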
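# Methods

## The composition tree

The 15 measured T/B subsets form a four-level hierarchy under the total
live-lymphocyte gate: T and B cells at level 1; CD4+/CD8+ T cells at
level 2; naïve (N), central memory (CM), effector memory (EM) and
terminally differentiated effector memory (TDEM) stages at level 3, and
naïve/IgD−/IgD+ memory B cells at level 2. Because the measured children
of a node do not generally sum to 100% of their parent, each internal node
(including the root) receives exactly one *derived* complement child —
other lymphocytes (LYMPO), other T (TO), other CD4+ (TCD4O), other CD8+
(TCD8O), other B (BO) — giving 21 nodes and 16 terminal subsets.

Subjects are excluded before conversion if any measured percentage is
missing, out of [0, 100], or if the measured children of any node sum
beyond 100 (tolerance 1e-9 on the percent scale; sums of exactly 100 are
valid and yield a zero complement). The leaf composition is the product of
relative proportions along each root→leaf path; by construction each row
closes to 1 exactly (up to float error), which the converter asserts at
1e-9. Complement values within 1e-9 of zero are snapped to exact zero so
that subtraction noise is never mistaken for a tiny real part.

**Zeros.** Exact zeros (common for near-detection-limit subsets) are
replaced by the smallest positive value observed for the same cell type
across the dataset — a per-column, data-driven detection-limit convention.
Rows are *not* re-closed afterwards by default: the perturbation is tiny
relative to every part, and leaving the remaining parts untouched keeps
their values interpretable; `renormalize=True` re-closes when exact
closure matters downstream. Internally everything is on the proportion
scale (sum 1); I/O uses percentages.

## Total logratio variance and stepwise selection

All pairwise logratios L_ij = ln(x_i/x_j), i<j in the fixed canonical leaf
order, give C(16,2)=120 columns. With uniform part weights 1/D the total
logratio variance is

    T = (1/D²) Σ_{i<j} Var(L_ij) = (1/D) · trace Cov(clr(x)),

using n−1 sample variances. A part-mean weighting (weights = mean closed
proportions) is available via `weights="part_means"`; uniform is the
default because it treats rare subsets and abundant subsets symmetrically
and makes T interpretable as mean CLR variance. Natural logs throughout
(the base only rescales variances and never changes selection order).

Stepwise selection is greedy forward selection over the 120 columns. The
explained variance of a candidate set S is the uniformly weighted variance
of the least-squares projection of the centred CLR matrix onto span(S),
divided by T — redundancy-analysis semantics: the selected logratios are
rated by how much of the full compositional geometry they reproduce, not
by their own variance. The implementation maintains an orthonormal basis
of the selected columns and scores each remaining candidate by the squared
norm of the projection of the CLR matrix onto the candidate's residual
direction, which is algebraically identical to refitting from scratch (the
test suite checks this against a brute-force oracle that re-solves the
projection for every candidate at every step).

Ties are real, not cosmetic: once a pair is selected, distinct pairs can
span the identical augmented subspace (e.g. {a/b, a/c} vs {a/b, b/c}), so
gains are compared with an absolute tolerance of 1e-10 on the fraction
scale and the lexicographically first maximiser wins. This keeps the trace
deterministic and invariant to per-subject rescaling of the raw inputs.
On generic data the selection reaches 100% of T in exactly rank(CLR) =
D−1 = 15 steps; with fewer subjects than parts it stops when no candidate
adds variance.

## Conditional-dependence network

The composition is CLR-transformed (rows sum to zero) and a sparse
conditional-dependence graph is estimated two ways:

* **glasso** — L1-penalized precision estimation on the CLR covariance;
  edge (i,j) present iff Θ_ij ≠ 0 (threshold 1e-8), signed and weighted by
  the partial correlation −Θ_ij/√(Θ_ii Θ_jj). Because the CLR covariance
  is singular (rank ≤ D−1), a ridge of 1e-6 × mean variance is added at
  penalty 0 only.
* **MB** — node-wise lasso of each CLR column on the others; OR rule by
  default (edge if either direction selects it; AND available), weight =
  mean of the two directed coefficients, sign from that mean.

The penalty comes from StARS: for each of 30 log-spaced penalties
(descending from the empty-graph level), the graph is refit on B=50
subsamples without replacement of size min(⌊10√n⌋, ⌊0.8n⌋); edge
frequencies ξ give mean instability 2ξ(1−ξ); the curve is monotonized by a
running maximum as the penalty decreases; the *smallest* penalty whose
monotonized instability stays ≤ 0.05 is selected — the densest graph that
is still reproducible under subsampling. If nothing is stable the largest
grid penalty is returned with a warning.

**Known property, not a bug.** CLR is only an approximation to the latent
log-scale covariance. Closure induces negative marginal couplings of order
(σ_i²+σ_j²)/D that concentrate on the highest-variance parts; with four
near-detection-limit subsets at latent sd ≈ 1.2 and n in the thousands,
StARS+glasso occasionally reports one or a few such closure edges even
when the latent precision is diagonal (MB is less susceptible). The null
tests budget for ≤1 spurious edge per fit averaged across both methods.

## Penalized log-contrast regression

For outcome y (ordinal outcomes treated as numeric), log-composition
matrix Z = ln(x) and unpenalized covariate block W (tier 1: intercept;
tier 2: + age, sex; tier 3: + race, education, CMV dummies):

    min_{β,γ} (1/2n)‖y − Zβ − Wγ‖² + λ‖β‖₁   s.t.  Σβ = 0.

Zero-sum log-contrast coefficients are invariant to per-subject rescaling
of the raw parts and to closure, so the fit carries only relative
information. Columns of Z are centred but *not* standardized to unit
variance by default: per-column standard deviations are not invariant to
per-subject rescaling, so per-column standardization would break the exact
invariance contract (it is available via `standardize="columns"` for users
who want penalty equivariance across parts; log-scale spreads of the 16
subsets are similar enough that the default is not materially unfair).

The solver residualises y and Z on W (exact for an unpenalized block),
then runs coordinate descent on the Gram form inside an augmented
Lagrangian on the constraint; the active set is re-projected exactly onto
Σβ=0 at the end. At λ=0 the solution matches the Lagrange closed form of
equality-constrained least squares to <1e-6 (tested); the constraint holds
to <1e-8 at every path point.

λ is selected by BIC(λ) = n ln(RSS/n) + df(λ) ln n with df = #nonzero β +
dim(γ) (the standard lasso df estimate); the grid is 30 log-spaced values
from the smallest all-zero-β penalty down 3 decades; ties go to the larger
λ. 95% intervals are case-resampling percentile bootstrap with B=200
refits at the *originally selected* λ (per-replicate re-tuning available
by flag); degenerate resamples with constant outcome are skipped and
counted; everything is reproducible under a seed.

## OLS on selected logratios

The top-K logratios from the selection trace (default: enough to explain
90% of T) enter an OLS with classical 95% intervals per covariate tier.
Aliased columns are dropped greedily by rank and logged. The comparison
model on all 120 logratios is fit by minimum-norm least squares (the
design has rank ≤ 15) and its adjusted R² uses the design's effective rank
as degrees of freedom.

Outcome constructions: the chronic disease index is the integer sum of 8
binary condition flags (0–8). The frailty index is the mean of 44 deficit
items in [0,1]; categories use half-open bins [0, 0.15), [0.15, 0.25),
[0.25, 0.35), [0.35, 1] → levels 1–4. The printed two-decimal ranges
(0.15–0.24, 0.25–0.34) are read as half-open intervals because that is the
unique exhaustive, non-overlapping completion of the stated cut points.

## Synthetic cohort generator

The generator emulates the target study's conditions with known truth:

* **Compositions**: latent 16-vector ~ MVN(μ, Ω⁻¹) mapped to the simplex
  by exponentiate-and-close. Ω plants exactly three conditional-dependence
  edges (TCD4CM–TCD4O +0.35, TCD4CM–LYMPO −0.35, TCD8CM–TCD8O +0.35
  partial correlation) and nothing else above |0.2|, so network-recovery
  truth is unambiguous. Latent sd is 0.7 for abundant parts and 1.2 for
  the four smallest-median subsets (TCD4EM, TCD8EM, BMIgD−, BO), whose
  published interquartile ranges span several fold-changes. μ is
  calibrated to the published subset medians (LYMPO ≈ 21%, TCD4N ≈ 20%, …)
  with a −σ²/2 correction so the high-variance parts do not siphon share
  from the abundant parts through the closure denominator.
* **Zeros**: detection-limit style — within each of the four small parts,
  values below the 14.3% quantile become exact 0 and rows are re-closed;
  per-part rate 0.143 gives ≈46% of subjects at least one zero
  (1−(1−0.143)⁴). Real zero patterns are unpublished; this scheme is a
  declared stand-in.
* **Covariates**: age = 50 + lognormal(ln 18, 0.6012), which reproduces
  the published quartiles (62, 68, 77) exactly at the population level;
  sex, race, education and CMV are independent categorical draws at the
  published shares (57.4% women, 71.4% CMV-reactive, …).
* **Outcomes**: a latent health score s = ln(x)·β* + covariate effects +
  noise drives all outcomes: a continuous score (Gaussian noise, sd 1), a
  binomial(8, logistic(−1.1+s)) chronic disease index, a five-level
  self-reported health rating from fixed thresholds on a noisy copy of s,
  and 44 Bernoulli deficits with logit-linear item difficulties whose mean
  is the frailty index. β* has five nonzeros with the sign pattern seen in
  the reported associations (TCD4N −, TCD4O +, TCD8CM +, TCD8O −,
  LYMPO +), sums to zero exactly, and is rescaled analytically so the
  composition signal attains SNR 2 against the noise
  (Var(ln(x)·β*) = β*ᵀΣβ* — exact, because the zero-sum constraint
  cancels the closure term). Default medians land at CDI 2, self-reported
  health 3, frailty level 2, matching the published cohort.

Everything is bit-reproducible from (parameters, seed); the truth object
is serialized next to every generated dataset. What the generator does
*not* emulate: survey weights, attrition, CMV–composition causal coupling,
longitudinal structure, real zero co-occurrence patterns, and the
empirical inter-outcome correlations (the shared latent score makes the
synthetic outcomes correlate ≈0.7, above the ≈0.4–0.6 reported in real
data). Passing tests therefore demonstrate correctness of the machinery
and recoverability under a known logistic-normal truth — not that real
cohorts satisfy these models.

## Problem sizes and numerical choices

Unit and property tests run at n = 200–1200; recovery suites use n = 2000
(regression, 20 seeds) and n = 4000 (networks, 5 recovery + 10 null
replicates per method with 25 StARS subsamples) — sizes at which the
planted effects are comfortably identifiable while the whole suite stays
fast. Key tolerances: closure 1e-9; oversum 1e-9 (percent scale);
constrained-lasso objective/constraint 1e-8; SRDA tie tolerance 1e-10;
glasso edge threshold 1e-8. Degenerate inputs (all-zero columns, constant
compositions, empty panels, rank-deficient covariates) raise informative
errors rather than propagating NaNs.
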
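# Methods

## Model and procedure

All views are n × d matrices over the same ordered samples (`align_samples`
restricts every input to the sorted intersection of sample IDs, so alignment
is deterministic).  Covariances are computed on column-centered data with
1/(n−1) scaling; condition numbers and canonical correlations are invariant
to the scalar, and centering matches the z-scored inputs the genomics
pipeline produces.

**Two-view CCA.**  The solver whitens each view with the inverse symmetric
square root of its regularized covariance C̃ = C + αI (or C + α(I + L) with
a network) and takes the SVD of the whitened cross-covariance.  This is
algebraically the generalized-eigenproblem formulation of CCA but
numerically stabler; the singular values are the canonical correlations and
the back-transformed singular vectors satisfy wᵀC̃w = I exactly.  Eigen
directions of C̃ below 1e-10 of the leading eigenvalue are dropped from the
whitener (they carry no usable variance).  Weight-column signs are fixed for
cross-platform determinism: the left column's largest-magnitude entry is
made positive and the right column inherits the same flip, so
cov(u_left, u_right) is always nonnegative.  (Fixing both sides
independently would be equally deterministic but can negate the achieved
correlation, which breaks the loading-space association downstream.)

**Component count.**  The number of retained components per merge follows a
PCA-style rule on the canonical-correlation spectrum (ρ, not ρ²): the
largest k whose cumulative share of the total is ≤ p/100, boundary
inclusive, minimum 1, with entries below 1e-12 of the leading value excluded
from the total.  Default p = 85.

**Reconditioning.**  For a target condition number c (default 4 — inside
the "well-conditioned below 10" rule of thumb), α = (λ_max − c·λ_min)/(c−1)
makes κ(C + αI) = c exactly when κ(C) > c, and α is clamped to 0 otherwise
(a negative ridge is unsound).  With a normalized graph Laplacian the
eigenvalues of I + L lie in [1, 3], so Weyl's inequality bounds
κ(C + α(I+L)) by (λ_max + 3α)/(λ_min + α); solving for c gives
α = (λ_max − c·λ_min)/(c − 3) and requires c > 3.  The bound is an
inequality, not an equality, so the network variant guarantees κ ≤ c.
Singular values below 1e-14 of the largest are treated as exact zeros
(double-precision noise floor) and give κ = ∞.

**Hierarchy.**  At each level the pair of remaining datasets whose
cross-covariance has the smallest condition number is merged; ties break
lexicographically and an infinite κ loses to any finite one.  The merged
pair is replaced by the concatenated canonical variables.  Merged
pseudo-views are treated as plain matrices afterwards: no interaction graph
is defined on canonical variables, and they are not re-standardized (their
columns already have unit generalized norm).  α is re-estimated with the
same c at every level.  The first merge can be pinned
(`fixed_first_pair`) so a chosen view pair — e.g. genes and geoclimate —
can be read off at every level of the loading analysis; later levels revert
to condition-number selection.

A note on what the minimum-κ rule rewards: a pair sharing a *low-rank*
latent factor has a large σ_max but a noise-level σ_min, hence a *large*
condition number.  The rule favors pairs whose shared structure spans the
smaller view's full feature space (full-rank, well-conditioned
cross-covariance).  In practice this also systematically favors pairs
involving the lowest-dimensional view (a d_i × d_j cross-covariance with
min(d) > n is numerically singular), which is why a narrow environmental
table tends to be merged before two wide genomic views.

**Baselines.**  Pairwise multiset CCA solves the SUMCOR relaxation: the
generalized eigenproblem of the off-diagonal block cross-covariance against
the block-diagonal regularized covariance, followed by per-view rescaling
to the unit-variance constraints.  Tensor CCA whitens each view, forms the
order-N covariance tensor (an element budget, default 1e7, guards memory;
the tool refuses rather than thrash), and runs rank-k CP alternating least
squares with deterministic SVD initialization.  Each ALS subproblem is an
exact least-squares solve, so the reconstruction error is monotonically
non-increasing; the objective trace reports the CP fit per sweep.  For two
views the tensor is the whitened cross-covariance matrix and CP reduces to
the SVD, i.e. to CCA — the module's primary oracle.  For three or more
views the covariance tensor is a third-order cross-moment, which vanishes
identically for jointly Gaussian factors; TCCA therefore only detects
higher-order structure when the latent factors are non-Gaussian (the test
suite plants a centered-exponential factor), one concrete reason it can
underperform pairwise methods on near-Gaussian omics data.

**Prediction.**  Epsilon-insensitive SVR with Gaussian kernel
K(x,x') = exp(−γ‖x−x'‖²).  The grid searches box constraint
C ∈ {0.1, 1, 10, 100}, ε ∈ {0.01, 0.1, 1}, and γ around the
median-pairwise-distance heuristic γ₀ = 1/(2·median²) with multipliers
{0.25, 1, 4}, minimizing 10-fold cross-validated MSE on the training split
only.  R² is computed about the *training* mean (the held-out denominator
uses the baseline a deployed model would have), margin proportions report
the fraction of predictions within 5/10/15% of each true value, and the
whole evaluation is repeated over seeded random 80/20 splits.  Following
the application's protocol the representation is learned once on all
samples before splitting; a strict no-leakage variant (fit the hierarchy on
training rows, `transform` the held-out rows) is available and the test
suite verifies that perturbing held-out rows never changes the fitted model.

## Synthetic data and what it does (not) show

The generator is a Gaussian linear factor model X_v = Z B_v + E_v with
factors visible globally or only within declared view groups, three loading
styles (modular blocks with constant within-block loadings, orthonormal
maps, dense Gaussian), linear phenotypes y = Zβ + ε, and stochastic block
networks aligned with the modular loadings.  Closed forms make it an exact
oracle: two 1-feature views sharing a factor with loading b and noise sd σ
have population canonical correlation b²/(b²+σ²), and the attainable
phenotype R² is ‖β‖²/(‖β‖²+σ_y²).

Canned scenarios (fixed study conditions; the seed only moves the noise):

* `two_view_1d` — b = 1, σ = 0.5, n = 2000: population ρ = 0.8, used for
  parameter-recovery checks.
* `grouped3` — two 15-feature views sharing a rank-15 orthonormal latent
  space (κ of their cross-covariance ≈ 3–4) plus an independent third view
  (κ ≈ 50–80): the minimum-κ rule recovers the planted pair.
* `fourview` — three 40-feature "genomic" views and one 12-feature "climate"
  view; four phenotype factors visible everywhere (feature noise sd 0.45,
  so one view recovers ≈ 83% of a factor's variance and the ensemble
  ≈ 95%), plus weaker full-rank group factors pairing mutation with climate
  and expression with methylation, which drives the merge order; phenotype
  noise sets the analytic R² ceiling to 0.5.  At n = 300 and 50 repeated
  splits the joint representation scores ≈ 0.46, above every single view
  (≈ 0.31–0.41) and within 0.05 of the ceiling.

Scenario sizes (n = 150–2000, d = 12–40, 50 evaluation repeats rather than
hundreds) are chosen so the full suite runs on a laptop-class single CPU;
they are desk-scale stand-ins, not the application's dimensions.

What passing these tests does *not* show: the generator is linear and
Gaussian with homoscedastic noise and no population structure, linkage,
count overdispersion, or batch effects; real multi-omics data have all of
these.  Results on synthetic scenarios certify the implementation and the
method's behavior under its own assumptions, not biological performance.

An important structural finding the scenarios expose: hierarchical merging
with the 85% component rule discards signal that is not shared across a
merge boundary (a factor private to one side survives a merge only through
incidentally retained low-correlation components).  Phenotype signal
therefore persists to the root only when it is visible on both sides of
every merge on its path — which shaped the `fourview` design: integration
helps by averaging noise on commonly visible factors, not by pooling
factors that only one view sees.

## Numerical choices and degenerate inputs

* Variance filtering uses ddof = 1 and breaks exact ties toward the earlier
  column; it runs on pre-normalization values, then z-scoring.
* Constant features are zeroed (z-score) or given loading 0 with a flag
  (association) rather than dropped or NaN-propagated, keeping IDs stable.
* Flanked gene windows are half-open [max(0, start−flank), end+flank);
  symmetric flanks make strand handling moot.  An event overlapping several
  flanked genes counts toward each; a gene with several intervals
  accumulates over all of them.
* Network edge lists: self-loops dropped, duplicate edges keep the maximum
  weight, isolated features get an identity row in the normalized
  Laplacian.
* Serialization is JSON (Python float repr round-trips exactly); files
  carry a format/version stamp and corrupt or mismatched files are
  rejected.
* All randomness flows through explicit integer seeds; fitting itself is
  deterministic (two runs on identical inputs are bitwise identical).

## Known limitations

* The condition-number merge rule needs n comfortably above the smaller
  view's dimension; when every pairwise cross-covariance is numerically
  singular the selection degenerates to noise-floor comparisons.
* TCCA's covariance tensor is dense; dimensionality must be reduced (or k
  kept small) before use on wide views — the element budget refuses
  otherwise.
* Laplacian smoothing applies only to original feature spaces, not merged
  pseudo-views, and requires c > 3.
* The association analysis assumes transitivity of correlation, which holds
  exactly only in the noiseless regime; the test suite verifies it there.
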
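# hcca — hierarchical canonical correlation analysis for multiview integration

`hcca` integrates two or more sample-aligned, high-dimensional datasets
("views" — e.g. per-gene mutation counts, expression, DNA methylation, and
geoclimatic variables for the same *Arabidopsis thaliana* accessions) into a
single joint feature representation, and evaluates that representation for
continuous phenotype prediction (e.g. flowering time) and for gene–environment
association analysis.

## The method

Classical CCA finds weight pairs (w₁, w₂) maximizing

    corr(X₁w₁, X₂w₂) = w₁ᵀC₁₂w₂ / √(w₁ᵀC̃₁₁w₁ · w₂ᵀC̃₂₂w₂),

with the within-view covariances regularized as C̃ᵢᵢ = Cᵢᵢ + αI.  `hcca` adds
three ingredients:

* **Reconditioning.**  Instead of tuning α directly, the user picks a target
  condition number c (default 4): α = (λ_max − c·λ_min)/(c − 1) makes
  κ(C + αI) = c exactly.  With a protein-interaction network, the
  regularizer becomes α(I + L) with L the normalized graph Laplacian (which
  pulls the weights of interacting features together), and Weyl's inequality
  gives the safe choice α = (λ_max − c·λ_min)/(c − 3), requiring c > 3.
* **Condition-number-guided hierarchy.**  With N views, the pair whose
  cross-covariance XᵢᵀXⱼ has the *smallest* condition number — the pair least
  similar to singular, i.e. most robustly correlated — is merged first by
  CCA; the pair is replaced by the concatenated canonical variables
  [Xᵢwᵢ | Xⱼwⱼ] and the procedure recurses until a single joint matrix
  remains.  The number of components per merge follows a PCA-style
  cumulative-spectrum rule (default 85%).
* **Canonical factor loadings.**  The Pearson correlation of each original
  feature with the canonical variables places genes and environmental
  variables in one low-dimensional space, where Euclidean nearest neighbors
  propose gene–environment associations, at any level of the hierarchy.

Baselines with identical interfaces: pairwise multiset CCA (SUMCOR
generalized eigenproblem), tensor CCA (CP-ALS on the whitened covariance
tensor), and plain feature stacking.  Prediction uses grid-searched
Gaussian-kernel support vector regression with R² about the training mean,
over repeated random train/test splits.

## Worked example

All inputs can be simulated with known ground truth:

```bash
hcca simulate --scenario grouped3 --out demo --seed 3
hcca pairs demo/view0.tsv demo/view1.tsv demo/view2.tsv
```

```
i       j       kappa
0       1       3.6215372773783856
0       2       31.63170852483016
1       2       32.382723639113784
```

Views 0 and 1 share a planted full-rank latent space, and their
cross-covariance condition number (κ ≈ 3.6) is an order of magnitude below
the independent pairs — so HCCA merges them first:

```bash
hcca fit demo/view0.tsv demo/view1.tsv demo/view2.tsv --out-dir demo/fit --seed 3
cat demo/fit/merge_log.tsv
```

```
level   i       j       kappa   alpha_left      alpha_right     k
1       0       1       3.6215372773783856      0.0     0.0     12
2       0       1       15.568104238855378      0.0     0.5453720136871673      9
```

Level 1 merges the planted pair (0, 1) at κ ≈ 3.6 with 12 canonical
components (both views are already well-conditioned, so the reconditioning
rule leaves α = 0); level 2 folds in the remaining view, this time with a
ridge on the merged side.  The joint representation
lands in `demo/fit/joint_representation.tsv`, and
`hcca evaluate --rep ... --phenotype ...` scores it by repeated-split SVR
(`mean R^2 = ...` printed per run).  `hcca associate` ranks the features of
one view nearest a target feature of another view in canonical-loading
space and writes a TSV gene list.

In Python the same pipeline is three calls:

```python
import hcca

sc = hcca.scenario("fourview", seed=1)           # 4 views + phenotype, known truth
model = hcca.fit_hcca(sc["views"], config=hcca.RunConfig(seed=1))
report = hcca.repeated_evaluation(model.root.U, sc["phenotype"].to_numpy(),
                                  hcca.RunConfig(seed=1), n_repeats=50)
print(report.mean_r2, sc["truth"].r2_ceiling)  # e.g. 0.456 vs analytic ceiling 0.5
```

The joint representation predicts the phenotype better than any single view
(single-view means ≈ 0.31–0.41 on this scenario) and approaches the
generative model's analytic R² ceiling.

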
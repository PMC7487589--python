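# gnbfactor

Bayesian factor analysis of single-cell RNA-seq count matrices with a
hierarchical gamma–negative binomial model — dimensionality reduction that
absorbs dropout through over-dispersion instead of an explicit zero-inflation
term.

## The problem

scRNA-seq count matrices are dominated by zeros: transcripts present in a
cell are frequently missed by capture and sequencing (dropout), and counts
are strongly over-dispersed between cells. Zero-inflated methods model the
excess zeros with a separate point mass, which can over-emphasize zeros and
bias the recovered latent structure. This package takes the alternative
route: a negative binomial (NB) likelihood whose **cell-specific dispersion**
carries a hierarchical gamma prior, so deeply and shallowly sequenced cells
get their own dropout burden, while the latent structure lives on the logit
of the NB probability parameter. No normalization or zero-inflation term is
needed; raw counts go in.

## The model

For gene v ∈ {1..V} and cell j ∈ {1..J},

    n_vj ~ NB(r_j, p_vj)                    counts
    r_j  ~ Gamma(e0, rate h)                cell dispersion, h learned
    ψ_vj = logit(p_vj) = βᵥᵀxⱼ + δⱼᵀzᵥ + φᵥᵀθⱼ

where xⱼ (P cell covariates) and zᵥ (Q gene covariates) carry known designs
(intercepts by default), βᵥ and δⱼ are regression coefficients with
automatic-relevance-determination (ARD) normal–gamma priors, and φᵥᵀθⱼ is a
K-factor bilinear term: loadings φᵥ ~ N(0, I_K), scores θⱼ ~ N(0, diag(γ)⁻¹).
The expected count is E[n_vj] = r_j e^{ψ_vj}.

Inference is a fully conjugate Gibbs sampler built on two data
augmentations: Chinese-Restaurant-Table (CRT) counts make the dispersion
update a gamma draw, and Polya-Gamma (PG) variables ω_vj ~ PG(n_vj + r_j, ψ_vj)
make every coefficient and factor block a multivariate-normal draw. The PG
sampler (implemented here for arbitrary real shape) uses the gamma-series
representation with an exactly moment-matched tail. The reported point
estimate is the post-burn-in sample with the highest data log-likelihood.

## Worked example

```python
import numpy as np
from gnbfactor import GNBFactorModel, ZinbSimConfig, simulate_zinb, silhouette

# zero-inflated benchmark: 3 cell clusters, ~60% zeros, known labels
sim = simulate_zinb(ZinbSimConfig(V=600, J=100, target_zero_fraction=0.6,
                                  sample_genes=300, seed=1))
print(f"{sim.counts.n_genes} genes x {sim.counts.n_cells} cells, "
      f"zero fraction {sim.realized_zero_fraction:.3f}")

model = GNBFactorModel(n_components=2, n_iter=300, burn_in=150, random_state=1)
scores = model.fit_transform(sim.counts.counts.T)   # cells x genes in
print(f"log-likelihood {model.log_likelihood_:.1f}")
print(f"silhouette of factor scores vs true clusters: "
      f"{silhouette(scores, sim.labels).average_width:.3f}")
```

prints

```
300 genes x 100 cells, zero fraction 0.596
log-likelihood -67208.5
silhouette of factor scores vs true clusters: 0.434
```

The silhouette width (average of (b−a)/max(a,b) over cells, a = within-cluster
mean distance, b = nearest-other-cluster mean distance) measures how well the
2-D factor scores separate the three simulated cell clusters despite 60% zeros:
0.43 here against 0.47 for the noise-free generating scores themselves.

The same workflow is available from the shell:

```sh
gnbfactor simulate-zinb --genes 600 --cells 100 --zero-fraction 0.6 \
    --sample-genes 300 --seed 1 --out sim/
gnbfactor fit --counts sim/counts.mtx --factors 2 --iters 300 --burnin 150 \
    --seed 1 --out fit/
gnbfactor evaluate --scores fit/theta.tsv --labels sim/labels.tsv --out eval/
```

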
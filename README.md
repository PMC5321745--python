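# metacap

Spatially realistic metapopulation analysis for species living in highly
fragmented landscapes — many small habitat patches holding unstable local
populations linked by dispersal, as in the long-term Glanville fritillary
butterfly system of dry-meadow networks.

The package implements the full analysis chain as an importable library
(`src/metacap/`) with numbered driver scripts (`analysis/`):

1. **Landscape & quality** — patch tables (coordinates in km, areas in ha,
   four habitat-quality variables), pairwise distances, and the composite
   quality index Q̃ ∈ [−1, 1] (min–max rescaled host abundance, dry and low
   vegetation, minus grazing).
2. **Networks** — agglomerative geometric-average-linkage clustering of
   patches on the connectivity similarity sᵢⱼ = (AᵢAⱼ)ᵇ·e^(−α·dᵢⱼ), plus
   per-network summaries and between-network connectivity.
3. **Capacity** — the landscape matrix **M** with mᵢᵢ = 0 and
   mᵢⱼ = Aᵢˣ·e^(y·Q̃ᵢ)·Aⱼᵉᵐ·e^(−α·dᵢⱼ); its leading eigenvalue λ_M
   (metapopulation capacity), eigenvector occupancy weights, the weighted
   metapopulation size p_λ, and the equilibrium prediction
   **p\*_λ = 1 − δ/λ_M** with the extinction threshold δ = e/c. A network
   supports a viable metapopulation iff λ_M > δ.
4. **Occupancy fit** — the equilibrium incidence model
   p̄ᵢ = Vᵢ/(Vᵢ + δ), Vᵢ = Aᵢˣ·e^(y·Q̃ᵢ)·Rᵢ, fitted in two stages
   (structure only, then structure + quality) by nonlinear least squares
   on multi-year average occupancy of large well-occupied networks.
5. **Turnover** — annual colonization/extinction events; Bayesian
   estimation of the mechanistic rates (P_col = 1 − e^(−c·Sᵢ),
   P_ext = 1 − e^(−e·Aᵢ^(−ex)·e^(−y·Q̃ᵢ))) by MCMC with δ summarised from
   the joint posterior; varying-intercepts hierarchical logistic models of
   the events with patch area, connectivity and the immigrant
   dispersive-genotype frequency as covariates; control-survey detection
   GLMs.
6. **Genetics** — the pooled dispersive-genotype frequency f_disp of a
   flight-metabolism SNP per network, emigrant enrichment
   f̃ = Δf/(Δf+1−f) with Δ = 2, connectivity-share weighted immigrant
   frequency f^S, network-level association regressions and a neutral
   SNP-panel QQ calibration.
7. **Simulation & synthetic data** — a stochastic patch occupancy
   simulator (annual synchronous updates, optional genotype layer) and a
   full study generator (clustered landscape, log-normal patch areas with
   median 0.06 ha, 22-year surveys with partial early coverage and
   imperfect detection, genotype samples with planted effects) so every
   stage is testable without any field data.

## Worked example

```python
import numpy as np
from metacap import SynthConfig, generate_study, equilibrium_prediction
from metacap.pipeline import build_network_table

cfg = SynthConfig()                      # the default synthetic study
study = generate_study(cfg, seed=11)
table = build_network_table(study["landscape"], study["assignment"],
                            study["observed_history"], study["quality"],
                            cfg.params, genotypes=study["genotypes"])
n_below = int((~table["viable"]).sum())
print(f"{n_below}/{len(table)} networks below the extinction threshold "
      f"(delta = {cfg.params.delta:.2f})")
pred = equilibrium_prediction(6.1, 5.47)
print(f"lambda_M = 6.1, delta = 5.47 -> p*_lambda = {pred.p_lambda_star:.4f}")
```

prints

```
24/30 networks below the extinction threshold (delta = 3.45)
lambda_M = 6.1, delta = 5.47 -> p*_lambda = 0.1033
```

i.e. most of the synthetic landscape's networks cannot persist without
immigration (their λ_M falls short of δ), and a network barely above the
threshold is predicted to keep only ~10% weighted occupancy at
equilibrium.

Running the full chain on the default study
(`python analysis/01_generate_study.py` … `04_genetics.py`) reproduces the
qualitative structure of a real fragmented-landscape analysis: capacity
explains a substantial share of between-network variation in observed
metapopulation size, below-threshold networks go extinct far more often,
the dispersive-genotype frequency rises with turnover and falls with
pooled habitat area (R² ≈ 0.4), and only the planted candidate SNP — never
the 18 neutral ones — stands out against the uniform-null QQ line.
`analysis/05_threshold_experiment.py` verifies the equilibrium identity by
brute-force simulation: quasi-equilibrium p_λ lands within a few percent
of 1 − δ/λ_M above the threshold and persistence collapses below it.

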
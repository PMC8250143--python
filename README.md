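# gsblup

Linear mixed models with **user-defined covariance structures** for genomic
selection: REML variance components, BLUPs for phenotyped and unphenotyped
genotypes, kernel bandwidth selection, and genotype-level cross-validation.

Plant and animal breeders rank selection candidates by predicted genetic
merit from genome-wide markers and/or pedigree.  The workhorse model is

    y = Xβ + Σⱼ Zⱼuⱼ + e,    uⱼ ~ N(0, σⱼ² Kⱼ),    e ~ N(0, σₑ² I)

where each Kⱼ encodes relatedness among genotypes: the pedigree numerator
relationship matrix **A**, the genomic relationship matrix **G** = WW′/p
from centered/standardized markers, Gaussian/exponential kernels
exp(−θ·d²ᵢⱼ/m) on marker distances, or Kronecker products K₁⊗K₂ for hybrid
combining-ability models.  General-purpose mixed-model software typically
cannot accept an arbitrary Kⱼ; `gsblup` absorbs it into the design via
Zⱼ* = ZⱼLⱼ with LⱼLⱼ′ = Kⱼ (Cholesky or eigendecomposition), fits the
resulting independent-effects model by profiled REML, and maps the BLUPs
back with ûⱼ = Lⱼûⱼ*.  Unphenotyped genotypes are predicted by the
conditional mean û₂ = K₂₁K₁₁⁻¹û₁ from the partitioned covariance.

The fitting engine reproduces R lme4's REML results to machine-level
agreement (see `tests/test_lme4_crosscheck.py`) while remaining a compact,
dense, pure-Python implementation suited to panels of up to a few thousand
genotypes.

## Worked example

Fit a GBLUP model to a simulated 200-line panel (300 biallelic markers,
genetic variance 0.22, residual 0.035) and cross-validate by genotype:

```python
import numpy as np
from gsblup import (UserCovLMM, RandomTermSpec, compute_G, kfold,
                    cross_validate)
from gsblup.simdata import SimConfig, simulate_markers, simulate_phenotypes

markers = simulate_markers(SimConfig(n_individuals=200, m_markers=300, seed=11))
G = compute_G(markers)                       # genomic relationship matrix
Z = np.eye(200)
data, true_u, _ = simulate_phenotypes([(Z, G, 0.22)], 0.035, seed=12,
                                      term_names=["GID"])

est = UserCovLMM(response="y",
                 random_terms=[RandomTermSpec("grm", "GID", G)]).fit(data)
print(est.summary())
```

```
Linear mixed model fit by REML (user covariance)
  restricted log-likelihood: -110.2532
  converged: True
  variance components:
             grm  0.191323
        residual  0.033157
  fixed effects:
     (Intercept)  0.009563
  heritability (all terms): 0.8523
```

The REML estimates recover the generative components (0.19 vs 0.22 genetic,
0.033 vs 0.035 residual on a single draw), and the heritability helper
evaluates σ̂²_grm/(σ̂²_grm + σ̂ₑ²).  Five-fold cross-validation by genotype id:

```python
plan = kfold(data["GID"].unique(), k=5, seed=1)
res = cross_validate(data, "y", [RandomTermSpec("grm", "GID", G)], plan)
print(res.to_frame().to_string(index=False))
```

```
fold  train_r  train_mse   test_r  test_mse
   1 0.992074   0.006840 0.524499  0.195775
   2 0.984315   0.015744 0.755088  0.127262
   3 0.997603   0.002337 0.380692  0.131512
   4 0.999982   0.000016 0.334099  0.189440
   5 0.969069   0.028821 0.750416  0.162589
 avg 0.988609   0.010752 0.548959  0.161316
  sd 0.012475   0.011756 0.198841  0.031733
```

Training accuracy is near 1 (in-sample fitted values) while held-out
genotypes are predicted with r ≈ 0.55 at this signal-to-noise — the gap is
the expected cost of predicting genetic merit from relatives only.

## Command line

Each subcommand is a thin wrapper over the library:

```sh
gsblup simulate --n 200 --m 300 --seed 3 --outdir sim     # synthetic fixture
gsblup fit --config model.yaml --out fit_out               # REML fit + BLUPs
gsblup predict --fit fit_out/fit.json --cov grm=G.csv \
               --newdata new.csv --out pred_out            # new genotypes
gsblup cv --config model.yaml --k 5 --seed 1 --out cv_out  # cross-validation
gsblup bandwidth --config model.yaml --kernel gaussian \
               --out bw_out                                # theta selection
```

`model.yaml` names the phenotype file, response column, fixed terms and
random terms (each a factor column plus a covariance source: pedigree file,
marker file, kernel, Kronecker product, or a precomputed matrix).  See the
`gsblup.cli` module docstring for the schema.

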
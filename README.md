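# hybridtrace

Tools for tracing historical species replacement through a hybrid zone:
design and validation of species-diagnostic SNP panels, admixture and
introgression-footprint detection, and a two-species climate distribution
model — aimed at population geneticists working on contact zones between
closely related taxa (the motivating system is a pair of marbled newt
species, *Triturus marmoratus* and *T. pygmaeus*, where an enclave of one
species survives inside the range of the other).

The package is organised around two fitted models plus the statistics that
surround them:

* **Admixture model.** Individual i draws each allele copy at locus l from
  cluster k with probability q_ik; the copy is the species-M allele with
  probability p_kl, so the dosage is Binomial(ploidy_l, Σ_k q_ik p_kl).
  `AdmixtureModel(genotypes).fit(K)` maximises this likelihood by EM and
  returns ancestry proportions Q, cluster allele frequencies P and the
  log-likelihood; `evanno_delta_k` chooses K by
  ΔK = mean(|L″(K)|)/sd(L(K)), and individuals are classified pure/admixed
  at Q_m > 0.95 / < 0.05.
* **Two-species distribution model.**
  `SpeciesDistributionModel(env).fit()` prunes collinear climate variables
  (UPGMA on 1 − |r_s|, cut at |r_s| = 0.7), then runs forward stepwise
  logistic regression under the likelihood-ratio criterion
  (p_in = 0.05, p_out = 0.10), reporting AUC with its Hanley–McNeil
  standard error and hindcasting onto raster climate sets.
* **Around them:** exon-based marker design (priority rules, 100–400 bp
  filter, top-192 ranking), Cohen's-κ diagnosticity screening (κ ≥ 0.9),
  exact Hardy–Weinberg tests, permutation G-tests of genotypic LD with
  Benjamini–Hochberg correction, Barton–Gale admixture LD with a 1,000-
  replicate bootstrap, genotype PCA with weighted geographic score
  surfaces, and seeded synthetic-data generators for all of the above.

## Worked example

```python
import numpy as np
import pandas as pd
from hybridtrace import (AdmixtureModel, GenotypeMatrix, SampleTable,
                         SimPanelSpec, enclave_landscape,
                         simulate_admixed_landscape,
                         simulate_reference_panels)

panel = SimPanelSpec(seed=7)                     # 60 nuclear SNPs + mtDNA
ref_g, ref_s = simulate_reference_panels(panel, n_marmoratus=25,
                                         n_pygmaeus=25, n_populations=2)
land = enclave_landscape(n_enclave=2, n_pure=6,  # admixed enclave at q=0.93
                         enclave_q=0.93, seed=7)
study_g, study_s = simulate_admixed_landscape(panel, land)

genotypes = GenotypeMatrix(ref_g.individual_ids + study_g.individual_ids,
                           panel.locus_ids,
                           np.vstack([ref_g.dosage, study_g.dosage]),
                           panel.ploidy)
samples = SampleTable(pd.concat([ref_s.df, study_s.df], ignore_index=True))

results = AdmixtureModel(genotypes, samples).fit(2, seed=1, restarts=5)
print(results.summary())
```

```
Admixture model (maximum-likelihood EM)
===========================================
clusters (K):        2
individuals:         138
loci:                61
log-likelihood:      -1811.611
EM iterations:       470 (converged)

population mean Q_m:
  refpop01         1.000
  refpop02         0.000
  enclave1         0.941
  enclave2         0.946
  pond01           0.009
  pond02           0.005
  pond03           0.002
  pond04           0.003
  pond05           0.004
  pond06           0.010
```

The pure reference populations anchor the two clusters (Q_m = 1 and 0),
the two enclave ponds recover their simulated admixture level
(mean Q_m ≈ 0.94, i.e. mostly species-M genome with measurable
introgression from species P), and every surrounding pond is pure
species P (Q_m ≈ 0) — the textbook signature of an enclave left behind by
species replacement.

The distribution model reads a locality table instead:

```python
from hybridtrace import SpeciesDistributionModel, SimEnvSpec, simulate_env_presence

env = simulate_env_presence(SimEnvSpec(n_localities=10_000, seed=5))
model = SpeciesDistributionModel(env)
print(model.fit().summary())
```

```
Two-species distribution model (stepwise logistic regression)
==============================================================
observations:     10000
selected:         bio17
log-likelihood:   -2062.233
AUC:              0.974 +/- 0.002
model:            p_M = 1/(1 + exp(-0.160*bio17 +7.989))

term              coef   std err
const          -7.9889    0.1832
bio17           0.1600    0.0036
```

Here species M occupies the wetter summers: its presence probability
follows a logistic in bio17 (precipitation of the driest quarter, mm),
and the refit recovers the generating coefficients (−0.156, 7.767) within
sampling error.

A thin CLI wraps the same stages:
`hybridtrace simulate|design|markers|popgen|admixture|pca|sdm`.

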
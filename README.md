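# ventseep

Population divergence and larval connectivity of deep-sea hydrothermal-vent
and hydrocarbon-seep invertebrates, as one tested pipeline: coalescent
simulation of competing demographic scenarios, a GBS SNP filtering cascade,
population-genetic statistics, directional relative migration, approximate
Bayesian computation (ABC) for demographic inference, and Lagrangian
particle-release experiments on a synthetic ocean.

## The scientific problem

Chemosynthesis-fueled habitats — hydrothermal vents and hydrocarbon seeps —
are rare, widely separated oases on the deep seafloor.  A limpet that
colonizes both habitat types across thousands of kilometres raises two
linked questions: *how did its populations form* (which habitat is
ancestral, and were new habitats colonized by large migrations or by a
handful of founding larvae?) and *how are they connected today* (can
larvae physically drift between sites, given seafloor topography and the
depth-decaying ocean currents)?

The package addresses both with synthetic data carrying the statistical
structure such studies assume.  Four genetic groups are modeled — three
seep groups (JR: Jiaolong Ridge, OH: Off Hatsushima, KK: Kuroshima Knoll)
and one vent group (OT: Okinawa Trough) — under three competing
divergence/founder scenarios.  In scenario 1, an ancestral population
splits at time `T_A` into a deeper-seep lineage and the KK lineage; a
propagule of `N_KKP` larvae leaves KK at `T_3`, persists as a small
founder population, and becomes the OT vent group of size `N_OT` at
`T_2`; the deeper-seep lineage splits into JR and OH at `T_1`.
Scenarios 2 and 3 make the deeper-seep or the KK lineage ancestral
instead.  All times are generations before present (`T_1 < T_2 < T_3
(< T_4) < T_A`); sizes are diploid effective sizes; the coalescent uses
the standard diploid rate `k(k-1)/(4N)`.

The core statistical machinery:

* **Weir & Cockerham (1984) F_ST** — the ratio-of-averages estimator
  `theta = sum(a) / sum(a+b+c)` over loci, with a permutation test
  (individuals shuffled between the two groups).
* **Diversity statistics** per group over variant sites: `H_exp = 2p(1-p)`,
  observed heterozygosity, nucleotide diversity `pi = 2p(1-p)·2n/(2n-1)`,
  and `F_IS = 1 - H_obs/H_exp`.
* **Directional relative migration** (the divMigrate method): for each
  group pair a hypothetical migrant pool with the mean allele frequencies
  is formed; Nei's G_ST between each member and the pool converts to
  `Nm = (1/G_ST - 1)/4`, and the matrix is normalized to a maximum of 1.
* **ABC** (DIYABC-style): a reference table of (scenario, parameters,
  40 summary statistics); scenario choice by the *direct* method (share
  among the 500 closest simulations) and by weighted multinomial
  *logistic regression* on the closest 1%; parameter posteriors by
  Beaumont-style local-linear regression adjustment after
  logit-transforming parameters to their prior bounds; PCA model checking.
* **Ocean particles**: a synthetic semi-enclosed trough with a sill at
  750 m, gap channels, a boundary current decaying as
  `U(z) = U0·exp(-z/H)` from 1 m/s at the surface to 0.1 m/s at 1,000 m,
  and a non-divergent mesoscale eddy field; particles advect with an
  adaptive Dormand–Prince RK5(4) scheme and bicubic velocity
  interpolation, beach on seafloor shallower than their depth, and their
  basin entries/exits are attributed to named gates.

## Worked example

```python
import numpy as np
from ventseep import SampleConfig, published_median_params, simulate_dataset
from ventseep.popstats import group_summary, pairwise_fst

params = published_median_params()           # scenario-1 point estimates
gm = simulate_dataset(params, SampleConfig(), n_loci=2000, rng_seed=1)
print(group_summary(gm)[["n", "poly", "H_exp", "H_obs", "pi", "F_IS"]])
r = pairwise_fst(gm, "JR", "OH", n_perm=1000, rng_seed=0)
print(f"F_ST(JR, OH) = {r.estimate:.4f}  (p = {r.p_value:.4f})")
r2 = pairwise_fst(gm, "JR", "KK", n_perm=0)
print(f"F_ST(JR, KK) = {r2.estimate:.4f}")
```

prints

```
        n  poly     H_exp     H_obs        pi      F_IS
group
JR     12   830  0.122196  0.125958  0.127509 -0.013907
OH     25  1007  0.127651  0.127780  0.130256 -0.004208
KK     21   964  0.126715  0.129095  0.129806 -0.010125
OT     63   395  0.009243  0.009444  0.009317 -0.001638
F_ST(JR, OH) = 0.0305  (p = 0.0010)
F_ST(JR, KK) = 0.2551
```

The two deeper-seep groups (JR, OH) diverged only ~1,220 generations ago
and remain much more similar to each other (F_ST ≈ 0.03) than either is
to the shallower KK group (F_ST ≈ 0.26), whose lineage split ~24,400
generations ago — the habitat-linked divergence pattern the scenarios
encode.  The vent group (OT) carries the clear signature of its founder
bottleneck: few polymorphic sites and an order-of-magnitude lower
heterozygosity, because a propagule of ~650 larvae founded it and most
ancestral variation coalesced inside that bottleneck.

An end-to-end run (simulation → GBS noise → filtering → statistics →
migration → a desk-scale ABC fit) is one command:

```bash
ventseep run-all --seed 1 --out demo_run
```

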
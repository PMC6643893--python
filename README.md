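# looksel — deadline-aware genomic selection

`looksel` implements **look-ahead selection (LAS)** for plant-breeding
programs: instead of ranking individuals by their own genomic estimated
breeding values (GEBVs), LAS chooses *which* parents to select, *how* to
pair them into crosses, and *how many* progenies each cross gets, so as to
maximize the expected GEBV of the **best offspring at a deadline
generation T**. It is built for breeders and quantitative geneticists who
want to study the trade-off between short-term genetic gain and long-term
potential under explicit time and resource budgets.

The package also implements the standard comparators — conventional GS
(truncation on GEBV), weighted GS, optimal haploid value (OHV) and optimal
population value (OPV) — and a stochastic multi-generation
breeding-campaign simulator for head-to-head evaluation, plus a synthetic
data generator so everything runs without external downloads.

## The model in brief

For phased biallelic genotypes `G[l, m, n] ∈ {0, 1}` (locus l, homolog m,
individual n; 1 = major allele) with additive effects β:

* `GEBV_n = Σ_l Σ_m G[l,m,n] β_l`
* `OHV_n = 2 Σ_b max_m Σ_{l∈b} G[l,m,n] β_l` over haplotype blocks b
* `OPV(x) = 2 Σ_b max_{n∈x, m} Σ_{l∈b} G[l,m,n] β_l` for a group x
* `f_LAS(x, y, r, T−t)` = expected GEBV of the best terminal-generation
  offspring of the ordered, paired selection (x, y), given recombination
  frequencies r and the remaining horizon T − t.

f_LAS is estimated by Monte Carlo from a gamete-ancestry Markov chain over
the 2S selected haplotypes, whose cross-family mixing is governed by the
accumulated recombination `R_l = (S−2)[1 − (1−r_l)^n]/S`; with one
generation left the exact within-pair meiosis model is used. Group
objectives (OPV, LAS) are optimized by pairwise-swap local search with
common random numbers. Progeny budgets are allocated to crosses in
proportion to the mate pair's genetic diversity
`Σ_l [max_{n,m} G β − min_{n,m} G β]`. See `docs/methods.md` for details
and assumptions.

## Worked example

```python
import numpy as np
from looksel import (CampaignConfig, LookaheadParams, ScenarioSpec,
                     make_scenario, run_program, selection_limits)

pop, genome = make_scenario(ScenarioSpec(seed=0))   # 50 inbred founders, 300 loci
print(selection_limits(pop, genome)[1])             # -> 100.0
cfg = CampaignConfig(method="las", T=5, N=50, S=10, total_progeny=50,
                     las=LookaheadParams(n_progeny_samples=50, n_reps=4))
print(run_program(pop, genome, cfg, seed=1).frame.round(2).to_string(index=False))
```

```
 generation    min  mean   max  diversity   lower  upper  gain
          0 -48.06 -7.73 43.51     106.30 -112.59 100.00  0.00
          1  -5.79  8.23 34.94      96.46  -94.91  98.02 15.96
          2   5.41 22.95 43.36      92.35  -89.48  95.22 30.68
          3  18.71 32.34 56.13      83.53  -72.93  94.14 40.06
          4  19.22 38.87 57.18      79.84  -70.31  89.37 46.60
          5  35.80 49.99 62.82      52.30  -17.13  87.47 57.72
```

Each row is one generation: GEBV minimum/mean/maximum of the population
(on the 0–100 potential scale), its genetic diversity, the lower/upper
selection limits (worst/best genotype assemblable from alleles still
present), and the cumulative gain in mean GEBV over the founders. Note the
LAS signature: diversity and the upper limit are held high through the
campaign (upper 87.5 at the deadline), and the method switches to
exploitation in the last generation (diversity 79.8 → 52.3, gain +11.1).

The same campaigns are available from the shell:

```bash
looksel synth --out-dir scenario --seed 0
looksel compare --genotypes scenario/haplotypes.csv --map scenario/map.csv \
    --effects scenario/effects.csv --methods cgs,ohv,opv,las \
    --generations 10 --select 10 --pop-size 50 --total-progeny 50 \
    --reps 10 --seed 7 --out-dir results/
```

which writes per-generation trajectories, Table-style terminal summaries
and the per-repetition terminal maxima (CDF-ready) as CSV.

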
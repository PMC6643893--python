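# Methods

## Problem setting

A genomic-selection breeding campaign starts from a founder population of
diploid individuals genotyped at L biallelic loci with known additive
marker effects, and repeats a select → mate → reproduce cycle until a
deadline generation T. Each generation, S parents are chosen from the
population of N individuals and grouped into S/2 crosses, which together
produce a fixed number of progenies that become the next generation. The
quantity of interest is genetic gain — the change in mean genomic
estimated breeding value (GEBV) of the population — by the deadline, and
the genetic diversity retained along the way.

All genotypes are phased 0/1 haplotypes with allele 1 the major allele in
the founders; the effect β_l attaches to the major allele and may carry
either sign. Effects are rescaled once so that the founders' *upper
selection limit* — the GEBV of the best genotype assemblable from alleles
present in the population, 2·Σ_l max(attainable per-locus contribution) —
equals 100, putting every campaign on a common 0–100 scale.

## Selection criteria

* **CGS** — truncation selection on GEBV, `GEBV_n = Σ_l Σ_m G[l,m,n] β_l`.
* **Weighted GS** — GEBV with each effect divided by `max(w_l, 1/N)`,
  where `w_l` is the favorable-allele frequency, up-weighting rare
  favorable alleles. By default the favorable allele is the coded-1 major
  allele regardless of the sign of β (the convention under which an absent
  allele gives `w = 0`); a sign-aware variant is available.
* **OHV** — the GEBV of an individual's best doubled haploid, computed
  over haplotype blocks: `OHV_n = 2 Σ_b max_m Σ_{l∈b} G[l,m,n] β_l`.
* **OPV** — the group analogue: block-wise best haplotype over the whole
  selected set, scoring the best progeny derivable from the group given
  unlimited generations.
* **LAS** — the look-ahead objective: the expected GEBV of the best
  offspring in the terminal generation, given the remaining horizon T − t,
  for an *ordered* selection whose consecutive positions form mate pairs.

Haplotype blocks are contiguous runs of loci within a chromosome, split
into B near-equal-count blocks per chromosome (remainder on the first
blocks). B = 12 for OHV and B = 1 for OPV by default; both methods first
drop the fraction F of lowest-GEBV individuals (F = 0.7 and 0.4
respectively).

The genetic diversity of a set of individuals is the aggregated per-locus
range of effect contributions: a locus contributes |β_l| when both alleles
are present in the set and 0 when it is fixed. A block-wise variant
(range of per-block haplotype scores) is available behind a flag; the
per-locus form is the default and is what the campaign records.

## The look-ahead objective

Evaluating the expected best terminal offspring exactly is intractable,
so the terminal population is approximated by a gamete-ancestry Markov
chain over the 2S selected haplotypes: walking along the genome, the
ancestry of a terminal gamete stays on its haplotype, switches within the
parent or to the parent's mate with one meiosis' recombination frequency
r_l, or jumps to a haplotype of another mate pair with a probability set
by the accumulated recombination

    R_l = (S − 2) [1 − (1 − r_l)^n] / S,

which saturates at (S − 2)/S as the number n of intermating meioses grows.
A terminal progeny is the union of two independent chain gametes, and the
objective is estimated as the mean over `n_reps` repetitions of the
maximum GEBV among K sampled progenies.

Two semantic choices deserve note:

* **Horizon accounting.** The chain's explicit r factors describe the
  final meiosis and its mate-switch case describes the pair-hybrid (F1)
  stage, so the accumulated term spans only the random-intermating
  meioses between them: `n = horizon − 2` (zero at horizon 2). Publishing
  conventions sometimes write the full horizon in the exponent; that
  variant is available (`accumulation="printed"`), but with it the
  objective lets a single cross inherit from several families, which
  overstates short-horizon potential and suppresses the characteristic
  end-of-campaign exploitation. `accumulated_recomb` itself always
  evaluates the printed formula for the exponent it is given.
* **Exact horizon 1.** With one generation left, the terminal offspring
  distribution is known exactly — each progeny is a direct cross of one
  mate pair, sampled by ordinary meiosis — and the estimator uses that
  exact model instead of the chain. This is what makes look-ahead
  selection switch to exploiting at the deadline (selecting and pairing
  high-GEBV parents), matching its intended deadline-aware behaviour.

Defaults: K = 200 progenies with `n_reps = 1` at the full campaign scale
(K mirrors the per-generation population size); the reduced-scale study
below uses K = 50 (again the per-generation population size) with
`n_reps = 4`, since averaging a few repetitions stabilizes swap-move
comparisons at small K.

## Optimization

CGS, weighted GS and OHV are separable, so truncation selection is exact
(ties broken toward the lower index). OPV and LAS are group objectives
and are optimized by first-improvement pairwise-swap local search:
scan every (selected, unselected) exchange — for LAS, position-wise, plus
re-pairing exchanges between two selected positions of different pairs —
and accept any move that improves the objective, until a full scan yields
no improvement. OPV restarts from random subsets; LAS starts from the
top-S GEBV group (so the result is never worse than truncation selection
under the evaluation randomness) with optional random restarts.

All LAS evaluations within one search share *common random numbers*: the
chain's law depends only on (r, R, S), not on which individuals occupy
the parent slots, so ancestry paths are sampled once and reused for every
candidate, removing Monte-Carlo noise from move comparisons (a move must
improve by more than a configurable tolerance, default 0).

Progeny budgets are allocated across crosses proportionally to each
pair's genetic diversity (largest-remainder rounding; every pair keeps at
least one progeny, topped up from the largest allocation; equal split
when all diversities are zero). Methods other than LAS split the budget
equally.

## Simulation engine

Each generation: method-dispatched selection → mate pairing (uniform
random perfect matching for the truncation and OPV methods; the optimized
ordering for LAS) → per-cross meiosis. Gametes follow the two-state
origin chain — fair coin at the first locus, switch with probability r_l
between adjacent loci — i.e. crossovers without interference (consistent
with Haldane's mapping function, the default cM → r conversion) and no
mutation. Random streams are spawned per (generation, cross) from one
root seed, so one cross's progeny count never perturbs another's draws;
fixed seeds give bit-identical campaigns.

Generation-0 statistics are computed on the founders before any
selection; the terminal generation is the product of the last
reproduction step. Multi-method comparisons share one founder draw per
repetition (a random subset of size N when the founder pool is larger),
making across-method contrasts paired; dispersion is reported as the
standard deviation across repetitions (ddof = 0, so a single repetition
reports 0).

## Synthetic scenarios

The generator emulates a diversity panel of inbred lines: fully
homozygous founders (outbred mode available), loci placed uniformly at
random along each chromosome's genetic map, per-locus major-allele
frequencies drawn uniformly from (0.5, 0.95), and sparse effects (20% of
loci nonzero by default, half-normal magnitudes with a configurable sign
mix, default half positive). Defaults give a desk-scale scenario of 50
founders and 300 loci on 5 chromosomes of 150 cM. Linkage disequilibrium
beyond inbreeding is *not* modelled; real panels carry strong LD, under
which truncation selection exhausts its usable variation faster than in
these scenarios, so reduced-scale results understate the advantage of the
group-based methods at short deadlines.

## Reduced-scale study conditions

The packaged head-to-head study (tests and `scripts/acceptance.py`) runs
30 paired repetitions of a 10-generation campaign: 50 founders drawn per
repetition from a 150-line synthetic pool, 300 loci on 5 chromosomes,
S = 10 parents, 5 crosses, 50 progenies per generation; LAS uses K = 50,
`n_reps = 4`, one warm start. These sizes keep a full 4-method comparison
within minutes on one CPU while preserving the published design's
proportions (parents : population = 1 : 5, progenies per cross = 10).
The deadline T = 10 is the published comparison's deadline; it matters
here because, without LD, conventional GS keeps gaining through
generation ~5 and only plateaus later, so shorter desk-scale deadlines
would conflate scale artefacts with method differences.

## Numerical choices and edge cases

* Chromosome-boundary intervals carry r = 0.5; all r are clamped to
  [0, 0.5]. Zero map distance gives r = 0; negative within-chromosome
  distances are errors.
* For S = 2 the cross-pair chain case does not exist; the accumulated
  term is treated as structurally zero (its S − 2 factor vanishes), and
  the kernel normalizes exactly.
* Ties: truncation keeps the lower index; prefiltering drops the higher
  index first; largest-remainder rounding favours the lower pair index.
* Missing genotypes and unphased VCF records are rejected, never imputed.
* GEBV-monomorphic populations cannot be potential-scaled (error).

## Known limitations

* The look-ahead chain ignores selection pressure in intermediate
  generations (it models random intermating), so it understates the
  quality of the realized terminal population; this is inherent to the
  approximation.
* No crossover interference, no mutation, no dominance or epistasis.
* The swap search is a local heuristic; global optimality is only
  verified on tiny instances against exhaustive enumeration.
* Marker-effect estimation, phasing and imputation are out of scope;
  effects are trusted inputs.
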
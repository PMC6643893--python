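"""The look-ahead selection objective.

Look-ahead selection (LAS) scores an *ordered* group of S breeding parents
(consecutive positions form mate pairs) by the expected GEBV of the best
offspring in the terminal generation of the breeding program, given the
number of generations remaining before the deadline.

Evaluating that expectation exactly is intractable, so the terminal
population is approximated by a gamete-ancestry Markov chain: a random
gamete produced in the last meiosis is described by a chain over the 2S
parental haplotypes.  Walking along the genome, the ancestry of the next
locus either stays on the same haplotype, switches within the same parent
or its mate (one meiosis' recombination, frequency ``r``), or jumps to a
haplotype of a different mate pair, with a probability governed by the
*accumulated* recombination

    R_l = (S - 2) [1 - (1 - r_l)^(T - t)] / S ,

the effective chance that at least one crossover in the remaining
``T - t`` generations moved the ancestry across families.  A terminal
progeny is the union of two independent such gametes, and the objective is
estimated as the maximum GEBV over a Monte-Carlo sample of K progenies.

For ``S = 2`` there are no non-mate pairs and the accumulated term is
structurally zero (the ``S - 2`` factor vanishes), so the chain reduces to
ordinary single-family meiosis.

The chain approximates several generations of random intermating, so it is
used for horizons of two or more generations.  With exactly one generation
left the terminal offspring distribution is known in closed form — each
progeny is a direct cross of one mate pair — and the objective estimator
samples that exact distribution instead (see :class:`FlasEvaluator`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .popgenome import GenomeSpec, Population
from .meiosis import Gamete

logger = logging.getLogger(__name__)

__all__ = [
    "LookaheadParams",
    "accumulated_recomb",
    "transition_probability",
    "initial_state_probability",
    "sample_ancestry_paths",
    "sample_terminal_gamete",
    "FlasEvaluator",
    "estimate_flas",
]


@dataclass
class LookaheadParams:
    """Monte-Carlo settings for the look-ahead objective.

    Parameters
    ----------
    n_progeny_samples : int
        K, the number of terminal progenies sampled per evaluation.
    n_reps : int
        Outer repetitions; the objective is the mean over repetitions of
        the per-repetition maximum GEBV.  ``n_reps=1`` is the
        single-sample rule.
    """

    n_progeny_samples: int = 200
    n_reps: int = 1

    def __post_init__(self) -> None:
        if self.n_progeny_samples < 1:
            raise ValueError("n_progeny_samples must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def accumulated_recomb(r: np.ndarray, S: int, horizon: int) -> np.ndarray:
    """Accumulated cross-family recombination over the remaining generations.

    ``R[l] = (S - 2) (1 - (1 - r[l])^horizon) / S`` elementwise.  Zero
    whenever ``r[l] = 0`` or ``S = 2``.
    """
    if S < 2:
        raise ValueError("S must be >= 2")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if horizon == 1 and S > 2:
        logger.debug(
            "horizon=1: accumulated recombination is nonzero for S>2 by construction"
        )
    r = np.asarray(r, dtype=float)
    return (S - 2) * (1.0 - (1.0 - r) ** horizon) / S


def initial_state_probability(S: int) -> float:
    """Uniform law over the 2S parental haplotypes at the first locus."""
    return 1.0 / (2 * S)


def transition_probability(
    i0: int, m0: int, i1: int, m1: int, r_next: float, R_next: float, S: int
) -> float:
    """One-step ancestry transition probability between adjacent loci.

    States are (parent ``i`` in ``0..S-1``, homolog ``m`` in ``{0, 1}``);
    parents are paired consecutively, ``(0,1), (2,3), ...``.  Cases, in
    order of precedence:

    - same parent, same homolog: ``(1-r)^2 (1-R)``
    - same parent, other homolog: ``r (1-r) (1-R)``
    - the parent's mate (either homolog): ``r (1-R) / 2``
    - any haplotype of another pair: ``R / (2 (S-2))``

    For ``S = 2`` no other pair exists; the accumulated term is treated as
    zero (its ``S - 2`` factor vanishes) and the cross-pair case has
    probability 0.
    """
    for name, v, hi in (("i0", i0, S), ("i1", i1, S)):
        if not 0 <= v < hi:
            raise ValueError(f"{name} must be in 0..{hi - 1}")
    if m0 not in (0, 1) or m1 not in (0, 1):
        raise ValueError("homolog indices must be 0 or 1")
    r = float(r_next)
    R = 0.0 if S == 2 else float(R_next)
    if i0 == i1 and m0 == m1:
        return (1.0 - r) ** 2 * (1.0 - R)
    if i0 == i1:
        return r * (1.0 - r) * (1.0 - R)
    if i0 // 2 == i1 // 2:
        return 0.5 * r * (1.0 - R)
    if S == 2:
        return 0.0
    return R / (2.0 * (S - 2))


def sample_ancestry_paths(
    S: int,
    r: np.ndarray,
    R: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample *n* ancestry paths of the terminal-gamete chain.

    Returns ``(parents, homologs)``, each of shape ``(n, L)``, giving for
    every path and locus the parent index (``0..S-1``) and homolog
    (``0/1``) whose allele the gamete copies.
    """
    r = np.asarray(r, dtype=float)
    R = np.zeros_like(r) if S == 2 else np.asarray(R, dtype=float)
    L = len(r) + 1
    parents = np.empty((n, L), dtype=np.int64)
    homologs = np.empty((n, L), dtype=np.int8)
    i = rng.integers(0, S, size=n)
    m = rng.integers(0, 2, size=n).astype(np.int8)
    parents[:, 0] = i
    homologs[:, 0] = m
    n_pairs = S // 2
    for l in range(L - 1):
        rl, Rl = r[l], R[l]
        p_stay = (1.0 - rl) ** 2 * (1.0 - Rl)
        p_flip = rl * (1.0 - rl) * (1.0 - Rl)
        p_mate = rl * (1.0 - Rl)          # both mate homologs combined
        u = rng.random(n)
        c_flip = (u >= p_stay) & (u < p_stay + p_flip)
        c_mate = (u >= p_stay + p_flip) & (u < p_stay + p_flip + p_mate)
        c_far = u >= p_stay + p_flip + p_mate
        i = i.copy()
        m = m.copy()
        m[c_flip] ^= 1
        if c_mate.any():
            i[c_mate] ^= 1
            m[c_mate] = rng.integers(0, 2, size=int(c_mate.sum()), dtype=np.int8)
        if c_far.any():
            k = int(c_far.sum())
            own_pair = i[c_far] // 2
            pair = rng.integers(0, n_pairs - 1, size=k)
            pair = pair + (pair >= own_pair)  # skip own pair
            i[c_far] = 2 * pair + rng.integers(0, 2, size=k)
            m[c_far] = rng.integers(0, 2, size=k, dtype=np.int8)
        parents[:, l + 1] = i
        homologs[:, l + 1] = m
    return parents, homologs


def sample_terminal_gamete(
    selected: Population,
    r: np.ndarray,
    R: np.ndarray,
    rng: np.random.Generator,
) -> Gamete:
    """Draw one random gamete of the terminal generation.

    ``selected`` holds the S ordered breeding parents (consecutive pairs
    are mates); S must be even.
    """
    S = selected.n_individuals
    if S % 2 != 0:
        raise ValueError("the number of selected parents must be even")
    parents, homologs = sample_ancestry_paths(S, r, R, 1, rng)
    L = selected.n_loci
    alleles = selected.G[np.arange(L), homologs[0], parents[0]]
    return Gamete(g=alleles.astype(np.int8), origin=homologs[0])


class FlasEvaluator:
    """Look-ahead objective with frozen (common) random numbers.

    The ancestry chain's law depends only on ``(r, R, S)`` — not on which
    individuals occupy the S parent slots — so the chain's random paths
    can be sampled once and reused to score every candidate ordered
    selection.  Scoring then reduces to gathering alleles along the frozen
    paths and taking GEBV maxima, which both makes swap-search cheap and
    removes Monte-Carlo noise from candidate comparisons.
    """

    def __init__(
        self,
        pop: Population,
        spec: GenomeSpec,
        S: int,
        horizon: int,
        params: LookaheadParams,
        rng: np.random.Generator,
        accumulation: str = "intermating",
    ) -> None:
        if S % 2 != 0 or S < 2:
            raise ValueError("S must be even and >= 2")
        if accumulation not in ("intermating", "printed"):
            raise ValueError("accumulation must be 'intermating' or 'printed'")
        self.pop = pop
        self.spec = spec
        self.S = S
        self.horizon = horizon
        self.params = params
        n = params.n_progeny_samples * params.n_reps
        if horizon == 1:
            # With one generation left the terminal offspring distribution
            # is known exactly: each progeny comes from one mate pair, one
            # ordinary meiotic gamete from each parent.  The ancestry-chain
            # approximation (built for multi-generation intermating) is not
            # needed and would let ancestry cross families within a single
            # cross, so the exact model is used instead.
            from .meiosis import _origin_paths

            pair = rng.integers(0, S // 2, size=n)
            self._m1 = _origin_paths(spec.r, n, rng)
            self._m2 = _origin_paths(spec.r, n, rng)
            L = spec.n_loci
            self._i1 = np.broadcast_to((2 * pair)[:, None], (n, L))
            self._i2 = np.broadcast_to((2 * pair + 1)[:, None], (n, L))
        else:
            # the chain's explicit r factors cover the final meiosis and its
            # mate-jump case covers the pair-hybrid (F1) stage, so the
            # accumulated term spans the random-intermating meioses between
            # them: horizon - 2 of them.  "printed" uses the published
            # exponent (the full horizon) instead.
            n_mix = horizon - 2 if accumulation == "intermating" else horizon
            if n_mix <= 0:
                R = np.zeros(max(spec.n_loci - 1, 0))
            else:
                R = accumulated_recomb(spec.r, S, n_mix)
            self._i1, self._m1 = sample_ancestry_paths(S, spec.r, R, n, rng)
            self._i2, self._m2 = sample_ancestry_paths(S, spec.r, R, n, rng)
        self._lidx = np.arange(spec.n_loci)[None, :]

    def __call__(self, ordered_selection: np.ndarray) -> float:
        """Estimate the objective for an ordered selection of S parents."""
        sel = np.asarray(ordered_selection, dtype=int)
        if len(sel) != self.S:
            raise ValueError(f"expected {self.S} ordered parents, got {len(sel)}")
        Gs = self.pop.G[:, :, sel]  # (L, 2, S)
        a1 = Gs[self._lidx, self._m1, self._i1]
        a2 = Gs[self._lidx, self._m2, self._i2]
        gebv = (a1 + a2).astype(float) @ self.spec.beta
        per_rep = gebv.reshape(self.params.n_reps, self.params.n_progeny_samples)
        return float(per_rep.max(axis=1).mean())


def estimate_flas(
    selected: Population,
    spec: GenomeSpec,
    horizon: int,
    params: LookaheadParams,
    rng: np.random.Generator,
    accumulation: str = "intermating",
) -> float:
    """Monte-Carlo estimate of the look-ahead objective for ordered parents.

    Draws K terminal progenies — at horizon 1 each is a direct cross of
    one mate pair; otherwise each is the union of two independent
    chain-sampled terminal gametes — and returns the mean over ``n_reps``
    repetitions of the maximum progeny GEBV.
    """
    S = selected.n_individuals
    if S % 2 != 0:
        raise ValueError("the number of selected parents must be even")
    ev = FlasEvaluator(selected, spec, S, horizon, params, rng, accumulation)
    return ev(np.arange(S))
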
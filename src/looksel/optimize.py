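"""Selection, mating and resource-allocation decisions.

Truncation selection handles the separable criteria (GEBV, weighted GS,
OHV).  The group-based criteria (OPV and the look-ahead objective) are
optimized by a pairwise-swap local search: starting from a random
candidate group, every (selected, unselected) exchange is scanned and the
first strictly improving move is taken, until a full scan yields no
improvement.  For the look-ahead objective the candidate is an *ordered*
list — consecutive positions are mate pairs — so swaps target positions,
and re-pairing moves (exchanging two selected positions) are scanned as
well; all candidates within one search share common random numbers.

Progeny allocation splits a generation's budget across crosses in
proportion to each mate pair's genetic diversity, so crosses with wider
predicted offspring distributions get more draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popgenome import GenomeSpec, Population, compute_gebv
from .criteria import BlockPartition, diversity
from .lookahead import FlasEvaluator, LookaheadParams

__all__ = [
    "MatingPlan",
    "truncation_select",
    "prefilter_by_gebv",
    "random_pairing",
    "swap_optimize_opv",
    "swap_optimize_las",
    "allocate_progenies",
]


@dataclass
class MatingPlan:
    """An ordered selection with consecutive mate pairs and progeny counts.

    ``selected[0]`` mates ``selected[1]``, ``selected[2]`` mates
    ``selected[3]``, and so on; ``n_progeny[p]`` is the number of
    offspring of pair *p* (empty until allocated).
    """

    selected: np.ndarray
    n_progeny: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=np.int64)
        self.n_progeny = np.asarray(self.n_progeny, dtype=np.int64)
        if len(self.selected) % 2 != 0:
            raise ValueError("selected must pair up (even length)")
        if self.n_progeny.size and self.n_progeny.size != self.n_pairs:
            raise ValueError("n_progeny must have one entry per pair")

    @property
    def n_pairs(self) -> int:
        return len(self.selected) // 2

    @property
    def pairs(self) -> list[tuple[int, int]]:
        s = self.selected
        return [(int(s[2 * p]), int(s[2 * p + 1])) for p in range(self.n_pairs)]


def truncation_select(scores: np.ndarray, S: int) -> np.ndarray:
    """Indices of the S largest scores; ties broken toward the lowest index."""
    scores = np.asarray(scores, dtype=float)
    if S > len(scores):
        raise ValueError(f"cannot select {S} from {len(scores)} individuals")
    # stable sort on (-score, index): lowest index wins ties
    order = np.lexsort((np.arange(len(scores)), -scores))
    return np.sort(order[:S])


def prefilter_by_gebv(pop: Population, spec: GenomeSpec, F: float) -> np.ndarray:
    """Drop the fraction F of individuals with the lowest GEBVs.

    Removes ``floor(F * N)`` individuals (GEBV ties: the higher index is
    removed first) and returns the survivors in their original order.
    """
    if not 0.0 <= F < 1.0:
        raise ValueError("F must be in [0, 1)")
    N = pop.n_individuals
    n_drop = int(np.floor(F * N))
    if n_drop == 0:
        return np.arange(N)
    gebv = compute_gebv(pop, spec)
    # ascending score; among ties the higher index sorts first (dropped first)
    order = np.lexsort((-np.arange(N), gebv))
    dropped = set(order[:n_drop].tolist())
    return np.array([n for n in range(N) if n not in dropped], dtype=np.int64)


def random_pairing(selected: np.ndarray, rng: np.random.Generator) -> MatingPlan:
    """Uniform random perfect matching: shuffle, then pair consecutively."""
    selected = np.asarray(selected, dtype=np.int64)
    if len(selected) % 2 != 0:
        raise ValueError("cannot pair an odd number of individuals")
    perm = rng.permutation(len(selected))
    return MatingPlan(selected=selected[perm])


def _swap_scan_set(
    objective,
    selected: list[int],
    candidates: np.ndarray,
    max_iters: int,
) -> tuple[list[int], float]:
    """First-improvement swap search over unordered sets."""
    best = objective(selected)
    for _ in range(max_iters):
        improved = False
        for pos in range(len(selected)):
            in_set = set(selected)
            for cand in candidates:
                if int(cand) in in_set:
                    continue
                trial = list(selected)
                trial[pos] = int(cand)
                val = objective(trial)
                if val > best:
                    selected, best = trial, val
                    improved = True
                    in_set = set(selected)
        if not improved:
            break
    return selected, best


def swap_optimize_opv(
    pop: Population,
    spec: GenomeSpec,
    blocks: BlockPartition,
    S: int,
    F: float,
    rng: np.random.Generator,
    max_iters: int = 100,
    n_restarts: int = 1,
) -> np.ndarray:
    """Select the group of S individuals with (near-)maximal OPV.

    Random-start pairwise-swap local search over the survivors of the
    GEBV prefilter; with several restarts the best local optimum is
    returned.  Accepted swaps strictly increase the objective, so the
    result is never worse than its initialization.
    """
    survivors = prefilter_by_gebv(pop, spec, F)
    if len(survivors) < S:
        raise ValueError(f"only {len(survivors)} survivors for S={S}")
    # precompute per-individual best-homolog block scores once
    contrib = pop.G * spec.beta[:, None, None]
    bs = np.add.reduceat(contrib, blocks.starts, axis=0)  # (B, 2, N)
    hb = bs.max(axis=1)  # (B, N)

    def objective(subset: list[int]) -> float:
        return 2.0 * float(hb[:, subset].max(axis=1).sum())

    best_set: list[int] | None = None
    best_val = -np.inf
    for _ in range(max(1, n_restarts)):
        start = list(rng.choice(survivors, size=S, replace=False))
        sel, val = _swap_scan_set(objective, start, survivors, max_iters)
        if val > best_val:
            best_set, best_val = sel, val
    assert best_set is not None
    return np.sort(np.asarray(best_set, dtype=np.int64))


def swap_optimize_las(
    pop: Population,
    spec: GenomeSpec,
    S: int,
    horizon: int,
    params: LookaheadParams,
    rng: np.random.Generator,
    F: float = 0.0,
    max_iters: int = 100,
    n_restarts: int = 1,
    tol: float = 0.0,
    scan_repairing: bool = True,
    warm_start: bool = True,
) -> MatingPlan:
    """Optimize the ordered look-ahead selection (positions define mates).

    Swap moves replace the individual at one position with an unselected
    survivor; re-pairing moves exchange two selected positions belonging
    to different pairs.  All evaluations within the search share the same
    frozen chain randomness, and a move is accepted only if the common-
    random-number objective improves by more than ``tol``.  With
    ``warm_start`` one start is the top-S GEBV group, so the result is
    never worse than truncation selection under the frozen randomness;
    remaining restarts are random.  Returns the ordered selection without
    progeny counts.
    """
    if S % 2 != 0:
        raise ValueError("S must be even")
    survivors = prefilter_by_gebv(pop, spec, F)
    if len(survivors) < S:
        raise ValueError(f"only {len(survivors)} survivors for S={S}")
    evaluator = FlasEvaluator(pop, spec, S, horizon, params, rng)

    starts: list[np.ndarray] = []
    if warm_start:
        gebv = compute_gebv(pop, spec)[survivors]
        starts.append(survivors[truncation_select(gebv, S)].astype(np.int64))
    while len(starts) < max(1, n_restarts):
        starts.append(rng.choice(survivors, size=S, replace=False).astype(np.int64))

    best_sel: np.ndarray | None = None
    best_val = -np.inf
    for sel in starts:
        val = evaluator(sel)
        for _ in range(max_iters):
            improved = False
            in_set = set(sel.tolist())
            for pos in range(S):
                for cand in survivors:
                    if int(cand) in in_set:
                        continue
                    trial = sel.copy()
                    trial[pos] = cand
                    tv = evaluator(trial)
                    if tv > val + tol:
                        sel, val = trial, tv
                        improved = True
                        in_set = set(sel.tolist())
            if scan_repairing:
                for p in range(S):
                    for q in range(p + 1, S):
                        if p // 2 == q // 2:
                            continue  # same pair: pairing unchanged
                        trial = sel.copy()
                        trial[p], trial[q] = trial[q], trial[p]
                        tv = evaluator(trial)
                        if tv > val + tol:
                            sel, val = trial, tv
                            improved = True
            if not improved:
                break
        if val > best_val:
            best_sel, best_val = sel, val
    assert best_sel is not None
    return MatingPlan(selected=best_sel)


def allocate_progenies(
    plan: MatingPlan,
    pop: Population,
    spec: GenomeSpec,
    total: int,
) -> MatingPlan:
    """Allocate a progeny budget across crosses proportionally to diversity.

    Each pair's quota is ``total * d_p / sum(d)`` where ``d_p`` is the
    pair's genetic diversity (equal split if every diversity is zero),
    rounded by largest remainder; pairs rounded to zero then receive one
    progeny taken from the currently largest allocation.  The returned
    counts are positive and sum to ``total``.
    """
    n_pairs = plan.n_pairs
    if total < n_pairs:
        raise ValueError(f"budget {total} cannot give every one of {n_pairs} pairs a progeny")
    d = np.array(
        [diversity(pop, spec, subset=[i, j]) for i, j in plan.pairs], dtype=float
    )
    if d.sum() == 0.0:
        raw = np.full(n_pairs, total / n_pairs)
    else:
        raw = total * d / d.sum()
    counts = np.floor(raw).astype(np.int64)
    remainder = total - counts.sum()
    if remainder > 0:
        frac = raw - np.floor(raw)
        # largest remainders first; ties toward the lower pair index
        order = np.lexsort((np.arange(n_pairs), -frac))
        counts[order[:remainder]] += 1
    while (counts == 0).any():
        counts[int(np.argmax(counts))] -= 1
        counts[int(np.argmin(counts))] += 1
    return MatingPlan(selected=plan.selected.copy(), n_progeny=counts)
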
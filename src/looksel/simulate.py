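"""Multi-generation breeding-campaign simulation and method comparison.

One campaign iterates a select → mate → reproduce cycle until a deadline
generation T.  Each generation, the configured selection method picks S
parents from the population, pairs them into ``S/2`` crosses, and the
crosses produce a fixed total number of progenies that form the next
generation.  Per-generation population statistics (GEBV summary, genetic
diversity, selection limits, cumulative gain) are recorded in a
:class:`Trajectory`.

``compare_methods`` runs several methods head-to-head: within each
repetition every method starts from the same founder draw, so the
comparison is paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popgenome import (
    GenomeSpec,
    Population,
    compute_gebv,
    selection_limits,
)
from .criteria import BlockPartition, compute_ohv, diversity, weighted_gebv
from .meiosis import cross
from .lookahead import LookaheadParams
from .optimize import (
    MatingPlan,
    allocate_progenies,
    prefilter_by_gebv,
    random_pairing,
    swap_optimize_las,
    swap_optimize_opv,
    truncation_select,
)

logger = logging.getLogger(__name__)

__all__ = ["CampaignConfig", "Trajectory", "advance_generation", "run_program",
           "compare_methods", "ComparisonResult", "sweep_deadlines"]

METHODS = ("cgs", "wgs", "ohv", "opv", "las")

# per-method defaults for haplotype blocks per chromosome and the fraction
# of lowest-GEBV individuals removed before optimizing the selection
_DEFAULT_B = {"ohv": 12, "opv": 1}
_DEFAULT_F = {"ohv": 0.7, "opv": 0.4}


@dataclass
class CampaignConfig:
    """Settings of one breeding campaign.

    Defaults correspond to the standard comparison design: population size
    ``N = 200``, ``S = 20`` parents forming ``nc = 10`` crosses, 200
    progenies per generation, deadline ``T = 10``; OHV uses 12 blocks per
    chromosome with 70% prefiltering, OPV one block per chromosome with
    40% prefiltering.
    """

    method: str = "cgs"
    T: int = 10
    N: int = 200
    S: int = 20
    total_progeny: int = 200
    B: int | None = None
    F: float | None = None
    las: LookaheadParams = field(default_factory=LookaheadParams)
    las_F: float = 0.0
    las_restarts: int = 1
    las_max_iters: int = 100
    opv_restarts: int = 1
    opv_max_iters: int = 100
    allow_selfing: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.S % 2 != 0 or self.S < 2:
            raise ValueError("S must be even and >= 2")
        if self.total_progeny < self.n_crosses:
            raise ValueError("total progeny must cover at least one per cross")
        if self.B is None:
            self.B = _DEFAULT_B.get(self.method, 1)
        if self.F is None:
            self.F = _DEFAULT_F.get(self.method, 0.0)

    @property
    def n_crosses(self) -> int:
        return self.S // 2


@dataclass
class Trajectory:
    """Per-generation population statistics of one campaign."""

    frame: pd.DataFrame  # columns: generation, min, mean, max, diversity,
    #                      lower, upper, gain

    @property
    def terminal(self) -> pd.Series:
        return self.frame.iloc[-1]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _stats_row(pop: Population, spec: GenomeSpec, t: int, mean0: float | None) -> dict:
    gebv = compute_gebv(pop, spec)
    lower, upper = selection_limits(pop, spec)
    mean = float(gebv.mean())
    return {
        "generation": t,
        "min": float(gebv.min()),
        "mean": mean,
        "max": float(gebv.max()),
        "diversity": diversity(pop, spec),
        "lower": lower,
        "upper": upper,
        "gain": 0.0 if mean0 is None else mean - mean0,
    }


def _equal_counts(total: int, n_pairs: int) -> np.ndarray:
    base, rem = divmod(total, n_pairs)
    counts = np.full(n_pairs, base, dtype=np.int64)
    counts[:rem] += 1
    return counts


def _make_plan(
    pop: Population,
    spec: GenomeSpec,
    config: CampaignConfig,
    t: int,
    rng: np.random.Generator,
) -> MatingPlan:
    """Method-dispatched selection and mating for generation t."""
    method = config.method
    if method in ("cgs", "wgs", "ohv"):
        if method == "cgs":
            survivors = np.arange(pop.n_individuals)
            scores = compute_gebv(pop, spec)
        elif method == "wgs":
            survivors = np.arange(pop.n_individuals)
            scores = weighted_gebv(pop, spec)
        else:
            survivors = prefilter_by_gebv(pop, spec, config.F)
            blocks = BlockPartition.equal_count(spec, config.B)
            scores = compute_ohv(pop.subset(survivors), spec, blocks)
        top = truncation_select(scores, config.S)
        selected = survivors[top]
        plan = random_pairing(selected, rng)
    elif method == "opv":
        blocks = BlockPartition.equal_count(spec, config.B)
        selected = swap_optimize_opv(
            pop, spec, blocks, config.S, config.F, rng,
            max_iters=config.opv_max_iters, n_restarts=config.opv_restarts,
        )
        plan = random_pairing(selected, rng)
    elif method == "las":
        horizon = config.T - t
        plan = swap_optimize_las(
            pop, spec, config.S, horizon, config.las, rng,
            F=config.las_F, max_iters=config.las_max_iters,
            n_restarts=config.las_restarts,
        )
    else:  # pragma: no cover
        raise ValueError(method)
    if method == "las":
        plan = allocate_progenies(plan, pop, spec, config.total_progeny)
    else:
        plan = MatingPlan(
            selected=plan.selected,
            n_progeny=_equal_counts(config.total_progeny, plan.n_pairs),
        )
    return plan


def advance_generation(
    pop: Population,
    spec: GenomeSpec,
    config: CampaignConfig,
    t: int,
    seed_seq: np.random.SeedSequence,
) -> Population:
    """Run one select → mate → reproduce cycle; returns the progeny population.

    ``t`` is the current generation number (0-based), so the look-ahead
    horizon is ``T - t``.  Random streams are spawned per cross from
    ``seed_seq`` so that one cross's progeny count never perturbs
    another's draws.
    """
    if t >= config.T:
        raise ValueError(f"generation {t} is at or past the deadline T={config.T}")
    sel_ss, *cross_ss = seed_seq.spawn(1 + config.n_crosses)
    plan = _make_plan(pop, spec, config, t, np.random.default_rng(sel_ss))
    offspring = []
    for p, (i, j) in enumerate(plan.pairs):
        offspring.append(
            cross(pop, i, j, int(plan.n_progeny[p]), spec,
                  np.random.default_rng(cross_ss[p]))
        )
    G = np.concatenate([o.G for o in offspring], axis=2)
    ids = [f"g{t + 1}-{k}" for k in range(G.shape[2])]
    return Population(G, ids)


def run_program(
    founders: Population,
    spec: GenomeSpec,
    config: CampaignConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> Trajectory:
    """Run a whole campaign from founders to the deadline generation.

    Generation-0 statistics are computed on the founders before any
    selection; the terminal generation is the population produced by the
    last reproduction step.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        config.seed if seed is None else seed
    )
    gen_seeds = ss.spawn(config.T) if config.T > 0 else []
    rows = [_stats_row(founders, spec, 0, None)]
    mean0 = rows[0]["mean"]
    pop = founders
    for t in range(config.T):
        pop = advance_generation(pop, spec, config, t, gen_seeds[t])
        rows.append(_stats_row(pop, spec, t + 1, mean0))
        logger.info(
            "%s generation %d/%d: mean GEBV %.3f (gain %.3f)",
            config.method, t + 1, config.T, rows[-1]["mean"], rows[-1]["gain"],
        )
    return Trajectory(frame=pd.DataFrame(rows))


@dataclass
class ComparisonResult:
    """Tidy per-(method, repetition, generation) statistics plus summaries."""

    frame: pd.DataFrame  # columns: method, rep, generation, min, mean, max,
    #                      diversity, lower, upper, gain

    def gain_trajectories(self) -> pd.DataFrame:
        """Mean cumulative gain per method and generation."""
        return (
            self.frame.groupby(["method", "generation"])["gain"]
            .mean()
            .unstack("method")
        )

    def diversity_trajectories(self) -> pd.DataFrame:
        return (
            self.frame.groupby(["method", "generation"])["diversity"]
            .mean()
            .unstack("method")
        )

    def terminal_stats(self) -> pd.DataFrame:
        """Terminal-generation min/mean/max, mean ± SD across repetitions."""
        term = self.frame[self.frame["generation"] == self.frame["generation"].max()]
        out = term.groupby("method")[["min", "mean", "max"]].agg(
            ["mean", lambda s: s.std(ddof=0)]
        )
        out.columns = [
            f"{stat}_{'std' if agg == '<lambda_0>' else agg}" for stat, agg in out.columns
        ]
        return out

    def terminal_values(self, column: str = "max") -> pd.DataFrame:
        """Per-repetition terminal values (one column per method), CDF-ready."""
        term = self.frame[self.frame["generation"] == self.frame["generation"].max()]
        return term.pivot(index="rep", columns="method", values=column)


def _draw_founders(
    founders: Population, spec: GenomeSpec, N: int, rng: np.random.Generator
) -> Population:
    if founders.n_individuals > N:
        idx = np.sort(rng.choice(founders.n_individuals, size=N, replace=False))
        return founders.subset(idx)
    return founders


def compare_methods(
    founders: Population,
    spec: GenomeSpec,
    configs: Mapping[str, CampaignConfig],
    reps: int = 1,
    seed: int | None = None,
) -> ComparisonResult:
    """Head-to-head comparison of selection methods over shared founders.

    For each repetition one founder draw (a random subset of size N when
    the founder pool is larger) is shared by every method, making the
    across-method comparison paired; methods then evolve under
    independent random streams.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    Ns = {c.N for c in configs.values()}
    if len(Ns) != 1:
        raise ValueError("all configs must share the same population size N")
    N = Ns.pop()
    root = np.random.SeedSequence(seed)
    rows = []
    for rep in range(reps):
        founder_ss, *method_ss = root.spawn(1 + len(configs))
        shared = _draw_founders(founders, spec, N, np.random.default_rng(founder_ss))
        for (name, config), mss in zip(configs.items(), method_ss):
            traj = run_program(shared, spec, config, seed=mss)
            f = traj.frame.copy()
            f.insert(0, "rep", rep)
            f.insert(0, "method", name)
            rows.append(f)
        logger.info("repetition %d/%d done", rep + 1, reps)
    return ComparisonResult(frame=pd.concat(rows, ignore_index=True))


def sweep_deadlines(
    founders: Population,
    spec: GenomeSpec,
    base_config: CampaignConfig,
    deadlines: Sequence[int],
    reps: int = 1,
    seed: int | None = None,
) -> ComparisonResult:
    """Run one method across several deadlines T, sharing founders per rep.

    Results are labelled ``<method>@T<deadline>``.
    """
    configs = {
        f"{base_config.method}@T{T}": replace(base_config, T=int(T))
        for T in deadlines
    }
    return compare_methods(founders, spec, configs, reps=reps, seed=seed)
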
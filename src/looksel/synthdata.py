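"""Synthetic founder populations, genetic maps and marker effects.

The generator emulates the structure of a diversity panel of inbred lines
genotyped at many biallelic SNPs: phased 0/1 haplotypes over several
chromosomes, marker positions on a centimorgan map (converted to
recombination frequencies with the Haldane function), and sparse
real-valued additive effects.  Effects are rescaled so that the founder
population's maximum genetic potential (upper selection limit) equals 100,
which puts every campaign on a common 0–100 gain scale.

Founders default to fully homozygous ("inbred") individuals; linkage
disequilibrium beyond inbreeding is not modelled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .popgenome import (
    GenomeSpec,
    Population,
    map_to_recomb,
    scale_to_potential,
    write_effects_csv,
    write_haplotypes_csv,
    write_map_csv,
)

__all__ = ["ScenarioSpec", "synth_map", "synth_effects", "synth_population",
           "make_scenario", "write_scenario"]


@dataclass
class ScenarioSpec:
    """Parameters of a synthetic breeding scenario.

    Defaults give a small desk-scale scenario: 50 inbred founders, 300
    loci on 5 chromosomes of 150 cM each, 20% of loci carrying an effect
    drawn from a standard normal (half positive, half negative in
    expectation), major-allele frequencies uniform on (0.5, 0.95).
    """

    N: int = 50
    L: int = 300
    n_chrom: int = 5
    chrom_length_cM: float = 150.0
    maf_low: float = 0.5
    maf_high: float = 0.95
    effect_fraction: float = 0.2
    effect_scale: float = 1.0
    effect_positive_fraction: float = 0.5
    inbred: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must be in (0, 1]")
        if not (0.0 < self.maf_low <= self.maf_high <= 1.0):
            raise ValueError("major-allele frequency bounds must satisfy 0 < low <= high <= 1")
        if self.n_chrom < 1 or self.L < self.n_chrom:
            raise ValueError("need at least one locus per chromosome")


def _loci_per_chrom(spec: ScenarioSpec) -> list[int]:
    base, rem = divmod(spec.L, spec.n_chrom)
    return [base + (1 if c < rem else 0) for c in range(spec.n_chrom)]


def synth_map(spec: ScenarioSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place loci uniformly at random along each chromosome; returns
    ``(loci, chrom, pos_cM)`` genome-wide, sorted within chromosomes."""
    loci, chroms, pos = [], [], []
    width = len(str(spec.n_chrom))  # zero-pad so lexical chromosome order = numeric
    for c, n in enumerate(_loci_per_chrom(spec)):
        name = f"chr{c + 1:0{width}d}"
        p = np.sort(rng.uniform(0.0, spec.chrom_length_cM, size=n))
        for k in range(n):
            loci.append(f"{name}_m{k}")
            chroms.append(name)
        pos.extend(p.tolist())
    return (
        np.asarray(loci, dtype=object),
        np.asarray(chroms, dtype=object),
        np.asarray(pos, dtype=float),
    )


def synth_effects(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """Sparse additive effects: each locus carries a nonzero effect with
    probability ``effect_fraction``; magnitudes are half-normal with the
    configured scale and signs follow ``effect_positive_fraction``."""
    nonzero = rng.random(spec.L) < spec.effect_fraction
    mag = np.abs(rng.normal(0.0, spec.effect_scale, size=spec.L))
    sign = np.where(rng.random(spec.L) < spec.effect_positive_fraction, 1.0, -1.0)
    beta = np.where(nonzero, sign * mag, 0.0)
    if spec.effect_scale == 0.0:
        beta = np.zeros(spec.L)
    return beta


def synth_population(spec: ScenarioSpec, rng: np.random.Generator) -> Population:
    """Draw founder haplotypes locus-independently at the configured
    major-allele frequencies; in inbred mode one haplotype per individual
    is copied to both homologs (fully homozygous founders)."""
    freq = rng.uniform(spec.maf_low, spec.maf_high, size=spec.L)
    if spec.inbred:
        hap = (rng.random((spec.L, 1, spec.N)) < freq[:, None, None])
        G = np.repeat(hap, 2, axis=1)
    else:
        G = rng.random((spec.L, 2, spec.N)) < freq[:, None, None]
    ids = [f"founder{n}" for n in range(spec.N)]
    return Population(G.astype(np.int8), ids)


def make_scenario(
    spec: ScenarioSpec | None = None,
    rng: np.random.Generator | None = None,
    target_potential: float = 100.0,
) -> tuple[Population, GenomeSpec]:
    """Generate a complete scenario with effects scaled to the target potential.

    Resamples effects in the rare event that the unscaled upper selection
    limit is exactly zero (nothing to scale).
    """
    spec = spec or ScenarioSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    loci, chroms, pos = synth_map(spec, rng)
    pop = synth_population(spec, rng)
    for _ in range(100):
        beta = synth_effects(spec, rng)
        genome = GenomeSpec(
            loci=loci, chrom=chroms, pos_cM=pos, beta=beta,
            r=map_to_recomb(chroms, pos, "haldane"),
        )
        try:
            return pop, scale_to_potential(pop, genome, target_potential)
        except ValueError:
            continue
    raise RuntimeError("could not draw effects with a nonzero upper selection limit")


def write_scenario(
    pop: Population,
    genome: GenomeSpec,
    out_dir: str | Path,
    scenario: ScenarioSpec | None = None,
) -> dict[str, str]:
    """Write the scenario in the standard CSV dialects plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "haplotypes": str(out / "haplotypes.csv"),
        "map": str(out / "map.csv"),
        "effects": str(out / "effects.csv"),
        "manifest": str(out / "manifest.json"),
    }
    write_haplotypes_csv(pop, genome, paths["haplotypes"])
    write_map_csv(genome, paths["map"])
    write_effects_csv(genome, paths["effects"])
    manifest = {
        "n_individuals": pop.n_individuals,
        "n_loci": genome.n_loci,
        "scenario": asdict(scenario) if scenario is not None else None,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
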
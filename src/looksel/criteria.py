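"""Selection criteria: GEBV, weighted GS, OHV, OPV, and genetic diversity.

All criteria are additive in marker effects.  OHV and OPV work on
haplotype blocks — contiguous runs of loci within a chromosome that are
treated as non-recombining units — and score, respectively, the best
doubled haploid derivable from one individual and the best genotype
assemblable from a group of individuals given unlimited generations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .popgenome import GenomeSpec, Population

__all__ = [
    "BlockPartition",
    "weighted_gebv",
    "compute_ohv",
    "compute_opv",
    "diversity",
    "pair_diversity",
]


@dataclass(frozen=True)
class BlockPartition:
    """Partition of loci into contiguous haplotype blocks.

    ``block_ids[l]`` is the genome-wide block index of locus *l*; blocks are
    contiguous, never span chromosomes, and within a chromosome have
    near-equal locus counts (the remainder goes to the first blocks).
    """

    block_ids: np.ndarray
    n_blocks: int

    @classmethod
    def equal_count(cls, spec: GenomeSpec, blocks_per_chrom: int) -> "BlockPartition":
        """Split each chromosome into ``blocks_per_chrom`` contiguous blocks.

        A chromosome with fewer loci than requested blocks gets one locus
        per block.
        """
        if blocks_per_chrom < 1:
            raise ValueError("blocks_per_chrom must be >= 1")
        ids = np.empty(spec.n_loci, dtype=np.int64)
        next_block = 0
        for ch in dict.fromkeys(spec.chrom):  # preserves chromosome order
            locus_idx = np.flatnonzero(spec.chrom == ch)
            n = len(locus_idx)
            B = min(blocks_per_chrom, n)
            base, rem = divmod(n, B)
            sizes = [base + (1 if b < rem else 0) for b in range(B)]
            start = 0
            for size in sizes:
                ids[locus_idx[start : start + size]] = next_block
                next_block += 1
                start += size
        return cls(block_ids=ids, n_blocks=next_block)

    @property
    def starts(self) -> np.ndarray:
        """First locus index of each block (blocks are contiguous runs)."""
        return np.flatnonzero(np.diff(self.block_ids, prepend=self.block_ids[0] - 1))


def _block_scores(pop: Population, spec: GenomeSpec, blocks: BlockPartition) -> np.ndarray:
    """Per-block haplotype scores, shape (n_blocks, 2, N)."""
    contrib = pop.G * spec.beta[:, None, None]
    return np.add.reduceat(contrib, blocks.starts, axis=0)


def weighted_gebv(
    pop: Population, spec: GenomeSpec, favorable: str = "major"
) -> np.ndarray:
    """Weighted genomic selection score.

    Each effect is divided by ``max(w_l, 1/N)`` where ``w_l`` is the
    frequency of the favorable allele over all ``2N`` haplotypes, boosting
    rare favorable alleles.  With ``favorable="major"`` the favorable
    allele is the coded-1 major allele regardless of the sign of the
    effect; ``favorable="sign"`` counts the coded-1 allele where
    ``beta >= 0`` and the coded-0 allele where ``beta < 0``.
    """
    N = pop.n_individuals
    freq1 = pop.G.mean(axis=(1, 2))
    if favorable == "major":
        w = freq1
    elif favorable == "sign":
        w = np.where(spec.beta >= 0, freq1, 1.0 - freq1)
    else:
        raise ValueError("favorable must be 'major' or 'sign'")
    scaled = spec.beta / np.maximum(w, 1.0 / N)
    counts = pop.G.sum(axis=1)
    return counts.T.astype(float) @ scaled


def compute_ohv(
    pop: Population, spec: GenomeSpec, blocks: BlockPartition
) -> np.ndarray:
    """Optimal haploid values: GEBV of each individual's best doubled haploid.

    ``OHV[n] = 2 sum_b max_m sum_{l in b} G[l,m,n] beta[l]``.
    """
    bs = _block_scores(pop, spec, blocks)
    return 2.0 * bs.max(axis=1).sum(axis=0)


def compute_opv(
    pop: Population,
    spec: GenomeSpec,
    blocks: BlockPartition,
    subset: Sequence[int] | None = None,
) -> float:
    """Optimal population value of a group of individuals.

    The GEBV of the best genotype assemblable by combining, block by
    block, the best haplotype present anywhere in the group:
    ``OPV = 2 sum_b max_{n in subset, m} sum_{l in b} G[l,m,n] beta[l]``.
    """
    bs = _block_scores(pop, spec, blocks)
    if subset is not None:
        idx = np.asarray(subset, dtype=int)
        if idx.size == 0:
            raise ValueError("subset must be non-empty")
        bs = bs[:, :, idx]
    return 2.0 * float(bs.max(axis=(1, 2)).sum())


def diversity(
    pop: Population,
    spec: GenomeSpec,
    subset: Sequence[int] | None = None,
    blocks: BlockPartition | None = None,
) -> float:
    """Genetic diversity: aggregated per-locus range of effect contributions.

    For each locus, the range (max minus min over the subset's haplotypes)
    of ``G beta`` is accumulated; a locus contributes ``|beta|`` when both
    alleles are present in the subset and 0 when it is fixed.  With a
    block partition supplied, the range is taken over per-block haplotype
    scores instead (a coarser, block-wise variant).
    """
    G = pop.G
    if subset is not None:
        idx = np.asarray(subset, dtype=int)
        if idx.size == 0:
            raise ValueError("subset must be non-empty")
        G = G[:, :, idx]
    if blocks is None:
        any1 = G.any(axis=(1, 2))
        any0 = (G == 0).any(axis=(1, 2))
        return float(np.abs(spec.beta[any1 & any0]).sum())
    contrib = G * spec.beta[:, None, None]
    bs = np.add.reduceat(contrib, blocks.starts, axis=0)
    return float((bs.max(axis=(1, 2)) - bs.min(axis=(1, 2))).sum())


def pair_diversity(pop: Population, spec: GenomeSpec, i: int, j: int) -> float:
    """Diversity of a mate pair, used for progeny allocation."""
    return diversity(pop, spec, subset=[i, j])
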
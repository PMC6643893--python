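"""Meiosis and progeny construction.

A gamete is formed by walking the genome locus by locus: the first locus
copies either parental homolog with probability 1/2, and at each interval
the copied homolog switches with the interval's recombination frequency
``r[l]`` (a two-state Markov chain, i.e. crossovers without interference).
A progeny pairs one gamete from each parent.  There is no mutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgenome import GenomeSpec, Population

__all__ = ["Gamete", "sample_gamete", "sample_gametes", "cross"]


@dataclass
class Gamete:
    """A haploid genome with the homolog-of-origin path kept for diagnostics."""

    g: np.ndarray        # (L,) alleles in {0,1}
    origin: np.ndarray   # (L,) parental homolog index in {0,1}


def _origin_paths(r: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample *n* homolog-of-origin paths of length ``len(r) + 1``.

    Vectorized over gametes: the path is the parity of an initial fair coin
    plus the running count of interval switch events, each Bernoulli(r[l]).
    """
    L = len(r) + 1
    start = rng.integers(0, 2, size=n, dtype=np.int8)
    if L == 1:
        return start[:, None]
    switches = rng.random(size=(n, L - 1)) < r[None, :]
    path = np.empty((n, L), dtype=np.int8)
    path[:, 0] = start
    path[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1, dtype=np.int64)) % 2
    return path


def sample_gamete(
    parent: np.ndarray, r: np.ndarray, rng: np.random.Generator
) -> Gamete:
    """Draw one gamete from a parent given as its two haplotypes ``(L, 2)``.

    Accepts either an ``(L, 2)`` haplotype matrix or a population slice
    ``G[:, :, n]`` of shape ``(L, 2)``.
    """
    parent = np.asarray(parent)
    if parent.ndim != 2 or parent.shape[1] != 2:
        raise ValueError("parent must have shape (L, 2)")
    if len(r) != parent.shape[0] - 1:
        raise ValueError("r must have length L - 1")
    path = _origin_paths(np.asarray(r, dtype=float), 1, rng)[0]
    alleles = parent[np.arange(parent.shape[0]), path]
    return Gamete(g=alleles.astype(np.int8), origin=path)


def sample_gametes(
    parent: np.ndarray, r: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw *n* gametes from one parent; returns an ``(n, L)`` allele array."""
    paths = _origin_paths(np.asarray(r, dtype=float), n, rng)
    L = parent.shape[0]
    return parent[np.arange(L)[None, :], paths].astype(np.int8)


def cross(
    pop: Population,
    i: int,
    j: int,
    n_progeny: int,
    spec: GenomeSpec,
    rng: np.random.Generator,
) -> Population:
    """Cross individuals *i* and *j*, producing ``n_progeny`` offspring.

    ``i == j`` is selfing, in which case the two gametes are still drawn
    independently.  Each progeny pairs one independent gamete from each
    parent.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    gam_i = sample_gametes(pop.G[:, :, i], spec.r, n_progeny, rng)
    gam_j = sample_gametes(pop.G[:, :, j], spec.r, n_progeny, rng)
    G = np.stack([gam_i.T, gam_j.T], axis=1)  # (L, 2, n_progeny)
    ids = [f"{pop.ids[i]}x{pop.ids[j]}-{k}" for k in range(n_progeny)]
    return Population(G, ids)
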
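import numpy as np
import pytest

from looksel import GenomeSpec, Population


def make_spec(beta, chrom=None, pos=None, r=None):
    """Small GenomeSpec helper: single chromosome, unit spacing by default."""
    L = len(beta)
    chrom = np.asarray(chrom if chrom is not None else ["1"] * L, dtype=object)
    pos = np.asarray(pos if pos is not None else np.arange(L, dtype=float))
    if r is None:
        boundary = chrom[:-1] != chrom[1:]
        r = np.where(boundary, 0.5, 0.1)[: L - 1] if L > 1 else np.zeros(0)
    return GenomeSpec(
        loci=np.array([f"m{i}" for i in range(L)], dtype=object),
        chrom=chrom,
        pos_cM=pos,
        beta=np.asarray(beta, dtype=float),
        r=np.asarray(r, dtype=float),
    )


def pop_from_haplotypes(*individuals):
    """Build a Population from per-individual (hap1, hap2) tuples."""
    G = np.stack(
        [np.stack([np.asarray(h1), np.asarray(h2)], axis=0) for h1, h2 in individuals],
        axis=2,
    ).transpose(1, 0, 2)
    return Population(G.astype(np.int8))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_population(rng):
    """A 20-individual, 12-locus outbred population with signed effects."""
    L, N = 12, 20
    G = (rng.random((L, 2, N)) < 0.5).astype(np.int8)
    beta = rng.normal(0, 1, size=L)
    return Population(G), make_spec(beta)
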
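"""Phased populations, genetic maps and marker effects.

The central objects are :class:`Population` — a phased, biallelic 0/1
genotype tensor ``G[l, m, n]`` over loci *l*, homologs *m* and individuals
*n* — and :class:`GenomeSpec`, which carries the locus order, chromosome
assignment, map positions in centimorgans, additive effects of the major
(coded-1) allele, and the vector ``r`` of recombination frequencies between
adjacent loci.

Alleles are coded so that 1 is the major allele in the founder population
and the per-locus effect ``beta`` is the effect of that allele (the minor
allele contributes 0).  Loci are kept in a single genome-wide order,
chromosome-major and position-minor, with ``r[l]`` referring to the
interval between locus ``l`` and locus ``l + 1``; intervals spanning a
chromosome boundary carry ``r = 0.5`` (free recombination).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Population",
    "GenomeSpec",
    "load_population",
    "map_to_recomb",
    "compute_gebv",
    "selection_limits",
    "scale_to_potential",
    "read_haplotypes_csv",
    "write_haplotypes_csv",
    "read_map_csv",
    "write_map_csv",
    "read_effects_csv",
    "write_effects_csv",
]

_HAP_SUFFIXES = ("_h1", "_h2")


class GenotypeDataError(ValueError):
    """Raised for malformed or unsupported genotype input."""


@dataclass
class GenomeSpec:
    """Marker metadata shared by every individual of a population.

    Parameters
    ----------
    loci : array of str
        Marker identifiers, genome-wide order (chromosome-major).
    chrom : array of str
        Chromosome identifier per locus.
    pos_cM : array of float
        Genetic-map position per locus, centimorgan, non-decreasing
        within each chromosome.
    beta : array of float
        Additive effect of the major (coded-1) allele, trait units.
        Signed values are supported.
    r : array of float, length ``L - 1``
        Recombination frequency between adjacent loci, in ``[0, 0.5]``;
        exactly 0.5 at chromosome boundaries.
    """

    loci: np.ndarray
    chrom: np.ndarray
    pos_cM: np.ndarray
    beta: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.loci = np.asarray(self.loci, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_cM = np.asarray(self.pos_cM, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        L = len(self.loci)
        if not (len(self.chrom) == len(self.pos_cM) == len(self.beta) == L):
            raise ValueError("loci, chrom, pos_cM and beta must have equal length")
        if len(self.r) != max(L - 1, 0):
            raise ValueError(f"r must have length L-1 = {L - 1}, got {len(self.r)}")
        if L > 1:
            if np.any(self.r < 0) or np.any(self.r > 0.5):
                raise ValueError("recombination frequencies must lie in [0, 0.5]")
            boundary = self.chrom[:-1] != self.chrom[1:]
            if not np.all(self.r[boundary] == 0.5):
                raise ValueError("chromosome-boundary entries of r must equal 0.5")
            same = ~boundary
            d = np.diff(self.pos_cM)
            if np.any(d[same] < 0):
                raise ValueError("pos_cM must be non-decreasing within a chromosome")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def chrom_boundaries(self) -> np.ndarray:
        """Boolean mask over the L-1 intervals; True where chromosomes change."""
        return self.chrom[:-1] != self.chrom[1:]

    def with_beta(self, beta: np.ndarray) -> "GenomeSpec":
        return replace(self, beta=np.asarray(beta, dtype=float))


@dataclass
class Population:
    """A phased diploid population.

    ``G`` has shape ``(L, 2, N)`` with entries in ``{0, 1}``; ``G[l, m, n]``
    is the allele at locus *l* on homolog *m* of individual *n*
    (1 = major allele).
    """

    G: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.G = np.ascontiguousarray(self.G, dtype=np.int8)
        if self.G.ndim != 3 or self.G.shape[1] != 2:
            raise ValueError("G must have shape (L, 2, N)")
        if self.G.size and (self.G.min() < 0 or self.G.max() > 1):
            raise ValueError("G entries must be 0 or 1")
        if not self.ids:
            self.ids = [f"ind{n}" for n in range(self.G.shape[2])]
        if len(self.ids) != self.G.shape[2]:
            raise ValueError("ids length must equal N")

    @property
    def n_loci(self) -> int:
        return self.G.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.G.shape[2]

    def subset(self, indices: Sequence[int]) -> "Population":
        idx = np.asarray(indices, dtype=int)
        return Population(self.G[:, :, idx], [self.ids[i] for i in idx])


def map_to_recomb(
    chrom: np.ndarray,
    pos_cM: np.ndarray,
    mapping_function: str = "haldane",
) -> np.ndarray:
    """Convert adjacent map distances to recombination frequencies.

    ``haldane`` assumes no crossover interference,
    ``r = 0.5 (1 - exp(-2 d))`` with *d* in Morgans; ``kosambi`` is
    ``r = 0.5 tanh(2 d)``; ``direct`` takes the position column itself as
    the recombination frequency between a locus and its predecessor on the
    same chromosome (the first locus of each chromosome is ignored).
    Chromosome-boundary intervals are set to 0.5 and all values are clamped
    to ``[0, 0.5]``.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos_cM, dtype=float)
    L = len(pos)
    if L < 2:
        return np.zeros(0)
    boundary = chrom[:-1] != chrom[1:]
    if mapping_function == "direct":
        r = pos[1:].copy()
        bad = (~boundary) & ((r < 0) | (r > 0.5))
        if np.any(bad):
            raise ValueError("direct recombination frequencies must lie in [0, 0.5]")
    else:
        d = np.diff(pos)
        if np.any(d[~boundary] < 0):
            first = int(np.flatnonzero((~boundary) & (d < 0))[0])
            raise ValueError(
                f"negative map distance between adjacent loci {first} and {first + 1}"
            )
        morgans = d / 100.0
        if mapping_function == "haldane":
            r = 0.5 * (1.0 - np.exp(-2.0 * morgans))
        elif mapping_function == "kosambi":
            r = 0.5 * np.tanh(2.0 * morgans)
        else:
            raise ValueError(f"unknown mapping function: {mapping_function!r}")
    r[boundary] = 0.5
    return np.clip(r, 0.0, 0.5)


def compute_gebv(pop: Population, spec: GenomeSpec) -> np.ndarray:
    """Genomic estimated breeding values: GEBV[n] = sum_l sum_m G[l,m,n] beta[l]."""
    if pop.n_loci != spec.n_loci:
        raise ValueError("population and genome spec disagree on locus count")
    counts = pop.G.sum(axis=1)  # (L, N) allele dosage in {0, 1, 2}
    return counts.T.astype(float) @ spec.beta


def selection_limits(pop: Population, spec: GenomeSpec) -> tuple[float, float]:
    """Lower and upper selection limits of a population.

    The upper limit is the GEBV of the best genotype assemblable from
    alleles currently present in the population (twice the per-locus best
    haploid contribution); the lower limit is its worst counterpart.  For
    a locus the attainable haploid contributions are ``beta`` (if any
    haplotype carries the major allele) and 0 (if any carries the minor).
    """
    if pop.n_individuals == 0:
        raise ValueError("population is empty")
    any_major = pop.G.any(axis=(1, 2))
    any_minor = (pop.G == 0).any(axis=(1, 2))
    # attainable haploid contributions per locus: {beta if any_major, 0 if any_minor}
    upper = np.where(
        any_major & any_minor,
        np.maximum(spec.beta, 0.0),
        np.where(any_major, spec.beta, 0.0),
    )
    lower = np.where(
        any_major & any_minor,
        np.minimum(spec.beta, 0.0),
        np.where(any_major, spec.beta, 0.0),
    )
    return 2.0 * float(lower.sum()), 2.0 * float(upper.sum())


def scale_to_potential(
    pop: Population, spec: GenomeSpec, target: float = 100.0
) -> GenomeSpec:
    """Rescale effects so the population's upper selection limit equals *target*.

    Genotypes are untouched; only ``beta`` is multiplied by a constant.
    """
    _, upper = selection_limits(pop, spec)
    if upper == 0.0:
        raise ValueError(
            "upper selection limit is 0; population carries no scorable variation"
        )
    return spec.with_beta(spec.beta * (target / upper))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_map_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"marker": str, "chrom": str})
    missing = {"marker", "chrom", "pos_cM"} - set(df.columns)
    if missing:
        raise GenotypeDataError(f"map CSV missing columns: {sorted(missing)}")
    return df


def write_map_csv(spec: GenomeSpec, path: str | Path) -> None:
    pd.DataFrame(
        {"marker": spec.loci, "chrom": spec.chrom, "pos_cM": spec.pos_cM}
    ).to_csv(path, index=False)


def read_effects_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"marker": str})
    missing = {"marker", "beta"} - set(df.columns)
    if missing:
        raise GenotypeDataError(f"effects CSV missing columns: {sorted(missing)}")
    return df


def write_effects_csv(spec: GenomeSpec, path: str | Path) -> None:
    pd.DataFrame({"marker": spec.loci, "beta": spec.beta}).to_csv(path, index=False)


def write_haplotypes_csv(pop: Population, spec: GenomeSpec, path: str | Path) -> None:
    """Write phased genotypes as a loci-by-haplotypes CSV.

    One row per locus; two columns per individual, headed ``<id>_h1`` and
    ``<id>_h2``; the first column carries the marker id.
    """
    cols: dict[str, np.ndarray] = {"marker": spec.loci}
    for n, ind in enumerate(pop.ids):
        cols[f"{ind}_h1"] = pop.G[:, 0, n]
        cols[f"{ind}_h2"] = pop.G[:, 1, n]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_haplotypes_csv(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read the haplotype CSV dialect; returns (frame indexed by marker, ids)."""
    df = pd.read_csv(path, dtype={"marker": str})
    if "marker" not in df.columns:
        raise GenotypeDataError("haplotype CSV must have a 'marker' column")
    df = df.set_index("marker")
    hap_cols = list(df.columns)
    if len(hap_cols) % 2 != 0:
        raise GenotypeDataError("haplotype CSV must have two columns per individual")
    ids = []
    for c1, c2 in zip(hap_cols[0::2], hap_cols[1::2]):
        if not (c1.endswith(_HAP_SUFFIXES[0]) and c2.endswith(_HAP_SUFFIXES[1])):
            raise GenotypeDataError(
                f"haplotype columns must come in '<id>_h1','<id>_h2' pairs, got {c1!r},{c2!r}"
            )
        if c1[: -len(_HAP_SUFFIXES[0])] != c2[: -len(_HAP_SUFFIXES[1])]:
            raise GenotypeDataError(f"mismatched haplotype pair: {c1!r}, {c2!r}")
        ids.append(c1[: -len(_HAP_SUFFIXES[0])])
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise GenotypeDataError("haplotype CSV entries must be 0 or 1")
    return df, ids


def _read_vcf(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a phased biallelic VCF into a loci-by-haplotypes frame.

    ALT-allele dosage per haplotype is returned; major/minor recoding
    happens later, once frequencies over the founders are known.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    ids = list(vf.header.samples)
    markers: list[str] = []
    rows: list[list[int]] = []
    for rec in vf.fetch() if vf.index is not None else vf:
        name = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
        if rec.alts is None or len(rec.alts) != 1:
            raise GenotypeDataError(f"non-biallelic site at {rec.chrom}:{rec.pos}")
        row: list[int] = []
        for sample in ids:
            call = rec.samples[sample]
            gt = call["GT"]
            if gt is None or any(a is None for a in gt) or len(gt) != 2:
                raise GenotypeDataError(
                    f"missing or non-diploid genotype at {rec.chrom}:{rec.pos} ({sample})"
                )
            if not call.phased:
                raise GenotypeDataError(
                    f"unphased genotype ('/' separator) at {rec.chrom}:{rec.pos} "
                    f"sample {sample}; phased input is required"
                )
            row.extend(int(a) for a in gt)
        markers.append(name)
        rows.append(row)
    cols = [f"{i}{s}" for i in ids for s in _HAP_SUFFIXES]
    frame = pd.DataFrame(rows, index=pd.Index(markers, name="marker"), columns=cols)
    return frame, ids


def load_population(
    genotype_file: str | Path,
    map_file: str | Path,
    effects_file: str | Path,
    mapping_function: str = "haldane",
) -> tuple[Population, GenomeSpec]:
    """Load a phased population together with its genome spec.

    ``genotype_file`` is a phased VCF (``.vcf``) or a haplotype CSV.  The
    three inputs are intersected on marker id and returned in map order;
    markers absent from any input are dropped with a warning.  For VCF
    input, REF/ALT are recoded so that allele 1 is the major allele by
    frequency in the loaded individuals (ties resolved toward REF);
    effects are taken to be effects of the major allele.
    """
    genotype_file = Path(genotype_file)
    if genotype_file.suffix.lower() == ".vcf" or genotype_file.name.endswith(
        (".vcf.gz", ".vcf.bgz")
    ):
        hap_frame, ids = _read_vcf(genotype_file)
        is_vcf = True
    else:
        hap_frame, ids = read_haplotypes_csv(genotype_file)
        is_vcf = False

    map_df = read_map_csv(map_file)
    eff_df = read_effects_csv(effects_file)

    keep = (
        set(hap_frame.index) & set(map_df["marker"]) & set(eff_df["marker"])
    )
    if not keep:
        raise GenotypeDataError("no marker ids shared by genotypes, map and effects")
    n_drop = (
        (len(hap_frame) - len(set(hap_frame.index) & keep))
        + (len(map_df) - len(set(map_df["marker"]) & keep))
        + (len(eff_df) - len(set(eff_df["marker"]) & keep))
    )
    if n_drop:
        logger.warning(
            "dropping markers outside the genotype/map/effects intersection "
            "(%d file entries affected)", n_drop
        )

    map_df = map_df[map_df["marker"].isin(keep)]
    # map order: keep file order within chromosome, chromosome-major
    map_df = map_df.sort_values(["chrom", "pos_cM"], kind="stable")
    order = map_df["marker"].to_numpy()
    hap = hap_frame.loc[order].to_numpy(dtype=np.int8)
    L, twoN = hap.shape
    G = hap.reshape(L, twoN // 2, 2).transpose(0, 2, 1)

    if is_vcf:
        # recode to major=1 per locus; ties keep REF (ALT dosage < half)
        alt_freq = G.mean(axis=(1, 2))
        flip = alt_freq < 0.5  # ALT minor -> REF is major -> invert coding
        G = np.where(flip[:, None, None], 1 - G, G).astype(np.int8)

    eff = eff_df.set_index("marker")["beta"]
    beta = eff.loc[order].to_numpy(dtype=float)
    chrom = map_df["chrom"].to_numpy(dtype=object)
    pos = map_df["pos_cM"].to_numpy(dtype=float)
    r = map_to_recomb(chrom, pos, mapping_function)
    spec = GenomeSpec(loci=order.astype(object), chrom=chrom, pos_cM=pos, beta=beta, r=r)
    return Population(G, list(ids)), spec
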
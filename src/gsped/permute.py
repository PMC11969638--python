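"""Within-population permutation of genotype matrices.

Genotypes live in an N x 2L matrix (two adjacent allele entries per locus
per individual).  Permutation is always within populations, so per-locus
per-population allele counts — and hence allele frequencies — are exactly
conserved; variability is created without sampling with replacement.

Two options control the unit that moves (mirroring the four panels of the
permutation schemes):

* ``preserve_individuals=True`` — whole individuals are permuted;
* ``preserve_individuals="BY_CHROM"`` — an individual's homologous
  chromosome pair moves intact, but different chromosomes are permuted
  independently (within-chromosome LD is preserved);
* ``preserve_individuals=False`` — single gene copies are shuffled freely
  per locus, the maximal scrambling; with ``preserve_haplotypes=True`` the
  shuffled units are instead whole per-chromosome haplotype blocks (only
  meaningful for phased data).

Every permutation records a provenance map (destination cell -> source
cell), a bijection within each population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genetic_map import MarkerMap

__all__ = ["GenotypeMatrix", "PermutationPlan", "permute_genotypes",
           "invert_permutation", "concat_genotypes"]


@dataclass
class GenotypeMatrix:
    """N individuals x 2L allele codes, with population labels and locus metadata.

    ``alleles[i, 2*l + c]`` is gene copy ``c`` (0 or 1) of individual ``i``
    at locus ``l``.  Missing data uses the sentinel ``"0"`` (the PLINK
    convention) and permutes like any other value.  Each individual belongs
    to exactly one population.
    """

    alleles: np.ndarray
    ids: np.ndarray
    pops: np.ndarray
    markers: MarkerMap | None = None
    phased: bool = False

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles)
        self.ids = np.asarray(self.ids, dtype=str)
        self.pops = np.asarray(self.pops, dtype=str)
        if self.alleles.ndim != 2 or self.alleles.shape[1] % 2:
            raise ValueError("alleles must be N x 2L")
        if len(self.ids) != self.n_ind or len(self.pops) != self.n_ind:
            raise ValueError("ids/pops length must match the number of individuals")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        if self.markers is not None and self.markers.n_markers != self.n_loci:
            raise ValueError(
                f"marker map has {self.markers.n_markers} loci, matrix has {self.n_loci}"
            )

    @property
    def n_ind(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1] // 2

    def rows_of(self, pop) -> np.ndarray:
        return np.flatnonzero(self.pops == str(pop))

    def columns_of_chrom(self, chrom) -> np.ndarray:
        """Allele-column indices for one chromosome's loci, in locus order."""
        if self.markers is None:
            raise ValueError("no marker metadata attached")
        loci = self.markers.indices_of(chrom)
        return np.stack([2 * loci, 2 * loci + 1], axis=1).reshape(-1)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.alleles.copy(), self.ids.copy(), self.pops.copy(),
                              self.markers, self.phased)

    def __repr__(self):
        pops = ", ".join(f"{p}:{(self.pops == p).sum()}" for p in dict.fromkeys(self.pops))
        return f"GenotypeMatrix({self.n_ind} x 2*{self.n_loci}; pops {pops})"


def concat_genotypes(parts) -> GenotypeMatrix:
    """Stack genotype matrices sharing the same loci."""
    parts = list(parts)
    first = parts[0]
    for p in parts[1:]:
        if p.n_loci != first.n_loci:
            raise ValueError("matrices differ in locus count")
    return GenotypeMatrix(
        np.concatenate([p.alleles for p in parts], axis=0),
        np.concatenate([p.ids for p in parts]),
        np.concatenate([p.pops for p in parts]),
        first.markers,
        all(p.phased for p in parts),
    )


@dataclass
class PermutationPlan:
    """Permutation options plus (after running) the provenance map.

    ``provenance[i, j]`` is the flat index (into the original N x 2L matrix)
    of the value now at cell (i, j).
    """

    preserve_individuals: object = True  # True | "BY_CHROM" | False
    preserve_haplotypes: bool = False
    seed: int = 0
    provenance: np.ndarray | None = None

    def __post_init__(self):
        mode = self.preserve_individuals
        if isinstance(mode, str):
            m = mode.strip().upper()
            if m in ("TRUE",):
                mode = True
            elif m in ("FALSE",):
                mode = False
            elif m == "BY_CHROM":
                mode = "BY_CHROM"
            else:
                raise ValueError(f"unknown preserve_individuals value {mode!r}")
        elif mode not in (True, False):
            raise ValueError(f"unknown preserve_individuals value {mode!r}")
        self.preserve_individuals = mode


def _interleaved(block, n, L):
    """(n, 2L) block -> (2n, L) with rows (ind0 copy0, ind0 copy1, ind1 copy0, ...)."""
    return block.reshape(n, L, 2).transpose(0, 2, 1).reshape(2 * n, L)


def _deinterleave(stacked, n, L):
    return stacked.reshape(n, 2, L).transpose(0, 2, 1).reshape(n, 2 * L)


def permute_genotypes(geno: GenotypeMatrix, plan: PermutationPlan):
    """Permute alleles within populations; returns (matrix, plan with provenance).

    Randomness uses one sub-stream per population (and per chromosome where
    chromosomes are permuted independently), derived from ``plan.seed``;
    populations are processed in sorted label order for determinism.
    """
    mode = plan.preserve_individuals
    hap = plan.preserve_haplotypes
    N, L = geno.n_ind, geno.n_loci
    needs_chrom = mode == "BY_CHROM" or (mode is False and hap)
    if needs_chrom and geno.markers is None:
        raise ValueError("this permutation mode needs chromosome metadata on the matrix")
    if hap and not geno.phased:
        warnings.warn(
            "preserve_haplotypes=True on data not flagged as phased; proceeding"
        )

    src = np.arange(N * 2 * L, dtype=np.int64).reshape(N, 2 * L)
    pops_sorted = sorted(set(geno.pops.tolist()))
    chroms = geno.markers.chroms if geno.markers is not None else ()

    def rng_for(*key):
        return np.random.default_rng(
            np.random.SeedSequence(entropy=plan.seed, spawn_key=key)
        )

    for pi, pop in enumerate(pops_sorted):
        rows = geno.rows_of(pop)
        n = len(rows)
        if mode is True:
            perm = rng_for(pi).permutation(n)
            src[rows] = src[rows[perm]]
        elif mode == "BY_CHROM":
            for ci, chrom in enumerate(chroms):
                cols = geno.columns_of_chrom(chrom)
                perm = rng_for(pi, ci).permutation(n)
                src[np.ix_(rows, cols)] = src[np.ix_(rows[perm], cols)]
        elif hap:  # free permutation of whole per-chromosome haplotype blocks
            for ci, chrom in enumerate(chroms):
                cols = geno.columns_of_chrom(chrom)
                Lc = len(cols) // 2
                block = src[np.ix_(rows, cols)]
                stacked = _interleaved(block, n, Lc)
                perm = rng_for(pi, ci).permutation(2 * n)
                src[np.ix_(rows, cols)] = _deinterleave(stacked[perm], n, Lc)
        else:  # free permutation of single gene copies, per locus
            rng = rng_for(pi)
            block = src[rows]
            stacked = _interleaved(block, n, L)
            order = np.argsort(rng.random((2 * n, L)), axis=0)
            shuffled = np.take_along_axis(stacked, order, axis=0)
            src[rows] = _deinterleave(shuffled, n, L)

    out = geno.copy()
    out.alleles = geno.alleles.reshape(-1)[src.reshape(-1)].reshape(N, 2 * L)
    return out, replace(plan, provenance=src)


def invert_permutation(permuted: GenotypeMatrix, plan: PermutationPlan) -> GenotypeMatrix:
    """Recover the original matrix through the provenance map."""
    if plan.provenance is None:
        raise ValueError("plan carries no provenance map")
    N, twoL = permuted.alleles.shape
    flat = np.empty(N * twoL, dtype=permuted.alleles.dtype)
    flat[plan.provenance.reshape(-1)] = permuted.alleles.reshape(-1)
    out = permuted.copy()
    out.alleles = flat.reshape(N, twoL)
    return out
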
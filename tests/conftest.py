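import numpy as np
import pandas as pd
import pytest

from gsped.genetic_map import GenomeSpec, MarkerMap, build_rec_map, pig_genome
from gsped.permute import GenotypeMatrix


@pytest.fixture(scope="session")
def toy_genome():
    """Three 10-Mb chromosomes."""
    return GenomeSpec(("1", "2", "3"), (10_000_000,) * 3)


@pytest.fixture(scope="session")
def toy_recmap(toy_genome):
    """1 cM/Mb on the toy genome, boundaries every megabase."""
    return build_rec_map(toy_genome, cM_per_Mb=1.0, spacing=1_000_000)


@pytest.fixture(scope="session")
def pig():
    return pig_genome()


@pytest.fixture(scope="session")
def pig_recmap(pig):
    return build_rec_map(pig, cM_per_Mb=1.0, spacing=1_000_000)


def make_marker_map(n_per_chrom=(4, 3, 2), spacing_bp=1000):
    rows = []
    k = 0
    for ci, n in enumerate(n_per_chrom, start=1):
        for j in range(n):
            rows.append((str(ci), f"m{k + 1}", 0.0, (j + 1) * spacing_bp))
            k += 1
    return MarkerMap(pd.DataFrame(rows, columns=["chrom", "marker_id", "cM", "bp"]))


def make_geno(rng, n_per_pop=(5, 4), n_per_chrom=(4, 3, 2), alphabet=("A", "C"),
              phased=False):
    """Random genotype matrix over a small multi-chromosome marker map."""
    mm = make_marker_map(n_per_chrom)
    n = sum(n_per_pop)
    alleles = np.array(alphabet)[rng.integers(0, len(alphabet), size=(n, 2 * mm.n_markers))]
    ids = np.array([f"i{k}" for k in range(n)])
    pops = np.concatenate(
        [np.full(c, f"P{j + 1}") for j, c in enumerate(n_per_pop)]
    )
    return GenotypeMatrix(alleles, ids, pops, mm, phased=phased)


@pytest.fixture
def small_geno():
    return make_geno(np.random.default_rng(7))


def check_conservation(samples, ledger, genome):
    """Segments across all samples must tile every founder haplotype exactly."""
    tiles = {}
    for s in samples:
        for gam in s.gametes:
            for c, segs in gam.items():
                for start, end, slot in segs:
                    key = (slot.gsp_id, slot.replicate, slot.founder, slot.haplotype)
                    tiles.setdefault(key, {}).setdefault(c, []).append((start, end))
    assert len(tiles) == len(ledger), "some founder slots delivered nothing"
    for key, per_chrom in tiles.items():
        assert set(per_chrom) == set(genome.chroms), key
        for c, ivs in per_chrom.items():
            ivs.sort()
            assert ivs[0][0] == 0, (key, c)
            assert ivs[-1][1] == genome.length_of(c), (key, c)
            for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
                assert e1 == s2, f"gap or overlap in {key} chrom {c}"
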
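"""Paint alleles onto segregated segments, and PLINK .ped/.map text IO.

``segments2markers`` closes the loop: the (optionally permuted) input
individuals are assigned, in order, to the founder slots of the pedigree,
and each simulated individual's alleles are copied from the founder
haplotype that its segments say it inherited at each marker.  Individuals
not consumed as founders are returned as the retained reference panel, so
every input gene copy appears exactly once across the simulated and
retained outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_map import MarkerMap, read_plink_map
from .permute import GenotypeMatrix, PermutationPlan, permute_genotypes

__all__ = [
    "PaintedOutput",
    "segments2markers",
    "read_plink_ped",
    "write_plink",
    "write_plink_map",
]

MISSING = "0"  # PLINK missing-allele sentinel, kept verbatim internally


@dataclass
class PaintedOutput:
    """Result of painting: simulated rows, retained rows, founder assignments."""

    simulated: GenotypeMatrix
    retained: GenotypeMatrix
    assignments: pd.DataFrame  # rep, founder, population, group, indiv_id, row
    plan: PermutationPlan


def _slot_sort_key(slot):
    return (slot.replicate, slot.founder, slot.haplotype)


def segments2markers(samples, ledger, geno: GenotypeMatrix, groups=None,
                     plan: PermutationPlan | None = None) -> PaintedOutput:
    """Assign permuted individuals to founders and paint sample genotypes.

    Parameters
    ----------
    samples, ledger
        Output of :func:`gsped.segregate.segregate`.
    geno
        The empirical genotype matrix (must carry a marker map).
    groups
        Mapping from GSP founder population labels to population labels in
        ``geno`` (default: identity).
    plan
        Permutation applied to ``geno`` before founder assignment; ``None``
        leaves the matrix unpermuted (identity provenance).

    Founders are taken in (replicate, founder id, haplotype) order and
    consume whole individuals from each mapped population, in matrix order
    of the permuted data.
    """
    if geno.markers is None:
        raise ValueError("genotype matrix needs a marker map for painting")

    if plan is not None:
        permuted, plan = permute_genotypes(geno, plan)
    else:
        src = np.arange(geno.n_ind * 2 * geno.n_loci, dtype=np.int64)
        plan = PermutationPlan(provenance=src.reshape(geno.n_ind, 2 * geno.n_loci))
        permuted = geno.copy()

    slots = sorted(ledger, key=_slot_sort_key)
    founder_keys = []  # (rep, founder) in assignment order
    founder_pop = {}
    for s in slots:
        key = (s.replicate, s.founder)
        if key not in founder_pop:
            founder_keys.append(key)
            founder_pop[key] = set()
        founder_pop[key].add(s.population)
    for key, pops in founder_pop.items():
        if len(pops) != 1:
            raise ValueError(
                f"founder {key[1]} (rep {key[0]}) has mixed haplotype populations "
                f"{sorted(pops)}; painting requires single-population founders"
            )
    founder_pop = {k: next(iter(v)) for k, v in founder_pop.items()}

    present = set(permuted.pops.tolist())
    if groups is None:
        groups = {p: p for p in set(founder_pop.values())}
    for gsp_pop, grp in groups.items():
        if str(grp) not in present:
            raise ValueError(f"group {grp!r} (for GSP population {gsp_pop!r}) "
                             f"not present in the genotype matrix")

    # supply check, then assignment in order
    needed = {}
    for key in founder_keys:
        pop = founder_pop[key]
        if pop not in groups:
            raise ValueError(f"GSP population {pop!r} missing from the group mapping")
        grp = str(groups[pop])
        needed[grp] = needed.get(grp, 0) + 1
    queues = {}
    for grp, need in needed.items():
        rows = permuted.rows_of(grp)
        if need > len(rows):
            raise ValueError(
                f"population {grp!r}: {need} founders required but only "
                f"{len(rows)} individuals available"
            )
        queues[grp] = list(rows)

    row_of = {}
    assign_rows = []
    for key in founder_keys:
        grp = str(groups[founder_pop[key]])
        row = queues[grp].pop(0)
        row_of[key] = row
        assign_rows.append(
            {
                "rep": key[0],
                "founder": key[1],
                "population": founder_pop[key],
                "group": grp,
                "indiv_id": permuted.ids[row],
                "row": row,
            }
        )
    assignments = pd.DataFrame(assign_rows)
    consumed = set(row_of.values())

    # painting: per sample, per gamete, per segment, gather marker columns
    mm = geno.markers
    chrom_bp = {c: mm.bp_of(c) for c in mm.chroms}
    chrom_loci = {c: mm.indices_of(c) for c in mm.chroms}
    twoL = 2 * geno.n_loci
    out = np.empty((len(samples), twoL), dtype=permuted.alleles.dtype)
    for si, sample in enumerate(samples):
        for k, gam in enumerate(sample.gametes):
            for chrom, segs in gam.items():
                bp = chrom_bp[chrom]
                loci = chrom_loci[chrom]
                for start, end, slot in segs:
                    lo, hi = np.searchsorted(bp, [start, end])
                    if lo == hi:
                        continue
                    frow = row_of[(slot.replicate, slot.founder)]
                    cols = 2 * loci[lo:hi]
                    out[si, cols + k] = permuted.alleles[frow, cols + (slot.haplotype - 1)]

    simulated = GenotypeMatrix(
        out,
        np.array([s.sample_id for s in samples]),
        np.array([s.node for s in samples]),
        mm,
        phased=True,
    )
    keep = np.array([i for i in range(permuted.n_ind) if i not in consumed], dtype=int)
    retained = GenotypeMatrix(
        permuted.alleles[keep], permuted.ids[keep], permuted.pops[keep], mm,
        permuted.phased,
    )
    return PaintedOutput(simulated=simulated, retained=retained,
                         assignments=assignments, plan=plan)


# ---------------------------------------------------------------------------
# PLINK text IO
# ---------------------------------------------------------------------------


def read_plink_ped(prefix, pops=None) -> GenotypeMatrix:
    """Read ``prefix.ped`` / ``prefix.map`` into a genotype matrix.

    Population labels come from the ``pops`` table (columns id, group; a
    DataFrame or CSV path) when given, else from the .ped family column.
    """
    prefix = str(prefix)
    mm = read_plink_map(prefix + ".map")
    fams, ids, rows = [], [], []
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * mm.n_markers:
                raise ValueError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * mm.n_markers} "
                    f"fields, got {len(fields)}"
                )
            fams.append(fields[0])
            ids.append(fields[1])
            rows.append(fields[6:])
    if not rows:
        raise ValueError("empty .ped file")
    alleles = np.array(rows)
    ids = np.array(ids)
    if pops is not None:
        if not isinstance(pops, pd.DataFrame):
            pops = pd.read_csv(pops, dtype=str)
        lookup = dict(zip(pops["id"].astype(str), pops["group"].astype(str)))
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise ValueError(f"pops table is missing individuals: {missing}")
        labels = np.array([lookup[i] for i in ids])
    else:
        labels = np.array(fams)
    return GenotypeMatrix(alleles, ids, labels, mm)


def write_plink_map(marker_map: MarkerMap, path) -> None:
    """Write a 4-column .map file (bp written 1-based)."""
    with open(path, "w") as fh:
        for row in marker_map.df.itertuples():
            cm = f"{row.cM:g}"
            fh.write(f"{row.chrom} {row.marker_id} {cm} {row.bp + 1}\n")


def write_plink(geno: GenotypeMatrix, marker_map: MarkerMap | None = None,
                prefix="out") -> tuple:
    """Write ``prefix.ped`` and ``prefix.map``; returns the two paths.

    The .ped leading columns are (family=population, id, 0, 0, 0, -9);
    missing alleles are written as ``0``.
    """
    mm = marker_map if marker_map is not None else geno.markers
    if mm is None:
        raise ValueError("no marker map to write")
    if mm.n_markers != geno.n_loci:
        raise ValueError(
            f"marker map has {mm.n_markers} loci, matrix has {geno.n_loci}"
        )
    prefix = str(prefix)
    ped_path, map_path = prefix + ".ped", prefix + ".map"
    with open(ped_path, "w") as fh:
        for i in range(geno.n_ind):
            lead = f"{geno.pops[i]} {geno.ids[i]} 0 0 0 -9"
            fh.write(lead + " " + " ".join(geno.alleles[i].tolist()) + "\n")
    write_plink_map(mm, map_path)
    return Path(ped_path), Path(map_path)
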
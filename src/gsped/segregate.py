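"""Drop genome segments from founders to samples through a valid GSP.

Each founder contributes two haploid genomes (founder *slots*).  One
meiosis per founder recombines them into two complementary gametes; at
every nonfounder, incoming gametes are paired at random, sample pairs are
set aside as simulated individuals, and the remaining pairs are recombined
again and dealt down the out-edges.  Because every meiosis emits a gamete
*and its complement*, and gamete counts balance by the validity conditions,
the segments delivered to the samples tile every founder haplotype exactly
once: no genetic material is duplicated or lost.

Coordinates are 0-based half-open bp intervals.  Crossovers occur exactly
at recombination-map boundary positions, so segment arithmetic is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_map import GenomeSpec, RecombMap, sample_crossover_mask
from .gsp import GSP, GspInvalidError, validate_gsp

__all__ = [
    "FounderSlot",
    "SimSample",
    "meiosis",
    "segregate",
    "admixture_fraction",
    "ancestry_genotype_fractions",
    "segments_to_frame",
    "frame_to_samples",
]


@dataclass(frozen=True)
class FounderSlot:
    """One haploid genome of one founder in one replicate — the unit of provenance."""

    gsp_id: str
    replicate: int
    founder: str
    haplotype: int  # 1 or 2
    population: str


# A gamete maps chromosome id -> list of (start, end, FounderSlot) segments
# tiling [0, chromosome length) exactly.


@dataclass(frozen=True)
class SimSample:
    """A simulated individual: two gametes plus provenance."""

    sample_id: str
    gametes: tuple  # (gamete1, gamete2)
    gsp_id: str
    replicate: int
    node: str       # sample node id
    index: int      # position within the sample node (0-based)


def _slice_segments(segments, lo, hi):
    """Portions of a segment list overlapping [lo, hi)."""
    out = []
    for start, end, slot in segments:
        if end <= lo:
            continue
        if start >= hi:
            break
        out.append((max(start, lo), min(end, hi), slot))
    return out


def _merge(segments):
    """Merge adjacent segments with the same origin slot (canonical form)."""
    if not segments:
        return segments
    out = [segments[0]]
    for seg in segments[1:]:
        last = out[-1]
        if seg[2] is last[2] and last[1] == seg[0]:
            out[-1] = (last[0], seg[1], last[2])
        else:
            out.append(seg)
    return out


def _check_genome_match(gamete, rec_map):
    if set(gamete) != set(rec_map.chroms):
        raise ValueError("parent gamete and recombination map cover different chromosomes")
    for c, segs in gamete.items():
        if segs[0][0] != 0 or segs[-1][1] != rec_map.lengths[c]:
            raise ValueError(
                f"parent gamete does not tile chromosome {c} of the recombination map"
            )


def _recombine(parent, mask, length):
    """Apply one crossover mask to a pair of chromosome segment lists.

    Returns the gamete and its complement (the complement carries the other
    parental haplotype at every bp).
    """
    cuts = [0, *mask.positions.tolist(), length]
    src = mask.start_slot - 1
    out1, out2 = [], []
    for i in range(len(cuts) - 1):
        lo, hi = cuts[i], cuts[i + 1]
        out1.extend(_slice_segments(parent[src], lo, hi))
        out2.extend(_slice_segments(parent[1 - src], lo, hi))
        src = 1 - src
    return _merge(out1), _merge(out2)


def meiosis(parent, rec_map: RecombMap, rng):
    """One meiosis: two complementary recombined gametes from a gamete pair.

    One crossover mask is drawn per chromosome; the second output carries
    the opposite parental haplotype at every position (antithetic gamete).
    """
    g1, g2 = parent
    _check_genome_match(g1, rec_map)
    _check_genome_match(g2, rec_map)
    out1, out2 = {}, {}
    for chrom in rec_map.chroms:
        mask = sample_crossover_mask(rec_map, chrom, rng)
        out1[chrom], out2[chrom] = _recombine(
            (g1[chrom], g2[chrom]), mask, rec_map.lengths[chrom]
        )
    return out1, out2


def _node_rng(seed, rep, node_index):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(rep, node_index))
    )


def segregate(gsp: GSP, rec_map: RecombMap, n_reps: int = 1, seed: int = 0,
              gsp_id: str = "gsp1"):
    """Segregate founder genomes to sample nodes, ``n_reps`` times.

    Returns ``(samples, ledger)``: the simulated individuals and the list of
    every :class:`FounderSlot` instantiated.  Each replicate consumes fresh
    founder slots, so no founder material is ever reused.  Randomness is
    drawn from one sub-stream per (replicate, node), derived from ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    report = validate_gsp(gsp)
    if not report.valid:
        raise GspInvalidError(report)

    order = gsp.topological_order()
    node_index = {nid: i for i, nid in enumerate(order)}
    chroms = rec_map.chroms

    samples, ledger = [], []
    for rep in range(n_reps):
        # gametes waiting at each nonfounder, keyed by incoming edge
        inbox = {nid: {0: [], 1: []} for nid in gsp.nonfounders}

        def deliver(parent_id, products, rng):
            """Shuffle meiosis products and deal them along the out-edges."""
            edges = gsp.out_edges.get(parent_id, ())
            if not edges:
                return
            idx = rng.permutation(len(products))
            pos = 0
            for e in edges:
                take = [products[i] for i in idx[pos:pos + e.gametes]]
                pos += e.gametes
                slot01 = 0 if gsp.in_edges[e.child][0] is e else 1
                inbox[e.child][slot01].extend(take)

        for nid in order:
            rng = _node_rng(seed, rep, node_index[nid])
            node = gsp.nodes[nid]
            if node.kind == "founder":
                slots = [
                    FounderSlot(gsp_id, rep, nid, h, node.hap_pops[h - 1])
                    for h in (1, 2)
                ]
                ledger.extend(slots)
                pair = tuple(
                    {c: [(0, rec_map.lengths[c], s)] for c in chroms} for s in slots
                )
                p1, p2 = meiosis(pair, rec_map, rng)
                deliver(nid, [p1, p2], rng)
                continue

            lst1, lst2 = inbox[nid][0], inbox[nid][1]
            perm = rng.permutation(len(lst2))
            pairs = [(lst1[i], lst2[perm[i]]) for i in range(len(lst1))]

            snode = gsp.sample_of.get(nid)
            if snode is not None:
                chosen = rng.choice(len(pairs), size=snode.n_samples, replace=False)
                chosen_set = set(int(i) for i in chosen)
                for k, i in enumerate(sorted(chosen_set)):
                    samples.append(
                        SimSample(
                            sample_id=f"{gsp_id}-rep{rep}-{snode.node_id}-{k + 1}",
                            gametes=pairs[i],
                            gsp_id=gsp_id,
                            replicate=rep,
                            node=snode.node_id,
                            index=k,
                        )
                    )
                pairs = [p for i, p in enumerate(pairs) if i not in chosen_set]

            products = []
            for pair in pairs:
                p1, p2 = meiosis(pair, rec_map, rng)
                products += [p1, p2]
            deliver(nid, products, rng)

    return samples, ledger


def admixture_fraction(sample: SimSample, pop, genome: GenomeSpec) -> float:
    """Cumulative length of segments originating from ``pop`` over 2x genome length."""
    pop = str(pop)
    total = 2 * genome.total_length
    hit = 0
    seen = set()
    for gam in sample.gametes:
        for segs in gam.values():
            for start, end, slot in segs:
                seen.add(slot.population)
                if slot.population == pop:
                    hit += end - start
    if pop not in seen:
        warnings.warn(f"population {pop!r} does not occur in this sample's segments")
        return 0.0
    return hit / total


def ancestry_genotype_fractions(sample: SimSample, pop, genome: GenomeSpec):
    """Genome fractions carrying (2, 1, 0) copies of ``pop`` ancestry.

    Computed by interval intersection of the two gametes' population
    indicators; the three fractions sum to one exactly.
    """
    pop = str(pop)
    acc = [0, 0, 0]  # bp with 2, 1, 0 copies
    seen = set()
    g1, g2 = sample.gametes
    for chrom in genome.chroms:
        s1, s2 = g1[chrom], g2[chrom]
        for _, _, slot in s1 + s2:
            seen.add(slot.population)
        i = j = 0
        pos = 0
        L = genome.length_of(chrom)
        while pos < L:
            e1, e2 = s1[i][1], s2[j][1]
            nxt = min(e1, e2)
            copies = (s1[i][2].population == pop) + (s2[j][2].population == pop)
            acc[2 - copies] += nxt - pos
            pos = nxt
            if e1 == nxt:
                i += 1
            if e2 == nxt:
                j += 1
    if pop not in seen:
        warnings.warn(f"population {pop!r} does not occur in this sample's segments")
    total = genome.total_length
    return acc[0] / total, acc[1] / total, acc[2] / total


# ---------------------------------------------------------------------------
# Segment serialisation
# ---------------------------------------------------------------------------

_SEG_COLUMNS = [
    "sample_id", "gamete_index", "chrom", "start", "end",
    "rep", "founder_node", "haplotype", "population",
]


def segments_to_frame(samples) -> pd.DataFrame:
    """Tidy table of all segments (0-based half-open coordinates)."""
    rows = []
    for s in samples:
        for k, gam in enumerate(s.gametes, start=1):
            for chrom, segs in gam.items():
                for start, end, slot in segs:
                    rows.append(
                        (s.sample_id, k, chrom, start, end,
                         slot.replicate, slot.founder, slot.haplotype, slot.population)
                    )
    return pd.DataFrame(rows, columns=_SEG_COLUMNS)


def frame_to_samples(df: pd.DataFrame, genome: GenomeSpec, gsp_id: str = "gsp1"):
    """Rebuild ``(samples, ledger)`` from a segment table."""
    samples = []
    slots = {}

    def slot_of(row):
        key = (row.rep, str(row.founder_node), int(row.haplotype))
        if key not in slots:
            slots[key] = FounderSlot(
                gsp_id, int(row.rep), str(row.founder_node),
                int(row.haplotype), str(row.population),
            )
        return slots[key]

    for sid, sub in df.groupby("sample_id", sort=False):
        gametes = []
        for k in (1, 2):
            gam = {c: [] for c in genome.chroms}
            part = sub[sub["gamete_index"] == k].sort_values(["chrom", "start"])
            for row in part.itertuples():
                gam[str(row.chrom)].append((int(row.start), int(row.end), slot_of(row)))
            gametes.append(gam)
        rep = int(sub["rep"].iloc[0])
        samples.append(
            SimSample(sample_id=sid, gametes=tuple(gametes), gsp_id=gsp_id,
                      replicate=rep, node="", index=0)
        )
    return samples, list(slots.values())
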
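"""Marker maps, recombination maps, and per-meiosis crossover sampling.

A :class:`RecombMap` discretises each chromosome into intervals separated by
ordered *boundaries*; each boundary carries the probability ``r`` that a
gamete switches parental haplotype there during one meiosis.  Rates are
obtained from genetic map positions, or from physical positions under a
uniform cM/Mb rate, through the Haldane map function

    r = 0.5 * (1 - exp(-2 d))

with ``d`` the genetic length in Morgans of the interval ending at the
boundary.  Switches at distinct boundaries are independent (no crossover
interference), and each chromosome of a gamete starts on either parental
haplotype with probability 1/2 (independent assortment).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "MarkerMap",
    "RecombMap",
    "BreakpointList",
    "read_plink_map",
    "build_rec_map",
    "sample_crossover_mask",
    "haldane",
    "pig_genome",
]


def haldane(d_morgans):
    """Recombination fraction for a genetic distance in Morgans (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float)))


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome ids with physical lengths in bp."""

    chroms: tuple
    lengths: tuple

    def __post_init__(self):
        chroms = tuple(str(c) for c in self.chroms)
        lengths = tuple(int(x) for x in self.lengths)
        if len(chroms) != len(lengths):
            raise ValueError("chroms and lengths differ in length")
        if len(set(chroms)) != len(chroms):
            raise ValueError("duplicate chromosome ids")
        if any(x <= 0 for x in lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "lengths", lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def length_of(self, chrom) -> int:
        try:
            return self.lengths[self.chroms.index(str(chrom))]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def items(self):
        return zip(self.chroms, self.lengths)


# Sus scrofa 11.1 autosome lengths (bp), used only for their proportions.
_PIG_AUTOSOME_BP = (
    274330532, 151935994, 132848913, 130910915, 104526007, 170843587,
    121844099, 138966237, 139512083, 69359453, 79169978, 61602749,
    208334590, 141755446, 140412725, 79944280, 63494081, 55982971,
)


def pig_genome(total_bp: int = 2_350_000_000) -> GenomeSpec:
    """An 18-autosome, 2.35-Gb pig-like genome.

    Chromosome proportions follow the pig reference assembly; lengths are
    rescaled so the genome totals exactly ``total_bp``.
    """
    raw = np.array(_PIG_AUTOSOME_BP, dtype=float)
    scaled = np.floor(raw / raw.sum() * total_bp).astype(int)
    scaled[-1] += total_bp - scaled.sum()  # absorb rounding in the last autosome
    return GenomeSpec(tuple(str(i) for i in range(1, 19)), tuple(scaled))


class MarkerMap:
    """Ordered marker positions, grouped by chromosome.

    Wraps a DataFrame with columns ``chrom`` (str), ``marker_id`` (str),
    ``cM`` (float, 0 when unknown) and ``bp`` (int, 0-based).  Within each
    chromosome bp positions are strictly increasing; marker ids are unique.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True).copy()
        df["chrom"] = df["chrom"].astype(str)
        df["marker_id"] = df["marker_id"].astype(str)
        df["cM"] = df["cM"].astype(float)
        df["bp"] = df["bp"].astype(np.int64)
        if len(df) == 0:
            raise ValueError("no markers")
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        for chrom, sub in df.groupby("chrom", sort=False):
            bad = np.flatnonzero(np.diff(sub["bp"].to_numpy()) <= 0)
            if bad.size:
                name = sub["marker_id"].iloc[bad[0] + 1]
                raise ValueError(
                    f"bp positions not strictly increasing on chromosome {chrom} "
                    f"at marker {name!r}"
                )
        self.df = df
        self._by_chrom = {c: sub for c, sub in df.groupby("chrom", sort=False)}

    @property
    def chroms(self) -> tuple:
        return tuple(self._by_chrom)

    @property
    def n_markers(self) -> int:
        return len(self.df)

    def bp_of(self, chrom) -> np.ndarray:
        return self._by_chrom[str(chrom)]["bp"].to_numpy()

    def cm_of(self, chrom) -> np.ndarray:
        return self._by_chrom[str(chrom)]["cM"].to_numpy()

    def indices_of(self, chrom) -> np.ndarray:
        """Row indices (locus order) of a chromosome's markers."""
        return self._by_chrom[str(chrom)].index.to_numpy()

    @property
    def has_genetic_pos(self) -> bool:
        """True when the cM column carries information (not identically zero)."""
        return bool((self.df["cM"] != 0).any())

    def implied_genome(self) -> GenomeSpec:
        """Minimal genome covering all markers: length = last marker bp + 1."""
        return GenomeSpec(
            self.chroms, tuple(int(self.bp_of(c)[-1]) + 1 for c in self.chroms)
        )

    def __eq__(self, other):
        return isinstance(other, MarkerMap) and self.df.equals(other.df)

    def __repr__(self):
        return f"MarkerMap({self.n_markers} markers on {len(self.chroms)} chromosomes)"


@dataclass(frozen=True)
class BreakpointList:
    """Realisation of one meiosis on one chromosome.

    ``start_slot`` is the parental haplotype (1 or 2) the gamete begins on;
    ``positions`` are the boundary bp positions where it switches.
    """

    chrom: str
    start_slot: int
    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        if self.start_slot not in (1, 2):
            raise ValueError("start_slot must be 1 or 2")
        if pos.size and (np.diff(pos) <= 0).any():
            raise ValueError("breakpoints must be strictly increasing")
        object.__setattr__(self, "positions", pos)


class RecombMap:
    """Per-chromosome crossover boundaries with switch probabilities."""

    def __init__(self, lengths: dict, boundaries: dict, rates: dict):
        self.chroms = tuple(str(c) for c in lengths)
        self.lengths = {str(c): int(v) for c, v in lengths.items()}
        self.boundaries = {}
        self.rates = {}
        for c in self.chroms:
            b = np.asarray(boundaries[c], dtype=np.int64)
            r = np.asarray(rates[c], dtype=float)
            L = self.lengths[c]
            if L <= 0:
                raise ValueError(f"zero-length chromosome {c}")
            if b.shape != r.shape:
                raise ValueError("boundaries and rates differ in shape")
            if b.size:
                if b[0] <= 0 or b[-1] >= L or (np.diff(b) <= 0).any():
                    raise ValueError(
                        f"boundaries on chromosome {c} must be strictly increasing in (0, length)"
                    )
            if ((r < 0) | (r > 0.5)).any():
                raise ValueError("switch probabilities must lie in [0, 0.5]")
            self.boundaries[c] = b
            self.rates[c] = r

    def genome(self) -> GenomeSpec:
        return GenomeSpec(self.chroms, tuple(self.lengths[c] for c in self.chroms))

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def expected_crossovers(self, chrom=None) -> float:
        """Expected breakpoint count per meiosis (sum of r)."""
        if chrom is not None:
            return float(self.rates[str(chrom)].sum())
        return float(sum(r.sum() for r in self.rates.values()))

    # -- serialisation: a chromosome-length header table, then boundary rows --

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.chroms:
                fh.write(f"#length,{c},{self.lengths[c]}\n")
            fh.write("chrom,boundary_bp,r\n")
            for c in self.chroms:
                for b, r in zip(self.boundaries[c], self.rates[c]):
                    fh.write(f"{c},{b},{r:.10g}\n")

    @classmethod
    def from_csv(cls, path) -> "RecombMap":
        lengths = {}
        body = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#length,"):
                    _, c, v = line.strip().split(",")
                    lengths[c] = int(v)
                else:
                    body.append(line)
        if not lengths:
            raise ValueError("missing chromosome-length header rows")
        df = pd.read_csv(io.StringIO("".join(body)), dtype={"chrom": str})
        boundaries = {c: np.array([], dtype=np.int64) for c in lengths}
        rates = {c: np.array([], dtype=float) for c in lengths}
        for c, sub in df.groupby("chrom", sort=False):
            boundaries[c] = sub["boundary_bp"].to_numpy(np.int64)
            rates[c] = sub["r"].to_numpy(float)
        return cls(lengths, boundaries, rates)

    def __repr__(self):
        nb = sum(len(b) for b in self.boundaries.values())
        return (
            f"RecombMap({len(self.chroms)} chromosomes, {self.total_length} bp, "
            f"{nb} boundaries, E[crossovers]={self.expected_crossovers():.2f})"
        )


def read_plink_map(path) -> MarkerMap:
    """Read a 4-column PLINK .map file (chrom, id, cM, bp; bp 1-based).

    Positions are converted to the 0-based convention used internally.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ValueError(f"line {lineno}: expected 4 columns, got {len(fields)}")
            chrom, mid, cm, bp = fields
            try:
                cm = float(cm)
                bp = int(bp)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric position ({exc})") from None
            rows.append((chrom, mid, cm, bp - 1))
    if not rows:
        raise ValueError("no markers")
    df = pd.DataFrame(rows, columns=["chrom", "marker_id", "cM", "bp"])
    return MarkerMap(df)


def _interval_rates(widths_bp, cm_per_mb):
    d = np.asarray(widths_bp, dtype=float) * cm_per_mb / 100.0 / 1e6  # Morgans
    return haldane(d)


def build_rec_map(source, cM_per_Mb: float = 1.0, spacing="markers") -> RecombMap:
    """Construct a recombination map from a marker map or a bare genome spec.

    Parameters
    ----------
    source
        A :class:`MarkerMap` or a :class:`GenomeSpec`.
    cM_per_Mb
        Uniform recombination rate used wherever genetic positions are
        unavailable (default 1 cM/Mb).
    spacing
        ``"markers"`` places one boundary at each marker position after the
        first on its chromosome; an integer places boundaries at multiples
        of that many bp.  A bare :class:`GenomeSpec` has no marker
        positions, so an integer spacing is required for it.
    """
    if cM_per_Mb < 0:
        raise ValueError("cM_per_Mb must be >= 0")

    if isinstance(source, GenomeSpec):
        if spacing == "markers":
            raise ValueError("a GenomeSpec has no markers; give an integer spacing")
        step = int(spacing)
        if step <= 0:
            raise ValueError("spacing must be a positive integer")
        lengths, bounds, rates = {}, {}, {}
        for chrom, L in source.items():
            b = np.arange(step, L, step, dtype=np.int64)
            lengths[chrom] = L
            bounds[chrom] = b
            if b.size:
                widths = np.diff(np.concatenate(([0], b)))
                rates[chrom] = _interval_rates(widths, cM_per_Mb)
            else:
                rates[chrom] = np.array([], dtype=float)
        return RecombMap(lengths, bounds, rates)

    if not isinstance(source, MarkerMap):
        raise TypeError("source must be a MarkerMap or GenomeSpec")

    lengths, bounds, rates = {}, {}, {}
    use_cm = source.has_genetic_pos
    for chrom in source.chroms:
        bp = source.bp_of(chrom)
        cm = source.cm_of(chrom)
        L = int(bp[-1]) + 1
        lengths[chrom] = L
        if spacing == "markers":
            b = bp[1:].astype(np.int64)
            if use_cm:
                d = np.diff(cm) / 100.0
                r = haldane(np.maximum(d, 0.0))
            else:
                r = _interval_rates(np.diff(bp), cM_per_Mb)
        else:
            step = int(spacing)
            if step <= 0:
                raise ValueError("spacing must be a positive integer")
            b = np.arange(step, L, step, dtype=np.int64)
            edges = np.concatenate(([0], b))
            if use_cm:
                cm_at = np.interp(edges, bp, cm)
                r = haldane(np.maximum(np.diff(cm_at), 0.0) / 100.0)
            else:
                r = _interval_rates(np.diff(edges), cM_per_Mb)
        bounds[chrom] = b
        rates[chrom] = np.asarray(r, dtype=float)
    return RecombMap(lengths, bounds, rates)


def sample_crossover_mask(rec_map: RecombMap, chrom, rng) -> BreakpointList:
    """Draw one meiosis on one chromosome: a start slot and breakpoint set.

    The start slot is a fair coin (independent assortment); each boundary is
    independently a breakpoint with its switch probability ``r``.
    """
    chrom = str(chrom)
    if chrom not in rec_map.lengths:
        raise KeyError(f"unknown chromosome {chrom!r}")
    r = rec_map.rates[chrom]
    start_slot = 1 + int(rng.random() < 0.5)
    if r.size:
        hit = rng.random(r.size) < r
        positions = rec_map.boundaries[chrom][hit]
    else:
        positions = np.array([], dtype=np.int64)
    return BreakpointList(chrom=chrom, start_slot=start_slot, positions=positions)
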
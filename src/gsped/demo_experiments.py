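"""Synthetic reference panels and the package's motivating experiments.

Three phenomena are covered, each runnable at desk scale:

1. **RISPI** (resampling-induced spurious power inflation): when two
   reference samples are drawn from one population and new "admixed"
   genotypes are simulated by sampling alleles *with replacement* from the
   sample frequencies, a supervised admixture estimator appears able to
   recover the nominal admixture fraction — pure artefact, strongest at
   many loci and small reference samples.
2. **No RISPI under pedigree simulation**: the same experiment with
   individuals built by segregating segments through genomic simulation
   pedigrees and painting alleles by within-population permutation yields
   estimates centred on 0.5, as they should be for indistinguishable
   sources.
3. **Physical linkage**: admixture fractions of hybrids simulated locus by
   locus (unlinked) concentrate as 1/L, while segment-based simulation on a
   genome-scale map retains the true, much larger between-individual
   variance.

Reference panels use Beta-distributed biallelic allele frequencies with
Hardy-Weinberg genotypes.  The supervised estimator is a per-individual EM
maximum-likelihood fit of the admixture model (each gene copy originates
from population A with probability q), with the panel allele frequencies
treated as known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_map import GenomeSpec, MarkerMap, build_rec_map, pig_genome
from .gsp import (GSP, backcross_gsp, bc1xbc2_gsp, f1_gsp, f2_gsp, f2xbc1_gsp,
                  pure_gsp)
from .markers import MISSING, segments2markers
from .permute import GenotypeMatrix, PermutationPlan, concat_genotypes
from .segregate import admixture_fraction, segregate

__all__ = [
    "PanelConfig",
    "ExperimentConfig",
    "CategoryProbs",
    "QEstimate",
    "cross_probs",
    "backcross_probs",
    "category_probs",
    "category_gsp",
    "gsp_for_admixture",
    "sim_reference_panels",
    "sim_admixed_with_replacement",
    "sim_unlinked_hybrids",
    "sim_unlinked_admixture",
    "supervised_q_mle",
    "supervised_q_mle_many",
    "run_rispi_experiment",
    "linkage_experiment",
    "DEFAULT_Q_GRID",
]

DEFAULT_Q_GRID = (0.0, 1 / 8, 1 / 4, 3 / 8, 1 / 2, 5 / 8, 3 / 4, 7 / 8, 1.0)


@dataclass(frozen=True)
class PanelConfig:
    """Shape of a pair of synthetic reference panels.

    ``L`` biallelic loci with frequencies drawn once from
    Beta(``beta_a``, ``beta_b``) (defaults 1 and 8, a typical SNP
    site-frequency shape); ``N`` diploids per panel under Hardy-Weinberg.
    """

    L: int = 1000
    N: int = 50
    beta_a: float = 1.0
    beta_b: float = 8.0

    def __post_init__(self):
        if self.L < 1 or self.N < 1:
            raise ValueError("L and N must be >= 1")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta shape parameters must be positive")


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid for the RISPI experiments.

    ``R * n`` individuals are simulated per (L, N, q) cell in total.  The
    scaled-down default grid keeps R*n = 96 per cell; pass larger values to
    approach the original design (R*n = 480).
    """

    L_values: tuple = (100, 1000, 10000)
    N_values: tuple = (25, 50)
    n: int = 12
    R: int = 8
    q_grid: tuple = DEFAULT_Q_GRID

    def __post_init__(self):
        if self.n < 1 or self.R < 1:
            raise ValueError("n and R must be >= 1")
        if any(q < 0 or q > 1 for q in self.q_grid):
            raise ValueError("q values must lie in [0, 1]")


@dataclass(frozen=True)
class CategoryProbs:
    """Expected ancestry-genotype frequencies (2, 1, 0 copies from population a)."""

    name: str
    f_aa: float
    f_ab: float
    f_bb: float

    def __post_init__(self):
        t = (self.f_aa, self.f_ab, self.f_bb)
        if any(x < 0 for x in t) or abs(sum(t) - 1.0) > 1e-9:
            raise ValueError("category probabilities must be nonnegative and sum to 1")

    @property
    def triplet(self):
        return (self.f_aa, self.f_ab, self.f_bb)

    @property
    def expected_q(self):
        return self.f_aa + 0.5 * self.f_ab


def cross_probs(name, gamete_a1: float, gamete_a2: float) -> CategoryProbs:
    """Genotype triplet for offspring of two parents with given gamete a-probabilities."""
    p, q = float(gamete_a1), float(gamete_a2)
    return CategoryProbs(name, p * q, p * (1 - q) + (1 - p) * q, (1 - p) * (1 - q))


def backcross_probs(g: int) -> CategoryProbs:
    """BCg toward population a: (1 - 2^-g, 2^-g, 0)."""
    if g < 1:
        raise ValueError("g must be >= 1")
    return CategoryProbs(f"BC{g}", 1 - 2.0 ** -g, 2.0 ** -g, 0.0)


def _gamete_a_prob(cat: CategoryProbs) -> float:
    return cat.f_aa + 0.5 * cat.f_ab


def category_probs(name: str) -> CategoryProbs:
    """Built-in hybrid-category triplets (ancestry toward population a)."""
    name = name.upper()
    if name in ("PURE_A", "A"):
        return CategoryProbs("PURE_A", 1, 0, 0)
    if name in ("PURE_B", "B"):
        return CategoryProbs("PURE_B", 0, 0, 1)
    if name == "F1":
        return cross_probs("F1", 1.0, 0.0)
    if name == "F2":
        return cross_probs("F2", 0.5, 0.5)
    if name.startswith("BC") and name[2:].isdigit():
        return backcross_probs(int(name[2:]))
    if name in ("BC1XBC2", "BC1_X_BC2"):
        return cross_probs(
            "BC1xBC2", _gamete_a_prob(backcross_probs(1)), _gamete_a_prob(backcross_probs(2))
        )
    raise KeyError(f"unknown hybrid category {name!r}")


def category_gsp(name: str, pop_a="A", pop_b="B") -> GSP:
    """Pedigree whose sample node produces the named hybrid category."""
    name = name.upper()
    if name in ("PURE_A", "A"):
        return pure_gsp(pop_a)
    if name in ("PURE_B", "B"):
        return pure_gsp(pop_b)
    if name == "F1":
        return f1_gsp(pop_a, pop_b)
    if name == "F2":
        return f2_gsp(pop_a, pop_b)
    if name.startswith("BC") and name[2:].isdigit():
        return backcross_gsp(int(name[2:]), pop_a, pop_b)
    if name in ("BC1XBC2", "BC1_X_BC2"):
        return bc1xbc2_gsp(pop_a, pop_b)
    if name in ("F2XBC1", "BC1XF2"):
        return f2xbc1_gsp(pop_a, pop_b)
    raise KeyError(f"unknown hybrid category {name!r}")


# q values realisable exactly by a small pedigree (toward pop_a)
_Q_BUILDERS = {
    0.0: lambda a, b: pure_gsp(b),
    1 / 8: lambda a, b: backcross_gsp(2, b, a),
    1 / 4: lambda a, b: backcross_gsp(1, b, a),
    3 / 8: lambda a, b: f2xbc1_gsp(b, a),
    1 / 2: lambda a, b: f1_gsp(a, b),
    5 / 8: lambda a, b: f2xbc1_gsp(a, b),
    3 / 4: lambda a, b: backcross_gsp(1, a, b),
    7 / 8: lambda a, b: backcross_gsp(2, a, b),
    1.0: lambda a, b: pure_gsp(a),
}


def gsp_for_admixture(q: float, pop_a="A", pop_b="B"):
    """Pedigree realising admixture fraction ``q`` from ``pop_a``.

    Returns ``(gsp, realised_q)``; when ``q`` is not exactly realisable by a
    built-in pedigree the nearest realisable value is used and returned.
    """
    if q < 0 or q > 1:
        raise ValueError("q must lie in [0, 1]")
    realised = min(_Q_BUILDERS, key=lambda v: (abs(v - q), v))
    return _Q_BUILDERS[realised](pop_a, pop_b), realised


# ---------------------------------------------------------------------------
# Synthetic panels and naive simulators
# ---------------------------------------------------------------------------


def _uniform_marker_map(L, genome: GenomeSpec, rng) -> MarkerMap:
    """L distinct marker positions spread uniformly over a genome."""
    lengths = np.array(genome.lengths, dtype=float)
    probs = lengths / lengths.sum()
    while True:
        chrom_idx = rng.choice(len(lengths), size=L, p=probs)
        pos = rng.integers(0, np.array(genome.lengths)[chrom_idx])
        df = pd.DataFrame({"ci": chrom_idx, "bp": pos}).sort_values(["ci", "bp"])
        if not df.duplicated().any():
            break
    df["chrom"] = [genome.chroms[i] for i in df["ci"]]
    df["marker_id"] = [f"m{k + 1:06d}" for k in range(L)]
    df["cM"] = 0.0
    return MarkerMap(df[["chrom", "marker_id", "cM", "bp"]])


def _hwe_panel(freqs, N, ids_prefix, pop, markers, rng) -> GenotypeMatrix:
    p = np.repeat(freqs, 2)[None, :]  # per gene copy
    alleles = np.where(rng.random((N, 2 * len(freqs))) < p, "1", "2")
    ids = np.array([f"{ids_prefix}{i + 1:04d}" for i in range(N)])
    return GenotypeMatrix(alleles, ids, np.full(N, pop), markers)


def sim_reference_panels(cfg: PanelConfig, genome: GenomeSpec | None = None,
                         rng=None, pops=("A", "B")):
    """Two HWE panels drawn from one Beta-distributed frequency vector.

    Both panels share the *same* true frequencies — any apparent
    differentiation between them is pure sampling noise.  Loci are placed
    uniformly over ``genome`` (default: the pig-like genome) so the
    pedigree pathway can run on them.  Allele ``"1"`` has frequency ``p``.
    """
    rng = np.random.default_rng(rng)
    genome = genome or pig_genome()
    freqs = rng.beta(cfg.beta_a, cfg.beta_b, size=cfg.L)
    mm = _uniform_marker_map(cfg.L, genome, rng)
    panel_a = _hwe_panel(freqs, cfg.N, f"{pops[0]}-", pops[0], mm, rng)
    panel_b = _hwe_panel(freqs, cfg.N, f"{pops[1]}-", pops[1], mm, rng)
    return panel_a, panel_b, freqs


def _stacked_copies(panel: GenotypeMatrix):
    """Panel alleles as a (2N, L) array of gene copies."""
    N, L = panel.n_ind, panel.n_loci
    return panel.alleles.reshape(N, L, 2).transpose(0, 2, 1).reshape(2 * N, L)


def sim_admixed_with_replacement(panel_a: GenotypeMatrix, panel_b: GenotypeMatrix,
                                 qA: float, n: int, rng) -> GenotypeMatrix:
    """Naive admixed genotypes: per gene copy, origin ~ Bernoulli(qA), then an
    allele drawn *with replacement* from that panel's gene copies at the locus.

    This is the admixture-model simulation that induces RISPI.
    """
    if not 0 <= qA <= 1:
        raise ValueError("qA must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    L = panel_a.n_loci
    if panel_b.n_loci != L:
        raise ValueError("panels differ in locus count")
    ids = np.array([f"q{qA:g}-{i + 1}" for i in range(n)])
    if n == 0:
        return GenotypeMatrix(np.empty((0, 2 * L), dtype=panel_a.alleles.dtype),
                              ids, ids, panel_a.markers)
    sa, sb = _stacked_copies(panel_a), _stacked_copies(panel_b)
    locus_of_copy = np.repeat(np.arange(L), 2)
    origin_a = rng.random((n, 2 * L)) < qA
    draw_a = sa[rng.integers(0, sa.shape[0], size=(n, 2 * L)), locus_of_copy]
    draw_b = sb[rng.integers(0, sb.shape[0], size=(n, 2 * L)), locus_of_copy]
    alleles = np.where(origin_a, draw_a, draw_b)
    return GenotypeMatrix(alleles, ids, np.full(n, f"q{qA:g}"), panel_a.markers)


def sim_unlinked_hybrids(panel_a: GenotypeMatrix, panel_b: GenotypeMatrix,
                         cat: CategoryProbs, n: int, rng):
    """Hybrid genotypes with every locus segregating independently.

    Each locus of each individual draws 2, 1 or 0 population-a gene copies
    from the category triplet; allelic types are then sampled with
    replacement from the corresponding panel.  Returns ``(genotypes, q)``
    with ``q`` the exact fraction of the 2L gene copies originating from a.
    """
    rng = np.random.default_rng(rng)
    L = panel_a.n_loci
    u = rng.random((n, L))
    copies_a = np.where(u < cat.f_aa, 2, np.where(u < cat.f_aa + cat.f_ab, 1, 0))
    which = rng.integers(0, 2, size=(n, L))  # slot of the single a copy
    a0 = (copies_a == 2) | ((copies_a == 1) & (which == 0))
    a1 = (copies_a == 2) | ((copies_a == 1) & (which == 1))
    origin_a = np.empty((n, 2 * L), dtype=bool)
    origin_a[:, 0::2] = a0
    origin_a[:, 1::2] = a1
    sa, sb = _stacked_copies(panel_a), _stacked_copies(panel_b)
    locus_of_copy = np.repeat(np.arange(L), 2)
    draw_a = sa[rng.integers(0, sa.shape[0], size=(n, 2 * L)), locus_of_copy]
    draw_b = sb[rng.integers(0, sb.shape[0], size=(n, 2 * L)), locus_of_copy]
    alleles = np.where(origin_a, draw_a, draw_b)
    ids = np.array([f"{cat.name}-{i + 1}" for i in range(n)])
    geno = GenotypeMatrix(alleles, ids, np.full(n, cat.name), panel_a.markers)
    q = copies_a.sum(axis=1) / (2 * L)
    return geno, q


def sim_unlinked_admixture(cat: CategoryProbs, L: int, n: int, rng) -> np.ndarray:
    """Admixture fractions of unlinked-locus hybrids, without the genotypes.

    Exact multinomial shortcut — identical in distribution to the fractions
    returned by :func:`sim_unlinked_hybrids`, usable at very large L.
    """
    rng = np.random.default_rng(rng)
    counts = rng.multinomial(L, (cat.f_aa, cat.f_ab, cat.f_bb), size=n)
    return (2 * counts[:, 0] + counts[:, 1]) / (2 * L)


# ---------------------------------------------------------------------------
# Supervised admixture estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QEstimate:
    """Maximum-likelihood admixture estimate for one individual."""

    indiv_id: str
    q_hat: float
    log_lik: float
    iterations: int


def _clamp(freqs, n_ref):
    eps = 1.0 / (2 * n_ref + 1)
    return np.clip(np.asarray(freqs, dtype=float), eps, 1 - eps)


def _copy_probs(alleles_row, freqs):
    """Per-gene-copy probability under a frequency vector; NaN where missing."""
    p = np.repeat(freqs, 2)
    x = alleles_row
    out = np.where(x == "1", p, 1 - p)
    return np.where(x == MISSING, np.nan, out)


def supervised_q_mle_many(geno: GenotypeMatrix, freq_a, freq_b, n_ref_a, n_ref_b,
                          tol: float = 1e-6, max_iter: int = 500):
    """Vectorised EM over all rows of a genotype matrix; returns QEstimate list.

    Maximises sum over gene copies of log(q * pA + (1-q) * pB), with
    frequencies clamped away from 0 and 1 by 1/(2N+1).  A flat likelihood
    stays at the 0.5 starting point (the tie-break).
    """
    fa = _clamp(freq_a, n_ref_a)
    fb = _clamp(freq_b, n_ref_b)
    a = np.stack([_copy_probs(row, fa) for row in geno.alleles])
    b = np.stack([_copy_probs(row, fb) for row in geno.alleles])
    valid = ~np.isnan(a)
    n_valid = valid.sum(axis=1)
    a = np.nan_to_num(a, nan=0.5)
    b = np.nan_to_num(b, nan=0.5)

    q = np.full(geno.n_ind, 0.5)
    its = np.zeros(geno.n_ind, dtype=int)
    active = n_valid > 0
    if (~active).any():
        warnings.warn("individual(s) with zero informative loci; q set to 0.5")
    for it in range(1, max_iter + 1):
        qa = q[:, None] * a
        denom = qa + (1 - q)[:, None] * b
        w = np.where(valid, qa / denom, 0.0)
        q_new = np.where(active, w.sum(axis=1) / np.maximum(n_valid, 1), 0.5)
        moved = np.abs(q_new - q) > tol
        its = np.where(moved & active, it, its)
        q = q_new
        if not moved.any():
            break
    ll = np.where(valid, np.log(q[:, None] * a + (1 - q)[:, None] * b), 0.0).sum(axis=1)
    return [
        QEstimate(str(geno.ids[i]), float(q[i]), float(ll[i]), int(its[i]))
        for i in range(geno.n_ind)
    ]


def supervised_q_mle(alleles_row, freq_a, freq_b, n_ref_a, n_ref_b,
                     indiv_id="ind", tol: float = 1e-6, max_iter: int = 500) -> QEstimate:
    """EM admixture MLE for a single 2L allele row (see supervised_q_mle_many)."""
    row = np.asarray(alleles_row)
    mm = None
    geno = GenotypeMatrix(row[None, :], np.array([indiv_id]),
                          np.array(["?"]), mm)
    return supervised_q_mle_many(geno, freq_a, freq_b, n_ref_a, n_ref_b,
                                 tol=tol, max_iter=max_iter)[0]


def _observed_freqs(geno: GenotypeMatrix, pop):
    """Frequency of allele "1" per locus in one population (missing excluded)."""
    rows = geno.rows_of(pop)
    sub = geno.alleles[rows]
    ones = (sub == "1").reshape(len(rows), -1, 2).sum(axis=(0, 2))
    called = (sub != MISSING).reshape(len(rows), -1, 2).sum(axis=(0, 2))
    with np.errstate(invalid="ignore"):
        f = ones / called
    return np.where(called > 0, f, 0.5), len(rows)


# ---------------------------------------------------------------------------
# The experiments
# ---------------------------------------------------------------------------


def _rispi_one_q_with_replacement(panel_a, panel_b, q, n, rng):
    geno = sim_admixed_with_replacement(panel_a, panel_b, q, n, rng)
    fa, na = _observed_freqs(panel_a, panel_a.pops[0])
    fb, nb = _observed_freqs(panel_b, panel_b.pops[0])
    return geno, supervised_q_mle_many(geno, fa, fb, na, nb), q


def _balanced_retained(retained: GenotypeMatrix, pop_a, pop_b):
    """Equal-size retained reference panels.

    Founder consumption leaves the two retained panels with different sizes
    (a backcross pedigree draws far more founders from one population), and
    the fixed-frequency MLE is pulled toward the larger, less noisy
    reference.  Subsampling the larger panel to the smaller's size (the
    retained matrix is already in permuted random order) restores the
    balanced design and removes that pull.
    """
    ra, rb = retained.rows_of(pop_a), retained.rows_of(pop_b)
    m = min(len(ra), len(rb))
    sub = GenotypeMatrix(
        np.vstack([retained.alleles[ra[:m]], retained.alleles[rb[:m]]]),
        np.concatenate([retained.ids[ra[:m]], retained.ids[rb[:m]]]),
        np.array([str(pop_a)] * m + [str(pop_b)] * m),
        retained.markers,
    )
    return sub


def _rispi_one_q_gsp(panel_a, panel_b, q, rec_map, seed, rng):
    pop_a, pop_b = panel_a.pops[0], panel_b.pops[0]
    gsp, realised = gsp_for_admixture(q, pop_a, pop_b)
    combined = concat_genotypes([panel_a, panel_b])
    samples, ledger = segregate(gsp, rec_map, n_reps=1, seed=seed,
                                gsp_id=f"q{q:g}")
    plan = PermutationPlan(preserve_individuals=True, preserve_haplotypes=False,
                           seed=seed + 1)
    painted = segments2markers(samples, ledger, combined, plan=plan)
    ref = _balanced_retained(painted.retained, pop_a, pop_b)
    fa, na = _observed_freqs(ref, pop_a)
    fb, nb = _observed_freqs(ref, pop_b)
    return painted.simulated, supervised_q_mle_many(painted.simulated, fa, fb, na, nb), realised


def run_rispi_experiment(cfg: ExperimentConfig, method: str, seed: int = 0,
                         genome: GenomeSpec | None = None) -> pd.DataFrame:
    """Run the RISPI grid; returns a tidy table (L, N, n, qA, rep, id, q_hat, ...).

    ``method`` is ``"with_replacement"`` (naive frequency resampling; the
    estimator is handed the panel frequencies it was simulated from) or
    ``"gsp"`` (pedigree segregation painted by permutation; the estimator
    uses frequencies from the retained, non-founder individuals).  Both
    panels are always drawn from a single population, so an informative
    estimate is spurious by construction.  ``realised_q`` flags the
    admixture value a pedigree actually delivers (equal to qA for every
    default grid value).
    """
    method = method.replace("-", "_").lower()
    if method not in ("with_replacement", "gsp"):
        raise ValueError("method must be 'with_replacement' or 'gsp'")
    genome = genome or pig_genome()
    rows = []
    for L in cfg.L_values:
        for N in cfg.N_values:
            for rep in range(cfg.R):
                ss = np.random.SeedSequence(
                    entropy=seed, spawn_key=(int(L), int(N), rep)
                )
                rng = np.random.default_rng(ss)
                panel_a, panel_b, _ = sim_reference_panels(
                    PanelConfig(L=L, N=N), genome, rng
                )
                rec_map = (build_rec_map(panel_a.markers, cM_per_Mb=1.0)
                           if method == "gsp" else None)
                for q in cfg.q_grid:
                    if method == "with_replacement":
                        _, ests, realised = _rispi_one_q_with_replacement(
                            panel_a, panel_b, q, cfg.n, rng
                        )
                    else:
                        sub_seed = (int(ss.generate_state(1)[0]) + int(round(q * 8))) % (2**31 - 1)
                        _, ests, realised = _rispi_one_q_gsp(
                            panel_a, panel_b, q, rec_map, sub_seed, rng
                        )
                    for e in ests:
                        rows.append(
                            (L, N, cfg.n, q, rep, e.indiv_id, e.q_hat, realised, method)
                        )
    return pd.DataFrame(
        rows,
        columns=["L", "N", "n", "qA", "rep", "id", "q_hat", "realised_q", "method"],
    )


def linkage_experiment(categories=("F1", "F2", "BC1", "BC2", "BC3", "BC4"),
                       L_values=(100, 1000, 10000, 100000), n: int = 1000,
                       rec_map=None, genome: GenomeSpec | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Admixture-fraction spread: unlinked loci vs segment-based simulation.

    For each hybrid category, unlinked fractions are simulated at each L
    (variance shrinks as 1/L) and linked fractions by segregating ``n``
    samples through the category's pedigree on ``rec_map`` (default: the
    pig-like genome at 1 cM/Mb) — the linked spread is the real one.
    Returns a tidy table (category, source, L, n, mean, sd).
    """
    genome = genome or pig_genome()
    if rec_map is None:
        rec_map = build_rec_map(genome, cM_per_Mb=1.0, spacing=1_000_000)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    rows = []
    for ci, name in enumerate(categories):
        cat = category_probs(name)
        for L in L_values:
            q = sim_unlinked_admixture(cat, L, n, rng)
            rows.append((cat.name, "unlinked", L, n, q.mean(), q.std(ddof=1)))
        gsp = category_gsp(name)
        target = {nid for nid, c in gsp.categories.items() if c.upper() == cat.name.upper()}
        per_rep = sum(gsp.sample_nodes[nid].n_samples for nid in target)
        reps = max(1, -(-n // per_rep))
        samples, _ = segregate(gsp, rec_map, n_reps=reps, seed=seed + 101 + ci)
        q = np.array(
            [admixture_fraction(s, "A", genome) for s in samples if s.node in target]
        )[:n]
        rows.append((cat.name, "linked", None, len(q), q.mean(), q.std(ddof=1)))
    return pd.DataFrame(rows, columns=["category", "source", "L", "n", "mean", "sd"])
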
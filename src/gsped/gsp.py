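"""Genomic simulation pedigrees (GSPs): representation, presets, validation.

A GSP is a loop-free directed pedigree with three node kinds:

* **founder** — no parents; carries two haploid genomes, each labelled with
  a population of origin;
* **nonfounder** — exactly two incoming edges (one per parent), each edge
  annotated with the number of gametes segregated along it;
* **sample** — attached to exactly one nonfounder; absorbs ``S`` united
  gamete pairs as simulated individuals.

Validity requires that every piece of founder genetic material is delivered
to a sample exactly once: the number of samples equals the number of
founders, each founder segregates exactly two gametes, and gamete counts
balance at every nonfounder.  Inbreeding loops are forbidden because a
shared ancestor would let one founder gene copy be duplicated among
descendants (sampling with replacement by the back door).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "GspNode",
    "GspEdge",
    "GSP",
    "ValidationReport",
    "GspStructureError",
    "GspInvalidError",
    "load_gsp",
    "create_gsp",
    "validate_gsp",
    "f1_gsp",
    "f2_gsp",
    "pure_gsp",
    "backcross_gsp",
    "bc1xbc2_gsp",
    "f2xbc1_gsp",
    "union_gsp",
    "random_gsp",
    "write_gsp_csvs",
]

KINDS = ("founder", "nonfounder", "sample")


class GspStructureError(ValueError):
    """The node/edge tables do not form a structurally well-formed GSP."""


class GspInvalidError(ValueError):
    """A structurally well-formed GSP failed the validity conditions."""

    def __init__(self, report):
        self.report = report
        lines = "; ".join(m for _, m, _ in report.violations)
        super().__init__(f"invalid GSP: {lines}")


@dataclass(frozen=True)
class GspNode:
    node_id: str
    kind: str
    hap_pops: tuple | None = None  # founders: (pop of haplotype 1, pop of haplotype 2)
    parent: str | None = None      # sample nodes: the adjacent nonfounder
    n_samples: int | None = None   # sample nodes: S

    def __post_init__(self):
        object.__setattr__(self, "node_id", str(self.node_id))
        if self.kind not in KINDS:
            raise GspStructureError(f"node {self.node_id}: unknown kind {self.kind!r}")
        if self.kind == "founder":
            if self.hap_pops is None or len(self.hap_pops) != 2:
                raise GspStructureError(
                    f"founder {self.node_id} needs two haplotype population labels"
                )
            object.__setattr__(self, "hap_pops", tuple(str(p) for p in self.hap_pops))
        if self.kind == "sample":
            if self.parent is None:
                raise GspStructureError(f"sample node {self.node_id} needs a parent")
            object.__setattr__(self, "parent", str(self.parent))
            if self.n_samples is None or int(self.n_samples) < 1:
                raise GspStructureError(
                    f"sample node {self.node_id}: n_samples must be >= 1"
                )
            object.__setattr__(self, "n_samples", int(self.n_samples))


@dataclass(frozen=True)
class GspEdge:
    parent: str
    child: str
    gametes: int

    def __post_init__(self):
        object.__setattr__(self, "parent", str(self.parent))
        object.__setattr__(self, "child", str(self.child))
        object.__setattr__(self, "gametes", int(self.gametes))
        if self.gametes < 1:
            raise GspStructureError(
                f"edge {self.parent}->{self.child}: gametes must be >= 1"
            )


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of the validity check; ``violations`` holds (condition, message, ids)."""

    valid: bool
    violations: tuple

    @property
    def conditions(self):
        return {c for c, _, _ in self.violations}

    def __str__(self):
        if self.valid:
            return "valid GSP"
        return "invalid GSP:\n" + "\n".join(
            f"  [{c}] {m} (nodes/edges: {', '.join(ids)})"
            for c, m, ids in self.violations
        )


class GSP:
    """A structurally well-formed genomic simulation pedigree.

    Construction enforces structure only (two parent edges per nonfounder,
    founders parentless, at most one sample node per nonfounder); the
    gamete-accounting conditions are checked by :func:`validate_gsp`.
    """

    def __init__(self, nodes, edges, categories: dict | None = None):
        self.nodes = {n.node_id: n for n in nodes}
        if len(self.nodes) != len(list(nodes)):
            raise GspStructureError("duplicate node ids")
        self.edges = tuple(edges)
        self.founders = {i: n for i, n in self.nodes.items() if n.kind == "founder"}
        self.nonfounders = {i: n for i, n in self.nodes.items() if n.kind == "nonfounder"}
        self.sample_nodes = {i: n for i, n in self.nodes.items() if n.kind == "sample"}
        # optional annotation: sample node id -> hybrid-category name
        self.categories = dict(categories or {})

        self.in_edges = {i: [] for i in self.nonfounders}
        self.out_edges = {i: [] for i in self.nodes}
        for e in self.edges:
            if e.parent not in self.nodes:
                raise GspStructureError(f"edge references unknown node {e.parent!r}")
            if e.child not in self.nodes:
                raise GspStructureError(f"edge references unknown node {e.child!r}")
            if self.nodes[e.parent].kind == "sample":
                raise GspStructureError(f"sample node {e.parent} cannot have children")
            if self.nodes[e.child].kind != "nonfounder":
                raise GspStructureError(
                    f"edge {e.parent}->{e.child}: only nonfounders receive gametes"
                )
            self.in_edges[e.child].append(e)
            self.out_edges[e.parent].append(e)

        for i, es in self.in_edges.items():
            if len(es) != 2:
                raise GspStructureError(
                    f"nonfounder {i} has {len(es)} incoming edges (needs exactly 2)"
                )

        self.sample_of = {}
        for i, s in self.sample_nodes.items():
            if s.parent not in self.nonfounders:
                raise GspStructureError(
                    f"sample node {i}: parent {s.parent!r} is not a nonfounder"
                )
            if s.parent in self.sample_of:
                raise GspStructureError(
                    f"nonfounder {s.parent} has more than one sample node"
                )
            self.sample_of[s.parent] = s

        self._check_acyclic()

    # -- graph helpers -------------------------------------------------

    def _check_acyclic(self):
        order = self.topological_order()
        if len(order) != len(self.founders) + len(self.nonfounders):
            raise GspStructureError("pedigree graph contains a cycle")

    def topological_order(self):
        """Founders and nonfounders, parents always before children."""
        indeg = {i: 0 for i in self.founders}
        indeg.update({i: len(self.in_edges[i]) for i in self.nonfounders})
        ready = [i for i, d in indeg.items() if d == 0]
        order = []
        while ready:
            ready.sort()  # deterministic
            i = ready.pop(0)
            order.append(i)
            for e in self.out_edges.get(i, ()):
                indeg[e.child] -= 1
                if indeg[e.child] == 0:
                    ready.append(e.child)
        return order

    def ancestors(self, node_id):
        """All founder/nonfounder ancestors of a node (excluding itself)."""
        seen = set()
        stack = [e.parent for e in self.in_edges.get(node_id, ())]
        while stack:
            p = stack.pop()
            if p in seen:
                continue
            seen.add(p)
            stack.extend(e.parent for e in self.in_edges.get(p, ()))
        return seen

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_founders(self):
        return len(self.founders)

    @property
    def n_samples(self):
        return sum(s.n_samples for s in self.sample_nodes.values())

    @property
    def populations(self):
        pops = []
        for f in self.founders.values():
            for p in f.hap_pops:
                if p not in pops:
                    pops.append(p)
        return tuple(pops)

    def founder_haplotype_counts(self):
        """Haploid genomes required per population (for painting supply checks)."""
        counts = {}
        for f in self.founders.values():
            for p in f.hap_pops:
                counts[p] = counts.get(p, 0) + 1
        return counts

    # -- tables --------------------------------------------------------

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n in self.nodes.values():
            rows.append(
                {
                    "id": n.node_id,
                    "kind": n.kind,
                    "hpop1": n.hap_pops[0] if n.hap_pops else "",
                    "hpop2": n.hap_pops[1] if n.hap_pops else "",
                    "parent": n.parent or "",
                    "n_samples": n.n_samples if n.n_samples is not None else "",
                }
            )
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"parent": e.parent, "child": e.child, "gametes": e.gametes} for e in self.edges]
        )

    def __repr__(self):
        return (
            f"GSP({self.n_founders} founders, {len(self.nonfounders)} nonfounders, "
            f"{len(self.sample_nodes)} sample nodes, {self.n_samples} samples/rep)"
        )


def load_gsp(nodes, edges) -> GSP:
    """Build a GSP from node/edge tables (DataFrames or CSV paths).

    nodes.csv columns: id, kind(founder|nonfounder|sample), hpop1, hpop2
    (founders only), parent, n_samples (sample nodes only).
    edges.csv columns: parent, child, gametes.
    """
    if not isinstance(nodes, pd.DataFrame):
        nodes = pd.read_csv(nodes, dtype=str).fillna("")
    if not isinstance(edges, pd.DataFrame):
        edges = pd.read_csv(edges, dtype=str).fillna("")
    node_objs = []
    for _, row in nodes.iterrows():
        kind = str(row["kind"]).strip().lower()
        hap = None
        if kind == "founder":
            hap = (row.get("hpop1", ""), row.get("hpop2", ""))
            if "" in hap:
                raise GspStructureError(f"founder {row['id']}: missing hpop1/hpop2")
        parent = str(row.get("parent", "") or "") or None
        ns = row.get("n_samples", "")
        ns = int(ns) if str(ns).strip() not in ("", "nan") else None
        node_objs.append(
            GspNode(node_id=row["id"], kind=kind, hap_pops=hap, parent=parent, n_samples=ns)
        )
    edge_objs = [
        GspEdge(parent=row["parent"], child=row["child"], gametes=int(row["gametes"]))
        for _, row in edges.iterrows()
    ]
    return GSP(node_objs, edge_objs)


def write_gsp_csvs(gsp: GSP, directory) -> tuple:
    """Write nodes.csv/edges.csv into a directory; returns the two paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    npath, epath = d / "nodes.csv", d / "edges.csv"
    gsp.node_table().to_csv(npath, index=False)
    gsp.edge_table().to_csv(epath, index=False)
    return npath, epath


def validate_gsp(gsp: GSP) -> ValidationReport:
    """Check the gamete-accounting conditions and loop-freeness.

    Violations are reported as data, never raised:

    * c1 — total samples equal total founders;
    * c2 — each founder segregates exactly two gametes over at most two edges;
    * c3 — a nonfounder's two incoming edges carry equal gamete counts;
    * c4 — no-sample nonfounders: gametes out equal gametes in;
    * c5 — sample-only nonfounders: gametes in equal twice the sample count;
    * c6 — both: gametes in equal twice the sample count plus gametes out;
    * loop — DAG with disjoint ancestries for the two parents of every
      nonfounder (no inbreeding loops).
    """
    violations = []

    total_s = gsp.n_samples
    if total_s != gsp.n_founders:
        violations.append(
            (
                "c1",
                f"samples ({total_s}) != founders ({gsp.n_founders})",
                tuple(sorted(gsp.sample_nodes))
                or ("<none>",),
            )
        )

    for fid in gsp.founders:
        es = gsp.out_edges.get(fid, ())
        total = sum(e.gametes for e in es)
        if total != 2 or len(es) > 2:
            violations.append(
                (
                    "c2",
                    f"founder {fid} segregates {total} gametes over {len(es)} edges "
                    f"(must be exactly 2 over at most 2 edges)",
                    (fid,),
                )
            )

    for nid in gsp.nonfounders:
        e1, e2 = gsp.in_edges[nid]
        if e1.gametes != e2.gametes:
            violations.append(
                (
                    "c3",
                    f"nonfounder {nid}: unequal parent edges ({e1.gametes} vs {e2.gametes})",
                    (nid,),
                )
            )
        g_in = e1.gametes + e2.gametes
        g_out = sum(e.gametes for e in gsp.out_edges.get(nid, ()))
        s = gsp.sample_of.get(nid)
        if s is None and g_out > 0:
            if g_out != g_in:
                violations.append(
                    ("c4", f"nonfounder {nid}: {g_in} gametes in, {g_out} out", (nid,))
                )
        elif s is not None and g_out == 0:
            if g_in != 2 * s.n_samples:
                violations.append(
                    (
                        "c5",
                        f"nonfounder {nid}: {g_in} gametes in != 2*S ({2 * s.n_samples})",
                        (nid, s.node_id),
                    )
                )
        elif s is not None:
            if g_in != 2 * s.n_samples + g_out:
                violations.append(
                    (
                        "c6",
                        f"nonfounder {nid}: {g_in} gametes in != 2*S + out "
                        f"({2 * s.n_samples} + {g_out})",
                        (nid, s.node_id),
                    )
                )
        else:  # no samples, no out edges: dead end, material lost
            violations.append(
                ("c4", f"nonfounder {nid}: gametes in but no samples or out edges", (nid,))
            )

    for nid in gsp.nonfounders:
        p1, p2 = (e.parent for e in gsp.in_edges[nid])
        a1 = gsp.ancestors(p1) | {p1}
        a2 = gsp.ancestors(p2) | {p2}
        shared = a1 & a2
        if shared:
            violations.append(
                (
                    "loop",
                    f"nonfounder {nid}: parents {p1} and {p2} share ancestors "
                    f"{sorted(shared)} (inbreeding loop)",
                    (nid,),
                )
            )

    return ValidationReport(valid=not violations, violations=tuple(violations))


# ---------------------------------------------------------------------------
# Preset pedigrees
# ---------------------------------------------------------------------------


def _gsp(nodes, edges, categories):
    g = GSP(nodes, edges, categories)
    report = validate_gsp(g)
    if not report.valid:  # presets are constructed valid; guard against bugs
        raise GspInvalidError(report)
    return g


def _founder(i, pop):
    return GspNode(str(i), "founder", hap_pops=(pop, pop))


def _nonf(i):
    return GspNode(str(i), "nonfounder")


def _samp(i, parent, s):
    return GspNode(str(i), "sample", parent=str(parent), n_samples=s)


def pure_gsp(pop, label=None) -> GSP:
    """Two founders from one population; two unadmixed samples."""
    nodes = [_founder(1, pop), _founder(2, pop), _nonf(3), _samp("s3", 3, 2)]
    edges = [GspEdge(1, 3, 2), GspEdge(2, 3, 2)]
    return _gsp(nodes, edges, {"s3": label or f"PURE_{pop}"})


def f1_gsp(pop_a, pop_b) -> GSP:
    """Minimal F1 pedigree: two founders, one cross node, two F1 samples."""
    nodes = [_founder(1, pop_a), _founder(2, pop_b), _nonf(3), _samp("s3", 3, 2)]
    edges = [GspEdge(1, 3, 2), GspEdge(2, 3, 2)]
    return _gsp(nodes, edges, {"s3": "F1"})


def f2_gsp(pop_a, pop_b) -> GSP:
    """The worked-example F2 pedigree: four founders, two F1 nodes, four F2 samples.

    Nodes 5 and 6 are each an F1 (one pure-A and one pure-B parent); node 7
    unites gametes from the two F1s and delivers four F2 samples.
    """
    nodes = [
        _founder(1, pop_a),
        _founder(2, pop_b),
        _founder(3, pop_a),
        _founder(4, pop_b),
        _nonf(5),
        _nonf(6),
        _nonf(7),
        _samp("s7", 7, 4),
    ]
    edges = [
        GspEdge(1, 5, 2),
        GspEdge(2, 5, 2),
        GspEdge(3, 6, 2),
        GspEdge(4, 6, 2),
        GspEdge(5, 7, 4),
        GspEdge(6, 7, 4),
    ]
    return _gsp(nodes, edges, {"s7": "F2"})


def _pure_supply(next_id, pop, n_gametes, nodes, edges):
    """Build a subtree delivering ``n_gametes`` recombined pure-``pop`` gametes.

    Returns (node id emitting the gametes, next free id).  ``n_gametes`` must
    be a power of two >= 4: a node fed by two founders yields 4; larger
    supplies merge two half-size supplies.
    """
    if n_gametes == 4:
        f1, f2, m = str(next_id), str(next_id + 1), str(next_id + 2)
        nodes += [_founder(f1, pop), _founder(f2, pop), _nonf(m)]
        edges += [GspEdge(f1, m, 2), GspEdge(f2, m, 2)]
        return m, next_id + 3
    half = n_gametes // 2
    left, next_id = _pure_supply(next_id, pop, half, nodes, edges)
    right, next_id = _pure_supply(next_id, pop, half, nodes, edges)
    m = str(next_id)
    nodes.append(_nonf(m))
    edges += [GspEdge(left, m, half), GspEdge(right, m, half)]
    return m, next_id + 1


def backcross_gsp(generation: int, recurrent, other) -> GSP:
    """A BCg-only pedigree backcrossing toward ``recurrent``.

    BC1 = F1 x pure, BC2 = BC1 x pure, and so on.  Material conservation
    forces 2**(g+1) founders (all but one from the recurrent population) and
    the same number of samples.
    """
    g = int(generation)
    if g < 1:
        raise ValueError("generation must be >= 1")
    nodes, edges = [], []
    nodes += [_founder(1, recurrent), _founder(2, other), _nonf(3)]
    edges += [GspEdge(1, 3, 2), GspEdge(2, 3, 2)]
    hybrid, gametes, next_id = "3", 4, 4
    for _ in range(1, g):
        supply, next_id = _pure_supply(next_id, recurrent, gametes, nodes, edges)
        m = str(next_id)
        next_id += 1
        nodes.append(_nonf(m))
        edges += [GspEdge(hybrid, m, gametes), GspEdge(supply, m, gametes)]
        hybrid, gametes = m, gametes * 2
    supply, next_id = _pure_supply(next_id, recurrent, gametes, nodes, edges)
    final = str(next_id)
    next_id += 1
    s = gametes  # united pairs
    nodes += [_nonf(final), _samp(f"s{final}", final, s)]
    edges += [GspEdge(hybrid, final, gametes), GspEdge(supply, final, gametes)]
    return _gsp(nodes, edges, {f"s{final}": f"BC{g}"})


def bc1xbc2_gsp(recurrent, other) -> GSP:
    """Offspring of a BC1 parent and a BC2 parent (both toward ``recurrent``).

    Eight compound samples plus one incidental F1 sample (required to
    balance the gamete accounting with nine founders).
    """
    n, e = [], []
    # F1 node x1 feeding the BC1 line
    n += [_founder(1, recurrent), _founder(2, other), _nonf("x1")]
    e += [GspEdge(1, "x1", 2), GspEdge(2, "x1", 2)]
    # pure supply for the BC1 line
    q1, nid = _pure_supply(3, recurrent, 4, n, e)
    n.append(_nonf("b1"))
    e += [GspEdge("x1", "b1", 4), GspEdge(q1, "b1", 4)]  # b1: BC1, 8 gametes out
    # second F1 node with one sample taken, feeding the BC2 line
    fa, fb = str(nid), str(nid + 1)
    nid += 2
    n += [_founder(fa, recurrent), _founder(fb, other), _nonf("x2"), _samp("sx2", "x2", 1)]
    e += [GspEdge(fa, "x2", 2), GspEdge(fb, "x2", 2)]
    a3 = str(nid)
    nid += 1
    n += [_founder(a3, recurrent), _nonf("b3")]
    e += [GspEdge("x2", "b3", 2), GspEdge(a3, "b3", 2)]  # b3: BC1, 4 gametes out
    q3, nid = _pure_supply(nid, recurrent, 4, n, e)
    n.append(_nonf("b2"))
    e += [GspEdge("b3", "b2", 4), GspEdge(q3, "b2", 4)]  # b2: BC2, 8 gametes out
    n += [_nonf("z"), _samp("sz", "z", 8)]
    e += [GspEdge("b1", "z", 8), GspEdge("b2", "z", 8)]
    return _gsp(n, e, {"sz": "BC1xBC2", "sx2": "F1"})


def f2xbc1_gsp(recurrent, other) -> GSP:
    """Offspring of a BC1 parent (toward ``recurrent``) and an F2 parent.

    Expected admixture from ``recurrent`` is 5/8 — an F2 gamete carries the
    same 1/2 ancestry marginal as an F1 gamete, and this pedigree balances
    with 8 founders and 8 samples.
    """
    n, e = [], []
    n += [_founder(1, recurrent), _founder(2, other), _nonf("x1")]
    e += [GspEdge(1, "x1", 2), GspEdge(2, "x1", 2)]
    q1, nid = _pure_supply(3, recurrent, 4, n, e)
    n.append(_nonf("b1"))
    e += [GspEdge("x1", "b1", 4), GspEdge(q1, "b1", 4)]  # BC1, out 8
    f3, f4, f5, f6 = (str(i) for i in range(nid, nid + 4))
    n += [
        _founder(f3, recurrent),
        _founder(f4, other),
        _founder(f5, recurrent),
        _founder(f6, other),
        _nonf("x2"),
        _nonf("x3"),
        _nonf("m"),
    ]
    e += [
        GspEdge(f3, "x2", 2),
        GspEdge(f4, "x2", 2),
        GspEdge(f5, "x3", 2),
        GspEdge(f6, "x3", 2),
        GspEdge("x2", "m", 4),
        GspEdge("x3", "m", 4),
    ]  # m: F2 node, out 8
    n += [_nonf("z"), _samp("sz", "z", 8)]
    e += [GspEdge("b1", "z", 8), GspEdge("m", "z", 8)]
    return _gsp(n, e, {"sz": "F2xBC1"})


def _all_categories_gsp(pop_a, pop_b) -> GSP:
    """The four-category convenience pedigree: 1 F1, 2 F2, 1 BC1, 2 BC2.

    Six founders and six samples.  Node numbering: founders 1-6,
    nonfounders 7-11, sample nodes s7 (F1), s9 (BC1), s10 (BC2), s11 (F2).
    """
    nodes = [
        _founder(1, pop_a),
        _founder(2, pop_b),
        _founder(3, pop_a),
        _founder(4, pop_b),
        _founder(5, pop_a),
        _founder(6, pop_a),
        _nonf(7),
        _nonf(8),
        _nonf(9),
        _nonf(10),
        _nonf(11),
        _samp("s7", 7, 1),
        _samp("s9", 9, 1),
        _samp("s10", 10, 2),
        _samp("s11", 11, 2),
    ]
    edges = [
        GspEdge(1, 7, 2),
        GspEdge(2, 7, 2),
        GspEdge(3, 8, 2),
        GspEdge(4, 8, 2),
        GspEdge(7, 11, 2),
        GspEdge(8, 11, 2),
        GspEdge(8, 9, 2),
        GspEdge(5, 9, 2),
        GspEdge(9, 10, 2),
        GspEdge(6, 10, 2),
    ]
    return _gsp(
        nodes, edges, {"s7": "F1", "s9": "BC1", "s10": "BC2", "s11": "F2"}
    )


def union_gsp(gsps, prefixes=None) -> GSP:
    """Disjoint union of GSPs with relabelled node ids.

    Every validity condition is local to a node or sums over the whole
    pedigree, so a disjoint union of valid GSPs is valid.
    """
    gsps = list(gsps)
    if prefixes is None:
        prefixes = [f"g{k}." for k in range(1, len(gsps) + 1)]
    nodes, edges, cats = [], [], {}
    for g, pre in zip(gsps, prefixes):
        for n in g.nodes.values():
            nodes.append(
                GspNode(
                    node_id=pre + n.node_id,
                    kind=n.kind,
                    hap_pops=n.hap_pops,
                    parent=(pre + n.parent) if n.parent else None,
                    n_samples=n.n_samples,
                )
            )
        edges.extend(
            GspEdge(pre + e.parent, pre + e.child, e.gametes) for e in g.edges
        )
        cats.update({pre + k: v for k, v in g.categories.items()})
    return GSP(nodes, edges, cats)


def create_gsp(pop_a, pop_b, F1=False, F2=False, BC1=False, BC2=False) -> GSP:
    """Convenience presets for hybrid categories up to second-generation backcross.

    Single flags return minimal pedigrees (the F2-only preset is the
    worked-example pedigree).  All four flags return the combined pedigree
    delivering 1 F1, 2 F2, 1 BC1 and 2 BC2 samples from six founders.  Other
    combinations return the disjoint union of the single-flag presets.
    Backcrosses are toward ``pop_a``.
    """
    flags = [("F1", F1), ("F2", F2), ("BC1", BC1), ("BC2", BC2)]
    wanted = [name for name, on in flags if on]
    if not wanted:
        raise ValueError("at least one of F1, F2, BC1, BC2 must be requested")
    if len(wanted) == 4:
        return _all_categories_gsp(pop_a, pop_b)
    builders = {
        "F1": lambda: f1_gsp(pop_a, pop_b),
        "F2": lambda: f2_gsp(pop_a, pop_b),
        "BC1": lambda: backcross_gsp(1, pop_a, pop_b),
        "BC2": lambda: backcross_gsp(2, pop_a, pop_b),
    }
    if len(wanted) == 1:
        return builders[wanted[0]]()
    return union_gsp(
        [builders[name]() for name in wanted], prefixes=[f"{name}." for name in wanted]
    )


def random_gsp(rng, pops=("A", "B")) -> GSP:
    """A random valid GSP: a disjoint union of randomly parameterised blocks.

    Used for property testing (conservation must hold on any valid GSP).
    Occasionally emits founders whose two haplotypes carry different
    population labels, which segregation supports.
    """
    a, b = pops

    def mixed_pure():
        nodes = [
            GspNode("1", "founder", hap_pops=(a, b)),
            GspNode("2", "founder", hap_pops=(b, a)),
            _nonf(3),
            _samp("s3", 3, 2),
        ]
        edges = [GspEdge(1, 3, 2), GspEdge(2, 3, 2)]
        return GSP(nodes, edges, {"s3": "MIXED"})

    blocks = [
        lambda: pure_gsp(a),
        lambda: pure_gsp(b),
        lambda: f1_gsp(a, b),
        lambda: f2_gsp(a, b),
        lambda: backcross_gsp(1, a, b),
        lambda: backcross_gsp(1, b, a),
        lambda: backcross_gsp(2, a, b),
        lambda: backcross_gsp(3, a, b),
        lambda: bc1xbc2_gsp(a, b),
        lambda: f2xbc1_gsp(a, b),
        lambda: _all_categories_gsp(a, b),
        mixed_pure,
    ]
    k = int(rng.integers(1, 4))
    picks = rng.integers(0, len(blocks), size=k)
    return union_gsp([blocks[i]() for i in picks])
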
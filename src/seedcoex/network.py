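"""Seed-gene neighborhoods, cutoff networks, seed connectivity, orthologs.

Implements the seed-guided network workflow: per-seed candidate neighbor
lists (top-k or GCC-threshold), their union set, the cutoff coexpression
graph, the per-node seed-connectivity statistic k_seed (the count of edges a
node shares with seed genes; "k_PhQ" when the seeds are the phylloquinone
pathway), and ortholog-group collapsing for cross-species comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .gcc import GCCProfile, gcc_pairwise
from .io import ExpressionMatrix, OrthologTable, SeedGeneSet

logger = logging.getLogger("seedcoex")

__all__ = [
    "CandidateSet",
    "ConnectivityTable",
    "extract_candidates",
    "build_network",
    "compute_kphq",
    "collapse_orthologs",
    "export_network",
    "import_network",
]


@dataclass
class CandidateSet:
    """Per-seed ranked neighbor lists and their union.

    ``per_seed`` maps seed id -> list of (gene id, gcc_sym) sorted by
    descending signed correlation, ties broken lexicographically by gene id.
    Seeds and excluded-as-seed genes are eligible members of *other* seeds'
    lists; a seed's self-pair never appears in its own list.
    """

    per_seed: dict[str, list[tuple[str, float]]]
    mode: str
    k: int | None = None
    min_gcc: float | None = None
    union: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.union:
            self.union = {g for lst in self.per_seed.values() for g, _ in lst}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s, rank + 1, g, v)
            for s, lst in self.per_seed.items()
            for rank, (g, v) in enumerate(lst)
        ]
        return pd.DataFrame(rows, columns=["seed_id", "rank", "gene_id", "gcc_sym"])


def extract_candidates(
    profile: GCCProfile,
    mode: str = "top_k",
    k: int = 500,
    min_gcc: float = 0.8,
    use_abs: bool = False,
) -> CandidateSet:
    """Per-seed candidate neighbors: the k most highly correlated genes, or
    all genes with GCC >= ``min_gcc`` (inclusive).

    "Most highly correlated" means signed descending GCC (coexpression, not
    anti-correlation); ``use_abs=True`` ranks by absolute value instead.
    A seed's own self-pair is excluded from its list; other seeds and
    excluded-as-seed genes remain rankable targets.
    """
    if mode not in {"top_k", "threshold"}:
        raise ValueError(f"unknown candidate mode {mode!r}")
    if mode == "top_k" and k <= 0:
        raise ValueError("k must be positive")
    if mode == "threshold" and not (-1.0 < min_gcc <= 1.0):
        raise ValueError("min_gcc must lie in (-1, 1]")
    per_seed: dict[str, list[tuple[str, float]]] = {}
    for s in profile.seed_ids:
        row = profile.gcc_sym.loc[s]
        items = [(g, float(v)) for g, v in row.items() if g != s]
        key = (lambda t: (-abs(t[1]), t[0])) if use_abs else (lambda t: (-t[1], t[0]))
        items.sort(key=key)
        if mode == "top_k":
            per_seed[s] = items[:k]
        else:
            score = (lambda v: abs(v)) if use_abs else (lambda v: v)
            per_seed[s] = [(g, v) for g, v in items if score(v) >= min_gcc]
    return CandidateSet(
        per_seed,
        mode,
        k=k if mode == "top_k" else None,
        min_gcc=min_gcc if mode == "threshold" else None,
    )


def build_network(
    matrix: ExpressionMatrix,
    nodes,
    seeds: SeedGeneSet | None = None,
    cutoff: float = 0.6,
    drop_isolated: bool = True,
    pairwise: pd.DataFrame | None = None,
) -> nx.Graph:
    """Undirected coexpression graph over ``nodes`` with edges where the
    symmetrized GCC >= ``cutoff`` (inclusive).

    Nodes carry a ``role`` attribute (``seed`` or ``candidate``); edges a
    ``weight`` (the gcc_sym value). Isolated nodes are dropped with a logged
    count, so downstream fractions describe the visualized network. A
    precomputed ``pairwise`` matrix may be supplied to skip recomputation.
    """
    nodes = list(dict.fromkeys(nodes))
    if matrix is not None:
        missing = [g for g in nodes if g not in matrix]
        if missing:
            raise KeyError(f"network nodes missing from matrix: {missing}")
    if pairwise is None:
        if matrix is None:
            raise ValueError("either a matrix or a precomputed pairwise table is required")
        pairwise = gcc_pairwise(matrix, nodes)
    seed_ids = set(seeds.seeds) if seeds is not None else set()
    g = nx.Graph(cutoff=cutoff)
    for n in nodes:
        g.add_node(n, role="seed" if n in seed_ids else "candidate")
    vals = pairwise.loc[nodes, nodes].to_numpy()
    iu, ju = np.triu_indices(len(nodes), 1)
    hit = vals[iu, ju] >= cutoff
    for i, j in zip(iu[hit], ju[hit]):
        g.add_edge(nodes[i], nodes[j], weight=float(vals[i, j]))
    if drop_isolated:
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        if isolated:
            logger.warning("WARN isolated_nodes_dropped count=%d", len(isolated))
            g.remove_nodes_from(isolated)
    if g.number_of_edges() == 0:
        logger.warning("WARN empty_network no edge reaches cutoff=%s", cutoff)
    return g


@dataclass
class ConnectivityTable:
    """Per-node seed-edge counts (k_PhQ) and threshold-fraction summaries.

    ``table`` has columns node, role, k_phq and is sorted by descending
    k_phq then node id. Summary fractions are reported both over all
    retained network nodes and over non-seed nodes, since either denominator
    is defensible for a seed-anchored network.
    """

    table: pd.DataFrame
    n_seeds: int

    def k_of(self, node: str) -> int:
        return int(self.table.set_index("node").at[node, "k_phq"])

    def fraction_at_least(self, t: int, denominator: str = "all") -> float:
        """Fraction of nodes with k_phq >= t; denominator 'all' or 'nonseed'."""
        sub = self.table if denominator == "all" else self.table[self.table.role != "seed"]
        if len(sub) == 0:
            return 0.0
        return float((sub.k_phq >= t).mean())

    def fraction_band(self, lo: int, hi: int, denominator: str = "all") -> float:
        """Fraction of nodes with lo <= k_phq <= hi (e.g. the 4-6 band)."""
        sub = self.table if denominator == "all" else self.table[self.table.role != "seed"]
        if len(sub) == 0:
            return 0.0
        return float(((sub.k_phq >= lo) & (sub.k_phq <= hi)).mean())

    def summary(self, thresholds=None) -> pd.DataFrame:
        thresholds = list(thresholds) if thresholds is not None else list(range(1, self.n_seeds + 1))
        rows = [
            (t, self.fraction_at_least(t, "all"), self.fraction_at_least(t, "nonseed"))
            for t in thresholds
        ]
        return pd.DataFrame(rows, columns=["k_phq_min", "fraction_all_nodes", "fraction_nonseed_nodes"])


def compute_kphq(net: nx.Graph, seeds: SeedGeneSet) -> ConnectivityTable:
    """Count, per node, the incident edges whose other endpoint is a seed.

    Seed nodes are included (seed-seed edges count for both endpoints). The
    invariant sum(non-seed k_phq) == #(seed-nonseed edges) always holds.
    """
    seed_ids = set(seeds.seeds)
    rows = []
    for n in net.nodes:
        k = sum(1 for nb in net.neighbors(n) if nb in seed_ids)
        role = "seed" if n in seed_ids else "candidate"
        rows.append((n, role, k))
    table = pd.DataFrame(rows, columns=["node", "role", "k_phq"])
    table = table.sort_values(["k_phq", "node"], ascending=[False, True]).reset_index(drop=True)
    n_seeds = len([n for n in net.nodes if n in seed_ids])
    return ConnectivityTable(table, n_seeds=max(n_seeds, len(seed_ids)))


def collapse_orthologs(
    sets: dict[str, set[str]],
    orthologs: OrthologTable,
    transcriptomes: dict[str, set[str]] | None = None,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Cross-species nonredundant comparison sets via orthogroup collapsing.

    Each species' set is expanded by members of every orthogroup hit in ANY
    species' input set (restricted to that species' filtered transcriptome,
    if given), then reduced to one representative transcript per orthogroup
    per species — the lexicographically smallest id. Genes absent from the
    ortholog table survive as their own singleton groups (``singleton:<id>``).

    Returns (per-species nonredundant sets, orthogroup x species presence
    table of booleans).
    """
    species_maps = {sp: orthologs.species_map(sp) for sp in sets}
    hit_groups: set[str] = set()
    singletons: dict[str, set[str]] = {sp: set() for sp in sets}
    for sp, genes in sets.items():
        gmap = species_maps[sp]
        for gene in genes:
            og = gmap.get(gene)
            if og is None:
                singletons[sp].add(gene)
            else:
                hit_groups.add(og)
    out: dict[str, set[str]] = {}
    presence_rows: dict[str, dict[str, bool]] = {}
    for sp in sets:
        gmap = species_maps[sp]
        allowed = transcriptomes.get(sp) if transcriptomes else None
        members_by_group: dict[str, list[str]] = {}
        for gene, og in gmap.items():
            if og in hit_groups and (allowed is None or gene in allowed):
                members_by_group.setdefault(og, []).append(gene)
        chosen = {min(members) for members in members_by_group.values()}
        out[sp] = chosen | singletons[sp]
        for og in hit_groups:
            presence_rows.setdefault(og, {})[sp] = og in members_by_group
        for gene in singletons[sp]:
            row = presence_rows.setdefault(f"singleton:{gene}", {s: False for s in sets})
            row[sp] = True
    presence = (
        pd.DataFrame.from_dict(presence_rows, orient="index")
        .reindex(columns=list(sets))
        .fillna(False)
        .astype(bool)
        .sort_index()
    )
    presence.index.name = "orthogroup"
    return out, presence


def export_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Write a network as GraphML, SIF or edge TSV (Cytoscape-compatible).

    GraphML and edge TSV round-trip losslessly (roles and weights kept);
    SIF is weightless by design.
    """
    path = str(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(net.edges):
                fh.write(f"{a}\tcoexpressed\t{b}\n")
            for n in sorted(n for n in net.nodes if net.degree(n) == 0):
                fh.write(f"{n}\n")
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("node_a\trole_a\tnode_b\trole_b\tweight\n")
            for a, b in sorted(net.edges):
                fh.write(
                    f"{a}\t{net.nodes[a]['role']}\t{b}\t{net.nodes[b]['role']}\t"
                    f"{net.edges[a, b]['weight']:.10g}\n"
                )
            for n in sorted(n for n in net.nodes if net.degree(n) == 0):
                fh.write(f"{n}\t{net.nodes[n]['role']}\t\t\t\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def import_network(path, format: str = "graphml") -> nx.Graph:
    """Read back a network written by :func:`export_network`."""
    path = str(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return g
    if format == "edge_tsv":
        g = nx.Graph()
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for _, row in df.iterrows():
            g.add_node(row.node_a, role=row.role_a)
            if row.node_b:
                g.add_node(row.node_b, role=row.role_b)
                g.add_edge(row.node_a, row.node_b, weight=float(row.weight))
        return g
    raise ValueError(f"round-trip import supports graphml and edge_tsv, not {format!r}")
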
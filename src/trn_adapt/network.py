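"""Directed TF-TF graph construction and TRN statistics.

A regulon table lists (regulator, target, effect) records.  The TF-TF graph
keeps only genes that themselves act as regulators: there is an edge
``u -> v`` whenever ``u`` regulates ``v`` and ``v`` is a regulator.  Effect
signs are ignored for graph statistics (they matter only for knockout
scoring); parallel records collapse to a single edge and self-loops are
dropped.

The statistics quantify how central a regulator is to cross-TF regulation:
what fraction of ordered TF pairs can reach each other through directed
regulation, how much that fraction drops when a node is deleted, how many
shortest regulator-to-regulator paths pass through a node, and how skewed
the degree distribution of a TF's own regulon subnetwork is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from trn_adapt.errors import DegenerateStatisticError, InvalidSpecError

EFFECTS = ("activation", "repression", "dual")

#: regulon TSV effect symbols <-> canonical effect names
_EFFECT_FROM_SYMBOL = {"+": "activation", "-": "repression", "+-": "dual"}
_SYMBOL_FROM_EFFECT = {v: k for k, v in _EFFECT_FROM_SYMBOL.items()}


@dataclass(frozen=True)
class RegulonTable:
    """Regulator -> target edges with effect signs.

    ``records`` has columns ``regulator``, ``target``, ``effect`` with
    effect in {"activation", "repression", "dual"}.  Duplicate
    (regulator, target, effect) rows are removed on construction.
    Self-records (a gene regulating itself) are allowed in the table; they
    are dropped only at graph build time.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"regulator", "target", "effect"}
        missing = required - set(self.records.columns)
        if missing:
            raise InvalidSpecError(f"regulon table missing columns: {sorted(missing)}")
        bad = set(self.records["effect"]) - set(EFFECTS)
        if bad:
            raise InvalidSpecError(f"unknown effect values: {sorted(bad)}")
        deduped = self.records.drop_duplicates(
            subset=["regulator", "target", "effect"]
        ).reset_index(drop=True)
        object.__setattr__(self, "records", deduped)

    @property
    def regulators(self) -> set[str]:
        return set(self.records["regulator"])

    def targets_of(self, tf: str) -> set[str]:
        return set(self.records.loc[self.records["regulator"] == tf, "target"])

    @classmethod
    def from_tsv(cls, path: str | Path, column_map: Mapping[str, str] | None = None) -> "RegulonTable":
        """Read the regulon TSV dialect: ``regulator<TAB>target<TAB>effect``.

        Effects are encoded ``+`` (activation), ``-`` (repression), ``+-``
        (dual).  ``column_map`` maps this dialect's column names to the
        columns of a foreign export, e.g. a RegulonDB network file.
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        if column_map:
            df = df.rename(columns={v: k for k, v in column_map.items()})
        df = df[["regulator", "target", "effect"]].copy()
        df["effect"] = df["effect"].map(lambda s: _EFFECT_FROM_SYMBOL.get(s, s))
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.records.copy()
        out["effect"] = out["effect"].map(_SYMBOL_FROM_EFFECT)
        out.to_csv(path, sep="\t", index=False)


def build_tf_graph(regulon: RegulonTable) -> nx.DiGraph:
    """Build the directed TF-TF graph from a regulon table.

    Nodes are all genes that appear as a regulator; an edge u->v exists
    when u regulates v and v is itself a regulator.  Self-loops are
    dropped and edge multiplicity (dual + activation records, say)
    collapses to one edge.
    """
    if regulon.records.empty:
        raise InvalidSpecError("cannot build a TF graph from an empty regulon table")
    tfs = regulon.regulators
    g = nx.DiGraph()
    g.add_nodes_from(tfs)
    for reg, tgt in regulon.records[["regulator", "target"]].itertuples(index=False):
        if tgt in tfs and reg != tgt:
            g.add_edge(reg, tgt)
    return g


def component_fraction(g: nx.DiGraph) -> float:
    """Fraction of nodes in the largest weakly connected component."""
    if g.number_of_nodes() == 0:
        raise InvalidSpecError("component_fraction undefined on an empty graph")
    largest = max(nx.weakly_connected_components(g), key=len)
    return len(largest) / g.number_of_nodes()


def pair_connectivity(g: nx.DiGraph) -> float:
    """Fraction of ordered node pairs (u, v), u != v, with a directed path u->v.

    All regulator nodes enter the denominator, including isolated ones.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise InvalidSpecError("pair_connectivity needs at least 2 nodes")
    reachable = sum(len(nx.descendants(g, u)) for u in g.nodes)
    return reachable / (n * (n - 1))


def removal_impact(g: nx.DiGraph, node) -> tuple[float, float]:
    """Pair connectivity after deleting ``node``, and the relative drop.

    Returns ``(new_fraction, relative_drop_percent)`` where the relative
    drop is ``100 * (f0 - f1) / f0``.  Both are returned so that "drops
    by X%" (relative) and "drops to X%" (absolute) statements can be made
    from one call.  The denominator of the recomputed fraction uses the
    remaining node count.
    """
    if node not in g:
        raise InvalidSpecError(f"node {node!r} not in graph")
    if g.number_of_nodes() < 3:
        raise InvalidSpecError("graph minus node must retain >= 2 nodes")
    f0 = pair_connectivity(g)
    h = g.copy()
    h.remove_node(node)
    f1 = pair_connectivity(h)
    if f0 == 0:
        raise DegenerateStatisticError(
            "relative connectivity drop undefined: baseline connectivity is 0"
        )
    return f1, 100.0 * (f0 - f1) / f0


def betweenness(g: nx.DiGraph) -> dict:
    """Directed shortest-path betweenness centrality, normalized by (n-1)(n-2)."""
    if g.number_of_nodes() < 3:
        raise InvalidSpecError("betweenness needs at least 3 nodes")
    return nx.betweenness_centrality(g, normalized=True)


def _bfs_counts(g: nx.DiGraph, source) -> tuple[dict, dict]:
    """Unweighted shortest-path distances and path counts from ``source``."""
    dist = {source: 0}
    sigma = {source: 1}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in g.successors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        frontier = nxt
    return dist, sigma


def shortest_path_through_fraction(g: nx.DiGraph, node, mode: str = "pair") -> float:
    """Fraction of regulator-to-regulator shortest paths passing through ``node``.

    ``mode="pair"`` (default): among ordered pairs (s, t) with s, t != node
    and a directed s->t path, the fraction for which ``node`` lies on at
    least one shortest s->t path.

    ``mode="path"``: shortest paths are counted with multiplicity over those
    pairs; the fraction of them that contain ``node``.
    """
    if node not in g:
        raise InvalidSpecError(f"node {node!r} not in graph")
    if mode not in ("pair", "path"):
        raise InvalidSpecError(f"unknown mode {mode!r}")
    dist_x, sigma_x = _bfs_counts(g, node)
    n_pairs = 0
    n_through = 0.0
    total_paths = 0
    through_paths = 0
    for s in g.nodes:
        if s == node:
            continue
        dist_s, sigma_s = _bfs_counts(g, s)
        for t, d_st in dist_s.items():
            if t == s or t == node:
                continue
            n_pairs += 1
            on_path = (
                node in dist_s
                and t in dist_x
                and dist_s[node] + dist_x[t] == d_st
            )
            total_paths += sigma_s[t]
            if on_path:
                n_through += 1
                through_paths += sigma_s[node] * sigma_x[t]
    if n_pairs == 0:
        raise DegenerateStatisticError("no connected ordered pairs avoid the node")
    if mode == "pair":
        return n_through / n_pairs
    return through_paths / total_paths


def regulon_subnetwork_skewness(
    regulon: RegulonTable, tf: str, adjusted: bool = False
) -> float:
    """Fisher-Pearson skewness of total degree in a TF's regulon subnetwork.

    The subnetwork is induced by {tf} union targets(tf), keeping every
    regulon record among those genes.  Degree is in-degree + out-degree of
    the collapsed directed graph.  The biased (population) g1 coefficient
    is returned by default; ``adjusted=True`` applies the sample-size
    correction.
    """
    members = {tf} | regulon.targets_of(tf)
    if len(members) < 3:
        raise InvalidSpecError(
            f"subnetwork of {tf!r} has {len(members)} nodes; need >= 3"
        )
    sub = nx.DiGraph()
    sub.add_nodes_from(members)
    for reg, tgt in regulon.records[["regulator", "target"]].itertuples(index=False):
        if reg in members and tgt in members and reg != tgt:
            sub.add_edge(reg, tgt)
    degrees = np.array([sub.in_degree(v) + sub.out_degree(v) for v in sub.nodes], dtype=float)
    if np.ptp(degrees) == 0:
        raise DegenerateStatisticError(
            f"degree distribution of {tf!r} subnetwork has zero variance"
        )
    return float(stats.skew(degrees, bias=not adjusted))


def sole_regulator_counts(regulon: RegulonTable) -> dict:
    """Per TF, the number of its targets having exactly one distinct regulator."""
    if regulon.records.empty:
        raise InvalidSpecError("regulon table is empty")
    n_regs = regulon.records.groupby("target")["regulator"].nunique()
    sole_genes = set(n_regs[n_regs == 1].index)
    counts = {tf: 0 for tf in regulon.regulators}
    for tf in counts:
        counts[tf] = len(regulon.targets_of(tf) & sole_genes)
    return counts


def regulators_per_gene(regulon: RegulonTable, gene_set: Iterable[str]) -> list[int]:
    """Distinct-regulator count for each gene in ``gene_set`` (0 if absent)."""
    genes = list(gene_set)
    if not genes:
        raise InvalidSpecError("gene_set is empty")
    n_regs = regulon.records.groupby("target")["regulator"].nunique()
    return [int(n_regs.get(g, 0)) for g in genes]


def network_statistics(regulon: RegulonTable) -> pd.DataFrame:
    """Per-TF summary table: betweenness, subnetwork skewness, sole-regulator count.

    Skewness is NaN where undefined (fewer than 3 subnetwork nodes or zero
    degree variance); betweenness requires >= 3 TF nodes.
    """
    g = build_tf_graph(regulon)
    bc = betweenness(g) if g.number_of_nodes() >= 3 else {v: np.nan for v in g.nodes}
    sole = sole_regulator_counts(regulon)
    rows = []
    for tf in sorted(regulon.regulators):
        try:
            skew = regulon_subnetwork_skewness(regulon, tf)
        except (InvalidSpecError, DegenerateStatisticError):
            skew = np.nan
        rows.append(
            {
                "tf": tf,
                "regulon_size": len(regulon.targets_of(tf)),
                "betweenness": bc.get(tf, np.nan),
                "subnetwork_skewness": skew,
                "sole_regulator_targets": sole.get(tf, 0),
            }
        )
    return pd.DataFrame(rows)
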
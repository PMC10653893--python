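"""Gene-level dereplication and sequence similarity networks.

Dereplication follows the greedy incremental scheme of cd-hit: sequences
sorted longest-first, each joining the best existing representative whose
identity (matches over the shorter sequence, from a global alignment)
meets the threshold, default 99%.

The SSN collapses (near-)identical sequences into nodes and draws an edge
between node representatives whose pairwise aligned-column identity exceeds
``edge_min`` (default 80%); connected components of this graph are the
sequence clusters reported downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import networkx as nx
import pandas as pd

from . import homology
from .homology import DEFAULT_PARAMS, ScoringParams
from .seq_io import SeqRecord


@dataclass
class ClusterSet:
    clusters: list[tuple[str, list[str]]]  # (representative id, member ids incl. rep)
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def representative_ids(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def membership(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters for m in members}


def _identity_short(a: SeqRecord, b: SeqRecord, params: ScoringParams) -> float:
    return homology.align(a, b, params, mode="global").identity_short


def dereplicate(
    seqs: Sequence[SeqRecord],
    threshold: float = 0.99,
    params: ScoringParams = DEFAULT_PARAMS,
    identity_fn: Optional[Callable[[SeqRecord, SeqRecord, ScoringParams], float]] = None,
) -> ClusterSet:
    """Greedy incremental clustering at ``threshold`` identity.

    Deterministic: sort by length descending (ties lexicographic by id);
    each sequence joins the best-identity existing representative at or
    above threshold, else founds its own cluster.  Identical residue
    strings take a fast path and never trigger an alignment.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    ident = identity_fn or _identity_short
    order = sorted(seqs, key=lambda s: (-len(s), s.id))
    reps: list[SeqRecord] = []
    members: dict[str, list[str]] = {}
    for s in order:
        best_rep, best_id = None, -1.0
        for r in reps:
            # identical strings need no alignment; ties keep the first rep
            i = 1.0 if s.upper == r.upper else ident(s, r, params)
            if i > best_id:
                best_rep, best_id = r, i
            if best_id == 1.0:
                break
        if best_rep is not None and best_id >= threshold:
            members[best_rep.id].append(s.id)
        else:
            reps.append(s)
            members[s.id] = [s.id]
    return ClusterSet(
        clusters=[(r.id, members[r.id]) for r in reps],
        threshold=threshold,
    )


@dataclass
class SSNGraph:
    nodes: list[tuple[str, list[str]]]  # (representative id, member ids)
    edges: list[tuple[str, str, float]]  # undirected, identity on each edge
    edge_min: float
    collapse_min: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for rep, mem in self.nodes:
            g.add_node(rep, members=list(mem), size=len(mem))
        for u, v, ident in self.edges:
            g.add_edge(u, v, identity=ident)
        return g


def build_ssn(
    seqs: Sequence[SeqRecord],
    collapse_min: float = 1.00,
    edge_min: float = 0.80,
    params: ScoringParams = DEFAULT_PARAMS,
) -> SSNGraph:
    """Build a sequence similarity network.

    Nodes are clusters from :func:`dereplicate` at ``collapse_min``
    (default: exact duplicates only); an undirected edge joins two node
    representatives when their global aligned-column identity is strictly
    above ``edge_min``.  No self-loops.
    """
    if not (0.0 < edge_min <= collapse_min <= 1.0):
        raise ValueError("require 0 < edge_min <= collapse_min <= 1")
    clusters = dereplicate(seqs, threshold=collapse_min, params=params)
    by_id = {s.id: s for s in seqs}
    reps = [by_id[rep] for rep in clusters.representative_ids]
    edges: list[tuple[str, str, float]] = []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            ident = homology.align(reps[i], reps[j], params, mode="global").pct_identity
            if ident > edge_min:
                edges.append((reps[i].id, reps[j].id, ident))
    return SSNGraph(
        nodes=list(clusters.clusters),
        edges=edges,
        edge_min=edge_min,
        collapse_min=collapse_min,
    )


def components(graph: SSNGraph) -> list[list[str]]:
    """Connected components of the SSN, the 'clusters' reported downstream.

    Sorted by size descending, ties by smallest member id; node ids within
    each component sorted lexicographically.
    """
    g = graph.to_networkx()
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def composition(
    clusters: list[list[str]],
    node_members: dict[str, list[str]],
    annotations: dict[str, dict[str, str]],
    keys: Sequence[str] = ("genus", "gene_type"),
) -> pd.DataFrame:
    """Per-cluster member counts by annotation value.

    ``clusters`` are lists of node ids; ``node_members`` expands each node
    to its member sequence ids; ``annotations`` maps sequence id to a dict
    of annotation values.  Members missing a key count as 'unassigned'.
    Rows are (cluster index, key, value) with a 'count' column; counts per
    cluster sum to the cluster's member total for every key.
    """
    rows = []
    for ci, comp in enumerate(clusters):
        seq_ids = [m for node in comp for m in node_members.get(node, [node])]
        for key in keys:
            tally: dict[str, int] = {}
            for sid in seq_ids:
                val = annotations.get(sid, {}).get(key, "unassigned")
                tally[val] = tally.get(val, 0) + 1
            for val, n in sorted(tally.items()):
                rows.append({"cluster": ci, "key": key, "value": val, "count": n})
    return pd.DataFrame(rows, columns=["cluster", "key", "value", "count"])


def write_edge_list(graph: SSNGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tidentity\n")
        for u, v, ident in graph.edges:
            fh.write(f"{u}\t{v}\t{ident:.6f}\n")


def write_graphml(graph: SSNGraph, path) -> None:
    g = graph.to_networkx()
    for _, data in g.nodes(data=True):
        data["members"] = ",".join(data.pop("members"))
    nx.write_graphml(g, path)
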
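"""Pedigree topology and divergence-time bookkeeping.

A pedigree is a rooted tree of nodes with non-decreasing time stamps
along every root-to-leaf path: generations for mutation-accumulation
lines, years for the branch phylogeny of a tree.  Internally all times
are shifted so the founder sits at t = 1, which is the convention the
divergence model's matrix exponents assume (the ancestor distribution
uses G'^(t_ij - 1)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd

__all__ = [
    "PedigreeError",
    "PedigreeNode",
    "PairTimes",
    "Pedigree",
    "build_pedigree",
    "read_pedigree_tables",
]


class PedigreeError(ValueError):
    """Invalid pedigree structure or query."""


@dataclass(frozen=True)
class PedigreeNode:
    node_id: str
    time: float
    sample_ref: Optional[str] = None

    @property
    def is_sample(self) -> bool:
        return self.sample_ref is not None


@dataclass(frozen=True)
class PairTimes:
    """Times for one unordered sample pair, on the internal scale.

    ``delta_t = (t_i - t_ij) + (t_j - t_ij)`` is the total divergence
    time through the most recent common ancestor and is invariant under
    the internal founder-at-1 shift.
    """

    sample_i: str
    sample_j: str
    t_i: float
    t_j: float
    t_ij: float
    delta_t: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.delta_t is None:
            object.__setattr__(
                self, "delta_t", (self.t_i - self.t_ij) + (self.t_j - self.t_ij)
            )
        if self.t_ij > min(self.t_i, self.t_j) + 1e-9:
            raise PedigreeError("ancestor time exceeds a sample time")
        if self.delta_t < -1e-9:
            raise PedigreeError("negative divergence time")


class Pedigree:
    """Rooted, time-annotated lineage tree with MRCA queries."""

    def __init__(self, nodes: Iterable[PedigreeNode], edges: Iterable[tuple[str, str]]):
        self._nodes: dict[str, PedigreeNode] = {}
        for node in nodes:
            if node.node_id in self._nodes:
                raise PedigreeError(f"duplicate node id {node.node_id!r}")
            self._nodes[node.node_id] = node

        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self._nodes)
        self._parent: dict[str, str] = {}
        for parent, child in edges:
            for nid in (parent, child):
                if nid not in self._nodes:
                    raise PedigreeError(f"edge references unknown node {nid!r}")
            if child in self._parent:
                raise PedigreeError(
                    f"node {child!r} has multiple parents; two-parent designs "
                    "(sibling mating) are not supported"
                )
            self._parent[child] = parent
            self.graph.add_edge(parent, child)

        roots = [nid for nid in self._nodes if nid not in self._parent]
        if not roots:
            raise PedigreeError("no root: the edge list contains a cycle")
        if len(roots) > 1:
            raise PedigreeError(f"multiple roots: {sorted(roots)}")
        self.root = roots[0]

        if not nx.is_directed_acyclic_graph(self.graph):
            raise PedigreeError("cycle detected in pedigree")
        reachable = set(nx.descendants(self.graph, self.root)) | {self.root}
        missing = set(self._nodes) - reachable
        if missing:
            raise PedigreeError(f"nodes unreachable from the founder: {sorted(missing)}")

        for child, parent in self._parent.items():
            if self._nodes[child].time < self._nodes[parent].time - 1e-12:
                raise PedigreeError(
                    f"child {child!r} (t={self._nodes[child].time}) precedes its "
                    f"parent {parent!r} (t={self._nodes[parent].time})"
                )

        self._sample_to_node: dict[str, str] = {}
        for node in self._nodes.values():
            if node.sample_ref is not None:
                if node.sample_ref in self._sample_to_node:
                    raise PedigreeError(f"duplicate sample_ref {node.sample_ref!r}")
                self._sample_to_node[node.sample_ref] = node.node_id

        # internal shift placing the founder at t = 1
        self.founder_time_offset = 1.0 - self._nodes[self.root].time

    # -- basic accessors -------------------------------------------------
    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node(self, node_id: str) -> PedigreeNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise PedigreeError(f"node {node_id!r} not in pedigree") from None

    @property
    def nodes(self) -> Mapping[str, PedigreeNode]:
        return dict(self._nodes)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self._sample_to_node)

    def resolve_sample(self, sample_id: str) -> str:
        """Node id carrying this sample (sample_ref first, node id second)."""
        if sample_id in self._sample_to_node:
            return self._sample_to_node[sample_id]
        if sample_id in self._nodes:
            return sample_id
        raise PedigreeError(f"sample {sample_id!r} not attached to any pedigree node")

    def internal_time(self, node_id: str) -> float:
        return self.node(node_id).time + self.founder_time_offset

    # -- ancestry --------------------------------------------------------
    def ancestor_chain(self, node_id: str) -> list[str]:
        """Node ids from ``node_id`` up to the root (a node is its own ancestor)."""
        chain = [node_id]
        nid = node_id
        while nid in self._parent:
            nid = self._parent[nid]
            chain.append(nid)
        return chain

    def mrca(self, a: str, b: str) -> str:
        self.node(a), self.node(b)
        ancestors_a = set(self.ancestor_chain(a))
        for nid in self.ancestor_chain(b):
            if nid in ancestors_a:
                return nid
        raise PedigreeError(f"no common ancestor of {a!r} and {b!r}")  # unreachable

    def mrca_time(self, a: str, b: str) -> float:
        """Original (unshifted) time of the deepest common ancestor."""
        return self.node(self.mrca(a, b)).time

    # -- pair bookkeeping ------------------------------------------------
    def pair_times(self, samples: Optional[Sequence[str]] = None) -> list[PairTimes]:
        """PairTimes (internal scale) for all unique sample pairs.

        ``samples`` are sample ids (matched against node ``sample_ref``
        first, then against node ids); defaults to all sampled nodes.
        Pairs are ordered lexicographically.
        """
        if samples is None:
            samples = self.sample_ids
        ids = sorted(dict.fromkeys(samples))
        if len(ids) < 2:
            raise PedigreeError("need at least two samples for pairwise times")
        out = []
        for si, sj in itertools.combinations(ids, 2):
            ni, nj = self.resolve_sample(si), self.resolve_sample(sj)
            t_ij = self.internal_time(self.mrca(ni, nj))
            out.append(
                PairTimes(si, sj, self.internal_time(ni), self.internal_time(nj), t_ij)
            )
        return out


def build_pedigree(
    node_table: Union[pd.DataFrame, Iterable[tuple]],
    edge_table: Union[pd.DataFrame, Iterable[tuple[str, str]]],
) -> Pedigree:
    """Build and validate a pedigree from node and edge tables.

    ``node_table`` rows are (node_id, time[, sample_ref]); ``edge_table``
    rows are (parent_id, child_id).  Times may be non-integer.
    """
    if isinstance(node_table, pd.DataFrame):
        cols = {c.lower(): c for c in node_table.columns}
        if "node_id" not in cols or "time" not in cols:
            raise PedigreeError("node table needs columns node_id and time")
        rows = []
        for _, r in node_table.iterrows():
            ref = r[cols["sample_ref"]] if "sample_ref" in cols else None
            if ref is not None and (pd.isna(ref) or str(ref).strip() == ""):
                ref = None
            rows.append((str(r[cols["node_id"]]), float(r[cols["time"]]), ref))
    else:
        rows = []
        for row in node_table:
            row = tuple(row)
            ref = row[2] if len(row) > 2 else None
            rows.append((str(row[0]), float(row[1]), ref))

    nodes = []
    for node_id, time, ref in rows:
        if not pd.notna(time):
            raise PedigreeError(f"non-finite time for node {node_id!r}")
        nodes.append(PedigreeNode(node_id, time, None if ref is None else str(ref)))

    if isinstance(edge_table, pd.DataFrame):
        cols = {c.lower(): c for c in edge_table.columns}
        if "parent_id" not in cols or "child_id" not in cols:
            raise PedigreeError("edge table needs columns parent_id and child_id")
        edges = [
            (str(r[cols["parent_id"]]), str(r[cols["child_id"]]))
            for _, r in edge_table.iterrows()
        ]
    else:
        edges = [(str(p), str(c)) for p, c in edge_table]

    return Pedigree(nodes, edges)


def read_pedigree_tables(node_path, edge_path) -> Pedigree:
    """Read tab-separated node (node_id, time[, sample_ref]) and edge
    (parent_id, child_id) files with header rows."""
    nodes = pd.read_csv(node_path, sep="\t", dtype={0: str})
    edges = pd.read_csv(edge_path, sep="\t", dtype=str)
    return build_pedigree(nodes, edges)
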
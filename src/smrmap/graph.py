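"""Area adjacency graphs for spatial smoothing.

The neighbourhood structure of the intrinsic CAR prior is an undirected
graph over areas (municipalities): areas sharing a border are neighbours,
and extra edges (regular sea routes between islands and the mainland) can
be appended so that no area is left without neighbours.  Adjacency is read
from a GAL-dialect neighbour list; merge maps collapse areas that must be
aggregated (e.g. city wards created mid-period).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AreaGraph",
    "read_neighbor_list",
    "read_edge_csv",
    "read_merge_map",
    "add_edges",
    "validate_graph",
    "aggregate_areas",
]


class GraphParseError(ValueError):
    """Raised when a neighbour-list file violates the GAL dialect."""


@dataclass(frozen=True)
class AreaGraph:
    """Undirected adjacency over uniquely identified areas.

    Parameters
    ----------
    area_ids
        Ordered unique string identifiers; this order fixes the row order
        of every vector/matrix indexed by area.
    adjacency
        Symmetric neighbour sets keyed by area id, no self loops.
    """

    area_ids: tuple[str, ...]
    adjacency: Mapping[str, frozenset[str]]
    component_labels: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        ids = self.area_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate area ids")
        idx = {a: i for i, a in enumerate(ids)}
        for a, nbrs in self.adjacency.items():
            if a not in idx:
                raise ValueError(f"adjacency key {a!r} not in area_ids")
            if a in nbrs:
                raise ValueError(f"self-loop at area {a!r}")
            for b in nbrs:
                if b not in idx:
                    raise ValueError(f"neighbour {b!r} of {a!r} unknown")
                if a not in self.adjacency.get(b, frozenset()):
                    raise ValueError(f"asymmetric edge {a!r}-{b!r}")
        if self.component_labels is None:
            object.__setattr__(
                self, "component_labels", tuple(self._compute_components())
            )

    # -- derived structure -------------------------------------------------
    def _compute_components(self) -> list[int]:
        g = self.to_networkx()
        labels = {}
        for k, comp in enumerate(sorted(nx.connected_components(g), key=min)):
            for a in comp:
                labels[a] = k
        return [labels[a] for a in self.area_ids]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.area_ids)
        for a, nbrs in self.adjacency.items():
            g.add_edges_from((a, b) for b in nbrs)
        return g

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_components(self) -> int:
        return len(set(self.component_labels))

    @property
    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.area_ids)}

    def degrees(self) -> np.ndarray:
        return np.array([len(self.adjacency[a]) for a in self.area_ids])

    def edges(self) -> list[tuple[str, str]]:
        """Unordered edges, each reported once with endpoints sorted."""
        out = set()
        for a, nbrs in self.adjacency.items():
            for b in nbrs:
                out.add((a, b) if a < b else (b, a))
        return sorted(out)

    def edge_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as parallel integer-index arrays (i < j)."""
        idx = self.index
        pairs = [(idx[a], idx[b]) for a, b in self.edges()]
        if not pairs:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        arr = np.array(pairs, dtype=int)
        return arr[:, 0], arr[:, 1]

    @classmethod
    def from_edges(
        cls, area_ids: Sequence[str], edges: Iterable[tuple[str, str]]
    ) -> "AreaGraph":
        adj: dict[str, set[str]] = {str(a): set() for a in area_ids}
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                continue
            adj[a].add(b)
            adj[b].add(a)
        return cls(
            tuple(str(a) for a in area_ids),
            {a: frozenset(s) for a, s in adj.items()},
        )


def read_neighbor_list(path: str | Path) -> AreaGraph:
    """Read a GAL-dialect neighbour file.

    Format: a header line holding the area count, then for each area one
    line ``<id> <n_neighbours>`` followed by one line listing the
    neighbour ids (literal ids, not ordinals).  Asymmetric entries are
    symmetrised with a warning; unknown neighbour ids and duplicate area
    ids are errors.
    """
    path = Path(path)
    tokens_per_line = [
        (lineno, line.split())
        for lineno, line in enumerate(path.read_text().splitlines(), start=1)
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not tokens_per_line:
        raise GraphParseError(f"{path}: empty file")
    header = tokens_per_line[0][1]
    try:
        n = int(header[-1])  # tolerate leading "0" of classic GAL headers
    except ValueError as exc:
        raise GraphParseError(f"{path}: bad header {header!r}") from exc

    order: list[str] = []
    raw_adj: dict[str, list[str]] = {}
    lines = tokens_per_line[1:]
    pos = 0
    while pos < len(lines):
        lineno, toks = lines[pos]
        if len(toks) != 2:
            raise GraphParseError(f"{path}:{lineno}: expected '<id> <count>'")
        area, k = toks[0], int(toks[1])
        if area in raw_adj:
            raise GraphParseError(f"{path}:{lineno}: duplicate area id {area!r}")
        pos += 1
        nbrs: list[str] = []
        if k > 0:
            if pos >= len(lines):
                raise GraphParseError(f"{path}:{lineno}: missing neighbour line")
            nlineno, ntoks = lines[pos]
            if len(ntoks) != k:
                raise GraphParseError(
                    f"{path}:{nlineno}: expected {k} neighbour ids, got {len(ntoks)}"
                )
            nbrs = ntoks
            pos += 1
        order.append(area)
        raw_adj[area] = nbrs
    if len(order) != n:
        raise GraphParseError(f"{path}: header says {n} areas, found {len(order)}")

    known = set(order)
    for lineno_area, nbrs in raw_adj.items():
        for b in nbrs:
            if b not in known:
                raise GraphParseError(
                    f"{path}: area {lineno_area!r} lists unknown neighbour {b!r}"
                )
    # symmetrise (union), warn on one-sided entries
    for a in order:
        for b in raw_adj[a]:
            if a not in raw_adj[b]:
                logger.warning(
                    "neighbour list asymmetric: %s lists %s but not vice versa; "
                    "symmetrising",
                    a,
                    b,
                )
    edges = {tuple(sorted((a, b))) for a in order for b in raw_adj[a] if a != b}
    return AreaGraph.from_edges(order, edges)


def write_neighbor_list(graph: AreaGraph, path: str | Path) -> None:
    """Write the GAL dialect that :func:`read_neighbor_list` reads."""
    lines = [str(graph.n_areas)]
    for a in graph.area_ids:
        nbrs = sorted(graph.adjacency[a])
        lines.append(f"{a} {len(nbrs)}")
        if nbrs:
            lines.append(" ".join(nbrs))
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_csv(path: str | Path) -> list[tuple[str, str]]:
    """Extra-edge list (e.g. sea routes) with columns area_a,area_b."""
    df = pd.read_csv(path, dtype=str)
    missing = {"area_a", "area_b"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [(r.area_a, r.area_b) for r in df.itertuples()]


def read_merge_map(path: str | Path) -> dict[str, str]:
    """Merge-map CSV with columns area_id,group_id."""
    df = pd.read_csv(path, dtype=str)
    missing = {"area_id", "group_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["area_id"].duplicated().any():
        dup = df.loc[df["area_id"].duplicated(), "area_id"].iloc[0]
        raise ValueError(f"{path}: area {dup!r} appears in more than one group")
    return dict(zip(df["area_id"], df["group_id"]))


def add_edges(graph: AreaGraph, extra: Iterable[tuple[str, str]]) -> AreaGraph:
    """Return a graph containing the union of existing and extra edges.

    Adding an already-present edge is a no-op; endpoints must exist.
    """
    known = set(graph.area_ids)
    new_edges = set(graph.edges())
    for a, b in extra:
        a, b = str(a), str(b)
        for endpoint in (a, b):
            if endpoint not in known:
                raise KeyError(f"edge endpoint {endpoint!r} not in graph")
        if a == b:
            raise ValueError(f"self-loop edge {a!r}-{b!r} not allowed")
        new_edges.add((a, b) if a < b else (b, a))
    return AreaGraph.from_edges(graph.area_ids, new_edges)


def validate_graph(graph: AreaGraph) -> dict:
    """Structural report: isolated areas, components, degree distribution."""
    deg = graph.degrees()
    isolated = [a for a, d in zip(graph.area_ids, deg) if d == 0]
    if isolated:
        logger.warning("graph has %d isolated area(s): %s", len(isolated), isolated[:10])
    values, counts = np.unique(deg, return_counts=True)
    return {
        "n_areas": graph.n_areas,
        "n_edges": len(graph.edges()),
        "n_components": graph.n_components,
        "isolated_areas": isolated,
        "degree_min": int(deg.min()) if len(deg) else 0,
        "degree_max": int(deg.max()) if len(deg) else 0,
        "degree_distribution": {int(v): int(c) for v, c in zip(values, counts)},
    }


def aggregate_areas(
    graph: AreaGraph,
    merge_map: Mapping[str, str],
    additive_tables: Sequence[pd.DataFrame] = (),
    area_col: str = "area_id",
) -> tuple[AreaGraph, list[pd.DataFrame]]:
    """Merge groups of areas into single aggregated areas.

    ``merge_map`` sends member area ids to a group id (the merged area's
    new id); areas not mentioned keep their identity.  The merged area's
    neighbour set is the union of its members' neighbours minus internal
    edges.  Each additive table (rows keyed by ``area_col``, all other
    numeric columns summed; non-numeric grouping columns preserved) is
    re-aggregated accordingly, preserving column totals exactly.
    """
    known = set(graph.area_ids)
    unknown = [a for a in merge_map if a not in known]
    if unknown:
        raise KeyError(f"merge map references unknown area(s): {unknown[:5]}")
    for g in set(merge_map.values()):
        # a group id may reuse a member's id, but not silently absorb an
        # unrelated existing area
        if g in known and merge_map.get(g) != g and g not in merge_map:
            raise ValueError(
                f"group id {g!r} is an existing area that is not part of the group"
            )

    def new_id(a: str) -> str:
        return merge_map.get(a, a)

    new_order: list[str] = []
    seen = set()
    for a in graph.area_ids:
        na = new_id(a)
        if na not in seen:
            seen.add(na)
            new_order.append(na)
    new_edges = set()
    for a, b in graph.edges():
        na, nb = new_id(a), new_id(b)
        if na != nb:
            new_edges.add((na, nb) if na < nb else (nb, na))
    merged_graph = AreaGraph.from_edges(new_order, new_edges)

    merged_tables = []
    for df in additive_tables:
        out = df.copy()
        out[area_col] = out[area_col].map(new_id)
        group_cols = [area_col] + [
            c
            for c in out.columns
            if c != area_col and not pd.api.types.is_numeric_dtype(out[c])
        ]
        out = out.groupby(group_cols, as_index=False, sort=False).sum()
        merged_tables.append(out)
    return merged_graph, merged_tables
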
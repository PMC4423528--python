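"""Enzymatic Step Sequences (ESS): linear EC-code paths through a map.

A metabolic map is linearized by building one breadth-first-search tree
per *initialization node* and emitting one sequence per root-to-leaf
branch of each tree.  An initialization node is the metabolic input of a
pathway: either (i) none of its substrates is produced by another enzyme
in the same map, or (ii) at least one substrate arrives from another map
and the node has at most two neighbors in the graph.

Each step of a sequence is the three-level EC code of the enzyme, so an
ESS reads like ``5.3.1,2.7.1,4.1.2``.
"""

from __future__ import annotations

import csv
import logging
import os
from collections import deque
from dataclasses import dataclass, field

import pandas as pd

from .ec import ECCode
from .kgml import MetabolicMap

logger = logging.getLogger(__name__)

STEP_SEPARATOR = ","


@dataclass(frozen=True, slots=True)
class ESS:
    """One enzymatic step sequence with its provenance."""

    ess_id: str
    map_id: str
    root_id: str
    steps: tuple[ECCode, ...]

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise ValueError("an ESS has at least one step")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def text(self) -> str:
        return STEP_SEPARATOR.join(str(ec) for ec in self.steps)


@dataclass
class ESSCollection:
    """A set of ESS drawn from one or more maps; ids are unique."""

    items: list[ESS]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.ess_id for e in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ess_id in collection")
        if not self.provenance:
            seen: list[str] = []
            for e in self.items:
                if e.map_id not in seen:
                    seen.append(e.map_id)
            self.provenance = seen

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def by_id(self, ess_id: str) -> ESS:
        for e in self.items:
            if e.ess_id == ess_id:
                return e
        raise KeyError(ess_id)

    def write_tsv(self, path_or_buf) -> None:
        close = False
        if isinstance(path_or_buf, (str, os.PathLike)):
            fh = open(path_or_buf, "w", newline="")
            close = True
        else:
            fh = path_or_buf
        try:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["ess_id", "map_id", "root_id", "steps"])
            for e in self.items:
                w.writerow([e.ess_id, e.map_id, e.root_id, e.text])
        finally:
            if close:
                fh.close()

    @classmethod
    def read_tsv(cls, path_or_buf) -> "ESSCollection":
        close = False
        if isinstance(path_or_buf, (str, os.PathLike)):
            fh = open(path_or_buf, newline="")
            close = True
        else:
            fh = path_or_buf
        try:
            r = csv.reader(fh, delimiter="\t")
            header = next(r)
            if header[:4] != ["ess_id", "map_id", "root_id", "steps"]:
                raise ValueError(f"unexpected ESS TSV header: {header}")
            items = [
                ESS(
                    ess_id=row[0],
                    map_id=row[1],
                    root_id=row[2],
                    steps=tuple(
                        ECCode.parse(tok) for tok in row[3].split(STEP_SEPARATOR)
                    ),
                )
                for row in r
                if row
            ]
        finally:
            if close:
                fh.close()
        return cls(items=items)


def find_initialization_nodes(metabolic_map: MetabolicMap) -> set[str]:
    """BFS roots: criterion (i) no substrate produced in-map by another
    enzyme, or (ii) an external-map substrate and <= 2 graph neighbors."""
    producers: dict[str, set[str]] = {}
    for node in metabolic_map.nodes.values():
        for c in node.outputs():
            producers.setdefault(c, set()).add(node.node_id)
    roots: set[str] = set()
    for node in metabolic_map.nodes.values():
        crit_i = not any(
            producers.get(c, set()) - {node.node_id} for c in node.substrates
        )
        crit_ii = bool(node.external_substrates) and len(
            metabolic_map.neighbors(node.node_id)
        ) <= 2
        if crit_i or crit_ii:
            roots.add(node.node_id)
    return roots


@dataclass
class BFSTree:
    """BFS tree over the directed edges of a map, children in ascending
    node_id order for determinism."""

    root: str
    parent: dict[str, str | None]
    children: dict[str, list[str]]

    def leaves(self) -> list[str]:
        return sorted(n for n, ch in self.children.items() if not ch)

    def path_to(self, node_id: str) -> list[str]:
        path = [node_id]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])  # type: ignore[arg-type]
        return path[::-1]


def build_bfs_tree(metabolic_map: MetabolicMap, root: str) -> BFSTree:
    metabolic_map.node(root)
    parent: dict[str, str | None] = {root: None}
    children: dict[str, list[str]] = {root: []}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in sorted(metabolic_map.out_neighbors(u)):
            if v not in parent:
                parent[v] = u
                children[v] = []
                children[u].append(v)
                queue.append(v)
    return BFSTree(root=root, parent=parent, children=children)


def extract_ess(metabolic_map: MetabolicMap, min_length: int = 1) -> list[ESS]:
    """One ESS per root-to-leaf branch of each initialization-node BFS
    tree; steps are the EC codes along the path.  Exact duplicates
    (same map, root and step string) are collapsed."""
    roots = find_initialization_nodes(metabolic_map)
    if not roots:
        logger.warning("map %s: no initialization nodes, no ESS", metabolic_map.map_id)
        return []
    out: list[ESS] = []
    for root in sorted(roots):
        tree = build_bfs_tree(metabolic_map, root)
        seen: set[str] = set()
        idx = 0
        for leaf in tree.leaves():
            steps = tuple(
                metabolic_map.nodes[n].ec for n in tree.path_to(leaf)
            )
            if len(steps) < min_length:
                continue
            key = STEP_SEPARATOR.join(str(ec) for ec in steps)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                ESS(
                    ess_id=f"{metabolic_map.map_id}|{root}|{idx}",
                    map_id=metabolic_map.map_id,
                    root_id=root,
                    steps=steps,
                )
            )
            idx += 1
    return out


def extract_ess_collection(maps, min_length: int = 1) -> ESSCollection:
    """Run :func:`extract_ess` over several maps into one collection."""
    items: list[ESS] = []
    prov: list[str] = []
    for m in maps:
        items.extend(extract_ess(m, min_length=min_length))
        prov.append(m.map_id)
    return ESSCollection(items=items, provenance=prov)


def ess_statistics(collection: ESSCollection) -> pd.DataFrame:
    """Per-map count, mean length and sample SD of length (SD = 0 for a
    single sequence)."""
    if len(collection) == 0:
        raise ValueError("empty ESS collection")
    frame = pd.DataFrame(
        {"map_id": [e.map_id for e in collection], "length": [len(e) for e in collection]}
    )
    stats = (
        frame.groupby("map_id")["length"]
        .agg(n_ess="count", mean_length="mean", sd_length=lambda s: s.std(ddof=1))
        .reset_index()
    )
    stats["sd_length"] = stats["sd_length"].fillna(0.0)
    return stats
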
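"""KGML metabolic-map parsing and the directed enzyme graph.

A KEGG pathway (KGML dialect) is turned into a graph whose nodes are
enzymes and whose directed edges connect two enzymes that share a
compound: ``u -> v`` via compound ``c`` exists when ``c`` is a product of
``u`` and a substrate of ``v``.  Reaction reversibility is honoured: a
reversible enzyme offers both its substrate and product sets on either
side of the rule.

Entries of type ``enzyme``/``gene``/``ortholog`` that carry EC annotations
become nodes (one node per distinct EC code on the entry); entries without
any EC annotation are dropped with a logged warning.  Compounds shared
with other maps (KGML ``maplink`` relations) are recorded per node as
*external substrates*, which feed the initialization-node criteria used
for sequence extraction.
"""

from __future__ import annotations

import logging
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import NamedTuple

from .ec import ECCode

logger = logging.getLogger(__name__)

_ENZYME_ENTRY_TYPES = {"enzyme", "gene", "ortholog"}


class KGMLError(ValueError):
    """Base class for KGML input problems."""


class KGMLParseError(KGMLError):
    """Malformed XML or structurally unusable KGML."""


class EmptyMapError(KGMLError):
    """A well-formed KGML document with zero enzyme-like entries."""


class Edge(NamedTuple):
    source: str
    target: str
    compound: str


@dataclass(frozen=True, slots=True)
class EnzymeNode:
    """One enzyme (one EC code) of a metabolic map."""

    node_id: str
    ec: ECCode
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False
    #: substrates annotated as arriving from another metabolic map
    external_substrates: frozenset[str] = field(default=frozenset())

    def inputs(self) -> frozenset[str]:
        """Compounds this node can consume (both sides if reversible)."""
        return self.substrates | self.products if self.reversible else self.substrates

    def outputs(self) -> frozenset[str]:
        """Compounds this node can produce (both sides if reversible)."""
        return self.substrates | self.products if self.reversible else self.products


def build_edges(nodes: dict[str, EnzymeNode]) -> list[Edge]:
    """Shared-compound rule with reversibility.

    Base edge (u, v, c) when c is in outputs(u) and inputs(v) (a
    reversible enzyme offers both its compound sets on either side);
    additionally, a step involving a reversible enzyme can be walked
    backwards, so every base edge incident to a reversible node also
    contributes its reverse.  No self-loops; deterministically sorted.
    """
    consumers: dict[str, list[str]] = {}
    for v in nodes.values():
        for c in v.inputs():
            consumers.setdefault(c, []).append(v.node_id)
    edges: set[Edge] = set()
    for u in nodes.values():
        for c in u.outputs():
            for vid in consumers.get(c, ()):
                if vid != u.node_id:
                    edges.add(Edge(u.node_id, vid, c))
    reverses = {
        Edge(e.target, e.source, e.compound)
        for e in edges
        if nodes[e.source].reversible or nodes[e.target].reversible
    }
    return sorted(edges | reverses)


@dataclass
class MetabolicMap:
    """A directed enzyme graph parsed from one KGML pathway."""

    map_id: str
    name: str
    nodes: dict[str, EnzymeNode]
    edges: list[Edge]

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: str) -> EnzymeNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown node {node_id!r} in map {self.map_id}") from None

    def out_neighbors(self, node_id: str) -> set[str]:
        self.node(node_id)
        return {e.target for e in self.edges if e.source == node_id}

    def in_neighbors(self, node_id: str) -> set[str]:
        self.node(node_id)
        return {e.source for e in self.edges if e.target == node_id}

    def neighbors(self, node_id: str) -> set[str]:
        """Undirected adjacency (union of in- and out-neighbors)."""
        return self.out_neighbors(node_id) | self.in_neighbors(node_id)


def graph_neighbors(metabolic_map: MetabolicMap, node_id: str) -> set[str]:
    """Set of nodes adjacent to ``node_id`` regardless of edge direction."""
    return metabolic_map.neighbors(node_id)


def _read_xml(source) -> ET.Element:
    if isinstance(source, (str, os.PathLike)) and os.path.exists(os.fspath(source)):
        label = os.fspath(source)
        try:
            return ET.parse(source).getroot()
        except ET.ParseError as exc:
            raise KGMLParseError(f"{label}: malformed KGML XML ({exc})") from exc
    if isinstance(source, str):
        try:
            return ET.fromstring(source)
        except ET.ParseError as exc:
            raise KGMLParseError(f"<string>: malformed KGML XML ({exc})") from exc
    try:
        return ET.parse(source).getroot()
    except ET.ParseError as exc:
        raise KGMLParseError(f"malformed KGML XML ({exc})") from exc


def parse_kgml(source) -> MetabolicMap:
    """Parse a KGML document (path, XML string, or file-like object).

    Raises
    ------
    KGMLParseError
        for malformed XML.
    EmptyMapError
        for well-formed KGML with no enzyme-like entries.
    """
    root = _read_xml(source)
    if root.tag != "pathway":
        raise KGMLParseError(f"root element is <{root.tag}>, expected <pathway>")
    map_id = root.get("number") or root.get("name") or "map"
    title = root.get("title", "")

    reactions: dict[str, tuple[bool, list[str], list[str]]] = {}
    for rx in root.findall("reaction"):
        rname = rx.get("name", "")
        reversible = rx.get("type") == "reversible"
        subs = [s.get("name", "") for s in rx.findall("substrate")]
        prods = [p.get("name", "") for p in rx.findall("product")]
        for token in rname.split():
            reactions[token] = (reversible, subs, prods)

    compound_entries: dict[str, str] = {}
    map_entry_ids: set[str] = set()
    enzyme_entries: list[tuple[str, list[ECCode], list[str]]] = []
    n_enzyme_like = 0
    for entry in root.findall("entry"):
        etype = entry.get("type", "")
        eid = entry.get("id", "")
        ename = entry.get("name", "")
        if etype == "compound":
            compound_entries[eid] = ename
        elif etype == "map":
            map_entry_ids.add(eid)
        elif etype in _ENZYME_ENTRY_TYPES:
            n_enzyme_like += 1
            from .ec import parse_ec_tokens

            ecs = parse_ec_tokens(ename)
            if not ecs:
                logger.warning(
                    "map %s: entry %s (%r) has no EC annotation; dropped",
                    map_id, eid, ename,
                )
                continue
            enzyme_entries.append((eid, ecs, entry.get("reaction", "").split()))
    if n_enzyme_like == 0:
        raise EmptyMapError(f"map {map_id}: no enzyme entries in KGML document")

    # maplink relations mark compounds shared with other maps
    external_by_entry: dict[str, set[str]] = {}
    ecrel_pairs: list[tuple[str, str, str]] = []
    for rel in root.findall("relation"):
        rtype = rel.get("type", "")
        e1, e2 = rel.get("entry1", ""), rel.get("entry2", "")
        cpds = [
            compound_entries.get(st.get("value", ""), st.get("value", ""))
            for st in rel.findall("subtype")
            if st.get("name") == "compound"
        ]
        if rtype == "maplink":
            for endpoint in (e1, e2):
                if endpoint in map_entry_ids:
                    continue
                external_by_entry.setdefault(endpoint, set()).update(c for c in cpds if c)
        elif rtype == "ECrel":
            for c in cpds or [""]:
                ecrel_pairs.append((e1, e2, c))

    nodes: dict[str, EnzymeNode] = {}
    for eid, ecs, rnames in enzyme_entries:
        subs: set[str] = set()
        prods: set[str] = set()
        reversible = False
        for rn in rnames:
            if rn in reactions:
                rev, s, p = reactions[rn]
                reversible = reversible or rev
                subs.update(s)
                prods.update(p)
        external = frozenset(external_by_entry.get(eid, set()) & subs)
        for ec in ecs:
            nid = f"{eid}:{ec}"
            nodes[nid] = EnzymeNode(
                node_id=nid,
                ec=ec,
                substrates=frozenset(subs),
                products=frozenset(prods),
                reversible=reversible,
                external_substrates=external,
            )

    edges = build_edges(nodes)
    if not edges and not reactions and ecrel_pairs:
        # fallback: no reaction data at all, use ECrel relations
        by_entry: dict[str, list[str]] = {}
        for nid in nodes:
            by_entry.setdefault(nid.split(":", 1)[0], []).append(nid)
        fallback: set[Edge] = set()
        for e1, e2, c in ecrel_pairs:
            for u in by_entry.get(e1, ()):
                for v in by_entry.get(e2, ()):
                    if u != v:
                        fallback.add(Edge(u, v, c))
                        fallback.add(Edge(v, u, c))
        edges = sorted(fallback)

    return MetabolicMap(map_id=map_id, name=title, nodes=nodes, edges=edges)


def write_kgml(metabolic_map: MetabolicMap, path=None) -> str:
    """Serialize a map back to minimal KGML (entries + reactions +
    maplink relations for external substrates).

    Entry ids are zero-padded and assigned in sorted node order, so a
    parse -> write -> parse round trip is stable.  Returns the XML text;
    also writes it to ``path`` when given.
    """
    node_ids = sorted(metabolic_map.nodes)
    width = max(3, len(str(len(node_ids))))
    entry_of = {nid: f"{i + 1:0{width}d}" for i, nid in enumerate(node_ids)}
    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name="path:{metabolic_map.map_id}" number="{metabolic_map.map_id}"'
        f' title="{metabolic_map.name}">',
    ]
    for nid in node_ids:
        node = metabolic_map.nodes[nid]
        eid = entry_of[nid]
        lines.append(
            f'  <entry id="{eid}" name="ec:{node.ec}" type="enzyme" reaction="rn:R{eid}"/>'
        )
    for nid in node_ids:
        node = metabolic_map.nodes[nid]
        eid = entry_of[nid]
        rtype = "reversible" if node.reversible else "irreversible"
        lines.append(f'  <reaction name="rn:R{eid}" type="{rtype}">')
        for c in sorted(node.substrates):
            lines.append(f'    <substrate name="{c}"/>')
        for c in sorted(node.products):
            lines.append(f'    <product name="{c}"/>')
        lines.append("  </reaction>")
    external = sorted(
        {c for n in metabolic_map.nodes.values() for c in n.external_substrates}
    )
    if external:
        map_eid = f"M{len(node_ids) + 1:0{width}d}"
        lines.append(f'  <entry id="{map_eid}" name="path:external" type="map"/>')
        cpd_eid = {}
        for i, c in enumerate(external):
            cid = f"C{len(node_ids) + 2 + i:0{width}d}"
            cpd_eid[c] = cid
            lines.append(f'  <entry id="{cid}" name="{c}" type="compound"/>')
        for nid in node_ids:
            node = metabolic_map.nodes[nid]
            for c in sorted(node.external_substrates):
                lines.append(
                    f'  <relation entry1="{map_eid}" entry2="{entry_of[nid]}" type="maplink">'
                )
                lines.append(f'    <subtype name="compound" value="{cpd_eid[c]}"/>')
                lines.append("  </relation>")
    lines.append("</pathway>")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_edge_list(metabolic_map: MetabolicMap, path_or_buf) -> None:
    """Inspection TSV: map_id, source node, target node, shared compound."""
    close = False
    if isinstance(path_or_buf, (str, os.PathLike)):
        fh = open(path_or_buf, "w")
        close = True
    else:
        fh = path_or_buf
    try:
        fh.write("map_id\tfrom\tto\tcompound\n")
        for e in metabolic_map.edges:
            fh.write(f"{metabolic_map.map_id}\t{e.source}\t{e.target}\t{e.compound}\n")
    finally:
        if close:
            fh.close()
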
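"""Bipartite sRNA-target regulatory network assembly and export.

Nodes are sRNAs on one side and target transcripts on the other; an edge is
one validated (sRNA, transcript) interaction, annotated with whether its
best cleavage evidence was canonical (sRNA position 10/11), its t-plot
category, and — when expression contrasts are supplied — whether the target
gene shows contrary expression.  A gene-collapsed view is derived on demand
(isoforms of one gene merge into one node), never stored independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .degradome import ValidatedInteraction
from .expression import ExpressionContrast
from .io_core import strip_isoform_suffix, write_network


@dataclass
class RegulatoryNetwork:
    srna_nodes: set[str] = field(default_factory=set)
    transcript_nodes: set[str] = field(default_factory=set)
    #: (srna_id, transcript_id) -> attrs {canonical, category, contrary?}
    edges: dict[tuple[str, str], dict] = field(default_factory=dict)

    @property
    def gene_nodes(self) -> set[str]:
        return {strip_isoform_suffix(t) for t in self.transcript_nodes}

    def degree(self, node: str) -> int:
        return sum(1 for s, t in self.edges if s == node or t == node)

    def shared_target_hubs(self, min_regulators: int = 2) -> dict[str, list[str]]:
        """Transcripts regulated by >= min_regulators distinct sRNAs."""
        regulators: dict[str, set[str]] = {}
        for s, t in self.edges:
            regulators.setdefault(t, set()).add(s)
        return {t: sorted(r) for t, r in sorted(regulators.items()) if len(r) >= min_regulators}

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph()
        for s in sorted(self.srna_nodes):
            graph.add_node(s, type="srna")
        for t in sorted(self.transcript_nodes):
            graph.add_node(t, type="transcript")
        for (s, t), attrs in sorted(self.edges.items()):
            graph.add_edge(s, t, **attrs)
        return graph

    def write(self, path, format: str = "GraphML") -> None:
        write_network([(s, t, attrs) for (s, t), attrs in self.edges.items()], path, format)


def build_network(
    interactions: Sequence[ValidatedInteraction],
    contrasts: Sequence[ExpressionContrast] | None = None,
    srna_compartments: Mapping[str, str] | None = None,
) -> RegulatoryNetwork:
    """Assemble validated interactions into a bipartite network.

    Multiple validated sites between one (sRNA, transcript) pair collapse to
    a single edge keeping the best (lowest-category, then canonical-first)
    evidence attributes.  ``contrasts`` attach a ``contrary`` edge attribute
    via the target's gene and the sRNA's compartment; without contrasts the
    attribute is absent.
    """
    contrary_by_key: dict[tuple[str, str], bool] = {}
    if contrasts:
        for c in contrasts:
            if not c.missing:
                contrary_by_key[(c.gene_id, c.srna_compartment)] = c.contrary

    net = RegulatoryNetwork()
    for v in interactions:
        key = (v.srna_id, v.transcript_id)
        e = v.best_evidence
        attrs = {"canonical": e.canonical, "category": e.category}
        if contrasts and srna_compartments is not None:
            gene = strip_isoform_suffix(v.transcript_id)
            ckey = (gene, srna_compartments[v.srna_id])
            if ckey in contrary_by_key:
                attrs["contrary"] = contrary_by_key[ckey]
        existing = net.edges.get(key)
        if existing is None or (attrs["category"], not attrs["canonical"]) < (
            existing["category"],
            not existing["canonical"],
        ):
            net.edges[key] = attrs
        net.srna_nodes.add(v.srna_id)
        net.transcript_nodes.add(v.transcript_id)
    return net
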
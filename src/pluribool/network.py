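"""Signed directed gene-regulatory networks: data model, TSV I/O, statistics,
pruning and integration of curated with inferred topologies.

A :class:`SignedNetwork` is a set of annotated gene nodes plus at most one
signed interaction per ordered (source, target) pair.  Signs are activation
(``+``), inhibition (``-``) or undefined (``?``); undefined signs occur in
curated networks where the literature reports a link but not its mode, and
are resolved during integration with an inferred topology.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

# gene categories (node annotation)
CATEGORIES = ("pluripotency_tf", "differentiation", "epigenetic", "other")

# interaction signs
ACTIVATION = "activation"
INHIBITION = "inhibition"
UNDEFINED = "undefined"
SIGNS = (ACTIVATION, INHIBITION, UNDEFINED)

_SIGN_TO_CHAR = {ACTIVATION: "+", INHIBITION: "-", UNDEFINED: "?"}
_CHAR_TO_SIGN = {v: k for k, v in _SIGN_TO_CHAR.items()}

# interaction provenance
CURATED = "curated"
INFERRED = "inferred"
INTEGRATED = "integrated"


@dataclass(frozen=True)
class GeneNode:
    """A gene (or gene product) in the network with its functional category."""

    name: str
    category: str = "other"

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for gene {self.name!r}; "
                f"expected one of {CATEGORIES}"
            )


@dataclass(frozen=True)
class Interaction:
    """A signed directed regulatory edge. Self-interactions are permitted."""

    source: str
    target: str
    sign: str = ACTIVATION
    provenance: str = CURATED

    def __post_init__(self):
        if self.sign not in SIGNS:
            raise ValueError(f"bad sign {self.sign!r}; expected one of {SIGNS}")
        if self.provenance not in (CURATED, INFERRED, INTEGRATED):
            raise ValueError(f"bad provenance {self.provenance!r}")

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target

    @property
    def sign_char(self) -> str:
        return _SIGN_TO_CHAR[self.sign]


class SignedNetwork:
    """Annotated gene nodes plus signed directed interactions.

    Interactions are keyed by ordered (source, target) pair; every endpoint
    must resolve to a node.  Iteration orders are deterministic
    (lexicographic) so that serialization is byte-stable.
    """

    def __init__(self, nodes: Iterable[GeneNode] = (),
                 interactions: Iterable[Interaction] = ()):
        self._nodes: dict[str, GeneNode] = {}
        self._edges: dict[tuple[str, str], Interaction] = {}
        for node in nodes:
            self.add_node(node)
        for inter in interactions:
            self.add_interaction(inter)

    # -- construction -----------------------------------------------------
    def add_node(self, node: GeneNode) -> None:
        prev = self._nodes.get(node.name)
        if prev is not None and prev != node:
            raise ValueError(f"conflicting duplicate node {node.name!r}")
        self._nodes[node.name] = node

    def add_interaction(self, inter: Interaction) -> None:
        for endpoint in (inter.source, inter.target):
            if endpoint not in self._nodes:
                raise ValueError(
                    f"interaction endpoint {endpoint!r} is not a node"
                )
        key = (inter.source, inter.target)
        if key in self._edges:
            raise ValueError(
                f"duplicate interaction for pair {inter.source}->{inter.target}"
            )
        self._edges[key] = inter

    # -- access -----------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return sorted(self._nodes)

    @property
    def nodes(self) -> list[GeneNode]:
        return [self._nodes[g] for g in self.genes]

    @property
    def interactions(self) -> list[Interaction]:
        return [self._edges[k] for k in sorted(self._edges)]

    def node(self, name: str) -> GeneNode:
        return self._nodes[name]

    def category(self, name: str) -> str:
        return self._nodes[name].category

    def has_interaction(self, source: str, target: str) -> bool:
        return (source, target) in self._edges

    def interaction(self, source: str, target: str) -> Interaction:
        return self._edges[(source, target)]

    def regulators(self, target: str) -> list[Interaction]:
        """Incoming interactions of ``target``, sorted by source symbol."""
        return [e for e in self.interactions if e.target == target]

    def __contains__(self, gene: str) -> bool:
        return gene in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return (f"SignedNetwork({len(self._nodes)} nodes, "
                f"{len(self._edges)} interactions)")

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(self.nodes, self.interactions)


@dataclass(frozen=True)
class StatsReport:
    """Topology summary: counts recomputable from the network itself."""

    n_nodes: int
    n_edges: int                  # non-self edges
    n_self_loops: int
    n_self_activations: int
    n_self_inhibitions: int
    n_interactions: int           # edges + self-loops
    nodes_per_category: Mapping[str, int]

    def __post_init__(self):
        assert self.n_interactions == self.n_edges + self.n_self_loops


def network_stats(network: SignedNetwork) -> StatsReport:
    """Node / edge / auto-regulatory-loop counts, split by sign and category."""
    edges = [e for e in network.interactions if not e.is_self_loop]
    loops = [e for e in network.interactions if e.is_self_loop]
    per_cat = {c: 0 for c in CATEGORIES}
    for node in network.nodes:
        per_cat[node.category] += 1
    return StatsReport(
        n_nodes=len(network),
        n_edges=len(edges),
        n_self_loops=len(loops),
        n_self_activations=sum(1 for e in loops if e.sign == ACTIVATION),
        n_self_inhibitions=sum(1 for e in loops if e.sign == INHIBITION),
        n_interactions=len(edges) + len(loops),
        nodes_per_category=per_cat,
    )


# ---------------------------------------------------------------------------
# I/O: 3-column TSV edge list (source, sign, target) and annotation TSV
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, str]:
    """Read a ``gene<TAB>category`` TSV; unknown categories map to ``other``."""
    annotations: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "gene":  # header
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene<TAB>category")
            gene, category = parts[0], parts[1]
            if category not in CATEGORIES:
                warnings.warn(
                    f"{path}:{lineno}: unknown category {category!r} for "
                    f"{gene}; mapping to 'other'"
                )
                category = "other"
            annotations[gene] = category
    return annotations


def read_network(edge_file: str | Path,
                 annotation_file: str | Path) -> SignedNetwork:
    """Load a signed network from an edge TSV and an annotation TSV.

    The edge file has columns ``source``, ``sign`` (+/-/?), ``target``;
    comment lines start with ``#``.  Every annotated gene becomes a node even
    if it has no edges; edge endpoints missing from the annotations are added
    with category ``other`` and a warning.  A duplicated (source, target)
    pair is a hard error.
    """
    annotations = read_annotations(annotation_file)
    net = SignedNetwork()
    for gene in sorted(annotations):
        net.add_node(GeneNode(gene, annotations[gene]))

    with open(edge_file) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "source":  # header
                continue
            if len(parts) < 3:
                raise ValueError(
                    f"{edge_file}:{lineno}: expected source<TAB>sign<TAB>target"
                )
            source, sign_char, target = parts[0], parts[1], parts[2]
            if sign_char not in _CHAR_TO_SIGN:
                raise ValueError(
                    f"{edge_file}:{lineno}: bad sign {sign_char!r} "
                    "(expected +, - or ?)"
                )
            provenance = parts[3] if len(parts) > 3 else CURATED
            for endpoint in (source, target):
                if endpoint not in net:
                    warnings.warn(
                        f"{edge_file}:{lineno}: {endpoint!r} missing from "
                        "annotations; adding with category 'other'"
                    )
                    net.add_node(GeneNode(endpoint, "other"))
            if net.has_interaction(source, target):
                raise ValueError(
                    f"{edge_file}:{lineno}: duplicate interaction "
                    f"{source}->{target}"
                )
            net.add_interaction(
                Interaction(source, target, _CHAR_TO_SIGN[sign_char],
                            provenance)
            )
    return net


def write_network(network: SignedNetwork, edge_file: str | Path,
                  annotation_file: str | Path) -> None:
    """Write edge and annotation TSVs, sorted so output is byte-stable."""
    with open(edge_file, "w") as fh:
        fh.write("source\tsign\ttarget\tprovenance\n")
        for e in network.interactions:  # already sorted by (source, target)
            fh.write(f"{e.source}\t{e.sign_char}\t{e.target}\t{e.provenance}\n")
    with open(annotation_file, "w") as fh:
        fh.write("gene\tcategory\n")
        for node in network.nodes:
            fh.write(f"{node.name}\t{node.category}\n")


# ---------------------------------------------------------------------------
# Pruning and integration
# ---------------------------------------------------------------------------

def prune_to_genes(network: SignedNetwork, keep: Iterable[str]) -> SignedNetwork:
    """Induced subnetwork on ``keep``: kept nodes plus interactions whose
    both endpoints are kept.  Provenance is preserved."""
    keep_set = set(keep)
    unknown = sorted(keep_set - set(network.genes))
    if unknown:
        raise ValueError(f"genes not in network: {', '.join(unknown)}")
    pruned = SignedNetwork(
        (n for n in network.nodes if n.name in keep_set),
        (e for e in network.interactions
         if e.source in keep_set and e.target in keep_set),
    )
    return pruned


@dataclass
class IntegrationReport:
    """What integration changed: new edges, resolved signs, kept conflicts."""

    added: list[Interaction] = field(default_factory=list)
    sign_resolved: list[Interaction] = field(default_factory=list)
    conflicts: list[tuple[Interaction, Interaction]] = field(default_factory=list)


def integrate_networks(original: SignedNetwork, inferred: SignedNetwork,
                       ) -> tuple[SignedNetwork, IntegrationReport]:
    """Union of the curated topology with an inferred one.

    Edges present only in ``inferred`` are added with provenance
    ``inferred``.  Curated edges with undefined sign adopt the inferred sign
    for the same ordered pair.  When both networks define the sign and they
    differ, the original sign is kept and the conflict reported (not fatal).
    """
    if set(original.genes) != set(inferred.genes):
        raise ValueError("networks must share the same gene universe")
    report = IntegrationReport()
    merged = SignedNetwork(original.nodes)
    for e in original.interactions:
        if e.sign == UNDEFINED and inferred.has_interaction(e.source, e.target):
            inf = inferred.interaction(e.source, e.target)
            if inf.sign != UNDEFINED:
                e = replace(e, sign=inf.sign)
                report.sign_resolved.append(e)
        merged.add_interaction(e)
    for e in inferred.interactions:
        if not original.has_interaction(e.source, e.target):
            novel = replace(e, provenance=INFERRED)
            merged.add_interaction(novel)
            report.added.append(novel)
        else:
            orig = original.interaction(e.source, e.target)
            if (orig.sign != UNDEFINED and e.sign != UNDEFINED
                    and orig.sign != e.sign):
                report.conflicts.append((orig, e))
                logger.warning(
                    "sign conflict %s->%s: keeping original %s over inferred %s",
                    e.source, e.target, orig.sign, e.sign,
                )
    return merged, report
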
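"""Stage co-regulatory networks: assembly from FFLs, degree-based hub
detection, cross-stage common modules and stage comparison, plus GraphML /
SIF / TSV interchange for Cytoscape.

A stage network is exactly the union of its FFLs' edges: three edges per
TF-FFL or miRNA-FFL, four per composite. Hubs are regulators whose
out-edge proportion (out-degree / degree) strictly exceeds the mean of
their class, capped at five per class; when the strict filter eliminates
every node of a class (single node, or all proportions tied) the
implementation falls back to plain out-degree ranking and logs that it did.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from ._ids import GENE, MIRNA, TF
from .catalog import InteractionCatalog
from .ffl import COMPOSITE, FFLInstance, MIRNA_FFL, TF_FFL

logger = logging.getLogger(__name__)

#: directed edge: (source, target, regulator_class of the source)
Edge = tuple[str, str, str]

_SIF_RELATIONS = {TF: "tf_regulates", MIRNA: "mirna_represses"}
_SIF_CLASSES = {rel: cls for cls, rel in _SIF_RELATIONS.items()}


@dataclass
class StageNetwork:
    """Typed directed graph of one stage's co-regulatory relations."""

    stage: str
    nodes: dict[str, str] = field(default_factory=dict)   # id -> node class
    edges: set[Edge] = field(default_factory=set)

    def add_edge(self, source: str, source_class: str,
                 target: str, target_class: str) -> None:
        self.nodes.setdefault(source, source_class)
        self.nodes.setdefault(target, target_class)
        self.edges.add((source, target, source_class))

    def nodes_of_class(self, node_class: str) -> set[str]:
        return {n for n, c in self.nodes.items() if c == node_class}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(stage=self.stage)
        for node, cls in sorted(self.nodes.items()):
            g.add_node(node, node_class=cls)
        for src, tgt, rc in sorted(self.edges):
            g.add_edge(src, tgt, regulator_class=rc)
        return g


@dataclass
class HubReport:
    """The top-ranked regulators and TF–miRNA pairs of one stage network."""

    stage: str
    hub_tfs: list[str]
    hub_mirnas: list[str]
    hub_pairs: list[tuple[str, str, int, bool]]  # (tf, mirna, n_common, mutual)

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.stage, "TF", t, "", "") for t in self.hub_tfs]
        rows += [(self.stage, "miRNA", m, "", "") for m in self.hub_mirnas]
        rows += [(self.stage, "pair", f"{t}|{m}", n, mut)
                 for t, m, n, mut in self.hub_pairs]
        return pd.DataFrame(
            rows, columns=["stage", "hub_class", "identifier",
                           "n_common_targets", "mutual"])


@dataclass
class CommonModule:
    """Edges (with induced nodes) shared by every listed stage network."""

    stages: frozenset[str]
    nodes: dict[str, str]
    edges: set[Edge]


@dataclass
class StageComparison:
    """Shared vs stage-specific regulators and shared target genes."""

    stage_a: str
    stage_b: str
    shared_regulators: set[str]
    specific_to_a: set[str]
    specific_to_b: set[str]
    shared_targets: set[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ident in sorted(self.shared_regulators):
            rows.append((ident, "regulator", "shared"))
        for ident in sorted(self.specific_to_a):
            rows.append((ident, "regulator", "a_only"))
        for ident in sorted(self.specific_to_b):
            rows.append((ident, "regulator", "b_only"))
        for ident in sorted(self.shared_targets):
            rows.append((ident, "gene", "shared"))
        return pd.DataFrame(
            rows, columns=["identifier", "class", "membership"])


# ---------------------------------------------------------------------------
# assembly and summary


def build_network(ffls: Iterable[FFLInstance], stage: str) -> StageNetwork:
    """Union of all constituent FFL edges, nodes classed by role."""
    net = StageNetwork(stage=stage)
    for ffl in ffls:
        net.add_edge(ffl.tf, TF, ffl.gene, GENE)
        net.add_edge(ffl.mirna, MIRNA, ffl.gene, GENE)
        if ffl.ffl_type in (TF_FFL, COMPOSITE):
            net.add_edge(ffl.tf, TF, ffl.mirna, MIRNA)
        if ffl.ffl_type in (MIRNA_FFL, COMPOSITE):
            net.add_edge(ffl.mirna, MIRNA, ffl.tf, TF)
    return net


def network_summary(network: StageNetwork) -> tuple[int, int, int, int]:
    """(n_edges, n_mirna, n_tf, n_gene) — the per-stage network characteristics."""
    return (
        network.n_edges,
        len(network.nodes_of_class(MIRNA)),
        len(network.nodes_of_class(TF)),
        len(network.nodes_of_class(GENE)),
    )


# ---------------------------------------------------------------------------
# hubs


def _degrees(network: StageNetwork) -> dict[str, tuple[int, int]]:
    """node -> (in_degree, out_degree) within the network."""
    deg = {n: [0, 0] for n in network.nodes}
    for src, tgt, _ in network.edges:
        deg[src][1] += 1
        deg[tgt][0] += 1
    return {n: (i, o) for n, (i, o) in deg.items()}


def _class_hubs(network: StageNetwork, node_class: str,
                deg: dict[str, tuple[int, int]], max_hubs: int) -> list[str]:
    members = sorted(network.nodes_of_class(node_class))
    members = [n for n in members if sum(deg[n]) > 0]
    if not members:
        return []
    frac = {n: deg[n][1] / (deg[n][0] + deg[n][1]) for n in members}
    mean_frac = sum(frac.values()) / len(members)
    hubs = [n for n in members if frac[n] > mean_frac]
    if not hubs:
        logger.warning(
            "stage %s: out-fraction filter removed every %s node "
            "(degenerate mean %.3f); falling back to out-degree ranking",
            network.stage, node_class, mean_frac)
        hubs = members
    hubs.sort(key=lambda n: (-deg[n][1], -(deg[n][0] + deg[n][1]), n))
    return hubs[:max_hubs]


def find_hub_regulators(network: StageNetwork, max_hubs: int = 5,
                        ) -> tuple[list[str], list[str]]:
    """Hub TFs and miRNAs of a stage network.

    A hub's out-edge proportion strictly exceeds the mean of its node class;
    candidates are ranked by out-degree (desc), then total degree (desc),
    then identifier, and truncated to ``max_hubs``.
    """
    deg = _degrees(network)
    return (
        _class_hubs(network, TF, deg, max_hubs),
        _class_hubs(network, MIRNA, deg, max_hubs),
    )


def find_hub_pairs(ffls: Sequence[FFLInstance], max_hubs: int = 5,
                   catalog: InteractionCatalog | None = None,
                   ) -> list[tuple[str, str, int, bool]]:
    """Hub TF–miRNA pairs ranked by number of common FFL target genes.

    A pair qualifies when its distinct-common-target count strictly exceeds
    the mean over all co-occurring pairs; ties break lexicographically.
    ``mutual`` marks reciprocal TF↔miRNA regulation (read from the catalog
    when given, otherwise inferred from composite motif membership).
    """
    targets: dict[tuple[str, str], set[str]] = {}
    mutual: dict[tuple[str, str], bool] = {}
    for ffl in ffls:
        pair = (ffl.tf, ffl.mirna)
        targets.setdefault(pair, set()).add(ffl.gene)
        mutual[pair] = mutual.get(pair, False) or ffl.ffl_type == COMPOSITE
    if catalog is not None:
        for tf, mirna in targets:
            mutual[(tf, mirna)] = ((tf, mirna) in catalog.tf_to_mirna
                                   and (mirna, tf) in catalog.mirna_to_tf)
    if not targets:
        return []
    counts = {pair: len(g) for pair, g in targets.items()}
    mean_count = sum(counts.values()) / len(counts)
    hubs = [pair for pair, c in counts.items() if c > mean_count]
    if not hubs:
        logger.warning(
            "common-target filter removed every TF-miRNA pair "
            "(degenerate mean %.3f); falling back to count ranking",
            mean_count)
        hubs = list(counts)
    hubs.sort(key=lambda p: (-counts[p], p))
    return [(tf, mirna, counts[(tf, mirna)], mutual[(tf, mirna)])
            for tf, mirna in hubs[:max_hubs]]


def hub_report(network: StageNetwork, ffls: Sequence[FFLInstance],
               max_hubs: int = 5,
               catalog: InteractionCatalog | None = None) -> HubReport:
    hub_tfs, hub_mirnas = find_hub_regulators(network, max_hubs)
    return HubReport(
        stage=network.stage,
        hub_tfs=hub_tfs,
        hub_mirnas=hub_mirnas,
        hub_pairs=find_hub_pairs(ffls, max_hubs, catalog),
    )


# ---------------------------------------------------------------------------
# cross-stage


def common_modules(networks: Sequence[StageNetwork], min_stages: int = 2,
                   ) -> list[CommonModule]:
    """Edge-set intersections shared across stage subsets.

    Each edge is assigned to the maximal set of stages containing it; one
    module is reported per distinct maximal stage set of size >= min_stages.
    """
    if len(networks) < 2:
        raise ValueError("need at least two stage networks")
    stage_edges = {net.stage: net.edges for net in networks}
    node_class: dict[str, str] = {}
    for net in networks:
        node_class.update(net.nodes)

    membership: dict[Edge, frozenset[str]] = {}
    for stage, edges in stage_edges.items():
        for edge in edges:
            membership[edge] = membership.get(edge, frozenset()) | {stage}

    by_stages: dict[frozenset[str], set[Edge]] = {}
    for edge, stages in membership.items():
        if len(stages) >= min_stages:
            by_stages.setdefault(stages, set()).add(edge)

    modules = []
    for stages, edges in by_stages.items():
        nodes = {n: node_class[n]
                 for edge in edges for n in (edge[0], edge[1])}
        modules.append(CommonModule(stages=stages, nodes=nodes, edges=edges))
    modules.sort(key=lambda m: (-len(m.stages), sorted(m.stages)))
    return modules


def compare_stages(net_a: StageNetwork, net_b: StageNetwork,
                   ) -> StageComparison:
    """Shared and stage-specific regulators, and shared targeted genes."""
    reg_a = net_a.nodes_of_class(TF) | net_a.nodes_of_class(MIRNA)
    reg_b = net_b.nodes_of_class(TF) | net_b.nodes_of_class(MIRNA)
    targeted_a = {tgt for _, tgt, _ in net_a.edges
                  if net_a.nodes.get(tgt) == GENE}
    targeted_b = {tgt for _, tgt, _ in net_b.edges
                  if net_b.nodes.get(tgt) == GENE}
    return StageComparison(
        stage_a=net_a.stage,
        stage_b=net_b.stage,
        shared_regulators=reg_a & reg_b,
        specific_to_a=reg_a - reg_b,
        specific_to_b=reg_b - reg_a,
        shared_targets=targeted_a & targeted_b,
    )


# ---------------------------------------------------------------------------
# interchange formats


def write_network(network: StageNetwork, path: str | Path,
                  fmt: str = "graphml") -> None:
    """Write a stage network as ``graphml``, ``sif`` or ``tsv``.

    GraphML carries ``node_class`` and ``regulator_class`` attributes and
    round-trips exactly; SIF uses the relation tokens ``tf_regulates`` /
    ``mirna_represses``.
    """
    path = Path(path)
    if not network.edges and not network.nodes:
        warnings.warn(f"writing empty network for stage {network.stage}")
    if fmt == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    elif fmt == "sif":
        lines = [f"{src}\t{_SIF_RELATIONS[rc]}\t{tgt}"
                 for src, tgt, rc in sorted(network.edges)]
        linked = {n for s, t, _ in network.edges for n in (s, t)}
        lines += sorted(network.nodes.keys() - linked)
        path.write_text("".join(line + "\n" for line in lines),
                        encoding="utf-8")
    elif fmt == "tsv":
        df = pd.DataFrame(
            [(src, rc, tgt, network.nodes[tgt])
             for src, tgt, rc in sorted(network.edges)],
            columns=["source", "source_class", "target", "target_class"])
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def read_network(path: str | Path, fmt: str = "graphml",
                 stage: str = "") -> StageNetwork:
    """Read a network written by :func:`write_network`.

    SIF carries no explicit node classes; they are recovered from the
    relation tokens (sources of ``tf_regulates`` are TFs, sources of
    ``mirna_represses`` are miRNAs, pure targets are genes), which is exact
    for FFL-union networks where every regulator has an outgoing edge.
    """
    path = Path(path)
    net = StageNetwork(stage=stage)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        for node, data in g.nodes(data=True):
            net.nodes[str(node)] = data["node_class"]
        for src, tgt, data in g.edges(data=True):
            net.edges.add((str(src), str(tgt), data["regulator_class"]))
        net.stage = stage or g.graph.get("stage", "")
    elif fmt == "sif":
        targets: set[str] = set()
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                net.nodes.setdefault(parts[0], GENE)
                continue
            src, rel, tgt = parts[0], parts[1], parts[2]
            try:
                rc = _SIF_CLASSES[rel]
            except KeyError:
                raise ValueError(f"unknown SIF relation: {rel!r}") from None
            net.nodes[src] = rc
            targets.add(tgt)
            net.edges.add((src, tgt, rc))
        for tgt in targets:
            net.nodes.setdefault(tgt, GENE)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for row in df.itertuples(index=False):
            net.add_edge(row.source, row.source_class,
                         row.target, row.target_class)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")
    return net
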
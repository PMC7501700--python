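"""Global drug-target network assembly and descriptive statistics.

The bipartite network joins experimentally known DTIs with diffusion
predictions (provenance retained per edge; a known edge wins when the
same pair occurs in both).  Degree statistics, herb-level overlap
matrices, common-target cores and induced subnetworks follow the usual
network-pharmacology readouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .datamodel import DTIRecord, HerbFormula, KNOWN, PREDICTED

log = logging.getLogger(__name__)

__all__ = [
    "DTINetwork",
    "DegreeSummary",
    "OverlapMatrix",
    "assemble_network",
    "degree_summary",
    "herb_overlap",
    "common_targets",
    "extract_subnetwork",
    "high_degree_nodes",
    "round_half_up_1dp",
]


def round_half_up_1dp(x: float) -> float:
    """Report-style rounding: half-up to one decimal place."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class DTINetwork:
    """Bipartite compound-target network with per-edge provenance."""

    def __init__(self, edges: dict[tuple[str, str], tuple[str, Optional[float]]]) -> None:
        self._edges = dict(edges)
        self._compound_adj: dict[str, set[str]] = {}
        self._target_adj: dict[str, set[str]] = {}
        for (c, t) in self._edges:
            self._compound_adj.setdefault(c, set()).add(t)
            self._target_adj.setdefault(t, set()).add(c)

    @property
    def compounds(self) -> set[str]:
        return set(self._compound_adj)

    @property
    def targets(self) -> set[str]:
        return set(self._target_adj)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edge_count(self, provenance: Optional[str] = None) -> int:
        if provenance is None:
            return len(self._edges)
        return sum(1 for prov, _ in self._edges.values() if prov == provenance)

    def targets_of(self, compound_id: str) -> set[str]:
        return set(self._compound_adj.get(compound_id, set()))

    def compounds_of(self, target: str) -> set[str]:
        return set(self._target_adj.get(target, set()))

    def has_edge(self, compound_id: str, target: str) -> bool:
        return (compound_id, target) in self._edges

    def provenance(self, compound_id: str, target: str) -> str:
        return self._edges[(compound_id, target)][0]

    def to_records(self) -> list[DTIRecord]:
        return [
            DTIRecord(c, t, prov, score)
            for (c, t), (prov, score) in sorted(self._edges.items())
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"compound_id": c, "gene_symbol": t, "provenance": prov, "score": score}
                for (c, t), (prov, score) in sorted(self._edges.items())
            ]
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.compounds, bipartite="compound")
        g.add_nodes_from(self.targets, bipartite="target")
        for (c, t), (prov, score) in self._edges.items():
            g.add_edge(c, t, provenance=prov, score=score)
        return g

    def filtered(self, provenance: str) -> "DTINetwork":
        return DTINetwork(
            {pair: v for pair, v in self._edges.items() if v[0] == provenance}
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DTINetwork) and self._edges == other._edges


def assemble_network(
    known: Iterable[DTIRecord], predicted: Iterable[DTIRecord] = ()
) -> DTINetwork:
    """Union of known and predicted DTIs; known wins on collision."""
    edges: dict[tuple[str, str], tuple[str, Optional[float]]] = {}
    n_pred = 0
    for r in predicted:
        edges[(r.compound_id, r.target)] = (PREDICTED, r.score)
        n_pred += 1
    n_known = 0
    for r in known:
        edges[(r.compound_id, r.target)] = (KNOWN, None)
        n_known += 1
    net = DTINetwork(edges)
    log.info(
        "assembled network: %d edges (%d known records, %d predicted records, "
        "%d collisions resolved to known)",
        net.n_edges, n_known, n_pred,
        n_known + n_pred - net.n_edges,
    )
    return net


@dataclass(frozen=True)
class DegreeSummary:
    """Mean degrees and per-node degree table of a bipartite DTI network.

    ``mean_compound_degree`` is edges / compounds (the average number of
    targets a compound hits); ``mean_target_degree`` is edges / targets.
    Rounded values use half-up at one decimal, full precision is kept in
    the exact fields.
    """

    n_edges: int
    n_compounds: int
    n_targets: int
    mean_compound_degree_exact: float
    mean_target_degree_exact: float
    degree_table: pd.DataFrame  # columns: node, side, degree
    top_compounds: tuple[tuple[str, int], ...]
    top_targets: tuple[tuple[str, int], ...]

    @property
    def mean_compound_degree(self) -> float:
        return round_half_up_1dp(self.mean_compound_degree_exact)

    @property
    def mean_target_degree(self) -> float:
        return round_half_up_1dp(self.mean_target_degree_exact)


def degree_summary(network: DTINetwork, top_n: int = 10) -> DegreeSummary:
    if network.n_edges == 0:
        raise ValueError("cannot summarise an empty network")
    c_deg = {c: len(network.targets_of(c)) for c in network.compounds}
    t_deg = {t: len(network.compounds_of(t)) for t in network.targets}
    table = pd.DataFrame(
        [{"node": c, "side": "compound", "degree": d} for c, d in sorted(c_deg.items())]
        + [{"node": t, "side": "target", "degree": d} for t, d in sorted(t_deg.items())]
    )
    by_deg = lambda items: tuple(sorted(items, key=lambda kv: (-kv[1], kv[0]))[:top_n])
    return DegreeSummary(
        n_edges=network.n_edges,
        n_compounds=len(c_deg),
        n_targets=len(t_deg),
        mean_compound_degree_exact=network.n_edges / len(c_deg),
        mean_target_degree_exact=network.n_edges / len(t_deg),
        degree_table=table,
        top_compounds=by_deg(c_deg.items()),
        top_targets=by_deg(t_deg.items()),
    )


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric herb x herb shared-item counts; diagonal = set sizes."""

    herb_ids: tuple[str, ...]
    item: str  # "compounds" | "targets"
    counts: pd.DataFrame  # herb x herb integer frame

    def overlap(self, a: str, b: str) -> int:
        return int(self.counts.loc[a, b])


def _herb_items(
    herb: HerbFormula, item: str, network: Optional[DTINetwork]
) -> set[str]:
    if item == "compounds":
        return set(herb.compound_ids)
    if item == "targets":
        if network is None:
            raise ValueError("item='targets' requires a network")
        out: set[str] = set()
        for cid in herb.compound_ids:
            out |= network.targets_of(cid)
        return out
    raise ValueError(f"unknown overlap item {item!r}")


def herb_overlap(
    herbs: Sequence[HerbFormula],
    item: str = "compounds",
    network: Optional[DTINetwork] = None,
) -> OverlapMatrix:
    """Pairwise shared-compound or shared-target counts between herbs.

    A herb's target set is the union of its member compounds' network
    neighbours.
    """
    ids = [h.herb_id for h in herbs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate herb ids")
    sets = {h.herb_id: _herb_items(h, item, network) for h in herbs}
    counts = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in ids] for a in ids],
        index=ids,
        columns=ids,
        dtype=int,
    )
    return OverlapMatrix(tuple(ids), item, counts)


def common_targets(herbs: Sequence[HerbFormula], network: DTINetwork) -> set[str]:
    """Genes targeted by every herb (intersection over herb target sets)."""
    if len(herbs) < 2:
        raise ValueError("need at least two herbs for a common-target core")
    sets = [_herb_items(h, "targets", network) for h in herbs]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def extract_subnetwork(network: DTINetwork, compound_ids: Iterable[str]) -> DTINetwork:
    """Induced bipartite subgraph of the listed compounds and their targets."""
    ids = set(compound_ids)
    if not ids:
        raise ValueError("empty compound id list")
    unknown = ids - network.compounds
    if unknown:
        raise ValueError(f"compound id(s) not in network: {sorted(unknown)}")
    return DTINetwork(
        {
            (c, t): (network.provenance(c, t), network._edges[(c, t)][1])
            for c in ids
            for t in network.targets_of(c)
        }
    )


def high_degree_nodes(
    network: DTINetwork,
    side: str,
    threshold: int,
    provenance: Optional[str] = None,
) -> list[tuple[str, int]]:
    """Nodes with degree strictly above ``threshold``.

    ``provenance`` restricts the counted edges to known or predicted
    only; the default counts both, matching how published top-degree
    lists mix them.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    net = network if provenance is None else network.filtered(provenance)
    if side == "compound":
        deg = {c: len(net.targets_of(c)) for c in net.compounds}
    elif side == "target":
        deg = {t: len(net.compounds_of(t)) for t in net.targets}
    else:
        raise ValueError(f"side must be compound|target, got {side!r}")
    hits = [(n, d) for n, d in deg.items() if d > threshold]
    return sorted(hits, key=lambda kv: (-kv[1], kv[0]))
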
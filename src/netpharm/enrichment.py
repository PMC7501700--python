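"""Compound-disease prioritisation and gene-set over-representation.

The statistical model asks, per compound, whether the compound's target
profile is enriched for disease genes within a fixed gene universe: a
one-sided (right-tail) Fisher's exact test on the 2x2 table

    a = |targets(c) ∩ disease|        b = |targets(c) \\ disease|
    c = |disease ∩ universe \\ T(c)|   d = |universe \\ (T(c) ∪ disease)|

followed by Benjamini-Hochberg adjustment over all tested compounds.
A generic hypergeometric over-representation analysis (ORA) against GMT
annotation collections uses the same machinery per gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneSet, normalize_gene
from .network import DTINetwork

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EnrichmentRecord",
    "OraRecord",
    "fisher_right_tail",
    "bh_adjust",
    "compound_disease_enrichment",
    "ora_hypergeometric",
    "CompoundDiseasePrioritizer",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts with fixed margins; total = universe size."""

    a: int  # targets ∩ disease
    b: int  # targets \ disease
    c: int  # disease ∩ universe \ targets
    d: int  # neither

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_right_tail(table: ContingencyTable) -> float:
    """One-sided Fisher's exact p in the enrichment direction.

    With margins fixed, the first cell follows a hypergeometric law:
    p = P(X >= a) for X ~ Hypergeom(N = total, K = a + c, n = a + b).
    """
    N = table.total
    if N == 0:
        return 1.0
    return float(hypergeom.sf(table.a - 1, N, table.a + table.c, table.a + table.b))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


@dataclass(frozen=True)
class EnrichmentRecord:
    compound_id: str
    table: ContingencyTable
    p: float
    q: float
    significant: bool


@dataclass(frozen=True)
class OraRecord:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    q: float


def _build_universe(
    network: DTINetwork, disease: GeneSet, universe_policy: str
) -> set[str]:
    if universe_policy == "network":
        return network.targets
    if universe_policy == "union":
        return network.targets | disease.genes
    raise ValueError(f"unknown universe policy {universe_policy!r}")


def compound_disease_enrichment(
    network: DTINetwork,
    disease: GeneSet,
    universe_policy: str = "network",
    q_star: float = 0.05,
) -> list[EnrichmentRecord]:
    """Fisher/BH disease-enrichment screen over every networked compound.

    The default universe is the network's own target set; compounds with
    no targets inside the universe are excluded from testing (they
    cannot be enriched and would distort the BH family).  Output is
    sorted by compound id; BH is applied across all tested compounds.
    """
    if network.n_edges == 0:
        raise ValueError("empty network")
    universe = _build_universe(network, disease, universe_policy)
    dis = disease.genes & universe
    if not dis:
        raise ValueError("disease gene set does not intersect the universe")

    ids, tables, pvals = [], [], []
    for cid in sorted(network.compounds):
        targets = network.targets_of(cid) & universe
        if not targets:
            continue
        a = len(targets & dis)
        b = len(targets - dis)
        c = len(dis - targets)
        d = len(universe) - a - b - c
        table = ContingencyTable(a, b, c, d)
        ids.append(cid)
        tables.append(table)
        pvals.append(fisher_right_tail(table))
    qvals = bh_adjust(pvals)
    return [
        EnrichmentRecord(cid, tab, p, q, q < q_star)
        for cid, tab, p, q in zip(ids, tables, pvals, qvals)
    ]


def ora_hypergeometric(
    query_genes: Iterable[str],
    annotations: Sequence[GeneSet],
    universe: Iterable[str],
    q_star: float = 0.05,
) -> list[OraRecord]:
    """Upper-tail hypergeometric ORA of a gene list against GMT sets.

    Query genes outside the universe are dropped with a warning.  Output
    is sorted by adjusted q then set id.
    """
    uni = {normalize_gene(g) for g in universe}
    if not uni:
        raise ValueError("empty universe")
    query = {normalize_gene(g) for g in query_genes}
    dropped = query - uni
    if dropped:
        log.warning("%d query gene(s) outside the universe dropped: %s",
                    len(dropped), sorted(dropped)[:5])
    query &= uni

    records = []
    pvals = []
    for gs in annotations:
        inset = gs.genes & uni
        overlap = len(query & inset)
        p = float(hypergeom.sf(overlap - 1, len(uni), len(inset), len(query)))
        records.append((gs.set_id, overlap, len(inset)))
        pvals.append(p)
    qvals = bh_adjust(pvals)
    out = [
        OraRecord(sid, ov, size, len(query), len(uni), p, q)
        for (sid, ov, size), p, q in zip(records, pvals, qvals)
    ]
    return sorted(out, key=lambda r: (r.q, r.set_id))


class CompoundDiseasePrioritizer(BaseEstimator):
    """Network-based compound-disease prioritisation model.

    ``fit(network, disease)`` runs the Fisher/BH screen; fitted
    attributes expose the per-compound records (``records_``), the ids
    called significant at ``q < q_star`` (``significant_``), and the
    universe used (``universe_``).
    """

    def __init__(self, universe_policy: str = "network", q_star: float = 0.05) -> None:
        self.universe_policy = universe_policy
        self.q_star = q_star

    def fit(self, network: DTINetwork, disease: GeneSet) -> "CompoundDiseasePrioritizer":
        self.records_ = compound_disease_enrichment(
            network, disease, self.universe_policy, self.q_star
        )
        self.universe_ = _build_universe(network, disease, self.universe_policy)
        self.significant_ = {r.compound_id for r in self.records_ if r.significant}
        return self

    def q_values(self) -> dict[str, float]:
        if not hasattr(self, "records_"):
            raise RuntimeError("prioritizer is not fitted; call fit() first")
        return {r.compound_id: r.q for r in self.records_}
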
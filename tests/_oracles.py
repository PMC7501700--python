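"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (dict-based diffusion,
exact-rational hypergeometric sums, hand step-up BH) kept free of any
package internals beyond the public data types, so they can arbitrate
the optimised implementations.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np


def oracle_propagate(
    fp_rows: dict[str, set[str]],
    dti_pairs: set[tuple[str, str]],
    r0: dict[tuple[str, str], float],
    beta: float,
    gamma: float,
    k: int,
) -> dict[tuple[str, str], float]:
    """Dense dict-based diffusion, straight from the rule's definition.

    Nodes are ('drug', id) / ('substructure', id) / ('target', id); one
    round returns peripheral mass evenly to drugs, then each drug splits
    beta/(1-beta) across sides with degree**gamma allocation inside a
    side.  Degrees are total tripartite degrees, fixed up front.
    """
    drugs = sorted(fp_rows)
    subs_of = {d: set(bs) for d, bs in fp_rows.items()}
    tgts_of: dict[str, set[str]] = defaultdict(set)
    drugs_of_sub: dict[str, set[str]] = defaultdict(set)
    drugs_of_tgt: dict[str, set[str]] = defaultdict(set)
    for d, bs in fp_rows.items():
        for b in bs:
            drugs_of_sub[b].add(d)
    for d, t in dti_pairs:
        tgts_of[d].add(t)
        drugs_of_tgt[t].add(d)

    degree: dict[tuple[str, str], int] = {}
    for d in drugs:
        degree[("drug", d)] = len(subs_of[d]) + len(tgts_of[d])
    for s, ds in drugs_of_sub.items():
        degree[("substructure", s)] = len(ds)
    for t, ds in drugs_of_tgt.items():
        degree[("target", t)] = len(ds)

    r = dict(r0)
    for _ in range(k):
        returned: dict[str, float] = defaultdict(float)
        for (kind, node), mass in r.items():
            if mass == 0:
                continue
            if kind == "drug":
                returned[node] += mass
            elif kind == "substructure":
                for d in drugs_of_sub[node]:
                    returned[d] += mass / len(drugs_of_sub[node])
            else:
                for d in drugs_of_tgt[node]:
                    returned[d] += mass / len(drugs_of_tgt[node])
        nxt: dict[tuple[str, str], float] = defaultdict(float)
        for d, mass in returned.items():
            if mass == 0:
                continue
            subs, tgts = subs_of[d], tgts_of[d]
            side_sub = beta if tgts else 1.0
            side_tgt = (1.0 - beta) if tgts else 0.0
            w_sub = {s: degree[("substructure", s)] ** gamma for s in subs}
            z_sub = sum(w_sub.values())
            for s, w in w_sub.items():
                nxt[("substructure", s)] += mass * side_sub * w / z_sub
            if tgts:
                w_tgt = {t: degree[("target", t)] ** gamma for t in tgts}
                z_tgt = sum(w_tgt.values())
                for t, w in w_tgt.items():
                    nxt[("target", t)] += mass * side_tgt * w / z_tgt
        r = dict(nxt)
    return r


def random_tripartite(rng: np.random.Generator, max_nodes: int = 12):
    """A random small tripartite instance: fingerprint rows + DTI pairs."""
    n_drugs = int(rng.integers(1, 5))
    n_bits = int(rng.integers(1, 5))
    n_targets = int(rng.integers(0, max(1, max_nodes - n_drugs - n_bits) + 1))
    drugs = [f"d{i}" for i in range(n_drugs)]
    bit_names = [f"b{i}" for i in range(n_bits)]
    targets = [f"T{i}" for i in range(n_targets)]
    bits = rng.integers(0, 2, size=(n_drugs, n_bits))
    for i in range(n_drugs):  # every drug needs a substructure
        if not bits[i].any():
            bits[i, rng.integers(n_bits)] = 1
    pairs = {
        (d, t)
        for d in drugs
        for t in targets
        if rng.random() < 0.4
    }
    return drugs, bit_names, bits, targets, pairs


def fisher_pmf_oracle(a: int, b: int, c: int, d: int) -> float:
    """Right-tail Fisher p by exact-rational pmf summation.

    Sums hypergeometric probabilities of all tables at least as extreme
    as ``a`` given fixed margins, using integer binomials.
    """
    n_row = a + b
    n_col = a + c
    total = a + b + c + d
    if total == 0:
        return 1.0
    denom = math.comb(total, n_row)
    hi = min(n_row, n_col)
    num = sum(
        math.comb(n_col, x) * math.comb(total - n_col, n_row - x)
        for x in range(a, hi + 1)
    )
    return num / denom


def bh_stepup_oracle(pvals: list[float]) -> list[float]:
    """Hand Benjamini-Hochberg: q_(i) = min_{j>=i} p_(j) * m / j, clipped."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out
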
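import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.datamodel import DTIRecord, GeneSet
from netpharm.enrichment import (
    CompoundDiseasePrioritizer,
    ContingencyTable,
    bh_adjust,
    compound_disease_enrichment,
    fisher_right_tail,
    ora_hypergeometric,
)
from netpharm.network import assemble_network

from _oracles import bh_stepup_oracle, fisher_pmf_oracle


class TestFisherRightTail:
    def test_two_by_two_enumeration_value(self):
        # margins (2,2) in a universe of 4: only a=2 is as-or-more
        # extreme; C(2,2)C(2,0)/C(4,2) = 1/6
        assert fisher_right_tail(ContingencyTable(2, 0, 0, 2)) == pytest.approx(1 / 6)

    def test_zero_overlap_gives_one(self):
        assert fisher_right_tail(ContingencyTable(0, 5, 3, 10)) == pytest.approx(1.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    def test_matches_pmf_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            cells = rng.multinomial(int(rng.integers(1, 31)), [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            assert fisher_right_tail(ContingencyTable(a, b, c, d)) == pytest.approx(
                fisher_pmf_oracle(a, b, c, d), rel=1e-9
            )


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)
        assert bh_adjust([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_oracle_and_dominates_p(self, pvals):
        q = bh_adjust(pvals)
        want = bh_stepup_oracle(pvals)
        assert q == pytest.approx(want)
        for pi, qi in zip(pvals, q):
            assert qi >= pi - 1e-12 and qi <= 1.0 + 1e-12


def _network_from(pairs):
    return assemble_network([DTIRecord(c, t) for c, t in pairs])


class TestCompoundDiseaseEnrichment:
    def test_published_universe_composition(self):
        """A compound hitting 10/10 disease targets in a 490-gene universe
        (37 disease genes) gets the exact hypergeometric tail value and
        vastly outranks a compound hitting none."""
        disease_genes = [f"D{i}" for i in range(37)]
        other_genes = [f"N{i}" for i in range(453)]
        pairs = [("hit", g) for g in disease_genes[:10]]
        pairs += [("miss", g) for g in other_genes[:10]]
        # pad the universe to the full 490 targets
        pairs += [("pad", g) for g in disease_genes + other_genes]
        net = _network_from(pairs)
        disease = GeneSet("AD", "d", frozenset(disease_genes))
        recs = {r.compound_id: r for r in compound_disease_enrichment(net, disease)}
        want = fisher_pmf_oracle(10, 0, 27, 453)
        assert recs["hit"].p == pytest.approx(want, rel=1e-9)
        assert recs["miss"].p == pytest.approx(1.0)
        assert recs["hit"].p < 1e-9 < recs["miss"].p

    def test_disjoint_targets_p_one(self):
        net = _network_from([("c1", "N1"), ("c1", "N2"), ("c2", "D1")])
        disease = GeneSet("S", "d", frozenset({"D1"}))
        recs = {r.compound_id: r for r in compound_disease_enrichment(net, disease)}
        assert recs["c1"].table.a == 0 and recs["c1"].p == pytest.approx(1.0)

    def test_record_order_independent_q(self):
        pairs = [("a", "D1"), ("b", "N1"), ("c", "D1"), ("c", "N2")]
        net1 = _network_from(pairs)
        net2 = _network_from(list(reversed(pairs)))
        disease = GeneSet("S", "d", frozenset({"D1"}))
        q1 = {r.compound_id: r.q for r in compound_disease_enrichment(net1, disease)}
        q2 = {r.compound_id: r.q for r in compound_disease_enrichment(net2, disease)}
        assert q1 == q2

    def test_empty_disease_intersection_rejected(self):
        net = _network_from([("c1", "T1")])
        with pytest.raises(ValueError):
            compound_disease_enrichment(net, GeneSet("S", "d", frozenset({"ELSEWHERE"})))

    def test_planted_compounds_rank_above_background(self, default_dataset, default_network):
        recs = compound_disease_enrichment(default_network, default_dataset.disease)
        qs = {r.compound_id: r.q for r in recs}
        planted = [qs[c] for c in default_dataset.planted]
        background = [q for c, q in qs.items() if c not in default_dataset.planted]
        assert np.median(planted) < np.median(background)

    def test_estimator_interface(self, default_dataset, default_network):
        model = CompoundDiseasePrioritizer().fit(default_network, default_dataset.disease)
        assert model.significant_ <= {r.compound_id for r in model.records_}
        assert model.get_params()["q_star"] == 0.05


class TestOra:
    def test_closed_form_single_term(self):
        universe = [f"G{i}" for i in range(100)]
        inset = GeneSet("S", "s", frozenset(universe[:5]))
        (rec,) = ora_hypergeometric(universe[:5], [inset], universe)
        import math

        want = math.comb(5, 5) * math.comb(95, 0) / math.comb(100, 5)
        assert rec.p == pytest.approx(want, rel=1e-9)

    def test_query_equal_universe_forced_overlap(self):
        universe = ["A", "B", "C"]
        (rec,) = ora_hypergeometric(universe, [GeneSet("S", "s", frozenset(universe))], universe)
        assert rec.p == pytest.approx(1.0)

    def test_disjoint_query_and_set(self):
        universe = [f"G{i}" for i in range(20)]
        gs = GeneSet("S", "s", frozenset(universe[10:]))
        (rec,) = ora_hypergeometric(universe[:5], [gs], universe)
        assert rec.overlap == 0 and rec.p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(["A"], [], [])
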
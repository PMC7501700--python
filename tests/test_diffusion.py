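import numpy as np
import pytest

from netpharm.datamodel import DTIRecord, FingerprintTable
from netpharm.diffusion import (
    DiffusionParams,
    NetworkTargetPredictor,
    build_tripartite,
    evaluate_auc,
    initial_resource,
    predict_targets,
    propagate,
)

from _oracles import oracle_propagate, random_tripartite


def _graph(bits_rows, dti_pairs, drugs=None, bit_names=None):
    drugs = drugs or [f"d{i}" for i in range(len(bits_rows))]
    bit_names = bit_names or [f"b{i}" for i in range(len(bits_rows[0]))]
    fp = FingerprintTable(drugs, bit_names, np.array(bits_rows))
    return build_tripartite(fp, [DTIRecord(c, t) for c, t in dti_pairs])


class TestBuildTripartite:
    def test_layer_counts_from_construction(self):
        g = _graph([[1, 0, 1], [0, 1, 1]], [("d0", "T1")])
        assert len(g.drugs) == 2 and len(g.substructures) == 3 and len(g.targets) == 1
        assert g.drug_sub.nnz == 4 and g.drug_target.nnz == 1

    def test_zero_fingerprint_drug_excluded(self):
        fp = FingerprintTable(["d0", "d1"], ["b0"], np.array([[1], [0]]))
        g = build_tripartite(fp, [])
        assert g.drugs == ["d0"] and g.excluded_drugs == ["d1"]

    def test_all_zero_rows_error(self):
        fp = FingerprintTable(["d0"], ["b0"], np.array([[0]]))
        with pytest.raises(ValueError, match="no usable drugs"):
            build_tripartite(fp, [])

    def test_empty_dti_list_gives_new_chemical_entity_mode(self):
        g = _graph([[1, 1], [1, 0]], [])
        assert g.targets == []
        # predictions still come back (empty: no targets exist at all)
        assert predict_targets(g, "d0", DiffusionParams()).predictions == ()

    def test_dti_compound_missing_from_fingerprints_is_error(self):
        fp = FingerprintTable(["d0"], ["b0"], np.array([[1]]))
        with pytest.raises(ValueError, match="ghost"):
            build_tripartite(fp, [DTIRecord("ghost", "T1")])


class TestInitialResource:
    def test_alpha_split_two_substructures_two_targets(self):
        g = _graph([[1, 1]], [("d0", "T1"), ("d0", "T2")])
        r = initial_resource(g, "d0", alpha=0.1)
        assert np.allclose(r.sub_mass, [0.05, 0.05])
        assert np.allclose(r.target_mass, [0.45, 0.45])

    def test_no_targets_all_mass_to_substructures(self):
        g = _graph([[1, 1, 1, 1]], [])
        r = initial_resource(g, "d0", alpha=0.3)
        assert np.allclose(r.sub_mass, [0.25] * 4)

    def test_unit_total(self):
        g = _graph([[1, 0, 1], [0, 1, 1]], [("d0", "T1"), ("d1", "T2")])
        for d in ("d0", "d1"):
            assert initial_resource(g, d, 0.37).total() == pytest.approx(1.0)

    def test_unknown_drug_raises(self):
        g = _graph([[1]], [])
        with pytest.raises(KeyError):
            initial_resource(g, "nope", 0.1)


class TestPropagate:
    def test_mass_conserved_when_gamma_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            drugs, bit_names, bits, targets, pairs = random_tripartite(rng)
            g = build_tripartite(
                FingerprintTable(drugs, bit_names, bits),
                [DTIRecord(c, t) for c, t in pairs],
            )
            r = initial_resource(g, g.drugs[0], alpha=0.3)
            for k in (1, 2, 3):
                out = propagate(g, r, DiffusionParams(0.3, 0.6, 0.0, k))
                assert abs(out.total() - 1.0) < 1e-9

    def test_single_path_hand_computation(self):
        # 1 drug - 1 substructure - 1 target: each round returns all mass
        # to the drug, then splits beta/(1-beta)
        g = _graph([[1]], [("d0", "T1")])
        r = propagate(g, initial_resource(g, "d0", 0.5), DiffusionParams(0.5, 0.5, 0.0, 1))
        assert r.sub_mass[0] == pytest.approx(0.5)
        assert r.target_mass[0] == pytest.approx(0.5)

    def test_hub_penalty_share_matches_formula(self):
        # d0 links a hub target (degree 5, via d1..d4) and a leaf target
        # (degree 1); with gamma = -0.5 and all mass placed on d0, the
        # hub receives 5**-.5 / (5**-.5 + 1) of d0's target-side mass
        from netpharm.diffusion import ResourceVector

        rows = [[1]] * 5
        pairs = [(f"d{i}", "HUB") for i in range(5)] + [("d0", "LEAF")]
        g = _graph(rows, pairs)
        r0 = ResourceVector(
            g,
            drug_mass=np.eye(len(g.drugs))[g.drug_idx("d0")].astype(float),
            sub_mass=np.zeros(len(g.substructures)),
            target_mass=np.zeros(len(g.targets)),
        )
        out = propagate(g, r0, DiffusionParams(alpha=0.5, beta=0.0, gamma=-0.5, k=1))
        ti = {t: j for j, t in enumerate(g.targets)}
        w = 5 ** -0.5 / (5 ** -0.5 + 1.0)
        assert out.target_mass[ti["HUB"]] == pytest.approx(w)
        assert out.target_mass[ti["LEAF"]] == pytest.approx(1.0 - w)

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            DiffusionParams(k=0)

    def test_matches_dense_oracle_on_random_graphs(self):
        """propagate equals the independent dict-based oracle (many seeds)."""
        rng = np.random.default_rng(42)
        for trial in range(200):
            drugs, bit_names, bits, targets, pairs = random_tripartite(rng)
            fp = FingerprintTable(drugs, bit_names, bits)
            g = build_tripartite(fp, [DTIRecord(c, t) for c, t in pairs])
            alpha = float(rng.random())
            beta = float(rng.random())
            gamma = float(rng.uniform(-1, 1))
            k = int(rng.integers(1, 4))
            drug = drugs[int(rng.integers(len(drugs)))]
            got = propagate(
                g, initial_resource(g, drug, alpha), DiffusionParams(alpha, beta, gamma, k)
            ).as_dict()

            fp_rows = {d: {b for b, v in zip(bit_names, row) if v} for d, row in zip(drugs, bits)}
            subs = fp_rows[drug]
            tgts = {t for c, t in pairs if c == drug}
            r0 = {("substructure", s): (alpha if tgts else 1.0) / len(subs) for s in subs}
            r0.update({("target", t): (1 - alpha) / len(tgts) for t in tgts})
            want = oracle_propagate(fp_rows, pairs, r0, beta, gamma, k)
            for node, mass in got.items():
                assert mass == pytest.approx(want.get(node, 0.0), abs=1e-12), (trial, node)


class TestPredictTargets:
    def _chain_graph(self):
        # d0 and d1 share b0; d1 knows T1..T3; d0 knows T0
        rows = [[1, 1], [1, 0]]
        pairs = [("d1", "T1"), ("d1", "T2"), ("d1", "T3"), ("d0", "T0")]
        return _graph(rows, pairs)

    def test_known_targets_excluded_and_scores_sorted(self):
        g = self._chain_graph()
        out = predict_targets(g, "d0", DiffusionParams(top_n=20))
        assert "T0" not in out.genes()
        scores = [s for _, s in out.predictions]
        assert scores == sorted(scores, reverse=True)

    def test_truncation_to_top_n(self):
        pairs = [("d1", f"T{i}") for i in range(25)]
        g = _graph([[1, 1], [1, 0]], pairs)
        out = predict_targets(g, "d0", DiffusionParams(top_n=20))
        assert len(out) == 20
        out7 = predict_targets(g, "d0", DiffusionParams(top_n=7))
        assert len(out7) == 7

    def test_only_known_targets_gives_empty_list(self):
        g = _graph([[1]], [("d0", "T1")])
        out = predict_targets(g, "d0", DiffusionParams())
        assert out.predictions == ()

    def test_ties_broken_lexicographically(self):
        # two symmetric targets must rank alphabetically
        g = _graph([[1, 1], [1, 1]], [("d1", "TB"), ("d1", "TA")])
        out = predict_targets(g, "d0", DiffusionParams())
        assert out.genes() == ["TA", "TB"]

    def test_row_order_permutation_invariance(self):
        rows = [[1, 0, 1], [0, 1, 1], [1, 1, 0]]
        drugs = ["d0", "d1", "d2"]
        pairs = [("d1", "T1"), ("d2", "T2"), ("d1", "T3")]
        g1 = _graph(rows, pairs, drugs=drugs)
        perm = [2, 0, 1]
        g2 = _graph([rows[i] for i in perm], list(reversed(pairs)),
                    drugs=[drugs[i] for i in perm])
        p1 = predict_targets(g1, "d0", DiffusionParams())
        p2 = predict_targets(g2, "d0", DiffusionParams())
        assert p1.genes() == p2.genes()
        for (ga, sa), (gb, sb) in zip(p1.predictions, p2.predictions):
            assert ga == gb and sa == pytest.approx(sb)


class TestEstimatorShell:
    def test_sklearn_param_interface(self):
        est = NetworkTargetPredictor(alpha=0.2)
        assert est.get_params()["alpha"] == 0.2
        est.set_params(k=3)
        assert est.k == 3

    def test_fit_predict_matches_functions(self, tiny_fingerprints, tiny_dtis):
        est = NetworkTargetPredictor().fit(tiny_fingerprints, tiny_dtis)
        (d2,) = est.predict(["d2"])
        g = build_tripartite(tiny_fingerprints, tiny_dtis)
        assert d2.predictions == predict_targets(g, "d2", DiffusionParams()).predictions

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="fit"):
            NetworkTargetPredictor().predict()


class TestEvaluateAuc:
    def test_requires_ten_dtis(self, tiny_fingerprints, tiny_dtis):
        with pytest.raises(ValueError, match="10"):
            evaluate_auc(tiny_fingerprints, tiny_dtis, 0.2, DiffusionParams(), 0)

    def test_same_seed_reproduces(self, default_dataset):
        ds = default_dataset
        a = evaluate_auc(ds.fingerprints, ds.dtis, 0.2, DiffusionParams(), seed=3)
        b = evaluate_auc(ds.fingerprints, ds.dtis, 0.2, DiffusionParams(), seed=3)
        assert a.auc == b.auc and a.n_positive == b.n_positive
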
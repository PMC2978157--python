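import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cepin import (
    ExpressionMatrix,
    SampleDesign,
    classify_by_clustering,
    classify_edge_dynamics,
    mean_expression_shift,
    mean_pairwise_pcc,
    mean_pcc_change,
    module_activity,
    module_dynamics_zscores,
    random_subnetwork_null,
    roc_auc,
)
from cepin.correlation import EdgeScore
from cepin.evaluation import ClassificationReport, _stat_summary


def _design(na=3, nb=3):
    assignment = {f"a{i}": "A" for i in range(na)}
    assignment.update({f"b{i}": "B" for i in range(nb)})
    return SampleDesign(assignment, "A")


def _expr(rows, genes, design):
    cols = design.samples_of("A") + design.samples_of("B")
    return ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=cols))


class TestModuleActivity:
    def test_single_gene_identity(self):
        d = _design()
        e = _expr([[1, 2, 3, 4, 5, 6.0]], ["G1"], d)
        act = module_activity(["G1"], e)
        assert act == {s: float(v) for s, v in zip(e.sample_ids, [1, 2, 3, 4, 5, 6])}

    def test_mean_of_two(self):
        d = _design()
        e = _expr([[1] * 6, [3] * 6], ["G1", "G2"], d)
        assert all(v == 2.0 for v in module_activity(["G1", "G2"], e).values())

    def test_masked_mean_with_missing_member(self):
        d = _design()
        rows = [[1, 1, 1, 1, 1, 1.0], [3, np.nan, 3, 3, 3, 3]]
        e = _expr(rows, ["G1", "G2"], d)
        act = module_activity(["G1", "G2"], e)
        assert act[e.sample_ids[1]] == 1.0  # only G1 measured there
        assert act[e.sample_ids[0]] == 2.0

    def test_no_measured_member_errors(self):
        d = _design()
        e = _expr([[1] * 6], ["G1"], d)
        with pytest.raises(ValueError, match="no module member"):
            module_activity(["ZZ"], e)


class TestRocAuc:
    def test_perfect_separation(self):
        d = _design(2, 2) if False else _design(3, 3)
        scores = {"a0": 0.9, "a1": 0.8, "a2": 0.85, "b0": 0.2, "b1": 0.1, "b2": 0.15}
        points, auc, orientation = roc_auc(scores, d)
        assert auc == 1.0 and orientation == 1
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_all_ties_half_credit(self):
        d = _design()
        points, auc, _ = roc_auc({s: 1.0 for s in d.assignment}, d)
        assert auc == 0.5

    def test_pairwise_concordance_worked_value(self):
        # positives {0.8, 0.4, 0.9}, negatives {0.6, 0.2, 0.1}:
        # 8 of 9 pairs concordant -> AUC 8/9 (hand-counted oracle)
        d = _design(3, 3)
        scores = {"a0": 0.8, "a1": 0.4, "a2": 0.9,
                  "b0": 0.6, "b1": 0.2, "b2": 0.1}
        _, auc, orientation = roc_auc(scores, d)
        assert orientation == 1
        assert auc == pytest.approx(8 / 9)

    def test_orientation_auto_flip(self):
        d = _design()
        scores = {"a0": 0.1, "a1": 0.2, "a2": 0.15, "b0": 0.8, "b1": 0.9, "b2": 0.85}
        _, auc, orientation = roc_auc(scores, d)
        assert auc == 1.0 and orientation == -1

    def test_monotone_roc_and_trapezoid_equals_u(self):
        rng = np.random.default_rng(3)
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            na, nb = int(rng.integers(3, 25)), int(rng.integers(3, 25))
            d = _design(na, nb)
            vals = np.round(rng.standard_normal(na + nb), 1)  # force some ties
            scores = dict(zip(d.samples_of("A") + d.samples_of("B"), vals))
            points, auc, orientation = roc_auc(scores, d)
            fpr = [p[0] for p in points]
            tpr = [p[1] for p in points]
            assert all(x2 >= x1 for x1, x2 in zip(fpr, fpr[1:]))
            assert all(y2 >= y1 for y1, y2 in zip(tpr, tpr[1:]))
            y = [1] * na + [0] * nb
            oriented = vals if orientation == 1 else -vals
            ref = roc_auc_score(y, oriented)
            assert auc == pytest.approx(ref, abs=1e-12)
            trapezoid = np.trapezoid(tpr, fpr)
            assert auc == pytest.approx(trapezoid, abs=1e-12)


class TestClassifyByClustering:
    def test_perfect_blocks(self):
        d = _design(4, 4)
        rng = np.random.default_rng(0)
        rows = np.hstack([rng.normal(5, 0.1, (6, 4)), rng.normal(-5, 0.1, (6, 4))])
        e = _expr(rows, [f"G{i}" for i in range(6)], d)
        rep = classify_by_clustering([f"G{i}" for i in range(6)], e, d)
        assert rep.accuracy == 1.0
        assert rep.tp == 4 and rep.tn == 4

    def test_report_identities(self):
        rep = ClassificationReport(
            tp=5, fp=1, tn=6, fn=2,
            sensitivity=5 / 7, specificity=6 / 7, accuracy=11 / 14,
            roc_points=[(0, 0), (1, 1)], auc=0.5)
        assert rep.sensitivity == pytest.approx(0.714, abs=1e-3)
        assert rep.specificity == pytest.approx(0.857, abs=1e-3)
        assert rep.accuracy == pytest.approx(0.786, abs=1e-3)

    def test_inconsistent_report_rejected(self):
        with pytest.raises(AssertionError):
            ClassificationReport(tp=5, fp=1, tn=6, fn=2,
                                 sensitivity=0.9, specificity=6 / 7,
                                 accuracy=11 / 14, roc_points=[], auc=0.5)

    def test_degenerate_identical_samples(self):
        d = _design()
        e = _expr([[1.0] * 6, [2.0] * 6], ["G1", "G2"], d)
        with pytest.raises(ValueError, match="degenerate"):
            classify_by_clustering(["G1", "G2"], e, d)

    def test_positive_group_is_majority_branch(self):
        d = _design(4, 4)
        rows = np.hstack([np.full((3, 4), 4.0), np.full((3, 4), -4.0)])
        rows += np.random.default_rng(1).normal(0, 0.01, rows.shape)
        e = _expr(rows, ["G1", "G2", "G3"], d)
        rep = classify_by_clustering(["G1", "G2", "G3"], e, d)
        assert rep.tp + rep.fn == 4  # positives partition correctly
        assert rep.tn + rep.fp == 4


class TestRandomSubnetworkNull:
    def test_constant_statistic_degenerate(self):
        null = random_subnetwork_null([f"g{i}" for i in range(10)], 3, 50, 0,
                                      lambda genes: 1.5)
        s = _stat_summary(1.5, null, 50)
        assert s.null_sd == 0.0 and math.isnan(s.z)

    def test_seed_reproducibility(self):
        genes = [f"g{i}" for i in range(20)]
        stat = lambda gs: float(len(set(gs)))
        rng_draws = [random_subnetwork_null(genes, 5, 25, 7, lambda gs: hash(tuple(gs)) % 97)
                     for _ in range(2)]
        assert np.array_equal(rng_draws[0], rng_draws[1])

    def test_full_size_saturation(self):
        genes = [f"g{i}" for i in range(8)]
        null = random_subnetwork_null(genes, 8, 20, 0, lambda gs: float(len(gs)))
        assert np.all(null == 8.0)

    def test_oversize_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            random_subnetwork_null(["a", "b"], 3, 5, 0, lambda gs: 0.0)

    def test_connected_mode_draws_connected_sets(self):
        g = nx.path_graph(30)
        null = random_subnetwork_null(
            g, 5, 20, 1,
            lambda gs: float(nx.is_connected(g.subgraph([int(x) for x in gs]))),
            mode="connected")
        assert np.all(null == 1.0)


class TestDynamicsStats:
    def test_z_formula(self):
        s = _stat_summary(0.5, np.array([0.3, 0.2, 0.4]), 3)
        assert s.z == pytest.approx((0.5 - 0.3) / 0.1)

    def test_observed_equal_to_null_mean_zero_z(self):
        s = _stat_summary(0.3, np.array([0.2, 0.3, 0.4]), 3)
        assert s.z == pytest.approx(0.0)

    def test_add_one_empirical_p(self):
        null = np.linspace(0, 0.9, 999)
        s = _stat_summary(1.0, null, 999)
        assert s.p_empirical == pytest.approx(1 / 1000)

    def test_planted_module_strong_z(self, default_dataset):
        ds = default_dataset
        from conftest import discover_modules
        from cepin import assemble_module

        excl, cepins, _ = discover_modules(ds)
        mod = assemble_module("GO:9000001", cepins["A"], ds.ann, ds.dag)
        report = module_dynamics_zscores(mod, ds.expr, ds.design,
                                         n_null=200, seed=5)
        assert report.mean_pcc["A"].z > 3
        assert report.mean_pcc["A"].observed > 0.6
        assert report.expression_shift.observed > 0.5

    def test_pairwise_statistics_against_direct_formulas(self, default_dataset):
        ds = default_dataset
        genes = ds.spec.members_of(ds.spec.planted_terms[0])[:5]
        cols_a = ds.design.samples_of("A")
        V = ds.expr.data.loc[genes, cols_a].to_numpy(float)
        C = np.corrcoef(V)
        expected = C[np.triu_indices(5, 1)].mean()
        assert mean_pairwise_pcc(genes, ds.expr, ds.design, "A") == pytest.approx(
            expected, abs=1e-12)
        a, b = ds.design.conditions
        va = ds.expr.data.loc[genes, ds.design.samples_of(a)].mean(axis=1)
        vb = ds.expr.data.loc[genes, ds.design.samples_of(b)].mean(axis=1)
        assert mean_expression_shift(genes, ds.expr, ds.design) == pytest.approx(
            float(np.abs(va - vb).mean()), abs=1e-12)


class TestEdgeDynamics:
    def _scores(self, values, condition):
        return {tuple(sorted(e)): EdgeScore(tuple(sorted(e)), condition, v, 10, 0.01)
                for e, v in values.items()}

    def test_threshold_rules(self):
        a = self._scores({("x", "y"): 0.6, ("y", "z"): 0.55, ("p", "q"): 0.1}, "A")
        b = self._scores({("x", "y"): 0.1, ("y", "z"): -0.72, ("p", "q"): 0.2}, "B")
        classes = {c.edge: c.label for c in classify_edge_dynamics(a, b)}
        assert classes[("x", "y")] == "a_specific"
        assert classes[("y", "z")] == "both"
        assert classes[("p", "q")] == "neither"

    def test_zero_threshold_everything_both(self):
        a = self._scores({("x", "y"): 0.01}, "A")
        b = self._scores({("x", "y"): -0.01}, "B")
        classes = classify_edge_dynamics(a, b, threshold=0.0)
        assert classes[0].label == "both"

    def test_missing_score_is_neither_flagged(self):
        a = self._scores({("x", "y"): 0.9}, "A")
        classes = classify_edge_dynamics(a, {}, 0.5)
        assert classes[0].label == "neither" and classes[0].missing
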
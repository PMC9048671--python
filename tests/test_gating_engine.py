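"""Thresholded gating decisions and the hierarchical engine."""

import numpy as np
import pytest

from cellgate import (
    GateParams,
    GatePurifier,
    PurityCall,
    ScoreMatrix,
    ScoringParams,
    SmoothingParams,
    build_model,
    gate_level,
    run_gating,
)
from cellgate.gating_model import GatingLevel, GatingModel, Signature, parse_gene_token
from cellgate.synthetic_data import PopulationSpec, generate

from conftest import make_matrix


def sig(name, *tokens):
    return Signature(name=name, genes=[parse_gene_token(t) for t in tokens])


def smoothed(names, values):
    values = np.asarray(values, dtype=float)
    return ScoreMatrix(
        values=values,
        signature_names=list(names),
        cell_ids=np.array([f"c{i}" for i in range(values.shape[0])], dtype=object),
        smoothed=True,
    )


def two_pop_dataset(seed=0):
    """A small separable A/B mixture for engine-level tests.

    Desk-scale analogue of sparse count data: a low baseline detection
    rate so that single stray counts fall past a small rank cap, and a
    6-gene program per population so the embedding separates them.
    """
    a_prog = [f"AM{i}" for i in range(1, 7)]
    b_prog = [f"BM{i}" for i in range(1, 7)]
    return generate(
        [
            PopulationSpec("A", 120, a_prog, marker_fold=50,
                           baseline_mean=0.1, dropout_extra=0.05),
            PopulationSpec("B", 120, b_prog, marker_fold=50,
                           baseline_mean=0.1, dropout_extra=0.05),
        ],
        n_features=400,
        seed=seed,
    )


# scoring/smoothing scaled to the fixture above
SMALL_SCORING = ScoringParams(max_rank=15)
SMALL_SMOOTH = SmoothingParams(k=10, n_hvg=100, n_pcs=10)


class TestGateLevel:
    def test_clear_margin_passes(self):
        level = GatingLevel(1, [sig("s", "x")])
        ok = gate_level(smoothed(["s"], [[0.9], [0.05]]), level, GateParams())
        assert list(ok) == [True, False]

    def test_negative_signature_vetoes(self):
        level = GatingLevel(1, [sig("p", "x")], [sig("n", "y")])
        sm = smoothed(["p", "n"], [[0.9, 0.8], [0.9, 0.1]])
        ok = gate_level(sm, level, GateParams())
        assert list(ok) == [False, True]

    def test_positive_boundary_is_inclusive_negative_exclusive(self):
        level = GatingLevel(1, [sig("p", "x")], [sig("n", "y")])
        sm = smoothed(["p", "n"], [[0.2, 0.0], [0.2, 0.2]])
        ok = gate_level(sm, level, GateParams(pos_threshold=0.2, neg_threshold=0.2))
        assert list(ok) == [True, False]

    def test_multiple_positive_signatures_combine_by_any(self):
        level = GatingLevel(1, [sig("p1", "x"), sig("p2", "y")])
        sm = smoothed(["p1", "p2"], [[0.05, 0.9], [0.05, 0.05]])
        ok = gate_level(sm, level, GateParams())
        assert list(ok) == [True, False]

    def test_cells_outside_active_mask_stay_false(self):
        level = GatingLevel(1, [sig("s", "x")])
        sm = smoothed(["s"], [[0.9], [0.9]])
        ok = gate_level(sm, level, GateParams(), active=np.array([True, False]))
        assert list(ok) == [True, False]

    def test_missing_signature_column_named(self):
        level = GatingLevel(1, [sig("absent", "x")])
        with pytest.raises(KeyError, match="absent"):
            gate_level(smoothed(["other"], [[0.5]]), level, GateParams())

    def test_raw_scores_rejected(self):
        level = GatingLevel(1, [sig("s", "x")])
        raw = smoothed(["s"], [[0.5]])
        raw.smoothed = False
        with pytest.raises(ValueError, match="smoothed"):
            gate_level(raw, level, GateParams())

    def test_threshold_monotonicity(self, rng):
        """Raising pos_threshold never grows the pass set; raising
        neg_threshold never shrinks it."""
        level = GatingLevel(1, [sig("p", "x")], [sig("n", "y")])
        sm = smoothed(["p", "n"], rng.random((50, 2)))
        thresholds = [0.0, 0.2, 0.5, 0.9, 1.0]
        prev = None
        for t in thresholds:
            cur = gate_level(sm, level, GateParams(pos_threshold=t))
            if prev is not None:
                assert not np.any(cur & ~prev)
            prev = cur
        prev = None
        for t in thresholds:
            cur = gate_level(sm, level, GateParams(neg_threshold=t))
            if prev is not None:
                assert not np.any(prev & ~cur)
            prev = cur


class TestPurityCallInvariants:
    def test_final_must_match_conjunction(self):
        with pytest.raises(ValueError, match="inconsistent"):
            PurityCall(
                cell_ids=np.array(["a"], dtype=object),
                per_level=np.array([[True, True]]),
                final=np.array(["Impure"], dtype=object),
            )

    def test_pass_pattern_must_be_prefix_closed(self):
        with pytest.raises(ValueError, match="level"):
            PurityCall(
                cell_ids=np.array(["a"], dtype=object),
                per_level=np.array([[False, True]]),
                final=np.array(["Impure"], dtype=object),
            )


class TestRunGating:
    def test_two_level_hierarchy_is_monotone_and_final_is_intersection(self):
        ds = two_pop_dataset()
        model = GatingModel(
            "AB",
            [
                GatingLevel(1, [sig("a", "AM1", "AM2")]),
                GatingLevel(2, [sig("b", "AM3")]),
            ],
        )
        calls = run_gating(
            ds.matrix, model, scoring=SMALL_SCORING, smooth=SMALL_SMOOTH, seed=0
        )
        assert not np.any(calls.per_level[:, 1] & ~calls.per_level[:, 0])
        np.testing.assert_array_equal(
            calls.pure_mask, calls.per_level.all(axis=1)
        )

    def test_absent_positive_marker_fails_before_computation(self):
        ds = two_pop_dataset()
        model = build_model("x", ["NOT_A_GENE"])
        with pytest.raises(ValueError, match="unusable"):
            run_gating(ds.matrix, model, seed=0)

    def test_same_seed_reproduces_calls(self):
        ds = two_pop_dataset()
        model = build_model("A", ["AM1", "AM2", "AM3"])
        a = run_gating(ds.matrix, model, scoring=SMALL_SCORING,
                       smooth=SMALL_SMOOTH, seed=5)
        b = run_gating(ds.matrix, model, scoring=SMALL_SCORING,
                       smooth=SMALL_SMOOTH, seed=5)
        assert np.array_equal(a.per_level, b.per_level)
        assert list(a.final) == list(b.final)

    def test_single_marker_purifies_its_population(self):
        ds = two_pop_dataset()
        model = build_model("A", ["AM1", "AM2"])
        calls = run_gating(
            ds.matrix, model, scoring=SMALL_SCORING, smooth=SMALL_SMOOTH, seed=0
        )
        truth = ds.truth.as_series()[list(calls.cell_ids)].to_numpy()
        pure = calls.pure_mask
        assert (truth[pure] == "A").mean() > 0.9
        assert pure[truth == "A"].mean() > 0.9

    def test_without_per_level_recompute_extra_signatures_are_inert(self):
        """With a shared graph, level-1 calls do not depend on other
        levels' signatures being present in the score matrix."""
        ds = two_pop_dataset()
        base = GatingModel("m1", [GatingLevel(1, [sig("a", "AM1", "AM2")])])
        padded = GatingModel(
            "m2",
            [
                GatingLevel(1, [sig("a", "AM1", "AM2")]),
                GatingLevel(2, [sig("b", "BM1", "BM2")]),
            ],
        )
        gate = GateParams(recompute_graph_per_level=False)
        a = run_gating(ds.matrix, base, gate=gate, scoring=SMALL_SCORING,
                       smooth=SMALL_SMOOTH, seed=1)
        b = run_gating(ds.matrix, padded, gate=gate, scoring=SMALL_SCORING,
                       smooth=SMALL_SMOOTH, seed=1)
        assert np.array_equal(a.per_level[:, 0], b.per_level[:, 0])

    def test_failsafe_when_a_level_leaves_fewer_than_two_cells(self, rng):
        # with k=1 (identity smoothing) exactly one cell clears level 1,
        # so level 2 cannot build a neighbourhood and must fail-safe
        values = rng.poisson(1.0, size=(40, 30)).astype(float)
        values[:, 0] = 0.0
        values[0, 0] = 50.0  # only cell 0 expresses RARE at all
        fm = make_matrix(values, feature_ids=["RARE"] + [f"g{j}" for j in range(29)])
        model = GatingModel(
            "rare",
            [
                GatingLevel(1, [sig("r", "RARE")]),
                GatingLevel(2, [sig("other", "g0")]),
            ],
        )
        with pytest.warns(UserWarning, match="fail-safe"):
            calls = run_gating(
                fm, model,
                gate=GateParams(pos_threshold=0.95),
                smooth=SmoothingParams(k=1),
                seed=0,
            )
        assert calls.per_level[0, 0] and calls.per_level[0, 1]
        assert calls.final[0] == "Pure"
        assert calls.per_level[1:, 0].sum() == 0

    def test_zero_cell_matrix_rejected(self):
        fm = make_matrix(np.zeros((0, 3)))
        with pytest.raises(ValueError, match="zero cells"):
            run_gating(fm, build_model("x", ["g0"]), seed=0)


class TestGatePurifierEstimator:
    def test_fit_predict_and_fitted_attributes(self):
        ds = two_pop_dataset()
        model = build_model("A", ["AM1", "AM2"])
        est = GatePurifier(model=model, max_rank=15, n_hvg=100, n_pcs=10,
                           random_state=0)
        labels = est.fit_predict(ds.matrix)
        assert set(labels) <= {"Pure", "Impure"}
        assert est.purity_call_.n_levels == 1
        assert est.raw_scores_.values.shape == (ds.matrix.n_cells, 1)
        assert est.smoothed_scores_.smoothed

    def test_sklearn_param_interface(self):
        est = GatePurifier(pos_threshold=0.3)
        params = est.get_params()
        assert params["pos_threshold"] == 0.3
        est.set_params(k=5, neg_threshold=0.1)
        assert est.k == 5 and est.neg_threshold == 0.1

    def test_model_required(self):
        with pytest.raises(ValueError, match="GatingModel"):
            GatePurifier().fit(make_matrix(np.ones((3, 3))))
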
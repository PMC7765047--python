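"""Modular variance decomposition: splines, corrected R², order scans."""

from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
import pytest

import spherovar as sv
from spherovar.decomposition import (
    MODULES,
    ModuleMatrices,
    build_modules,
    corrected_r2,
    decompose_condition,
    marginal_sequence,
    neighbor_features,
    order_scan,
    select_ordering,
    shapley_average,
    spline_basis,
)
from conftest import attach_values, build_graph
from spherovar.synthetic import MarkerSpec, SyntheticConfig


class TestSplineBasis:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 50, size=500)
        B = spline_basis(x)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_interpolates_smooth_function(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, size=2000)
        y = np.sin(x / 20.0)
        B = spline_basis(x)
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        resid = y - B @ coef
        r2 = 1 - resid.var() / y.var()
        assert r2 > 0.99

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            spline_basis(np.array([1.0, 2.0, 3.0] * 10))

    def test_tied_quantiles_collapse_with_warning(self):
        x = np.concatenate([np.zeros(500), np.random.default_rng(2).uniform(0, 1, 500)])
        with pytest.warns(UserWarning):
            B = spline_basis(x)
        assert np.all(np.isfinite(B))


class TestCorrectedR2:
    @pytest.mark.parametrize(
        "uncorr,tech,expected",
        [(0.4, 0.0, 0.4), (0.3, 0.3, 0.0), (0.6, 0.2, 0.5)],
    )
    def test_formula(self, uncorr, tech, expected):
        assert corrected_r2(uncorr, tech) == pytest.approx(expected)

    def test_can_be_negative(self):
        assert corrected_r2(0.1, 0.2) < 0

    def test_tech_at_one_rejected(self):
        with pytest.raises(ValueError):
            corrected_r2(0.5, 1.0)


class TestNeighborFeatures:
    def test_mean_and_isolation(self):
        pos = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0], [500.0, 0.0]])
        g = sv.build_neighbor_graph(pos, np.zeros(4), 12.0)
        vals = pd.DataFrame({"m": [1.0, 2.0, 3.0, 9.0]})
        feats, isolated = neighbor_features(vals, g)
        assert feats["nb_m"].iloc[0] == pytest.approx(2.0)
        assert feats["nb_m"].iloc[1] == pytest.approx(2.0)
        assert isolated.tolist() == [False, False, False, True]
        assert np.isnan(feats["nb_m"].iloc[3])


@pytest.fixture(scope="module")
def module_matrices(default_condition):
    cfg, cells, truth, graph, markers = default_condition
    vals = cells[[f"value_{m}" for m in markers]].copy()
    vals.columns = markers
    nb_feats, _ = neighbor_features(vals, graph)
    return {
        m: build_modules(cells, m, markers, nb_feats=nb_feats) for m in markers[:6]
    }


class TestModularFits:
    def test_unknown_target_rejected(self, default_condition):
        cfg, cells, truth, graph, markers = default_condition
        with pytest.raises(ValueError):
            build_modules(cells, "nonexistent", markers, graph=graph)

    def test_target_not_among_own_predictors(self, module_matrices, default_condition):
        *_, markers = default_condition
        mm = next(iter(module_matrices.values()))
        # nb and int blocks both span all markers except the target
        assert mm.blocks["int"].shape[1] == len(markers) - 1
        assert mm.blocks["nb"].shape[1] == len(markers) - 1
        assert mm.blocks["self"].shape[1] == 1

    def test_telescoping_over_all_orderings(self, module_matrices):
        for mm in module_matrices.values():
            full = mm.corrected(frozenset(MODULES))
            for perm in permutations(MODULES):
                marg = marginal_sequence(mm, perm)
                assert marg.sum() == pytest.approx(full, abs=1e-9)

    def test_monotone_in_added_modules(self, module_matrices):
        for mm in module_matrices.values():
            for sub in [("dist",), ("dist", "nb"), ("dist", "nb", "self")]:
                smaller = mm.corrected(frozenset(sub))
                larger = mm.corrected(frozenset(sub) | {"int"})
                assert larger >= smaller - 0.01

    def test_cache_equals_fresh_fit(self, module_matrices):
        mm = next(iter(module_matrices.values()))
        cached = mm.fit(frozenset(["dist", "nb"])).r2_uncorr
        fresh = ModuleMatrices(
            target=mm.target, y=mm.y, image_dummies=mm.image_dummies,
            blocks=mm.blocks,
        ).fit(frozenset(["dist", "nb"])).r2_uncorr
        assert cached == pytest.approx(fresh, abs=1e-10)

    def test_order_scan_shape_and_shapley_sum(self, module_matrices):
        mm = next(iter(module_matrices.values()))
        scan = order_scan(mm)
        assert len(scan) == factorial(len(MODULES))
        shap = shapley_average(scan)
        full = mm.corrected(frozenset(MODULES))
        assert shap.sum() == pytest.approx(full, abs=1e-9)

    def test_shapley_matches_subset_weight_oracle(self, module_matrices):
        # independent oracle: Shapley value via the subset-weight formula
        # phi_i = sum_S |S|!(n-|S|-1)!/n! [v(S+i) - v(S)]
        from itertools import combinations
        from math import factorial as fact

        mm = next(iter(module_matrices.values()))
        mods = ["dist", "nb", "self"]
        scan = order_scan(mm, modules=mods)
        shap = shapley_average(scan)
        n = len(mods)
        for i in mods:
            others = [m for m in mods if m != i]
            phi = 0.0
            for k in range(n):
                for S in combinations(others, k):
                    w = fact(k) * fact(n - k - 1) / fact(n)
                    phi += w * (
                        mm.corrected(frozenset(S) | {i}) - mm.corrected(frozenset(S))
                    )
            assert shap[i] == pytest.approx(phi, abs=1e-9)


class TestSelectOrdering:
    def test_lexicographic_tie_break(self):
        scans = [
            pd.DataFrame(
                {"ordering": list(permutations(("b", "a"))), "variance": [0.5, 0.5]}
            )
        ]
        assert select_ordering(scans) == ("a", "b")


class TestGroundTruthRecovery:
    def test_gradient_only_marker_dist_share(self):
        cfg = sv.recovery_config(markers=[
            MarkerSpec("grad", "signaling", w1=0.6, noise_sd=0.3, w3=(),
                       gradient_shape="monotone_out"),
            MarkerSpec("other", "other", noise_sd=0.5, w3=()),
        ])
        cells, truth = sv.generate_condition(cfg, 2)
        attach_values(cells, ["grad", "other"])
        graph = build_graph(cells, cfg)
        mm = build_modules(cells, "grad", ["grad", "other"], graph=graph)
        true_share = truth.shares.loc["grad", "dist"]
        assert mm.corrected(frozenset(["dist"])) == pytest.approx(true_share, abs=0.05)
        # and the full explained variance stays near the dist share: the
        # pure-gradient marker has nothing else to explain
        marg = marginal_sequence(mm, MODULES)
        assert marg[0] == pytest.approx(true_share, abs=0.05)
        assert abs(marg[1:]).max() < 0.03

    def test_ablating_nb_changes_nothing_for_unloaded_marker(self):
        cfg = sv.recovery_config(markers=[
            MarkerSpec("grad", "signaling", w1=0.6, noise_sd=0.3, w3=()),
            MarkerSpec("other", "other", noise_sd=0.5, w3=()),
        ])
        cells, _ = sv.generate_condition(cfg, 3)
        attach_values(cells, ["grad", "other"])
        graph = build_graph(cells, cfg)
        mm = build_modules(cells, "grad", ["grad", "other"], graph=graph)
        with_nb = mm.corrected(frozenset(MODULES))
        without = mm.corrected(frozenset(["dist", "self", "int"]))
        assert abs(with_nb - without) < 0.01


def test_stacked_bar_export(small_condition, tmp_path):
    from spherovar.decomposition import plot_stacked_contributions

    cfg, cells, truth, graph, markers = small_condition
    res = decompose_condition(cells, markers[:4], graph)
    fig = plot_stacked_contributions(res, tmp_path / "stack.png")
    assert (tmp_path / "stack.png").exists()
    import matplotlib.pyplot as plt

    plt.close(fig)


class TestDecomposeCondition:
    def test_zero_variance_marker_gets_reason(self, small_condition):
        cfg, cells, truth, graph, markers = small_condition
        cells = cells.copy()
        cells["value_const"] = 1.0
        res = decompose_condition(cells, ["const"] + markers[:3], graph)
        row = res[res["marker"] == "const"].iloc[0]
        assert row["reason"] == "zero variance"

    def test_stacks_sum_to_full(self, small_condition):
        cfg, cells, truth, graph, markers = small_condition
        res = decompose_condition(cells, markers[:6], graph)
        stack_cols = [c for c in res.columns if c.startswith("stack_")]
        total = res[stack_cols].sum(axis=1)
        assert np.allclose(total, res["r2_full"], atol=1e-9)

    def test_cell_cycle_split_adds_module(self, small_condition):
        cfg, cells, truth, graph, markers = small_condition
        cc = [m.name for m in cfg.markers if m.class_label == "cell_cycle"][:2]
        subset = markers[:4] + cc
        res = decompose_condition(cells, subset, graph, cc_markers=cc)
        assert "stack_cc" in res.columns
        stack_cols = [c for c in res.columns if c.startswith("stack_")]
        assert len(stack_cols) == 5
        assert np.allclose(res[stack_cols].sum(axis=1), res["r2_full"], atol=1e-9)
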
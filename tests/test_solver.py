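"""NNLS deconvolution, colinearity filter, alternative sampling, report."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gmapsolve.solver import (FitResult, GlycanDeconvolver, SolverConfig,
                              filter_colinear, make_report, nnls_fit,
                              sample_alternatives, solution_fit_quality)


def nnls_enumerate(C: np.ndarray, d: np.ndarray):
    """Independent oracle: exhaustive enumeration over column subsets.

    The NNLS optimum is attained at a support whose unconstrained
    least-squares solution is nonnegative; enumerating every subset and
    keeping the best nonnegative one therefore yields the global optimum.
    """
    n, m = C.shape
    best_res = float(d @ d)
    best_w = np.zeros(m)
    for k in range(1, m + 1):
        for S in itertools.combinations(range(m), k):
            sub = C[:, S]
            x, *_ = np.linalg.lstsq(sub, d, rcond=None)
            if np.all(x >= -1e-12):
                r = d - sub @ x
                res = float(r @ r)
                if res < best_res - 1e-12:
                    best_res = res
                    best_w = np.zeros(m)
                    best_w[list(S)] = np.clip(x, 0.0, None)
    return best_w, best_res


def _frame(cols: dict) -> pd.DataFrame:
    n = len(next(iter(cols.values())))
    idx = pd.MultiIndex.from_tuples([("c", f"L{i}") for i in range(n)],
                                    names=["condition", "lectin"])
    return pd.DataFrame(cols, index=idx, dtype=float)


class TestNNLSFit:
    def test_identity_exact(self):
        C = _frame({"a": [1, 0], "b": [0, 1]})
        fit = nnls_fit(C, [0.5, 0.25])
        np.testing.assert_allclose(fit.weights.to_numpy(), [0.5, 0.25])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.predicted == ("a", "b")

    def test_active_constraint(self):
        # unconstrained optimum has a negative weight; constraint binds
        C = _frame({"a": [1, 0], "b": [1, 1]})
        fit = nnls_fit(C, [0, 1])
        np.testing.assert_allclose(fit.weights.to_numpy(), [0.0, 0.5],
                                   atol=1e-12)
        assert fit.residual_ss == pytest.approx(0.5)
        assert fit.r2 == pytest.approx(0.0)

    def test_zero_target(self):
        C = _frame({"a": [1, 0], "b": [0, 1]})
        fit = nnls_fit(C, [0.0, 0.0])
        np.testing.assert_allclose(fit.weights.to_numpy(), 0.0)
        assert fit.r2 == 1.0  # constant d fitted exactly

    def test_dimension_mismatch(self):
        C = _frame({"a": [1, 0]})
        with pytest.raises(ValueError):
            nnls_fit(C, [1, 2, 3])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(20240917)
        for _ in range(100):
            # n >= m keeps the optimum unique so weights are comparable
            m = int(rng.integers(1, 5))
            n = int(rng.integers(m, 7))
            C = rng.random((n, m))
            d = rng.random(n)
            fit = nnls_fit(C, d)
            w_oracle, res_oracle = nnls_enumerate(C, d)
            assert np.max(np.abs(fit.weights.to_numpy() - w_oracle)) < 1e-6
            assert fit.residual_ss == pytest.approx(res_oracle, abs=1e-9)


class TestFilterColinear:
    def test_proportional_columns_collapse(self):
        C = _frame({"a": [1, 0, 1], "b": [2, 0, 2], "c": [0, 1, 0]})
        reduced, groups = filter_colinear(C)
        assert reduced.shape[1] == 2
        survivors = set(reduced.columns)
        assert "c" in survivors
        assert len(survivors & {"a", "b"}) == 1

    def test_independent_columns_untouched(self):
        C = _frame({"a": [1, 0], "b": [1, 1]})
        reduced, groups = filter_colinear(C)
        assert list(reduced.columns) == ["a", "b"]
        assert groups == {"a": ("a",), "b": ("b",)}

    def test_no_proportional_pair_remains(self, small_matrix, small_library,
                                           extended_panel):
        gmap = {g.id: g for g in small_library}
        reduced, _ = filter_colinear(small_matrix, gmap, extended_panel)
        X = reduced.to_numpy()
        norms = np.linalg.norm(X, axis=0)
        assert np.all(norms > 0) or X.shape[1] == 1
        U = X / np.where(norms > 0, norms, 1.0)
        G = U.T @ U
        np.fill_diagonal(G, 0.0)
        assert G.max() < 1 - 1e-9

    def test_representative_has_most_probed_residues(self, extended_panel):
        # identical response columns; the glycan with an extra probed residue
        # (an additional sialylated arm variant) must win over id order
        from gmapsolve.synthetic import build_n_glycan
        from gmapsolve.response_model import build_model_matrix, normalize_per_lectin
        g_small = build_n_glycan([("a2-6", "b1-4"), (None, None)], id="a_small")
        g_big = build_n_glycan([("a2-6", "b1-4"), (None, None)],
                               core_fucose=True, id="z_big")
        m = normalize_per_lectin(
            build_model_matrix([g_small, g_big], extended_panel))
        # drop the fucose-sensitive lectin rows so the columns are identical
        keep = m.index.get_level_values("lectin") != "AAL-like"
        m = m[keep]
        gmap = {"a_small": g_small, "z_big": g_big}
        reduced, groups = filter_colinear(m, gmap, extended_panel)
        assert list(reduced.columns) == ["z_big"]
        assert groups["z_big"] == ("a_small", "z_big")


class TestSampleAlternatives:
    def test_dominant_column_is_irreplaceable(self):
        C = _frame({"a": [1, 0, 0], "b": [0.1, 1, 0]})
        d = [1.0, 0.05, 0.0]
        initial = nnls_fit(C, d)
        accepted = sample_alternatives(C, d, initial)
        # excluding 'a' cannot reach R2 within 0.05 of the exact initial fit
        freqs = {g: sum(1 for f in accepted if g in f.predicted) / len(accepted)
                 for g in ("a",)}
        assert freqs["a"] == 1.0

    def test_near_duplicate_columns_share_frequency(self):
        C = _frame({"a": [1.0, 0.0, 0.2], "b": [1.0, 0.02, 0.2]})
        d = [1.0, 0.01, 0.2]
        initial = nnls_fit(C, d)
        accepted = sample_alternatives(C, d, initial)
        count_a = sum(1 for f in accepted if "a" in f.predicted)
        count_b = sum(1 for f in accepted if "b" in f.predicted)
        assert len(accepted) >= 2
        assert count_a >= 1 and count_b >= 1

    def test_budget_bound(self, small_matrix):
        rng = np.random.default_rng(5)
        d = small_matrix.to_numpy() @ rng.dirichlet([1] * small_matrix.shape[1])
        cfg = SolverConfig(samples_per_glycan=7, r2_window=0.5,
                           max_additional_glycans=5)
        initial = nnls_fit(small_matrix, d)
        stats = {}
        sample_alternatives(small_matrix, d, initial, cfg, stats)
        assert stats["n_refits"] <= 7 * len(initial.predicted)

    def test_r2_window_and_extra_glycan_rules(self):
        C = _frame({"a": [1, 0, 0], "b": [0.9, 0.1, 0], "c": [0, 0, 1]})
        d = [1.0, 0.0, 0.0]
        initial = nnls_fit(C, d)
        cfg = SolverConfig(r2_window=0.05, max_additional_glycans=2)
        accepted = sample_alternatives(C, d, initial, cfg)
        floor = initial.r2 - cfg.r2_window
        init_set = set(initial.predicted)
        for fit in accepted[1:]:
            assert fit.r2 >= floor
            assert sum(1 for g in fit.predicted if g not in init_set) <= 2

    def test_initial_fit_always_first(self):
        C = _frame({"a": [1, 0], "b": [0, 1]})
        d = [0.7, 0.3]
        initial = nnls_fit(C, d)
        accepted = sample_alternatives(C, d, initial)
        assert accepted[0] is initial


class TestMakeReport:
    def _fits(self, matrix, weight_rows):
        fits = []
        for row in weight_rows:
            w = pd.Series(row, index=matrix.columns, dtype=float)
            fits.append(FitResult(w, 0.0, 1.0,
                                  tuple(w.index[w > 1e-8])))
        return fits

    def test_always_included_glycan(self):
        C = _frame({"a": [1, 0], "b": [0, 1]})
        fits = self._fits(C, [[0.4, 0.0], [0.4, 0.1]])
        rep = make_report(fits, C)
        assert rep.table.loc["a", "inclusion_frequency"] == 1.0
        assert rep.table.loc["a", "mean_weight"] == pytest.approx(0.4)

    def test_below_threshold_dropped(self):
        C = _frame({"a": [1, 0], "b": [0, 1]})
        rows = [[0.4, 0.0]] * 19 + [[0.4, 0.3]]
        rep = make_report(self._fits(C, rows), C)
        assert "b" not in rep.table.index  # 1/20 = 5% < 10%
        assert "a" in rep.table.index

    def test_zero_filled_averaging(self):
        C = _frame({"a": [1, 0], "b": [0, 1]})
        rep = make_report(self._fits(C, [[0.4, 0.2], [0.0, 0.2]]), C)
        assert rep.table.loc["a", "mean_weight"] == pytest.approx(0.2)
        rep2 = make_report(self._fits(C, [[0.4, 0.2], [0.0, 0.2]]), C,
                           SolverConfig(average_over="containing"))
        assert rep2.table.loc["a", "mean_weight"] == pytest.approx(0.4)

    def test_contributions_sum_to_one(self):
        C = _frame({"a": [1, 0], "b": [0.5, 1]})
        rep = make_report(self._fits(C, [[0.4, 0.2]]), C)
        assert rep.table["contribution"].sum() == pytest.approx(1.0)
        assert (rep.table["contribution"] >= 0).all()

    def test_empty_accepted_rejected(self):
        C = _frame({"a": [1, 0]})
        with pytest.raises(ValueError):
            make_report([], C)


class TestEndToEnd:
    def test_noiseless_recovery_order_invariant(self, small_matrix):
        rng = np.random.default_rng(11)
        ids = list(small_matrix.columns)
        a_true = pd.Series(0.0, index=ids)
        a_true[ids[0]] = 0.6
        a_true[ids[5]] = 0.4
        d = small_matrix.to_numpy() @ a_true.to_numpy()
        model = GlycanDeconvolver().fit(small_matrix, d)
        perm = rng.permutation(len(ids))
        shuffled = small_matrix.iloc[:, perm]
        model2 = GlycanDeconvolver().fit(shuffled, d)
        t1 = model.report_.table.sort_index()
        t2 = model2.report_.table.sort_index()
        pd.testing.assert_frame_equal(t1, t2)

    def test_weights_nonnegative_frequencies_in_unit_interval(self, small_matrix):
        rng = np.random.default_rng(3)
        d = small_matrix.to_numpy() @ rng.dirichlet([1] * small_matrix.shape[1])
        model = GlycanDeconvolver().fit(small_matrix, d)
        tbl = model.report_.table
        assert (model.weights_ >= 0).all()
        assert tbl["inclusion_frequency"].between(0, 1).all()
        assert tbl["contribution"].sum() == pytest.approx(1.0)

    def test_solution_fit_quality_exact(self):
        C = _frame({"a": [1, 0], "b": [0, 1]})
        d = [0.7, 0.3]
        model = GlycanDeconvolver().fit(C, d)
        r, r2 = solution_fit_quality(model.report_, d)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_sklearn_param_interface(self):
        est = GlycanDeconvolver(r2_window=0.1)
        assert est.get_params()["r2_window"] == 0.1
        est.set_params(samples_per_glycan=10)
        assert est.samples_per_glycan == 10
        C = _frame({"a": [1, 0], "b": [0, 1]})
        est.fit(C, [0.5, 0.5])
        pred = est.predict(C)
        np.testing.assert_allclose(pred, [0.5, 0.5], atol=1e-10)
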
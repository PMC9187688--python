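import numpy as np
import pandas as pd
import pytest

from circsc.deconv import (
    MixtureResult,
    SignatureMatrix,
    aggregate_types,
    build_signature,
    deconvolve,
    evaluate_fit,
)
from circsc.quantify import ExpressionMatrix
from circsc.specificity import MarkerResult, find_markers
from circsc import synthetic


def grid_search_two_type(S: np.ndarray, b: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Exhaustive search oracle for 2-type problems: brute-force the
    non-negative least-squares objective on a grid, then renormalize to
    fractions exactly as the solver under test does."""
    grid = np.arange(0.0, 2.0 + step / 2, step)
    f1, f2 = np.meshgrid(grid, grid, indexing="ij")
    loss = ((S[:, 0, None, None] * f1 + S[:, 1, None, None] * f2 - b[:, None, None]) ** 2).sum(axis=0)
    i, j = np.unravel_index(np.argmin(loss), loss.shape)
    f = np.array([grid[i], grid[j]])
    return f / f.sum() if f.sum() else f


class TestBuildSignature:
    def synthetic_marker_data(self):
        """3 cell types x 20 cells, 3 planted marker blocks of 20 features."""
        rng = np.random.default_rng(3)
        types = ["T cells", "B-cell", "NK cells"]
        cells = [f"c{j}" for j in range(60)]
        cell_types = {c: types[j // 20] for j, c in enumerate(cells)}
        X = rng.gamma(2.0, 0.5, size=(60, 60)) + 0.5  # detected everywhere
        for k in range(3):
            X[20 * k : 20 * (k + 1), 20 * k : 20 * (k + 1)] += 30.0
        expr = ExpressionMatrix(X, [f"f{i}" for i in range(60)], cells, "cpm")
        return expr, cell_types

    def test_planted_marker_sets_fully_retained(self):
        expr, cell_types = self.synthetic_marker_data()
        markers = find_markers(expr, cell_types, min_fold=3.0)
        sig = build_signature(expr, cell_types, markers)
        assert sig.values.shape == (60, 3)
        assert set(sig.cell_types) == {"T cells", "B-cell", "NK cells"}

    def make_marker(self, fid, ctype, fold=5.0, is_marker=True):
        return MarkerResult(fid, ctype, 0.001, 0.01, fold, is_marker)

    def test_feature_detected_in_one_type_excluded(self):
        cells = ["a", "b", "c", "d"]
        cell_types = {"a": "A", "b": "A", "c": "B", "d": "B"}
        X = np.array([[9.0, 8.0, 0.0, 0.0], [5.0, 5.0, 1.0, 1.0], [1.0, 1.0, 6.0, 7.0]])
        expr = ExpressionMatrix(X, ["only_A", "f1", "f2"], cells, "cpm")
        markers = [
            self.make_marker("only_A", "A"),
            self.make_marker("f1", "A"),
            self.make_marker("f2", "B"),
        ]
        sig = build_signature(expr, cell_types, markers)
        assert "only_A" not in sig.feature_ids

    def test_multi_type_marker_excluded(self):
        cells = ["a", "b", "c", "d"]
        cell_types = {"a": "A", "b": "A", "c": "B", "d": "B"}
        X = np.ones((3, 4)) + np.arange(12).reshape(3, 4)
        expr = ExpressionMatrix(X, ["amb", "f1", "f2"], cells, "cpm")
        markers = [
            self.make_marker("amb", "A"),
            self.make_marker("amb", "B"),
            self.make_marker("f1", "A"),
            self.make_marker("f2", "B"),
        ]
        sig = build_signature(expr, cell_types, markers)
        assert "amb" not in sig.feature_ids

    def test_unidentifiable_signature_rejected(self):
        cells = ["a", "b", "c", "d"]
        cell_types = {"a": "A", "b": "A", "c": "B", "d": "B"}
        expr = ExpressionMatrix(np.ones((1, 4)), ["f1"], cells, "cpm")
        with pytest.raises(ValueError, match="unidentifiable"):
            build_signature(expr, cell_types, [self.make_marker("f1", "A")])


class TestDeconvolve:
    def test_exact_identity_mixture(self):
        sig = SignatureMatrix(
            pd.DataFrame(np.diag([10.0, 10.0]), index=["f1", "f2"], columns=["A", "B"]),
            provenance={},
        )
        [res] = deconvolve(sig, pd.Series([3.0, 7.0], index=["f1", "f2"], name="s"))
        assert np.allclose(res.fractions, [0.3, 0.7])
        assert res.rmse == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_forward_backward_recovery(self):
        rng = np.random.default_rng(11)
        S = rng.lognormal(1.0, 1.0, size=(30, 3))
        f_true = np.array([0.2, 0.3, 0.5])
        sig = SignatureMatrix(
            pd.DataFrame(S, index=[f"f{i}" for i in range(30)], columns=list("ABC")),
            provenance={},
        )
        bulk = pd.Series(S @ f_true, index=sig.feature_ids, name="s")
        [res] = deconvolve(sig, bulk)
        assert np.abs(res.fractions.to_numpy() - f_true).max() < 1e-6

    def test_matches_grid_search_on_two_type_problems(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            S = rng.lognormal(1.0, 0.8, size=(15, 2))
            f_true = rng.dirichlet([1.0, 1.0])
            b = (S @ f_true) * rng.lognormal(0, 0.05, size=15)
            sig = SignatureMatrix(
                pd.DataFrame(S, index=[f"f{i}" for i in range(15)], columns=list("AB")),
                provenance={},
            )
            [res] = deconvolve(sig, pd.Series(b, index=sig.feature_ids, name="s"))
            oracle = grid_search_two_type(S, b)
            assert np.abs(res.fractions.to_numpy() - oracle).max() <= 0.01

    def test_bulk_missing_features_imputed_with_warning(self):
        sig = SignatureMatrix(
            pd.DataFrame(np.diag([10.0, 10.0]), index=["f1", "f2"], columns=["A", "B"]),
            provenance={},
        )
        with pytest.warns(UserWarning, match="imputed"):
            [res] = deconvolve(sig, pd.Series([3.0], index=["f1"], name="s"))
        assert res.fractions.sum() == pytest.approx(1.0)

    def test_all_zero_bulk_rejected(self):
        sig = SignatureMatrix(
            pd.DataFrame(np.diag([10.0, 10.0]), index=["f1", "f2"], columns=["A", "B"]),
            provenance={},
        )
        with pytest.raises(ValueError, match="all zero"):
            deconvolve(sig, pd.Series([0.0, 0.0], index=["f1", "f2"], name="s"))

    def test_poorly_explained_bulk_still_solvable(self):
        sig = SignatureMatrix(
            pd.DataFrame([[1.0, 1.0], [1.0, 1.0], [5.0, 0.1]], index=["f1", "f2", "f3"],
                         columns=["A", "B"]),
            provenance={},
        )
        bulk = pd.Series([9.0, 0.1, 0.1], index=["f1", "f2", "f3"], name="s")
        [res] = deconvolve(sig, bulk)
        assert res.rmse > 0
        assert res.fractions.sum() == pytest.approx(1.0)

    def test_svr_mode_close_to_truth_on_conditioned_signature(self):
        rng = np.random.default_rng(13)
        S = rng.lognormal(1.0, 1.0, size=(40, 3))
        f_true = np.array([0.15, 0.25, 0.6])
        b = (S @ f_true) * rng.lognormal(0, 0.05, size=40)
        sig = SignatureMatrix(
            pd.DataFrame(S, index=[f"f{i}" for i in range(40)], columns=list("ABC")),
            provenance={},
        )
        [res] = deconvolve(sig, pd.Series(b, index=sig.feature_ids, name="s"), method="svr")
        assert np.abs(res.fractions.to_numpy() - f_true).max() < 0.1


class TestEvaluateFit:
    def sig(self, S, types):
        return SignatureMatrix(
            pd.DataFrame(S, index=[f"f{i}" for i in range(len(S))], columns=types),
            provenance={},
        )

    def test_perfect_reconstruction(self):
        sig = self.sig(np.diag([10.0, 10.0]), ["A", "B"])
        rmse, r = evaluate_fit(sig, pd.Series([0.3, 0.7], index=["A", "B"]),
                               pd.Series([3.0, 7.0], index=["f0", "f1"]))
        assert rmse == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_degenerate_constant_reconstruction(self):
        # b = (0, 2) standardizes to (-1, 1); constant yhat = (1, 1) is left
        # unchanged by the degenerate convention, so rmse = sqrt(2)
        sig = self.sig(np.array([[1.0], [1.0]]), ["A"])
        with pytest.warns(UserWarning, match="constant"):
            rmse, r = evaluate_fit(sig, pd.Series([1.0], index=["A"]),
                                   pd.Series([0.0, 2.0], index=["f0", "f1"]))
        assert rmse == pytest.approx(np.sqrt(2.0))
        assert np.isnan(r)

    def test_scale_invariance(self):
        rng = np.random.default_rng(14)
        S = rng.lognormal(0, 1, size=(10, 2))
        f = pd.Series([0.4, 0.6], index=["A", "B"])
        b = pd.Series(rng.lognormal(0, 1, size=10), index=[f"f{i}" for i in range(10)])
        rmse1, _ = evaluate_fit(self.sig(S, ["A", "B"]), f, b)
        rmse2, _ = evaluate_fit(self.sig(2 * S, ["A", "B"]), f, 2 * b)
        assert rmse1 == pytest.approx(rmse2)


class TestAggregateTypes:
    def test_sums_fine_into_coarse(self):
        out = aggregate_types(
            pd.Series({"T mem": 0.1, "T naive": 0.2, "B": 0.7}),
            {"T mem": "T cells", "T naive": "T cells", "B": "B cells"},
        )
        assert out["T cells"] == pytest.approx(0.3)
        assert out.sum() == pytest.approx(1.0)

    def test_identity_mapping_unchanged(self):
        f = pd.Series({"A": 0.4, "B": 0.6})
        assert aggregate_types(f, {"A": "A", "B": "B"}).sort_index().equals(f.sort_index())

    def test_unmapped_type_rejected(self):
        with pytest.raises(ValueError, match="without a coarse"):
            aggregate_types(pd.Series({"A": 1.0}), {})


def test_mixture_result_invariants():
    with pytest.raises(ValueError):
        MixtureResult("s", pd.Series([0.5, 0.6]), 0.0, 1.0)
    with pytest.raises(ValueError):
        MixtureResult("s", pd.Series([-0.1, 1.1]), 0.0, 1.0)


def test_parameter_recovery_over_many_mixture_sizes():
    """3-8 cell types, Dirichlet fractions, 5% noise: per-run r >= 0.95."""
    rng = np.random.default_rng(15)
    run = 0
    for n_types in range(3, 9):
        for rep in range(3):
            seed = 100 + run
            run += 1
            types = [f"type{k}" for k in range(n_types)]
            profiles = pd.DataFrame(
                np.random.default_rng(seed).lognormal(1.0, 1.0, size=(10 * n_types, n_types)),
                index=[f"f{i}" for i in range(10 * n_types)],
                columns=types,
            )
            bulk, truth = synthetic.simulate_bulk_mixtures(
                profiles, n_samples=5, dirichlet_alpha=1.0, noise_sd=0.05, seed=seed
            )
            sig = SignatureMatrix(profiles, provenance={})
            for res, (_, t) in zip(deconvolve(sig, bulk), truth.iterrows()):
                r = np.corrcoef(res.fractions.reindex(t.index), t)[0, 1]
                assert r >= 0.95
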
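import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

from circsc.io_model import CellAnnotation, CountMatrix
from circsc.quantify import ExpressionMatrix
from circsc.specificity import (
    classify_pattern,
    feature_correlation,
    find_markers,
    group_mean_profile,
    markers_frame,
    tau_specificity,
    tau_table,
)


class TestTau:
    def test_single_group_expression_gives_one(self):
        assert tau_specificity([0, 0, 7]) == 1.0

    def test_uniform_profile_gives_zero(self):
        assert tau_specificity([5, 5, 5, 5]) == 0.0

    def test_worked_value(self):
        # x_hat = (0.25, 0.5, 1); T = (0.75 + 0.5 + 0) / 2
        assert tau_specificity([1, 2, 4]) == pytest.approx(0.625, abs=1e-15)

    def test_all_zero_profile_is_missing(self):
        assert np.isnan(tau_specificity([0.0, 0.0]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tau_specificity([3.0])
        with pytest.raises(ValueError):
            tau_specificity([1.0, -1.0])

    @given(
        x=st.lists(st.floats(0.0, 1e6), min_size=2, max_size=10).filter(
            lambda v: max(v) > 0
        ),
        c=st.floats(1e-6, 1e6),
    )
    def test_scale_invariance(self, x, c):
        assert tau_specificity(np.array(x) * c) == pytest.approx(
            tau_specificity(x), abs=1e-9
        )

    @given(
        x=st.lists(st.floats(0.1, 100.0), min_size=3, max_size=8),
        frac=st.floats(0.0, 1.0),
    )
    def test_concentrating_mass_never_decreases_tau(self, x, frac):
        x = np.array(x)
        i_max = int(np.argmax(x))
        i_other = (i_max + 1) % len(x)
        eps = frac * x[i_other]
        moved = x.copy()
        moved[i_other] -= eps
        moved[i_max] += eps
        assert tau_specificity(moved) >= tau_specificity(x) - 1e-12

    def test_table_matches_scalar(self):
        profiles = pd.DataFrame(
            [[1, 2, 4], [5, 5, 5], [0, 0, 0]], index=["a", "b", "c"]
        )
        tau = tau_table(profiles)
        assert tau["a"] == pytest.approx(0.625)
        assert tau["b"] == 0.0
        assert np.isnan(tau["c"])


class TestGroupMeanProfile:
    def test_means_and_singletons(self):
        expr = ExpressionMatrix(np.array([[2.0, 4.0, 9.0]]), ["f"], ["a", "b", "c"], "cpm")
        out = group_mean_profile(expr, {"a": "g1", "b": "g1", "c": "g2"})
        assert out.loc["f", "g1"] == 3.0
        assert out.loc["f", "g2"] == 9.0

    def test_unassigned_cell_rejected(self):
        expr = ExpressionMatrix(np.zeros((1, 2)), ["f"], ["a", "b"], "cpm")
        with pytest.raises(ValueError):
            group_mean_profile(expr, {"a": "g"})


class TestClassifyPattern:
    def annotations(self, spec):
        return [
            CellAnnotation(f"c{j}", tissue=t, cell_type=ct)
            for j, (ct, t) in enumerate(spec)
        ]

    def matrix(self, row, n):
        return CountMatrix(sp.csr_matrix(np.array([row])), ["f"], [f"c{j}" for j in range(n)], "circ")

    def test_single_cell_is_lowly_expressed(self):
        ann = self.annotations([("GABA", "brain")] * 4)
        out = classify_pattern(self.matrix([0, 3, 0, 0], 4), ann)
        assert out.loc["f", "category"] == "lowly_expressed"

    def test_one_cell_type_is_cell_type_enriched(self):
        ann = self.annotations([("GABA", "brain")] * 6)
        out = classify_pattern(self.matrix([1, 1, 1, 1, 1, 1], 6), ann)
        assert out.loc["f", "category"] == "cell_type_enriched"

    def test_one_tissue_many_types_is_tissue_enriched(self):
        ann = self.annotations([("GABA", "brain"), ("GLUT", "brain"), ("MG", "brain"), ("T", "blood")])
        out = classify_pattern(self.matrix([1, 1, 1, 0], 4), ann)
        assert out.loc["f", "category"] == "tissue_enriched"

    def test_majority_detection_is_general_enriched(self):
        spec = [("GABA", "brain")] * 3 + [("T", "blood")] * 3 + [("hep", "liver")] * 4
        ann = self.annotations(spec)
        out = classify_pattern(self.matrix([1, 1, 1, 1, 1, 1, 0, 0, 0, 0], 10), ann)
        assert out.loc["f", "category"] == "general_enriched"

    def test_residual_is_group_enriched(self):
        spec = [("GABA", "brain")] * 2 + [("T", "blood")] * 2 + [("hep", "liver")] * 4
        ann = self.annotations(spec)
        out = classify_pattern(self.matrix([1, 0, 1, 0, 0, 0, 0, 0], 8), ann)
        assert out.loc["f", "category"] == "group_enriched"

    def test_undetected_feature_rejected(self):
        ann = self.annotations([("GABA", "brain")] * 2)
        with pytest.raises(ValueError, match="no cell"):
            classify_pattern(self.matrix([0, 0], 2), ann)

    def test_categories_partition_detected_features(self):
        rng = np.random.default_rng(9)
        n_cells = 60
        types = ["GABA", "GLUT", "T", "hep"]
        tissues = {"GABA": "brain", "GLUT": "brain", "T": "blood", "hep": "liver"}
        picks = rng.choice(types, size=n_cells)
        ann = [
            CellAnnotation(f"c{j}", tissue=tissues[picks[j]], cell_type=picks[j])
            for j in range(n_cells)
        ]
        counts = rng.poisson(0.5, size=(40, n_cells))
        counts[counts.sum(axis=1) == 0, 0] = 1
        mat = CountMatrix(sp.csr_matrix(counts), [f"f{i}" for i in range(40)], [f"c{j}" for j in range(n_cells)], "circ")
        out = classify_pattern(mat, ann)
        assert out["category"].notna().all()
        assert len(out) == 40


class TestFindMarkers:
    def expr(self, rows, cells):
        return ExpressionMatrix(
            np.asarray(rows, dtype=float),
            [f"f{i}" for i in range(len(rows))],
            cells,
            "cpm",
        )

    def test_complete_separation_exact_p(self):
        cells = [f"c{j}" for j in range(8)]
        types = {c: ("A" if j < 4 else "B") for j, c in enumerate(cells)}
        markers = find_markers(self.expr([[5, 6, 7, 8, 0, 0, 0, 1]], cells), types)
        pA = [m for m in markers if m.target_cell_type == "A"][0]
        assert pA.p_value == pytest.approx(2 / 70)

    def test_identical_groups_give_p_one(self):
        cells = [f"c{j}" for j in range(6)]
        types = {c: ("A" if j < 3 else "B") for j, c in enumerate(cells)}
        markers = find_markers(self.expr([[1, 2, 3, 1, 2, 3]], cells), types)
        assert all(m.p_value == 1.0 for m in markers)

    def test_all_tied_values_give_p_one(self):
        cells = [f"c{j}" for j in range(6)]
        types = {c: ("A" if j < 3 else "B") for j, c in enumerate(cells)}
        markers = find_markers(self.expr([[2, 2, 2, 2, 2, 2]], cells), types)
        assert all(m.p_value == 1.0 for m in markers)

    def test_fold_change_boundary(self):
        # target mean 9, best other mean 3 -> fold approx 3 passes min_fold=3
        cells = [f"c{j}" for j in range(8)]
        types = {c: ("A" if j < 4 else "B") for j, c in enumerate(cells)}
        markers = find_markers(
            self.expr([[9, 9, 9, 9, 3, 3, 3, 3]], cells), types, min_fold=3.0
        )
        mA = [m for m in markers if m.target_cell_type == "A"][0]
        assert mA.fold_change == pytest.approx((9 + 0.01) / (3 + 0.01))
        assert mA.fold_change >= 3.0 or mA.fold_change == pytest.approx(3.0, rel=1e-2)

    def test_bh_adjustment_is_monotone_step_up(self):
        rng = np.random.default_rng(13)
        cells = [f"c{j}" for j in range(30)]
        types = {c: ("A" if j < 15 else "B") for j, c in enumerate(cells)}
        rows = rng.gamma(2.0, 1.0, size=(50, 30))
        frame = markers_frame(find_markers(self.expr(rows, cells), types))
        frame = frame.sort_values("p_value")
        assert frame["adjusted_p"].is_monotonic_increasing
        assert frame["adjusted_p"].between(0, 1).all()

    def test_requires_two_cell_types(self):
        with pytest.raises(ValueError):
            find_markers(self.expr([[1, 2]], ["a", "b"]), {"a": "A", "b": "A"})

    def test_planted_marker_detected(self):
        rng = np.random.default_rng(21)
        cells = [f"c{j}" for j in range(60)]
        types = {c: ("A" if j < 20 else ("B" if j < 40 else "C")) for j, c in enumerate(cells)}
        base = rng.gamma(2.0, 0.5, size=(10, 60))
        base[0, :20] += 20.0  # strong A marker
        markers = [
            m
            for m in find_markers(self.expr(base, cells), types)
            if m.feature_id == "f0" and m.target_cell_type == "A"
        ]
        assert markers[0].is_marker


class TestFeatureCorrelation:
    def test_perfect_linear_and_monotone(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert feature_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert feature_correlation(x, 2 * x + 1, method="spearman") == pytest.approx(1.0)
        assert feature_correlation(x, -x) == pytest.approx(-1.0)

    def test_spearman_worked_value(self):
        assert feature_correlation(
            [1, 2, 3], [1, 3, 2], method="spearman"
        ) == pytest.approx(0.5)

    def test_zero_variance_gives_missing_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r = feature_correlation([1, 1, 1], [1, 2, 3])
        assert np.isnan(r)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            feature_correlation([1, 2], [3, 4])
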
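"""Covariate extraction, standardization, VIF, interactions, sign reversal."""

import numpy as np
import pandas as pd
import pytest

from bearshield import (
    GridSpec,
    Standardization,
    add_survival_interactions,
    compute_vif,
    distance_to_features,
    extract_at_points,
    reverse_distance_signs,
    standardize,
)
from bearshield.design import compute_gvif, interaction_col
from bearshield.landscape import FeatureSet


class TestDistanceRasters:
    def test_three_four_five_triangle(self):
        grid = GridSpec(cell_size=25.0, n_rows=20, n_cols=20)
        features = FeatureSet(habitations=np.array([[12.5, 12.5]]))
        d = distance_to_features(grid, features, "habitations")
        # cell centre at (312.5, 412.5) is 300 m east, 400 m north of the feature
        row, col = grid.index_of(312.5, 412.5)
        assert d[row, col] == pytest.approx(0.5, abs=1e-12)

    def test_feature_on_cell_centre_gives_zero(self):
        grid = GridSpec(n_rows=10, n_cols=10)
        features = FeatureSet(habitations=np.array([[137.5, 62.5]]))
        d = distance_to_features(grid, features, "habitations")
        assert d.min() == 0.0

    def test_matches_brute_force_segment_oracle(self):
        rng = np.random.default_rng(0)
        grid = GridSpec(n_rows=100, n_cols=100)
        lines = [rng.uniform(0, 2500, size=(4, 2)) for _ in range(3)]
        features = FeatureSet(habitations=np.empty((0, 2)), roads=lines)
        d = distance_to_features(grid, features, "roads")

        def seg_dist(p, a, b):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
            return np.hypot(*(a + t * ab - p))

        X, Y = grid.cell_centers()
        for row, col in rng.integers(0, 100, size=(40, 2)):
            p = np.array([X[row, col], Y[row, col]])
            best = min(
                seg_dist(p, line[i], line[i + 1])
                for line in lines
                for i in range(len(line) - 1)
            )
            assert d[row, col] == pytest.approx(best / 1000.0, abs=1e-9)


class TestExtraction:
    def test_cell_centre_returns_cell_values(self, small_landscape):
        stack, _ = small_landscape
        X, Y = stack.grid.cell_centers()
        rows = extract_at_points(stack, [X[7, 11]], [Y[7, 11]])
        assert rows["ndvi"].iloc[0] == stack.continuous["ndvi"][7, 11]

    def test_boundary_point_assigned_half_open(self, small_landscape):
        stack, _ = small_landscape
        # point exactly on the edge between cells (., 3) and (., 4) -> cell 4
        x_edge = stack.grid.origin_x + 4 * stack.grid.cell_size
        y = stack.grid.origin_y + 12.5
        rows = extract_at_points(stack, [x_edge], [y])
        assert rows["ndvi"].iloc[0] == stack.continuous["ndvi"][0, 4]

    def test_matches_per_point_loop(self, small_landscape):
        stack, _ = small_landscape
        rng = np.random.default_rng(1)
        xmin, ymin, xmax, ymax = stack.grid.extent
        xs = rng.uniform(xmin, xmax - 1e-6, 1000)
        ys = rng.uniform(ymin, ymax - 1e-6, 1000)
        rows = extract_at_points(stack, xs, ys)
        for i in rng.integers(0, 1000, 50):
            r, c = stack.grid.index_of(xs[i], ys[i])
            assert rows["dist_road"].iloc[i] == stack.continuous["dist_road"][r, c]
            code = stack.landcover[r, c]
            indicators = rows.iloc[i][["bog", "trb", "clearcut", "young", "mid_aged", "old"]]
            assert indicators.sum() in (0.0, 1.0)
            if code < 6:
                assert indicators.iloc[code] == 1.0

    def test_outside_point_raises_with_coordinates(self, small_landscape):
        stack, _ = small_landscape
        with pytest.raises(ValueError, match="outside"):
            extract_at_points(stack, [-1e5], [0.0])


class TestStandardize:
    def test_simple_column(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, std = standardize(table, ["a"])
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])
        assert std.mean["a"] == 2.0 and std.sd["a"] == 1.0

    def test_idempotent_on_z_scores(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({"a": rng.normal(3.0, 2.0, 500)})
        once, _ = standardize(table, ["a"])
        twice, _ = standardize(once, ["a"])
        np.testing.assert_allclose(once["a"], twice["a"], atol=1e-12)

    def test_moments_after_transform(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"a": rng.exponential(4.0, 1000)})
        out, std = standardize(table, ["a"])
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-8)
        assert out["a"].var(ddof=1) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(std.invert(out)["a"], table["a"], atol=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0]}), ["a"])


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 400
        t = np.arange(n)
        table = pd.DataFrame({"a": np.sin(t), "b": np.cos(t)})
        vif = compute_vif(table, ["a", "b"])
        assert vif["a"] == pytest.approx(1.0, abs=0.02)

    def test_closed_form_at_r_08(self):
        rng = np.random.default_rng(4)
        n = 200_000
        a = rng.normal(size=n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=n)
        vif = compute_vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        assert vif["a"] == pytest.approx(1.0 / (1.0 - 0.64), abs=0.03)

    def test_matches_independent_regression_oracle(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(300, 2))
        X = np.column_stack(
            [
                base[:, 0],
                base[:, 1],
                0.6 * base[:, 0] + rng.normal(0, 0.7, 300),
                0.3 * base[:, 0] - 0.5 * base[:, 1] + rng.normal(0, 1, 300),
                rng.normal(size=300),
            ]
        )
        names = list("abcde")
        table = pd.DataFrame(X, columns=names)
        vif = compute_vif(table, names)
        for j, name in enumerate(names):
            yj = X[:, j]
            Z = np.column_stack([np.ones(300), np.delete(X, j, axis=1)])
            resid = yj - Z @ np.linalg.lstsq(Z, yj, rcond=None)[0]
            r2 = 1.0 - resid.var() / yj.var()
            assert vif[name] == pytest.approx(1.0 / (1.0 - r2), abs=1e-8)

    def test_exact_collinearity_reported_infinite(self):
        a = np.arange(50, dtype=float)
        table = pd.DataFrame({"a": a, "b": 2.0 * a, "c": np.random.default_rng(0).normal(size=50)})
        vif = compute_vif(table, ["a", "b", "c"])
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])

    def test_grouped_gvif_baseline_invariant(self):
        """Dummy-set GVIF is the same whichever class is the baseline."""
        rng = np.random.default_rng(6)
        codes = rng.integers(0, 4, 3000)
        x = rng.normal(size=3000) + 0.3 * (codes == 1)
        table = pd.DataFrame({"x": x})
        for drop in (0, 3):
            for c in range(4):
                if c != drop:
                    table[f"d{drop}_{c}"] = (codes == c).astype(float)
        g0 = compute_gvif(table, {"x": ["x"], "d": [f"d0_{c}" for c in (1, 2, 3)]})
        g3 = compute_gvif(table, {"x": ["x"], "d": [f"d3_{c}" for c in (0, 1, 2)]})
        assert g0["d"] == pytest.approx(g3["d"], rel=1e-6)
        assert g0["x"] == pytest.approx(g3["x"], rel=1e-6)


class TestInteractionsAndSigns:
    def _table(self):
        rng = np.random.default_rng(7)
        return pd.DataFrame(
            {
                "survival": np.repeat([0, 1], 25),
                "dist_habitation": rng.normal(size=50),
                "ndvi": rng.normal(size=50),
            }
        )

    def test_products_elementwise(self):
        table = self._table()
        out = add_survival_interactions(table, ["dist_habitation", "ndvi"])
        for term in ("dist_habitation", "ndvi"):
            np.testing.assert_array_equal(
                out[interaction_col(term)], table[term] * table["survival"]
            )
        assert (out.loc[out["survival"] == 0, "ndvi:survival"] == 0).all()

    def test_unknown_term_raises(self):
        with pytest.raises(KeyError, match="elevation"):
            add_survival_interactions(self._table(), ["elevation"])

    def test_sign_reversal_flips_distance_terms_only(self):
        from dataclasses import dataclass

        @dataclass
        class MiniFit:
            beta: dict
            se: dict

        fit = MiniFit(
            beta={"dist_habitation": 0.21, "ndvi": 0.19, "dist_habitation:survival": -0.73},
            se={"dist_habitation": 0.02, "ndvi": 0.02, "dist_habitation:survival": 0.03},
        )
        rep = reverse_distance_signs(fit)
        assert rep.beta["dist_habitation"] == -0.21
        assert rep.beta["dist_habitation:survival"] == 0.73
        assert rep.beta["ndvi"] == 0.19
        assert rep.se == fit.se

    def test_sign_reversal_is_involution(self):
        from dataclasses import dataclass

        @dataclass
        class MiniFit:
            beta: dict
            se: dict

        fit = MiniFit(beta={"dist_road": -0.557, "bog": -0.761}, se={})
        assert reverse_distance_signs(reverse_distance_signs(fit)).beta == fit.beta


def test_standardization_validates_sd():
    with pytest.raises(ValueError, match="positive"):
        Standardization(mean={"a": 0.0}, sd={"a": 0.0})
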
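"""Spatial gating, composition, and distance-to-ECM statistics."""

import numpy as np
import pandas as pd
import pytest

from tumorkit import spatial


@pytest.fixture
def gating_tree():
    return spatial.parse_gating_tree(
        {
            "marker": "CD45",
            "threshold": 0.3,
            "name": "immune_split",
            "above": {
                "marker": "CD3",
                "threshold": 0.25,
                "name": "tcell_split",
                "above": {
                    "marker": "CD8",
                    "threshold": 0.4,
                    "name": "cd8_split",
                    "above": "cd8_tcell",
                    "below": "other_tcell",
                },
                "below": "other_immune",
            },
            "below": "nonimmune",
        }
    )


def random_cells(rng, n=100):
    return pd.DataFrame(
        {
            "CD45": rng.random(n),
            "CD3": rng.random(n),
            "CD8": rng.random(n),
        }
    )


class TestNormalization:
    def test_max_cell_is_one_and_brute_force(self, rng):
        cells = random_cells(rng) * 500
        cells["image"] = np.repeat(["im1", "im2"], 50)
        norm = spatial.normalize_intensities(cells, ["CD45", "CD3"], image_col="image")
        for im, sub in cells.groupby("image"):
            got = norm.loc[sub.index]
            for m in ["CD45", "CD3"]:
                assert got[m].max() == pytest.approx(1.0)
                assert np.allclose(got[m], sub[m] / sub[m].max())

    def test_all_zero_marker_flagged(self):
        cells = pd.DataFrame({"M": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="all zero"):
            norm = spatial.normalize_intensities(cells, ["M"])
        assert (norm["M"] == 0).all()

    def test_gating_scale_invariance(self, rng, gating_tree):
        cells = random_cells(rng)
        labels1 = spatial.apply_gating_tree(
            spatial.normalize_intensities(cells, ["CD45", "CD3", "CD8"]), gating_tree
        )
        scaled = cells * 123.0
        labels2 = spatial.apply_gating_tree(
            spatial.normalize_intensities(scaled, ["CD45", "CD3", "CD8"]), gating_tree
        )
        assert (labels1 == labels2).all()


class TestGating:
    def test_counts_match_boolean_oracle(self, rng, gating_tree):
        cells = random_cells(rng)
        labels = spatial.apply_gating_tree(cells, gating_tree)
        oracle = np.where(
            cells["CD45"] < 0.3,
            "nonimmune",
            np.where(
                cells["CD3"] < 0.25,
                "other_immune",
                np.where(cells["CD8"] >= 0.4, "cd8_tcell", "other_tcell"),
            ),
        )
        assert (labels.to_numpy() == oracle).all()

    def test_threshold_boundary_goes_above(self):
        tree = spatial.parse_gating_tree(
            {"marker": "M", "threshold": 0.5, "above": "pos", "below": "neg"}
        )
        cells = pd.DataFrame({"M": [0.5, 0.4999]})
        labels = spatial.apply_gating_tree(cells, tree)
        assert labels.tolist() == ["pos", "neg"]

    def test_missing_marker_names_node(self, gating_tree):
        cells = pd.DataFrame({"CD45": [1.0]})
        with pytest.raises(KeyError, match="CD3"):
            spatial.apply_gating_tree(cells, gating_tree)

    def test_parent_counts_sum_children(self, rng, gating_tree):
        cells = random_cells(rng, 500)
        counts = spatial.population_counts(cells, gating_tree)
        by_name = counts.set_index("population")["count"]
        for parent in counts.loc[~counts["is_leaf"], "population"]:
            children = counts.loc[counts["parent"] == parent, "count"]
            if len(children):
                assert children.sum() == by_name[parent]


class TestComposition:
    def test_percent_and_density(self):
        tree = spatial.parse_gating_tree(
            {"marker": "CD45", "threshold": 0.5, "above": "immune", "below": "other"}
        )
        cells = pd.DataFrame({"CD45": [0.9] * 9 + [0.1] * 91})
        report = spatial.composition_metrics(cells, tree, tissue_area_mm2=1.0)
        immune = report.set_index("population").loc["immune"]
        assert immune["percent_of_total"] == pytest.approx(9.0)
        assert immune["density_per_mm2"] == pytest.approx(9.0)

    def test_pooled_rois_before_percentages(self):
        tree = spatial.parse_gating_tree(
            {"marker": "M", "threshold": 0.5, "above": "pos", "below": "neg"}
        )
        roi1 = pd.DataFrame({"M": [1.0] * 30 + [0.0] * 30})
        roi2 = pd.DataFrame({"M": [1.0] * 10 + [0.0] * 30})
        pooled = pd.concat([roi1, roi2], ignore_index=True)
        report = spatial.composition_metrics(pooled, tree, tissue_area_mm2=2.0)
        pos = report.set_index("population").loc["pos"]
        assert pos["percent_of_total"] == pytest.approx(100 * 40 / 100)
        assert pos["density_per_mm2"] == pytest.approx(20.0)

    def test_sibling_percentages_sum_to_parent(self, rng, gating_tree):
        cells = random_cells(rng, 300)
        report = spatial.composition_metrics(cells, gating_tree, 1.0)
        by_name = report.set_index("population")
        for parent in report.loc[~report["is_leaf"], "population"]:
            kids = report.loc[report["parent"] == parent]
            if len(kids):
                assert kids["percent_of_total"].sum() == pytest.approx(
                    by_name.loc[parent, "percent_of_total"], abs=1e-9
                )

    def test_empty_parent_percentage_missing(self):
        tree = spatial.parse_gating_tree(
            {
                "marker": "A",
                "threshold": 0.5,
                "name": "root_split",
                "above": {
                    "marker": "B",
                    "threshold": 0.5,
                    "name": "empty_parent",
                    "above": "x",
                    "below": "y",
                },
                "below": "z",
            }
        )
        cells = pd.DataFrame({"A": [0.0, 0.1], "B": [0.0, 0.0]})
        report = spatial.composition_metrics(cells, tree, 1.0)
        x = report.set_index("population").loc["x"]
        assert np.isnan(x["percent_of_parent"])


def brute_force_distance(cells, mask):
    """Exhaustive all-pixels scan oracle mirroring the pixel-center rule."""
    ps = mask.pixel_size
    rows, cols = np.nonzero(mask.data)
    out = np.empty(len(cells))
    for i, (x, y) in enumerate(zip(cells["x_um"], cells["y_um"])):
        ci, ri = int(np.floor(x / ps)), int(np.floor(y / ps))
        if (
            0 <= ri < mask.data.shape[0]
            and 0 <= ci < mask.data.shape[1]
            and mask.data[ri, ci]
        ):
            out[i] = 0.0
            continue
        out[i] = np.min(
            np.hypot((cols + 0.5) * ps - x, (rows + 0.5) * ps - y)
        )
    return out


class TestDistanceToMask:
    def test_centroid_on_positive_pixel_is_zero(self):
        data = np.zeros((4, 4), dtype=bool)
        data[2, 1] = True
        mask = spatial.ECMMask(data=data, pixel_size=2.0)
        cells = pd.DataFrame({"x_um": [2.5], "y_um": [4.5]})  # inside pixel (2,1)
        assert spatial.distance_to_mask(cells, mask)[0] == 0.0

    def test_single_pixel_exact_geometry(self):
        data = np.zeros((10, 10), dtype=bool)
        data[0, 0] = True  # center at (0.5, 0.5) um for pixel_size 1
        mask = spatial.ECMMask(data=data, pixel_size=1.0)
        cells = pd.DataFrame({"x_um": [3.5], "y_um": [4.5]})
        assert spatial.distance_to_mask(cells, mask)[0] == pytest.approx(5.0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            data = rng.random((20, 30)) < 0.05
            if not data.any():
                data[0, 0] = True
            mask = spatial.ECMMask(data=data, pixel_size=1.5)
            cells = pd.DataFrame(
                {"x_um": rng.uniform(0, 45, 40), "y_um": rng.uniform(0, 30, 40)}
            )
            got = spatial.distance_to_mask(cells, mask)
            assert np.allclose(got, brute_force_distance(cells, mask), atol=1e-9)

    def test_empty_mask_error(self):
        mask = spatial.ECMMask(data=np.zeros((3, 3), dtype=bool), pixel_size=1.0)
        with pytest.raises(ValueError, match="no positive"):
            spatial.distance_to_mask(pd.DataFrame({"x_um": [1.0], "y_um": [1.0]}), mask)


class TestBinAndTest:
    def test_identical_bin_values_give_f_zero(self):
        d = np.array([10.0] * 3 + [30.0] * 3 + [60.0] * 3)
        x = np.array([1.0, 2.0, 3.0] * 3)
        res = spatial.bin_and_test(x, d)
        assert res.f_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_boundary_distance_in_second_bin(self):
        d = np.array([25.0] * 4 + [10.0] * 4)
        x = np.arange(8.0)
        res = spatial.bin_and_test(x, d)
        assert res.bin_counts == (4, 4, 0)

    def test_cells_beyond_last_edge_excluded(self):
        d = np.array([10.0, 80.0, 75.0, 30.0, 12.0, 40.0])
        res = spatial.bin_and_test(np.arange(6.0), d)
        assert sum(res.bin_counts) == 4

    def test_untestable_with_single_bin(self):
        d = np.full(5, 10.0)
        res = spatial.bin_and_test(np.arange(5.0), d)
        assert not res.testable and not res.significant

    def test_bonferroni_adjustment_caps_at_one(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 75, 300)
        x = rng.normal(size=300)
        res = spatial.bin_and_test(x, d, n_tests=50)
        assert res.p_adjusted <= 1.0
        assert res.p_adjusted == pytest.approx(min(res.p_value * 50, 1.0))

    def test_planted_gradient_detected(self):
        from tumorkit import simulate

        params = simulate.SimParams(seed=11, gradient_slope=5.0)
        cells, mask = simulate.simulate_spatial_tissue(params)
        dist = spatial.distance_to_mask(cells, mask)
        res = spatial.bin_and_test(cells["marker"], dist)
        assert res.significant and res.p_adjusted < 0.001
        # means decrease monotonically away from the rim... toward the center
        assert res.bin_means[0] > res.bin_means[1] > res.bin_means[2]
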
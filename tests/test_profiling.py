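"""Feature extraction, control-informed gating, bins, neighbor graphs."""

import numpy as np
import pytest
from scipy import ndimage

from lfseg.profiling import (
    GateSpec,
    control_threshold,
    expression_bins,
    extract_features,
    find_neighbors,
    gate_cells,
    negative_for_all,
    neighbor_pair_map,
    positive_for,
)
from lfseg.types import MultichannelImage


class TestControlThreshold:
    def test_matches_order_statistic_on_1_to_100(self):
        control = np.arange(1, 101, dtype=float).reshape(10, 10)
        # brute-force 95th percentile with linear interpolation
        assert control_threshold(control, 0.95) == pytest.approx(95.05)

    def test_constant_control_returns_value(self):
        assert control_threshold(np.full((5, 5), 3.7)) == pytest.approx(3.7)

    def test_all_zero_control_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert control_threshold(np.zeros((4, 4))) == 0.0

    def test_default_fraction_is_95_percent(self):
        control = np.arange(1, 101, dtype=float)
        assert control_threshold(control) == control_threshold(control, 0.95)


def _square_objects():
    objects = np.zeros((20, 30), dtype=np.int32)
    objects[2:12, 2:7] = 1   # 50 px
    objects[2:12, 12:17] = 2  # 50 px
    return objects


class TestExtractFeatures:
    def test_fluorescence_area_counts_suprathreshold_pixels(self):
        objects = _square_objects()
        marker = np.zeros(objects.shape)
        marker[2:4, 2:7] = 2.0  # 10 px of cell 1 above cutoff
        channels = MultichannelImage(channels={"marker": marker})
        df = extract_features(objects, channels, {"marker": 1.0})
        row1 = df[df.cell_id == 1].iloc[0]
        assert row1["area"] == 50
        assert row1["fluor_area_marker"] == 10
        assert df[df.cell_id == 2].iloc[0]["fluor_area_marker"] == 0

    def test_all_below_cutoff_gives_zero_area(self):
        objects = _square_objects()
        channels = MultichannelImage(channels={"marker": np.full(objects.shape, 0.1)})
        df = extract_features(objects, channels, {"marker": 1.0})
        assert (df["fluor_area_marker"] == 0).all()

    def test_integrated_equals_mean_times_area(self):
        objects = _square_objects()
        rng = np.random.default_rng(0)
        channels = MultichannelImage(channels={"m": rng.random(objects.shape)})
        df = extract_features(objects, channels, {"m": 0.5})
        assert np.allclose(df["integrated_m"], df["mean_m"] * df["area"])
        assert (df["fluor_area_m"] <= df["area"]).all()

    def test_missing_cutoff_flagged(self):
        objects = _square_objects()
        channels = MultichannelImage(channels={"m": np.ones(objects.shape)})
        with pytest.warns(UserWarning, match="no cutoff"):
            df = extract_features(objects, channels)
        assert df["fluor_area_m"].isna().all()
        assert df.attrs["missing_cutoffs"] == ["m"]

    def test_planted_positives_brighter_than_far_negatives(self, scene2d_clean):
        scene = scene2d_clean
        df = extract_features(scene.truth, scene.channels, {"marker": 0.5})
        by_id = df.set_index("cell_id")
        struct = ndimage.generate_binary_structure(2, 2)
        pos_zone = ndimage.binary_dilation(
            np.isin(scene.truth, list(scene.positives)), struct, iterations=3
        )
        far_negatives = [
            c for c in by_id.index
            if c not in scene.positives and not pos_zone[scene.truth == c].any()
        ]
        assert far_negatives
        min_pos = by_id.loc[list(scene.positives), "integrated_marker"].min()
        max_neg = by_id.loc[far_negatives, "integrated_marker"].max()
        assert min_pos > max_neg


class TestGateCells:
    def _table(self, scene):
        return extract_features(scene.truth, scene.channels, {"marker": 0.3})

    def test_zero_area_fraction_is_pure_intensity_gate(self, scene2d_clean):
        table = self._table(scene2d_clean)
        g0 = GateSpec("marker", intensity_cutoff=0.05, min_area_fraction=0.0)
        g_int = gate_cells(table, g0)
        manual = set(
            table[table["mean_marker"] >= 0.05]["cell_id"].astype(int)
        )
        assert g_int == manual

    def test_area_gate_removes_bystanders(self, scene2d_clean):
        table = self._table(scene2d_clean)
        planted = set(scene2d_clean.positives)
        intensity_only = gate_cells(
            table, GateSpec("marker", intensity_cutoff=0.05, min_area_fraction=0.0)
        )
        sequential = gate_cells(
            table, GateSpec("marker", intensity_cutoff=0.05, min_area_fraction=0.25)
        )
        fp_int = intensity_only - planted
        fp_seq = sequential - planted
        assert fp_seq < fp_int  # strict reduction of bystander positives
        sens = len(sequential & planted) / len(planted)
        prec = len(sequential & planted) / max(1, len(sequential))
        assert sens >= 0.9 and prec >= 0.9

    def test_gating_is_monotone_in_cutoff(self, scene2d_clean):
        table = self._table(scene2d_clean)
        sets = [
            gate_cells(table, GateSpec("marker", intensity_cutoff=c))
            for c in (0.02, 0.05, 0.1, 0.3)
        ]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger

    def test_empty_table_gives_empty_set(self):
        import pandas as pd

        assert gate_cells(pd.DataFrame(), GateSpec("marker", 0.5)) == set()


class TestExpressionBins:
    def _table_with_intensities(self, values):
        import pandas as pd

        return pd.DataFrame(
            {"cell_id": range(1, len(values) + 1), "mean_m": values, "area": 10}
        )

    def test_eight_cells_quartile_split(self):
        table = self._table_with_intensities([1, 2, 3, 4, 5, 6, 7, 8])
        bins = expression_bins(table, "m", set(range(1, 9)))
        assert [bins[i] for i in range(1, 9)] == [
            "dim", "dim", "low", "low",
            "intermediate", "intermediate", "high", "high",
        ]

    def test_ties_fall_to_lower_bin(self):
        table = self._table_with_intensities([2.0] * 6)
        bins = expression_bins(table, "m", set(range(1, 7)))
        assert set(bins.values()) == {"dim"}

    def test_four_distinct_one_per_bin(self):
        table = self._table_with_intensities([1.0, 2.0, 3.0, 4.0])
        bins = expression_bins(table, "m", {1, 2, 3, 4})
        assert [bins[i] for i in (1, 2, 3, 4)] == [
            "dim", "low", "intermediate", "high",
        ]

    def test_fewer_than_four_warns_all_dim(self):
        table = self._table_with_intensities([1.0, 5.0])
        with pytest.warns(UserWarning, match="fewer than 4"):
            bins = expression_bins(table, "m", {1, 2})
        assert set(bins.values()) == {"dim"}

    def test_empty_positive_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            expression_bins(self._table_with_intensities([1.0]), "m", set())

    def test_bins_partition_positive_set(self, scene2d_clean):
        table = extract_features(
            scene2d_clean.truth, scene2d_clean.channels, {"marker": 0.3}
        )
        positives = gate_cells(
            table, GateSpec("marker", intensity_cutoff=0.05, min_area_fraction=0.25)
        )
        bins = expression_bins(table, "marker", positives)
        assert set(bins) == positives


class TestFindNeighbors:
    def test_distant_objects_not_connected(self):
        objects = np.zeros((20, 20), dtype=np.int32)
        objects[2:5, 2:5] = 1
        objects[12:15, 12:15] = 2  # min gap ~9.9 px
        graph = find_neighbors(objects, dilation_px=3)
        assert graph.number_of_edges() == 0

    def test_touching_objects_connected_at_radius_one(self):
        objects = np.zeros((10, 10), dtype=np.int32)
        objects[2:5, 2:5] = 1
        objects[2:5, 5:8] = 2  # share a boundary
        graph = find_neighbors(objects, dilation_px=1)
        assert graph.has_edge(1, 2)

    def test_unknown_startpoint_rejected(self):
        objects = np.zeros((8, 8), dtype=np.int32)
        objects[2:4, 2:4] = 1
        with pytest.raises(ValueError, match="unknown startpoint"):
            find_neighbors(objects, startpoints={5})

    def test_matches_exhaustive_distance_oracle(self, scene2d_small):
        objects = scene2d_small.truth
        graph = find_neighbors(objects, dilation_px=3)
        ids = [int(i) for i in np.unique(objects) if i > 0]
        coords = {i: np.argwhere(objects == i) for i in ids}
        expected = set()
        for a_idx, a in enumerate(ids):
            for b in ids[a_idx + 1:]:
                d2 = (
                    ((coords[a][:, None, :] - coords[b][None, :, :]) ** 2)
                    .sum(-1)
                    .min()
                )
                if d2 <= 9:  # Euclidean distance <= 3
                    expected.add((a, b))
        got = {tuple(sorted(e)) for e in graph.edges}
        assert got == expected

    def test_graph_symmetric_no_self_edges(self, scene2d_small):
        graph = find_neighbors(scene2d_small.truth, dilation_px=3)
        assert all(u != v for u, v in graph.edges)


class TestNeighborPairMap:
    def test_empty_graph_empty_output(self):
        import networkx as nx

        pairs, mask = neighbor_pair_map(
            nx.Graph(), {"m": set()}, (positive_for("m"), negative_for_all())
        )
        assert pairs == [] and mask is None

    def test_simple_positive_negative_pair(self):
        import networkx as nx

        graph = nx.Graph([(1, 2)])
        pairs, _ = neighbor_pair_map(
            graph, {"m": {1}}, (positive_for("m"), negative_for_all())
        )
        assert pairs == [(1, 2)]

    def test_counts_match_truth_filter(self, scene2d_small):
        objects = scene2d_small.truth
        graph = find_neighbors(objects, dilation_px=3)
        positives = set(scene2d_small.positives)
        pairs, mask = neighbor_pair_map(
            graph,
            {"marker": positives},
            (positive_for("marker"), negative_for_all()),
            objects=objects,
        )
        expected = {
            (u, v) if u in positives else (v, u)
            for u, v in graph.edges
            if (u in positives) != (v in positives)
        }
        assert set(pairs) == expected
        involved = {i for p in pairs for i in p}
        assert set(np.unique(mask)) - {0} == involved
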
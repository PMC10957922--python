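import numpy as np
import pandas as pd
import pytest

from spatialsr.data_model import CellTable
from spatialsr.segmentation import (
    BandwidthError,
    assign_compartments,
    compute_compartment_areas,
    compute_intensity_surface,
    select_bandwidth_lcv,
    split_foci,
    total_areas,
    trim_distal_stroma,
)
from tests.conftest import make_cell_table


def brute_force_dbscan(xy, eps, min_pts):
    """Reference density-reachability clustering (BFS from core points)."""
    n = len(xy)
    d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels


def blob(center, n, sd, rng):
    return np.asarray(center) + rng.normal(0, sd, (n, 2))


class TestSplitFoci:
    def test_two_separated_blobs(self, rng):
        pts = np.concatenate([blob((0, 0), 100, 20, rng), blob((2000, 0), 100, 20, rng)])
        ct = make_cell_table({"cancer": pts})
        out = split_foci(ct)
        labels = out.df["focus_id"]
        assert set(labels) == {0, 1}

    def test_few_cells_all_noise(self, rng):
        ct = make_cell_table({"cancer": rng.uniform(0, 100, (10, 2))})
        out = split_foci(ct)
        assert set(out.df["focus_id"]) == {-1}

    def test_matches_density_reachability_oracle(self, rng):
        pts = blob((0, 0), 500, 80, rng)
        ct = make_cell_table({"negative": pts})
        out = split_foci(ct, eps=100, min_pts=20)
        oracle = brute_force_dbscan(pts, eps=100, min_pts=20)
        got = out.df["focus_id"].to_numpy()
        # same noise set, and the dense core forms a single focus in both
        assert np.array_equal(got == -1, oracle == -1)
        assert set(got[got != -1]) == {0}
        assert set(oracle[oracle != -1]) == {0}


class TestIntensitySurface:
    def test_single_point_peak(self):
        surf = compute_intensity_surface(
            np.array([[50.0, 50.0]]), (0, 100, 0, 100), pixel_size=10, bandwidth=10
        )
        assert surf.values.max() == pytest.approx(1.0)
        peak = np.unravel_index(surf.values.argmax(), surf.values.shape)
        xc = surf.x0 + (peak[0] + 0.5) * surf.pixel_size
        yc = surf.y0 + (peak[1] + 0.5) * surf.pixel_size
        assert abs(xc - 50) <= surf.pixel_size and abs(yc - 50) <= surf.pixel_size

    def test_deterministic(self, rng):
        pts = rng.uniform(0, 200, (50, 2))
        s1 = compute_intensity_surface(pts, (0, 200, 0, 200), bandwidth=20)
        s2 = compute_intensity_surface(pts, (0, 200, 0, 200), bandwidth=20)
        assert np.array_equal(s1.values, s2.values)

    def test_auto_bandwidth_needs_two_points(self):
        with pytest.raises(BandwidthError):
            compute_intensity_surface(np.array([[1.0, 1.0]]), (0, 10, 0, 10), bandwidth="auto")

    def test_csr_covers_interior(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 1000, (2000, 2))
        surf = compute_intensity_surface(pts, (0, 1000, 0, 1000), bandwidth="auto")
        bw = surf.bandwidth
        nx, ny = surf.values.shape
        xc = surf.x0 + (np.arange(nx) + 0.5) * surf.pixel_size
        yc = surf.y0 + (np.arange(ny) + 0.5) * surf.pixel_size
        interior = (
            (xc[:, None] >= 2 * bw) & (xc[:, None] <= 1000 - 2 * bw)
            & (yc[None, :] >= 2 * bw) & (yc[None, :] <= 1000 - 2 * bw)
        )
        frac = np.mean(surf.values[interior] > 0.1)
        assert frac >= 0.95


class TestAssignCompartments:
    def _segmented_two_blob(self, rng, n=300):
        cancer = blob((200, 300), n, 60, rng)
        negative = blob((700, 300), n, 60, rng)
        ct = make_cell_table({"cancer": cancer, "negative": negative})
        ct = split_foci(ct, eps=300, min_pts=20)
        return assign_compartments(ct)

    def test_two_blob_accuracy(self, rng):
        out = self._segmented_two_blob(rng)
        df = out.df
        acc_t = (df.loc[df.cell_type == "cancer", "compartment"] == "tumor").mean()
        acc_s = (df.loc[df.cell_type == "negative", "compartment"] == "stroma").mean()
        assert acc_t >= 0.95
        assert acc_s >= 0.95

    def test_cancer_only_focus_all_tumor(self, rng):
        ct = make_cell_table({"cancer": blob((0, 0), 200, 50, rng)})
        ct = split_foci(ct, eps=300, min_pts=20)
        out = assign_compartments(ct)
        assert (out.df["compartment"] == "tumor").all()

    def test_negative_only_focus_all_stroma(self, rng):
        ct = make_cell_table({"negative": blob((0, 0), 200, 50, rng)})
        ct = split_foci(ct, eps=300, min_pts=20)
        out = assign_compartments(ct)
        assert (out.df["compartment"] == "stroma").all()

    def test_rigid_motion_invariance(self, rng):
        base = self._segmented_two_blob(rng, n=150)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        df = base.df.copy()
        xy = df[["x", "y"]].to_numpy() @ rot.T + np.array([1234.5, -987.6])
        df["x"], df["y"] = xy[:, 0], xy[:, 1]
        df["compartment"] = "unassigned"
        moved = assign_compartments(CellTable(df=df))
        agree = (moved.df["compartment"].to_numpy() == base.df["compartment"].to_numpy()).mean()
        # grid discretization can flip a handful of boundary cells
        assert agree >= 0.98


class TestAreas:
    def test_no_cells_zero_area(self):
        df = pd.DataFrame(
            {"sample_id": ["s"], "x": [0.0], "y": [0.0], "cell_type": ["cd8_t"], "focus_id": [0]}
        )
        ct = CellTable.from_dataframe(df)
        areas = total_areas(compute_compartment_areas(ct))
        assert areas.iloc[0]["tumor_area"] == 0.0
        assert areas.iloc[0]["total_area"] == 0.0

    def test_dense_slab_area(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1000, (4000, 2))
        ct = make_cell_table({"cancer": pts})
        ct = split_foci(ct, eps=300, min_pts=20)
        areas = total_areas(compute_compartment_areas(ct))
        assert areas.iloc[0]["tumor_area"] == pytest.approx(1e6, rel=0.15)

    def test_stroma_is_total_minus_tumor(self, rng):
        cancer = blob((200, 300), 250, 60, rng)
        negative = blob((650, 300), 250, 60, rng)
        ct = make_cell_table({"cancer": cancer, "negative": negative})
        ct = split_foci(ct, eps=300, min_pts=20)
        per_focus = compute_compartment_areas(ct)
        assert np.allclose(
            per_focus["stroma_area"], per_focus["total_area"] - per_focus["tumor_area"]
        )
        assert (per_focus[["tumor_area", "stroma_area", "total_area"]] >= 0).all().all()


class TestTrimDistalStroma:
    def _table(self):
        rows = [
            ("s", 0.0, 0.0, "cancer", 0, "tumor"),
            ("s", 10.0, 0.0, "cancer", 0, "tumor"),
            ("s", 100.0, 0.0, "cd8_t", 0, "stroma"),   # within 150 μm: kept
            ("s", 200.0, 0.0, "cd8_t", 0, "stroma"),   # beyond 150 μm: removed
            ("s", 500.0, 0.0, "negative", 0, "tumor"),  # tumor compartment: untouched
        ]
        df = pd.DataFrame(
            rows, columns=["sample_id", "x", "y", "cell_type", "focus_id", "compartment"]
        )
        return CellTable.from_dataframe(df)

    def test_removes_exactly_distal_stroma(self):
        out = trim_distal_stroma(self._table(), max_dist=150.0)
        kept = set(zip(out.df["x"], out.df["compartment"]))
        assert (200.0, "stroma") not in kept
        assert (100.0, "stroma") in kept
        assert (500.0, "tumor") in kept
        assert len(out) == 4

    def test_no_cancer_cells_is_noop_with_warning(self, caplog):
        df = pd.DataFrame(
            {
                "sample_id": ["s", "s"],
                "x": [0.0, 1000.0],
                "y": [0.0, 0.0],
                "cell_type": ["cd8_t", "b_cell"],
                "compartment": ["stroma", "stroma"],
            }
        )
        ct = CellTable.from_dataframe(df)
        with caplog.at_level("WARNING"):
            out = trim_distal_stroma(ct)
        assert len(out) == 2
        assert any("no cancer cells" in r.message for r in caplog.records)


def test_lcv_bandwidth_is_interior_or_scott(rng):
    pts = rng.normal(0, 30, (300, 2))
    bw = select_bandwidth_lcv(pts, (-150, 150, -150, 150))
    assert 2.0 < bw < 150.0
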
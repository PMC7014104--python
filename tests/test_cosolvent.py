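"""Density-grid construction, normalization identities, hotspot extraction."""

import numpy as np
import pytest

from allosite.cosolvent import (
    bulk_number_density,
    compare_density_maps,
    compute_density_grid,
    extract_hotspots,
    mean_probe_count,
)
from allosite.errors import EmptyInputError, GridMismatchError
from allosite.grids import DensityGrid
from allosite.synthetic import HotspotSpec, ProbeTrajectoryConfig, gen_probe_trajectory


def _grid(values, spacing=1.0, origin=(0, 0, 0)):
    return DensityGrid(origin=np.array(origin, dtype=float), spacing=spacing,
                       values=np.asarray(values, dtype=float), probe="IPA")


class TestBulkDensity:
    def test_count_over_volume(self):
        assert bulk_number_density(100, 1000.0) == pytest.approx(0.1)

    def test_zero_probes(self):
        assert bulk_number_density(0, 1000.0) == 0.0

    def test_zero_volume_is_error(self):
        with pytest.raises(ValueError):
            bulk_number_density(10, 0.0)

    def test_matches_per_frame_averaging_oracle(self):
        cfg = ProbeTrajectoryConfig(seed=3, box=(20.0, 20.0, 20.0),
                                    n_probes=40, n_frames=12)
        frames, truth = gen_probe_trajectory(cfg)
        # oracle: count/volume per frame, averaged
        per_frame = [len(f) / cfg.box_volume for f in frames]
        oracle = float(np.mean(per_frame))
        got = bulk_number_density(mean_probe_count(frames, "IPA"), cfg.box_volume)
        assert got == pytest.approx(oracle, rel=1e-12)
        assert got == pytest.approx(truth["bulk_density"], rel=1e-12)


class TestComputeDensityGrid:
    def test_single_voxel_closed_form(self):
        # all probe atoms of every frame land in one voxel of volume v
        cfg = ProbeTrajectoryConfig(seed=0, box=(4.0, 4.0, 4.0),
                                    n_probes=5, n_frames=3)
        frames, _ = gen_probe_trajectory(cfg)
        squeezed = [f.with_coords(np.full((len(f), 3), 0.5)) for f in frames]
        from allosite.structio import TrajectoryFrames
        traj = TrajectoryFrames(squeezed)
        bulk = 0.2
        grid = compute_density_grid(traj, "IPA", origin=(0, 0, 0),
                                    dims=(4, 4, 4), spacing=1.0,
                                    bulk_density=bulk)
        n, v = 5, 1.0
        assert grid.values[0, 0, 0] == pytest.approx(n / (v * bulk))
        assert grid.values.sum() == pytest.approx(n / (v * bulk))

    def test_uniform_bulk_normalizes_to_one(self):
        cfg = ProbeTrajectoryConfig(seed=1, box=(40.0, 40.0, 40.0),
                                    n_probes=200, n_frames=200)
        frames, truth = gen_probe_trajectory(cfg)
        grid = compute_density_grid(frames, "IPA", origin=(0, 0, 0),
                                    dims=(40, 40, 40), spacing=1.0,
                                    bulk_density=truth["bulk_density"])
        assert grid.values.mean() == pytest.approx(1.0, abs=0.01)

    def test_mass_conservation_identity(self):
        cfg = ProbeTrajectoryConfig(seed=2, box=(20.0, 20.0, 20.0),
                                    n_probes=50, n_frames=20)
        frames, truth = gen_probe_trajectory(cfg)
        bulk = truth["bulk_density"]
        grid = compute_density_grid(frames, "IPA", origin=(0, 0, 0),
                                    dims=(20, 20, 20), spacing=1.0,
                                    bulk_density=bulk)
        lhs = grid.values.sum() * grid.voxel_volume * bulk
        mean_in_grid = np.mean([len(f) for f in frames])
        assert lhs == pytest.approx(mean_in_grid, abs=1e-9)

    def test_doubling_bulk_halves_values(self):
        cfg = ProbeTrajectoryConfig(seed=4, box=(10.0, 10.0, 10.0),
                                    n_probes=20, n_frames=5)
        frames, truth = gen_probe_trajectory(cfg)
        kw = dict(origin=(0, 0, 0), dims=(10, 10, 10), spacing=1.0)
        g1 = compute_density_grid(frames, "IPA", bulk_density=truth["bulk_density"], **kw)
        g2 = compute_density_grid(frames, "IPA",
                                  bulk_density=2 * truth["bulk_density"], **kw)
        np.testing.assert_allclose(g2.values, g1.values / 2.0, atol=1e-12)

    def test_out_of_grid_probes_ignored(self):
        cfg = ProbeTrajectoryConfig(seed=5, box=(20.0, 20.0, 20.0),
                                    n_probes=30, n_frames=4)
        frames, truth = gen_probe_trajectory(cfg)
        grid = compute_density_grid(frames, "IPA", origin=(0, 0, 0),
                                    dims=(5, 5, 5), spacing=1.0,
                                    bulk_density=truth["bulk_density"])
        in_grid = grid.values.sum() * grid.voxel_volume * truth["bulk_density"]
        assert in_grid <= np.mean([len(f) for f in frames])

    def test_empty_selector_is_error(self):
        cfg = ProbeTrajectoryConfig(seed=6, box=(10.0, 10.0, 10.0),
                                    n_probes=5, n_frames=2)
        frames, _ = gen_probe_trajectory(cfg)
        with pytest.raises(EmptyInputError):
            compute_density_grid(frames, "XXX", origin=(0, 0, 0),
                                 dims=(5, 5, 5), spacing=1.0, bulk_density=0.1)

    def test_planted_blob_recovered_near_center(self):
        spot = HotspotSpec(center=(20.0, 20.0, 20.0), sigma=1.5, enrichment=20.0)
        cfg = ProbeTrajectoryConfig(seed=7, box=(40.0, 40.0, 40.0),
                                    n_probes=200, n_frames=2000,
                                    hotspots=(spot,))
        frames, truth = gen_probe_trajectory(cfg)
        grid = compute_density_grid(frames, "IPA", origin=(0, 0, 0),
                                    dims=(40, 40, 40), spacing=1.0,
                                    bulk_density=truth["bulk_density"])
        peak_idx = np.unravel_index(np.argmax(grid.values), grid.dims)
        peak_center = grid.voxel_centers(np.array([peak_idx]))[0]
        assert np.all(np.abs(peak_center - spot.center) <= 1.0 + 1e-9)
        # planted 20x enrichment → grid max near 20
        assert 15.0 <= grid.values.max() <= 25.0


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """Face-connected component oracle by explicit BFS flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    nx, ny, nz = mask.shape
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        comp, queue = set(), [start]
        seen[start] = True
        while queue:
            cur = queue.pop()
            comp.add(cur)
            x, y, z = cur
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                               (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                nb = (x + dx, y + dy, z + dz)
                if (0 <= nb[0] < nx and 0 <= nb[1] < ny and 0 <= nb[2] < nz
                        and mask[nb] and not seen[nb]):
                    seen[nb] = True
                    queue.append(nb)
        comps.append(comp)
    return comps


class TestExtractHotspots:
    def test_all_ones_grid_empty(self):
        assert extract_hotspots(_grid(np.ones((4, 4, 4))), isovalue=12.0) == []

    def test_single_hot_voxel(self):
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = 20.0
        spots = extract_hotspots(_grid(vals), isovalue=12.0)
        assert len(spots) == 1
        assert spots[0].volume == pytest.approx(1.0)
        assert spots[0].peak == 20.0
        np.testing.assert_allclose(spots[0].centroid, [2.5, 2.5, 2.5])

    def test_two_disjoint_blobs(self):
        vals = np.zeros((10, 10, 10))
        vals[1:3, 1:3, 1:3] = 15.0
        vals[7:9, 7:9, 7:9] = 18.0
        spots = extract_hotspots(_grid(vals), isovalue=12.0)
        assert len(spots) == 2
        # sorted by peak descending
        assert spots[0].peak == 18.0
        np.testing.assert_allclose(spots[0].centroid, [8.0, 8.0, 8.0])
        np.testing.assert_allclose(spots[1].centroid, [2.0, 2.0, 2.0])

    def test_components_match_flood_fill_oracle(self):
        rng = np.random.default_rng(23)
        vals = rng.uniform(0, 16, size=(12, 12, 12))
        spots = extract_hotspots(_grid(vals), isovalue=12.0)
        oracle = flood_fill_components(vals >= 12.0)
        got_sets = [set(map(tuple, h.voxels)) for h in spots]
        assert len(got_sets) == len(oracle)
        assert {frozenset(s) for s in got_sets} == {frozenset(s) for s in oracle}

    def test_diagonal_touch_is_not_connected(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, 0] = 13.0
        vals[1, 1, 0] = 13.0  # edge-diagonal neighbor, not face-adjacent
        assert len(extract_hotspots(_grid(vals), isovalue=12.0)) == 2

    def test_threshold_monotone(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 30, size=(8, 8, 8))
        low = extract_hotspots(_grid(vals), isovalue=10.0)
        high = extract_hotspots(_grid(vals), isovalue=20.0)
        low_union = set().union(*[set(map(tuple, h.voxels)) for h in low]) if low else set()
        high_union = set().union(*[set(map(tuple, h.voxels)) for h in high]) if high else set()
        assert high_union <= low_union

    def test_min_voxels_filter(self):
        vals = np.zeros((6, 6, 6))
        vals[0, 0, 0] = 20.0           # singleton
        vals[3:5, 3, 3] = 20.0         # pair
        spots = extract_hotspots(_grid(vals), isovalue=12.0, min_voxels=2)
        assert len(spots) == 1 and spots[0].n_voxels == 2


class TestCompareDensityMaps:
    def test_identical_grids_jaccard_one(self):
        vals = np.zeros((6, 6, 6))
        vals[2:4, 2:4, 2:4] = 15.0
        rep = compare_density_maps(_grid(vals), _grid(vals.copy()))
        assert rep.jaccard == 1.0
        assert rep.unique_volume_a == rep.unique_volume_b == 0.0

    def test_disjoint_supports_jaccard_zero(self):
        a = np.zeros((6, 6, 6)); a[0, 0, 0] = 15.0
        b = np.zeros((6, 6, 6)); b[5, 5, 5] = 15.0
        assert compare_density_maps(_grid(a), _grid(b)).jaccard == 0.0

    def test_half_overlap_matches_set_oracle(self):
        a = np.zeros((8, 8, 8)); a[0:2, 0:4, 0] = 15.0
        b = np.zeros((8, 8, 8)); b[0:2, 2:6, 0] = 15.0
        rep = compare_density_maps(_grid(a), _grid(b))
        set_a = set(map(tuple, np.argwhere(a >= 12.0)))
        set_b = set(map(tuple, np.argwhere(b >= 12.0)))
        assert rep.jaccard == pytest.approx(len(set_a & set_b) / len(set_a | set_b))

    def test_incongruent_grids_rejected(self):
        with pytest.raises(GridMismatchError):
            compare_density_maps(_grid(np.zeros((4, 4, 4))),
                                 _grid(np.zeros((5, 5, 5))))
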
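"""Water clustering, occupancy, conservation filtering and consensus matching."""

import numpy as np
import pytest

from allosite.errors import EmptyInputError
from allosite.hydration import (
    DEFAULT_OCCUPANCY_SCHEDULE,
    HydrationSite,
    WaterObservationSet,
    cluster_sites,
    consensus_match,
    dbscan_cluster,
    extract_crystal_waters,
    filter_conserved,
    flag_favorable,
    occupancy_threshold,
    site_from_cluster,
    sites_to_dataframe,
)
from allosite.structio import Atom, StructureModel
from allosite.synthetic import (
    WaterObservationConfig,
    WaterSiteSpec,
    gen_water_observations,
)


# ---------------------------------------------------------------------------
# Brute-force DBSCAN oracle: O(n^2) region queries, classic expansion
# ---------------------------------------------------------------------------

def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    neighbors = [np.where(d[i] <= eps)[0] for i in range(n)]  # self included
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -2)  # -2 unvisited, -1 noise
    cluster = -1
    for i in range(n):
        if labels[i] != -2:
            continue
        if not core[i]:
            labels[i] = -1
            continue
        cluster += 1
        labels[i] = cluster
        seeds = list(neighbors[i])
        k = 0
        while k < len(seeds):
            j = seeds[k]
            k += 1
            if labels[j] == -1:
                labels[j] = cluster          # border point
            if labels[j] != -2:
                continue
            labels[j] = cluster
            if core[j]:
                seeds.extend(neighbors[j])
    return labels


def labels_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """Same partition and same noise set, label names ignored."""
    if (a == -1).tolist() != (b == -1).tolist():
        return False
    mapping: dict[int, int] = {}
    for la, lb in zip(a, b):
        if la == -1:
            continue
        if mapping.setdefault(la, lb) != lb:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestDBSCAN:
    def test_pair_within_epsilon_forms_cluster(self):
        pts = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        labels = dbscan_cluster(pts, epsilon=0.9, min_pts=2)
        assert list(labels) == [0, 0]

    def test_isolated_point_is_noise(self):
        pts = np.array([[0.0, 0, 0], [0.5, 0, 0], [5.0, 5, 5]])
        labels = dbscan_cluster(pts, epsilon=0.9, min_pts=2)
        assert labels[2] == -1

    def test_empty_input_empty_result(self):
        assert len(dbscan_cluster(np.empty((0, 3)))) == 0

    def test_min_pts_counts_self(self):
        # with min_pts=2, a pair is enough: each point has itself + 1 neighbor
        pts = np.array([[0.0, 0, 0], [0.8, 0, 0]])
        assert -1 not in dbscan_cluster(pts, epsilon=0.9, min_pts=2)

    @pytest.mark.parametrize("seed", range(12))
    def test_labels_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 6, size=(60, 3))
        got = dbscan_cluster(pts, epsilon=0.9, min_pts=2)
        oracle = brute_force_dbscan(pts, eps=0.9, min_pts=2)
        assert labels_equivalent(got, oracle)

    @pytest.mark.parametrize("eps,min_pts", [(0.5, 2), (1.2, 3), (2.0, 5)])
    def test_oracle_agreement_other_parameters(self, eps, min_pts):
        rng = np.random.default_rng(99)
        pts = rng.uniform(0, 5, size=(80, 3))
        assert labels_equivalent(
            dbscan_cluster(pts, epsilon=eps, min_pts=min_pts),
            brute_force_dbscan(pts, eps=eps, min_pts=min_pts),
        )


class TestSiteFromCluster:
    def test_centroid_and_occupancy(self):
        site = site_from_cluster(np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                                 [0, 1], source_count=10)
        np.testing.assert_allclose(site.centroid, [0.5, 0, 0])
        assert site.occupancy == pytest.approx(0.2)

    def test_occupancy_counts_distinct_sources(self):
        pts = np.zeros((10, 3))
        site = site_from_cluster(pts, [0] * 10, source_count=10)
        assert site.occupancy == pytest.approx(0.1)
        assert site.members == 10

    def test_occupancy_always_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(1, 30)
            nsrc = int(rng.integers(1, 15))
            srcs = rng.integers(0, nsrc, size=n)
            site = site_from_cluster(rng.normal(size=(n, 3)), srcs, nsrc)
            assert 0.0 <= site.occupancy <= 1.0


class TestConservedFilter:
    def test_above_threshold_kept(self):
        s = HydrationSite(np.zeros(3), 5, 0.8, "crystal")
        assert filter_conserved([s], 20, min_occupancy=0.5) == [s]

    def test_below_threshold_dropped(self):
        s = HydrationSite(np.zeros(3), 5, 0.3, "crystal")
        assert filter_conserved([s], 20, min_occupancy=0.5) == []

    @pytest.mark.parametrize("n_sources,expected", [
        (5, 0.5), (9, 0.5), (10, 0.4), (12, 0.4), (29, 0.4), (30, 0.3), (100, 0.3),
    ])
    def test_default_schedule_lookup(self, n_sources, expected):
        assert occupancy_threshold(n_sources) == expected

    def test_filter_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        sites = [HydrationSite(np.zeros(3), 1, float(o), "MD")
                 for o in rng.uniform(0, 1, size=30)]
        kept = [len(filter_conserved(sites, 5, min_occupancy=t))
                for t in (0.2, 0.4, 0.6, 0.8)]
        assert kept == sorted(kept, reverse=True)

    def test_custom_schedule(self):
        sched = ((0, 0.9),)
        assert occupancy_threshold(50, sched) == 0.9


# ---------------------------------------------------------------------------
# Consensus matching oracle: brute-force greedy (argmin over remaining pairs)
# ---------------------------------------------------------------------------

def greedy_match_oracle(md_xyz, xt_xyz, threshold):
    md_xyz = np.asarray(md_xyz, dtype=float)
    xt_xyz = np.asarray(xt_xyz, dtype=float)
    free_md = set(range(len(md_xyz)))
    free_xt = set(range(len(xt_xyz)))
    pairs = []
    while free_md and free_xt:
        best = None
        for i in sorted(free_md):
            for j in sorted(free_xt):
                dij = float(np.linalg.norm(md_xyz[i] - xt_xyz[j]))
                if dij <= threshold and (best is None or dij < best[0]):
                    best = (dij, i, j)
        if best is None:
            break
        _, i, j = best
        pairs.append((i, j))
        free_md.discard(i)
        free_xt.discard(j)
    return sorted(pairs)


def _sites(xyz, provenance="MD"):
    return [HydrationSite(np.asarray(p, dtype=float), 1, 1.0, provenance)
            for p in xyz]


class TestConsensusMatch:
    def test_within_threshold_matched(self):
        cons, um, ux = consensus_match(_sites([[0, 0, 0]]),
                                       _sites([[1.0, 0, 0]], "crystal"))
        assert len(cons) == 1 and not um and not ux
        np.testing.assert_allclose(cons[0].centroid, [0.5, 0, 0])
        assert cons[0].provenance == "consensus"

    def test_beyond_threshold_unmatched(self):
        cons, um, ux = consensus_match(_sites([[0, 0, 0]]),
                                       _sites([[1.5, 0, 0]], "crystal"))
        assert not cons and len(um) == 1 and len(ux) == 1

    def test_each_site_matched_at_most_once(self):
        md = _sites([[0, 0, 0], [0.5, 0, 0]])
        xt = _sites([[0.2, 0, 0]], "crystal")
        cons, um, ux = consensus_match(md, xt)
        assert len(cons) == 1 and len(um) == 1 and not ux

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        md_xyz = rng.uniform(0, 5, size=(rng.integers(1, 7), 3))
        xt_xyz = rng.uniform(0, 5, size=(rng.integers(1, 7), 3))
        cons, um, ux = consensus_match(_sites(md_xyz), _sites(xt_xyz, "crystal"), 1.4)
        oracle = greedy_match_oracle(md_xyz, xt_xyz, 1.4)
        # compare pairings through their consensus midpoints
        oracle_mids = sorted(tuple(np.round((md_xyz[i] + xt_xyz[j]) / 2, 9))
                             for i, j in oracle)
        got_mids = sorted(tuple(np.round(c.centroid, 9)) for c in cons)
        assert got_mids == oracle_mids

    def test_matching_symmetric_in_arguments(self):
        rng = np.random.default_rng(42)
        a = _sites(rng.uniform(0, 4, size=(5, 3)))
        b = _sites(rng.uniform(0, 4, size=(4, 3)), "crystal")
        cons_ab, _, _ = consensus_match(a, b)
        cons_ba, _, _ = consensus_match(b, a)
        mids_ab = sorted(tuple(np.round(c.centroid, 9)) for c in cons_ab)
        mids_ba = sorted(tuple(np.round(c.centroid, 9)) for c in cons_ba)
        assert mids_ab == mids_ba


class TestFlagFavorable:
    @pytest.mark.parametrize("dH,expected", [(-2.3, True), (-0.5, False),
                                             (None, False), (-1.0, False)])
    def test_cutoff(self, dH, expected):
        s = HydrationSite(np.zeros(3), 1, 1.0, "consensus", dH=dH)
        assert flag_favorable([s])[0].favorable is expected


class TestExtractCrystalWaters:
    def _water(self, chain, resnum, xyz, with_oxygen=True):
        atoms = []
        if with_oxygen:
            atoms.append(Atom(chain, resnum, "", "HOH", "O", "O",
                              *xyz, is_hetero=True))
        else:
            atoms.append(Atom(chain, resnum, "", "HOH", "H1", "H",
                              *xyz, is_hetero=True))
        return atoms

    def test_points_pooled_with_source_ids(self):
        st1 = StructureModel(sum([self._water("W", i, (i, 0, 0))
                                  for i in range(3)], []))
        st2 = StructureModel(sum([self._water("W", i, (0, i, 0))
                                  for i in range(4)], []))
        obs = extract_crystal_waters([st1, st2])
        assert len(obs) == 7
        assert obs.source_count == 2
        assert sorted(set(obs.sources)) == [0, 1]

    def test_water_without_oxygen_skipped_with_warning(self):
        st = StructureModel(self._water("W", 1, (0, 0, 0))
                            + self._water("W", 2, (1, 1, 1), with_oxygen=False))
        with pytest.warns(UserWarning):
            obs = extract_crystal_waters([st])
        assert len(obs) == 1

    def test_structure_without_waters_allowed(self):
        st_prot = StructureModel([Atom("A", 1, "", "ALA", "CA", "C", 0, 0, 0)])
        st_wat = StructureModel(self._water("W", 1, (0, 0, 0)))
        obs = extract_crystal_waters([st_prot, st_wat])
        assert len(obs) == 1 and obs.source_count == 2


class TestEndToEndRecovery:
    def test_planted_sites_recovered_no_spurious(self):
        """Planted sites at occupancy >= 0.7 recovered within 0.3 Å; the
        uniform background yields no spurious conserved site."""
        centers = [(5.0, 5.0, 5.0), (15.0, 10.0, 20.0), (25.0, 25.0, 8.0)]
        cfg = WaterObservationConfig(
            seed=17, n_sources=20,
            sites=tuple(WaterSiteSpec(c, occupancy=0.8, jitter=0.25)
                        for c in centers),
            background_per_source=2,
        )
        obs, truth = gen_water_observations(cfg)
        sites = cluster_sites(obs, epsilon=0.9, min_pts=2)
        conserved = filter_conserved(sites, obs.source_count)
        assert len(conserved) == len(centers)
        for c in centers:
            d = min(np.linalg.norm(s.centroid - np.array(c)) for s in conserved)
            assert d <= 0.3

    def test_cluster_count_matches_planted(self):
        cfg = WaterObservationConfig(
            seed=5, n_sources=10,
            sites=(WaterSiteSpec((10.0, 10.0, 10.0), 1.0, 0.0),
                   WaterSiteSpec((20.0, 20.0, 20.0), 1.0, 0.0)),
            background_per_source=0,
        )
        obs, _ = gen_water_observations(cfg)
        sites = cluster_sites(obs)
        assert len(sites) == 2
        assert all(s.occupancy == 1.0 for s in sites)

    def test_site_table_columns(self):
        s = HydrationSite(np.array([1.0, 2.0, 3.0]), 4, 0.5, "MD", dH=-1.5)
        df = sites_to_dataframe(flag_favorable([s]))
        assert list(df.columns) == ["provenance", "x", "y", "z", "members",
                                    "occupancy", "dH", "mTdS", "favorable_flag"]
        assert bool(df["favorable_flag"][0]) is True
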
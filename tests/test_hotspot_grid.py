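"""Grid occupancy, inverse-Boltzmann energies, hot spots and site scoring."""

import itertools
import math

import numpy as np
import pytest
from _util import micro_ensemble, point_spec

from probesite.hotspot_grid import (
    GridParams,
    HotSpot,
    OccupancyGrid,
    accumulate_occupancy,
    cluster_sites,
    detect_hotspots,
    score_site,
    site_table,
    voxel_free_energy,
)


def brute_force_occupancy(ensemble, params):
    """Naive frames × probes loop with explicit floor-division binning."""
    prot = ensemble.protein_heavy_indices
    counts = {p.probe_name: {} for p in ensemble.probe_instances}
    for f in range(ensemble.n_frames):
        prot_xyz = ensemble.coords[f, prot]
        for inst in ensemble.probe_instances:
            heavy = ensemble.coords[f, inst.heavy_indices]
            touching = False
            for a in heavy:
                for b in prot_xyz:
                    if math.dist(a, b) <= params.protein_contact_cutoff:
                        touching = True
                        break
                if touching:
                    break
            if touching:
                c = heavy.mean(axis=0)
                vox = tuple(int(math.floor(x / params.edge_length)) for x in c)
                d = counts[inst.probe_name]
                d[vox] = d.get(vox, 0) + 1
    return counts


class TestAccumulateOccupancy:
    def test_requires_superposed(self):
        ens = micro_ensemble([("A", 1, (0, 0, 0))],
                             [{"spec": point_spec(), "coords": [[9, 9, 9]]}],
                             superposed=False)
        with pytest.raises(ValueError, match="superposed"):
            accumulate_occupancy(ens, GridParams())

    def test_never_in_contact_counts_nothing(self):
        ens = micro_ensemble(
            [("A", 1, (0, 0, 0))],
            [{"spec": point_spec(), "coords": [[0, 0, 2.51]]}],
            n_frames=10,
        )
        grid = accumulate_occupancy(ens, GridParams())
        assert grid.total_counts["point"] == 0
        assert grid.counts["point"] == {}

    def test_fixed_contacting_probe_fills_one_voxel(self):
        ens = micro_ensemble(
            [("A", 1, (0, 0, 0))],
            [{"spec": point_spec(), "coords": [[0.0, 0.0, 2.1]]}],
            n_frames=100,
        )
        grid = accumulate_occupancy(ens, GridParams())
        assert grid.counts["point"] == {(0, 0, 4): 100}

    def test_matches_brute_force_on_random_fixture(self, random_superposed):
        params = GridParams()
        grid = accumulate_occupancy(random_superposed, params)
        oracle = brute_force_occupancy(random_superposed, params)
        for name, expected in oracle.items():
            assert grid.counts[name] == expected
        # count conservation: totals equal the qualifying (frame, probe) pairs
        for name in oracle:
            assert grid.total_counts[name] == sum(oracle[name].values())


class TestVoxelFreeEnergy:
    def test_count_equal_expected_is_zero(self):
        assert voxel_free_energy(7.0, 7.0) == pytest.approx(0.0)

    def test_e_fold_enrichment_is_minus_rt(self):
        assert voxel_free_energy(math.e * 10, 10, temperature=300.0) == pytest.approx(
            -0.596, abs=1e-3)

    def test_zero_count_is_infinite(self):
        assert voxel_free_energy(0, 5.0) == math.inf

    def test_bad_expected_errors(self):
        with pytest.raises(ValueError):
            voxel_free_energy(1, 0.0)

    def test_monotone_decreasing_in_count(self):
        vals = [voxel_free_energy(c, 3.0) for c in (1, 2, 5, 10, 100)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


def _grid(counts, protein_voxels=set(), n_frames=100):
    return OccupancyGrid(
        edge_length=0.5, n_frames=n_frames,
        counts={"point": dict(counts)},
        total_counts={"point": sum(counts.values())},
        protein_voxels=set(protein_voxels),
    )


class TestDetectHotspots:
    def test_uniform_grid_has_no_hotspots(self):
        # every voxel in the box at the expected count: zero enrichment
        counts = {(i, j, k): 5 for i in range(3) for j in range(3) for k in range(3)}
        assert detect_hotspots(_grid(counts), GridParams()) == []

    def test_two_close_voxels_merge_into_weighted_hotspot(self):
        counts = {(0, 0, 0): 6, (1, 0, 0): 4}
        grid = _grid(counts, protein_voxels={(20, 0, 0)})
        hs = detect_hotspots(grid, GridParams())
        assert len(hs) == 1
        assert hs[0].occupancy_count == 10
        np.testing.assert_allclose(hs[0].center, [0.45, 0.25, 0.25], atol=1e-9)

    def test_count_floor_suppresses_singletons(self):
        counts = {(0, 0, 0): 2, (30, 0, 0): 1}
        grid = _grid(counts, protein_voxels={(60, 0, 0)})
        assert detect_hotspots(grid, GridParams()) == []

    def test_stricter_cutoff_never_adds_candidates(self):
        rng = np.random.default_rng(0)
        counts = {(int(i), int(j), int(k)): int(c) for i, j, k, c in
                  rng.integers(0, 12, (60, 4))}
        counts = {v: c for v, c in counts.items() if c > 0}
        grid = _grid(counts)
        sizes = []
        for cutoff in (-0.25, -0.5, -1.0, -2.0):
            hs = detect_hotspots(grid, GridParams(hotspot_energy_cutoff=cutoff,
                                                  min_voxel_count=1))
            sizes.append(sum(len(h.member_voxels) for h in hs))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_planted_probe_yields_one_hotspot_at_known_center(self):
        from probesite.synthetic_fixtures import build_fixture, single_event_config
        from probesite.trajectory_io import superpose

        fx = build_fixture(
            single_event_config(n_frames=150, occupancy_prob=0.8,
                                bulk=(("isopropanol", 1),)), seed=2)
        ens = superpose(fx.to_ensemble(), fx.reference_structure())
        hs = detect_hotspots(accumulate_occupancy(ens, GridParams()), GridParams())
        ibu = [h for h in hs if h.probe_name == "isobutane"]
        assert len(ibu) == 1
        planted = np.array(fx.manifest.events[0]["center"])
        assert np.linalg.norm(ibu[0].center - planted) <= 1.0


def _hotspots(centers, delta_g=-1.5, probe="point"):
    return [
        HotSpot(hotspot_id=f"{probe}-{i + 1}", probe_name=probe,
                center=np.asarray(c, float), occupancy_count=10, delta_g=dg)
        for i, (c, dg) in enumerate(
            (c, delta_g if np.isscalar(delta_g) else delta_g[i])
            for i, c in enumerate(centers))
    ]


def brute_force_components(centers, cutoff):
    """O(n²) union-find over all pairs (single linkage, strict <)."""
    n = len(centers)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if math.dist(centers[i], centers[j]) < cutoff:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted((frozenset(c) for c in comps.values()), key=min)


class TestClusterSites:
    def test_five_hotspots_make_no_site(self):
        hs = _hotspots([(i * 1.0, 0, 0) for i in range(5)])
        assert cluster_sites(hs, GridParams()) == []

    def test_chain_of_six_is_one_site(self):
        hs = _hotspots([(i * 5.0, 0, 0) for i in range(6)])
        sites = cluster_sites(hs, GridParams())
        assert len(sites) == 1
        assert len(sites[0].hotspots) == 6
        assert sites[0].rank == 1

    def test_random_memberships_match_union_find_oracle(self, rng):
        centers = rng.uniform(0, 30, (30, 3))
        hs = _hotspots(centers)
        params = GridParams(min_hotspots_per_site=1)
        sites = cluster_sites(hs, params)
        got = sorted(
            (frozenset(int(h.hotspot_id.split("-")[1]) - 1 for h in s.hotspots)
             for s in sites), key=min)
        assert got == brute_force_components(centers, params.site_linkage)

    def test_ranks_ascend_with_score(self, rng):
        centers = np.vstack([rng.uniform(0, 4, (6, 3)),
                             rng.uniform(50, 54, (7, 3))])
        hs = _hotspots(centers, delta_g=[-1.0] * 6 + [-2.0] * 7)
        sites = cluster_sites(hs, GridParams())
        assert [s.rank for s in sites] == [1, 2]
        assert sites[0].site_score <= sites[1].site_score


def brute_force_site_score(site, params):
    """Exhaustive enumeration of all connected subsets of ≤ k hot spots."""
    hs = site.hotspots
    n = len(hs)
    adj = {
        i: {j for j in range(n) if j != i
            and math.dist(hs[i].center, hs[j].center) < params.site_linkage}
        for i in range(n)
    }

    def connected(sub):
        seen = {min(sub)}
        stack = [min(sub)]
        while stack:
            v = stack.pop()
            for u in adj[v] & sub:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return seen == sub

    best = math.inf
    for k in range(1, params.max_combination_size + 1):
        for combo in itertools.combinations(range(n), k):
            sub = set(combo)
            if connected(sub):
                best = min(best, sum(hs[i].delta_g for i in sub))
    return best


class TestScoreSite:
    def test_six_mutually_linked_sum(self):
        hs = _hotspots([(i * 0.5, 0, 0) for i in range(6)], delta_g=-1.0)
        sites = cluster_sites(hs, GridParams())
        assert sites[0].site_score == pytest.approx(-6.0)

    def test_cap_at_max_combination_size(self):
        hs = _hotspots([(i * 0.5, 0, 0) for i in range(8)], delta_g=-1.0)
        sites = cluster_sites(hs, GridParams())
        assert sites[0].site_score == pytest.approx(-7.0)

    def test_matches_exhaustive_oracle_on_random_site(self, rng):
        centers = rng.uniform(0, 9, (10, 3))
        dgs = -rng.uniform(1.0, 3.0, 10)
        hs = _hotspots(centers, delta_g=list(dgs))
        params = GridParams()
        sites = cluster_sites(hs, GridParams(min_hotspots_per_site=1))
        for site in sites:
            assert score_site(site, GridParams(min_hotspots_per_site=1)) == \
                pytest.approx(brute_force_site_score(site, params), rel=1e-12)


def test_site_table_deterministic(recovery_superposed):
    params = GridParams()
    tables = []
    for _ in range(2):
        grid = accumulate_occupancy(recovery_superposed, params)
        sites = cluster_sites(detect_hotspots(grid, params), params)
        tables.append(site_table(sites).to_csv(sep="\t", index=False))
    assert tables[0] == tables[1]
    assert len(tables[0].splitlines()) >= 2  # the planted site is present
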
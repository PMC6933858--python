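"""Grid occupancy, hot spots and druggable sites.

The superposed trajectory is discretised on a cubic lattice (0.5 Å edge by
default).  For every frame, each probe copy with a heavy atom within 2.5 Å
of a protein heavy atom is counted into the voxel containing its heavy-atom
centroid.  Voxel counts are converted to free energies by inverse-Boltzmann
statistics against a uniform accessible background,

    ΔG(v) = −RT ln( count(v) / expected_count ),

high-occupancy voxels (ΔG at or below a cutoff, −1.0 kcal/mol by default,
and at least ``min_voxel_count`` visits — at 0.5 Å voxel size single visits
carry enormous nominal enrichment but no statistical weight, so a count
floor is required to separate signal from Poisson noise) are greedily
merged into *hot spots* within 5.5 Å, and hot spots of all
probe types are single-linkage clustered into *druggable sites* of at least
six hot spots, ranked by an energy-like score.

The site score sums ΔG over the best connected combination of at most
``max_combination_size`` hot spots (seven by default, roughly a drug-
fragment budget); this scoring rule is this package's own convention for
turning a hot-spot cluster into a single energy-like number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .trajectory_io import TrajectoryEnsemble, write_pdb

logger = logging.getLogger(__name__)

#: Gas constant in kcal/(mol K); RT = 0.596 kcal/mol at 300 K.
R_KCAL = 0.0019872


@dataclass(frozen=True)
class GridParams:
    """All Step-1 lattice and clustering parameters (Å, kcal/mol, K)."""

    edge_length: float = 0.5
    protein_contact_cutoff: float = 2.5
    merge_distance: float = 5.5
    site_link_distance: float | None = None  # defaults to merge_distance
    min_hotspots_per_site: int = 6
    hotspot_energy_cutoff: float = -1.0
    min_voxel_count: int = 3
    temperature: float = 300.0
    max_combination_size: int = 7

    def __post_init__(self):
        if min(self.edge_length, self.protein_contact_cutoff, self.merge_distance) <= 0:
            raise ValueError("lengths must be positive")
        if self.min_hotspots_per_site < 1:
            raise ValueError("min_hotspots_per_site must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature

    @property
    def site_linkage(self) -> float:
        return self.merge_distance if self.site_link_distance is None else self.site_link_distance


@dataclass
class OccupancyGrid:
    """Sparse per-probe-type voxel counts on a lattice anchored at the origin.

    Voxel (i, j, k) spans [i·edge, (i+1)·edge) on each axis, so the grid
    origin is snapped to multiples of the edge length by construction.
    """

    edge_length: float
    n_frames: int
    counts: dict[str, dict[tuple[int, int, int], int]]
    total_counts: dict[str, int]
    protein_voxels: set[tuple[int, int, int]]

    def voxel_center(self, ijk) -> np.ndarray:
        return (np.asarray(ijk, dtype=float) + 0.5) * self.edge_length

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min_ijk, max_ijk) over protein voxels and all occupied voxels."""
        all_v = list(self.protein_voxels)
        for c in self.counts.values():
            all_v.extend(c)
        if not all_v:
            z = np.zeros(3, dtype=int)
            return z, z
        arr = np.array(all_v, dtype=int)
        return arr.min(axis=0), arr.max(axis=0)

    @property
    def n_accessible_voxels(self) -> int:
        lo, hi = self.bounding_box
        n_box = int(np.prod(hi - lo + 1))
        return max(n_box - len(self.protein_voxels), 1)

    def expected_count(self, probe_name: str) -> float:
        """Mean count per accessible voxel under a uniform background."""
        return self.total_counts.get(probe_name, 0) / self.n_accessible_voxels


@dataclass
class HotSpot:
    """A merged high-occupancy locus for one probe type."""

    hotspot_id: str
    probe_name: str
    center: np.ndarray  # Å
    occupancy_count: int
    delta_g: float  # kcal/mol
    member_voxels: list[tuple[int, int, int]] = field(default_factory=list)


@dataclass
class DruggableSite:
    """A cluster of ≥ min_hotspots_per_site hot spots, any mix of probe types."""

    site_id: str
    hotspots: list[HotSpot]
    site_score: float
    rank: int

    @property
    def probe_names(self) -> list[str]:
        return sorted({h.probe_name for h in self.hotspots})

    def hotspots_of(self, probe_name: str) -> list[HotSpot]:
        return [h for h in self.hotspots if h.probe_name == probe_name]


def _voxel_of(point: np.ndarray, edge: float) -> tuple[int, int, int]:
    return tuple(int(i) for i in np.floor(np.asarray(point) / edge).astype(int))


def accumulate_occupancy(ensemble: TrajectoryEnsemble, params: GridParams) -> OccupancyGrid:
    """Accumulate per-probe-type voxel visit counts over all frames.

    A probe copy is counted in a frame iff at least one of its heavy atoms
    lies within ``protein_contact_cutoff`` of a protein heavy atom; the
    count goes to the single voxel containing its heavy-atom centroid.
    The sparse grid expands automatically, so no visit is ever dropped.
    """
    if not ensemble.superposed:
        raise ValueError("ensemble must be superposed onto the reference first")
    edge = params.edge_length
    prot_idx = ensemble.protein_heavy_indices
    counts: dict[str, dict[tuple[int, int, int], int]] = {}
    totals: dict[str, int] = {}
    protein_voxels: set[tuple[int, int, int]] = set()
    for p in ensemble.probe_instances:
        counts.setdefault(p.probe_name, {})
        totals.setdefault(p.probe_name, 0)
    for f in range(ensemble.n_frames):
        prot_xyz = ensemble.coords[f, prot_idx]
        tree = cKDTree(prot_xyz)
        for ijk in np.floor(prot_xyz / edge).astype(int):
            protein_voxels.add(tuple(int(x) for x in ijk))
        for inst in ensemble.probe_instances:
            heavy_xyz = ensemble.coords[f, inst.heavy_indices]
            dmin, _ = tree.query(heavy_xyz, k=1)
            if dmin.min() <= params.protein_contact_cutoff:
                vox = _voxel_of(heavy_xyz.mean(axis=0), edge)
                c = counts[inst.probe_name]
                c[vox] = c.get(vox, 0) + 1
                totals[inst.probe_name] += 1
    logger.info("occupancy accumulated: %s qualifying probe-frames",
                {k: v for k, v in totals.items()})
    return OccupancyGrid(
        edge_length=edge, n_frames=ensemble.n_frames,
        counts=counts, total_counts=totals, protein_voxels=protein_voxels,
    )


def voxel_free_energy(count: float, expected_count: float, temperature: float = 300.0) -> float:
    """Inverse-Boltzmann voxel free energy, −RT ln(count/expected), kcal/mol.

    Zero count returns +inf (an unvisited voxel can never be a hot spot).
    """
    if expected_count <= 0:
        raise ValueError("expected_count must be positive")
    if count == 0:
        return math.inf
    return -R_KCAL * temperature * math.log(count / expected_count)


def detect_hotspots(grid: OccupancyGrid, params: GridParams) -> list[HotSpot]:
    """Detect per-probe-type hot spots by greedy merging of candidate voxels.

    Candidates (ΔG ≤ energy cutoff) are visited in descending occupancy
    (ties: lexicographic voxel index); each joins the nearest existing hot
    spot of its probe type closer than ``merge_distance``, else seeds a new
    one.  Centers are occupancy-weighted centroids; ΔG is recomputed from
    the summed count.
    """
    out: list[HotSpot] = []
    for probe_name in sorted(grid.counts):
        expected = grid.expected_count(probe_name)
        if expected <= 0:
            continue
        cand = [
            (vox, c) for vox, c in grid.counts[probe_name].items()
            if c >= params.min_voxel_count
            and voxel_free_energy(c, expected, params.temperature) <= params.hotspot_energy_cutoff
        ]
        cand.sort(key=lambda vc: (-vc[1], vc[0]))
        centers: list[np.ndarray] = []
        sums: list[int] = []
        weighted: list[np.ndarray] = []
        members: list[list[tuple[int, int, int]]] = []
        for vox, c in cand:
            xyz = grid.voxel_center(vox)
            best, best_d = -1, params.merge_distance
            for idx, ctr in enumerate(centers):
                d = float(np.linalg.norm(ctr - xyz))
                if d < best_d:
                    best, best_d = idx, d
            if best < 0:
                centers.append(xyz.copy())
                sums.append(c)
                weighted.append(xyz * c)
                members.append([vox])
            else:
                sums[best] += c
                weighted[best] += xyz * c
                centers[best] = weighted[best] / sums[best]
                members[best].append(vox)
        for idx in range(len(centers)):
            out.append(
                HotSpot(
                    hotspot_id=f"{probe_name}-{idx + 1}",
                    probe_name=probe_name,
                    center=centers[idx],
                    occupancy_count=int(sums[idx]),
                    delta_g=voxel_free_energy(sums[idx], expected, params.temperature),
                    member_voxels=members[idx],
                )
            )
    logger.info("detected %d hot spots", len(out))
    return out


def _linkage_components(centers: np.ndarray, cutoff: float) -> list[list[int]]:
    """Single-linkage components: edges where pairwise distance < cutoff."""
    n = len(centers)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    if n:
        tree = cKDTree(centers)
        for i, j in tree.query_pairs(cutoff):
            if np.linalg.norm(centers[i] - centers[j]) < cutoff:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(comps.values(), key=lambda c: min(c))


def cluster_sites(hotspots: list[HotSpot], params: GridParams) -> list[DruggableSite]:
    """Single-linkage cluster hot spots (all probe types pooled) into sites.

    Clusters with fewer than ``min_hotspots_per_site`` members are
    discarded.  Sites are scored by :func:`score_site` and ranked ascending
    (rank 1 = most negative = best).
    """
    if not hotspots:
        return []
    centers = np.array([h.center for h in hotspots])
    comps = _linkage_components(centers, params.site_linkage)
    raw = []
    for comp in comps:
        if len(comp) < params.min_hotspots_per_site:
            continue
        members = [hotspots[i] for i in comp]
        raw.append((score_site_members(members, params), members))
    raw.sort(key=lambda sm: (sm[0], tuple(sorted(h.hotspot_id for h in sm[1]))))
    sites = [
        DruggableSite(site_id=f"site-{i + 1}", hotspots=members,
                      site_score=score, rank=i + 1)
        for i, (score, members) in enumerate(raw)
    ]
    logger.info("clustered %d hot spots into %d druggable sites",
                len(hotspots), len(sites))
    return sites


def _connected_subsets_best(weights: np.ndarray, adj: list[set[int]], k: int) -> float:
    """Most negative sum of weights over connected induced subsets of size ≤ k.

    Exhaustive growth from each root vertex (restricted to higher-indexed
    vertices so each subset is rooted at its minimum vertex), deduplicated.
    """
    n = len(weights)
    best = math.inf
    for root in range(n):
        start = frozenset({root})
        seen = {start}
        stack = [start]
        while stack:
            sub = stack.pop()
            total = sum(weights[i] for i in sub)
            if total < best:
                best = total
            if len(sub) == k:
                continue
            frontier = {u for v in sub for u in adj[v] if u > root} - sub
            for u in frontier:
                ns = sub | {u}
                if ns not in seen:
                    seen.add(ns)
                    stack.append(ns)
    return best


def _greedy_best(weights: np.ndarray, adj: list[set[int]], k: int) -> float:
    best = math.inf
    n = len(weights)
    for seed in range(n):
        sub = {seed}
        total = weights[seed]
        best = min(best, total)
        while len(sub) < k:
            frontier = sorted(
                (u for v in sub for u in adj[v] if u not in sub),
                key=lambda u: (weights[u], u),
            )
            if not frontier:
                break
            u = frontier[0]
            sub.add(u)
            total += weights[u]
            best = min(best, total)
    return best


def score_site_members(members: list[HotSpot], params: GridParams) -> float:
    """Energy-like site score: ΔG sum of the best connected combination.

    Connectivity uses the site linkage distance; combinations are capped at
    ``max_combination_size`` hot spots.  Exact enumeration for up to 25 hot
    spots; a deterministic greedy expansion beyond that.
    """
    n = len(members)
    weights = np.array([h.delta_g for h in members])
    centers = np.array([h.center for h in members])
    cutoff = params.site_linkage
    adj: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(centers[i] - centers[j]) < cutoff:
                adj[i].add(j)
                adj[j].add(i)
    k = min(params.max_combination_size, n)
    if n <= 25:
        return _connected_subsets_best(weights, adj, k)
    return _greedy_best(weights, adj, k)


def score_site(site: DruggableSite, params: GridParams) -> float:
    """Score an assembled site (see :func:`score_site_members`)."""
    if len(site.hotspots) < params.min_hotspots_per_site:
        raise ValueError("site has fewer hot spots than min_hotspots_per_site")
    return score_site_members(site.hotspots, params)


# ---------------------------------------------------------------------------
# export

def write_hotspot_pdb(path, hotspots: list[HotSpot]) -> None:
    """One pseudo-atom per hot spot; occupancy count in the B-factor column."""
    if not hotspots:
        with open(path, "w") as fh:
            fh.write("END\n")
        return
    write_pdb(
        path,
        names=["DU" for _ in hotspots],
        resnames=[h.probe_name[:3].upper() for h in hotspots],
        chains=["X" for _ in hotspots],
        resnums=[i + 1 for i in range(len(hotspots))],
        coords=[h.center for h in hotspots],
        bfactors=[min(h.occupancy_count, 999999) for h in hotspots],
        elements=["D" for _ in hotspots],
        record="HETATM",
    )


def site_table(sites: list[DruggableSite]):
    """Site summary as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for s in sites:
        comp = {}
        for h in s.hotspots:
            comp[h.probe_name] = comp.get(h.probe_name, 0) + 1
        rows.append(
            {
                "site_id": s.site_id,
                "rank": s.rank,
                "n_hotspots": len(s.hotspots),
                "probe_composition": ",".join(f"{k}:{v}" for k, v in sorted(comp.items())),
                "site_score": round(s.site_score, 6),
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "rank", "n_hotspots",
                                       "probe_composition", "site_score"])
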
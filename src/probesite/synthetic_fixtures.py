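"""Synthetic reference + trajectory fixtures with planted probe-binding signal.

Real druggability trajectories are large and stochastic; these fixtures
emulate only the statistical structure the analysis relies on:

* a rigid toy protein (two short idealised helices) with small Gaussian
  backbone jitter and, optionally, a random rigid motion per frame (undone
  by superposition);
* *planted loci*: clusters of probe-binding events — one event per probe
  chemotype, centers a few Å apart, so each event yields one hot spot of
  its type and each locus yields one druggable site.  Each event binds in
  an independent Bernoulli(f) subset of frames, placed by rejection
  sampling inside distance windows that guarantee the event registers in
  the occupancy grid (protein contact), the binding-score profile (target
  residue contact) and the hot-spot assignment (an atom near the planted
  center) in exactly its bound frames;
* *bulk probes*: uniformly re-placed every frame (no dynamics — only
  occupancy statistics matter), providing honest background noise.

Everything the pipeline should recover is recorded in a
:class:`FixtureManifest` computed by direct, loop-level code independent of
the analysis modules, so manifest-vs-pipeline comparisons are true oracle
tests.  Identical (config, seed) pairs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .probes import BUILTIN_PROBES
from .trajectory_io import (
    ReferenceStructure,
    TrajectoryEnsemble,
    ensemble_from_arrays,
    format_pdb_atom,
)

# placement windows (Å); chosen so that every cutoff the analysis applies
# (2.5 contact, 4.0 residue contact, 1.5 hot-spot assignment) is satisfied
# with margin in bound frames and violated by construction in unbound ones
_PROT_CONTACT_WINDOW = (1.75, 2.45)
_TARGET_CONTACT_MAX = 3.8
_ATOM_CENTER_MAX = 1.0
_EXCLUSIVE_MIN_OTHERS = 4.3
_UNBOUND_MIN_PROTEIN = 6.0
_UNBOUND_MIN_CENTERS = 3.0
_JITTER_CLIP = 0.6
_CENTER_HEIGHT = 4.5  # planted pocket center: Å above the anchor Cα, radially
_LOCUS_RING_RADIUS = 2.2
_MIN_LOCUS_SEPARATION = 17.5  # > 3 × 5.5 Å merge distance

#: Rigid heavy-atom templates for the six probe chemotypes (Å, centroid-free
#: after mean subtraction; names match the built-in ProbeSpecs).
_T = 1.53 / math.sqrt(3.0)
PROBE_TEMPLATES: dict[str, tuple[list[str], np.ndarray]] = {
    "isopropanol": (["C1", "C2", "C3", "O1"],
                    np.array([[0, 0, 0], [-0.76, 1.33, 0], [-0.76, -1.33, 0],
                              [1.43, 0, 0]])),
    "acetamide": (["C1", "C2", "O1", "N1"],
                  np.array([[-1.51, 0, 0], [0, 0, 0], [0.62, 1.07, 0],
                            [0.67, -1.15, 0]])),
    "imidazole": (["N1", "C2", "N3", "C4", "C5"],
                  1.16 * np.array([[math.cos(math.radians(a)),
                                    math.sin(math.radians(a)), 0.0]
                                   for a in (90, 162, 234, 306, 18)])),
    "acetate": (["C1", "C2", "O1", "O2"],
                np.array([[-1.52, 0, 0], [0, 0, 0], [0.63, 1.07, 0],
                          [0.63, -1.07, 0]])),
    "isopropylamine": (["C1", "C2", "C3", "N1"],
                       np.array([[0, 0, 0], [-0.76, 1.33, 0],
                                 [-0.76, -1.33, 0], [1.47, 0, 0]])),
    "isobutane": (["C1", "C2", "C3", "C4"],
                  np.array([[0, 0, 0], [_T, _T, _T], [_T, -_T, -_T],
                            [-_T, _T, -_T]])),
}


@dataclass(frozen=True)
class PlantedEvent:
    """One probe copy planted at a binding center near a target residue."""

    probe_name: str
    target_chain: str
    target_resnum: int
    center: tuple[float, float, float]
    occupancy_prob: float = 0.8
    jitter_sigma: float = 0.3
    exclusive: bool = False  # keep ≥ 4.3 Å away from non-target residues

    def __post_init__(self):
        if not 0.0 <= self.occupancy_prob <= 1.0:
            raise ValueError("occupancy_prob must be in [0, 1]")


@dataclass(frozen=True)
class PlantedLocus:
    """A planted druggable site: a tight cluster of planted events."""

    center: tuple[float, float, float]
    events: tuple[PlantedEvent, ...]


@dataclass(frozen=True)
class FixtureConfig:
    n_frames: int = 300
    n_residues: int = 20
    chains: tuple[str, ...] = ("A", "B")
    chain_spacing: float = 20.0
    backbone_jitter: float = 0.1
    rigid_motion: bool = True
    loci: tuple[PlantedLocus, ...] = ()
    bulk: tuple[tuple[str, int], ...] = ()
    box_padding: float = 10.0
    frame_interval_ps: float = 4.0


# ---------------------------------------------------------------------------
# toy protein geometry

_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TWIST = math.radians(100.0)
_RES_ATOMS = ("N", "CA", "C", "O", "CB")
_RES_ELEMENTS = ("N", "C", "C", "O", "C")


def ideal_protein(config: FixtureConfig):
    """Ideal helical coordinates and per-atom metadata for the toy fold."""
    names, elements, resnames, resnums, chains, coords = [], [], [], [], [], []
    for ci, chain in enumerate(config.chains):
        ax = np.array([ci * config.chain_spacing, 0.0, 0.0])
        for i in range(config.n_residues):
            theta = i * _HELIX_TWIST
            e_r = np.array([math.cos(theta), math.sin(theta), 0.0])
            e_t = np.array([-math.sin(theta), math.cos(theta), 0.0])
            ca = ax + _HELIX_RADIUS * e_r + np.array([0, 0, _HELIX_RISE * i])
            atom_xyz = {
                "N": ca - 1.46 * e_t + np.array([0, 0, -0.5]),
                "CA": ca,
                "C": ca + 1.52 * e_t + np.array([0, 0, 0.5]),
                "O": ca + 1.52 * e_t + 1.23 * e_r + np.array([0, 0, 0.6]),
                "CB": ca + 1.52 * e_r,
            }
            for name, elem in zip(_RES_ATOMS, _RES_ELEMENTS):
                names.append(name)
                elements.append(elem)
                resnames.append("ALA")
                resnums.append(i + 1)
                chains.append(chain)
                coords.append(atom_xyz[name])
    return (np.array(names, dtype=object), np.array(elements, dtype=object),
            np.array(resnames, dtype=object), np.array(resnums, dtype=int),
            np.array(chains, dtype=object), np.array(coords, dtype=float))


def _outward_center(config: FixtureConfig, chain: str, resnum: int) -> np.ndarray:
    ci = list(config.chains).index(chain)
    ax = np.array([ci * config.chain_spacing, 0.0, 0.0])
    theta = (resnum - 1) * _HELIX_TWIST
    e_r = np.array([math.cos(theta), math.sin(theta), 0.0])
    ca = ax + _HELIX_RADIUS * e_r + np.array([0, 0, _HELIX_RISE * (resnum - 1)])
    # sub-voxel nudge keeps idealised centers off exact lattice planes
    return ca + _CENTER_HEIGHT * e_r + np.array([0.13, 0.17, 0.19])


def _feasible_anchors(config: FixtureConfig):
    """Anchor residues whose outward pocket center is clear of the protein."""
    _, _, _, resnums, chains, coords = ideal_protein(config)
    out = []
    for chain in config.chains:
        for i in range(2, config.n_residues):
            c0 = _outward_center(config, chain, i)
            if cdist(c0[None], coords).min() >= 2.8:
                out.append((chain, i, c0))
    return out


def _select_loci_anchors(config: FixtureConfig, k: int):
    """Greedy farthest-point selection of k well-separated anchors."""
    cand = _feasible_anchors(config)
    if not cand:
        raise ValueError("no feasible planted-locus anchors for this protein")
    chosen = [max(cand, key=lambda c: (c[2][2], c[0], c[1]))]
    while len(chosen) < k:
        best = max(
            cand,
            key=lambda c: (min(float(np.linalg.norm(c[2] - ch[2])) for ch in chosen),
                           c[0], c[1]),
        )
        sep = min(float(np.linalg.norm(best[2] - ch[2])) for ch in chosen)
        if sep < _MIN_LOCUS_SEPARATION:
            raise ValueError(
                f"cannot place {k} loci ≥ {_MIN_LOCUS_SEPARATION} Å apart; "
                f"best separation {sep:.1f} Å — enlarge the protein"
            )
        chosen.append(best)
    return chosen


def _ring_offsets(u: np.ndarray, n: int, radius: float) -> list[np.ndarray]:
    v1 = np.cross(u, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(v1) < 1e-8:
        v1 = np.cross(u, np.array([1.0, 0.0, 0.0]))
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(u, v1)
    v2 /= np.linalg.norm(v2)
    return [radius * (math.cos(2 * math.pi * j / n) * v1
                      + math.sin(2 * math.pi * j / n) * v2) for j in range(n)]


# ---------------------------------------------------------------------------
# ready-made configurations (the study conditions of the test suite)

_LOCUS_PROBE_ORDER = ("isobutane", "isopropanol", "acetamide", "imidazole",
                      "acetate", "isopropylamine")


def recovery_config(n_loci: int = 1, n_frames: int = 300,
                    occupancy_prob: float = 0.8, n_residues: int = 20,
                    jitter_sigma: float = 0.3) -> FixtureConfig:
    """1–3 planted druggable sites (6 probe events each) plus bulk noise."""
    base = FixtureConfig(n_frames=n_frames, n_residues=n_residues)
    _, _, _, p_resnums, p_chains, p_coords = ideal_protein(base)
    loci = []
    for chain, resnum, c0 in _select_loci_anchors(base, n_loci):
        ci = list(base.chains).index(chain)
        ax = np.array([ci * base.chain_spacing, 0.0, 0.0])
        u = c0 - np.array([ax[0], ax[1], c0[2]])
        u /= np.linalg.norm(u)
        events = []
        for p, off in zip(_LOCUS_PROBE_ORDER,
                          _ring_offsets(u, 6, _LOCUS_RING_RADIUS)):
            ec = c0 + off
            # target = the residue nearest this event's center
            nearest = int(cdist(ec[None], p_coords).argmin())
            events.append(
                PlantedEvent(
                    probe_name=p,
                    target_chain=str(p_chains[nearest]),
                    target_resnum=int(p_resnums[nearest]),
                    center=tuple(np.round(ec, 6)),
                    occupancy_prob=occupancy_prob,
                    jitter_sigma=jitter_sigma,
                )
            )
        loci.append(PlantedLocus(center=tuple(np.round(c0, 6)), events=tuple(events)))
    bulk = tuple((p, 1) for p in _LOCUS_PROBE_ORDER)
    return dataclasses.replace(base, loci=tuple(loci), bulk=bulk)


def single_event_config(probe_name: str = "isobutane", n_frames: int = 1000,
                        occupancy_prob: float = 0.9, jitter_sigma: float = 0.3,
                        exclusive: bool = True, backbone_jitter: float = 0.1,
                        rigid_motion: bool = True,
                        bulk: tuple[tuple[str, int], ...] = (("isobutane", 1),
                                                             ("isopropanol", 1)),
                        ) -> FixtureConfig:
    """One planted event with an exclusive high-affinity target residue."""
    base = FixtureConfig(n_frames=n_frames, backbone_jitter=backbone_jitter,
                         rigid_motion=rigid_motion)
    chain, resnum, c0 = _select_loci_anchors(base, 1)[0]
    event = PlantedEvent(
        probe_name=probe_name, target_chain=chain, target_resnum=resnum,
        center=tuple(np.round(c0, 6)), occupancy_prob=occupancy_prob,
        jitter_sigma=jitter_sigma, exclusive=exclusive,
    )
    locus = PlantedLocus(center=tuple(np.round(c0, 6)), events=(event,))
    return dataclasses.replace(base, loci=(locus,), bulk=bulk)


def frequency_config(n_frames: int = 2000, occupancy_prob: float = 0.3,
                     measured_probe: str = "isobutane") -> FixtureConfig:
    """One planted site whose ``measured_probe`` event binds with Bernoulli(f).

    Bulk probes are of other chemotypes only, so the measured residue–probe
    frequency is exactly the planted bound-frame count over n_frames.
    """
    cfg = recovery_config(n_loci=1, n_frames=n_frames, occupancy_prob=0.9)
    locus = cfg.loci[0]
    events = tuple(
        dataclasses.replace(e, occupancy_prob=occupancy_prob)
        if e.probe_name == measured_probe else e
        for e in locus.events
    )
    bulk = tuple((p, 1) for p in _LOCUS_PROBE_ORDER if p != measured_probe)
    return dataclasses.replace(
        cfg, loci=(dataclasses.replace(locus, events=events),), bulk=bulk
    )


def random_config(n_frames: int = 50, n_residues: int = 50,
                  n_probes: int = 30) -> FixtureConfig:
    """No planted signal: bulk probes in a tight box around a ~500-atom protein."""
    per = max(n_probes // len(_LOCUS_PROBE_ORDER), 1)
    bulk = tuple((p, per) for p in _LOCUS_PROBE_ORDER)
    extra = n_probes - per * len(_LOCUS_PROBE_ORDER)
    if extra > 0:
        bulk = (( _LOCUS_PROBE_ORDER[0], per + extra),) + bulk[1:]
    return FixtureConfig(n_frames=n_frames, n_residues=n_residues,
                         bulk=bulk, box_padding=4.0, backbone_jitter=0.15)


# ---------------------------------------------------------------------------
# generation

@dataclass
class FixtureManifest:
    seed: int
    n_frames: int
    config: dict
    protein: dict
    events: list[dict]
    loci: list[dict]
    bulk: list[dict]

    def to_json(self, path=None) -> str:
        doc = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, path) -> "FixtureManifest":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


@dataclass
class FixtureData:
    """In-memory fixture: metadata arrays, coordinates and the manifest."""

    config: FixtureConfig
    atom_names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resnums: np.ndarray
    chains: np.ndarray
    reference_coords: np.ndarray  # ideal protein only (n_protein_atoms, 3)
    coords_true: np.ndarray  # (n_frames, n_atoms, 3), reference frame
    coords_lab: np.ndarray  # with per-frame rigid motion applied
    n_protein_atoms: int
    manifest: FixtureManifest

    def to_ensemble(self, lab_frame: bool = True) -> TrajectoryEnsemble:
        return ensemble_from_arrays(
            self.atom_names, self.elements, self.resnames, self.resnums,
            self.chains, self.coords_lab if lab_frame else self.coords_true,
            frame_interval_ps=self.config.frame_interval_ps,
        )

    def reference_structure(self) -> ReferenceStructure:
        n = self.n_protein_atoms
        calpha = np.nonzero(self.atom_names[:n] == "CA")[0]
        return ReferenceStructure(
            atom_names=self.atom_names[:n], elements=self.elements[:n],
            resnames=self.resnames[:n], resnums=self.resnums[:n],
            icodes=np.full(n, "", dtype=object), chains=self.chains[:n],
            coords=self.reference_coords.copy(), calpha_indices=calpha,
        )


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _place_bound(rng, template, center, sigma, target_xyz, other_xyz,
                 protein_xyz, exclusive, max_tries=8000):
    center = np.asarray(center, dtype=float)
    clip = min(3.0 * sigma, _JITTER_CLIP) if sigma > 0 else 0.0
    lo, hi = _PROT_CONTACT_WINDOW
    for _ in range(max_tries):
        if sigma > 0:
            dc = rng.normal(0.0, sigma, 3)
            if np.linalg.norm(dc) > clip:
                continue
        else:
            dc = np.zeros(3)
        c = center + dc
        xyz = c + (template - template.mean(axis=0)) @ _random_rotation(rng).T
        d = cdist(xyz, protein_xyz)
        d_prot = d.min()
        if not lo <= d_prot <= hi:
            if sigma == 0:
                continue  # keep the centroid pinned exactly at the center
            # slide the probe along the closest-approach axis into the window
            ai, pi = np.unravel_index(d.argmin(), d.shape)
            u = xyz[ai] - protein_xyz[pi]
            u /= np.linalg.norm(u)
            xyz = xyz + (rng.uniform(lo + 0.1, hi - 0.1) - d_prot) * u
            d_prot = cdist(xyz, protein_xyz).min()
            if not lo <= d_prot <= hi:
                continue
        if np.linalg.norm(xyz.mean(axis=0) - center) > 1.0:
            continue
        if cdist(xyz, target_xyz).min() > _TARGET_CONTACT_MAX:
            continue
        if exclusive and other_xyz.size and cdist(xyz, other_xyz).min() < _EXCLUSIVE_MIN_OTHERS:
            continue
        if np.linalg.norm(xyz - center, axis=1).min() > _ATOM_CENTER_MAX:
            continue
        return xyz
    raise ValueError(
        f"infeasible geometry: could not place a bound probe at center "
        f"{np.round(center, 2).tolist()} after {max_tries} attempts"
    )


def _place_away(rng, template, lo, hi, protein_xyz, centers, min_protein,
                max_tries=500):
    for _ in range(max_tries):
        c = rng.uniform(lo, hi)
        xyz = c + (template - template.mean(axis=0)) @ _random_rotation(rng).T
        if cdist(xyz, protein_xyz).min() < min_protein:
            continue
        if centers.size and cdist(xyz, centers).min() < _UNBOUND_MIN_CENTERS:
            continue
        return xyz
    raise ValueError("could not place a probe away from the protein")


def build_fixture(config: FixtureConfig, seed: int) -> FixtureData:
    """Generate a fixture in memory; deterministic per (config, seed)."""
    rng = np.random.default_rng(seed)
    (p_names, p_elems, p_resnames, p_resnums, p_chains, p_coords) = ideal_protein(config)
    n_prot = len(p_names)

    # probe atom bookkeeping: events first, bulk after, chain "P"
    events = [e for locus in config.loci for e in locus.events]
    probe_entries = []  # (probe_name, template_names, template)
    for e in events:
        names, tmpl = PROBE_TEMPLATES[e.probe_name]
        probe_entries.append((e.probe_name, names, tmpl))
    bulk_names_flat: list[str] = []
    for name, count in config.bulk:
        bulk_names_flat.extend([name] * count)
    for name in bulk_names_flat:
        names, tmpl = PROBE_TEMPLATES[name]
        probe_entries.append((name, names, tmpl))

    names_all = list(p_names)
    elems_all = list(p_elems)
    resnames_all = list(p_resnames)
    resnums_all = list(p_resnums)
    chains_all = list(p_chains)
    for j, (pname, anames, _) in enumerate(probe_entries):
        spec = BUILTIN_PROBES[pname]
        names_all.extend(anames)
        elems_all.extend(n[0] for n in anames)
        resnames_all.extend([spec.topology_residue_name] * len(anames))
        resnums_all.extend([9001 + j] * len(anames))
        chains_all.extend(["P"] * len(anames))
    n_atoms = len(names_all)

    # pre-compute per-event target/other heavy index sets (protein is all-heavy)
    def _res_idx(chain, resnum):
        return np.nonzero((p_chains == chain) & (p_resnums == resnum))[0]

    event_target_idx = [_res_idx(e.target_chain, e.target_resnum) for e in events]
    planted_centers = (np.array([e.center for e in events], dtype=float)
                       if events else np.empty((0, 3)))
    for e in events:
        d = cdist(np.asarray(e.center, dtype=float)[None], p_coords).min()
        if d < 2.6:
            raise ValueError(
                f"infeasible geometry: planted center {e.center} is only "
                f"{d:.2f} Å from the protein core"
            )

    lo = p_coords.min(axis=0) - config.box_padding
    hi = p_coords.max(axis=0) + config.box_padding

    coords_true = np.empty((config.n_frames, n_atoms, 3))
    bound_flags = np.zeros((config.n_frames, len(events)), dtype=bool)
    for f in range(config.n_frames):
        if config.backbone_jitter > 0:
            prot = p_coords + rng.normal(0.0, config.backbone_jitter, p_coords.shape)
        else:
            prot = p_coords.copy()
        coords_true[f, :n_prot] = prot
        cursor = n_prot
        for j, e in enumerate(events):
            _, anames, tmpl = probe_entries[j]
            n_pa = len(anames)
            bound = rng.random() < e.occupancy_prob
            bound_flags[f, j] = bound
            if bound:
                t_idx = event_target_idx[j]
                mask = np.ones(n_prot, dtype=bool)
                mask[t_idx] = False
                xyz = _place_bound(
                    rng, tmpl, e.center, e.jitter_sigma,
                    prot[t_idx], prot[mask] if e.exclusive else np.empty((0, 3)),
                    prot, e.exclusive,
                )
            else:
                xyz = _place_away(rng, tmpl, lo, hi, prot, planted_centers,
                                  _UNBOUND_MIN_PROTEIN)
            coords_true[f, cursor:cursor + n_pa] = xyz
            cursor += n_pa
        for name in bulk_names_flat:
            _, tmpl = PROBE_TEMPLATES[name]
            xyz = _place_away(rng, tmpl, lo, hi, prot, np.empty((0, 3)), 1.8)
            coords_true[f, cursor:cursor + len(tmpl)] = xyz
            cursor += len(tmpl)

    # optional per-frame rigid motion (what superposition must undo)
    coords_lab = coords_true.copy()
    if config.rigid_motion:
        for f in range(config.n_frames):
            rot = _random_rotation(rng)
            trans = rng.uniform(-10.0, 10.0, 3)
            coords_lab[f] = coords_true[f] @ rot.T + trans

    manifest = _build_manifest(
        config, seed, events, probe_entries, event_target_idx,
        coords_true, n_prot, p_chains, p_resnums, bound_flags,
        bulk_names_flat,
    )
    return FixtureData(
        config=config,
        atom_names=np.array(names_all, dtype=object),
        elements=np.array(elems_all, dtype=object),
        resnames=np.array(resnames_all, dtype=object),
        resnums=np.array(resnums_all, dtype=int),
        chains=np.array(chains_all, dtype=object),
        reference_coords=p_coords,
        coords_true=coords_true,
        coords_lab=coords_lab,
        n_protein_atoms=n_prot,
        manifest=manifest,
    )


def _build_manifest(config, seed, events, probe_entries, event_target_idx,
                    coords_true, n_prot, p_chains, p_resnums, bound_flags,
                    bulk_names_flat) -> FixtureManifest:
    """Ground truth by direct computation (no reuse of the analysis modules)."""
    n_frames = config.n_frames
    # atom index ranges of every probe copy, and copies per probe type
    spans = []
    cursor = n_prot
    for _, anames, _t in probe_entries:
        spans.append((cursor, cursor + len(anames)))
        cursor += len(anames)
    type_spans: dict[str, list[tuple[int, int]]] = {}
    for (pname, _, _), span in zip(probe_entries, spans):
        type_spans.setdefault(pname, []).append(span)

    event_dicts = []
    for j, e in enumerate(events):
        a, b = spans[j]
        bound = sorted(int(f) for f in np.nonzero(bound_flags[:, j])[0])
        t_idx = event_target_idx[j]
        contact = []
        centroids = []
        for f in range(n_frames):
            xyz = coords_true[f, a:b]
            if cdist(xyz, coords_true[f, t_idx]).min() <= 4.0:
                contact.append(f)
            if bound_flags[f, j]:
                centroids.append(xyz.mean(axis=0))
        realized = (np.mean(centroids, axis=0).round(6).tolist()
                    if centroids else None)

        # naive binding-score profile for this probe type on the target chain
        chain_mask = p_chains == e.target_chain
        res_list = sorted(set(int(r) for r in p_resnums[chain_mask]))
        scores = {}
        for resnum in res_list:
            idx = np.nonzero(chain_mask & (p_resnums == resnum))[0]
            s = 0.0
            for f in range(n_frames):
                for (sa, sb) in type_spans[e.probe_name]:
                    d = cdist(coords_true[f, idx], coords_true[f, sa:sb])
                    sel = d[d <= 4.0]
                    if sel.size:
                        s += float(np.sum(1.0 / np.square(sel)))
            scores[resnum] = s
        other = {r: s for r, s in scores.items() if r != e.target_resnum}
        max_other_resnum = (max(other, key=lambda r: other[r]) if other else None)
        event_dicts.append(
            {
                "probe_name": e.probe_name,
                "instance_id": f"{e.probe_name}:P:{9001 + j}",
                "target_chain": e.target_chain,
                "target_resnum": int(e.target_resnum),
                "center": list(np.round(np.asarray(e.center), 6)),
                "occupancy_prob": e.occupancy_prob,
                "jitter_sigma": e.jitter_sigma,
                "exclusive": e.exclusive,
                "bound_frames": bound,
                "n_bound": len(bound),
                "contact_frames": contact,
                "realized_center": realized,
                "target_score": round(scores[e.target_resnum], 6),
                "max_other_score": round(max(other.values()), 6) if other else 0.0,
                "max_other_resnum": max_other_resnum,
            }
        )

    loci_dicts = [
        {
            "center": list(np.round(np.asarray(locus.center), 6)),
            "n_events": len(locus.events),
            "probe_names": sorted(e.probe_name for e in locus.events),
            "event_centers": [list(np.round(np.asarray(e.center), 6))
                              for e in locus.events],
        }
        for locus in config.loci
    ]
    bulk_dicts = [{"probe_name": n, "count": bulk_names_flat.count(n)}
                  for n in sorted(set(bulk_names_flat))]

    def _cfg_dict(obj):
        if dataclasses.is_dataclass(obj):
            return {k: _cfg_dict(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [_cfg_dict(v) for v in obj]
        if isinstance(obj, np.floating):
            return float(obj)
        return obj

    return FixtureManifest(
        seed=int(seed),
        n_frames=int(n_frames),
        config=_cfg_dict(config),
        protein={
            "chains": list(config.chains),
            "n_residues_per_chain": int(config.n_residues),
            "n_atoms": int(n_prot),
        },
        events=event_dicts,
        loci=loci_dicts,
        bulk=bulk_dicts,
    )


# ---------------------------------------------------------------------------
# file output

def _write_multimodel_pdb(path, fixture: FixtureData) -> None:
    lines = []
    n = len(fixture.atom_names)
    for f in range(fixture.coords_lab.shape[0]):
        lines.append(f"MODEL     {f + 1:4d}")
        for i in range(n):
            lines.append(
                format_pdb_atom(
                    i + 1, str(fixture.atom_names[i]), str(fixture.resnames[i]),
                    str(fixture.chains[i]), int(fixture.resnums[i]),
                    fixture.coords_lab[f, i],
                    element=str(fixture.elements[i]),
                    record="ATOM" if i < fixture.n_protein_atoms else "HETATM",
                )
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def generate_fixture(config: FixtureConfig, seed: int, out_dir,
                     write_dcd: bool = False):
    """Generate fixture files: reference.pdb, trajectory.pdb, manifest.json.

    Returns (reference_path, trajectory_path, manifest).  With
    ``write_dcd=True`` a binary DCD mirror plus its single-frame PDB
    topology are written as well (trajectory.dcd / topology.pdb).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fixture = build_fixture(config, seed)

    ref_path = out_dir / "reference.pdb"
    n = fixture.n_protein_atoms
    lines = [
        format_pdb_atom(i + 1, str(fixture.atom_names[i]),
                        str(fixture.resnames[i]), str(fixture.chains[i]),
                        int(fixture.resnums[i]), fixture.reference_coords[i],
                        element=str(fixture.elements[i]))
        for i in range(n)
    ]
    lines.append("END")
    ref_path.write_text("\n".join(lines) + "\n")

    traj_path = out_dir / "trajectory.pdb"
    _write_multimodel_pdb(traj_path, fixture)
    fixture.manifest.to_json(out_dir / "manifest.json")

    if write_dcd:
        import MDAnalysis as mda

        top_path = out_dir / "topology.pdb"
        one = dataclasses.replace(fixture)
        one_lab = fixture.coords_lab[:1]
        one = FixtureData(**{**fixture.__dict__, "coords_lab": one_lab,
                             "coords_true": fixture.coords_true[:1]})
        _write_multimodel_pdb(top_path, one)
        u = mda.Universe(str(top_path))
        with mda.Writer(str(out_dir / "trajectory.dcd"), n_atoms=len(u.atoms)) as w:
            for f in range(fixture.coords_lab.shape[0]):
                u.atoms.positions = fixture.coords_lab[f]
                w.write(u.atoms)
    return ref_path, traj_path, fixture.manifest
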
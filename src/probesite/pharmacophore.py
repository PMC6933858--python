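"""Co-occurrence snapshots and pharmacophore model export.

Frames where every top-ranked residue–probe interaction is satisfied
simultaneously are the co-occurrence snapshots: protein conformation and
probe poses are extracted from the same frame, so the pharmacophore
geometry and the receptor conformation used for screening are mutually
consistent.  Each bound probe copy contributes the typed features of its
chemotype (donor on the hydroxyl oxygen of isopropanol, hydrophobic on the
carbon centroid of isobutane, ...), emitted as 1 Å spheres and exported as
a Pharmit session JSON ready for virtual screening.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .hotspot_grid import DruggableSite
from .interaction_ranking import InteractionRecord
from .probes import ProbeSpec, resname_map
from .trajectory_io import TrajectoryEnsemble, write_pdb

logger = logging.getLogger(__name__)

DEFAULT_FEATURE_RADIUS = 1.0  # Å

#: Feature-kind → Pharmit point name (fixed mapping).
PHARMIT_NAMES = {
    "hbond_donor": "HydrogenDonor",
    "hbond_acceptor": "HydrogenAcceptor",
    "hydrophobic": "Hydrophobic",
    "aromatic": "Aromatic",
    "negative_ion": "NegativeIon",
    "positive_ion": "PositiveIon",
}
_KIND_FROM_PHARMIT = {v: k for k, v in PHARMIT_NAMES.items()}


@dataclass
class PharmacophoreFeature:
    feature_kind: str
    center: np.ndarray  # Å
    radius: float = DEFAULT_FEATURE_RADIUS
    enabled: bool = True
    provenance: dict = field(default_factory=dict)


@dataclass
class PharmacophoreModel:
    frame_id: int
    features: list[PharmacophoreFeature]
    source: str = ""


@dataclass
class Snapshot:
    """One extracted co-occurrence frame: protein + qualifying probe copies."""

    frame_id: int
    protein_path: Path
    probes_path: Path
    probe_instances: list[dict]  # instance_id, probe_name, atom_names, elements, coords


def find_cooccurrence_frames(top_set: list[InteractionRecord]) -> list[int]:
    """Frames present in the qualifying set of every top-ranked interaction."""
    if not top_set:
        raise ValueError("no interactions above cutoff — nothing to intersect")
    frames = set(top_set[0].qualifying_frames)
    for rec in top_set[1:]:
        frames &= rec.qualifying_frames
    if not frames:
        warnings.warn(
            "no frame satisfies all top-ranked interactions simultaneously; "
            "consider lowering the frequency cutoff",
            stacklevel=2,
        )
    return sorted(frames)


def conformer_rmsd(ensemble: TrajectoryEnsemble, frame_ids: list[int]) -> float:
    """Mean pairwise Cα RMSD over the selected frames (no per-pair refit)."""
    if len(frame_ids) < 2:
        raise ValueError("need at least two frames for a pairwise RMSD")
    ca = [
        i for i in ensemble.protein_indices
        if ensemble.atom_names[i] == "CA" and ensemble.elements[i] == "C"
    ]
    xyz = ensemble.coords[np.ix_(frame_ids, ca)]
    total = 0.0
    n_pairs = 0
    for a, b in combinations(range(len(frame_ids)), 2):
        diff = xyz[a] - xyz[b]
        total += math.sqrt(float(np.mean(np.sum(diff * diff, axis=1))))
        n_pairs += 1
    return total / n_pairs


def extract_snapshot(
    ensemble: TrajectoryEnsemble,
    frame_id: int,
    site: DruggableSite,
    top_set: list[InteractionRecord],
    out_dir,
) -> Snapshot:
    """Write the protein conformation and top-set probe poses of one frame.

    The probe file contains, once each, the probe copies recorded as the
    best qualifying instance of some top-set interaction in this frame.
    """
    if not (0 <= frame_id < ensemble.n_frames):
        raise ValueError(f"frame {frame_id} outside 0..{ensemble.n_frames - 1}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    prot = ensemble.protein_indices
    protein_path = out_dir / f"frame_{frame_id:06d}_protein.pdb"
    write_pdb(
        protein_path,
        names=ensemble.atom_names[prot],
        resnames=ensemble.resnames[prot],
        chains=ensemble.chains[prot],
        resnums=ensemble.resnums[prot],
        coords=ensemble.coords[frame_id, prot],
        icodes=ensemble.icodes[prot],
        elements=ensemble.elements[prot],
    )

    wanted_ids = []
    for rec in top_set:
        iid = rec.best_instance_by_frame.get(frame_id)
        if iid is not None and iid not in wanted_ids:
            wanted_ids.append(iid)
    instances = {p.instance_id: p for p in ensemble.probe_instances}
    probe_records = []
    names, resnames, chains, resnums, coords, elements = [], [], [], [], [], []
    for serial, iid in enumerate(wanted_ids, start=1):
        inst = instances[iid]
        idx = inst.atom_indices
        probe_records.append(
            {
                "instance_id": iid,
                "probe_name": inst.probe_name,
                "atom_names": [str(n) for n in ensemble.atom_names[idx]],
                "elements": [str(e) for e in ensemble.elements[idx]],
                "coords": ensemble.coords[frame_id, idx].copy(),
            }
        )
        names.extend(ensemble.atom_names[idx])
        resnames.extend(ensemble.resnames[idx])
        chains.extend(["P"] * len(idx))
        resnums.extend([serial] * len(idx))
        coords.extend(ensemble.coords[frame_id, idx])
        elements.extend(ensemble.elements[idx])
    probes_path = out_dir / f"frame_{frame_id:06d}_probes.pdb"
    write_pdb(probes_path, names=names, resnames=resnames, chains=chains,
              resnums=resnums, coords=np.array(coords).reshape(-1, 3),
              elements=elements, record="HETATM")
    return Snapshot(
        frame_id=frame_id, protein_path=protein_path, probes_path=probes_path,
        probe_instances=probe_records,
    )


def build_pharmacophore(
    snapshot: Snapshot,
    probe_specs=None,
    feature_selection: set[str] | None = None,
) -> PharmacophoreModel:
    """Turn a snapshot's probe poses into typed feature spheres.

    Every probe copy contributes the feature templates of its chemotype,
    optionally filtered by ``feature_selection`` (a set of feature kinds);
    anchors are heavy-atom positions or centroids of named heavy-atom
    subsets, radius 1 Å.
    """
    if not snapshot.probe_instances:
        raise ValueError(f"snapshot frame {snapshot.frame_id} contains no probes")
    if probe_specs is None or not isinstance(probe_specs, dict):
        specs_by_name = {s.probe_name: s for s in resname_map(probe_specs).values()}
    else:
        specs_by_name = {
            (v.probe_name if isinstance(v, ProbeSpec) else k): v
            for k, v in probe_specs.items()
        }
    features: list[PharmacophoreFeature] = []
    for rec in snapshot.probe_instances:
        spec = specs_by_name[rec["probe_name"]]
        pos = {n: np.asarray(c, dtype=float)
               for n, c in zip(rec["atom_names"], rec["coords"])}
        for tmpl in spec.feature_templates:
            if feature_selection is not None and tmpl.kind not in feature_selection:
                continue
            anchor_xyz = np.mean([pos[a] for a in tmpl.anchor_atoms], axis=0)
            features.append(
                PharmacophoreFeature(
                    feature_kind=tmpl.kind,
                    center=anchor_xyz,
                    radius=DEFAULT_FEATURE_RADIUS,
                    enabled=True,
                    provenance={
                        "instance_id": rec["instance_id"],
                        "probe_name": rec["probe_name"],
                        "anchor_atoms": list(tmpl.anchor_atoms),
                    },
                )
            )
    return PharmacophoreModel(
        frame_id=snapshot.frame_id, features=features,
        source=str(snapshot.probes_path),
    )


def write_pharmit_json(model: PharmacophoreModel, path=None) -> str:
    """Serialise a model as a Pharmit session JSON (top-level "points")."""
    if not model.features:
        raise ValueError("model has no features")
    points = []
    for f in model.features:
        if f.feature_kind not in PHARMIT_NAMES:
            raise ValueError(f"feature kind {f.feature_kind!r} has no Pharmit name")
        points.append(
            {
                "name": PHARMIT_NAMES[f.feature_kind],
                "x": float(f.center[0]),
                "y": float(f.center[1]),
                "z": float(f.center[2]),
                "radius": float(f.radius),
                "enabled": bool(f.enabled),
            }
        )
    doc = json.dumps({"points": points}, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(doc + "\n")
    return doc


def read_pharmit_json(source) -> PharmacophoreModel:
    """Parse a Pharmit session JSON back into a model (inverse of write)."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        raw = json.loads(Path(source).read_text())
    else:
        raw = json.loads(source)
    features = [
        PharmacophoreFeature(
            feature_kind=_KIND_FROM_PHARMIT[p["name"]],
            center=np.array([p["x"], p["y"], p["z"]], dtype=float),
            radius=float(p["radius"]),
            enabled=bool(p["enabled"]),
        )
        for p in raw["points"]
    ]
    return PharmacophoreModel(frame_id=-1, features=features)


def pec50_from_ec50(ec50_molar: float) -> float:
    """pEC50 = −log10(EC50 in molar); 2.0 nM → 8.699 (reported as 8.700)."""
    if not ec50_molar > 0:
        raise ValueError("EC50 must be a positive molar concentration")
    return -math.log10(ec50_molar)
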
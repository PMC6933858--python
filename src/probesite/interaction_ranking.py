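"""Frequency counting and ranking of residue–probe interactions.

For each site residue selected in the affinity step, a frame counts toward
the residue–probe interaction iff some probe copy of that type both (a)
touches the residue — any heavy atom within the 4 Å contact cutoff of a
residue heavy atom — and (b) occupies one of the site's hot spots of that
probe type — any atom of the probe (hydrogens included) within 1.5 Å of a
hot-spot center.  The heavy-atom/all-atom asymmetry between (a) and (b) is
intentional: contacts are a heavy-atom notion, while hot-spot occupancy
asks whether the probe envelope covers the locus.

A frame counts at most once per (residue, probe-type) pair, however many
copies qualify.  Frequencies are counts over the total number of frames;
pairs at or above the frequency cutoff (10% by default) form the top set
used for snapshot extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hotspot_grid import DruggableSite
from .residue_affinity import HighAffinityCall
from .trajectory_io import ResidueKey, TrajectoryEnsemble

logger = logging.getLogger(__name__)

DEFAULT_HOTSPOT_ASSIGN_CUTOFF = 1.5  # Å
DEFAULT_FREQUENCY_CUTOFF = 0.10


@dataclass
class InteractionRecord:
    """One residue–probe pair with its qualifying frames and frequency."""

    residue: ResidueKey
    resname: str
    probe_name: str
    qualifying_frames: frozenset[int]
    n_frames: int
    contributing_hotspot_ids: tuple[str, ...]
    best_instance_by_frame: dict[int, str] = field(default_factory=dict)
    binding_score: float = 0.0

    @property
    def count(self) -> int:
        return len(self.qualifying_frames)

    @property
    def frequency(self) -> float:
        return self.count / self.n_frames


def interaction_frequency(
    ensemble: TrajectoryEnsemble,
    residue: ResidueKey | HighAffinityCall,
    probe_name: str,
    site: DruggableSite,
    contact_cutoff: float = 4.0,
    hotspot_assign_cutoff: float = DEFAULT_HOTSPOT_ASSIGN_CUTOFF,
    binding_score: float | None = None,
) -> InteractionRecord:
    """Count frames where a probe copy contacts the residue AND sits on a hot spot."""
    if not ensemble.superposed:
        raise ValueError("ensemble must be superposed first")
    if isinstance(residue, HighAffinityCall):
        if binding_score is None:
            binding_score = residue.score
        residue = residue.residue
    hotspots = site.hotspots_of(probe_name)
    if not hotspots:
        raise ValueError(
            f"site {site.site_id} has no hot spots of probe type {probe_name!r}"
        )
    centers = np.array([h.center for h in hotspots])
    hs_ids = [h.hotspot_id for h in hotspots]
    res_atoms = ensemble.residue_heavy_indices(residue)
    if res_atoms.size == 0:
        raise ValueError(f"residue {residue} not found in the protein partition")
    instances = ensemble.instances_of(probe_name)
    if not instances:
        raise ValueError(f"no probe copies of type {probe_name!r}")

    frames: set[int] = set()
    contributing: set[str] = set()
    best_by_frame: dict[int, str] = {}
    for f in range(ensemble.n_frames):
        res_xyz = ensemble.coords[f, res_atoms]
        best_id, best_d = None, np.inf
        for inst in instances:
            heavy_xyz = ensemble.coords[f, inst.heavy_indices]
            d_contact = np.linalg.norm(
                heavy_xyz[:, None, :] - res_xyz[None, :, :], axis=-1
            ).min()
            if d_contact > contact_cutoff:
                continue
            all_xyz = ensemble.coords[f, inst.atom_indices]
            d_hs = np.linalg.norm(
                all_xyz[:, None, :] - centers[None, :, :], axis=-1
            )
            near = d_hs.min(axis=0) <= hotspot_assign_cutoff
            if not near.any():
                continue
            frames.add(f)
            contributing.update(hs_ids[i] for i in np.nonzero(near)[0])
            if d_contact < best_d:
                best_id, best_d = inst.instance_id, d_contact
        if best_id is not None:
            best_by_frame[f] = best_id
    rec = InteractionRecord(
        residue=residue,
        resname=str(ensemble.resnames[res_atoms[0]]),
        probe_name=probe_name,
        qualifying_frames=frozenset(frames),
        n_frames=ensemble.n_frames,
        contributing_hotspot_ids=tuple(sorted(contributing)),
        best_instance_by_frame=best_by_frame,
        binding_score=0.0 if binding_score is None else binding_score,
    )
    logger.info("%s–%s: %d/%d frames (frequency %.4f)",
                residue, probe_name, rec.count, rec.n_frames, rec.frequency)
    return rec


def rank_interactions(
    records: list[InteractionRecord],
    frequency_cutoff: float = DEFAULT_FREQUENCY_CUTOFF,
) -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """Sort by frequency (desc), then binding score (desc), then identity.

    Returns (ranked list, top set); the top set keeps records whose
    frequency is at or above the cutoff (inclusive).
    """
    ranked = sorted(
        records,
        key=lambda r: (
            -r.frequency,
            -r.binding_score,
            (r.residue.chain, r.residue.resnum, r.residue.icode, r.probe_name),
        ),
    )
    top = [r for r in ranked if r.frequency >= frequency_cutoff]
    return ranked, top


def rank_table(ranked: list[InteractionRecord], top: list[InteractionRecord]):
    """Ranked interaction table as a DataFrame (TSV-ready)."""
    import pandas as pd

    top_ids = {id(r) for r in top}
    rows = [
        {
            "rank": i + 1,
            "chain": r.residue.chain,
            "resnum": r.residue.resnum,
            "icode": r.residue.icode,
            "resname": r.resname,
            "probe": r.probe_name,
            "count": r.count,
            "frequency": round(r.frequency, 6),
            "top": id(r) in top_ids,
        }
        for i, r in enumerate(ranked)
    ]
    return pd.DataFrame(rows, columns=["rank", "chain", "resnum", "icode",
                                       "resname", "probe", "count",
                                       "frequency", "top"])
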
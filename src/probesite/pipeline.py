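"""End-to-end workflow: hot spots → profiles → site residues → ranking →
snapshots → pharmacophores, with defaults matching the published protocol."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._version import __version__
from .hotspot_grid import (
    GridParams,
    accumulate_occupancy,
    cluster_sites,
    detect_hotspots,
    site_table,
    write_hotspot_pdb,
)
from .interaction_ranking import interaction_frequency, rank_interactions, rank_table
from .pharmacophore import (
    build_pharmacophore,
    conformer_rmsd,
    extract_snapshot,
    find_cooccurrence_frames,
    write_pharmit_json,
)
from .residue_affinity import (
    binding_score_profile,
    calls_table,
    high_affinity_residues,
    select_site_residues,
)
from .trajectory_io import load_reference, load_trajectory, superpose

logger = logging.getLogger(__name__)

OK = "ok"
NO_SITES = "no-sites"


@dataclass
class RunConfig:
    """All workflow parameters; defaults are the published protocol values."""

    reference: str = ""
    topology: str = ""
    trajectory: str = ""
    out_dir: str = "probesite_out"
    grid: GridParams = field(default_factory=GridParams)
    contact_cutoff: float = 4.0  # Å, residue–probe heavy-atom contact
    score_threshold: float = 500.0  # Å⁻², high-affinity call (strict >)
    site_cutoff: float = 8.0  # Å, residue-to-hot-spot site selection
    hotspot_assign_cutoff: float = 1.5  # Å, probe-to-hot-spot assignment
    frequency_cutoff: float = 0.10  # inclusive top-set cutoff
    feature_selection: tuple[str, ...] | None = None
    site_id: str | None = None  # default: rank-1 site
    stride: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        grid = GridParams(**raw.pop("grid", {}))
        fs = raw.pop("feature_selection", None)
        if fs is not None:
            fs = tuple(fs)
        return cls(grid=grid, feature_selection=fs, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    status: str
    out_dir: Path
    message: str = ""
    n_sites: int = 0
    n_top_interactions: int = 0
    cooccurrence_frames: list[int] = field(default_factory=list)
    mean_conformer_rmsd: float | None = None


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow and write every intermediate artifact.

    Outputs under ``config.out_dir``: per-probe hot-spot PDBs, the ranked
    site table, per-probe/per-chain score profiles, high-affinity and
    site-residue tables, the ranked interaction table, snapshot PDBs, one
    Pharmit JSON per co-occurrence snapshot, an index table, and a
    provenance record.  Returns a :class:`PipelineResult` whose ``status``
    is ``"no-sites"`` if the trajectory supports no druggable site (or no
    interaction survives the cutoffs), ``"ok"`` otherwise.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for c in (config.contact_cutoff, config.score_threshold, config.site_cutoff,
              config.hotspot_assign_cutoff, config.frequency_cutoff):
        if c < 0:
            raise ValueError("cutoffs must be non-negative")
    logger.info("parameters: %s", config.to_dict())

    provenance = {
        "package": "probesite",
        "version": __version__,
        "parameters": config.to_dict(),
        "inputs": {},
    }
    for label, p in (("reference", config.reference),
                     ("topology", config.topology),
                     ("trajectory", config.trajectory)):
        if p:
            provenance["inputs"][label] = {"path": str(p), "sha256": _sha256(p)}
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )

    # stage 1: load + superpose + hot spots
    reference = load_reference(config.reference)
    ensemble = load_trajectory(
        config.topology or config.trajectory,
        config.trajectory if config.topology else None,
        stride=config.stride,
    )
    ensemble = superpose(ensemble, reference)
    grid = accumulate_occupancy(ensemble, config.grid)
    hotspots = detect_hotspots(grid, config.grid)
    hs_dir = out / "hotspots"
    hs_dir.mkdir(exist_ok=True)
    for probe_name in sorted({h.probe_name for h in hotspots} | set(grid.counts)):
        write_hotspot_pdb(hs_dir / f"{probe_name}_hotspots.pdb",
                          [h for h in hotspots if h.probe_name == probe_name])
    sites = cluster_sites(hotspots, config.grid)
    _write_tsv(site_table(sites), out / "sites.tsv")
    if not sites:
        return PipelineResult(NO_SITES, out, "no druggable sites detected")

    if config.site_id is None:
        site = sites[0]
    else:
        match = [s for s in sites if s.site_id == config.site_id]
        if not match:
            raise ValueError(f"unknown site id {config.site_id!r}; "
                             f"available: {[s.site_id for s in sites]}")
        site = match[0]
    logger.info("analyzing %s (rank %d, score %.3f kcal/mol)",
                site.site_id, site.rank, site.site_score)

    # stage 2: binding-score profiles + high-affinity calls
    prof_dir = out / "profiles"
    prof_dir.mkdir(exist_ok=True)
    chains = sorted({k.chain for k in ensemble.protein_residue_keys()})
    probe_names = sorted({p.probe_name for p in ensemble.probe_instances})
    calls = []
    profiles = {}
    for probe_name in probe_names:
        for chain in chains:
            prof = binding_score_profile(ensemble, probe_name, chain,
                                         config.contact_cutoff)
            profiles[(probe_name, chain)] = prof
            _write_tsv(prof.as_frame(), prof_dir / f"{probe_name}_{chain}.tsv")
            calls.extend(high_affinity_residues(prof, config.score_threshold))
    _write_tsv(
        calls_table({p: [c for c in calls if c.probe_name == p] for p in probe_names}),
        out / "high_affinity.tsv",
    )

    # stage 3: residues at the analyzed site
    selected = select_site_residues(calls, site, reference, config.site_cutoff)
    _write_tsv(calls_table(selected), out / "site_residues.tsv")
    n_selected = sum(len(v) for v in selected.values())
    if n_selected == 0:
        return PipelineResult(
            NO_SITES, out,
            f"no high-affinity residue lies within {config.site_cutoff} Å of "
            f"{site.site_id}", n_sites=len(sites),
        )

    # stage 4: interaction frequencies + ranking
    records = []
    for probe_name, plist in sorted(selected.items()):
        for call in plist:
            records.append(
                interaction_frequency(
                    ensemble, call, probe_name, site,
                    contact_cutoff=config.contact_cutoff,
                    hotspot_assign_cutoff=config.hotspot_assign_cutoff,
                )
            )
    ranked, top = rank_interactions(records, config.frequency_cutoff)
    _write_tsv(rank_table(ranked, top), out / "rank.tsv")
    if not top:
        return PipelineResult(NO_SITES, out,
                              "no interaction at or above the frequency cutoff",
                              n_sites=len(sites))

    # stage 5: co-occurrence snapshots + pharmacophores
    frames = find_cooccurrence_frames(top)
    if not frames:
        return PipelineResult(
            NO_SITES, out,
            "no frame satisfies all top interactions simultaneously",
            n_sites=len(sites), n_top_interactions=len(top),
        )
    mean_rmsd = conformer_rmsd(ensemble, frames) if len(frames) > 1 else 0.0
    snap_dir = out / "snapshots"
    pm_dir = out / "pharmacophores"
    pm_dir.mkdir(exist_ok=True)
    feature_selection = (set(config.feature_selection)
                         if config.feature_selection else None)
    index_rows = []
    for fid in frames:
        snap = extract_snapshot(ensemble, fid, site, top, snap_dir)
        model = build_pharmacophore(snap, feature_selection=feature_selection)
        write_pharmit_json(model, pm_dir / f"frame_{fid:06d}.json")
        index_rows.append({"frame_id": fid, "n_features": len(model.features),
                           "n_probes": len(snap.probe_instances)})
    import pandas as pd

    idx = pd.DataFrame(index_rows, columns=["frame_id", "n_features", "n_probes"])
    idx["mean_rmsd_to_others"] = round(mean_rmsd, 6)
    _write_tsv(idx, out / "pm_index.tsv")

    return PipelineResult(
        OK, out, f"{len(frames)} co-occurrence snapshots",
        n_sites=len(sites), n_top_interactions=len(top),
        cooccurrence_frames=frames, mean_conformer_rmsd=mean_rmsd,
    )
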
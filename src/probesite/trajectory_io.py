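"""Reading structures and trajectories, superposition, probe bookkeeping.

Druggability-MD systems contain the target protein, many copies of small
probe molecules, water and ions.  This module loads the reference structure
and the trajectory (PSF/DCD or multi-model PDB, via MDAnalysis), partitions
atoms into protein and probe instances (water/ions are dropped), and
superposes every frame onto the reference using Cα atoms, so that all
downstream grid and distance analyses live in one common frame.

Distances everywhere downstream use heavy (non-hydrogen) atoms; hydrogens
are retained in storage but flagged out via ``heavy_mask``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .probes import ProbeSpec, resname_map

logger = logging.getLogger(__name__)

#: Residue names dropped from analysis (solvent and common counter-ions).
SOLVENT_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP3", "TIP", "SPC", "SOL", "SOD", "CLA", "NA", "CL",
     "K", "POT", "MG", "CAL", "ZN", "NA+", "CL-"}
)

#: Standard amino-acid residue names (protein partition).
PROTEIN_RESNAMES = frozenset(
    {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
     "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
     "TRP", "TYR", "VAL"}
)


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


@dataclass(frozen=True)
class ResidueKey:
    """Residue identity: chain, residue number and insertion code."""

    chain: str
    resnum: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}:{self.resnum}{self.icode}"


@dataclass
class ReferenceStructure:
    """The reference protein structure defining the common coordinate frame."""

    atom_names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resnums: np.ndarray
    icodes: np.ndarray
    chains: np.ndarray
    coords: np.ndarray  # (n_atoms, 3) Å
    calpha_indices: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def residue_key(self, i: int) -> ResidueKey:
        return ResidueKey(str(self.chains[i]), int(self.resnums[i]), str(self.icodes[i]))

    def atom_indices_of_residue(self, key: ResidueKey, heavy_only: bool = True) -> np.ndarray:
        sel = (
            (self.chains == key.chain)
            & (self.resnums == key.resnum)
            & (self.icodes == key.icode)
        )
        if heavy_only:
            sel &= self.heavy_mask
        return np.nonzero(sel)[0]


@dataclass(frozen=True)
class ProbeInstance:
    """One copy of a probe molecule in the system."""

    instance_id: str
    probe_name: str
    atom_indices: np.ndarray  # all atoms of the copy
    heavy_indices: np.ndarray  # heavy-atom subset

    def __repr__(self) -> str:  # numpy arrays make the default repr noisy
        return f"ProbeInstance({self.instance_id}, {len(self.atom_indices)} atoms)"


@dataclass
class TrajectoryEnsemble:
    """All frames of a (protein + probes) trajectory, water/ions excluded."""

    atom_names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resnums: np.ndarray
    icodes: np.ndarray
    chains: np.ndarray
    coords: np.ndarray  # (n_frames, n_atoms, 3) Å
    protein_indices: np.ndarray
    probe_instances: list[ProbeInstance]
    frame_interval_ps: float = 4.0
    superposed: bool = False

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    @property
    def protein_heavy_indices(self) -> np.ndarray:
        return self.protein_indices[self.elements[self.protein_indices] != "H"]

    def instances_of(self, probe_name: str) -> list[ProbeInstance]:
        return [p for p in self.probe_instances if p.probe_name == probe_name]

    def protein_residue_keys(self, chain: str | None = None) -> list[ResidueKey]:
        """Ordered unique residue keys of the protein partition."""
        seen: dict[ResidueKey, None] = {}
        for i in self.protein_indices:
            key = ResidueKey(str(self.chains[i]), int(self.resnums[i]), str(self.icodes[i]))
            if chain is None or key.chain == chain:
                seen.setdefault(key, None)
        return list(seen)

    def residue_heavy_indices(self, key: ResidueKey) -> np.ndarray:
        sel = (
            (self.chains == key.chain)
            & (self.resnums == key.resnum)
            & (self.icodes == key.icode)
            & self.heavy_mask
        )
        sel_idx = np.nonzero(sel)[0]
        return sel_idx[np.isin(sel_idx, self.protein_indices)]


def _atoms_from_universe(u):
    """Pull parallel metadata arrays out of an MDAnalysis Universe."""
    atoms = u.atoms
    names = atoms.names.astype(str)
    if hasattr(atoms, "elements") and all(e.strip() for e in atoms.elements):
        elements = np.array([e.strip().capitalize().upper() if len(e.strip()) == 1
                             else e.strip()[0].upper() + e.strip()[1:].lower()
                             for e in atoms.elements])
        elements = np.array([e.upper() if len(e) == 1 else e for e in elements])
    else:
        elements = np.array([_element_from_name(n) for n in names])
    # normalise: single letter upper-case for the common organic set
    elements = np.array([e[0].upper() if e[0].upper() in "HCNOSP" else e for e in elements])
    resnames = atoms.resnames.astype(str)
    resnums = atoms.resids.astype(int)
    icodes = (atoms.icodes.astype(str) if hasattr(atoms, "icodes")
              else np.full(len(atoms), "", dtype=object))
    icodes = np.array([c.strip() for c in icodes], dtype=object)
    if hasattr(atoms, "chainIDs"):
        chains = np.array([c.strip() for c in atoms.chainIDs.astype(str)], dtype=object)
    else:
        chains = np.array([s.strip() for s in atoms.segids.astype(str)], dtype=object)
    return names, elements, resnames, resnums, icodes, chains


def _dedupe_altlocs(u):
    """Keep the first altloc of each (chain, resnum, icode, name); error on true duplicates."""
    atoms = u.atoms
    names, _, _, resnums, icodes, chains = _atoms_from_universe(u)
    altlocs = (atoms.altLocs.astype(str) if hasattr(atoms, "altLocs")
               else np.full(len(atoms), "", dtype=object))
    keep = []
    seen: dict[tuple, str] = {}
    for i in range(len(atoms)):
        key = (chains[i], int(resnums[i]), icodes[i], names[i])
        alt = altlocs[i].strip()
        if key in seen:
            if alt and alt != seen[key]:
                continue  # later altloc of an already-kept atom
            raise ValueError(
                f"duplicate atom record: chain {key[0]!r} residue {key[1]}{key[2]} "
                f"atom {key[3]!r}"
            )
        seen[key] = alt
        keep.append(i)
    return np.array(keep, dtype=int)


def load_reference(path) -> ReferenceStructure:
    """Load a reference protein structure from a PDB file.

    Chain IDs and residue numbers are preserved verbatim (no renumbering);
    residue numbering in all outputs refers to the numbering in this file.
    """
    import MDAnalysis as mda

    try:
        u = mda.Universe(str(path))
    except (OSError, ValueError, IndexError) as exc:
        raise ValueError(f"cannot read reference PDB {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise ValueError(f"reference PDB {path} contains no ATOM records")
    keep = _dedupe_altlocs(u)
    names, elements, resnames, resnums, icodes, chains = _atoms_from_universe(u)
    coords = u.atoms.positions.astype(float)
    names, elements, resnames = names[keep], elements[keep], resnames[keep]
    resnums, icodes, chains, coords = resnums[keep], icodes[keep], chains[keep], coords[keep]
    if not np.all(np.isfinite(coords)):
        raise ValueError(f"reference PDB {path} has non-finite coordinates")
    calpha = np.nonzero((names == "CA") & (elements == "C"))[0]
    if len(calpha) == 0:
        raise ValueError(f"reference PDB {path} contains no Cα atoms")
    return ReferenceStructure(
        atom_names=names, elements=elements, resnames=resnames,
        resnums=resnums, icodes=icodes, chains=chains,
        coords=coords, calpha_indices=calpha,
    )


def load_trajectory(
    topology,
    coords=None,
    probe_specs: Mapping[str, ProbeSpec] | Sequence[ProbeSpec] | None = None,
    stride: int = 1,
    frame_interval_ps: float = 4.0,
) -> TrajectoryEnsemble:
    """Load a trajectory (PSF/PDB topology + DCD, or multi-model PDB).

    Atoms are partitioned into protein (standard amino acids) and probe
    instances (matched by topology residue name against ``probe_specs``,
    default: the built-in probe library).  Water and ions are excluded.
    Unrecognised residue names raise an error listing them.
    """
    import MDAnalysis as mda

    rmap = resname_map(probe_specs)
    if coords is None:
        u = mda.Universe(str(topology))
    else:
        try:
            u = mda.Universe(str(topology), str(coords))
        except (OSError, ValueError, IOError) as exc:
            raise ValueError(
                f"cannot combine topology {topology} with trajectory {coords}: {exc}"
            ) from exc
    names, elements, resnames, resnums, icodes, chains = _atoms_from_universe(u)

    protein_mask = np.isin(resnames, sorted(PROTEIN_RESNAMES))
    solvent_mask = np.isin(resnames, sorted(SOLVENT_RESNAMES))
    probe_mask = np.isin(resnames, sorted(rmap))
    unknown = sorted(set(resnames[~(protein_mask | solvent_mask | probe_mask)]))
    if unknown:
        raise ValueError(
            f"unrecognised residue names (not protein, solvent/ion, or a known "
            f"probe): {unknown}"
        )

    keep = np.nonzero(protein_mask | probe_mask)[0]
    n_keep = len(keep)

    frames = []
    for ts in u.trajectory[::stride]:
        frames.append(u.atoms.positions[keep].astype(float).copy())
    all_coords = np.stack(frames, axis=0)

    names, elements, resnames = names[keep], elements[keep], resnames[keep]
    resnums, icodes, chains = resnums[keep], icodes[keep], chains[keep]
    protein_indices = np.nonzero(np.isin(resnames, sorted(PROTEIN_RESNAMES)))[0]

    # enumerate probe instances by (residue name, residue id)
    probe_instances: list[ProbeInstance] = []
    probe_sel = np.nonzero(np.isin(resnames, sorted(rmap)))[0]
    if len(probe_sel):
        keys = [
            (resnames[i], chains[i], int(resnums[i]), icodes[i]) for i in probe_sel
        ]
        seen: dict[tuple, list[int]] = {}
        for i, key in zip(probe_sel, keys):
            seen.setdefault(key, []).append(int(i))
        for (resname, chain, resnum, icode), idx in seen.items():
            spec = rmap[resname]
            idx_arr = np.array(sorted(idx), dtype=int)
            heavy = idx_arr[elements[idx_arr] != "H"]
            probe_instances.append(
                ProbeInstance(
                    instance_id=f"{spec.probe_name}:{chain}:{resnum}{icode}",
                    probe_name=spec.probe_name,
                    atom_indices=idx_arr,
                    heavy_indices=heavy,
                )
            )
    logger.info(
        "loaded trajectory: %d frames, %d atoms kept (%d protein, %d probe copies)",
        all_coords.shape[0], n_keep, len(protein_indices), len(probe_instances),
    )
    return TrajectoryEnsemble(
        atom_names=names, elements=elements, resnames=resnames,
        resnums=resnums, icodes=icodes, chains=chains,
        coords=all_coords, protein_indices=protein_indices,
        probe_instances=probe_instances,
        frame_interval_ps=frame_interval_ps * stride,
    )


def ensemble_from_arrays(
    atom_names, elements, resnames, resnums, chains, coords,
    probe_specs=None, icodes=None, frame_interval_ps: float = 4.0,
) -> TrajectoryEnsemble:
    """Build a TrajectoryEnsemble directly from arrays (scripting/testing API).

    ``coords`` has shape (n_frames, n_atoms, 3).  Probe copies are detected
    by residue name exactly as in :func:`load_trajectory`.
    """
    atom_names = np.asarray(atom_names, dtype=object)
    elements = np.asarray(elements, dtype=object)
    resnames = np.asarray(resnames, dtype=object)
    resnums = np.asarray(resnums, dtype=int)
    chains = np.asarray(chains, dtype=object)
    if icodes is None:
        icodes = np.full(len(atom_names), "", dtype=object)
    coords = np.asarray(coords, dtype=float)
    rmap = resname_map(probe_specs)
    protein_indices = np.nonzero(np.isin(resnames, sorted(PROTEIN_RESNAMES)))[0]
    probe_instances = []
    probe_sel = np.nonzero(np.isin(resnames, sorted(rmap)))[0]
    seen: dict[tuple, list[int]] = {}
    for i in probe_sel:
        key = (resnames[i], chains[i], int(resnums[i]), icodes[i])
        seen.setdefault(key, []).append(int(i))
    for (resname, chain, resnum, icode), idx in seen.items():
        spec = rmap[resname]
        idx_arr = np.array(sorted(idx), dtype=int)
        heavy = idx_arr[elements[idx_arr] != "H"]
        probe_instances.append(
            ProbeInstance(
                instance_id=f"{spec.probe_name}:{chain}:{resnum}{icode}",
                probe_name=spec.probe_name,
                atom_indices=idx_arr,
                heavy_indices=heavy,
            )
        )
    return TrajectoryEnsemble(
        atom_names=atom_names, elements=elements, resnames=resnames,
        resnums=resnums, icodes=icodes, chains=chains, coords=coords,
        protein_indices=protein_indices, probe_instances=probe_instances,
        frame_interval_ps=frame_interval_ps,
    )


def _calpha_map(ensemble: TrajectoryEnsemble) -> dict[ResidueKey, int]:
    out = {}
    for i in ensemble.protein_indices:
        if ensemble.atom_names[i] == "CA" and ensemble.elements[i] == "C":
            out[ResidueKey(str(ensemble.chains[i]), int(ensemble.resnums[i]),
                           str(ensemble.icodes[i]))] = int(i)
    return out


def superpose(ensemble: TrajectoryEnsemble, reference: ReferenceStructure) -> TrajectoryEnsemble:
    """Superpose every frame onto the reference by least-squares Cα fit.

    The optimal rigid transform (Kabsch) is computed on the Cα atoms matched
    by (chain, residue number, insertion code) and applied to *all* atoms of
    the frame, probes included.  Returns a new ensemble with
    ``superposed=True``; idempotent up to numerical precision.
    """
    ens_ca = _calpha_map(ensemble)
    ref_keys = [reference.residue_key(int(i)) for i in reference.calpha_indices]
    missing = [str(k) for k in ref_keys if k not in ens_ca]
    if missing:
        raise ValueError(
            f"Cα mapping incomplete: reference residues missing from "
            f"trajectory: {missing}"
        )
    ref_xyz = reference.coords[reference.calpha_indices]
    mob_idx = np.array([ens_ca[k] for k in ref_keys], dtype=int)

    new_coords = np.empty_like(ensemble.coords)
    ref_centroid = ref_xyz.mean(axis=0)
    ref_centered = ref_xyz - ref_centroid
    for f in range(ensemble.n_frames):
        mob = ensemble.coords[f, mob_idx]
        mob_centroid = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, mob - mob_centroid)
        new_coords[f] = rot.apply(ensemble.coords[f] - mob_centroid) + ref_centroid
    out = replace(ensemble, coords=new_coords, superposed=True)
    return out


# ---------------------------------------------------------------------------
# PDB writing (shared by hot-spot and snapshot exporters)

def format_pdb_atom(serial, name, resname, chain, resnum, xyz, *, icode="",
                    occupancy=1.0, bfactor=0.0, element="", record="ATOM") -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    if not element:
        element = _element_from_name(name)
    # resName occupies columns 18-21 (4-char residue names, CHARMM convention)
    return (
        f"{record:<6s}{serial:>5d} {name_field}{'':1s}{resname:<4s}"
        f"{chain[:1] if chain else ' ':1s}{resnum:>4d}{icode[:1] if icode else ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}{bfactor:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(path, names, resnames, chains, resnums, coords, *, icodes=None,
              elements=None, bfactors=None, record="ATOM") -> None:
    """Write a single-model PDB file (fixed-format, 3-decimal coordinates)."""
    n = len(names)
    icodes = icodes if icodes is not None else [""] * n
    elements = elements if elements is not None else ["" for _ in range(n)]
    bfactors = bfactors if bfactors is not None else np.zeros(n)
    lines = []
    for i in range(n):
        lines.append(
            format_pdb_atom(
                i + 1, str(names[i]), str(resnames[i]), str(chains[i]),
                int(resnums[i]), np.asarray(coords[i], dtype=float),
                icode=str(icodes[i]), bfactor=float(bfactors[i]),
                element=str(elements[i]), record=record,
            )
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
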
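"""Shared helpers for the test suite: micro-ensembles with exact geometry."""

from __future__ import annotations

import numpy as np

from probesite.probes import FeatureTemplate, ProbeSpec
from probesite.trajectory_io import (
    ReferenceStructure,
    TrajectoryEnsemble,
    ensemble_from_arrays,
)


def point_spec() -> ProbeSpec:
    """A one-heavy-atom probe for distance-controlled tests."""
    return ProbeSpec("point", "PNT", ("C1",),
                     (FeatureTemplate("hydrophobic", ("C1",)),))


def hydrogenated_spec() -> ProbeSpec:
    """A probe with one heavy atom and one hydrogen (asymmetry tests)."""
    return ProbeSpec("hprobe", "HPR", ("C1",),
                     (FeatureTemplate("hydrophobic", ("C1",)),))


def micro_ensemble(residues, probes, n_frames=1, superposed=True) -> TrajectoryEnsemble:
    """Build a tiny ensemble with single-CA residues and explicit probes.

    residues: list of (chain, resnum, xyz) — one Cα (carbon) atom each.
    probes: list of dicts with keys spec, coords ((n_frames, n_atoms, 3) or
            (n_atoms, 3), tiled), optional names / elements / resnum.
    """
    names, elements, resnames, resnums, chains = [], [], [], [], []
    frames = []
    for chain, resnum, xyz in residues:
        names.append("CA")
        elements.append("C")
        resnames.append("ALA")
        resnums.append(resnum)
        chains.append(chain)
        frames.append(np.tile(np.asarray(xyz, float), (n_frames, 1, 1))[:, 0, :][:, None, :])
    specs = []
    for k, p in enumerate(probes):
        spec = p["spec"]
        specs.append(spec)
        anames = p.get("names", list(spec.heavy_atom_names))
        elems = p.get("elements", [n[0] for n in anames])
        coords = np.asarray(p["coords"], float)
        if coords.ndim == 2:
            coords = np.tile(coords, (n_frames, 1, 1))
        assert coords.shape == (n_frames, len(anames), 3)
        names.extend(anames)
        elements.extend(elems)
        resnames.extend([spec.topology_residue_name] * len(anames))
        resnums.extend([p.get("resnum", 900 + k)] * len(anames))
        chains.extend(["P"] * len(anames))
        frames.append(coords)
    coords = np.concatenate(frames, axis=1)
    uniq = {s.probe_name: s for s in specs}
    ens = ensemble_from_arrays(names, elements, resnames, resnums, chains,
                               coords, probe_specs=list(uniq.values()))
    ens.superposed = superposed
    return ens


def reference_from_ensemble(ens: TrajectoryEnsemble, coords=None) -> ReferenceStructure:
    prot = ens.protein_indices
    sub = lambda a: a[prot]
    ref_coords = ens.coords[0, prot] if coords is None else np.asarray(coords, float)
    calpha = np.nonzero(sub(ens.atom_names) == "CA")[0]
    return ReferenceStructure(
        atom_names=sub(ens.atom_names), elements=sub(ens.elements),
        resnames=sub(ens.resnames), resnums=sub(ens.resnums),
        icodes=sub(ens.icodes), chains=sub(ens.chains),
        coords=ref_coords.copy(), calpha_indices=calpha,
    )


def horn_align(ref: np.ndarray, mob: np.ndarray, apply_to=None) -> np.ndarray:
    """Closed-form optimal superposition via Horn's quaternion method.

    Independent oracle for Kabsch-style fits: builds the 4×4 key matrix from
    the covariance of centered coordinates and rotates by the quaternion of
    its largest eigenvalue.
    """
    rc, mc = ref.mean(axis=0), mob.mean(axis=0)
    P, Q = mob - mc, ref - rc
    S = P.T @ Q
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    N = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    target = mob if apply_to is None else apply_to
    return (target - mc) @ R.T + rc
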
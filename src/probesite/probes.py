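"""Probe chemotype definitions.

A druggability simulation surrounds the target protein with small
drug-fragment-like probe molecules.  Each probe chemotype is described by a
:class:`ProbeSpec`: the residue name it carries in the simulation topology,
its heavy atoms, and the pharmacophore feature templates it contributes when
a bound copy is turned into a pharmacophore feature.

The six standard probes (isopropanol, acetamide, imidazole, acetate,
isopropylamine, isobutane) ship as built-ins; user-defined probes are added
by constructing additional :class:`ProbeSpec` objects or loading them from a
YAML mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

#: Closed vocabulary of pharmacophore feature kinds.
FEATURE_KINDS = frozenset(
    {
        "hbond_donor",
        "hbond_acceptor",
        "hydrophobic",
        "aromatic",
        "negative_ion",
        "positive_ion",
    }
)


@dataclass(frozen=True)
class FeatureTemplate:
    """One pharmacophore feature contributed by a probe chemotype.

    ``anchor_atoms`` names one heavy atom (feature sits on that atom) or
    several (feature sits on their centroid).
    """

    kind: str
    anchor_atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(
                f"unknown feature kind {self.kind!r}; "
                f"expected one of {sorted(FEATURE_KINDS)}"
            )
        if not self.anchor_atoms:
            raise ValueError("feature template needs at least one anchor atom")


@dataclass(frozen=True)
class ProbeSpec:
    """A probe chemotype: topology naming plus feature templates."""

    probe_name: str
    topology_residue_name: str
    heavy_atom_names: tuple[str, ...]
    feature_templates: tuple[FeatureTemplate, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.heavy_atom_names:
            raise ValueError(f"probe {self.probe_name!r} has no heavy atoms")
        heavy = set(self.heavy_atom_names)
        for tmpl in self.feature_templates:
            missing = set(tmpl.anchor_atoms) - heavy
            if missing:
                raise ValueError(
                    f"probe {self.probe_name!r}: feature anchor atoms "
                    f"{sorted(missing)} are not heavy atoms of the probe"
                )


def _spec(name, resname, heavy, templates):
    return ProbeSpec(
        probe_name=name,
        topology_residue_name=resname,
        heavy_atom_names=tuple(heavy),
        feature_templates=tuple(FeatureTemplate(k, tuple(a)) for k, a in templates),
    )


#: Built-in probe library keyed by probe name.  Residue names follow the
#: CGenFF-style conventions used in druggability simulation topologies.
BUILTIN_PROBES: dict[str, ProbeSpec] = {
    p.probe_name: p
    for p in [
        _spec(
            "isopropanol",
            "IPRO",
            ["C1", "C2", "C3", "O1"],
            [
                ("hbond_donor", ["O1"]),
                ("hydrophobic", ["C1", "C2", "C3"]),
            ],
        ),
        _spec(
            "acetamide",
            "ACAM",
            ["C1", "C2", "O1", "N1"],
            [
                ("hbond_donor", ["N1"]),
                ("hbond_acceptor", ["O1"]),
            ],
        ),
        _spec(
            "imidazole",
            "IMID",
            ["N1", "C2", "N3", "C4", "C5"],
            [
                ("aromatic", ["N1", "C2", "N3", "C4", "C5"]),
                ("hbond_donor", ["N1"]),
                ("hbond_acceptor", ["N3"]),
            ],
        ),
        _spec(
            "acetate",
            "ACET",
            ["C1", "C2", "O1", "O2"],
            [
                ("negative_ion", ["C2", "O1", "O2"]),
                ("hbond_acceptor", ["O1"]),
                ("hbond_acceptor", ["O2"]),
            ],
        ),
        _spec(
            "isopropylamine",
            "IPAM",
            ["C1", "C2", "C3", "N1"],
            [
                ("positive_ion", ["N1"]),
                ("hbond_donor", ["N1"]),
            ],
        ),
        _spec(
            "isobutane",
            "IBUT",
            ["C1", "C2", "C3", "C4"],
            [
                ("hydrophobic", ["C1", "C2", "C3", "C4"]),
            ],
        ),
    ]
}


def resname_map(specs: Sequence[ProbeSpec] | Mapping[str, ProbeSpec] | None = None) -> dict[str, ProbeSpec]:
    """Map topology residue name -> ProbeSpec for the given specs (default: built-ins)."""
    if specs is None:
        specs = BUILTIN_PROBES
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    return {s.topology_residue_name: s for s in specs}


def load_probe_specs(path) -> dict[str, ProbeSpec]:
    """Load user-defined probe specs from a YAML file.

    Expected layout::

        isoamylalcohol:
          residue_name: IAMO
          heavy_atoms: [C1, C2, C3, C4, O1]
          features:
            - {kind: hbond_donor, anchors: [O1]}
            - {kind: hydrophobic, anchors: [C1, C2, C3, C4]}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    specs = {}
    for name, entry in raw.items():
        templates = [
            (f["kind"], list(f["anchors"])) for f in entry.get("features", [])
        ]
        specs[name] = _spec(
            name, entry["residue_name"], list(entry["heavy_atoms"]), templates
        )
    return specs
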
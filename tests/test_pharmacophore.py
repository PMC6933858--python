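"""Co-occurrence frames, conformer RMSD, snapshots and Pharmit export."""

import itertools
import json
import math

import numpy as np
import pytest
from _util import micro_ensemble, point_spec

from probesite.hotspot_grid import DruggableSite, HotSpot
from probesite.interaction_ranking import InteractionRecord
from probesite.pharmacophore import (
    Snapshot,
    build_pharmacophore,
    conformer_rmsd,
    extract_snapshot,
    find_cooccurrence_frames,
    pec50_from_ec50,
    read_pharmit_json,
    write_pharmit_json,
)
from probesite.probes import BUILTIN_PROBES
from probesite.synthetic_fixtures import PROBE_TEMPLATES
from probesite.trajectory_io import ResidueKey, load_reference


def _rec(frames, resnum=1, probe="point", n=10, best=None):
    return InteractionRecord(
        residue=ResidueKey("A", resnum), resname="ALA", probe_name=probe,
        qualifying_frames=frozenset(frames), n_frames=n,
        contributing_hotspot_ids=(),
        best_instance_by_frame=best or {},
    )


class TestFindCooccurrenceFrames:
    def test_single_record_returns_its_frames(self):
        assert find_cooccurrence_frames([_rec({4, 1, 7})]) == [1, 4, 7]

    def test_intersection_of_two(self):
        assert find_cooccurrence_frames(
            [_rec({1, 3, 7}), _rec({3, 7, 9}, resnum=2)]) == [3, 7]

    def test_empty_top_set_errors(self):
        with pytest.raises(ValueError, match="cutoff"):
            find_cooccurrence_frames([])

    def test_empty_intersection_warns(self):
        with pytest.warns(UserWarning, match="no frame"):
            out = find_cooccurrence_frames([_rec({1}), _rec({2}, resnum=2)])
        assert out == []

    def test_planted_thirteen_frame_intersection(self, rng):
        # 12 records engineered so exactly 13 frames satisfy every one
        n = 200
        common = set(rng.choice(n, 13, replace=False).tolist())
        records = []
        for i in range(12):
            extra = set(rng.choice(n, 30, replace=False).tolist()) - common
            records.append(_rec(common | extra, resnum=i + 1, n=n))
        out = find_cooccurrence_frames(records)
        assert len(out) == 13
        assert set(out) == common
        for r in records:
            assert set(out) <= set(r.qualifying_frames)


class TestConformerRmsd:
    def _ens(self, coords):
        residues = [("A", i + 1, (0, 0, 0)) for i in range(coords.shape[1])]
        ens = micro_ensemble(residues, [], n_frames=coords.shape[0])
        ens.coords = coords.copy()
        return ens

    def test_identical_frames_zero(self):
        base = np.random.default_rng(0).uniform(0, 5, (1, 4, 3))
        ens = self._ens(np.repeat(base, 3, axis=0))
        assert conformer_rmsd(ens, [0, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_shift_gives_exact_rmsd(self):
        base = np.random.default_rng(0).uniform(0, 5, (4, 3))
        coords = np.stack([base, base + np.array([1.0, 0, 0])])
        ens = self._ens(coords)
        assert conformer_rmsd(ens, [0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.uniform(0, 10, (5, 6, 3))
        ens = self._ens(coords)
        got = conformer_rmsd(ens, list(range(5)))
        total, n = 0.0, 0
        for a, b in itertools.combinations(range(5), 2):
            sq = [math.dist(coords[a, i], coords[b, i]) ** 2 for i in range(6)]
            total += math.sqrt(sum(sq) / 6)
            n += 1
        assert got == pytest.approx(total / n, rel=1e-9)

    def test_fewer_than_two_frames_errors(self):
        ens = self._ens(np.zeros((3, 4, 3)))
        with pytest.raises(ValueError):
            conformer_rmsd(ens, [0])


def _snapshot_with(*probe_names):
    instances = []
    for i, name in enumerate(probe_names):
        anames, tmpl = PROBE_TEMPLATES[name]
        instances.append({
            "instance_id": f"{name}:P:{900 + i}",
            "probe_name": name,
            "atom_names": list(anames),
            "elements": [n[0] for n in anames],
            "coords": tmpl + np.array([10.0 * i, 0.0, 0.0]),
        })
    return Snapshot(frame_id=761, protein_path=None, probes_path=None,
                    probe_instances=instances)


class TestBuildPharmacophore:
    def test_isobutane_gives_one_hydrophobic_at_centroid(self):
        model = build_pharmacophore(_snapshot_with("isobutane"))
        assert [f.feature_kind for f in model.features] == ["hydrophobic"]
        anames, tmpl = PROBE_TEMPLATES["isobutane"]
        np.testing.assert_allclose(model.features[0].center, tmpl.mean(axis=0),
                                   atol=1e-9)

    def test_acetamide_donor_and_acceptor_on_named_atoms(self):
        model = build_pharmacophore(_snapshot_with("acetamide"))
        kinds = sorted(f.feature_kind for f in model.features)
        assert kinds == ["hbond_acceptor", "hbond_donor"]
        anames, tmpl = PROBE_TEMPLATES["acetamide"]
        pos = dict(zip(anames, tmpl))
        by_kind = {f.feature_kind: f.center for f in model.features}
        np.testing.assert_allclose(by_kind["hbond_donor"], pos["N1"], atol=1e-9)
        np.testing.assert_allclose(by_kind["hbond_acceptor"], pos["O1"], atol=1e-9)

    def test_reference_snapshot_composition(self):
        # one isobutane + one acetamide + one isopropanol
        model = build_pharmacophore(
            _snapshot_with("isobutane", "acetamide", "isopropanol"))
        counts = {}
        for f in model.features:
            counts[f.feature_kind] = counts.get(f.feature_kind, 0) + 1
        assert counts == {"hydrophobic": 2, "hbond_donor": 2, "hbond_acceptor": 1}
        assert all(f.radius == 1.0 for f in model.features)

    def test_feature_selection_filters(self):
        model = build_pharmacophore(
            _snapshot_with("isobutane", "acetamide", "isopropanol"),
            feature_selection={"hydrophobic"})
        assert {f.feature_kind for f in model.features} == {"hydrophobic"}
        assert len(model.features) == 2

    def test_empty_snapshot_errors(self):
        snap = Snapshot(frame_id=0, protein_path=None, probes_path=None,
                        probe_instances=[])
        with pytest.raises(ValueError, match="no probes"):
            build_pharmacophore(snap)

    def test_geometric_consistency(self):
        model = build_pharmacophore(
            _snapshot_with("acetamide", "isobutane", "imidazole"))
        for f in model.features:
            inst = next(i for i in _snapshot_with("acetamide", "isobutane",
                                                  "imidazole").probe_instances
                        if i["instance_id"] == f.provenance["instance_id"])
            pos = np.asarray(inst["coords"])
            if f.feature_kind in ("hbond_donor", "hbond_acceptor"):
                assert np.min(np.linalg.norm(pos - f.center, axis=1)) <= 1e-6
            else:  # centroid features lie inside the anchor bounding box
                anchors = np.array([pos[inst["atom_names"].index(a)]
                                    for a in f.provenance["anchor_atoms"]])
                assert np.all(f.center >= anchors.min(axis=0) - 1e-9)
                assert np.all(f.center <= anchors.max(axis=0) + 1e-9)


class TestPharmitJson:
    def test_round_trip_identity(self, tmp_path):
        model = build_pharmacophore(
            _snapshot_with("isobutane", "acetamide", "isopropanol"))
        path = tmp_path / "pm.json"
        doc = write_pharmit_json(model, path)
        back = read_pharmit_json(path)
        assert len(back.features) == len(model.features) == 5
        for a, b in zip(model.features, back.features):
            assert a.feature_kind == b.feature_kind
            assert a.radius == b.radius
            assert a.enabled == b.enabled
            np.testing.assert_array_equal(a.center, b.center)

    def test_point_schema(self):
        doc = json.loads(write_pharmit_json(build_pharmacophore(
            _snapshot_with("acetate", "isopropylamine", "imidazole"))))
        names = {p["name"] for p in doc["points"]}
        assert names <= {"Hydrophobic", "HydrogenDonor", "HydrogenAcceptor",
                         "Aromatic", "NegativeIon", "PositiveIon"}
        assert all(p["radius"] == 1.0 and p["enabled"] for p in doc["points"])

    def test_empty_model_errors(self):
        from probesite.pharmacophore import PharmacophoreModel

        with pytest.raises(ValueError):
            write_pharmit_json(PharmacophoreModel(frame_id=0, features=[]))

    def test_unmappable_kind_errors(self):
        from probesite.pharmacophore import PharmacophoreFeature, PharmacophoreModel

        feat = PharmacophoreFeature.__new__(PharmacophoreFeature)
        feat.feature_kind = "exotic"
        feat.center = np.zeros(3)
        feat.radius = 1.0
        feat.enabled = True
        feat.provenance = {}
        with pytest.raises(ValueError, match="exotic"):
            write_pharmit_json(PharmacophoreModel(frame_id=0, features=[feat]))


class TestExtractSnapshot:
    def _pipeline_bits(self):
        site = DruggableSite(
            "site-1",
            [HotSpot("point-1", "point", np.array([2.0, 0.0, 1.0]), 10, -2.0)],
            -6.0, 1)
        ens = micro_ensemble(
            [("A", 1, (0, 0, 0)), ("A", 2, (0, 30, 0)), ("A", 3, (30, 0, 0)),
             ("A", 4, (0, 0, 30))],
            [{"spec": point_spec(), "coords": [[2.0, 0, 0]], "resnum": 901},
             {"spec": point_spec(), "coords": [[90, 90, 90]], "resnum": 902}],
            n_frames=2,
        )
        rec = _rec({0, 1}, best={0: "point:P:901", 1: "point:P:901"})
        return ens, site, [rec]

    def test_protein_and_probe_files(self, tmp_path):
        ens, site, top = self._pipeline_bits()
        snap = extract_snapshot(ens, 0, site, top, tmp_path)
        ref = load_reference(snap.protein_path)
        assert ref.n_atoms == len(ens.protein_indices)
        np.testing.assert_allclose(ref.coords,
                                   ens.coords[0, ens.protein_indices], atol=1e-3)
        assert len(snap.probe_instances) == 1
        assert snap.probe_instances[0]["instance_id"] == "point:P:901"
        assert snap.probes_path.exists()

    def test_invalid_frame_errors(self, tmp_path):
        ens, site, top = self._pipeline_bits()
        with pytest.raises(ValueError):
            extract_snapshot(ens, 99, site, top, tmp_path)


class TestPec50:
    def test_two_nanomolar(self):
        val = pec50_from_ec50(2.0e-9)
        assert val == pytest.approx(9 - math.log10(2), abs=1e-12)
        assert abs(val - 8.700) < 2e-3  # printed as 8.700 at 3 decimals

    def test_molar_is_zero(self):
        assert pec50_from_ec50(1.0) == 0.0

    def test_micromolar(self):
        assert pec50_from_ec50(1.0e-6) == pytest.approx(6.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1e-9])
    def test_nonpositive_errors(self, bad):
        with pytest.raises(ValueError):
            pec50_from_ec50(bad)
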
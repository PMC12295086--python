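import warnings

import numpy as np
import pandas as pd
import pytest

from glycomap import glycan_topology as gt
from glycomap import subsite_mapping as sm
from glycomap.structure_io import (
    AtomRecord,
    ResidueRecord,
    StructureModel,
    classify_residues,
)
from glycomap.synthetic_data import (
    ComplexSpec,
    GlycanSpec,
    make_complex,
    make_glycan,
    make_scaffold,
    make_sugar,
    tune_end_to_end,
)


def _ring_pair_model(separation):
    a = make_sugar("Man", seq_num=1, chain_id="B")
    b = make_sugar("Man", seq_num=2, chain_id="C")
    for atom in b.atoms:
        atom.position = atom.position + np.array([separation, 0.0, 0.0])
    return classify_residues(StructureModel(id="PAIR", residues=[a, b]))


def _composite_of(model, source="SRC"):
    obs = sm._sugar_observations(model, source)
    return sm.Composite(reference_id="REF", model=model, observations=obs)


class TestTransfer:
    def test_reference_identity_transfer(self, scaffold, planted):
        models, _ = planted
        one = models[0]
        composite = sm.transfer_ligands([one], one)
        for obs in composite.observations:
            orig = one.find(obs.ring.residue.chain_id, obs.ring.residue.seq_num)
            orig_ring = np.array([a.position for a in orig.atoms[:6]])
            assert np.allclose(orig_ring, obs.ring.coords, atol=1e-9)

    def test_pairwise_geometry_preserved(self, scaffold, planted):
        models, _ = planted
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            composite = sm.transfer_ligands(models[:2], scaffold.model)
        by_source = {}
        for obs in composite.observations:
            by_source.setdefault(obs.source_id, []).append(obs.centroid)
        for source, cents in by_source.items():
            cents = np.array(cents)
            transferred = np.linalg.norm(cents[0] - cents[-1])
            # same distances as in the source model (rigid transfer)
            src = [m for m in models if m.id == source][0]
            rings = gt.detect_rings(src)
            orig = np.linalg.norm(rings[0].centroid - rings[-1].centroid)
            assert transferred == pytest.approx(orig, abs=1e-3)

    def test_unalignable_complex_skipped(self, scaffold, planted):
        models, _ = planted
        garbled = models[0].copy()
        garbled.id = "GARBLED"
        garbled.residues = [r for r in garbled.residues if r.category != "protein"]
        # no protein at all -> alignment error -> skipped with warning
        with pytest.warns(UserWarning, match="skipped"):
            composite = sm.transfer_ligands([garbled], scaffold.model)
        assert composite.skipped == ["GARBLED"]
        assert composite.observations == []


class TestClusterSubsites:
    def test_below_radius_merges(self):
        model = _ring_pair_model(0.5)
        subsites = sm.cluster_subsites(_composite_of(model))
        assert len(subsites) == 1
        assert subsites[0].member_count == 2

    def test_above_radius_splits(self):
        model = _ring_pair_model(6.0)
        subsites = sm.cluster_subsites(_composite_of(model))
        assert len(subsites) == 2

    def test_planted_nine_sites_recovered(self, subsite_map):
        smap, composite, truth = subsite_map
        assert len(smap.subsites) == 9
        assert all(s.member_count == 3 for s in smap.subsites)

    def test_provenance_tracked(self, subsite_map):
        smap, _, _ = subsite_map
        for s in smap.subsites:
            assert len(s.provenance) == s.member_count
            assert all(src.startswith("SOAK") for src, _ in s.provenance)


class TestAssignLabels:
    def test_planted_labels_match_truth(self, subsite_map):
        smap, _, truth = subsite_map
        labels = sorted((s.label for s in smap.subsites), reverse=True)
        assert labels == [3, 2, 1, -1, -2, -3, -4, -5, -6]
        for t in truth:
            for i, obs in enumerate(smap.observations):
                if obs.source_id == t["model_id"] and (
                    obs.ring.residue.chain_id,
                    obs.ring.residue.seq_num,
                ) == tuple(t["residue"]):
                    assert smap.assignments[i] == t["subsite_label"]

    def test_glcn_anchor_gets_plus_one(self, subsite_map):
        smap, _, _ = subsite_map
        plus_one = smap.subsite(1)
        comps = {res for _, res in plus_one.provenance}
        assert all(r.startswith("GCS") for r in comps)

    def test_chain_without_anchor_uses_dd_motif(self, scaffold):
        placements = [("GlcN", 2, 0.0), ("Man", 3, 0.0), ("Man", 4, 0.0), ("Man", 5, 0.0)]
        models, _ = make_complex(
            ComplexSpec(placements=placements, n_soaks=1, seed=2, scaffold=scaffold)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            composite = sm.transfer_ligands(models, scaffold.model)
        annotation = sm.ActiveSiteAnnotation.detect(scaffold.model)
        subsites = sm.cluster_subsites(composite)
        labelled = sm.assign_labels(subsites, scaffold.model, annotation)
        # GlcN planted over the DD motif -> +1; chain away -> -1, -2, -3
        assert sorted(s.label for s in labelled) == [-3, -2, -1, 1]

    def test_too_few_subsites(self, scaffold):
        annotation = sm.ActiveSiteAnnotation.detect(scaffold.model)
        with pytest.raises(ValueError, match="2 subsites"):
            sm.assign_labels([], scaffold.model, annotation)


class TestOccupancy:
    def test_rows_are_species_at_structure(self, subsite_map):
        smap, _, _ = subsite_map
        occ = sm.occupancy_matrix(smap)
        assert list(occ.columns) == [3, 2, 1, -1, -2, -3, -4, -5, -6]
        assert set(occ.values.ravel()) <= {0, 1}
        # each soak contributes a GlcN row with a single 1 at +1
        glcn_rows = occ.loc[[i for i in occ.index if i.startswith("GlcN@")]]
        assert (glcn_rows[1] == 1).all()
        assert glcn_rows.drop(columns=[1]).values.sum() == 0

    def test_empty_composite(self):
        smap = sm.SubsiteMap(
            reference_id="R", subsites=[], observations=[], assignments={}
        )
        occ = sm.occupancy_matrix(smap)
        assert occ.empty

    def test_invariant_under_complex_order(self, scaffold, planted):
        models, _ = planted
        annotation = sm.ActiveSiteAnnotation.detect(
            scaffold.model, wing_regions={"WR1": scaffold.wr1}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fwd = sm.build_subsite_map(
                sm.transfer_ligands(models, scaffold.model), scaffold.model, annotation
            )
            rev = sm.build_subsite_map(
                sm.transfer_ligands(models[::-1], scaffold.model), scaffold.model, annotation
            )
        a = sm.occupancy_matrix(fwd).sort_index()
        b = sm.occupancy_matrix(rev).sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestReassembly:
    def test_reassemble_path(self, subsite_map):
        smap, _, _ = subsite_map
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph, desc, model = sm.reassemble_glycan(smap, [1, -1, -2, -3])
        assert desc.n_residues == 4
        assert desc.end_to_end > 0
        assert len(model.residues) == 4

    def test_unoccupied_subsite_errors(self, subsite_map):
        smap, _, _ = subsite_map
        with pytest.raises(KeyError, match="no subsite"):
            sm.reassemble_glycan(smap, [1, 99])

    def test_path_of_two_is_undefined_shape(self, subsite_map):
        smap, _, _ = subsite_map
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, desc, _ = sm.reassemble_glycan(smap, [1, -1])
        assert desc.shape_class == "undefined"

    def test_planted_c_shape_distance(self, gpi_core_spec):
        # tune the synthetic GPI-core glycan to the C-shaped 11.3 Å span
        def end_to_end(model):
            rings = gt.detect_rings(model)
            graph = gt.build_glycan_graph(rings, gt.detect_linkages(rings, model))
            order = {r.residue.seq_num: r for r in rings}
            first, last = order[1], order[4]
            return float(
                np.linalg.norm(
                    first.ring_atom("C1").position - last.ring_atom("C4").position
                )
            )

        tuned, achieved = tune_end_to_end(gpi_core_spec, 11.3, end_to_end)
        assert achieved == pytest.approx(11.3, abs=0.1)
        model = make_glycan(tuned)
        rings = gt.detect_rings(model)
        desc = sm.shape_descriptor(rings[0], rings[-1], 4)
        assert desc.end_to_end == pytest.approx(11.3, abs=0.1)
        assert desc.shape_class == "C"


class TestShape:
    @pytest.mark.parametrize(
        "n,e2e,expected",
        [
            (5, 19.4, "linear"),  # 4.85 Å per residue
            (4, 11.3, "C"),  # 3.77 Å per residue
            (4, 7.0, "U"),  # 2.33 Å per residue
            (2, 5.0, "undefined"),
        ],
    )
    def test_thresholds(self, n, e2e, expected):
        assert sm.classify_shape(n, e2e) == expected

    def test_end_to_end_rigid_invariance(self, gpi_core_spec):
        model = make_glycan(gpi_core_spec)
        rings = gt.detect_rings(model)
        d1 = sm.shape_descriptor(rings[0], rings[-1], 4).end_to_end
        rng = np.random.default_rng(8)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        for res in model.residues:
            for atom in res.atoms:
                atom.position = rot @ atom.position + np.array([4.0, 5.0, -6.0])
        rings = gt.detect_rings(model)
        d2 = sm.shape_descriptor(rings[0], rings[-1], 4).end_to_end
        assert d2 == pytest.approx(d1, abs=1e-9)

    def test_bending_decreases_span(self):
        # straightened vs bent tetrasaccharide: psi bend reduces end-to-end
        base = GlycanSpec(
            residues=["Man"] * 4,
            linkages=[(1, 0, 6, "alpha"), (2, 1, 6, "alpha"), (3, 2, 6, "alpha")],
        )
        spans = []
        for psi in (60.0, 0.0, -60.0):
            spec = GlycanSpec(
                residues=base.residues,
                linkages=base.linkages,
                torsions=[(-100.0, psi)] * 3,
            )
            model = make_glycan(spec)
            rings = gt.detect_rings(model)
            order = {r.residue.seq_num: r for r in rings}
            spans.append(
                float(
                    np.linalg.norm(
                        order[1].ring_atom("C1").position
                        - order[4].ring_atom("C4").position
                    )
                )
            )
        assert spans[0] > spans[1] > spans[2]


class TestAnnotationGeometry:
    def test_disulfide_detection(self):
        def cys(seq, x):
            return ResidueRecord(
                chain_id="A",
                seq_num=seq,
                icode="",
                comp_name="CYS",
                atoms=[
                    AtomRecord(name="CA", element="C", position=np.array([x, 0.0, 2.0])),
                    AtomRecord(name="SG", element="S", position=np.array([x, 0.0, 0.0])),
                ],
            )

        close = classify_residues(
            StructureModel(id="SS", residues=[cys(204, 0.0), cys(279, 2.03)])
        )
        assert sm.detect_disulfides(close) == [(("A", 204), ("A", 279))]
        far = classify_residues(
            StructureModel(id="SS2", residues=[cys(1, 0.0), cys(2, 3.5)])
        )
        assert sm.detect_disulfides(far) == []

    def test_contact_table_planted_pair(self):
        sugar_res = make_sugar("Man")
        model = classify_residues(StructureModel(id="CT", residues=[sugar_res]))
        ring = gt.detect_rings(model)[0]
        o3 = sugar_res.atom("O3")
        prot = ResidueRecord(
            chain_id="A",
            seq_num=10,
            icode="",
            comp_name="SER",
            atoms=[
                AtomRecord(
                    name="OG",
                    element="O",
                    position=o3.position + np.array([2.8, 0.0, 0.0]),
                )
            ],
        )
        both = classify_residues(
            StructureModel(id="CT2", residues=[sugar_res, prot])
        )
        rows = sm.contact_table(ring, both)
        assert rows == sorted(rows, key=lambda r: r[3])
        o3_rows = [r for r in rows if r[1] == "OG" and r[2] == "O3"]
        assert len(o3_rows) == 1
        assert o3_rows[0][3] == pytest.approx(2.8, abs=1e-6)

    def test_contact_table_isolated_sugar(self):
        model = classify_residues(
            StructureModel(id="ISO", residues=[make_sugar("Man")])
        )
        ring = gt.detect_rings(model)[0]
        assert sm.contact_table(ring, model) == []

    def test_canyon_lining(self, subsite_map, scaffold):
        smap, composite, _ = subsite_map
        lining = sm.canyon_lining(scaffold.model, composite.model, aromatic_only=True)
        assert lining
        assert all(r.comp_name in sm.AROMATIC for r in lining)
        everything = sm.canyon_lining(scaffold.model, composite.model)
        assert len(everything) >= len(lining)

    def test_far_ligand_empty_lining(self, scaffold):
        sugar = make_sugar("Man")
        for atom in sugar.atoms:
            atom.position = atom.position + np.array([500.0, 500.0, 500.0])
        far = classify_residues(StructureModel(id="FAR", residues=[sugar]))
        assert sm.canyon_lining(scaffold.model, far) == []


class TestCompareOccupancy:
    def test_identical_model_full_agreement(self, subsite_map, scaffold, planted):
        smap, _, _ = subsite_map
        models, _ = planted
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sm.compare_occupancy(smap, [models[0]], scaffold.model)
        assert table.loc[models[0].id, "outside"] == 0
        assert table.loc[models[0].id, "inside"] == 9

    def test_displaced_ligand_outside(self, subsite_map, scaffold):
        smap, _, _ = subsite_map
        model = scaffold.model.copy()
        model.id = "PRED"
        sugar = make_sugar("Man", chain_id="Z")
        for atom in sugar.atoms:
            atom.position = atom.position + np.array([0.0, 40.0, 40.0])
        model.residues.append(sugar)
        classify_residues(model)
        table = sm.compare_occupancy(smap, [model], scaffold.model)
        assert table.loc["PRED", "outside"] == 1

    def test_planted_recovery_statistic(self, subsite_map, scaffold):
        # 30 predicted ligands, 14 planted at true subsites, 16 off-canyon
        smap, _, _ = subsite_map
        rng = np.random.default_rng(17)
        models = []
        n_at_sites = 0
        for k in range(5):
            model = scaffold.model.copy()
            model.id = f"PRED{k}"
            for j in range(6):
                sugar = make_sugar("Man", chain_id="WXYZUV"[j], seq_num=j + 1)
                planted_at_site = n_at_sites < 14 and (k * 6 + j) % 2 == 0
                if planted_at_site:
                    target = scaffold.centroids[(k * 6 + j) % 9]
                    n_at_sites += 1
                else:
                    target = np.array([60.0 + 12 * j, 80.0, 50.0 * k])
                ring = np.array([a.position for a in sugar.atoms[:6]])
                shift = target - ring.mean(axis=0)
                for atom in sugar.atoms:
                    atom.position = atom.position + shift
                model.residues.append(sugar)
            classify_residues(model)
            models.append(model)
        assert n_at_sites == 14
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sm.compare_occupancy(smap, models, scaffold.model)
        assert int(table["inside"].sum()) == 14
        assert int(table["outside"].sum()) == 16
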
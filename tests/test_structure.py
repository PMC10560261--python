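import random

import numpy as np
import pandas as pd
import pytest

from pacce.enrichment import DomainAnnotation
from pacce.simulate import generate_toy_structure
from pacce.structure import (
    AtomRecord,
    ChainRecord,
    DistanceRecord,
    NoRnaChainError,
    ResidueRecord,
    StructureModel,
    StructureParseError,
    all_cys_rna_distances,
    classify_chain,
    filter_structures,
    join_sites_to_structures,
    min_cys_rna_distance,
    parse_structure,
    renumber_to_reference,
    summarize_distance_by_class,
)

from conftest import make_quant
from pacce.calling import call_rs_cys


def atom_line(serial, name, resname, chain, resseq, x, y, z, element, altloc=" ", occ=1.0):
    name4 = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name4}{altloc}{resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def build_model(chains, structure_id="manual", resolution=None):
    return StructureModel(structure_id=structure_id, chains=tuple(chains), resolution=resolution)


def cys_chain(chain_id, entries, reference=True):
    """entries: list of (resnum, sg_xyz or None)."""
    residues = []
    for resnum, sg in entries:
        atoms = [AtomRecord("CA", "C", 0.0, 0.0, -5.0)]
        if sg is not None:
            atoms.append(AtomRecord("SG", "S", *sg))
        residues.append(
            ResidueRecord(resnum, "CYS", tuple(atoms), reference_number=resnum if reference else None)
        )
    return ChainRecord(chain_id, tuple(residues))


def rna_chain(chain_id, coords):
    residues = tuple(
        ResidueRecord(i + 1, "AUGC"[i % 4], (AtomRecord("O2'", "O", *xyz),))
        for i, xyz in enumerate(coords)
    )
    return ChainRecord(chain_id, residues)


class TestParseStructure:
    def test_toy_fixture_round_trips_all_atoms(self):
        text = generate_toy_structure([("A", 5, 7.0), ("A", 9, 12.0)])
        model = parse_structure(text, "toy")
        n_atoms = sum(len(r.atoms) for c in model.chains for r in c.residues)
        assert n_atoms == text.count("\nATOM")

    def test_two_models_keeps_first(self):
        body1 = [atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C")]
        body2 = [
            atom_line(2, "CA", "GLY", "A", 1, 9, 9, 9, "C"),
            atom_line(3, "CB", "GLY", "A", 1, 9, 9, 8, "C"),
        ]
        text = "\n".join(
            ["MODEL        1"] + body1 + ["ENDMDL", "MODEL        2"] + body2 + ["ENDMDL", "END"]
        )
        model = parse_structure(text, "twomodel")
        atoms = [a for c in model.chains for r in c.residues for a in r.atoms]
        assert len(atoms) == 1
        assert atoms[0].x == 0.0

    def test_altloc_resolved_to_highest_occupancy(self):
        text = "\n".join(
            [
                atom_line(1, "CA", "CYS", "A", 1, 0, 0, 0, "C"),
                atom_line(2, "SG", "CYS", "A", 1, 1.0, 0, 0, "S", altloc="A", occ=0.6),
                atom_line(3, "SG", "CYS", "A", 1, 2.0, 0, 0, "S", altloc="B", occ=0.4),
                "END",
            ]
        )
        model = parse_structure(text, "altloc")
        sg = [a for c in model.chains for r in c.residues for a in r.atoms if a.name == "SG"]
        assert len(sg) == 1
        assert sg[0].x == 1.0

    def test_no_coordinate_records_is_parse_error(self):
        with pytest.raises(StructureParseError):
            parse_structure("HEADER    EMPTY\nEND\n", "empty")

    def test_metadata_resolution_used_when_header_silent(self):
        text = generate_toy_structure([("A", 1, 5.0)])
        model = parse_structure(text, "toy", resolution=2.4)
        assert model.resolution == 2.4


class TestClassifyChain:
    def test_rna_requires_o2_prime(self):
        chain = rna_chain("R", [(0, 0, 0), (1, 0, 0)])
        assert classify_chain(chain) == "rna"
        no_o2 = ChainRecord(
            "R",
            tuple(
                ResidueRecord(i + 1, "A", (AtomRecord("C1'", "C", 0, 0, 0),))
                for i in range(2)
            ),
        )
        assert classify_chain(no_o2) != "rna"

    def test_dna_chain(self):
        chain = ChainRecord(
            "D",
            tuple(
                ResidueRecord(i + 1, name, (AtomRecord("C1'", "C", 0, 0, 0),))
                for i, name in enumerate(["DA", "DT", "DG"])
            ),
        )
        assert classify_chain(chain) == "dna"

    def test_protein_chain(self):
        assert classify_chain(cys_chain("A", [(1, (0, 0, 0))])) == "protein"

    def test_forty_percent_nucleotide_is_other(self):
        names = ["A", "A", "UNK", "UNX", "UNL"]  # 40% ribonucleotide names
        chain = ChainRecord(
            "X",
            tuple(
                ResidueRecord(i + 1, name, (AtomRecord("O2'", "O", 0, 0, 0),))
                for i, name in enumerate(names)
            ),
        )
        assert classify_chain(chain) == "other"


class TestRenumber:
    def _model(self):
        text = generate_toy_structure([("A", 47, 5.0)])
        return parse_structure(text, "toy")

    def test_identity_map(self):
        model = renumber_to_reference(self._model(), identity=True)
        res = model.chain("A").residues[0]
        assert res.reference_number == res.author_number == 47

    def test_offset_map(self):
        mapping = pd.DataFrame(
            [{"structure_id": "toy", "chain_id": "A", "author_number": 47, "reference_number": 57}]
        )
        model = renumber_to_reference(self._model(), mapping)
        assert model.chain("A").residues[0].reference_number == 57

    def test_unmapped_residue_excluded_from_joins(self):
        mapping = pd.DataFrame(
            [{"structure_id": "other", "chain_id": "A", "author_number": 47, "reference_number": 57}]
        )
        model = renumber_to_reference(self._model(), mapping)
        assert model.chain("A").residues[0].reference_number is None
        assert all_cys_rna_distances(model) == []

    def test_conflicting_mapping_rejected(self):
        mapping = pd.DataFrame(
            [
                {"structure_id": "toy", "chain_id": "A", "author_number": 47, "reference_number": 57},
                {"structure_id": "toy", "chain_id": "A", "author_number": 47, "reference_number": 58},
            ]
        )
        with pytest.raises(ValueError, match="conflict"):
            renumber_to_reference(self._model(), mapping)


class TestMinDistance:
    def test_three_four_five_triangle(self):
        model = build_model(
            [cys_chain("A", [(10, (0.0, 0.0, 0.0))]), rna_chain("R", [(3.0, 4.0, 0.0)])]
        )
        [rec] = min_cys_rna_distance(model, "A", 10)
        assert rec.distance == pytest.approx(5.0)

    def test_planted_twenty_three(self):
        text = generate_toy_structure([("A", 4, 23.0)])
        model = renumber_to_reference(parse_structure(text, "toy"), identity=True)
        [rec] = min_cys_rna_distance(model, "A", 4)
        assert rec.distance == pytest.approx(23.0, abs=1e-6)

    def test_brute_force_oracle_on_random_fixture(self):
        rng = np.random.default_rng(8)
        sg_positions = {i: tuple(rng.uniform(-50, 50, 3)) for i in range(1, 6)}
        rna_coords = [tuple(rng.uniform(-50, 50, 3)) for _ in range(200)]
        model = build_model(
            [cys_chain("A", list(sg_positions.items())), rna_chain("R", rna_coords)]
        )
        for resnum, sg in sg_positions.items():
            [rec] = min_cys_rna_distance(model, "A", resnum)
            oracle = min(
                sum((a - b) ** 2 for a, b in zip(sg, xyz)) ** 0.5 for xyz in rna_coords
            )
            assert rec.distance == pytest.approx(oracle, abs=1e-9)

    def test_multiple_instances_all_emitted(self):
        model = build_model(
            [
                cys_chain("A", [(10, (0.0, 0.0, 0.0))]),
                cys_chain("B", [(10, (10.0, 0.0, 0.0))]),
                rna_chain("R", [(3.0, 4.0, 0.0)]),
            ]
        )
        recs = min_cys_rna_distance(model, None, 10)
        assert len(recs) == 2
        assert sorted(r.distance for r in recs) == pytest.approx(
            [5.0, (49 + 16) ** 0.5]
        )
        assert [r.instance_index for r in recs] == [0, 1]

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(1)
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-100, 100, 3)

        def transform(atom):
            xyz = rot @ np.array([atom.x, atom.y, atom.z]) + shift
            return AtomRecord(atom.name, atom.element, *map(float, xyz))

        text = generate_toy_structure([("A", 1, 7.5), ("A", 2, 31.0)])
        model = renumber_to_reference(parse_structure(text, "toy"), identity=True)
        moved = StructureModel(
            model.structure_id,
            tuple(
                ChainRecord(
                    c.chain_id,
                    tuple(
                        ResidueRecord(
                            r.author_number,
                            r.name,
                            tuple(transform(a) for a in r.atoms),
                            r.reference_number,
                        )
                        for r in c.residues
                    ),
                )
                for c in model.chains
            ),
            model.resolution,
        )
        for resnum in (1, 2):
            [a] = min_cys_rna_distance(model, "A", resnum)
            [b] = min_cys_rna_distance(moved, "A", resnum)
            assert abs(a.distance - b.distance) < 1e-6

    def test_missing_sg_skipped_with_warning(self):
        model = build_model(
            [cys_chain("A", [(10, None)]), rna_chain("R", [(3.0, 4.0, 0.0)])]
        )
        with pytest.warns(UserWarning, match="SG"):
            assert min_cys_rna_distance(model, "A", 10) == []

    def test_no_rna_chain_raises(self):
        model = build_model([cys_chain("A", [(10, (0, 0, 0))])])
        with pytest.raises(NoRnaChainError):
            min_cys_rna_distance(model, "A", 10)

    def test_hydrogens_toggle(self):
        h_atom = AtomRecord("H5'", "H", 0.0, 0.0, 1.0)
        o_atom = AtomRecord("O2'", "O", 0.0, 0.0, 9.0)
        chain = ChainRecord("R", (ResidueRecord(1, "A", (h_atom, o_atom)),))
        model = build_model([cys_chain("A", [(1, (0, 0, 0))]), chain])
        [with_h] = min_cys_rna_distance(model, "A", 1, include_hydrogens=True)
        [without_h] = min_cys_rna_distance(model, "A", 1, include_hydrogens=False)
        assert with_h.distance == pytest.approx(1.0)
        assert without_h.distance == pytest.approx(9.0)


class TestJoinAndSummarize:
    def _records(self):
        return [
            DistanceRecord("S1", "A", 393, "C393", 8.0, 0, protein_id="P1"),
            DistanceRecord("S1", "A", 298, "C298", 29.0, 0, protein_id="P2"),
            DistanceRecord("S1", "A", 700, "C700", 40.0, 0, protein_id="P3"),
        ]

    def _calls(self):
        quants = [
            make_quant("P1", "C393", "pacce", [3.0, 3.5, 2.9, 3.1, 3.2, 3.3]),
            make_quant("P1", "C393", "mixing", [1.0, 1.1, 0.9]),
            make_quant("P2", "C298", "pacce", [1.0, 1.01, 0.98, 1.02, 0.99, 1.03]),
            make_quant("P2", "C298", "mixing", [1.0, 1.1, 0.9]),
        ]
        return call_rs_cys(quants)

    def test_rs_status_attached(self):
        joined = join_sites_to_structures(self._records(), self._calls())
        status = {r.site_key: r.rs_status for r in joined}
        assert status == {"C393": "rs", "C298": "insensitive", "C700": "not_quantified"}

    def test_single_record_mean(self):
        summary = summarize_distance_by_class(
            [DistanceRecord("S1", "A", 1, "C1", 8.0, 0, rs_status="rs")]
        )
        assert summary["all"]["mean_distance"] == 8.0
        assert summary["rs"] == {"mean_distance": 8.0, "n": 1}

    def test_planted_class_means_recovered(self):
        records = [
            DistanceRecord("S1", "A", i, f"C{i}", 10.0, 0, rs_status="rs", protein_id="P1")
            for i in range(1, 4)
        ] + [
            DistanceRecord("S1", "A", i, f"C{i}", 30.0, 0, rs_status="insensitive", protein_id="P1")
            for i in range(10, 13)
        ]
        summary = summarize_distance_by_class(records)
        assert summary["rs"]["mean_distance"] == pytest.approx(10.0)
        assert summary["insensitive"]["mean_distance"] == pytest.approx(30.0)
        assert summary["all"]["mean_distance"] == pytest.approx(20.0)

    def test_rbd_subclass(self):
        records = [
            DistanceRecord("S1", "A", 20, "C20", 11.0, 0, rs_status="rs", protein_id="P1"),
            DistanceRecord("S1", "A", 500, "C500", 25.0, 0, rs_status="rs", protein_id="P1"),
        ]
        rbd = [DomainAnnotation("P1", "RRM", 1, 100, "RBD")]
        summary = summarize_distance_by_class(records, rbd)
        assert summary["rs_in_rbd"] == {"mean_distance": 11.0, "n": 1}

    def test_shuffle_invariance_and_empty_class_absent(self):
        records = [
            DistanceRecord("S1", "A", i, f"C{i}", float(d), 0, rs_status="rs")
            for i, d in enumerate([5, 10, 15], 1)
        ]
        base = summarize_distance_by_class(records)
        shuffled = records[:]
        random.Random(0).shuffle(shuffled)
        assert summarize_distance_by_class(shuffled) == base
        assert "insensitive" not in base

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_distance_by_class([])


class TestFilterStructures:
    def test_resolution_and_exclusion(self):
        models = [
            build_model([cys_chain("A", [(1, (0, 0, 0))])], "GOOD", resolution=2.5),
            build_model([cys_chain("A", [(1, (0, 0, 0))])], "BLURRY", resolution=3.5),
            build_model([cys_chain("A", [(1, (0, 0, 0))])], "5JS2", resolution=2.0),
            build_model([cys_chain("A", [(1, (0, 0, 0))])], "NORES", resolution=None),
        ]
        kept = filter_structures(models, resolution_max=3.0, exclude_ids={"5js2"})
        assert [m.structure_id for m in kept] == ["GOOD", "NORES"]
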
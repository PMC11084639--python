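"""I/O layer: FASTA, topology tables, CA traces, Newick, config, RNG."""

import numpy as np
import pytest

from memhomology import core_io
from memhomology.core_io import (
    FormatError,
    RunConfig,
    Segment,
    SequenceRecord,
    Topology,
    ValidationError,
    spawn_rng,
)


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nMKT\n")
        (rec,) = core_io.parse_fasta(p)
        assert (rec.id, rec.residues) == ("a", "MKT")

    def test_round_trip_identity(self, tmp_path):
        recs = [SequenceRecord("x1", "MKTAYIAKQR", "first"),
                SequenceRecord("x2", "A" * 130)]
        path = core_io.emit_fasta(recs, tmp_path / "rt.fasta", width=60)
        back = core_io.parse_fasta(path)
        assert [(r.id, r.residues, r.description) for r in back] == \
               [(r.id, r.residues, r.description) for r in recs]

    def test_lowercase_normalised(self, tmp_path):
        p = tmp_path / "lc.fasta"
        p.write_text(">a\nmkt\n")
        assert core_io.parse_fasta(p)[0].residues == "MKT"

    def test_wrapping(self, tmp_path):
        rec = SequenceRecord("a", "L" * 80)
        path = core_io.emit_fasta([rec], tmp_path / "w.fasta", width=60)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3 and len(lines[1]) == 60 and len(lines[2]) == 20

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            core_io.parse_fasta(p)

    def test_illegal_character_names_position(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nMK9T\n")
        with pytest.raises(FormatError, match="position 3"):
            core_io.parse_fasta(p)

    def test_gaps_only_when_allowed(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">a\nMK-T\n>b\nMKTT\n")
        with pytest.raises(FormatError):
            core_io.parse_fasta(p)
        rows = core_io.parse_msa(p)
        assert rows[0].residues == "MK-T"

    def test_unequal_msa_rows_rejected(self, tmp_path):
        p = tmp_path / "m.fasta"
        p.write_text(">a\nMK-T\n>b\nMKT\n")
        with pytest.raises(FormatError):
            core_io.parse_msa(p)

    def test_empty_record_list_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            core_io.emit_fasta([], tmp_path / "x.fasta")


class TestTopologyTable:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("p1\t5\t24\tTMS\n")
        topo = core_io.read_topology_table(p)["p1"]
        assert topo.segments == (Segment(4, 24, "TMS"),)

    def test_abutting_segments_accepted(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("p1\t1\t10\tTMS\np1\t11\t20\tLOOP\n")
        topo = core_io.read_topology_table(p)["p1"]
        assert [s.kind for s in topo.segments] == ["TMS", "LOOP"]

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("p1\t1\t10\tTMS\np1\t8\t20\tLOOP\n")
        with pytest.raises(ValidationError, match="p1"):
            core_io.read_topology_table(p)

    def test_round_trip(self, tmp_path):
        topos = {"q": Topology((Segment(0, 21, "TMS"), Segment(21, 40, "LOOP"),
                                Segment(40, 58, "RL")))}
        path = core_io.write_topology_table(topos, tmp_path / "rt.tsv")
        assert core_io.read_topology_table(path)["q"].segments == topos["q"].segments


class TestStructureIO:
    def _toy_pdb(self, tmp_path, body):
        p = tmp_path / "toy.pdb"
        p.write_text(body + "END\n")
        return p

    def test_read_ca_in_order(self, tmp_path):
        body = "".join(
            f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
            f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C\n"
            for i in range(4)
        )
        chain = core_io.read_ca_coordinates(self._toy_pdb(tmp_path, body), "A")
        assert len(chain) == 4
        assert np.allclose(chain.coords[:, 0], [0, 1, 2, 3])

    def test_missing_chain(self, tmp_path):
        body = ("ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
                "  1.00  0.00           C\n")
        with pytest.raises(LookupError):
            core_io.read_ca_coordinates(self._toy_pdb(tmp_path, body), "Z")

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        body = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
        )
        chain = core_io.read_ca_coordinates(self._toy_pdb(tmp_path, body), "A")
        assert len(chain) == 2
        assert chain.coords[0, 0] == pytest.approx(9.0)

    def test_write_read_round_trip(self, tmp_path):
        from memhomology.core_io import StructureChain

        chain = StructureChain(np.arange(12, dtype=float).reshape(4, 3), (1, 2, 3, 4))
        path = core_io.write_ca_pdb(chain, tmp_path / "c.pdb")
        back = core_io.read_ca_coordinates(path, "A")
        assert np.allclose(back.coords, chain.coords, atol=1e-3)


class TestNewick:
    def _tree(self, merges, labels):
        from memhomology.clustering import Dendrogram

        return Dendrogram(tuple(merges), tuple(labels), "ward", 0.5)

    def test_two_leaf_shape(self, tmp_path):
        t = self._tree([(0, 1, 0.8)], ["a", "b"])
        text = core_io.write_newick(t, tmp_path / "t.nwk").read_text()
        assert text.strip() == "(a:0.8,b:0.8);"

    def test_ladder_parses_with_standard_reader(self, tmp_path):
        import dendropy

        t = self._tree([(0, 1, 0.5), (3, 2, 1.0)], ["a", "b", "c"])
        path = core_io.write_newick(t, tmp_path / "t.nwk")
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"a", "b", "c"}

    def test_duplicate_labels_rejected(self, tmp_path):
        t = self._tree([(0, 1, 0.5)], ["a", "a"])
        with pytest.raises(ValidationError):
            core_io.write_newick(t, tmp_path / "t.nwk")


class TestConfigAndRng:
    def test_config_validation(self):
        with pytest.raises(ValidationError):
            RunConfig(gap_open=0)
        with pytest.raises(ValidationError):
            RunConfig(n_shuffles=50)
        with pytest.raises(ValidationError):
            RunConfig(evalue_threshold=2.0)

    def test_config_json_round_trip(self, tmp_path):
        cfg = RunConfig(n_shuffles=200, master_seed=7)
        cfg.to_json(tmp_path / "c.json")
        assert RunConfig.from_json(tmp_path / "c.json") == cfg

    def test_seeded_streams_reproducible_and_distinct(self):
        a1 = spawn_rng(1, "stage").normal(size=5)
        a2 = spawn_rng(1, "stage").normal(size=5)
        b = spawn_rng(1, "other").normal(size=5)
        assert np.allclose(a1, a2)
        assert not np.allclose(a1, b)
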
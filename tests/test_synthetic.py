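"""Synthetic generator: composition contrast, evolution, composites, toys."""

import numpy as np
import pytest

from memhomology import synthetic as syn
from memhomology import topology as topo_mod
from memhomology.core_io import ValidationError
from memhomology.motifs import pwm_from_consensus
from memhomology.pairwise import smith_waterman


class TestSpecAndAncestor:
    def test_lengths_add_up(self, spec31, ancestor):
        assert len(ancestor) == spec31.total_length
        assert len(ancestor.topology.of_kind("TMS")) == 4

    def test_same_seed_identical(self, spec31):
        a = syn.sample_ancestor(spec31, 5)
        b = syn.sample_ancestor(spec31, 5)
        assert a.residues == b.residues

    def test_spec_must_alternate(self):
        with pytest.raises(ValidationError):
            syn.TopologySpec((("TMS", 21), ("TMS", 21)))
        with pytest.raises(ValidationError):
            syn.TopologySpec(())

    def test_hydropathy_contrast(self, spec31):
        """TMS residues are more hydrophobic than loops in >= 99/100 draws."""
        wins = 0
        for i in range(100):
            a = syn.sample_ancestor(spec31, 1000 + i)
            wins += (topo_mod.mean_segment_hydropathy(a)
                     > topo_mod.mean_loop_hydropathy(a))
        assert wins >= 99


class TestEvolveFamily:
    def test_zero_divergence_identical(self, ancestor):
        members, _ = syn.evolve_family(ancestor, 3, 0.0, 1)
        assert all(m.residues == ancestor.residues for m in members)

    def test_segment_count_preserved(self, ancestor):
        members, _ = syn.evolve_family(ancestor, 10, 0.8, 2)
        n_anc = len(ancestor.topology.membrane_segments())
        assert all(len(m.topology.membrane_segments()) == n_anc for m in members)

    def test_pairwise_identity_range_at_half_divergence(self, ancestor):
        members, _ = syn.evolve_family(ancestor, 10, 0.5, 3)
        idents = [
            smith_waterman(members[i], members[j]).identity_pct
            for i in range(4) for j in range(i + 1, 4)
        ]
        assert 20.0 <= np.mean(idents) <= 70.0

    def test_truth_flags_symmetric(self, family):
        members, truth = family
        for a in members[:3]:
            for b in members[:3]:
                assert truth.is_homologous(a.id, b.id) == truth.is_homologous(b.id, a.id)

    def test_negative_divergence_rejected(self, ancestor):
        with pytest.raises(ValidationError):
            syn.evolve_family(ancestor, 2, -0.1, 1)

    def test_topology_matches_residues_after_indels(self, ancestor):
        members, _ = syn.evolve_family(ancestor, 5, 0.6, 4)
        for m in members:
            m.topology.check_bounds(len(m))  # raises on violation
            assert m.topology.segments[-1].end == len(m)


class TestNonHomologPair:
    def test_same_topology_different_residues(self, spec31):
        a, b = syn.make_nonhomolog_pair(spec31, 9)
        assert a.residues != b.residues
        assert a.topology.segments == b.topology.segments

    def test_identical_subseeds_refused(self, spec31):
        with pytest.raises(ValidationError):
            syn.make_nonhomolog_pair(spec31, 9, sub_seeds=(3, 3))

    def test_nonhomologs_rarely_significant(self, spec31):
        evalues = []
        for i in range(15):
            a, b = syn.make_nonhomolog_pair(spec31, 100 + i)
            evalues.append(smith_waterman(a, b).evalue)
        assert np.median(evalues) > 1e-4


class TestImplantAndCompose:
    def test_implant_fractions(self, family):
        members, _ = family
        pwm = pwm_from_consensus("LIVFAWGMCLIV")
        full, truth = syn.implant_motif(members, pwm, segment_index=6,
                                        fraction=1.0, seed=1)
        assert len(truth.implants) == len(members)
        none, truth0 = syn.implant_motif(members, pwm, segment_index=6,
                                         fraction=0.0, seed=1)
        assert not truth0.implants
        assert [m.residues for m in none] == [m.residues for m in members]

    def test_implant_wider_than_segment_rejected(self, family):
        members, _ = family
        pwm = pwm_from_consensus("L" * 35)
        with pytest.raises(ValidationError):  # TMS 1 is only 21 residues
            syn.implant_motif(members, pwm, segment_index=1, fraction=1.0, seed=1)

    def test_implant_lands_inside_segment(self, family):
        members, _ = family
        pwm = pwm_from_consensus("LIVFAWGMCLIV")
        out, truth = syn.implant_motif(members, pwm, 6, 1.0, seed=2)
        for m in out:
            seg = m.topology.segments[6]
            s, e = truth.implants[m.id]
            assert seg.start <= s and e <= seg.end

    def test_tandem_doubles_membrane_segments(self):
        unit = syn.sample_ancestor(syn.three_tms_unit_spec(), 7, "u")
        dup, breakpoint = syn.compose_architectures(unit, None, "tandem",
                                                    linker=20, seed=8)
        assert len(dup.topology.of_kind("TMS")) == 6
        assert breakpoint == len(unit) + 20
        assert dup.residues[:len(unit)] == unit.residues
        # the duplicated unit may differ in length through loop indels
        assert len(dup) - breakpoint == pytest.approx(len(unit), abs=20)

    def test_fusion_marks_breakpoint(self, ancestor):
        other = syn.sample_ancestor(syn.four_tight_spec(), 13, "vpc")
        fused, breakpoint = syn.compose_architectures(ancestor, other, "fusion",
                                                      linker=10)
        assert breakpoint == len(ancestor) + 10
        assert fused.residues[:len(ancestor)] == ancestor.residues
        assert fused.residues[breakpoint:] == other.residues

    def test_convert_tms_to_rl(self, ancestor):
        converted = syn.convert_tms_to_rl(ancestor, 1)
        kinds = [s.kind for s in converted.topology.membrane_segments()]
        assert kinds == ["TMS", "RL", "TMS", "TMS"]
        assert converted.residues == ancestor.residues


class TestFamilyMsa:
    def test_rows_degap_to_members(self, family, family_msa_fixture, ancestor):
        members, _ = family
        rows, cols, consensus = family_msa_fixture
        for m, r in zip(members, rows):
            assert r.residues.replace("-", "") == m.residues
        assert len(cols) == len(rows[0].residues)
        assert len(consensus.membrane_segments()) == \
               len(ancestor.topology.membrane_segments())

    def test_match_columns_cover_ancestor(self, family_msa_fixture, ancestor):
        _, cols, _ = family_msa_fixture
        assert [c for c in cols if c is not None] == list(range(len(ancestor)))


class TestToyStructure:
    def test_ca_distances_near_virtual_bond(self, spec31):
        chain = syn.make_toy_structure(spec31, seed=3)
        d = np.linalg.norm(np.diff(chain.coords, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) < 0.2)
        assert len(chain) == spec31.total_length

    def test_helix_helix_turn_is_gly_glu(self):
        spec = syn.TopologySpec(
            (("LOOP", 12), ("TMS", 21), ("LOOP", 10), ("RL", 18),
             ("LOOP", 10), ("TMS", 21), ("LOOP", 12)), "rl")
        chain = syn.make_toy_structure(spec, rl_shape="helix_helix", seed=4)
        rl_pos = [i for i, lab in enumerate(chain.labels) if lab == "RL"]
        rl_seq = "".join(chain.sequence[i] for i in rl_pos)
        assert "GE" in rl_seq

    def test_same_seed_identical(self, spec31):
        c1 = syn.make_toy_structure(spec31, seed=5)
        c2 = syn.make_toy_structure(spec31, seed=5)
        assert np.array_equal(c1.coords, c2.coords)

    def test_unknown_rl_shape_rejected(self, spec31):
        with pytest.raises(ValidationError):
            syn.make_toy_structure(spec31, rl_shape="zigzag", seed=1)
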
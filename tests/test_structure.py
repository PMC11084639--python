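"""Kabsch superposition, TM-score, refinement rule, length statistics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from memhomology import structure as st
from memhomology import synthetic as syn
from memhomology.core_io import StructureChain, ValidationError, spawn_rng


def _chain(coords, labels=None):
    coords = np.asarray(coords, dtype=float)
    return StructureChain(coords, tuple(range(1, len(coords) + 1)),
                          labels=tuple(labels) if labels else None)


def _random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 10, size=3)
    return R, t


class TestKabsch:
    def test_identity_superposition(self):
        a = _chain(np.random.default_rng(1).normal(size=(8, 3)))
        sup = st.kabsch_superpose(a, a, [(i, i) for i in range(8)])
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_copy_exact_recovery(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(10, 3))
        R, t = _random_rigid(rng)
        b = _chain(coords @ R.T + t)
        a = _chain(coords)
        sup = st.kabsch_superpose(a, b, [(i, i) for i in range(10)])
        assert sup.rmsd < 1e-6
        assert np.allclose(sup.rotation, R.T, atol=1e-6)

    def test_rmsd_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(3)
        coords_a = rng.normal(size=(7, 3))
        coords_b = coords_a + rng.normal(0, 0.5, size=(7, 3))
        corr = [(i, i) for i in range(7)]
        base = st.kabsch_superpose(_chain(coords_a), _chain(coords_b), corr).rmsd
        R, t = _random_rigid(rng)
        moved = st.kabsch_superpose(_chain(coords_a @ R.T + t), _chain(coords_b), corr).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_matches_rotation_search_oracle(self):
        """Perturbed 4-point toy: optimal RMSD agrees with a grid-search
        (plus local refinement) over rotations to 1e-3 A."""
        pa = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 3.8]], float)
        pb = pa.copy()
        pb[2] += [0.7, -0.4, 0.5]

        def rmsd_for(angles):
            R = Rotation.from_euler("xyz", angles).as_matrix()
            qa = pa - pa.mean(axis=0)
            qb = (pb - pb.mean(axis=0)) @ R.T
            return float(np.sqrt(((qa - qb) ** 2).sum(axis=1).mean()))

        grid = np.linspace(-np.pi, np.pi, 13)
        best = min(
            ((rmsd_for((x, y, z)), (x, y, z))
             for x in grid for y in grid for z in grid),
            key=lambda v: v[0],
        )
        refined = min(
            minimize(rmsd_for, start, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for start in [best[1]]
        )
        sup = st.kabsch_superpose(_chain(pa), _chain(pb), [(i, i) for i in range(4)])
        assert sup.rmsd == pytest.approx(refined, abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        line = _chain([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValidationError):
            st.kabsch_superpose(line, line, [(i, i) for i in range(4)])
        good = _chain(np.random.default_rng(4).normal(size=(5, 3)))
        with pytest.raises(ValidationError):
            st.kabsch_superpose(good, good, [(0, 0), (1, 1)])


class TestTmScore:
    def test_identical_chains_score_one(self):
        coords = np.random.default_rng(5).normal(size=(30, 3)) * 5
        a = _chain(coords)
        tm = st.tm_score(a, a, [(i, i) for i in range(30)], reference="a")
        assert tm == pytest.approx(1.0, abs=1e-9)

    def test_asymmetric_under_reference_swap(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(40, 3)) * 5
        a = _chain(coords)
        b = _chain(coords[:20])
        corr = [(i, i) for i in range(20)]
        tm_a = st.tm_score(a, b, corr, reference="a")
        tm_b = st.tm_score(a, b, corr, reference="b")
        assert tm_a != tm_b and tm_a < tm_b

    def test_half_corresponded_copy_matches_direct_formula(self):
        """Perfectly superposable halves: TM equals n_pairs / L_ref."""
        coords = np.random.default_rng(7).normal(size=(32, 3)) * 5
        a = _chain(coords)
        b = _chain(coords)
        corr = [(i, i) for i in range(16)]
        tm = st.tm_score(a, b, corr, reference="a")
        assert tm == pytest.approx(16 / 32, abs=1e-9)

    def test_short_reference_rejected(self):
        a = _chain(np.random.default_rng(8).normal(size=(10, 3)))
        with pytest.raises(ValidationError):
            st.tm_score(a, a, [(i, i) for i in range(10)])


class TestRefinement:
    def _toy(self, dist, idx_gap):
        """A labeled RL block and one LOOP residue at a chosen distance and
        index separation from it."""
        n_rl = 4
        coords = [[3.8 * i, 0.0, 0.0] for i in range(n_rl)]
        labels = ["RL"] * n_rl
        # spacer residues keep the index distance honest
        for k in range(idx_gap - 1):
            coords.append([3.8 * (n_rl + k), 50.0, 0.0])
            labels.append("LOOP")
        coords.append([3.8 * (n_rl - 1) + dist, 0.0, 0.0])
        labels.append("LOOP")
        return _chain(coords, labels)

    def test_within_distance_and_index_added(self):
        chain = self._toy(dist=1.2, idx_gap=2)
        refined = st.refine_segment_assignments(chain)
        assert refined[-1] == "RL"

    def test_distance_fails(self):
        chain = self._toy(dist=1.6, idx_gap=2)
        assert st.refine_segment_assignments(chain)[-1] == "LOOP"

    def test_index_fails(self):
        chain = self._toy(dist=1.2, idx_gap=4)
        assert st.refine_segment_assignments(chain)[-1] == "LOOP"

    def test_idempotent_and_preserves_original_labels(self):
        chain = self._toy(dist=1.2, idx_gap=2)
        once = st.refine_segment_assignments(chain)
        twice = st.refine_segment_assignments(
            StructureChain(chain.coords, chain.residue_numbers, labels=once))
        assert once == twice
        for orig, new in zip(chain.labels, once):
            if orig != "LOOP":
                assert new == orig

    def test_tms_wins_over_rl_on_conflict(self):
        coords = [[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]
        labels = ["TMS", "LOOP", "RL"]
        refined = st.refine_segment_assignments(_chain(coords, labels))
        assert refined[1] == "TMS"


class TestLengthReport:
    def test_basic_means(self):
        c1 = _chain(np.zeros((38, 3)) + np.arange(38)[:, None],
                    ["TMS"] * 20 + ["RL"] * 18)
        c2 = _chain(np.zeros((22, 3)) + np.arange(22)[:, None], ["TMS"] * 22)
        rep = st.segment_length_report([c1, c2])
        assert rep.tms_mean == 21.0 and rep.rl_mean == 18.0
        assert rep.tms_n == 2 and rep.rl_n == 1

    def test_perfectly_correlated_lengths(self):
        chains = []
        rng = spawn_rng(10, "corr")
        for k in range(10):
            t = 15 + k
            r = 10 + k  # exactly linear in t
            labels = ["TMS"] * t + ["LOOP"] * 3 + ["RL"] * r
            coords = np.arange(len(labels))[:, None] * [3.8, 0, 0]
            chains.append(_chain(coords, labels))
        assert st.segment_length_report(chains).r_squared == pytest.approx(1.0)

    def test_independent_lengths_uncorrelated(self):
        """r^2 < 0.1 in >= 90% of seeded draws of 100 independent pairs."""
        wins = 0
        for trial in range(20):
            rng = spawn_rng(11, "indep", trial)
            chains = []
            for k in range(100):
                t = int(rng.integers(16, 28))
                r = int(rng.integers(13, 25))
                labels = ["TMS"] * t + ["LOOP"] * 3 + ["RL"] * r
                coords = np.arange(len(labels))[:, None] * [3.8, 0, 0]
                chains.append(_chain(coords, labels))
            wins += st.segment_length_report(chains).r_squared < 0.1
        assert wins >= 18

    def test_toy_structure_lengths_consistent(self, spec31):
        chain = syn.make_toy_structure(spec31, seed=12)
        rep_labels = [l for l in chain.labels if l == "TMS"]
        assert len(rep_labels) == 4 * 21
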
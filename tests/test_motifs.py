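"""OOPS motif discovery, exact scanning statistics, recovery rates."""

import numpy as np
import pytest
from scipy import stats

from memhomology import motifs as mot
from memhomology import synthetic as syn
from memhomology.composition import BACKGROUND_VECTOR, sample_residues
from memhomology.core_io import AA20, Segment, SequenceRecord, Topology, ValidationError, spawn_rng


def _background_seqs(n, length, seed):
    rng = spawn_rng(seed, "bg")
    return [SequenceRecord(f"b{i}", sample_residues(length, BACKGROUND_VECTOR, rng))
            for i in range(n)]


class TestDiscovery:
    def test_width_bounds_enforced(self):
        seqs = _background_seqs(5, 60, 1)
        with pytest.raises(ValidationError):
            mot.discover_motif_oops(seqs, 7)
        with pytest.raises(ValidationError):
            mot.discover_motif_oops(seqs, 51)

    def test_width_exceeding_shortest_sequence_rejected(self):
        seqs = [SequenceRecord("short", "MKTAYIA")]
        with pytest.raises(ValidationError):
            mot.discover_motif_oops(seqs, 8)

    def test_recovers_implanted_motif(self):
        """A strong implant in background sequences is recovered with sites
        at the implant positions and a near-matching consensus."""
        consensus = "WHCKDEPMNQYR"
        pwm0 = mot.pwm_from_consensus(consensus, identity=0.9)
        rng = spawn_rng(2, "implant")
        seqs = []
        starts = {}
        for i, rec in enumerate(_background_seqs(50, 80, 3)):
            pos = int(rng.integers(0, 80 - 12))
            s = rec.residues[:pos] + pwm0.sample(rng) + rec.residues[pos + 12:]
            seqs.append(SequenceRecord(rec.id, s))
            starts[rec.id] = pos
        pwm, sites = mot.discover_motif_oops(seqs, 12, n_starts=5, seed=4)
        agree = sum(a == b for a, b in zip(pwm.consensus, consensus))
        assert agree >= 10
        located = sum(starts[s.seq_id] == s.start for s in sites)
        assert located >= 45

    def test_information_content_positive_and_bounded(self):
        pwm = mot.pwm_from_consensus("WWWWWWWW", identity=0.95)
        # upper bound: a delta function on the rarest residue per position
        bound = 8 * np.log2(1.0 / BACKGROUND_VECTOR.min())
        assert 0 < pwm.information_content <= bound


class TestScoreDistribution:
    def test_tail_at_maximum_score_is_product_of_background(self):
        pwm = mot.pwm_from_consensus("WHCKDEPM", identity=0.9)
        dist = mot.pwm_score_distribution(pwm)
        lo = pwm.log_odds
        max_score = float(lo.max(axis=1).sum())
        expected = float(np.prod([pwm.background[int(i)] for i in lo.argmax(axis=1)]))
        assert dist.sf(max_score - 1e-6) == pytest.approx(expected, rel=1e-6)

    def test_tail_function_monotone(self):
        pwm = mot.pwm_from_consensus("WHCKDEPM", identity=0.8)
        dist = mot.pwm_score_distribution(pwm)
        values = [dist.sf(x) for x in np.linspace(-40, 40, 50)]
        assert all(b <= a for a, b in zip(values, values[1:]))
        assert dist.sf(-1e6) == 1.0 and dist.sf(1e6) == 0.0

    def test_window_pvalues_uniform_on_background(self):
        """Exact-null p-values of single background windows pass a KS
        uniformity test at alpha = 0.01.  (Uses a generic random PWM: a
        consensus-style PWM has near-degenerate per-position scores, whose
        atom-heavy null makes uniformity meaningless.)"""
        rng = spawn_rng(6, "ks")
        probs = rng.dirichlet(20 * BACKGROUND_VECTOR, size=16)
        pwm = mot.PositionWeightMatrix(probs, BACKGROUND_VECTOR.copy())
        dist = mot.pwm_score_distribution(pwm)
        pvals = []
        for _ in range(1000):
            window = sample_residues(pwm.width, BACKGROUND_VECTOR, rng)
            score_bits = sum(pwm.log_odds[t, AA20.index(c)]
                             for t, c in enumerate(window))
            pvals.append(dist.sf(float(score_bits)))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestScanning:
    def _implanted_family(self, fraction, seed, n=40):
        pwm = mot.pwm_from_consensus("WHCKDEPMNQYRLIV", identity=0.85)
        spec = syn.three_plus_one_spec()
        anc = syn.sample_ancestor(spec, seed, "sc")
        fam, _ = syn.evolve_family(anc, n, 1.0, seed + 1, f"scan{seed}")
        fam2, truth = syn.implant_motif(fam, pwm, segment_index=6,
                                        fraction=fraction, seed=seed + 2)
        return pwm, fam2, truth

    def test_implanted_members_recovered(self):
        pwm, fam, truth = self._implanted_family(1.0, 30)
        hits = mot.scan_sequences(pwm, fam, 1e-4)
        recovered = {h.seq_id for h in hits} & set(truth.implants)
        assert len(recovered) >= 0.9 * len(truth.implants)

    def test_background_yields_no_hits(self):
        pwm = mot.pwm_from_consensus("WHCKDEPMNQYRLIV", identity=0.85)
        hits = mot.scan_sequences(pwm, _background_seqs(40, 250, 31), 1e-4)
        assert len(hits) <= 1

    def test_short_sequence_skipped(self):
        pwm = mot.pwm_from_consensus("WHCKDEPM", identity=0.8)
        hits = mot.scan_sequences(pwm, [SequenceRecord("tiny", "MKT")], 1.0)
        assert hits == []

    def test_recovery_monotone_in_implant_fraction(self):
        rates = []
        for fraction in (0.2, 0.5, 0.8):
            pwm, fam, _ = self._implanted_family(fraction, 40)
            hits = mot.scan_sequences(pwm, fam, 1e-4)
            rates.append(mot.recovery_rate(hits, [m.id for m in fam]))
        assert rates[0] <= rates[1] <= rates[2]


class TestRecoveryAndLocation:
    def test_recovery_rate_arithmetic(self):
        hits = [mot.MotifHit(f"m{i}", 0, 10, 1e-9, 1e-7) for i in range(21)]
        members = [f"m{i}" for i in range(26)]
        assert mot.recovery_rate(hits, members) == pytest.approx(80.77, abs=0.01)
        assert mot.recovery_rate([], members) == 0.0

    def test_empty_family_rejected(self):
        with pytest.raises(ValidationError):
            mot.recovery_rate([], [])

    def test_locate_modal_segment_is_implant_target(self, family):
        members, _ = family
        pwm = mot.pwm_from_consensus("WHCKDEPMNQYR", identity=0.9)
        implanted, truth = syn.implant_motif(members, pwm, segment_index=5,
                                             fraction=1.0, seed=9)
        hits = mot.scan_sequences(pwm, implanted, 1e-4)
        topo_map = {m.id: m.topology for m in implanted}
        histogram = mot.locate_motif(hits, topo_map, pwm.width)
        assert histogram
        assert max(histogram, key=histogram.get) == "TMS 3"

    def test_loop_hit_counted_as_loop(self):
        topo = Topology((Segment(0, 21, "TMS"), Segment(21, 120, "LOOP")))
        hits = [mot.MotifHit("x", 60, 20, 1e-9, 1e-8)]
        assert mot.locate_motif(hits, {"x": topo}, 12) == {"loop": 1}

    def test_empty_hits_empty_histogram(self):
        assert mot.locate_motif([], {}, 12) == {}
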
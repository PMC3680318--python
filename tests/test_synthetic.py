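import numpy as np
import pytest

from mitescout.errors import ParameterError
from mitescout.family_eval import count_full_length_copies, sequence_identity
from mitescout.ir_scan import find_inverted_repeats, is_simple_arm, ScanParams
from mitescout.sequence_model import write_fasta
from mitescout.synthetic import (
    FamilySpec,
    evaluate_output,
    make_background,
    make_mite_consensus,
    plant_false_family,
    plant_family,
    plant_simple_repeats,
    simulate,
)
from mitescout.tsd import find_tsd

from conftest import random_seq


class TestMakeBackground:
    def test_gc_content_and_split(self):
        db = make_background(1_000_000, 4, 0.43, 7)
        assert len(db) == 4 and db.total_length == 1_000_000
        joined = "".join(e.residues for e in db)
        gc = (joined.count("G") + joined.count("C")) / len(joined)
        assert abs(gc - 0.43) <= 0.01

    def test_zero_gc_is_at_only(self):
        db = make_background(10_000, 1, 0.0, 1)
        assert set(db.entries[0].residues) <= {"A", "T"}

    def test_deterministic(self):
        a = make_background(50_000, 2, 0.5, 42)
        b = make_background(50_000, 2, 0.5, 42)
        assert all(x.residues == y.residues for x, y in zip(a, b))

    def test_invalid(self):
        with pytest.raises(ParameterError):
            make_background(2, 5, 0.5, 1)


class TestMakeMiteConsensus:
    def test_structure_detected_by_scanner(self):
        spec = FamilySpec("f", 200, 12, 3, 10)
        cons = make_mite_consensus(spec, 3)
        assert len(cons) == 200
        pairs = find_inverted_repeats(cons, ScanParams(min_element_len=50))
        assert any(
            p.left_start == 0 and p.right_end == 200 and p.arm_len >= 12 for p in pairs
        )
        assert not is_simple_arm(cons[:12])

    def test_tir_too_long_rejected(self):
        with pytest.raises(ParameterError):
            FamilySpec("f", 50, 25, 3, 10)

    def test_seed_variation(self):
        spec = FamilySpec("f", 200, 12, 3, 10)
        assert make_mite_consensus(spec, 1) != make_mite_consensus(spec, 2)


class TestPlantFamily:
    def test_zero_mutation_round_trip(self):
        spec = FamilySpec("f", 200, 14, 3, 12, 0.0)
        bg = make_background(120_000, 2, 0.5, 5)
        cons = make_mite_consensus(spec, 5)
        db, truths = plant_family(bg, cons, spec, 5)
        assert len(count_full_length_copies(cons, db)) == 12
        for t in truths:
            res = db.get(t.entry_id).residues
            assert res[t.start : t.end] == cons
            ts = res[t.start - spec.tsd_len : t.start]
            assert res[t.end : t.end + spec.tsd_len] == ts
            m = find_tsd(res[t.start - 10 : t.start], res[t.end : t.end + 10])
            assert m is not None and m.sequence.endswith(ts)

    def test_mutation_rate_reflected_in_identity(self):
        spec = FamilySpec("f", 400, 14, 3, 12, 0.05)
        bg = make_background(200_000, 1, 0.5, 6)
        cons = make_mite_consensus(spec, 6)
        db, truths = plant_family(bg, cons, spec, 6)
        measured = [
            sequence_identity(db.get(t.entry_id).residues[t.start : t.end], cons)
            for t in truths
        ]
        assert abs(float(np.mean(measured)) - 0.95) <= 0.015
        for t, m in zip(truths, measured):
            assert m == pytest.approx(t.identity, abs=0.01)

    def test_uniform_placement(self):
        """Fraction of copies in the first 37% of the genome approximates 37%."""
        spec = FamilySpec("f", 100, 12, 2, 12, 0.0)
        inside = total = 0
        for rep in range(50):
            bg = make_background(100_000, 1, 0.5, 100 + rep)
            cons = make_mite_consensus(spec, rep)
            _, truths = plant_family(bg, cons, spec, 200 + rep)
            for t in truths:
                total += 1
                if t.start < 0.37 * 100_000:
                    inside += 1
        frac = inside / total
        se = np.sqrt(0.37 * 0.63 / total)
        assert abs(frac - 0.37) <= 4 * se

    def test_insufficient_room(self):
        spec = FamilySpec("f", 400, 14, 3, 10, 0.0)
        bg = make_background(600, 1, 0.5, 1)
        with pytest.raises(ParameterError):
            plant_family(bg, make_mite_consensus(spec, 1), spec, 1)


class TestPlantFalseFamily:
    def test_core_passes_screens_and_shares_flanks(self):
        spec = FamilySpec("d", 240, 12, 4, 15, 0.0, "false_retro_like")
        bg = make_background(150_000, 1, 0.5, 12)
        db, truths, core = plant_false_family(bg, spec, 12)
        assert len(truths) == 15
        res = db.entries[0].residues
        t = truths[0]
        # core alone passes the TSD screen by construction
        m = find_tsd(res[t.start - 10 : t.start], res[t.end : t.end + 10])
        assert m is not None
        # identical 50-nt contexts at every copy
        contexts = {res[t.start - 54 : t.start - 4] for t in truths}
        assert len(contexts) == 1

    def test_kind_enforced(self):
        spec = FamilySpec("d", 240, 12, 4, 15, 0.0, "true_mite")
        bg = make_background(50_000, 1, 0.5, 1)
        with pytest.raises(ParameterError):
            plant_false_family(bg, spec, 1)


class TestPlantSimpleRepeats:
    def test_stretches_recorded_verbatim(self):
        bg = make_background(100_000, 1, 0.5, 3)
        db, intervals = plant_simple_repeats(bg, 10, (100, 200), 3)
        assert len(intervals) == 10
        for entry_id, start, end in intervals:
            region = db.get(entry_id).residues[start:end]
            assert is_simple_arm(region[:50])

    def test_no_ir_pairs_survive_simple_filter(self):
        bg = make_background(50_000, 1, 0.5, 4)
        db, intervals = plant_simple_repeats(bg, 1, (200, 200), 4)
        entry_id, start, end = intervals[0]
        window = db.get(entry_id).residues[start - 20 : end + 20]
        for p in find_inverted_repeats(window, ScanParams(max_element_len=300)):
            arm = window[p.left_start : p.left_end]
            assert not is_simple_arm(arm)

    def test_zero_stretches_identity(self):
        bg = make_background(20_000, 1, 0.5, 5)
        db, intervals = plant_simple_repeats(bg, 0, seed=5)
        assert intervals == []
        assert db.entries[0].residues == bg.entries[0].residues


class TestSimulateAndEvaluate:
    def test_deterministic(self):
        specs = [FamilySpec("m", 150, 12, 2, 10, 0.02)]
        a = simulate(100_000, 2, specs, seed=9, n_simple=2)
        b = simulate(100_000, 2, specs, seed=9, n_simple=2)
        assert all(x.residues == y.residues for x, y in zip(a.db, b.db))
        assert a.truths == b.truths

    def test_truth_matches_genome_content(self):
        specs = [FamilySpec("m", 150, 12, 2, 10, 0.03)]
        sim = simulate(100_000, 2, specs, seed=10)
        for t in sim.truths:
            region = sim.db.get(t.entry_id).residues[t.start : t.end]
            assert sequence_identity(region, sim.consensus_by_family["m"]) >= 0.9

    def test_evaluate_output_confusion_table(self, tmp_path, rng):
        cons_a = random_seq(rng, 200)
        cons_b = random_seq(rng, 180)
        decoy = random_seq(rng, 220)
        truths = []
        from mitescout.synthetic import TruthRecord

        for fid in ("a", "b"):
            truths.append(TruthRecord(fid, "chr1", 0, 1, "+", 1.0, f"{fid}_locus0"))
        truths.append(TruthRecord("d", "chr1", 0, 1, "+", 1.0, "d_shared"))
        cand = tmp_path / "c.fasta"
        false = tmp_path / "f.fasta"
        # candidates: family a exactly, plus one junk record
        write_fasta([("MD_1", cons_a), ("MD_2", random_seq(rng, 300))], cand)
        write_fasta([("MDF_1", decoy)], false)
        m = evaluate_output(
            cand, false, truths, {"a": cons_a, "b": cons_b, "d": decoy}
        )
        assert m["recall"] == pytest.approx(0.5)
        assert m["precision"] == pytest.approx(0.5)
        assert m["false_family_leakage"] == 0
        assert m["false_in_false_output"] == {"d": True}

    def test_empty_candidates_zero_recall(self, tmp_path, rng):
        from mitescout.synthetic import TruthRecord

        cons = random_seq(rng, 200)
        truths = [TruthRecord("a", "chr1", 0, 1, "+", 1.0, "a_locus0")]
        cand = tmp_path / "c.fasta"
        false = tmp_path / "f.fasta"
        cand.write_text("")
        false.write_text("")
        m = evaluate_output(cand, false, truths, {"a": cons})
        assert m["recall"] == 0.0
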
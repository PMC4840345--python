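import numpy as np
import pytest

from exolnc.rbp import (
    PWM,
    compare_rbp_counts,
    motif_is_binding_site,
    read_pwms,
    relative_score,
    scan_sequence,
    scan_set,
)
from exolnc.seqdata import TranscriptRecord, TranscriptSet
from exolnc.synthetic import SimConfig, generate_transcript_sets

from _oracles import brute_relative_score, brute_scan


def sharp_pwm(consensus: str, p: float = 0.85, name: str = "sharp") -> PWM:
    """Uniformly sharp PWM: p on the consensus base, the rest split evenly."""
    mat = np.full((4, len(consensus)), (1 - p) / 3)
    for j, base in enumerate(consensus):
        mat["ACGU".index(base), j] = p
    return PWM(name, mat)


def cols_of(pwm: PWM):
    return [
        {b: pwm.matrix["ACGU".index(b), j] for b in "ACGU"}
        for j in range(pwm.length)
    ]


class TestReadPwms:
    def test_frequency_block(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text(
            ">X\nA 0.7 0.1 0.1 0.1 0.1 0.1\nC 0.1 0.7 0.1 0.1 0.1 0.1\n"
            "G 0.1 0.1 0.7 0.1 0.1 0.1\nU 0.1 0.1 0.1 0.7 0.7 0.7\n"
        )
        (pwm,) = read_pwms(path)
        assert pwm.length == 6
        assert pwm.consensus == "ACGUUU"
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-6)

    def test_counts_normalised(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text(">X\nA 8 1 1 1\nC 1 8 1 1\nG 1 1 8 1\nU 0 0 0 7\n")
        (pwm,) = read_pwms(path)
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-6)
        assert pwm.consensus == "ACGU"

    def test_dna_t_row_bridged(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text(">X\nA 1 0 0 0\nC 0 1 0 0\nG 0 0 1 0\nT 0 0 0 1\n")
        (pwm,) = read_pwms(path)
        assert pwm.consensus == "ACGU"

    def test_row_length_mismatch(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text(">X\nA 1 0 0\nC 0 1 0 0\nG 0 0 1 0\nU 0 0 0 1\n")
        with pytest.raises(ValueError, match="mismatch"):
            read_pwms(path)

    def test_negative_entry(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text(">X\nA 1 0 0 -1\nC 0 1 0 0\nG 0 0 1 0\nU 0 0 0 1\n")
        with pytest.raises(ValueError, match="negative"):
            read_pwms(path)


class TestRelativeScore:
    def test_consensus_scores_one(self, demo_pwms):
        for pwm in demo_pwms:
            assert relative_score(pwm, pwm.consensus) == pytest.approx(1.0)

    def test_anticonsensus_scores_zero(self, demo_pwms):
        for pwm in demo_pwms:
            worst = "".join("ACGU"[i] for i in pwm.matrix.argmin(axis=0))
            assert relative_score(pwm, worst) == pytest.approx(0.0)

    def test_uniform_pwm_degenerate_convention(self):
        pwm = PWM("flat", np.full((4, 5), 0.25))
        assert relative_score(pwm, "ACGUA") == 1.0
        assert relative_score(pwm, "UUUUU") == 1.0

    def test_column_rescaling_invariance(self, rng):
        raw = rng.uniform(0.05, 1.0, size=(4, 6))
        scales = rng.uniform(0.1, 10.0, size=6)
        a = PWM("a", raw)
        b = PWM("b", raw * scales)
        for _ in range(20):
            window = "".join(rng.choice(list("ACGU"), size=6))
            assert relative_score(a, window) == pytest.approx(
                relative_score(b, window), abs=1e-12
            )

    def test_agrees_with_brute_force(self, demo_pwms, rng):
        for pwm in demo_pwms:
            cols = cols_of(pwm)
            for _ in range(25):
                window = "".join(rng.choice(list("ACGU"), size=pwm.length))
                assert relative_score(pwm, window) == pytest.approx(
                    brute_relative_score(cols, window), abs=1e-9
                )


class TestScan:
    def test_u_run_hits(self):
        # rel score of a window is (#consensus matches)/6 for a uniformly
        # sharp PWM, so CCUUUUUUCC yields hits at starts 2, 3, 4
        # (5, 6 and 5 matching positions) at threshold 0.8
        pwm = sharp_pwm("UUUUUU")
        hits = scan_sequence("CCUUUUUUCC", pwm, 0.8)
        assert [h[0] for h in hits] == [2, 3, 4]
        scores = {pos: s for pos, s in hits}
        assert scores[3] == pytest.approx(1.0)
        assert scores[2] == pytest.approx(5 / 6)

    def test_threshold_one_keeps_only_consensus(self):
        pwm = sharp_pwm("UUUUUU")
        hits = scan_sequence("CCUUUUUUCC", pwm, 1.0)
        assert [h[0] for h in hits] == [3]

    def test_n_windows_skipped(self):
        pwm = sharp_pwm("UUUUUU")
        # only the window clear of the N (1-based start 5) can score
        assert scan_sequence("UUUNUUUUUU", pwm, 0.5) == [(5, pytest.approx(1.0))]

    def test_empty_set(self, demo_pwms):
        hits, counts = scan_set(TranscriptSet([], label="test"), demo_pwms)
        assert hits == []
        assert set(counts.values()) == {0}

    def test_hit_count_monotone_in_threshold(self, demo_pwms, rng):
        seq = "".join(rng.choice(list("ACGU"), size=2000))
        tset = TranscriptSet([TranscriptRecord("t", seq)])
        previous = None
        for thr in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0):
            _, counts = scan_set(tset, demo_pwms, thr)
            total = sum(counts.values())
            if previous is not None:
                assert total <= previous
            previous = total

    def test_totals_equal_per_transcript_sums(self, demo_pwms, rng):
        recs = [
            TranscriptRecord(f"t{i}", "".join(rng.choice(list("ACGU"), size=300)))
            for i in range(5)
        ]
        tset = TranscriptSet(recs)
        hits, counts = scan_set(tset, demo_pwms, 0.7)
        for pwm in demo_pwms:
            assert counts[pwm.rbp_name] == sum(
                1 for h in hits if h.rbp_name == pwm.rbp_name
            )

    def test_oracle_reproduces_every_hit(self, demo_pwms, rng):
        seqs = ["".join(rng.choice(list("ACGUN"), size=80)) for _ in range(5)]
        tset = TranscriptSet([TranscriptRecord(f"t{i}", s) for i, s in enumerate(seqs)])
        hits, _ = scan_set(tset, demo_pwms, 0.6)
        got = {(h.transcript_id, h.rbp_name, h.start): h.rel_score for h in hits}
        expected = {}
        for rec in tset:
            for pwm in demo_pwms:
                for pos, score in brute_scan(rec.sequence, cols_of(pwm), 0.6):
                    expected[(rec.id, pwm.rbp_name, pos)] = score
        assert set(got) == set(expected)
        for key, score in expected.items():
            assert got[key] == pytest.approx(score, abs=1e-9)


class TestCompareCounts:
    def test_rate_ratio_arithmetic(self):
        (cmp,) = compare_rbp_counts({"X": 100}, {"X": 50}, 10, 10)
        assert cmp.rate_ratio == pytest.approx(2.0)

    def test_equal_rates(self):
        (cmp,) = compare_rbp_counts({"X": 40}, {"X": 40}, 10, 10)
        assert cmp.rate_ratio == pytest.approx(1.0)
        assert cmp.p_value > 0.9

    def test_one_sided_presence_filled_with_zero(self):
        out = compare_rbp_counts({"X": 10}, {"Y": 10}, 5, 5)
        by = {c.rbp_name: c for c in out}
        assert by["X"].count_control == 0
        assert by["Y"].count_test == 0

    def test_planted_site_rate_ratio_recovered(self):
        # AU-rich consensus sites planted at twice the control rate
        consensus = "UUUAUUU"
        cfg = SimConfig(
            rng_seed=77,
            n_test=150,
            n_control=150,
            length_median=600,
            planted_motifs=[(consensus, 1.0, 0.5)],
        )
        test_set, control_set, _ = generate_transcript_sets(cfg)
        pwm = sharp_pwm(consensus, p=0.9, name="ELAVL1-like")
        _, ct = scan_set(test_set, [pwm], 0.95)
        _, cc = scan_set(control_set, [pwm], 0.95)
        (cmp,) = compare_rbp_counts(ct, cc, len(test_set), len(control_set))
        assert abs(cmp.rate_ratio - 2.0) < 0.3
        assert cmp.p_value < 0.01


def test_motif_within_pwm(demo_pwms):
    elavl1 = demo_pwms[0]
    assert motif_is_binding_site(elavl1.consensus[:6], elavl1, 0.8)
    assert not motif_is_binding_site("GCGCGC", elavl1, 0.8)
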
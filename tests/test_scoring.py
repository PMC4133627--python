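import io

import numpy as np
import pytest

from alnreform import (
    additive_score,
    adjust_matrix,
    base_hoxd,
    params_from_apsi,
    position_gop,
    scale_gap_penalties,
)
from alnreform.msa import ALPHABET
from alnreform.profile import ProfilePosition
from alnreform.scoring import ScoringError, load_matrix

# Independent transcription of the HOXD70 table (Chiaromonte, Yap & Miller),
# frozen here so the packaged copy is cross-checked against it.
HOXD70 = {
    ("A", "A"): 91, ("A", "C"): -114, ("A", "G"): -31, ("A", "T"): -123,
    ("C", "C"): 100, ("C", "G"): -125, ("C", "T"): -31,
    ("G", "G"): 100, ("G", "T"): -114,
    ("T", "T"): 91,
}


class TestBaseHoxd:
    def test_matches_published_table(self):
        m = base_hoxd()
        for (a, b), v in HOXD70.items():
            assert m.score(a, b) == v
            assert m.score(b, a) == v

    def test_strand_symmetry(self):
        m = base_hoxd()
        assert m.score("A", "A") == m.score("T", "T")
        assert m.score("C", "C") == m.score("G", "G")


class TestAdjustMatrix:
    def test_identity_coeff_is_pure_shift(self):
        base = base_hoxd()
        adj = adjust_matrix(base, bonus=130.0, coeff=1.0)
        assert np.allclose(adj.table, base.table + 130.0)

    def test_all_entries_positive(self):
        adj = adjust_matrix(base_hoxd(), bonus=126.0, coeff=1.0)
        assert np.all(adj.table > 0)

    def test_bonus_too_small_rejected(self):
        with pytest.raises(ScoringError, match="bonus too small"):
            adjust_matrix(base_hoxd(), bonus=50.0, coeff=1.0)

    def test_full_recompute_at_fixed_apsi(self):
        params = params_from_apsi(60.0)
        base = base_hoxd()
        for a in ALPHABET:
            for b in ALPHABET:
                expect = base.score(a, b) * params.coeff + params.bonus
                assert params.matrix.score(a, b) == pytest.approx(expect)

    def test_match_mismatch_contrast_preserved(self):
        adj = adjust_matrix(base_hoxd(), bonus=200.0, coeff=1.4)
        for a in ALPHABET:
            for b in ALPHABET:
                if a != b:
                    assert adj.score(a, a) > adj.score(a, b)


class TestParamsFromApsi:
    def test_hand_evaluation_at_60(self):
        p = params_from_apsi(60.0)
        assert p.bonus == pytest.approx(220.0)
        assert p.coeff == pytest.approx(1.3)
        assert p.hgop == pytest.approx(-220.0)
        assert p.hgep == pytest.approx(-60.0)
        assert p.vgop == pytest.approx(-110.0)
        assert p.vgep == pytest.approx(-22.0)

    @pytest.mark.parametrize("apsi", range(0, 101, 10))
    def test_constraint_system(self, apsi):
        p = params_from_apsi(float(apsi))
        assert np.all(p.matrix.table > 0)
        assert p.hgop <= 0 and p.hgep <= 0 and p.vgop <= 0 and p.vgep <= 0
        assert abs(p.hgop) >= abs(p.hgep)
        assert abs(p.vgop) >= abs(p.vgep)
        # opening in the profile is costlier than opening in the sequence
        assert abs(p.hgop) >= abs(p.vgop)

    def test_out_of_range_rejected(self):
        with pytest.raises(ScoringError):
            params_from_apsi(101.0)


class TestScaleGapPenalties:
    def test_identity_at_equal_lengths(self):
        p = params_from_apsi(50.0)
        s = scale_gap_penalties(p, 80, 80)
        assert (s.hgop, s.hgep, s.vgop, s.vgep) == (p.hgop, p.hgep, p.vgop, p.vgep)

    def test_shorter_sequences_penalized_harder(self):
        p = params_from_apsi(50.0)
        s = scale_gap_penalties(p, 50, 100)
        for name in ("hgop", "hgep", "vgop", "vgep"):
            assert abs(getattr(s, name)) >= abs(getattr(p, name))

    def test_values_at_30_of_100(self):
        p = params_from_apsi(60.0)
        s = scale_gap_penalties(p, 30, 100)
        assert s.hgop == pytest.approx(-220.0 * 1.7)
        assert s.vgep == pytest.approx(-22.0 * 1.7)

    def test_monotone_in_sequence_length(self):
        p = params_from_apsi(40.0)
        mags = [abs(scale_gap_penalties(p, n, 100).hgop) for n in (10, 40, 70, 100)]
        assert mags == sorted(mags, reverse=True)

    def test_longer_than_max_rejected(self):
        with pytest.raises(ScoringError):
            scale_gap_penalties(params_from_apsi(50.0), 101, 100)


class TestAdditiveScore:
    def test_deep_column_beats_shallow(self):
        m = params_from_apsi(50.0).matrix
        deep = additive_score(ProfilePosition({"C": 5}), "C", m)
        shallow = additive_score(ProfilePosition({"C": 1}), "C", m)
        assert deep == pytest.approx(5 * shallow)
        assert deep > shallow

    def test_two_term_sum(self):
        m = base_hoxd()
        got = additive_score(ProfilePosition({"A": 1, "G": 1}), "C", m)
        assert got == pytest.approx(m.score("A", "C") + m.score("G", "C"))

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(77)
        m = params_from_apsi(30.0).matrix
        for _ in range(50):
            weights = {
                ALPHABET[i]: int(rng.integers(1, 6))
                for i in rng.choice(4, size=rng.integers(1, 5), replace=False)
            }
            b = ALPHABET[rng.integers(4)]
            expect = sum(c * m.score(a, b) for a, c in weights.items())
            assert additive_score(ProfilePosition(weights), b, m) == pytest.approx(expect)

    def test_linear_in_counts(self):
        m = base_hoxd()
        p1, p2 = ProfilePosition({"A": 2, "C": 1}), ProfilePosition({"A": 1, "T": 3})
        merged = ProfilePosition({"A": 3, "C": 1, "T": 3})
        assert additive_score(merged, "G", m) == pytest.approx(
            additive_score(p1, "G", m) + additive_score(p2, "G", m))


class TestPositionGop:
    def test_hand_value(self):
        assert position_gop(-10.0, 0.75, 20.0) == pytest.approx(-25.0)

    def test_linear_in_pcr(self):
        base = -10.0
        m1 = position_gop(base, 0.4, 20.0) - base
        m2 = position_gop(base, 0.8, 20.0) - base
        assert m2 == pytest.approx(2 * m1)

    def test_vanishing_modulation_limit(self):
        assert position_gop(-10.0, 1e-9, 20.0) == pytest.approx(-10.0)

    def test_magnitude_monotone(self):
        assert abs(position_gop(-10, 0.9, 20)) >= abs(position_gop(-10, 0.5, 20))
        assert abs(position_gop(-10, 0.5, 40)) >= abs(position_gop(-10, 0.5, 20))


class TestLoadMatrix:
    def test_roundtrip_table(self):
        text = "A C G T\n" + "\n".join(
            f"{r} " + " ".join(str(int(base_hoxd().score(r, c))) for c in ALPHABET)
            for r in ALPHABET
        )
        m = load_matrix(io.StringIO(text))
        assert np.allclose(m.table, base_hoxd().table)

    def test_bad_header_rejected(self):
        with pytest.raises(ScoringError):
            load_matrix(io.StringIO("A C G\n"))
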
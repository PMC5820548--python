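"""PSSM parsing and profile-feature checks with brute-force oracles."""

import math

import numpy as np
import pytest

from cancerlectin.pssm import (
    ProfileMatrix,
    PssmParseError,
    encode_profile,
    parse_pssm,
    profile_feature_names,
    pse_pssm,
    pssm_aac,
    pseudo_profile,
    scale_sigmoid,
)
from cancerlectin.sequence_io import AMINO_ACIDS

#: PSI-BLAST prints columns in this (non-alphabetical) order.
BLAST_ORDER = list("ARNDCQEGHILKMFPSTWYV")


def write_pssm_text(path, sequence, rows, col_order=BLAST_ORDER):
    """rows[i] maps residue letter -> score, written in col_order."""
    lines = ["", "Last position-specific scoring matrix computed", ""]
    lines[2] = "           " + " ".join(f"{a:>3}" for a in col_order) * 2
    for i, (res, row) in enumerate(zip(sequence, rows), start=1):
        scores = " ".join(f"{row[a]:>3d}" for a in col_order)
        pct = " ".join("  0" for _ in col_order)
        lines.append(f"{i:>5d} {res} {scores}  {pct}   0.35     1.00")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.13     0.31"]
    path.write_text("\n".join(lines) + "\n")


def random_rows(rng, length):
    return [
        {a: int(rng.integers(-8, 12)) for a in AMINO_ACIDS} for _ in range(length)
    ]


class TestParsePssm:
    def test_well_formed_file(self, tmp_path):
        rng = np.random.default_rng(0)
        seq = "MKVLA"
        rows = random_rows(rng, 5)
        p = tmp_path / "x.pssm"
        write_pssm_text(p, seq, rows)
        prof = parse_pssm(p)
        assert prof.residues == seq
        assert prof.raw.shape == (5, 20)
        # columns remapped from PSI-BLAST order to alphabetical order
        for i in range(5):
            for j, a in enumerate(AMINO_ACIDS):
                assert prof.raw[i, j] == rows[i][a]

    def test_truncated_score_row(self, tmp_path):
        p = tmp_path / "bad.pssm"
        header = "           " + " ".join(f"{a:>3}" for a in BLAST_ORDER)
        p.write_text(header + "\n    1 M " + " ".join(["1"] * 19) + "\n")
        with pytest.raises(PssmParseError, match="19 score columns"):
            parse_pssm(p)

    def test_noncontiguous_positions(self, tmp_path):
        p = tmp_path / "bad.pssm"
        header = "           " + " ".join(f"{a:>3}" for a in BLAST_ORDER)
        row = " ".join(["1"] * 20)
        p.write_text(f"{header}\n    1 M {row}\n    3 K {row}\n")
        with pytest.raises(PssmParseError, match="position 3"):
            parse_pssm(p)

    def test_missing_header(self, tmp_path):
        p = tmp_path / "bad.pssm"
        p.write_text("no pssm here\n")
        with pytest.raises(PssmParseError, match="header"):
            parse_pssm(p)

    def test_golden_transcription(self, tmp_path):
        # a hand-written 2-residue file checked value-by-value
        p = tmp_path / "g.pssm"
        rows = [
            {a: 0 for a in AMINO_ACIDS},
            {a: 0 for a in AMINO_ACIDS},
        ]
        rows[0]["A"] = 7
        rows[1]["W"] = -3
        write_pssm_text(p, "AW", rows)
        prof = parse_pssm(p)
        assert prof.raw[0, AMINO_ACIDS.index("A")] == 7
        assert prof.raw[1, AMINO_ACIDS.index("W")] == -3
        assert prof.raw.sum() == 4


class TestSigmoid:
    def test_known_values(self):
        assert scale_sigmoid(np.array(0.0)) == pytest.approx(0.5)
        assert scale_sigmoid(np.array(20.0)) > 0.9999999
        assert scale_sigmoid(np.array(-1.0)) == pytest.approx(
            1 / (1 + math.e), abs=1e-9
        )

    def test_monotone(self):
        x = np.linspace(-10, 10, 101)
        assert np.all(np.diff(scale_sigmoid(x)) > 0)


def make_profile(seed=0, length=7):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    raw = rng.integers(-8, 12, size=(length, 20)).astype(float)
    return ProfileMatrix(residues=seq, raw=raw)


class TestPssmAac:
    def test_zero_scores_give_half(self):
        prof = ProfileMatrix(residues="ACD", raw=np.zeros((3, 20)))
        np.testing.assert_allclose(pssm_aac(prof), 0.5)

    def test_single_row_identity(self):
        prof = make_profile(seed=1, length=1)
        np.testing.assert_allclose(pssm_aac(prof), prof.scaled[0])

    def test_column_mean_oracle(self):
        prof = make_profile(seed=2, length=3)
        scaled = 1 / (1 + np.exp(-prof.raw))
        expected = [scaled[:, k].sum() / 3 for k in range(20)]
        np.testing.assert_allclose(pssm_aac(prof), expected, atol=1e-12)

    def test_open_interval(self):
        prof = make_profile(seed=3, length=9)
        vec = pssm_aac(prof)
        assert np.all((vec > 0) & (vec < 1))


class TestPsePssm:
    def brute_force(self, scaled, gamma):
        L = scaled.shape[0]
        out = []
        for k in range(20):
            col = scaled[:, k]
            mean = col.sum() / L
            for j in range(1, gamma + 1):
                acc = 0.0
                for i in range(L - j):
                    acc += (col[i] - mean) * (col[i + j] - mean)
                out.append(acc / (L - j))
        return np.array(out)

    def test_matches_brute_force(self):
        prof = make_profile(seed=4, length=7)
        np.testing.assert_allclose(
            pse_pssm(prof, gamma=2), self.brute_force(prof.scaled, 2), atol=1e-9
        )

    def test_default_gamma_dimension(self):
        assert pse_pssm(make_profile(seed=5, length=12)).shape == (100,)

    def test_constant_column_zero_autocovariance(self):
        prof = ProfileMatrix(residues="ACDEFG", raw=np.full((6, 20), 3.0))
        np.testing.assert_allclose(pse_pssm(prof, gamma=3), 0, atol=1e-15)

    def test_reversal_invariance(self):
        prof = make_profile(seed=6, length=15)
        rev = ProfileMatrix(residues=prof.residues[::-1], raw=prof.raw[::-1])
        np.testing.assert_allclose(pse_pssm(prof), pse_pssm(rev), atol=1e-12)
        np.testing.assert_allclose(pssm_aac(prof), pssm_aac(rev), atol=1e-12)

    def test_lag_zero_analogue_equals_column_variance(self):
        prof = make_profile(seed=7, length=11)
        scaled = prof.scaled
        centered = scaled - scaled.mean(axis=0)
        lag0 = np.array([np.dot(c, c) / len(c) for c in centered.T])
        np.testing.assert_allclose(lag0, scaled.var(axis=0), atol=1e-12)

    def test_too_short_error(self):
        with pytest.raises(ValueError, match="length"):
            pse_pssm(make_profile(seed=8, length=4), gamma=5)


def test_encode_profile_contract():
    prof = make_profile(seed=9, length=20)
    vec = encode_profile(prof)
    assert vec.shape == (120,)
    names = profile_feature_names()
    assert len(names) == 120 and len(set(names)) == 120
    np.testing.assert_array_equal(vec, encode_profile(prof))  # determinism
    np.testing.assert_allclose(vec[:20], pssm_aac(prof))


def test_pseudo_profile_shape_and_range():
    prof = pseudo_profile("ACDEFGHIK")
    assert prof.raw.shape == (9, 20)
    # BLOSUM62 diagonal is positive, so each observed residue scores high
    for i, res in enumerate("ACDEFGHIK"):
        assert prof.raw[i, AMINO_ACIDS.index(res)] > 0
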
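"""Sequence I/O and TBM consensus scanning."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tbmkit.fasta import (
    AMINO_ACIDS,
    FastaFormatError,
    ProteinRecord,
    format_fasta,
    read_fasta,
)
from tbmkit.motif import (
    MotifHit,
    MotifPattern,
    RELAXED_TBM,
    STRICT_TBM,
    build_pssm,
    column_information,
    hits_to_frame,
    frame_to_hits,
    scan_motif,
    score_hit,
)


class TestReadFasta:
    def test_start_token_sets_native_numbering(self):
        records = read_fasta(">p1 start=391\nGYTEQGQEALQHL\n")
        assert len(records) == 1
        rec = records[0]
        assert rec.start_residue == 391
        assert len(rec) == 13
        assert rec.residue(398) == "E"

    def test_empty_stream_gives_empty_list(self):
        assert read_fasta(io.StringIO("")) == []

    def test_round_trip_identity(self):
        records = [
            ProteinRecord(id="a", sequence="ACDEFG", description="frag",
                          start_residue=7),
            ProteinRecord(id="b", sequence="MKVLITX"),
        ]
        assert read_fasta(format_fasta(records)) == records

    def test_invalid_residue_names_record_and_position(self):
        with pytest.raises(FastaFormatError, match="'p1'.*position 3"):
            read_fasta(">p1\nACZDE\n")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(FastaFormatError, match="duplicate"):
            read_fasta(">p1\nACD\n>p1\nEFG\n")

    def test_sequences_uppercased_and_order_kept(self):
        records = read_fasta(">b\nacd\n>a\nefg\n")
        assert [r.id for r in records] == ["b", "a"]
        assert records[0].sequence == "ACD"


# printed peptide sequences with their native numbering and the residue
# numbers of the mutated anchor glutamates
VALIDATED_PEPTIDES = [
    ("RILPL1", "GYTEQGQEALQHL", 391, STRICT_TBM, 394, 398),
    ("JIP3", "SQSTEEATEATEVPD", 889, STRICT_TBM, 893, 897),
    ("JIP4", "TAEEATEATEG", 887, STRICT_TBM, 889, 893),
    ("WDR81", "DDLEQATEALDS", 657, STRICT_TBM, 660, 664),
    ("OCRL", "VQEAEETLLID", 65, RELAXED_TBM, 66, 70),
]


class TestScanMotif:
    @pytest.mark.parametrize(
        "name,seq,start,pattern,anchor1,anchor2", VALIDATED_PEPTIDES
    )
    def test_validated_peptides_yield_single_hit_at_printed_anchors(
        self, name, seq, start, pattern, anchor1, anchor2
    ):
        rec = ProteinRecord(id=name, sequence=seq, start_residue=start)
        hits = scan_motif(rec, pattern)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.anchor1_residue, hit.anchor2_residue) == (anchor1, anchor2)
        assert rec.residue(hit.anchor2_residue) == "E"
        assert hit.end - hit.start + 1 == len(pattern)
        idx = hit.start - rec.start_residue
        assert hit.matched_sequence == seq[idx : idx + len(pattern)]

    def test_ocrl_peptide_has_no_strict_hit(self):
        rec = ProteinRecord(id="OCRL", sequence="VQEAEETLLID", start_residue=65)
        assert scan_motif(rec, STRICT_TBM) == []

    def test_sequence_shorter_than_pattern_gives_empty(self):
        rec = ProteinRecord(id="short", sequence="EAEAE")
        assert scan_motif(rec, STRICT_TBM) == []

    def test_x_never_satisfies_constrained_position(self):
        # X at the anchor-1 slot blocks the match; X at a wildcard does not
        assert scan_motif(ProteinRecord(id="x", sequence="XQGQEA"), STRICT_TBM) == []
        hits = scan_motif(ProteinRecord(id="x", sequence="EXGXEA"), STRICT_TBM)
        assert len(hits) == 1

    @given(
        seq=st.text(alphabet=AMINO_ACIDS + "X", min_size=1, max_size=200),
        pattern_sets=st.lists(
            st.one_of(
                st.none(),
                st.sets(st.sampled_from(AMINO_ACIDS), min_size=1, max_size=5),
            ),
            min_size=2,
            max_size=8,
        ),
        start=st.integers(min_value=1, max_value=5000),
    )
    def test_scan_equals_brute_force_membership_check(
        self, seq, pattern_sets, start
    ):
        pattern = MotifPattern(
            "rand",
            tuple(None if s is None else frozenset(s) for s in pattern_sets),
            (1, len(pattern_sets)),
        )
        rec = ProteinRecord(id="r", sequence=seq, start_residue=start)
        hits = scan_motif(rec, pattern)
        expected = []
        for i in range(len(seq) - len(pattern_sets) + 1):
            ok = all(
                s is None or seq[i + j] in s
                for j, s in enumerate(pattern_sets)
            )
            if ok:
                expected.append(start + i)
        assert [h.start for h in hits] == expected

    @given(
        seq=st.text(alphabet=AMINO_ACIDS, min_size=6, max_size=100),
        k=st.integers(min_value=1, max_value=1000),
    )
    def test_shifting_start_residue_translates_all_coordinates(self, seq, k):
        base = scan_motif(ProteinRecord(id="r", sequence=seq), STRICT_TBM)
        shifted = scan_motif(
            ProteinRecord(id="r", sequence=seq, start_residue=1 + k), STRICT_TBM
        )
        assert [(h.start + k, h.end + k, h.anchor2_residue + k) for h in base] == [
            (h.start, h.end, h.anchor2_residue) for h in shifted
        ]

    @given(seq=st.text(alphabet=AMINO_ACIDS, min_size=6, max_size=150))
    def test_every_strict_hit_contains_a_relaxed_hit_at_same_start(self, seq):
        rec = ProteinRecord(id="r", sequence=seq)
        strict_starts = {h.start for h in scan_motif(rec, STRICT_TBM)}
        relaxed_starts = {h.start for h in scan_motif(rec, RELAXED_TBM)}
        assert strict_starts <= relaxed_starts


class TestPSSM:
    def test_single_sequence_argmax_recovers_it(self):
        pssm = build_pssm(["EQGQEA"], pseudocount=0.1)
        assert "".join(pssm.idxmax(axis=1)) == "EQGQEA"

    def test_uniform_column_scores_to_zero(self):
        pssm = build_pssm(list(AMINO_ACIDS), pseudocount=1e-9)
        np.testing.assert_allclose(pssm.to_numpy()[0], 0.0, atol=1e-6)

    def test_column_odds_sum_to_one(self):
        pssm = build_pssm(["EQGQEA", "EEATEA"], pseudocount=0.5)
        sums = (np.exp(pssm.to_numpy()) / 20.0).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_pssm(["EQGQEA", "EQA"])

    def test_anchor_columns_carry_max_information_in_validated_cores(self):
        # the aligned six-residue motif cores of the five validated TBMs
        cores = ["EQGQEA", "EEATEA", "EEATEA", "EQATEA", "QEAEET"]
        info = column_information(cores)
        anchors = [0, 4]
        for a in anchors:
            assert info[a] >= info.max() - 1e-9 or all(
                info[a] >= info[j] - 1e-9 for j in range(6) if j not in anchors
            )
        # position 5 (anchor 2) is strictly invariant, hence the maximum
        assert info[4] == pytest.approx(info.max())

    def test_score_is_hand_summed_log_odds(self):
        pssm = build_pssm(["EQGQEA", "EEATEA"], pseudocount=0.5)
        hit = MotifHit("p", 1, 6, "EQGQEA", 1, 5, "strict")
        expected = sum(
            pssm.loc[j + 1, ch] for j, ch in enumerate("EQGQEA")
        )
        assert score_hit(hit, pssm) == pytest.approx(expected)

    def test_self_match_is_maximal_over_protein_windows(self):
        pssm = build_pssm(["EQGQEA"], pseudocount=0.1)
        seq = "MKVEQGQEALITRA"
        scores = []
        for i in range(len(seq) - 5):
            window = seq[i : i + 6]
            scores.append(
                score_hit(MotifHit("p", 1, 6, window, 1, 5, "w"), pssm)
            )
        self_score = score_hit(MotifHit("p", 1, 6, "EQGQEA", 1, 5, "w"), pssm)
        assert self_score == pytest.approx(max(scores))

    def test_zero_matrix_scores_zero_and_x_is_background(self):
        import pandas as pd

        zero = build_pssm(["EQGQEA"], pseudocount=0.1) * 0.0
        hit = MotifHit("p", 1, 6, "EXGQEA", 1, 5, "strict")
        assert score_hit(hit, zero) == 0.0


def test_hit_table_round_trip(tmp_path):
    rec = ProteinRecord(id="RILPL1", sequence="GYTEQGQEALQHL", start_residue=391)
    hits = scan_motif(rec, STRICT_TBM)
    path = tmp_path / "hits.tsv"
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
    import pandas as pd

    assert frame_to_hits(pd.read_csv(path, sep="\t")) == hits
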
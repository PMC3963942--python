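"""Catalogue, coordinate arithmetic and sequence I/O."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numtscreen import (
    Region,
    SequenceRecord,
    load_numt_matches,
    load_primer_table,
    read_fasta,
    region_length,
    revcomp,
    target_footprints,
    write_fasta,
)
from numtscreen.catalog import CoordinateError, SequenceParseError

from oracles import naive_revcomp

MT = dict(circular=True, genome_length=16569)


@pytest.mark.parametrize(
    "start,end,kwargs,expected",
    [
        (108, 638, {}, 531),
        (16344, 276, MT, 502),  # origin-spanning
        (5, 5, {}, 1),
        (15314, 90, MT, 1346),  # origin-spanning
        (1, 16569, MT, 16569),
    ],
)
def test_region_length(start, end, kwargs, expected):
    assert region_length(Region(start, end, **kwargs)) == expected


def test_region_validation():
    with pytest.raises(CoordinateError):
        Region(10, 5)  # wrap needs circular topology
    with pytest.raises(CoordinateError):
        Region(10, 5, circular=True)  # ... and a genome length
    with pytest.raises(CoordinateError):
        Region(0, 5)
    with pytest.raises(CoordinateError):
        Region(20000, 30, circular=True, genome_length=16569)


@given(st.integers(0, 16568), st.integers(1, 16569), st.integers(1, 16569))
@settings(derandomize=True, max_examples=200)
def test_region_length_rotation_invariant(shift, start, end):
    """Rotating all coordinates around the circle preserves region length."""
    L = 16569

    def rot(p):
        return (p - 1 + shift) % L + 1

    a = Region(start, end, circular=True, genome_length=L)
    b = Region(rot(start), rot(end), circular=True, genome_length=L)
    assert region_length(a) == region_length(b)


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", "ACGT"), ("AAACCC", "GGGTTT"), ("ARYN", "NRYT")],
)
def test_revcomp(seq, expected):
    assert revcomp(seq) == expected


def test_revcomp_rejects_non_iupac():
    with pytest.raises(SequenceParseError):
        revcomp("ACQT")


@given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=60))
@settings(derandomize=True, max_examples=200)
def test_revcomp_involution_and_oracle(seq):
    assert revcomp(seq) == naive_revcomp(seq)
    assert revcomp(revcomp(seq)) == seq


class TestPrimerTables:
    def test_bundled_catalogue_sizes(self, dm_pairs, sb_pairs):
        assert len(dm_pairs) == 48
        assert len(sb_pairs) == 17

    def test_printed_sizes_match_arithmetic(self, all_pairs):
        """Printed amplicon sizes agree with the coordinates except for the
        three known typographic exceptions, which are kept flagged."""
        inconsistent = {p.id for p in all_pairs if not p.size_consistent}
        assert inconsistent == {"DM#3", "SB#11", "SB#17"}
        for p in all_pairs:
            if p.size_consistent:
                assert p.printed_size == region_length(p.target)

    def test_origin_spanning_pairs(self, all_pairs):
        wrapped = {p.id for p in all_pairs if p.target.wraps_origin()}
        assert wrapped == {"DM#48", "SB#9", "SB#17"}

    def test_duplicate_id_rejected(self, tmp_path):
        t = tmp_path / "dup.tsv"
        t.write_text(
            "id\tforward_seq\treverse_seq\ttarget_start\ttarget_end\n"
            "P1\tACGTACGTACGTACGTACGT\tACGTACGTACGTACGTACGT\t10\t200\n"
            "P1\tACGTACGTACGTACGTACGT\tACGTACGTACGTACGTACGT\t30\t400\n"
        )
        with pytest.raises(SequenceParseError, match="dup.tsv:3"):
            load_primer_table(t)

    def test_malformed_row_reports_line(self, tmp_path):
        t = tmp_path / "bad.tsv"
        t.write_text(
            "id\tforward_seq\treverse_seq\ttarget_start\ttarget_end\n"
            "P1\tACGTACGTACGTACGTACGT\tACGTACGTACGTACGTACGT\tabc\t200\n"
        )
        with pytest.raises(SequenceParseError, match="bad.tsv:2"):
            load_primer_table(t)

    def test_empty_table(self, tmp_path, caplog):
        t = tmp_path / "empty.tsv"
        t.write_text("id\tforward_seq\treverse_seq\ttarget_start\ttarget_end\n")
        assert load_primer_table(t) == []

    def test_footprints_cover_target_ends(self, all_pairs):
        for p in all_pairs:
            fwd, rev = target_footprints(p)
            assert fwd.start == p.target.start
            assert rev.end == p.target.end
            assert region_length(fwd) == len(p.forward)
            assert region_length(rev) == len(p.reverse)


class TestNumtMatchAnnotations:
    def test_pair_counts_match_publication(self):
        """23 short-amplicon and 9 long-amplicon pairs carry at least one
        same-chromosome match annotation."""
        df = load_numt_matches()
        dm = df[df.pair_id.str.startswith("DM")]
        sb = df[df.pair_id.str.startswith("SB")]
        assert dm.pair_id.nunique() == 23
        assert sb.pair_id.nunique() == 9

    def test_flagged_rows_not_parsed(self):
        df = load_numt_matches()
        bad = df[df.status != "ok"]
        assert set(bad.status) == {
            "unparseable_position", "inconsistent_position",
            "undefined_symbol", "incomplete",
        }
        assert df.loc[df.status == "unparseable_position", "start"].isna().all()


class TestFasta:
    def test_round_trip(self, tmp_path):
        recs = [
            SequenceRecord("mt1", "ACGTACGTAA", "circular"),
            SequenceRecord("chr1", "TTTTACGT", "linear"),
        ]
        path = tmp_path / "x.fasta"
        write_fasta(recs, path)
        back = read_fasta(path)
        assert [(r.id, r.sequence, r.topology) for r in back] == [
            (r.id, r.sequence, r.topology) for r in recs
        ]

    def test_lowercase_normalised(self, tmp_path):
        path = tmp_path / "lc.fasta"
        path.write_text(">a\nacgtn\n")
        (rec,) = read_fasta(path)
        assert rec.sequence == "ACGTN"

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(SequenceParseError):
            read_fasta(path)


class TestSequenceRecord:
    def test_circular_fetch_wraps(self):
        rec = SequenceRecord("c", "ACGTACGTTT", "circular")
        assert rec.fetch(9, 2) == "TTAC"
        assert rec.fetch(1, 4) == "ACGT"

    def test_linear_fetch_rejects_wrap(self):
        rec = SequenceRecord("l", "ACGTACGTTT", "linear")
        with pytest.raises(CoordinateError):
            rec.fetch(9, 2)
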
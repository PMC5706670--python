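"""SAM dialect parsing, round trips, and pileup correctness."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctcseq.alignments import (
    AlignedReadRecord,
    SamFormatError,
    build_pileup,
    parse_cigar,
    read_sam,
    write_sam,
)

LENGTHS = {"G1": 200, "G2": 300}


def _sam(body_lines):
    head = ["@HD\tVN:1.6\tSO:unknown", "@SQ\tSN:G1\tLN:200", "@SQ\tSN:G2\tLN:300"]
    return io.StringIO("\n".join(head + body_lines) + "\n")


def _line(qname="r1", flag=65, rname="G1", pos=101, cigar="75M", seq=None):
    seq = seq if seq is not None else "A" * 75
    return f"{qname}\t{flag}\t{rname}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\tRG:Z:c1"


def test_pos_converted_to_zero_based():
    (rec,) = read_sam(_sam([_line(pos=101, cigar="75M")]))
    assert rec.start == 100
    assert rec.segments == (("M", 75),)
    assert rec.cell_id == "c1"


def test_cigar_with_deletion_parsed_and_spanned():
    (rec,) = read_sam(_sam([_line(pos=2, cigar="20M5D50M", seq="C" * 70)]))
    assert rec.segments == (("M", 20), ("D", 5), ("M", 50))
    assert rec.reference_span == 75
    assert rec.deletion_intervals() == [(21, 26)]


@pytest.mark.parametrize("cigar", ["30M10N35M", "75X", "5I70M", "75"])
def test_unsupported_cigar_is_parse_error(cigar):
    with pytest.raises(SamFormatError, match="r1"):
        read_sam(_sam([_line(cigar=cigar, seq="A" * 75)]))


def test_pos_beyond_reference_is_error():
    with pytest.raises(SamFormatError):
        read_sam(_sam([_line(pos=180, cigar="75M")]))


def test_unmapped_records_skipped():
    assert read_sam(_sam([_line(flag=69)])) == []


def test_write_read_round_trip_is_field_identical():
    records = [
        AlignedReadRecord("r1", "cellX", "G1", 5, (("M", 10), ("D", 4), ("M", 6)), 1, "ACGTACGTACGTACGT"),
        AlignedReadRecord("r1", "cellX", "G1", 60, (("S", 3), ("M", 13)), 2, "ACGTACGTACGTACGT"),
        AlignedReadRecord("r2", "cellX", "G2", 0, (("M", 20),), 1, "A" * 20),
    ]
    buf = io.StringIO()
    write_sam(records, LENGTHS, buf, cell_id="cellX")
    assert read_sam(io.StringIO(buf.getvalue())) == records


def test_written_sam_parses_with_pysam(tmp_path):
    pysam = pytest.importorskip("pysam")
    records = [
        AlignedReadRecord("r1", "c1", "G1", 5, (("M", 10), ("D", 4), ("M", 6)), 1, "A" * 16),
        AlignedReadRecord("r1", "c1", "G1", 30, (("M", 16),), 2, "C" * 16),
    ]
    path = tmp_path / "x.sam"
    with open(path, "w") as fh:
        write_sam(records, LENGTHS, fh, cell_id="c1")
    with pysam.AlignmentFile(str(path), "r") as af:
        got = list(af)
    assert [(r.query_name, r.reference_start, r.cigarstring) for r in got] == [
        ("r1", 5, "10M4D6M"),
        ("r1", 30, "16M"),
    ]


# ---------------------------------------------------------------- pileups

def _col_map(cols):
    return {c.position: c for c in cols}


def test_pileup_single_read_direct_mapping():
    rec = AlignedReadRecord("r", "c", "G1", 10, (("M", 3),), 1, "ACG")
    cols = _col_map(build_pileup([rec], "G1"))
    assert set(cols) == {10, 11, 12}
    assert cols[10].base_counts["A"] == 1
    assert cols[11].base_counts["C"] == 1
    assert cols[12].base_counts["G"] == 1


def test_pileup_overlap_additivity():
    recs = [
        AlignedReadRecord("r1", "c", "G1", 0, (("M", 3),), 1, "AAA"),
        AlignedReadRecord("r2", "c", "G1", 2, (("M", 3),), 1, "GGG"),
    ]
    cols = _col_map(build_pileup(recs, "G1"))
    assert cols[2].base_counts == {"A": 1, "C": 0, "G": 1, "T": 0}
    assert cols[2].depth == 2


def test_pileup_gap_semantics():
    rec = AlignedReadRecord("r", "c", "G1", 0, (("M", 2), ("D", 3), ("M", 2)), 1, "AAAA")
    cols = _col_map(build_pileup([rec], "G1"))
    for p in (2, 3, 4):
        assert cols[p].deletion_count == 1
        assert cols[p].depth == 0
    assert cols[0].depth == cols[6].depth == 1


def _brute_force_pileup(records, gene_id):
    """Independent per-read per-base enumeration."""
    bases, dels = {}, {}
    for rec in records:
        if rec.gene_id != gene_id:
            continue
        ref, q = rec.start, 0
        for op, ln in rec.segments:
            if op == "M":
                for k in range(ln):
                    bases.setdefault(ref + k, []).append(rec.seq[q + k])
                ref += ln
                q += ln
            elif op == "D":
                for k in range(ln):
                    dels[ref + k] = dels.get(ref + k, 0) + 1
                ref += ln
            else:
                q += ln
    out = {}
    for p in set(bases) | set(dels):
        counts = {b: bases.get(p, []).count(b) for b in "ACGT"}
        out[p] = (counts, dels.get(p, 0))
    return out


@st.composite
def read_batches(draw):
    n = draw(st.integers(1, 50))
    recs = []
    for i in range(n):
        start = draw(st.integers(0, 150))
        segs = []
        has_m = False
        for _ in range(draw(st.integers(1, 3))):
            op = draw(st.sampled_from("MDS"))
            ln = draw(st.integers(1, 12))
            segs.append((op, ln))
            has_m = has_m or op == "M"
        if not has_m:
            segs.append(("M", draw(st.integers(1, 12))))
        span = sum(ln for op, ln in segs if op in "MD")
        if start + span > 200:
            start = 200 - span
        qlen = sum(ln for op, ln in segs if op in "MS")
        seq = "".join(draw(st.sampled_from("ACGT")) for _ in range(qlen))
        recs.append(AlignedReadRecord(f"r{i}", "c", "G1", max(start, 0), tuple(segs), 1, seq))
    return recs


@given(read_batches())
def test_pileup_matches_brute_force_enumeration(records):
    cols = _col_map(build_pileup(records, "G1"))
    oracle = _brute_force_pileup(records, "G1")
    assert set(cols) == set(oracle)
    for p, (counts, ndel) in oracle.items():
        assert cols[p].base_counts == counts
        assert cols[p].deletion_count == ndel


@given(read_batches())
def test_pileup_depth_conserves_match_lengths(records):
    cols = build_pileup(records, "G1")
    total_depth = sum(c.depth for c in cols)
    total_match = sum(
        ln for r in records for op, ln in r.segments if op == "M"
    )
    assert total_depth == total_match


def test_empty_input_gives_empty_pileup():
    assert build_pileup([], "G1") == []
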
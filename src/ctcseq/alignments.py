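"""Minimal SAM dialect I/O and per-gene pileups with deletion tracking.

The dialect is deliberately narrow: headers carry @SQ (and optionally @RG)
lines; alignment records use FLAG only for mate pairing, 1-based POS, and
CIGAR restricted to M (aligned match), D (reference deletion) and S
(soft-clip). Anything else is a parse error — the simulator never emits it,
and silently accepting wider SAM would let unsupported semantics (splices,
insertions) slip through the variant counters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_CIGAR_RE = re.compile(r"(\d+)([A-Z=])")

# query-consuming / reference-consuming ops of the dialect
_ALLOWED_OPS = {"M", "D", "S"}

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


class SamFormatError(ValueError):
    """Raised on SAM records outside the supported dialect."""


@dataclass(frozen=True)
class AlignedReadRecord:
    """One aligned read on a transcript, 0-based start.

    ``segments`` is the parsed CIGAR: ordered (op, length) pairs with op in
    {"M", "D", "S"}. ``seq`` holds the query bases (soft-clipped bases
    included). Mates of one fragment share ``read_id`` and differ in
    ``mate_flag`` (1 or 2).
    """

    read_id: str
    cell_id: str
    gene_id: str
    start: int
    segments: tuple[tuple[str, int], ...]
    mate_flag: int = 1
    seq: str = ""

    def __post_init__(self):
        if not any(op == "M" for op, _ in self.segments):
            raise SamFormatError(f"read {self.read_id}: no aligned (M) segment")
        for op, ln in self.segments:
            if op not in _ALLOWED_OPS:
                raise SamFormatError(f"read {self.read_id}: unsupported CIGAR op {op}")
            if ln < 1:
                raise SamFormatError(f"read {self.read_id}: non-positive segment length")

    @property
    def reference_span(self) -> int:
        """Reference bases consumed (M + D)."""
        return sum(ln for op, ln in self.segments if op in ("M", "D"))

    @property
    def end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.start + self.reference_span

    @property
    def cigar(self) -> str:
        return "".join(f"{ln}{op}" for op, ln in self.segments)

    def deletion_intervals(self) -> list[tuple[int, int]]:
        """Reference intervals [start, end) covered by D segments."""
        out, ref = [], self.start
        for op, ln in self.segments:
            if op == "D":
                out.append((ref, ref + ln))
            if op in ("M", "D"):
                ref += ln
        return out


@dataclass
class PileupColumn:
    """Per-position base tally; deletion-spanning reads counted separately."""

    gene_id: str
    position: int
    base_counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in "ACGT"})
    deletion_count: int = 0

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


# --------------------------------------------------------------------- SAM IO

def parse_cigar(cigar: str, read_id: str = "?") -> tuple[tuple[str, int], ...]:
    if cigar == "*" or not cigar:
        raise SamFormatError(f"read {read_id}: missing CIGAR")
    segs, consumed = [], 0
    for m in _CIGAR_RE.finditer(cigar):
        ln, op = int(m.group(1)), m.group(2)
        if op not in _ALLOWED_OPS:
            raise SamFormatError(f"read {read_id}: unsupported CIGAR op {op!r} in {cigar}")
        segs.append((op, ln))
        consumed += len(m.group(0))
    if consumed != len(cigar):
        raise SamFormatError(f"read {read_id}: malformed CIGAR {cigar!r}")
    return tuple(segs)


def read_sam(stream, default_cell_id: str = "") -> list[AlignedReadRecord]:
    """Parse dialect SAM text into records (POS converted to 0-based).

    ``stream`` is an open text file or an iterable of lines. Unmapped records
    (FLAG 0x4) are skipped; order is otherwise preserved. Cell identity comes
    from the record's RG:Z tag, falling back to the single @RG header ID, then
    to ``default_cell_id``.
    """
    lengths: dict[str, int] = {}
    header_rg = default_cell_id
    records: list[AlignedReadRecord] = []
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("@"):
            fields = line.split("\t")
            if fields[0] == "@SQ":
                tags = dict(f.split(":", 1) for f in fields[1:])
                lengths[tags["SN"]] = int(tags["LN"])
            elif fields[0] == "@RG":
                tags = dict(f.split(":", 1) for f in fields[1:])
                header_rg = tags.get("ID", header_rg)
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise SamFormatError(f"truncated SAM record: {line[:60]!r}")
        qname, flag, rname, pos, _mapq, cigar = fields[:6]
        seq = fields[9]
        flag = int(flag)
        if flag & 0x4:
            continue
        cell = header_rg
        for tag in fields[11:]:
            if tag.startswith("RG:Z:"):
                cell = tag[5:]
        segments = parse_cigar(cigar, qname)
        start = int(pos) - 1
        if rname not in lengths:
            raise SamFormatError(f"read {qname}: unknown reference {rname}")
        span = sum(ln for op, ln in segments if op in ("M", "D"))
        if start < 0 or start + span > lengths[rname]:
            raise SamFormatError(
                f"read {qname}: span [{start}, {start + span}) outside {rname} "
                f"(length {lengths[rname]})"
            )
        mate = 2 if (flag & 0x80) else 1
        records.append(
            AlignedReadRecord(
                read_id=qname,
                cell_id=cell,
                gene_id=rname,
                start=start,
                segments=segments,
                mate_flag=mate,
                seq="" if seq == "*" else seq,
            )
        )
    return records


def write_sam(records: Iterable[AlignedReadRecord], lengths: dict[str, int], stream,
              cell_id: str | None = None) -> None:
    """Write dialect SAM. ``lengths`` maps gene_id -> transcript length.

    If ``cell_id`` is given a single @RG header line is emitted and records
    carry RG:Z tags; otherwise each record's own cell_id is tagged.
    """
    stream.write("@HD\tVN:1.6\tSO:unknown\n")
    for gid in lengths:
        stream.write(f"@SQ\tSN:{gid}\tLN:{lengths[gid]}\n")
    if cell_id is not None:
        stream.write(f"@RG\tID:{cell_id}\tSM:{cell_id}\n")
    for rec in records:
        flag = 0x1 | (0x40 if rec.mate_flag == 1 else 0x80)
        rg = cell_id if cell_id is not None else rec.cell_id
        stream.write(
            "\t".join(
                [
                    rec.read_id,
                    str(flag),
                    rec.gene_id,
                    str(rec.start + 1),
                    "60",
                    rec.cigar,
                    "*",
                    "0",
                    "0",
                    rec.seq or "*",
                    "*",
                    f"RG:Z:{rg}",
                ]
            )
            + "\n"
        )


# --------------------------------------------------------------------- pileup

def build_pileup(
    records: Sequence[AlignedReadRecord],
    gene_id: str,
    cell_filter: str | None = None,
) -> list[PileupColumn]:
    """Tally bases and deletion-spanning reads per position of one gene.

    Returns columns for touched positions only, sorted by position; untouched
    positions are implicitly depth 0. Soft-clips consume query bases but no
    reference and never contribute counts. Deletion segments add to
    ``deletion_count`` at each spanned position and contribute nothing to
    depth. Non-ACGT query bases are skipped.
    """
    pos_chunks: list[np.ndarray] = []
    code_chunks: list[np.ndarray] = []
    del_chunks: list[np.ndarray] = []
    for rec in records:
        if rec.gene_id != gene_id:
            continue
        if cell_filter is not None and rec.cell_id != cell_filter:
            continue
        ref, qoff = rec.start, 0
        seq_codes = _BASE_CODE[np.frombuffer(rec.seq.encode(), dtype=np.uint8)]
        for op, ln in rec.segments:
            if op == "M":
                codes = seq_codes[qoff : qoff + ln]
                if len(codes) != ln:
                    raise SamFormatError(
                        f"read {rec.read_id}: SEQ shorter than CIGAR query length"
                    )
                pos_chunks.append(np.arange(ref, ref + ln))
                code_chunks.append(codes)
                ref += ln
                qoff += ln
            elif op == "D":
                del_chunks.append(np.arange(ref, ref + ln))
                ref += ln
            else:  # S
                qoff += ln

    if not pos_chunks and not del_chunks:
        return []
    positions = np.concatenate(pos_chunks) if pos_chunks else np.empty(0, dtype=int)
    codes = np.concatenate(code_chunks) if code_chunks else np.empty(0, dtype=np.int8)
    dels = np.concatenate(del_chunks) if del_chunks else np.empty(0, dtype=int)
    keep = codes >= 0
    positions, codes = positions[keep], codes[keep]

    max_pos = int(max(positions.max(initial=-1), dels.max(initial=-1)))
    counts = np.zeros((max_pos + 1, 4), dtype=np.int64)
    np.add.at(counts, (positions, codes.astype(np.int64)), 1)
    del_counts = np.bincount(dels, minlength=max_pos + 1).astype(np.int64)

    touched = np.flatnonzero(counts.sum(axis=1) + del_counts)
    columns = []
    for p in touched:
        columns.append(
            PileupColumn(
                gene_id=gene_id,
                position=int(p),
                base_counts={b: int(counts[p, i]) for i, b in enumerate("ACGT")},
                deletion_count=int(del_counts[p]),
            )
        )
    return columns


def pileup_by_position(columns: Sequence[PileupColumn]) -> dict[int, PileupColumn]:
    return {c.position: c for c in columns}


def pileup_table(columns: Sequence[PileupColumn]):
    """Export columns as a tab-separable DataFrame (gene, pos, A, C, G, T, del, depth)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene": [c.gene_id for c in columns],
            "pos": [c.position for c in columns],
            **{b: [c.base_counts[b] for c in columns] for b in "ACGT"},
            "del": [c.deletion_count for c in columns],
            "depth": [c.depth for c in columns],
        }
    )
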
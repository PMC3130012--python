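"""Readers and writers for the toolkit's on-disk formats.

Supported formats: 9-column AGP, a TPF dialect (ordered component
accessions with optional gap rows), FASTA (via Biopython), a placements
TSV carrying block alignments of alternate/patch scaffolds onto primary
chromosomes, and the curation-issue TSV.

All readers normalise line endings to ``\\n`` and strip trailing
whitespace; writers never emit trailing whitespace.  ``write(read(x))``
is byte-identical for canonical files and ``read(write(y))`` reproduces
``y`` exactly.
"""
from __future__ import annotations

import logging
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AGPRow,
    ComponentRef,
    GAP_KINDS,
    GapSpec,
    PlacementRecord,
    TilingPath,
    TilingPathRow,
)

log = logging.getLogger("refasm")

__all__ = [
    "ParseError",
    "read_agp",
    "write_agp",
    "read_tpf",
    "write_tpf",
    "read_fasta",
    "write_fasta",
    "read_placements",
    "write_placements",
    "read_issues",
    "write_issues",
]


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _as_stream(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return open(source, "r", encoding="ascii", newline=None)
    return source


def _lines(stream: TextIO) -> Iterable[tuple[int, str]]:
    # keep tabs: a trailing tab delimits an empty final column
    for i, raw in enumerate(stream, start=1):
        yield i, raw.rstrip("\r\n ")


# ---------------------------------------------------------------- AGP

_GAP_CODES = {"N", "U"}
_COMPONENT_CODES = {"W", "F", "A", "D", "O", "P"}


def read_agp(source: Union[str, TextIO]) -> dict[str, list[AGPRow]]:
    """Parse an AGP file into ``{object_name: [AGPRow, ...]}``.

    All non-gap component codes (W/F/A/D/O/P) are treated uniformly as
    component rows; N and U are gaps (U means unknown size).  Orientation
    tokens ``?``, ``0`` and ``na`` are mapped to ``+`` with a warning.
    """
    objects: dict[str, list[AGPRow]] = {}
    with _maybe_close(source) as stream:
        for lineno, line in _lines(stream):
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"expected 9 tab-separated columns, got {len(fields)}", lineno)
            obj, beg_s, end_s, part_s, code = fields[:5]
            try:
                beg, end, part = int(beg_s), int(end_s), int(part_s)
            except ValueError:
                raise ParseError(f"non-integer coordinate in {fields[1:4]}", lineno) from None
            if code in _GAP_CODES:
                try:
                    gap_len = int(fields[5])
                except ValueError:
                    raise ParseError(f"non-integer gap length {fields[5]!r}", lineno) from None
                gap_kind = fields[6]
                if gap_kind not in GAP_KINDS:
                    log.warning("line %d: gap kind %r treated as scaffold-break", lineno, gap_kind)
                    gap_kind = "scaffold-break"
                row = AGPRow(
                    object_name=obj,
                    object_beg=beg,
                    object_end=end,
                    part_number=part,
                    row_kind="gap",
                    gap_length=None if code == "U" else gap_len,
                    gap_kind=gap_kind,
                    linkage=fields[7] == "yes",
                )
            elif code in _COMPONENT_CODES:
                try:
                    cbeg, cend = int(fields[6]), int(fields[7])
                except ValueError:
                    raise ParseError(
                        f"non-integer component coordinates {fields[6:8]}", lineno
                    ) from None
                ori = fields[8]
                if ori in ("?", "0", "na"):
                    log.warning("line %d: orientation %r mapped to '+'", lineno, ori)
                    ori = "+"
                if ori not in ("+", "-"):
                    raise ParseError(f"bad orientation {fields[8]!r}", lineno)
                row = AGPRow(
                    object_name=obj,
                    object_beg=beg,
                    object_end=end,
                    part_number=part,
                    row_kind="component",
                    component_id=fields[5],
                    component_beg=cbeg,
                    component_end=cend,
                    orientation=ori,
                )
            else:
                raise ParseError(f"unknown AGP row code {code!r}", lineno)
            objects.setdefault(obj, []).append(row)
    return objects


def write_agp(objects: dict[str, list[AGPRow]], stream: TextIO, header: str | None = None) -> None:
    """Write objects as canonical AGP (component code W, gap codes N/U)."""
    if header:
        for line in header.splitlines():
            stream.write(f"# {line}\n" if not line.startswith("#") else line + "\n")
    for rows in objects.values():
        for r in rows:
            if r.is_gap:
                code = "U" if r.gap_length is None else "N"
                length = r.span if r.gap_length is None else r.gap_length
                fields = [
                    r.object_name, str(r.object_beg), str(r.object_end), str(r.part_number),
                    code, str(length), r.gap_kind or "contig",
                    "yes" if r.linkage else "no", "na",
                ]
            else:
                fields = [
                    r.object_name, str(r.object_beg), str(r.object_end), str(r.part_number),
                    "W", r.component_id, str(r.component_beg), str(r.component_end),
                    r.orientation,
                ]
            stream.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------- TPF

def read_tpf(source: Union[str, TextIO]) -> list[TilingPath]:
    """Parse a TPF into tiling paths, one per object, in file order.

    Component rows: ``accession<TAB>object<TAB>orientation``.
    Gap rows: ``GAP<TAB>object<TAB>kind[<TAB>length]`` (omitted length
    means unknown size).  A component may appear only once per path.
    """
    paths: dict[str, list[TilingPathRow]] = {}
    seen: dict[str, set[str]] = {}
    lengths: dict[str, int] = {}
    with _maybe_close(source) as stream:
        for lineno, line in _lines(stream):
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "GAP":
                if len(fields) not in (3, 4):
                    raise ParseError("GAP rows take 3 or 4 columns", lineno)
                obj, kind = fields[1], fields[2]
                if kind not in GAP_KINDS:
                    log.warning("line %d: gap kind %r treated as scaffold-break", lineno, kind)
                    kind = "scaffold-break"
                size = None
                if len(fields) == 4 and fields[3] not in ("", "unknown"):
                    try:
                        size = int(fields[3])
                    except ValueError:
                        raise ParseError(f"non-integer gap size {fields[3]!r}", lineno) from None
                order = len(paths.setdefault(obj, [])) + 1
                paths[obj].append(
                    TilingPathRow(GapSpec(size, kind), orientation=None, local_order=order)
                )
            else:
                if len(fields) != 3:
                    raise ParseError(f"expected 3 columns, got {len(fields)}", lineno)
                acc, obj, ori = fields
                if ori not in ("+", "-"):
                    raise ParseError(f"bad orientation {ori!r}", lineno)
                if acc in seen.setdefault(obj, set()):
                    raise ParseError(f"component {acc} appears twice in path {obj}", lineno)
                seen[obj].add(acc)
                order = len(paths.setdefault(obj, [])) + 1
                # component length unknown at parse time; fill a
                # placeholder of 1 and let the builder attach real lengths
                paths[obj].append(
                    TilingPathRow(ComponentRef(acc, 1), orientation=ori, local_order=order)
                )
    return [TilingPath(obj, rows) for obj, rows in paths.items()]


def write_tpf(paths: list[TilingPath], stream: TextIO) -> None:
    for path in paths:
        for row in path.rows:
            if row.is_gap:
                gap = row.entry
                fields = ["GAP", path.object_name, gap.gap_kind]
                if gap.gap_length is not None:
                    fields.append(str(gap.gap_length))
                stream.write("\t".join(fields) + "\n")
            else:
                stream.write(
                    "\t".join([row.entry.accession, path.object_name, row.orientation]) + "\n"
                )


# ---------------------------------------------------------------- FASTA

def read_fasta(source: Union[str, TextIO]) -> dict[str, str]:
    """Read FASTA into an ordered ``{name: sequence}`` dict.

    Duplicate names are an error; case is preserved as read.
    """
    seqs: dict[str, str] = {}
    with _maybe_close(source) as stream:
        for record in SeqIO.parse(stream, "fasta"):
            if record.id in seqs:
                raise ValueError(f"duplicate sequence name {record.id!r}")
            seqs[record.id] = str(record.seq)
    return seqs


def write_fasta(seqs: dict[str, str], stream: TextIO, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    writer = SeqIO.FastaIO.FastaWriter(stream, wrap=width)
    writer.write_file(records)


# ---------------------------------------------------------------- placements

_PLACEMENT_HEADER = (
    "#alt_scaffold\talt_start\talt_stop\tparent_chromosome\t"
    "parent_start\tparent_stop\torientation\tblocks"
)


def _parse_blocks(text: str, lineno: int) -> list[tuple[int, int, int, int]]:
    blocks = []
    for part in text.split(";"):
        if not part:
            continue
        try:
            alt, parent = part.split(":")
            a1, a2 = (int(x) for x in alt.split("-"))
            p1, p2 = (int(x) for x in parent.split("-"))
        except ValueError:
            raise ParseError(f"malformed block {part!r}", lineno) from None
        blocks.append((a1, a2, p1, p2))
    return blocks


def read_placements(source: Union[str, TextIO]) -> list[PlacementRecord]:
    records = []
    with _maybe_close(source) as stream:
        for lineno, line in _lines(stream):
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(f"expected 8 columns, got {len(fields)}", lineno)
            try:
                rec = PlacementRecord(
                    alt_scaffold_name=fields[0],
                    alt_start=int(fields[1]),
                    alt_stop=int(fields[2]),
                    parent_chromosome=fields[3],
                    parent_start=int(fields[4]),
                    parent_stop=int(fields[5]),
                    orientation=fields[6],
                    blocks=_parse_blocks(fields[7], lineno),
                )
            except ValueError as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(str(exc), lineno) from None
            records.append(rec)
    return records


def write_placements(records: list[PlacementRecord], stream: TextIO,
                     header_comment: str | None = None) -> None:
    if header_comment:
        stream.write(f"# {header_comment}\n")
    stream.write(_PLACEMENT_HEADER + "\n")
    for rec in records:
        blocks = ";".join(f"{a1}-{a2}:{p1}-{p2}" for a1, a2, p1, p2 in rec.blocks)
        stream.write(
            "\t".join(
                [
                    rec.alt_scaffold_name,
                    str(rec.alt_start),
                    str(rec.alt_stop),
                    rec.parent_chromosome,
                    str(rec.parent_start),
                    str(rec.parent_stop),
                    rec.orientation,
                    blocks,
                ]
            )
            + "\n"
        )


# ---------------------------------------------------------------- issues

_ISSUE_HEADER = "#issue_id\tissue_type\tstatus\tchromosome\tstart\tstop\tresolution_release"


def read_issues(source: Union[str, TextIO]):
    """Read the curation-issue TSV into a list of Issue objects."""
    from .release import Issue  # local import avoids a cycle

    issues = []
    with _maybe_close(source) as stream:
        for lineno, line in _lines(stream):
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(f"expected 7 columns, got {len(fields)}", lineno)
            from .model import ReleaseVersion

            try:
                issue = Issue(
                    issue_id=fields[0],
                    issue_type=fields[1],
                    status=fields[2],
                    chromosome=fields[3] or None,
                    start=int(fields[4]) if fields[4] else None,
                    stop=int(fields[5]) if fields[5] else None,
                    resolution_release=(
                        ReleaseVersion.parse(fields[6]) if fields[6] else None
                    ),
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            issues.append(issue)
    return issues


def write_issues(issues, stream: TextIO) -> None:
    stream.write(_ISSUE_HEADER + "\n")
    for it in issues:
        stream.write(
            "\t".join(
                [
                    it.issue_id,
                    it.issue_type,
                    it.status,
                    it.chromosome or "",
                    str(it.start) if it.start is not None else "",
                    str(it.stop) if it.stop is not None else "",
                    str(it.resolution_release) if it.resolution_release else "",
                ]
            )
            + "\n"
        )


class _maybe_close:
    """Context manager opening paths and passing streams through unclosed."""

    def __init__(self, source: Union[str, TextIO]):
        self._source = source
        self._opened = False

    def __enter__(self) -> TextIO:
        if isinstance(self._source, str):
            self._opened = True
            self._stream = open(self._source, "r", encoding="ascii", newline=None)
        else:
            self._stream = self._source
        return self._stream

    def __exit__(self, *exc) -> None:
        if self._opened:
            self._stream.close()
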
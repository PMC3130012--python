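"""Build contigs/scaffolds from tiling paths.

A tiling path (TPF) orders overlapping components; the builder detects
the dovetail overlap between each adjacent pair, chooses a switch point
inside it, and emits AGP rows whose spans abut at the switch points so no
overlap sequence is duplicated — the non-redundant path through the
components.  There must be at least one switch point between adjacent
components in a contig; here there is exactly one per junction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    AGPRow,
    Assembly,
    AssembledObject,
    SwitchPoint,
    TilingPath,
    validate_agp_object,
)

__all__ = [
    "OverlapCall",
    "BuildError",
    "BuildResult",
    "find_overlap",
    "select_switch_point",
    "tpf_to_agp",
    "build_object_sequence",
    "provenance_map",
    "assembly_stats",
    "reverse_complement",
    "DEFAULT_MIN_OVERLAP",
    "DEFAULT_MIN_IDENTITY",
]

DEFAULT_MIN_OVERLAP = 20
DEFAULT_MIN_IDENTITY = 0.97

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class OverlapCall:
    """A verified suffix(left)/prefix(right) dovetail overlap.

    Spans are 1-based inclusive in each component's oriented sequence;
    both spans have the same length (the overlap model is
    substitution-only).  ``mismatch_offsets`` are 0-based offsets of
    mismatching columns within the overlap.
    """

    left_span: tuple[int, int]
    right_span: tuple[int, int]
    identity: float
    mismatch_offsets: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return self.left_span[1] - self.left_span[0] + 1


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_overlap(
    left_seq: str,
    right_seq: str,
    min_len: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> Optional[OverlapCall]:
    """Find the best dovetail overlap between two oriented sequences.

    Every candidate overlap length from ``min_len`` up to the shorter
    sequence is scored by exact column identity (the scan is exhaustive,
    so the result is the true optimum under the substitution-only overlap
    model).  Returns the highest-identity qualifying overlap, longest on
    ties, or ``None`` when nothing reaches ``min_identity``.
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    if not (0.9 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0.9, 1]")
    la, ra = _to_array(left_seq), _to_array(right_seq)
    max_len = min(len(la), len(ra))
    best: Optional[tuple[int, int]] = None  # (matches, length)
    for ell in range(min_len, max_len + 1):
        matches = int((la[-ell:] == ra[:ell]).sum())
        if matches < min_identity * ell:
            continue
        if best is None or matches * best[1] > best[0] * ell or (
            matches * best[1] == best[0] * ell and ell > best[1]
        ):
            best = (matches, ell)
    if best is None:
        return None
    matches, ell = best
    eq = la[-ell:] == ra[:ell]
    mism = tuple(int(i) for i in np.flatnonzero(~eq))
    return OverlapCall(
        left_span=(len(la) - ell + 1, len(la)),
        right_span=(1, ell),
        identity=matches / ell,
        mismatch_offsets=mism,
    )


def select_switch_point(
    overlap: OverlapCall, left_accession: str = "left", right_accession: str = "right"
) -> SwitchPoint:
    """Choose the switch point: midpoint of the longest exact-match run
    inside the overlap (leftmost run on ties, floor midpoint).

    Positions are reported in each component's oriented coordinates.
    """
    ell = overlap.length
    boundaries = [-1, *overlap.mismatch_offsets, ell]
    best_run: Optional[tuple[int, int]] = None  # 0-based [start, end] inclusive
    for lo, hi in zip(boundaries, boundaries[1:]):
        start, end = lo + 1, hi - 1
        if end < start:
            continue
        if best_run is None or (end - start) > (best_run[1] - best_run[0]):
            best_run = (start, end)
    if best_run is None:
        raise BuildError("overlap has no exact-match run to switch in")
    mid = (best_run[0] + best_run[1] + 2) // 2  # 1-based within overlap, floor midpoint
    return SwitchPoint(
        from_accession=left_accession,
        to_accession=right_accession,
        position_in_from=overlap.left_span[0] + mid - 1,
        position_in_to=overlap.right_span[0] + mid - 1,
    )


@dataclass
class BuildResult:
    object: AssembledObject
    switch_points: list[SwitchPoint] = field(default_factory=list)
    overlaps: list[OverlapCall] = field(default_factory=list)


def tpf_to_agp(
    tiling_path: TilingPath,
    component_seqs: dict[str, str],
    min_len: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> BuildResult:
    """Turn a tiling path plus component sequences into an AGP object.

    Adjacent components (no gap row between them) must share a dovetail
    overlap; each junction gets one switch point and the emitted component
    spans abut there, so every overlap base is represented exactly once.
    Gap rows pass through with their declared (or conventional unknown)
    length.
    """
    rows = tiling_path.rows
    if not rows:
        raise BuildError(f"tiling path {tiling_path.object_name} is empty")
    if rows[0].is_gap or rows[-1].is_gap:
        raise BuildError(f"tiling path {tiling_path.object_name} starts or ends with a gap")

    oriented: dict[int, str] = {}
    for i, row in enumerate(rows):
        if row.is_gap:
            continue
        acc = row.entry.accession
        if acc not in component_seqs:
            raise BuildError(f"missing sequence for component {acc}")
        seq = component_seqs[acc]
        oriented[i] = seq if row.orientation == "+" else reverse_complement(seq)

    # contributed oriented span per component row, trimmed at switch points
    spans = {i: [1, len(oriented[i])] for i in oriented}
    switches: list[SwitchPoint] = []
    overlaps: list[OverlapCall] = []
    for i, j in zip(range(len(rows)), range(1, len(rows))):
        if rows[i].is_gap or rows[j].is_gap:
            continue
        left_acc, right_acc = rows[i].entry.accession, rows[j].entry.accession
        ov = find_overlap(oriented[i], oriented[j], min_len, min_identity)
        if ov is None:
            raise BuildError(
                f"components {left_acc} and {right_acc} share no qualifying overlap; "
                "insert a gap row between them if they are not contiguous"
            )
        sp = select_switch_point(ov, left_acc, right_acc)
        spans[i][1] = sp.position_in_from
        spans[j][0] = sp.position_in_to + 1
        if spans[i][1] < spans[i][0]:
            raise BuildError(
                f"switch points collide inside component {left_acc}: "
                "overlaps with both neighbours intersect"
            )
        switches.append(sp)
        overlaps.append(ov)

    agp_rows: list[AGPRow] = []
    cursor = 1
    for i, row in enumerate(rows):
        part = len(agp_rows) + 1
        if row.is_gap:
            gap = row.entry
            length = gap.render_length
            agp_rows.append(
                AGPRow(
                    object_name=tiling_path.object_name,
                    object_beg=cursor,
                    object_end=cursor + length - 1,
                    part_number=part,
                    row_kind="gap",
                    gap_length=gap.gap_length,
                    gap_kind=gap.gap_kind,
                    linkage=gap.linkage,
                )
            )
            cursor += length
            continue
        s, e = spans[i]
        n = len(oriented[i])
        if row.orientation == "+":
            cbeg, cend = s, e
        else:
            cbeg, cend = n - e + 1, n - s + 1
        agp_rows.append(
            AGPRow(
                object_name=tiling_path.object_name,
                object_beg=cursor,
                object_end=cursor + (e - s),
                part_number=part,
                row_kind="component",
                component_id=row.entry.accession,
                component_beg=cbeg,
                component_end=cend,
                orientation=row.orientation,
            )
        )
        cursor += e - s + 1

    report = validate_agp_object(agp_rows)
    if report:
        raise BuildError(
            "internal error: built AGP fails validation: "
            + "; ".join(str(v) for v in report)
        )
    rank = "contig" if not any(r.is_gap for r in agp_rows) else "scaffold"
    obj = AssembledObject(name=tiling_path.object_name, rank=rank, rows=agp_rows)
    return BuildResult(object=obj, switch_points=switches, overlaps=overlaps)


def build_object_sequence(obj: AssembledObject, component_seqs: dict[str, str]) -> str:
    """Render the object sequence from its AGP rows.

    ``-`` rows contribute the reverse complement of the component span;
    gap rows contribute runs of N.
    """
    parts: list[str] = []
    for r in obj.rows:
        if r.is_gap:
            parts.append("N" * r.span)
            continue
        comp = component_seqs.get(r.component_id)
        if comp is None:
            raise BuildError(f"missing sequence for component {r.component_id}")
        if r.component_end > len(comp) or r.component_beg < 1:
            raise BuildError(
                f"component span {r.component_beg}-{r.component_end} outside "
                f"{r.component_id} (length {len(comp)})"
            )
        piece = comp[r.component_beg - 1 : r.component_end]
        parts.append(piece if r.orientation == "+" else reverse_complement(piece))
    return "".join(parts)


def provenance_map(obj: AssembledObject) -> list[tuple[str, Optional[int], Optional[str]]]:
    """Per-base provenance: for each object position (0-based list index),
    ``(component_id, component_position, strand)`` or ``("gap", None, None)``.
    Each object base comes from exactly one component base or one gap
    position when the AGP is valid.
    """
    out: list[tuple[str, Optional[int], Optional[str]]] = []
    for r in obj.rows:
        if r.is_gap:
            out.extend(("gap", None, None) for _ in range(r.span))
        elif r.orientation == "+":
            out.extend((r.component_id, p, "+") for p in range(r.component_beg, r.component_end + 1))
        else:
            out.extend((r.component_id, p, "-") for p in range(r.component_end, r.component_beg - 1, -1))
    return out


def assembly_stats(assembly: Assembly) -> dict[str, dict[str, int]]:
    """Per-unit totals: object count, total bp, gap row count, gap bp.

    The "total" entry is the sum over units.
    """
    stats: dict[str, dict[str, int]] = {}
    total = {"objects": 0, "total_bp": 0, "gap_count": 0, "gap_bp": 0}
    for unit in assembly.units.values():
        s = {"objects": 0, "total_bp": 0, "gap_count": 0, "gap_bp": 0}
        for obj in unit.members.values():
            s["objects"] += 1
            s["total_bp"] += obj.sequence_length
            s["gap_count"] += len(obj.gap_rows)
            s["gap_bp"] += sum(r.span for r in obj.gap_rows)
        stats[unit.unit_name] = s
        for k in total:
            total[k] += s[k]
    stats["total"] = total
    return stats
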
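"""Chromosome context for alternate loci and patches, via alignment.

Alternate-locus and patch scaffolds never receive chromosome coordinates
of their own; instead each is aligned to the span of the primary
chromosome it represents, and the resulting block alignment (a
:class:`~refasm.model.PlacementRecord`) is the bridge used for
coordinate liftover in both directions.

Placement is anchored: components shared between the alternate and the
primary tiling path pin down exact aligned blocks, and only the
inter-anchor segments (where the two haplotype paths genuinely differ)
are aligned with a sequence aligner.  Segment alignment is global
affine-gap alignment (match +1, mismatch −1, gap open −5, gap extend
−1) so that a structural difference shows up as one contiguous indel
rather than a scatter of coincidental single-base matches; the aligner
settings are written into the placement file header for provenance.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Align import PairwiseAligner

from .build import build_object_sequence
from .model import AssembledObject, PlacementRecord

__all__ = [
    "UnplaceableError",
    "LiftoverResult",
    "anchor_align",
    "placement_from_alignment",
    "liftover",
    "diff_blocks",
    "ALIGNER_DESCRIPTION",
]

ALIGNER_DESCRIPTION = (
    "global affine-gap alignment (match +1, mismatch -1, gap open -5, "
    "gap extend -1), anchored on shared components"
)


class UnplaceableError(ValueError):
    """The scaffold cannot be given chromosome context by anchoring."""


def _segment_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _segment_aligner()


def _aligned_blocks(
    alt_seg: str, parent_seg: str, alt_offset: int, parent_offset: int
) -> list[tuple[int, int, int, int]]:
    """Gapless aligned blocks of a global segment alignment.

    Offsets are 0-based positions of the segment start on each axis;
    returned coordinates are 1-based inclusive.
    """
    alignment = _ALIGNER.align(alt_seg, parent_seg)[0]
    alt_runs, parent_runs = alignment.aligned
    blocks: list[tuple[int, int, int, int]] = []
    for (a0, a1), (p0, p1) in zip(alt_runs, parent_runs):
        blocks.append(
            (
                alt_offset + int(a0) + 1,
                alt_offset + int(a1),
                parent_offset + int(p0) + 1,
                parent_offset + int(p1),
            )
        )
    return blocks


def _merge_blocks(blocks: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    merged: list[tuple[int, int, int, int]] = []
    for b in blocks:
        if merged and b[0] == merged[-1][1] + 1 and b[2] == merged[-1][3] + 1:
            prev = merged[-1]
            merged[-1] = (prev[0], b[1], prev[2], b[3])
        else:
            merged.append(b)
    return merged


def placement_from_alignment(
    alt_seq: str,
    parent_seq: str,
    alt_name: str,
    parent_chromosome: str,
    alt_offset: int = 0,
    parent_offset: int = 0,
) -> PlacementRecord:
    """Place an alt scaffold by direct global alignment (no anchors).

    Used when the whole alt sequence corresponds to the whole primary
    span, e.g. for synthetic patch scaffolds.  Offsets shift the reported
    coordinates when the aligned sequences are slices of larger objects.
    """
    blocks = _merge_blocks(_aligned_blocks(alt_seq, parent_seq, alt_offset, parent_offset))
    if not blocks:
        raise UnplaceableError(f"no aligned blocks between {alt_name} and {parent_chromosome}")
    return PlacementRecord(
        alt_scaffold_name=alt_name,
        alt_start=blocks[0][0],
        alt_stop=blocks[-1][1],
        parent_chromosome=parent_chromosome,
        parent_start=blocks[0][2],
        parent_stop=blocks[-1][3],
        orientation="+",
        blocks=blocks,
    )


def _component_to_object_map(obj: AssembledObject) -> dict[str, tuple]:
    """For each component of an object: (row, used component interval)."""
    out = {}
    for r in obj.rows:
        if not r.is_gap:
            out[r.component_id] = r
    return out


def _object_pos(row, comp_pos: int) -> int:
    """Map a component coordinate (within the used span) to object coords."""
    if row.orientation == "+":
        return row.object_beg + (comp_pos - row.component_beg)
    return row.object_beg + (row.component_end - comp_pos)


def anchor_align(
    alt_object: AssembledObject,
    primary_object: AssembledObject,
    component_seqs: dict[str, str],
    parent_chromosome: Optional[str] = None,
) -> PlacementRecord:
    """Place an alternate (or patch) scaffold onto its primary span.

    Components present in both tiling paths are anchors: the component
    interval used by both AGPs aligns exactly, base for base.  The
    first and last components of the alt path must be anchors, so the
    placement is pinned at both ends; the divergent sequence between
    anchors is globally aligned and split into gapless blocks.

    Raises :class:`UnplaceableError` when the paths share no usable
    anchors — such a scaffold stays unlocalized/unplaced.
    """
    parent_chromosome = parent_chromosome or primary_object.name
    alt_rows = _component_to_object_map(alt_object)
    pri_rows = _component_to_object_map(primary_object)
    shared = [cid for cid in alt_object.component_ids if cid in pri_rows]
    alt_comp_ids = alt_object.component_ids
    if not shared:
        raise UnplaceableError(
            f"{alt_object.name} and {primary_object.name} share no anchor components"
        )
    if alt_comp_ids[0] not in shared or alt_comp_ids[-1] not in shared:
        raise UnplaceableError(
            f"{alt_object.name} lacks a shared anchor component at each end"
        )

    anchor_blocks: list[tuple[int, int, int, int]] = []
    for cid in shared:
        ra, rp = alt_rows[cid], pri_rows[cid]
        if ra.orientation != rp.orientation:
            raise UnplaceableError(
                f"anchor {cid} used in opposite orientations; cannot anchor"
            )
        lo = max(ra.component_beg, rp.component_beg)
        hi = min(ra.component_end, rp.component_end)
        if hi < lo:
            continue  # disjoint usage; not a usable anchor
        a1, a2 = sorted((_object_pos(ra, lo), _object_pos(ra, hi)))
        p1, p2 = sorted((_object_pos(rp, lo), _object_pos(rp, hi)))
        anchor_blocks.append((a1, a2, p1, p2))
    if not anchor_blocks:
        raise UnplaceableError(f"{alt_object.name}: anchors share no component bases")
    anchor_blocks.sort()
    for prev, cur in zip(anchor_blocks, anchor_blocks[1:]):
        if cur[2] <= prev[3] or cur[0] <= prev[1]:
            raise UnplaceableError(
                f"{alt_object.name}: anchors are rearranged relative to the primary path"
            )

    alt_seq = build_object_sequence(alt_object, component_seqs)
    pri_seq = build_object_sequence(primary_object, component_seqs)

    blocks: list[tuple[int, int, int, int]] = []

    def align_segment(a_lo: int, a_hi: int, p_lo: int, p_hi: int) -> None:
        # 1-based inclusive segment bounds; either side may be empty
        if a_hi < a_lo or p_hi < p_lo:
            return  # pure indel between anchors: no aligned bases
        blocks.extend(
            _aligned_blocks(
                alt_seq[a_lo - 1 : a_hi], pri_seq[p_lo - 1 : p_hi], a_lo - 1, p_lo - 1
            )
        )

    first = anchor_blocks[0]
    if first[0] > 1 and first[2] > 1:
        align_segment(1, first[0] - 1, 1, first[2] - 1)
    for prev, cur in zip(anchor_blocks, anchor_blocks[1:]):
        blocks.append(prev)
        align_segment(prev[1] + 1, cur[0] - 1, prev[3] + 1, cur[2] - 1)
    blocks.append(anchor_blocks[-1])
    last = anchor_blocks[-1]
    if last[1] < len(alt_seq) and last[3] < len(pri_seq):
        align_segment(last[1] + 1, len(alt_seq), last[3] + 1, len(pri_seq))

    blocks = _merge_blocks(sorted(blocks))
    return PlacementRecord(
        alt_scaffold_name=alt_object.name,
        alt_start=blocks[0][0],
        alt_stop=blocks[-1][1],
        parent_chromosome=parent_chromosome,
        parent_start=blocks[0][2],
        parent_stop=blocks[-1][3],
        orientation="+",
        blocks=blocks,
    )


@dataclass(frozen=True)
class LiftoverResult:
    """Outcome of a liftover query.

    ``mapped`` is the target-axis position, or ``None`` when the query
    falls in an indel between aligned blocks; then ``flanks`` carries the
    nearest mapped target-axis positions on each side (either may be
    ``None`` at the placement edge).
    """

    mapped: Optional[int]
    flanks: Optional[tuple[Optional[int], Optional[int]]] = None

    @property
    def is_mapped(self) -> bool:
        return self.mapped is not None


def liftover(placement: PlacementRecord, position: int, direction: str) -> LiftoverResult:
    """Map a position across a placement.

    ``direction`` is ``"alt->primary"`` or ``"primary->alt"``.  Inside an
    aligned block the mapping is an exact offset; between blocks the
    query sits in an indel and the nearest flanking mapped positions are
    reported instead.  Positions outside the placement span raise
    ``ValueError``.
    """
    if direction == "alt->primary":
        src = lambda b: (b[0], b[1])
        dst = lambda b: (b[2], b[3])
        span = (placement.alt_start, placement.alt_stop)
    elif direction == "primary->alt":
        src = lambda b: (b[2], b[3])
        dst = lambda b: (b[0], b[1])
        span = (placement.parent_start, placement.parent_stop)
    else:
        raise ValueError(f"unknown liftover direction {direction!r}")
    if not (span[0] <= position <= span[1]):
        raise ValueError(
            f"position {position} outside placement span {span[0]}-{span[1]} "
            f"({placement.alt_scaffold_name}, {direction})"
        )
    left_flank: Optional[int] = None
    for b in placement.blocks:
        s1, s2 = src(b)
        d1, d2 = dst(b)
        if position < s1:
            return LiftoverResult(None, (left_flank, d1))
        if position <= s2:
            return LiftoverResult(d1 + (position - s1))
        left_flank = d2
    return LiftoverResult(None, (left_flank, None))


def diff_blocks(placement: PlacementRecord) -> list[tuple[str, tuple[int, int], tuple[int, int]]]:
    """Classify inter-block gaps as insertions or deletions in the alt.

    Returns ``(kind, primary_span, alt_span)`` per event, with kind
    ``"insertion-in-alt"`` (alt axis advances) or ``"deletion-in-alt"``
    (primary axis advances).  A gap where both axes advance yields one
    event of each kind.  The empty axis of an event is reported as the
    zero-length span ``(x+1, x)`` anchored after the last base before the
    gap.
    """
    events = []
    for prev, cur in zip(placement.blocks, placement.blocks[1:]):
        d_alt = cur[0] - prev[1] - 1
        d_par = cur[2] - prev[3] - 1
        if d_alt > 0:
            events.append(
                (
                    "insertion-in-alt",
                    (prev[3] + 1, prev[3]),
                    (prev[1] + 1, cur[0] - 1),
                )
            )
        if d_par > 0:
            events.append(
                (
                    "deletion-in-alt",
                    (prev[3] + 1, cur[2] - 1),
                    (prev[1] + 1, prev[1]),
                )
            )
    return events
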
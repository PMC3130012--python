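"""Release management: minor patch releases, major releases, issues.

The coordinate-stability contract is the heart of this module: a minor
release adds FIX/NOVEL patch scaffolds to the PATCHES assembly unit and
bumps the patch number, but never changes a primary chromosome sequence
or any existing placement — users get assembly improvements without the
coordinate system moving underneath their annotations.  Minor releases
are cumulative: the latest one carries every active patch.

At a major release the accumulated FIX patches are spliced into the
chromosomes (and retired), NOVEL patches are promoted to alt-loci units,
and a remap table records how old chromosome coordinates relate to new
ones.  Major releases are gated by a policy decision: at least 100 FIX
patches, or more than 1% of the euchromatic (non-gap primary) sequence
affected.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional, TextIO

from .model import (
    AGPRow,
    Assembly,
    AssembledObject,
    AssemblyUnit,
    PATCHES_UNIT,
    PlacementRecord,
    Region,
    ReleaseVersion,
)

__all__ = [
    "Patch",
    "Issue",
    "IssueTracker",
    "ISSUE_TYPES",
    "FIX_PATCH_THRESHOLD",
    "EUCHROMATIN_PCT_THRESHOLD",
    "ReleaseError",
    "minor_release",
    "release_decision",
    "pct_euchromatin_affected",
    "major_release",
    "RemapTable",
    "open_issue",
    "resolve_issue",
    "summarize_issues",
]

#: Major-release policy: at least this many FIX patches ...
FIX_PATCH_THRESHOLD = 100
#: ... or strictly more than this percentage of euchromatin affected.
EUCHROMATIN_PCT_THRESHOLD = 1.0

ISSUE_TYPES = (
    "clone-problem",
    "path-problem",
    "grc-housekeeping",
    "missing-sequence",
    "variation",
    "gap",
    "unknown",
)


class ReleaseError(ValueError):
    pass


@dataclass
class Patch:
    """A minor-release scaffold: FIX (corrects the assembly) or NOVEL
    (adds a new alternate locus).  Active patches live only in the
    PATCHES unit; their state changes only at a major release.
    """

    scaffold: AssembledObject
    sequence: str
    kind: str  # "FIX" | "NOVEL"
    placement: PlacementRecord
    region: Optional[Region] = None
    introduced_in: Optional[ReleaseVersion] = None
    state: str = "active"  # active | retired-into-major | promoted-to-alt
    #: sequences of components private to this patch scaffold
    component_seqs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("FIX", "NOVEL"):
            raise ValueError(f"patch kind must be FIX or NOVEL: {self.kind!r}")
        if len(self.sequence) != self.scaffold.sequence_length:
            raise ValueError(
                f"patch {self.scaffold.name}: sequence length {len(self.sequence)} "
                f"does not match AGP length {self.scaffold.sequence_length}"
            )


# ------------------------------------------------------------ minor releases

def _patch_overlap(a: PlacementRecord, b: PlacementRecord) -> bool:
    return (
        a.parent_chromosome == b.parent_chromosome
        and a.parent_start <= b.parent_stop
        and b.parent_start <= a.parent_stop
    )


def minor_release(assembly: Assembly, new_patches: list[Patch]) -> Assembly:
    """Produce the next minor release: previous patches plus the new ones.

    The returned assembly has patch_number + 1 and a PATCHES unit holding
    the union of previously active and new patches.  Every primary
    sequence and every pre-existing placement is byte-identical to the
    input (asserted).  New patches may overlap primary regions (that is
    what FIX patches are for) but must not overlap other active patches.
    """
    before_primary = {
        name: assembly.sequences[name]
        for name in assembly.primary_unit.members
        if name in assembly.sequences
    }
    out = copy.deepcopy(assembly)
    out.version = assembly.version.next_minor()
    patches_unit = None
    for unit in out.units.values():
        if unit.unit_kind == "patches":
            patches_unit = unit
    if patches_unit is None:
        patches_unit = out.add_unit(AssemblyUnit(PATCHES_UNIT, "patches"))

    chrom_names = set(out.primary_unit.members)
    for patch in new_patches:
        pl = patch.placement
        pl.validate()
        if pl.parent_chromosome not in chrom_names:
            raise ReleaseError(
                f"patch {patch.scaffold.name} targets unknown chromosome "
                f"{pl.parent_chromosome}"
            )
        for other in out.patches.values():
            if other.state == "active" and _patch_overlap(pl, other.placement):
                raise ReleaseError(
                    f"patch {patch.scaffold.name} overlaps active patch "
                    f"{other.scaffold.name} on {pl.parent_chromosome}"
                )
        patch = replace(patch, introduced_in=out.version)
        patches_unit.add(patch.scaffold)
        out.component_sequences.update(patch.component_seqs)
        out.sequences[patch.scaffold.name] = patch.sequence
        out.placements[patch.scaffold.name] = patch.placement
        out.patches[patch.scaffold.name] = patch
        if patch.region is not None:
            region = out.regions.setdefault(patch.region.region_name, patch.region)
            region.link(
                patch.scaffold.name,
                "fix-patch" if patch.kind == "FIX" else "novel-patch",
            )

    after_primary = {
        name: out.sequences[name] for name in before_primary
    }
    assert after_primary == before_primary, "minor release modified a primary sequence"
    return out


# ------------------------------------------------------------ release policy

def release_decision(n_fix_patches: int, pct_euchromatin_affected: float) -> bool:
    """Should the next major release happen?

    True when at least 100 FIX patches have accumulated or more than 1%
    of the euchromatic sequence is affected.
    """
    if n_fix_patches < 0:
        raise ValueError("n_fix_patches must be >= 0")
    if not (0.0 <= pct_euchromatin_affected <= 100.0):
        raise ValueError("percentage must be in [0, 100]")
    return (
        n_fix_patches >= FIX_PATCH_THRESHOLD
        or pct_euchromatin_affected > EUCHROMATIN_PCT_THRESHOLD
    )


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            total += hi - lo + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _non_gap_intervals(obj: AssembledObject) -> list[tuple[int, int]]:
    return [(r.object_beg, r.object_end) for r in obj.rows if not r.is_gap]


def pct_euchromatin_affected(active_fix_patches: list[Patch], assembly: Assembly) -> float:
    """Percentage of euchromatic sequence covered by active FIX patches.

    Euchromatin is operationalised as the non-gap sequence of the primary
    unit; coverage is the union of FIX-patch primary spans intersected
    with it, so overlapping patch spans count once.
    """
    primary = assembly.primary_unit
    total = sum(
        r.span for obj in primary.members.values() for r in obj.rows if not r.is_gap
    )
    if total == 0:
        return 0.0
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for patch in active_fix_patches:
        if patch.kind != "FIX":
            continue
        pl = patch.placement
        spans_by_chrom.setdefault(pl.parent_chromosome, []).append(
            (pl.parent_start, pl.parent_stop)
        )
    covered = 0
    for chrom, spans in spans_by_chrom.items():
        obj = primary.members.get(chrom)
        if obj is None:
            continue
        covered += _intersect(_merge_intervals(spans), _non_gap_intervals(obj))
    return 100.0 * covered / total


# ------------------------------------------------------------ major releases

@dataclass
class RemapTable:
    """Old↔new coordinate map emitted by a major release.

    Per chromosome, a list of ``(old_start, old_stop, new_start,
    new_stop, offset)`` rows for the preserved (unpatched) segments;
    positions inside a replaced span are unmappable because that
    sequence no longer exists in the new chromosome.
    """

    segments: dict[str, list[tuple[int, int, int, int, int]]] = field(default_factory=dict)

    def add(self, chrom: str, old_start: int, old_stop: int, new_start: int) -> None:
        if old_stop < old_start:
            return
        offset = new_start - old_start
        self.segments.setdefault(chrom, []).append(
            (old_start, old_stop, new_start, old_stop + offset, offset)
        )

    def map_forward(self, chrom: str, pos: int) -> Optional[int]:
        for o1, o2, n1, _n2, off in self.segments.get(chrom, ()):
            if o1 <= pos <= o2:
                return pos + off
        return None

    def map_back(self, chrom: str, pos: int) -> Optional[int]:
        for o1, o2, n1, n2, off in self.segments.get(chrom, ()):
            if n1 <= pos <= n2:
                return pos - off
        return None

    def write(self, stream: TextIO) -> None:
        stream.write("#chromosome\told_span\tnew_span\toffset\n")
        for chrom, segs in self.segments.items():
            for o1, o2, n1, n2, off in segs:
                stream.write(f"{chrom}\t{o1}-{o2}\t{n1}-{n2}\t{off:+d}\n")


def _cut_rows(rows: list[AGPRow], start: int, stop: int) -> list[AGPRow]:
    """Extract the rows covering object span [start, stop], rebased to 1."""
    out: list[AGPRow] = []
    for r in rows:
        b = max(r.object_beg, start)
        e = min(r.object_end, stop)
        if e < b:
            continue
        new = copy.copy(r)
        new.object_beg = b - start + 1
        new.object_end = e - start + 1
        if r.is_gap:
            if b != r.object_beg or e != r.object_end:
                new.gap_length = e - b + 1
        elif r.orientation == "+":
            new.component_beg = r.component_beg + (b - r.object_beg)
            new.component_end = r.component_beg + (e - r.object_beg)
        else:
            new.component_end = r.component_end - (b - r.object_beg)
            new.component_beg = r.component_end - (e - r.object_beg)
        out.append(new)
    return out


def _append_rows(dest: list[AGPRow], rows: list[AGPRow], object_name: str, offset: int) -> None:
    for r in rows:
        new = copy.copy(r)
        new.object_name = object_name
        new.object_beg = r.object_beg + offset
        new.object_end = r.object_end + offset
        new.part_number = len(dest) + 1
        dest.append(new)


def major_release(
    assembly: Assembly, force: bool = False
) -> tuple[Assembly, RemapTable]:
    """Integrate all active patches and produce the next major release.

    FIX patches are spliced into their chromosomes at their placement
    spans (each replaced span swapped for the patch scaffold's aligned
    span) and retired.  NOVEL patches are promoted into an alt-loci unit
    whose existing members they do not overlap on the new chromosome
    coordinates; a fresh unit is created when every existing one
    conflicts, since overlapping alternates are different representations
    of the same sequence and must stay in different units.  FIX splicing
    happens first so promoted placements target post-splice coordinates.

    Returns the new assembly and the old↔new remap table.
    """
    active = [p for p in assembly.patches.values() if p.state == "active"]
    fixes = [p for p in active if p.kind == "FIX"]
    novels = [p for p in active if p.kind == "NOVEL"]
    pct = pct_euchromatin_affected(fixes, assembly)
    if not release_decision(len(fixes), pct) and not force:
        raise ReleaseError(
            f"release policy not met ({len(fixes)} FIX patches, {pct:.3f}% affected); "
            "pass force=True to override"
        )

    out = copy.deepcopy(assembly)
    out.version = assembly.version.next_major()
    remap = RemapTable()

    by_chrom: dict[str, list[Patch]] = {}
    for p in fixes:
        by_chrom.setdefault(p.placement.parent_chromosome, []).append(p)
    for chrom, patches in by_chrom.items():
        patches.sort(key=lambda p: p.placement.parent_start)
        for a, b in zip(patches, patches[1:]):
            if a.placement.parent_stop >= b.placement.parent_start:
                raise ReleaseError(
                    f"FIX patches {a.scaffold.name} and {b.scaffold.name} have "
                    f"overlapping placements on {chrom}; curation required"
                )
        old_obj = out.primary_unit.members[chrom]
        old_seq = out.sequences[chrom]
        new_rows: list[AGPRow] = []
        new_parts: list[str] = []
        cursor = 1
        new_len = 0
        for p in patches:
            ps, pe = p.placement.parent_start, p.placement.parent_stop
            a1, a2 = p.placement.alt_start, p.placement.alt_stop
            if cursor <= ps - 1:
                seg_rows = _cut_rows(old_obj.rows, cursor, ps - 1)
                _append_rows(new_rows, seg_rows, chrom, new_len)
                new_parts.append(old_seq[cursor - 1 : ps - 1])
                remap.add(chrom, cursor, ps - 1, new_len + 1)
                new_len += ps - 1 - cursor + 1
            patch_rows = _cut_rows(p.scaffold.rows, a1, a2)
            _append_rows(new_rows, patch_rows, chrom, new_len)
            new_parts.append(out.sequences[p.scaffold.name][a1 - 1 : a2])
            new_len += a2 - a1 + 1
            cursor = pe + 1
        if cursor <= len(old_seq):
            seg_rows = _cut_rows(old_obj.rows, cursor, len(old_seq))
            _append_rows(new_rows, seg_rows, chrom, new_len)
            new_parts.append(old_seq[cursor - 1 :])
            remap.add(chrom, cursor, len(old_seq), new_len + 1)
            new_len += len(old_seq) - cursor + 1
        old_obj.rows = new_rows
        out.sequences[chrom] = "".join(new_parts)
        assert len(out.sequences[chrom]) == new_len

    # chromosomes untouched by FIX patches map identically
    for chrom, obj in out.primary_unit.members.items():
        if chrom not in by_chrom and obj.rank == "chromosome":
            remap.add(chrom, 1, obj.sequence_length, 1)

    patches_unit = next(
        (u for u in out.units.values() if u.unit_kind == "patches"), None
    )

    for p in fixes:
        out.patches[p.scaffold.name].state = "retired-into-major"
        if patches_unit and p.scaffold.name in patches_unit.members:
            del patches_unit.members[p.scaffold.name]
        out.sequences.pop(p.scaffold.name, None)
        out.placements.pop(p.scaffold.name, None)
        del out.patches[p.scaffold.name]

    alt_units = [u for u in out.units.values() if u.unit_kind == "alt-loci"]
    for p in novels:
        patch = out.patches[p.scaffold.name]
        old_pl = patch.placement
        chrom = old_pl.parent_chromosome
        new_blocks = []
        for a1, a2, p1, p2 in old_pl.blocks:
            n1 = remap.map_forward(chrom, p1)
            n2 = remap.map_forward(chrom, p2)
            if n1 is None or n2 is None or n2 - n1 != p2 - p1:
                raise ReleaseError(
                    f"NOVEL patch {p.scaffold.name} aligns into a span replaced by a "
                    f"FIX patch on {chrom}; curation required"
                )
            new_blocks.append((a1, a2, n1, n2))
        new_pl = PlacementRecord(
            alt_scaffold_name=old_pl.alt_scaffold_name,
            alt_start=old_pl.alt_start,
            alt_stop=old_pl.alt_stop,
            parent_chromosome=chrom,
            parent_start=new_blocks[0][2],
            parent_stop=new_blocks[-1][3],
            orientation="+",
            blocks=new_blocks,
        )
        home = None
        for unit in alt_units:
            conflict = any(
                _patch_overlap(new_pl, out.placements[m])
                for m in unit.members
                if m in out.placements
            )
            if not conflict:
                home = unit
                break
        if home is None:
            k = 1
            while f"alt-loci-{k}" in out.units:
                k += 1
            home = out.add_unit(AssemblyUnit(f"alt-loci-{k}", "alt-loci"))
            alt_units.append(home)
        if patches_unit and p.scaffold.name in patches_unit.members:
            del patches_unit.members[p.scaffold.name]
        home.add(patch.scaffold)
        out.placements[p.scaffold.name] = new_pl
        patch.state = "promoted-to-alt"
        patch.placement = new_pl
        del out.patches[p.scaffold.name]
        for region in out.regions.values():
            region.linked_sequences = [
                (n, "alt-locus" if n == p.scaffold.name else role)
                for n, role in region.linked_sequences
            ]

    out.version = assembly.version.next_major()
    return out, remap


# ------------------------------------------------------------ issue tracking

@dataclass
class Issue:
    """A tracked curation problem in a region of the assembly."""

    issue_id: str
    issue_type: str
    status: str = "open"
    chromosome: Optional[str] = None
    start: Optional[int] = None
    stop: Optional[int] = None
    resolution_release: Optional[ReleaseVersion] = None

    def __post_init__(self) -> None:
        if self.issue_type not in ISSUE_TYPES:
            raise ValueError(
                f"unknown issue type {self.issue_type!r}; expected one of {ISSUE_TYPES}"
            )
        if self.status not in ("open", "resolved"):
            raise ValueError(f"unknown issue status {self.status!r}")
        if self.status == "resolved" and self.resolution_release is None:
            raise ValueError(f"issue {self.issue_id}: resolved without a resolution release")


class IssueTracker:
    """In-memory issue tracker keyed by issue id."""

    def __init__(self, issues: Optional[list[Issue]] = None):
        self.issues: dict[str, Issue] = {}
        for issue in issues or []:
            if issue.issue_id in self.issues:
                raise ValueError(f"duplicate issue id {issue.issue_id}")
            self.issues[issue.issue_id] = issue

    def open_issue(
        self,
        issue_id: str,
        issue_type: str,
        chromosome: Optional[str] = None,
        start: Optional[int] = None,
        stop: Optional[int] = None,
    ) -> Issue:
        if issue_id in self.issues:
            raise ValueError(f"duplicate issue id {issue_id}")
        issue = Issue(issue_id, issue_type, "open", chromosome, start, stop)
        self.issues[issue_id] = issue
        return issue

    def resolve_issue(self, issue_id: str, release: ReleaseVersion) -> Issue:
        issue = self.issues[issue_id]
        if issue.status == "resolved":
            raise ValueError(f"issue {issue_id} is already resolved")
        issue.status = "resolved"
        issue.resolution_release = release
        return issue


def open_issue(tracker: IssueTracker, *args, **kwargs) -> Issue:
    return tracker.open_issue(*args, **kwargs)


def resolve_issue(tracker: IssueTracker, issue_id: str, release: ReleaseVersion) -> Issue:
    return tracker.resolve_issue(issue_id, release)


def summarize_issues(issues: list[Issue]) -> dict[str, dict[str, int]]:
    """Count resolved issues per resolution release per type.

    The grand total over the returned counts equals the number of
    resolved issues.
    """
    summary: dict[str, dict[str, int]] = {}
    for issue in issues:
        if issue.status != "resolved":
            continue
        rel = str(issue.resolution_release)
        per_type = summary.setdefault(rel, {t: 0 for t in ISSUE_TYPES})
        per_type[issue.issue_type] += 1
    return summary
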
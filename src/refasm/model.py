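"""Domain model for a curated reference assembly.

The model follows the modern reference-assembly structure used for the
human genome: an assembly is a versioned collection of *assembly units*.
The primary unit holds the non-redundant haploid chromosomes plus
unlocalized/unplaced scaffolds; alternate loci (extra tiling paths through
structurally variant regions) live in separate alt-loci units; minor-release
patch scaffolds live in a dedicated PATCHES unit.  Alternate loci and
patches get chromosome context by alignment (a :class:`PlacementRecord`),
never by chromosome coordinates of their own.

All external coordinates are 1-based inclusive, as in the AGP standard.
Validation never raises on bad data: violations are returned as values so
callers (and the CLI) can report them all at once.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

__all__ = [
    "ComponentRef",
    "GapSpec",
    "TilingPathRow",
    "TilingPath",
    "SwitchPoint",
    "AGPRow",
    "AssembledObject",
    "AssemblyUnit",
    "ScaffoldStatus",
    "Region",
    "ReleaseVersion",
    "PlacementRecord",
    "Assembly",
    "Violation",
    "validate_agp_object",
    "validate_assembly",
    "classify_scaffold",
    "PATCHES_UNIT",
    "PRIMARY_UNIT",
    "ALT_LOCUS_SIZE_WARNING_BP",
    "UNKNOWN_GAP_RENDER_LEN",
]

PRIMARY_UNIT = "primary"
PATCHES_UNIT = "PATCHES"

#: Alternate loci are typically under 5 Mb; larger ones draw a warning,
#: never a rejection (there is no hard size limit).
ALT_LOCUS_SIZE_WARNING_BP = 5_000_000

#: Rendered length for gaps of unknown size ("U" gaps in AGP).
UNKNOWN_GAP_RENDER_LEN = 100

_ACCESSION_RE = re.compile(r"^[A-Za-z0-9_]+\.\d+$")

GAP_KINDS = ("contig", "clone", "scaffold-break")


class SourceKind(str, Enum):
    clone = "clone"
    wgs = "wgs"
    pcr = "pcr"


@dataclass(frozen=True)
class ComponentRef:
    """A versioned component sequence: clone, WGS, or PCR fragment.

    Components are the raw material of the assembly; each carries a
    versioned accession (``NAME.version``) so the exact sequence is
    trackable.
    """

    accession: str
    length: int
    source_kind: SourceKind = SourceKind.clone

    def __post_init__(self) -> None:
        if not self.accession or not _ACCESSION_RE.match(self.accession):
            raise ValueError(
                f"component accession must be versioned (NAME.N): {self.accession!r}"
            )
        if self.length < 1:
            raise ValueError(f"component length must be >= 1: {self.length}")


@dataclass(frozen=True)
class GapSpec:
    """A gap in a scaffold: estimated (or unknown) size plus linkage evidence."""

    gap_length: Optional[int]  # None => unknown size
    gap_kind: str = "contig"
    linkage: bool = True

    def __post_init__(self) -> None:
        if self.gap_length is not None and self.gap_length < 1:
            raise ValueError(f"gap length must be >= 1: {self.gap_length}")
        if self.gap_kind not in GAP_KINDS:
            # unknown dialect gap types are normalised upstream; reaching
            # here with another kind is a programming error
            raise ValueError(f"unknown gap kind: {self.gap_kind!r}")

    @property
    def render_length(self) -> int:
        """Number of N bases this gap contributes to a built sequence."""
        return self.gap_length if self.gap_length is not None else UNKNOWN_GAP_RENDER_LEN


@dataclass(frozen=True)
class TilingPathRow:
    """One row of a tiling path: a component (with orientation) or a gap."""

    entry: Union[ComponentRef, GapSpec]
    orientation: Optional[str] = None  # "+" or "-", components only
    local_order: int = 0

    def __post_init__(self) -> None:
        if self.is_gap:
            if self.orientation is not None:
                raise ValueError("gap rows never carry an orientation")
        else:
            if self.orientation not in ("+", "-"):
                raise ValueError(f"component orientation must be + or -: {self.orientation!r}")

    @property
    def is_gap(self) -> bool:
        return isinstance(self.entry, GapSpec)


@dataclass
class TilingPath:
    """Ordered components (and gaps) defining how to build one object."""

    object_name: str
    rows: list[TilingPathRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        orders = [r.local_order for r in self.rows]
        if any(b <= a for a, b in zip(orders, orders[1:])):
            raise ValueError(f"tiling path {self.object_name}: orders must strictly increase")
        seen: set[str] = set()
        for row in self.rows:
            if not row.is_gap:
                acc = row.entry.accession
                if acc in seen:
                    raise ValueError(
                        f"tiling path {self.object_name}: component {acc} appears twice"
                    )
                seen.add(acc)

    @property
    def components(self) -> list[TilingPathRow]:
        return [r for r in self.rows if not r.is_gap]


@dataclass(frozen=True)
class SwitchPoint:
    """The base at which contig sequence stops coming from one component
    and starts coming from the next.  Positions are 1-based within each
    component's oriented sequence and must lie inside the verified overlap.
    """

    from_accession: str
    to_accession: str
    position_in_from: int
    position_in_to: int

    def __post_init__(self) -> None:
        if self.position_in_from < 1 or self.position_in_to < 1:
            raise ValueError("switch-point positions are 1-based")


@dataclass
class AGPRow:
    """One line of an AGP object: a component span or a gap."""

    object_name: str
    object_beg: int
    object_end: int
    part_number: int
    row_kind: str  # "component" | "gap"
    # component rows
    component_id: Optional[str] = None
    component_beg: Optional[int] = None
    component_end: Optional[int] = None
    orientation: Optional[str] = None
    # gap rows
    gap_length: Optional[int] = None
    gap_kind: Optional[str] = None
    linkage: Optional[bool] = None

    @property
    def span(self) -> int:
        return self.object_end - self.object_beg + 1

    @property
    def is_gap(self) -> bool:
        return self.row_kind == "gap"


@dataclass
class AssembledObject:
    """A contig, scaffold, or chromosome, described by its AGP rows.

    ``chromosome`` records association for scaffolds that belong to a
    chromosome but cannot be ordered/oriented on it (unlocalized).
    """

    name: str
    rank: str  # "contig" | "scaffold" | "chromosome"
    rows: list[AGPRow] = field(default_factory=list)
    chromosome: Optional[str] = None

    @property
    def sequence_length(self) -> int:
        return self.rows[-1].object_end if self.rows else 0

    @property
    def gap_rows(self) -> list[AGPRow]:
        return [r for r in self.rows if r.is_gap]

    @property
    def component_ids(self) -> list[str]:
        return [r.component_id for r in self.rows if not r.is_gap]


@dataclass
class AssemblyUnit:
    """A named container of assembled objects within an assembly."""

    unit_name: str
    unit_kind: str  # "primary" | "alt-loci" | "patches"
    members: dict[str, AssembledObject] = field(default_factory=dict)

    def add(self, obj: AssembledObject) -> None:
        if obj.name in self.members:
            raise ValueError(f"duplicate member {obj.name} in unit {self.unit_name}")
        self.members[obj.name] = obj


@dataclass(frozen=True)
class ScaffoldStatus:
    status: str  # placed | unlocalized | unplaced | alt | patch
    chromosome: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status == "unlocalized" and self.chromosome is None:
            raise ValueError("unlocalized scaffolds require a chromosome")
        if self.status == "unplaced" and self.chromosome is not None:
            raise ValueError("unplaced scaffolds carry no chromosome")


@dataclass
class Region:
    """A named span of a primary chromosome linked to extra-chromosomal
    sequence.  One region may simultaneously point at an alternate locus,
    a FIX patch and a NOVEL patch.
    """

    region_name: str
    chromosome: str
    primary_start: int
    primary_stop: int
    linked_sequences: list[tuple[str, str]] = field(default_factory=list)
    # roles: "alt-locus" | "fix-patch" | "novel-patch"

    def link(self, scaffold_name: str, role: str) -> None:
        if role not in ("alt-locus", "fix-patch", "novel-patch"):
            raise ValueError(f"unknown region role: {role!r}")
        self.linked_sequences.append((scaffold_name, role))


@dataclass(frozen=True, order=True)
class ReleaseVersion:
    """Assembly version: major release number plus cumulative patch number.

    Patch number 0 denotes the major release itself; minor releases
    increment it by one and a major release resets it to zero.
    """

    major: int
    patch_number: int = 0

    def __post_init__(self) -> None:
        if self.major < 1 or self.patch_number < 0:
            raise ValueError(f"invalid release version {self.major}.p{self.patch_number}")

    def next_minor(self) -> "ReleaseVersion":
        return ReleaseVersion(self.major, self.patch_number + 1)

    def next_major(self) -> "ReleaseVersion":
        return ReleaseVersion(self.major + 1, 0)

    def __str__(self) -> str:
        return f"{self.major}" if self.patch_number == 0 else f"{self.major}.p{self.patch_number}"

    @staticmethod
    def parse(text: str) -> "ReleaseVersion":
        m = re.match(r"^(\d+)(?:\.p(\d+))?$", text.strip())
        if not m:
            raise ValueError(f"cannot parse release version {text!r}")
        return ReleaseVersion(int(m.group(1)), int(m.group(2) or 0))


@dataclass
class PlacementRecord:
    """Block alignment of an alt/patch scaffold onto a primary chromosome.

    ``blocks`` are gapless aligned segments, as tuples
    ``(alt_start, alt_stop, parent_start, parent_stop)``, sorted and
    non-overlapping on both axes, with equal lengths on both axes.
    Placements are stored in forward orientation: alt scaffolds are
    oriented to match the primary strand when they are built.
    """

    alt_scaffold_name: str
    alt_start: int
    alt_stop: int
    parent_chromosome: str
    parent_start: int
    parent_stop: int
    orientation: str = "+"
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.orientation != "+":
            raise ValueError("placements are canonical forward orientation only")
        self.validate()

    def validate(self) -> None:
        prev_alt = prev_par = 0
        for a1, a2, p1, p2 in self.blocks:
            if a2 - a1 != p2 - p1:
                raise ValueError(
                    f"placement {self.alt_scaffold_name}: block length mismatch "
                    f"{a1}-{a2} vs {p1}-{p2}"
                )
            if a1 <= prev_alt or p1 <= prev_par:
                raise ValueError(
                    f"placement {self.alt_scaffold_name}: blocks overlap or are unsorted"
                )
            if a1 > a2:
                raise ValueError(f"placement {self.alt_scaffold_name}: empty block")
            prev_alt, prev_par = a2, p2
        if self.blocks:
            if self.alt_start > self.blocks[0][0] or self.alt_stop < self.blocks[-1][1]:
                raise ValueError(f"placement {self.alt_scaffold_name}: blocks exceed alt span")
            if self.parent_start > self.blocks[0][2] or self.parent_stop < self.blocks[-1][3]:
                raise ValueError(f"placement {self.alt_scaffold_name}: blocks exceed parent span")

    @property
    def aligned_bases(self) -> int:
        return sum(a2 - a1 + 1 for a1, a2, _, _ in self.blocks)


@dataclass
class Assembly:
    """A versioned assembly: units, object sequences, placements, regions."""

    name: str
    version: ReleaseVersion = field(default_factory=lambda: ReleaseVersion(1, 0))
    units: dict[str, AssemblyUnit] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    component_sequences: dict[str, str] = field(default_factory=dict)
    placements: dict[str, PlacementRecord] = field(default_factory=dict)
    regions: dict[str, Region] = field(default_factory=dict)
    #: active patches keyed by scaffold name (values are release.Patch)
    patches: dict[str, object] = field(default_factory=dict)

    def add_unit(self, unit: AssemblyUnit) -> AssemblyUnit:
        if unit.unit_name in self.units:
            raise ValueError(f"duplicate unit {unit.unit_name}")
        self.units[unit.unit_name] = unit
        return unit

    @property
    def primary_unit(self) -> AssemblyUnit:
        primaries = [u for u in self.units.values() if u.unit_kind == "primary"]
        if len(primaries) != 1:
            raise ValueError(f"assembly {self.name} has {len(primaries)} primary units")
        return primaries[0]

    def unit_of(self, scaffold_name: str) -> Optional[AssemblyUnit]:
        for unit in self.units.values():
            if scaffold_name in unit.members:
                return unit
        return None

    def find_object(self, scaffold_name: str) -> Optional[AssembledObject]:
        unit = self.unit_of(scaffold_name)
        return unit.members[scaffold_name] if unit else None


@dataclass(frozen=True)
class Violation:
    """A single validation finding; validation reports are lists of these."""

    code: str
    message: str
    object_name: Optional[str] = None

    def __str__(self) -> str:
        where = f" [{self.object_name}]" if self.object_name else ""
        return f"{self.code}{where}: {self.message}"


def validate_agp_object(rows: list[AGPRow]) -> list[Violation]:
    """Check that AGP rows tile one object perfectly.

    Returns every violated invariant: coordinate holes and overlaps,
    component-span/object-span length mismatches, part-number breaks,
    inverted spans, gap rows inside contig-rank objects are checked by
    :func:`validate_assembly` (rank is not visible here).  An empty report
    means the object is valid.
    """
    report: list[Violation] = []
    if not rows:
        return [Violation("empty-object", "no rows")]
    name = rows[0].object_name
    for r in rows:
        if r.object_name != name:
            report.append(
                Violation("mixed-object", f"row for {r.object_name} among rows for {name}", name)
            )
    expected_part = 1
    cursor = 1  # next expected object_beg
    for r in rows:
        if r.part_number != expected_part:
            report.append(
                Violation(
                    "part-number-break",
                    f"expected part {expected_part}, found {r.part_number}",
                    name,
                )
            )
            expected_part = r.part_number
        expected_part += 1
        if r.object_end < r.object_beg:
            report.append(
                Violation("inverted-span", f"object span {r.object_beg}-{r.object_end}", name)
            )
            continue
        if r.object_beg > cursor:
            report.append(
                Violation(
                    "coordinate-hole",
                    f"uncovered object span {cursor}-{r.object_beg - 1}",
                    name,
                )
            )
        elif r.object_beg < cursor:
            report.append(
                Violation(
                    "coordinate-overlap",
                    f"row at {r.object_beg}-{r.object_end} overlaps previous row ending {cursor - 1}",
                    name,
                )
            )
        cursor = max(cursor, r.object_end + 1)
        if r.is_gap:
            if r.gap_length is not None and r.gap_length != r.span:
                report.append(
                    Violation(
                        "gap-length-mismatch",
                        f"gap row spans {r.span} bp but declares {r.gap_length}",
                        name,
                    )
                )
        else:
            if r.component_beg is None or r.component_end is None:
                report.append(Violation("missing-component-span", "component row lacks span", name))
            elif (r.component_end - r.component_beg) != (r.object_end - r.object_beg):
                report.append(
                    Violation(
                        "length-mismatch",
                        f"object span {r.span} bp vs component span "
                        f"{r.component_end - r.component_beg + 1} bp "
                        f"({r.component_id})",
                        name,
                    )
                )
            if r.orientation not in ("+", "-"):
                report.append(
                    Violation("bad-orientation", f"orientation {r.orientation!r}", name)
                )
    return report


def _placement_overlap(a: PlacementRecord, b: PlacementRecord) -> bool:
    return (
        a.parent_chromosome == b.parent_chromosome
        and a.parent_start <= b.parent_stop
        and b.parent_start <= a.parent_stop
    )


def validate_assembly(assembly: Assembly) -> list[Violation]:
    """Validate assembly-level invariants.

    Checks: exactly one primary unit; every alt-loci/PATCHES member has a
    placement; placements within one alt-loci unit never overlap on the
    primary chromosome; unlocalized scaffolds carry a chromosome and
    unplaced ones do not; AGP validity of every member; contigs contain no
    gap rows; alternate loci above the customary 5 Mb draw a warning.
    """
    report: list[Violation] = []
    primaries = [u for u in assembly.units.values() if u.unit_kind == "primary"]
    if len(primaries) != 1:
        report.append(
            Violation("primary-unit-count", f"{len(primaries)} primary units (need exactly 1)")
        )
    chrom_embedded: set[str] = set()
    for unit in assembly.units.values():
        if unit.unit_kind == "primary":
            for obj in unit.members.values():
                if obj.rank == "chromosome":
                    chrom_embedded.update(obj.component_ids)
    for unit in assembly.units.values():
        placed_members: list[PlacementRecord] = []
        for obj in unit.members.values():
            report.extend(validate_agp_object(obj.rows))
            if obj.rank == "contig" and obj.gap_rows:
                report.append(
                    Violation("contig-with-gaps", f"{len(obj.gap_rows)} gap rows", obj.name)
                )
            if unit.unit_kind in ("alt-loci", "patches"):
                pl = assembly.placements.get(obj.name)
                if pl is None:
                    report.append(
                        Violation("missing-placement", "no chromosome-context placement", obj.name)
                    )
                elif unit.unit_kind == "alt-loci":
                    placed_members.append(pl)
                if (
                    unit.unit_kind == "alt-loci"
                    and obj.sequence_length > ALT_LOCUS_SIZE_WARNING_BP
                ):
                    report.append(
                        Violation(
                            "alt-locus-size-warning",
                            f"alternate locus spans {obj.sequence_length} bp (> "
                            f"{ALT_LOCUS_SIZE_WARNING_BP}); unusual but not rejected",
                            obj.name,
                        )
                    )
            elif unit.unit_kind == "primary" and obj.rank != "chromosome":
                if obj.name in chrom_embedded:
                    continue  # placed scaffold
                # unlocalized/unplaced bookkeeping is encoded on the object
                # itself; nothing further to check here
    for unit in assembly.units.values():
        if unit.unit_kind != "alt-loci":
            continue
        pls = [assembly.placements[o.name] for o in unit.members.values()
               if o.name in assembly.placements]
        for i in range(len(pls)):
            for j in range(i + 1, len(pls)):
                if _placement_overlap(pls[i], pls[j]):
                    report.append(
                        Violation(
                            "alt-placement-overlap",
                            f"{pls[i].alt_scaffold_name} and {pls[j].alt_scaffold_name} "
                            f"overlap on {pls[i].parent_chromosome}",
                            unit.unit_name,
                        )
                    )
    # patch membership: FIX/NOVEL patch scaffolds live only in PATCHES
    patches_units = [u for u in assembly.units.values() if u.unit_kind == "patches"]
    if len(patches_units) > 1:
        report.append(Violation("patches-unit-count", f"{len(patches_units)} patches units"))
    return report


def classify_scaffold(scaffold_name: str, assembly: Assembly) -> ScaffoldStatus:
    """Classify a scaffold as placed/unlocalized/unplaced/alt/patch.

    A primary-unit scaffold is *placed* when it is a chromosome or appears
    as a component of a chromosome AGP; *unlocalized* when it carries a
    chromosome association but no position; *unplaced* otherwise.
    """
    unit = assembly.unit_of(scaffold_name)
    if unit is None:
        raise KeyError(f"scaffold {scaffold_name!r} is not a member of any assembly unit")
    obj = unit.members[scaffold_name]
    if unit.unit_kind == "patches":
        return ScaffoldStatus("patch", obj.chromosome)
    if unit.unit_kind == "alt-loci":
        return ScaffoldStatus("alt", obj.chromosome)
    if obj.rank == "chromosome":
        return ScaffoldStatus("placed", obj.name)
    for member in unit.members.values():
        if member.rank == "chromosome" and scaffold_name in member.component_ids:
            return ScaffoldStatus("placed", member.name)
    if obj.chromosome is not None:
        return ScaffoldStatus("unlocalized", obj.chromosome)
    return ScaffoldStatus("unplaced", None)
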
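"""Synthetic clone paths, dual-haplotype regions, and read placement.

These generators emulate, at desk scale, the raw material the assembly
model manages: overlapping clone-like components tiling a hidden truth
sequence, and a structurally variant region with two haplotype tiling
paths — an insertion allele and a deletion allele sharing flanking
anchor components, the situation where one path goes into the chromosome
and the other becomes an alternate locus.

`evaluate_alt_awareness` demonstrates the point of alternate loci:
sequencing reads from the insertion haplotype are aligned against an
assembly whose primary chromosome carries the deletion allele, with and
without the insertion path as an alternate locus.  Without the alternate
locus, reads specific to the inserted sequence have nowhere correct to
go and are misplaced or dropped.

All generators are pure functions of their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np

from .build import build_object_sequence, tpf_to_agp
from .model import (
    Assembly,
    AssemblyUnit,
    ComponentRef,
    Region,
    ReleaseVersion,
    TilingPath,
    TilingPathRow,
)
from .placement import anchor_align, diff_blocks, liftover

__all__ = [
    "GeneratedComponents",
    "VariantRegion",
    "Read",
    "AltAwarenessReport",
    "gen_components",
    "gen_variant_region",
    "simulate_reads",
    "variant_assemblies",
    "evaluate_alt_awareness",
    "gen_patches",
    "write_reads",
    "read_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, error_rate: float,
            lo: int = 0, hi: Optional[int] = None) -> str:
    """Substitute bases in seq[lo:hi] with Bernoulli(error_rate) per base."""
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hi = len(arr) if hi is None else hi
    hits = np.flatnonzero(rng.random(hi - lo) < error_rate) + lo
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


@dataclass
class GeneratedComponents:
    """Clone-like components tiling a hidden truth sequence."""

    tiling_path: TilingPath
    component_seqs: dict[str, str]
    truth: str
    overlap_len: int


def gen_components(
    seed: int,
    n: int = 5,
    length: int = 5000,
    overlap_len: int = 500,
    error_rate: float = 0.01,
) -> GeneratedComponents:
    """Generate ``n`` components of ``length`` bp tiling a truth sequence
    with exact-position dovetail overlaps of ``overlap_len`` bp.

    Each overlap carries Bernoulli(``error_rate``) substitution
    mismatches, applied to the downstream component's prefix, mimicking
    sequencing discrepancies between clones.  Deterministic per seed.
    """
    if not (0 <= error_rate <= 0.05):
        raise ValueError("error_rate must be in [0, 0.05]")
    if overlap_len >= length:
        raise ValueError("overlap_len must be smaller than component length")
    rng = np.random.default_rng(seed)
    stride = length - overlap_len
    truth_len = n * length - (n - 1) * overlap_len
    truth = _random_seq(rng, truth_len)
    seqs: dict[str, str] = {}
    rows: list[TilingPathRow] = []
    for i in range(n):
        acc = f"SYN{i + 1:04d}.1"
        start = i * stride
        comp = truth[start : start + length]
        if i > 0:
            comp = _mutate(rng, comp, error_rate, lo=0, hi=overlap_len)
        seqs[acc] = comp
        rows.append(
            TilingPathRow(ComponentRef(acc, length), orientation="+", local_order=i + 1)
        )
    return GeneratedComponents(
        tiling_path=TilingPath("synthetic_obj", rows),
        component_seqs=seqs,
        truth=truth,
        overlap_len=overlap_len,
    )


@dataclass
class VariantRegion:
    """A dual-haplotype region: insertion path vs deletion path sharing
    flanking anchor components.
    """

    insertion_path: TilingPath
    deletion_path: TilingPath
    component_seqs: dict[str, str]
    anchor_accessions: list[str]
    insertion_truth: str
    deletion_truth: str
    insert_span: tuple[int, int]  # 1-based on the insertion haplotype
    insert_len: int


def gen_variant_region(
    seed: int,
    flank_len: int = 5000,
    insert_len: int = 2000,
    anchor_overlap: int = 500,
    spacer_len: int = 800,
) -> VariantRegion:
    """Generate the two-haplotype fixture: shared flanking anchors, a
    middle component per haplotype, and ``insert_len`` bp of sequence
    unique to the insertion allele.

    Layout (insertion haplotype): ``A + s_l + U + s_r + B`` where A/B are
    the anchor components' exclusive sequence, s_l/s_r shared spacers and
    U the unique insert; the deletion haplotype is ``A + s_l + s_r + B``.
    Both tiling paths are anchor, middle component, anchor; the middle
    components dovetail ``anchor_overlap`` bp into each anchor.
    """
    if insert_len < 200:
        raise ValueError("insert_len must be >= 200")
    rng = np.random.default_rng(seed)
    a = _random_seq(rng, flank_len)
    b = _random_seq(rng, flank_len)
    s_l = _random_seq(rng, spacer_len)
    s_r = _random_seq(rng, spacer_len)
    u = _random_seq(rng, insert_len)

    ins_truth = a + s_l + u + s_r + b
    del_truth = a + s_l + s_r + b
    anchor_l = "ANCHL001.1"
    anchor_r = "ANCHR001.1"
    mid_ins = "INSMID01.1"
    mid_del = "DELMID01.1"
    seqs = {
        anchor_l: a,
        anchor_r: b,
        # middle components reach anchor_overlap bp into each anchor
        mid_ins: a[-anchor_overlap:] + s_l + u + s_r + b[:anchor_overlap],
        mid_del: a[-anchor_overlap:] + s_l + s_r + b[:anchor_overlap],
    }

    def path(name: str, mid: str) -> TilingPath:
        return TilingPath(
            name,
            [
                TilingPathRow(ComponentRef(anchor_l, len(seqs[anchor_l])), "+", 1),
                TilingPathRow(ComponentRef(mid, len(seqs[mid])), "+", 2),
                TilingPathRow(ComponentRef(anchor_r, len(seqs[anchor_r])), "+", 3),
            ],
        )

    return VariantRegion(
        insertion_path=path("hap_insertion", mid_ins),
        deletion_path=path("hap_deletion", mid_del),
        component_seqs=seqs,
        anchor_accessions=[anchor_l, anchor_r],
        insertion_truth=ins_truth,
        deletion_truth=del_truth,
        insert_span=(flank_len + spacer_len + 1, flank_len + spacer_len + insert_len),
        insert_len=insert_len,
    )


@dataclass(frozen=True)
class Read:
    """A simulated read with its truth position on the source haplotype."""

    name: str
    sequence: str
    truth_start: int  # 1-based on the haplotype it was simulated from
    truth_end: int


def simulate_reads(
    seed: int,
    haplotype_seq: str,
    n_reads: int = 500,
    read_len: int = 100,
    error_rate: float = 0.01,
) -> list[Read]:
    """Simulate uniform-start reads with per-base substitution errors."""
    if read_len > len(haplotype_seq):
        raise ValueError("read length exceeds haplotype length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(haplotype_seq) - read_len + 1, size=n_reads)
    reads = []
    for i, s in enumerate(starts):
        seq = _mutate(rng, haplotype_seq[s : s + read_len], error_rate)
        reads.append(Read(f"read{i + 1:05d}", seq, int(s) + 1, int(s) + read_len))
    return reads


def gen_patches(
    seed: int,
    assembly: Assembly,
    n_fix: int = 1,
    n_novel: int = 1,
    span_len: int = 400,
    sub_rate: float = 0.01,
    indel_prob: float = 0.5,
    max_indel: int = 60,
) -> list:
    """Generate random valid FIX/NOVEL patches for an assembly.

    Each patch takes a random non-gap span of a primary chromosome,
    copies it with substitutions (and, with probability ``indel_prob``,
    one insertion or deletion of up to ``max_indel`` bp), wraps it as a
    single-component scaffold, and places it back onto the chromosome by
    alignment.  Spans avoid the assembly's active patches and each
    other, so the result is always valid input for a minor release.
    """
    from .placement import placement_from_alignment
    from .release import Patch

    rng = np.random.default_rng(seed)
    chroms = [
        obj for obj in assembly.primary_unit.members.values() if obj.rank == "chromosome"
    ]
    if not chroms:
        raise ValueError("assembly has no primary chromosomes")
    taken: dict[str, list[tuple[int, int]]] = {}
    for patch in assembly.patches.values():
        pl = patch.placement
        taken.setdefault(pl.parent_chromosome, []).append((pl.parent_start, pl.parent_stop))
    patches = []
    kinds = ["FIX"] * n_fix + ["NOVEL"] * n_novel
    for i, kind in enumerate(kinds):
        chrom = chroms[int(rng.integers(len(chroms)))]
        seq = assembly.sequences[chrom.name]
        for _attempt in range(200):
            ps = int(rng.integers(1, len(seq) - span_len + 1))
            pe = ps + span_len - 1
            spans = taken.setdefault(chrom.name, [])
            if all(pe < lo or ps > hi for lo, hi in spans):
                break
        else:
            raise ValueError("could not find a free span for a patch")
        spans.append((ps, pe))
        patch_seq = _mutate(rng, seq[ps - 1 : pe], sub_rate)
        if rng.random() < indel_prob:
            margin = max(10, span_len // 5)
            size = int(rng.integers(5, max(6, min(max_indel, span_len // 4) + 1)))
            at = int(rng.integers(margin, span_len - margin))
            if rng.random() < 0.5:
                patch_seq = patch_seq[:at] + _random_seq(rng, size) + patch_seq[at:]
            else:
                patch_seq = patch_seq[:at] + patch_seq[at + size :]
        name = f"PATCH_{kind}_{seed}_{i + 1}"
        acc = f"PC{seed % 10000:04d}{i:02d}.1"
        from .model import AGPRow, AssembledObject

        scaffold = AssembledObject(
            name=name,
            rank="scaffold",
            rows=[
                AGPRow(
                    object_name=name,
                    object_beg=1,
                    object_end=len(patch_seq),
                    part_number=1,
                    row_kind="component",
                    component_id=acc,
                    component_beg=1,
                    component_end=len(patch_seq),
                    orientation="+",
                )
            ],
        )
        placement = placement_from_alignment(
            patch_seq, seq[ps - 1 : pe], name, chrom.name, parent_offset=ps - 1
        )
        patches.append(
            Patch(
                scaffold=scaffold,
                sequence=patch_seq,
                kind=kind,
                placement=placement,
                component_seqs={acc: patch_seq},
            )
        )
    return patches


def write_reads(reads: list[Read], stream) -> None:
    """Write reads with truth positions as TSV (name, sequence, start, end)."""
    stream.write("#name\tsequence\ttruth_start\ttruth_end\n")
    for r in reads:
        stream.write(f"{r.name}\t{r.sequence}\t{r.truth_start}\t{r.truth_end}\n")


def read_reads(stream) -> list[Read]:
    reads = []
    for line in stream:
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        name, seq, start, end = line.split("\t")
        reads.append(Read(name, seq, int(start), int(end)))
    return reads


# ------------------------------------------------------------ evaluation

CHROMOSOME_NAME = "chrS"
ALT_SCAFFOLD_NAME = "alt_insertion"


def variant_assemblies(region: VariantRegion) -> tuple[Assembly, Assembly]:
    """Build (with_alt, without_alt) assemblies from a variant region.

    The primary chromosome carries the deletion allele; the with-alt
    assembly additionally carries the insertion path as an alternate
    locus placed by anchored alignment.
    """
    del_build = tpf_to_agp(region.deletion_path, region.component_seqs)
    ins_build = tpf_to_agp(region.insertion_path, region.component_seqs)
    del_obj, ins_obj = del_build.object, ins_build.object
    del_obj.name = CHROMOSOME_NAME
    for r in del_obj.rows:
        r.object_name = CHROMOSOME_NAME
    del_obj.rank = "chromosome"
    ins_obj.name = ALT_SCAFFOLD_NAME
    for r in ins_obj.rows:
        r.object_name = ALT_SCAFFOLD_NAME
    del_seq = build_object_sequence(del_obj, region.component_seqs)
    ins_seq = build_object_sequence(ins_obj, region.component_seqs)

    def base_assembly(name: str) -> Assembly:
        asm = Assembly(name=name, version=ReleaseVersion(1, 0))
        primary = asm.add_unit(AssemblyUnit("primary", "primary"))
        primary.add(del_obj)
        asm.sequences[CHROMOSOME_NAME] = del_seq
        asm.component_sequences.update(region.component_seqs)
        return asm

    without_alt = base_assembly("synthetic_without_alt")
    with_alt = base_assembly("synthetic_with_alt")
    placement = anchor_align(ins_obj, del_obj, region.component_seqs, CHROMOSOME_NAME)
    alt_unit = with_alt.add_unit(AssemblyUnit("alt-loci-1", "alt-loci"))
    alt_unit.add(ins_obj)
    with_alt.sequences[ALT_SCAFFOLD_NAME] = ins_seq
    with_alt.placements[ALT_SCAFFOLD_NAME] = placement
    insert_span = region.insert_span
    with_alt.regions["REG_variant"] = Region(
        "REG_variant",
        CHROMOSOME_NAME,
        placement.parent_start,
        placement.parent_stop,
        [(ALT_SCAFFOLD_NAME, "alt-locus")],
    )
    return with_alt, without_alt


def _align_read(
    read_seq: str, targets: dict[str, str], max_edits: int
) -> Optional[tuple[str, int]]:
    """Best infix placement of a read: (target name, 1-based start).

    Deterministic tie-break: smallest edit distance, then lexicographic
    target name, then the leftmost location edlib reports.
    """
    best: Optional[tuple[int, str, int]] = None
    for name in sorted(targets):
        res = edlib.align(read_seq, targets[name], mode="HW", task="locations", k=max_edits)
        if res["editDistance"] < 0:
            continue
        end_loc = res["locations"][0]
        start = (end_loc[0] if end_loc[0] is not None else 0) + 1
        cand = (res["editDistance"], name, start)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        return None
    return best[1], best[2]


@dataclass
class AltAwarenessReport:
    """Placement of alt-specific reads with and without the alternate locus."""

    n_reads: int
    n_alt_specific: int
    with_alt: dict[str, int] = field(default_factory=dict)
    without_alt: dict[str, int] = field(default_factory=dict)
    non_alt_agreement: float = 1.0

    def as_rows(self) -> list[tuple[str, int, int, int]]:
        return [
            (label, c["correct"], c["misplaced"], c["unaligned"])
            for label, c in (("with_alt", self.with_alt), ("without_alt", self.without_alt))
        ]


def evaluate_alt_awareness(
    reads: list[Read],
    assembly_with_alt: Assembly,
    assembly_without_alt: Assembly,
    max_edit_frac: float = 0.1,
    position_tolerance: int = 3,
) -> AltAwarenessReport:
    """Compare read placement with and without the alternate locus.

    Reads must come from the insertion-haplotype simulator (truth
    positions are required).  A read is *alt-specific* when its truth
    span overlaps the insertion that only the alternate locus carries;
    for those reads the report counts correct, misplaced, and unaligned
    placements per assembly.  Non-alt-specific reads are summarised by
    their placement agreement between the two assemblies, measured in
    haplotype coordinates.
    """
    for read in reads:
        if read.truth_start is None or read.truth_end is None:
            raise ValueError(f"read {read.name} has no truth position; not from the fixture")
    placement = assembly_with_alt.placements.get(ALT_SCAFFOLD_NAME)
    if placement is None:
        raise ValueError("with-alt assembly lacks the alternate-locus placement")
    insertions = [ev for ev in diff_blocks(placement) if ev[0] == "insertion-in-alt"]
    if not insertions:
        raise ValueError("placement shows no insertion in the alternate locus")
    ins_spans = [alt_span for _, _, alt_span in insertions]

    def is_alt_specific(read: Read) -> bool:
        return any(read.truth_start <= hi and lo <= read.truth_end for lo, hi in ins_spans)

    read_len = len(reads[0].sequence)
    max_edits = int(max_edit_frac * read_len)

    def targets(asm: Assembly) -> dict[str, str]:
        return {name: asm.sequences[name] for unit in asm.units.values()
                for name in unit.members if name in asm.sequences}

    t_with, t_without = targets(assembly_with_alt), targets(assembly_without_alt)

    def to_alt_coord(hit: Optional[tuple[str, int]]) -> Optional[int]:
        if hit is None:
            return None
        name, pos = hit
        if name == ALT_SCAFFOLD_NAME:
            return pos
        try:
            res = liftover(placement, pos, "primary->alt")
        except ValueError:
            return None
        return res.mapped

    counts_with = {"correct": 0, "misplaced": 0, "unaligned": 0}
    counts_without = {"correct": 0, "misplaced": 0, "unaligned": 0}
    n_alt = 0
    non_alt_agree = 0
    non_alt_total = 0
    for read in reads:
        hit_with = _align_read(read.sequence, t_with, max_edits)
        hit_without = _align_read(read.sequence, t_without, max_edits)
        if is_alt_specific(read):
            n_alt += 1
            for hit, counts in ((hit_with, counts_with), (hit_without, counts_without)):
                if hit is None:
                    counts["unaligned"] += 1
                    continue
                mapped = to_alt_coord(hit)
                if mapped is not None and abs(mapped - read.truth_start) <= position_tolerance:
                    counts["correct"] += 1
                else:
                    counts["misplaced"] += 1
        else:
            non_alt_total += 1
            a, b = to_alt_coord(hit_with), to_alt_coord(hit_without)
            if a is None and b is None:
                non_alt_agree += 1
            elif a is not None and b is not None and abs(a - b) <= position_tolerance:
                non_alt_agree += 1
    return AltAwarenessReport(
        n_reads=len(reads),
        n_alt_specific=n_alt,
        with_alt=counts_with,
        without_alt=counts_without,
        non_alt_agreement=(non_alt_agree / non_alt_total) if non_alt_total else 1.0,
    )
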
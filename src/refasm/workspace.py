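"""On-disk assembly directories.

An assembly lives in a directory of plain-text files:

* ``assembly.yaml`` — name, version, units and their members;
* ``objects.agp`` — AGP rows for every assembled object;
* ``components.fa`` — component sequences;
* ``placements.tsv`` — chromosome-context placements for alt/patch members;
* ``patches.tsv`` — kind and lifecycle state of active patches (optional).

Object sequences are not stored: they are rebuilt from the AGP and the
component sequences on load, which keeps the directory small and
guarantees the sequences and the build instructions cannot drift apart.
"""
from __future__ import annotations

import os

import yaml

from . import formats
from .build import build_object_sequence
from .model import (
    Assembly,
    AssembledObject,
    AssemblyUnit,
    ReleaseVersion,
)
from .release import Patch

__all__ = ["save_assembly", "load_assembly", "load_patch_set", "save_patch_set"]


def save_assembly(assembly: Assembly, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    meta = {
        "name": assembly.name,
        "version": str(assembly.version),
        "units": {
            unit.unit_name: {
                "kind": unit.unit_kind,
                "members": {
                    obj.name: {
                        "rank": obj.rank,
                        **({"chromosome": obj.chromosome} if obj.chromosome else {}),
                    }
                    for obj in unit.members.values()
                },
            }
            for unit in assembly.units.values()
        },
    }
    with open(os.path.join(directory, "assembly.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    objects = {}
    for unit in assembly.units.values():
        for obj in unit.members.values():
            objects[obj.name] = obj.rows
    with open(os.path.join(directory, "objects.agp"), "w") as fh:
        formats.write_agp(objects, fh)
    with open(os.path.join(directory, "components.fa"), "w") as fh:
        formats.write_fasta(assembly.component_sequences, fh)
    with open(os.path.join(directory, "placements.tsv"), "w") as fh:
        formats.write_placements(list(assembly.placements.values()), fh)
    if assembly.patches:
        with open(os.path.join(directory, "patches.tsv"), "w") as fh:
            fh.write("#scaffold\tkind\tintroduced_in\tstate\n")
            for patch in assembly.patches.values():
                fh.write(
                    f"{patch.scaffold.name}\t{patch.kind}\t"
                    f"{patch.introduced_in or ''}\t{patch.state}\n"
                )


def load_assembly(directory: str) -> Assembly:
    with open(os.path.join(directory, "assembly.yaml")) as fh:
        meta = yaml.safe_load(fh)
    agp = formats.read_agp(os.path.join(directory, "objects.agp"))
    components = formats.read_fasta(os.path.join(directory, "components.fa"))
    assembly = Assembly(
        name=meta["name"],
        version=ReleaseVersion.parse(str(meta["version"])),
        component_sequences=components,
    )
    for unit_name, unit_meta in meta["units"].items():
        unit = assembly.add_unit(AssemblyUnit(unit_name, unit_meta["kind"]))
        for obj_name, obj_meta in (unit_meta.get("members") or {}).items():
            obj = AssembledObject(
                name=obj_name,
                rank=obj_meta["rank"],
                rows=agp.get(obj_name, []),
                chromosome=obj_meta.get("chromosome"),
            )
            unit.add(obj)
            if obj.rows:
                assembly.sequences[obj_name] = build_object_sequence(obj, components)
    placements_path = os.path.join(directory, "placements.tsv")
    if os.path.exists(placements_path):
        for rec in formats.read_placements(placements_path):
            assembly.placements[rec.alt_scaffold_name] = rec
    patches_path = os.path.join(directory, "patches.tsv")
    if os.path.exists(patches_path):
        with open(patches_path) as fh:
            for line in fh:
                line = line.rstrip()
                if not line or line.startswith("#"):
                    continue
                name, kind, introduced, state = line.split("\t")
                obj = assembly.find_object(name)
                if obj is None:
                    raise ValueError(f"patches.tsv names unknown scaffold {name}")
                assembly.patches[name] = Patch(
                    scaffold=obj,
                    sequence=assembly.sequences[name],
                    kind=kind,
                    placement=assembly.placements[name],
                    introduced_in=ReleaseVersion.parse(introduced) if introduced else None,
                    state=state,
                )
    return assembly


def save_patch_set(patches: list[Patch], components: dict[str, str], directory: str) -> None:
    """Write a set of not-yet-released patches as a directory.

    Layout: ``objects.agp`` (patch scaffolds), ``components.fa``,
    ``placements.tsv``, ``kinds.tsv`` (scaffold, FIX|NOVEL).
    """
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "objects.agp"), "w") as fh:
        formats.write_agp({p.scaffold.name: p.scaffold.rows for p in patches}, fh)
    with open(os.path.join(directory, "components.fa"), "w") as fh:
        formats.write_fasta(components, fh)
    with open(os.path.join(directory, "placements.tsv"), "w") as fh:
        formats.write_placements([p.placement for p in patches], fh)
    with open(os.path.join(directory, "kinds.tsv"), "w") as fh:
        fh.write("#scaffold\tkind\n")
        for p in patches:
            fh.write(f"{p.scaffold.name}\t{p.kind}\n")


def load_patch_set(directory: str) -> list[Patch]:
    """Load a patch-set directory written by :func:`save_patch_set`."""
    agp = formats.read_agp(os.path.join(directory, "objects.agp"))
    components = formats.read_fasta(os.path.join(directory, "components.fa"))
    placements = {
        rec.alt_scaffold_name: rec
        for rec in formats.read_placements(os.path.join(directory, "placements.tsv"))
    }
    kinds: dict[str, str] = {}
    with open(os.path.join(directory, "kinds.tsv")) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            name, kind = line.split("\t")
            kinds[name] = kind
    patches = []
    for name, rows in agp.items():
        obj = AssembledObject(name=name, rank="scaffold", rows=rows)
        used = {r.component_id for r in rows if not r.is_gap}
        patches.append(
            Patch(
                scaffold=obj,
                sequence=build_object_sequence(obj, components),
                kind=kinds[name],
                placement=placements[name],
                component_seqs={cid: components[cid] for cid in used},
            )
        )
    return patches
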
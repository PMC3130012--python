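"""Shared fixtures: small synthetic assemblies built at test time."""
from __future__ import annotations

import numpy as np
import pytest

from refasm.build import build_object_sequence, tpf_to_agp
from refasm.model import Assembly, AssemblyUnit, ReleaseVersion
from refasm.simulate import gen_components, gen_variant_region, variant_assemblies

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def toy_assembly(
    seed: int = 11,
    n: int = 4,
    length: int = 3000,
    overlap_len: int = 300,
    chromosome: str = "chr1",
) -> Assembly:
    """One-chromosome assembly built from generated clone components."""
    gen = gen_components(seed, n=n, length=length, overlap_len=overlap_len, error_rate=0.0)
    result = tpf_to_agp(gen.tiling_path, gen.component_seqs)
    obj = result.object
    obj.name = chromosome
    obj.rank = "chromosome"
    for row in obj.rows:
        row.object_name = chromosome
    asm = Assembly("toy", ReleaseVersion(1, 0))
    asm.add_unit(AssemblyUnit("primary", "primary")).add(obj)
    asm.sequences[chromosome] = build_object_sequence(obj, gen.component_seqs)
    asm.component_sequences.update(gen.component_seqs)
    return asm


@pytest.fixture
def small_assembly() -> Assembly:
    return toy_assembly()


@pytest.fixture(scope="session")
def variant_fixture():
    """Scaled-down dual-haplotype region plus its two assemblies."""
    region = gen_variant_region(7, flank_len=1500, insert_len=400, anchor_overlap=300,
                                spacer_len=300)
    with_alt, without_alt = variant_assemblies(region)
    return region, with_alt, without_alt
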
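"""Overlap detection, switch points, AGP construction, sequence assembly."""
import numpy as np
import pytest

from conftest import random_seq, toy_assembly
from refasm.build import (
    BuildError,
    assembly_stats,
    build_object_sequence,
    find_overlap,
    provenance_map,
    reverse_complement,
    select_switch_point,
    tpf_to_agp,
)
from refasm.model import AssemblyUnit, ComponentRef, GapSpec, TilingPath, TilingPathRow
from refasm.simulate import gen_components


def path_of(seqs: dict[str, str], orientations=None, gaps=None) -> TilingPath:
    """Tiling path over the given components, optional gap after index i."""
    orientations = orientations or ["+"] * len(seqs)
    rows = []
    order = 1
    for i, (acc, seq) in enumerate(seqs.items()):
        rows.append(TilingPathRow(ComponentRef(acc, len(seq)), orientations[i], order))
        order += 1
        if gaps and i in gaps:
            rows.append(TilingPathRow(GapSpec(gaps[i], "contig"), None, order))
            order += 1
    return TilingPath("obj", rows)


class TestFindOverlap:
    def test_exact_dovetail_found(self):
        rng = np.random.default_rng(1)
        x, s, y = random_seq(rng, 900), random_seq(rng, 100), random_seq(rng, 900)
        ov = find_overlap(x + s, s + y, 20, 0.97)
        assert ov is not None
        assert ov.length == 100 and ov.identity == 1.0
        assert ov.left_span == (901, 1000) and ov.right_span == (1, 100)

    def test_two_mismatches_give_098(self):
        rng = np.random.default_rng(2)
        x, s, y = random_seq(rng, 900), random_seq(rng, 100), random_seq(rng, 900)
        s2 = list(s)
        for pos in (10, 60):
            s2[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s2[pos]]
        ov = find_overlap(x + s, "".join(s2) + y, 20, 0.97)
        assert ov is not None and ov.identity == pytest.approx(0.98)
        assert ov.mismatch_offsets == (10, 60)

    def test_unrelated_sequences_give_none(self):
        rng = np.random.default_rng(3)
        left, right = random_seq(rng, 1000), random_seq(rng, 1000)
        # brute-force oracle: no suffix/prefix pair >= 20 reaches 0.97
        la = np.frombuffer(left.encode(), dtype=np.uint8)
        ra = np.frombuffer(right.encode(), dtype=np.uint8)
        best = max((la[-l:] == ra[:l]).mean() for l in range(20, 1001))
        assert best < 0.97
        assert find_overlap(left, right, 20, 0.97) is None

    def test_parameter_bounds_enforced(self):
        with pytest.raises(ValueError):
            find_overlap("A" * 50, "A" * 50, min_len=10)
        with pytest.raises(ValueError):
            find_overlap("A" * 50, "A" * 50, min_identity=0.5)


class TestSelectSwitchPoint:
    def test_exact_overlap_midpoint(self):
        rng = np.random.default_rng(4)
        x, s = random_seq(rng, 900), random_seq(rng, 100)
        ov = find_overlap(x + s, s + random_seq(rng, 900))
        sp = select_switch_point(ov, "L.1", "R.1")
        assert sp.position_in_from == 950  # floor((901+1000)/2)
        assert sp.position_in_to == 50

    def test_central_mismatch_switches_in_longer_run(self):
        # overlap of 101 with one mismatch at its centre (offset 50):
        # runs are [0..49] and [51..100]; both length 50, leftmost wins,
        # midpoint of 1-based run [1..50] is 25 -- oracle by enumeration
        rng = np.random.default_rng(5)
        s = random_seq(rng, 101)
        s_mut = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
        ov = find_overlap(random_seq(rng, 899) + s, s_mut + random_seq(rng, 899),
                          20, 0.97)
        assert ov.mismatch_offsets == (50,)
        sp = select_switch_point(ov)
        runs = [(0, 49), (51, 100)]
        best = max(runs, key=lambda r: r[1] - r[0])  # tie -> first (leftmost)
        expected_offset = (best[0] + best[1] + 2) // 2
        assert sp.position_in_from == ov.left_span[0] + expected_offset - 1
        # the switch point sits strictly inside an exact run
        assert sp.position_in_to == ov.right_span[0] + expected_offset - 1

    def test_minimal_20bp_overlap_switches_at_10(self):
        rng = np.random.default_rng(6)
        s = random_seq(rng, 20)
        ov = find_overlap(random_seq(rng, 980) + s, s + random_seq(rng, 980))
        assert ov.length == 20
        sp = select_switch_point(ov)
        assert sp.position_in_to == 10


class TestTpfToAgp:
    def test_two_components_exact_dovetail_length(self):
        rng = np.random.default_rng(7)
        a = random_seq(rng, 1000)
        b = a[-100:] + random_seq(rng, 900)
        result = tpf_to_agp(path_of({"A1.1": a, "B1.1": b}), {"A1.1": a, "B1.1": b})
        assert result.object.sequence_length == 1900
        assert len(result.switch_points) == 1

    def test_gap_row_passes_through(self):
        rng = np.random.default_rng(8)
        a, b = random_seq(rng, 1000), random_seq(rng, 800)
        path = path_of({"A1.1": a, "B1.1": b}, gaps={0: 100})
        result = tpf_to_agp(path, {"A1.1": a, "B1.1": b})
        assert result.object.sequence_length == 1000 + 100 + 800
        assert result.object.rank == "scaffold"

    def test_three_components_closed_form_and_provenance(self):
        rng = np.random.default_rng(9)
        a = random_seq(rng, 1000)
        b = a[-100:] + random_seq(rng, 900)
        c = b[-150:] + random_seq(rng, 850)
        seqs = {"A1.1": a, "B1.1": b, "C1.1": c}
        result = tpf_to_agp(path_of(seqs), seqs)
        assert result.object.sequence_length == 3000 - 250
        built = build_object_sequence(result.object, seqs)
        # per-base provenance oracle: every object base equals the
        # component base it claims to come from, no gaps, monotone runs
        prov = provenance_map(result.object)
        assert len(prov) == len(built)
        for i, (cid, pos, strand) in enumerate(prov):
            assert strand == "+"
            assert built[i] == seqs[cid][pos - 1]
        assert [cid for cid, _, _ in prov] == sorted(
            [cid for cid, _, _ in prov],
            key=lambda c: ["A1.1", "B1.1", "C1.1"].index(c),
        )

    def test_missing_component_sequence_errors(self):
        rng = np.random.default_rng(10)
        a = random_seq(rng, 1000)
        with pytest.raises(BuildError, match="missing sequence"):
            tpf_to_agp(path_of({"A1.1": a, "B1.1": a}), {"A1.1": a})

    def test_no_overlap_directs_user_to_gap_row(self):
        rng = np.random.default_rng(11)
        seqs = {"A1.1": random_seq(rng, 1000), "B1.1": random_seq(rng, 1000)}
        with pytest.raises(BuildError, match="gap row"):
            tpf_to_agp(path_of(seqs), seqs)


class TestBuildObjectSequence:
    def test_single_plus_row_is_identity(self):
        rng = np.random.default_rng(12)
        g = gen_components(12, n=1, length=500, overlap_len=100, error_rate=0)
        result = tpf_to_agp(g.tiling_path, g.component_seqs)
        assert build_object_sequence(result.object, g.component_seqs) == g.truth

    def test_single_minus_row_is_reverse_complement(self):
        rng = np.random.default_rng(13)
        seq = random_seq(rng, 500)
        path = path_of({"A1.1": seq}, orientations=["-"])
        result = tpf_to_agp(path, {"A1.1": seq})
        assert build_object_sequence(result.object, {"A1.1": seq}) == reverse_complement(seq)

    def test_gap_renders_as_n_run(self):
        rng = np.random.default_rng(14)
        a, b = random_seq(rng, 300), random_seq(rng, 300)
        path = path_of({"A1.1": a, "B1.1": b}, gaps={0: 5})
        built = build_object_sequence(tpf_to_agp(path, {"A1.1": a, "B1.1": b}).object,
                                      {"A1.1": a, "B1.1": b})
        assert built == a + "NNNNN" + b

    def test_span_outside_component_errors(self):
        g = gen_components(15, n=2, length=500, overlap_len=100, error_rate=0)
        result = tpf_to_agp(g.tiling_path, g.component_seqs)
        truncated = {k: v[:-50] for k, v in g.component_seqs.items()}
        with pytest.raises(BuildError, match="outside"):
            build_object_sequence(result.object, truncated)

    def test_reverse_complement_involution(self):
        """Building the reversed, orientation-flipped path yields the
        reverse complement of the forward build."""
        rng = np.random.default_rng(16)
        a = random_seq(rng, 800)
        b = a[-120:] + random_seq(rng, 680)
        seqs = {"A1.1": a, "B1.1": b}
        fwd = tpf_to_agp(path_of(seqs), seqs)
        rev_path = TilingPath("obj", [
            TilingPathRow(ComponentRef("B1.1", 800), "-", 1),
            TilingPathRow(ComponentRef("A1.1", 800), "-", 2),
        ])
        rev = tpf_to_agp(rev_path, seqs)
        assert build_object_sequence(rev.object, seqs) == reverse_complement(
            build_object_sequence(fwd.object, seqs)
        )


class TestAssemblyStats:
    def test_no_gaps(self):
        stats = assembly_stats(toy_assembly())
        assert stats["primary"]["gap_count"] == 0
        assert stats["primary"]["objects"] == 1

    def test_gap_totals_and_additivity(self):
        asm = toy_assembly()
        rng = np.random.default_rng(17)
        seqs = {"G1.1": random_seq(rng, 300), "G2.1": random_seq(rng, 300),
                "G3.1": random_seq(rng, 300), "G4.1": random_seq(rng, 300)}
        p1 = path_of({k: seqs[k] for k in ("G1.1", "G2.1")}, gaps={0: 100})
        p2 = path_of({k: seqs[k] for k in ("G3.1", "G4.1")}, gaps={0: 100})
        unit = asm.add_unit(AssemblyUnit("extra", "alt-loci"))
        for i, p in enumerate((p1, p2)):
            obj = tpf_to_agp(p, seqs).object
            obj.name = f"scaf{i}"
            for r in obj.rows:
                r.object_name = obj.name
            unit.add(obj)
        stats = assembly_stats(asm)
        assert stats["extra"]["gap_count"] == 2
        assert stats["extra"]["gap_bp"] == 200
        for key in ("objects", "total_bp", "gap_count", "gap_bp"):
            assert stats["total"][key] == stats["primary"][key] + stats["extra"][key]
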
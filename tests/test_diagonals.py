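import pytest
from hypothesis import given, settings, strategies as st

from synblock.core_model import Chromosome, FamilySet, Gene, Genome
from synblock.diagonals import (
    METRICS,
    Diagonal,
    detect_synteny_blocks,
    diagonal_distance,
    distance,
    extract_sbs,
    extract_strict_diagonals,
    find_diag_type,
    infer_ancestral_orientation,
    merge_diagonals,
)
from synblock.tandem_mhp import MHP, TbChromosome, TandemBlock, rewrite_in_tbs

from conftest import random_genome_pair


def mhp_from_cells(cells, n_a=None, n_b=None):
    """Build a bare MHP carrying only coordinates and signs."""
    n_a = n_a or (max(x for x, _ in cells) + 1)
    n_b = n_b or (max(y for _, y in cells) + 1)

    def tbs(n, prefix):
        return TbChromosome(
            prefix,
            [TandemBlock(f"{prefix}{i}", [Gene(f"{prefix}g{i}", 1)], 1) for i in range(n)],
        )

    return MHP(tbs(n_a, "a"), tbs(n_b, "b"), dict(cells))


class TestDistance:
    @pytest.mark.parametrize(
        "metric,expected", [("DPD", 5), ("MD", 4), ("CD", 3), ("ED", 3)]
    )
    def test_worked_example_offsets(self, metric, expected):
        assert distance(metric, (5, 5), (8, 4)) == expected

    @settings(deadline=None, max_examples=60)
    @given(
        x1=st.integers(0, 50),
        y1=st.integers(0, 50),
        x2=st.integers(0, 50),
        y2=st.integers(0, 50),
    )
    def test_metric_axioms(self, x1, y1, x2, y2):
        p1, p2 = (x1, y1), (x2, y2)
        for m in METRICS:
            d = distance(m, p1, p2)
            assert d == distance(m, p2, p1)  # symmetry
            assert (d == 0) == (p1 == p2)  # identity of indiscernibles
        assert distance("CD", p1, p2) <= distance("MD", p1, p2)
        assert distance("CD", p1, p2) <= distance("DPD", p1, p2)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            distance("L3", (0, 0), (1, 1))


class TestFindDiagType:
    def test_known_signs_decide(self):
        assert find_diag_type(1, None) == "slash"
        assert find_diag_type(-1, None) == "backslash"

    def test_unknown_sign_uses_second_hp_position(self):
        assert find_diag_type(None, (1, 1)) == "slash"
        assert find_diag_type(None, (1, -1)) == "backslash"

    def test_isolated_unknown_sign_undetermined(self):
        assert find_diag_type(None, None) == "undetermined"


class TestStrictExtraction:
    def test_worked_example(self, fig3_mhp):
        diags = extract_strict_diagonals(fig3_mhp)
        multi = [d for d in diags if d.m > 1]
        singles = [d for d in diags if d.m == 1]
        assert len(multi) == 2 and len(singles) == 2
        assert all(d.diag_type == "backslash" for d in multi)
        assert sorted(len(d.hps) for d in multi) == [2, 2]
        assert {d.hps[0][:2] for d in singles} == {(0, 1), (2, 6)}

    def test_empty_mhp(self):
        assert extract_strict_diagonals(mhp_from_cells({}, 3, 3)) == []

    def test_antidiagonal_consumed_as_one(self):
        k = 5
        cells = {(i, k - 1 - i): -1 for i in range(k)}
        diags = extract_strict_diagonals(mhp_from_cells(cells))
        assert len(diags) == 1 and diags[0].m == k
        assert diags[0].diag_type == "backslash"

    def test_sign_break_splits_diagonal(self):
        cells = {(0, 0): 1, (1, 1): -1, (2, 2): 1}
        diags = extract_strict_diagonals(mhp_from_cells(cells))
        assert sorted(d.m for d in diags) == [1, 1, 1]

    def test_unknown_signs_typed_by_neighbour(self):
        cells = {(0, 2): None, (1, 1): None, (2, 0): None}
        diags = extract_strict_diagonals(mhp_from_cells(cells))
        assert len(diags) == 1 and diags[0].diag_type == "backslash"

    def test_every_hp_in_exactly_one_diagonal(self, fig3_mhp):
        diags = extract_strict_diagonals(fig3_mhp)
        seen = [h[:2] for d in diags for h in d.hps]
        assert sorted(seen) == sorted(fig3_mhp.cells)


class TestMerging:
    def test_worked_example_merge(self, fig3_mhp):
        strict = extract_strict_diagonals(fig3_mhp)
        merged = merge_diagonals(strict, "DPD", 4)
        big = max(merged, key=lambda d: d.m)
        assert big.m == 4 and big.diag_type == "backslash"
        assert [h[:2] for h in big.hps] == [(4, 6), (5, 5), (8, 4), (9, 3)]
        # the +1 single at (2,6) must stay out (sign inconsistent)
        assert {d.hps[0][:2] for d in merged if d.m == 1} == {(0, 1), (2, 6)}

    def test_gapmax_zero_is_identity(self, fig3_mhp):
        strict = extract_strict_diagonals(fig3_mhp)
        merged = merge_diagonals(strict, "DPD", 0)
        assert sorted(
            tuple(h[:2] for h in d.hps) for d in merged
        ) == sorted(tuple(h[:2] for h in d.hps) for d in strict)

    def test_unknown_sign_singles_merge_into_typed_diagonal(self):
        cells = {(0, 0): None, (2, 2): None}
        strict = extract_strict_diagonals(mhp_from_cells(cells, 4, 4))
        merged = merge_diagonals(strict, "CD", 1)
        assert len(merged) == 1
        assert merged[0].diag_type == "slash" and merged[0].m == 2

    def test_equal_y_extremities_never_pair(self):
        # a micro-rearrangement duplicate row: (0,1) and (2,1) cannot chain
        cells = {(0, 1): 1, (2, 1): 1}
        strict = extract_strict_diagonals(mhp_from_cells(cells, 4, 4))
        merged = merge_diagonals(strict, "MD", 5)
        assert len(merged) == 2

    def test_merge_distance_is_min_over_compatible_extremities(self):
        d1 = Diagonal("backslash", [(4, 6, -1), (5, 5, -1)])
        d2 = Diagonal("backslash", [(8, 4, -1), (9, 3, -1)])
        assert diagonal_distance(d1, d2, "DPD") == (5, "backslash")
        single = Diagonal("slash", [(2, 6, 1)])
        # closest compatible extremity pairing is (2,6)-(5,5) at DPD 5,
        # but the fusion itself is later rejected on sign grounds
        assert diagonal_distance(single, d1, "DPD") == (5, "backslash")

    def test_chained_merges_across_distances(self):
        # three singles on the main diagonal, gaps 1 and 1 (CD distance 2)
        cells = {(0, 0): 1, (2, 2): 1, (4, 4): 1}
        strict = extract_strict_diagonals(mhp_from_cells(cells, 6, 6))
        merged = merge_diagonals(strict, "CD", 1)
        assert len(merged) == 1 and merged[0].m == 3

    def test_equidistant_tie_resolved_deterministically(self):
        # an unknown-sign single at (2,2) sits at CD distance 2 from a
        # backslash diagonal (left) and a slash diagonal (right); both
        # fusions give 3 hps, so the leftmost partner wins and the single
        # is claimed by the backslash diagonal
        cells = {(0, 5): -1, (1, 4): -1, (2, 2): None, (4, 4): 1, (5, 5): 1}
        strict = extract_strict_diagonals(mhp_from_cells(cells, 7, 7))
        merged = merge_diagonals(strict, "CD", 1)
        assert sorted(d.m for d in merged) == [2, 3]
        big = max(merged, key=lambda d: d.m)
        assert big.diag_type == "backslash"
        assert [h[:2] for h in big.hps] == [(0, 5), (1, 4), (2, 2)]


@settings(deadline=None, max_examples=20)
@given(seed=st.integers(0, 10_000), metric=st.sampled_from(METRICS))
def test_final_diagonals_stay_consistent(seed, metric):
    """All slash (backslash) diagonals carry only {+1, unknown} ({-1,
    unknown}) signs after extraction and merging, and every hp is used
    exactly once."""
    from synblock.tandem_mhp import build_mhp

    ga, gb, fams = random_genome_pair(seed, n_genes=30, n_shared=20)
    tca = rewrite_in_tbs(ga.chromosomes[0], fams)
    tcb = rewrite_in_tbs(gb.chromosomes[0], fams)
    mhp = build_mhp(tca, tcb)
    strict = extract_strict_diagonals(mhp)
    merged = merge_diagonals(strict, metric, 3)
    used = []
    for d in merged:
        used.extend(h[:2] for h in d.hps)
        allowed = {
            "slash": {1, None},
            "backslash": {-1, None},
            "undetermined": {None},
        }[d.diag_type]
        assert {h[2] for h in d.hps} <= allowed
        xs = [h[0] for h in d.hps]
        ys = [h[1] for h in d.hps]
        assert xs == sorted(xs) and len(set(xs)) == len(xs)
        if d.diag_type == "slash":
            assert ys == sorted(ys) and len(set(ys)) == len(ys)
        elif d.diag_type == "backslash":
            assert ys == sorted(ys, reverse=True) and len(set(ys)) == len(ys)
    assert sorted(used) == sorted(mhp.cells)


@settings(deadline=None, max_examples=10)
@given(seed=st.integers(0, 10_000))
def test_chebyshev_blocks_obey_gapmax(seed):
    """Under the CD metric every reported block is a chain with Chebyshev
    gaps <= gap_max (the formal synteny block definition)."""
    gap_max = 3
    ga, gb, fams = random_genome_pair(seed, n_genes=30, n_shared=25)
    blocks = detect_synteny_blocks(
        ga, gb, fams, metric="CD", gap_max=gap_max, alpha=1.0
    )
    for b in blocks:
        assert b.max_gap <= gap_max


class TestAncestralOrientation:
    def test_tb_a_orientation_wins(self):
        for t in ("slash", "backslash", "undetermined"):
            assert infer_ancestral_orientation(t, 1, -1) == 1

    def test_inferred_from_tb_b_and_type(self):
        assert infer_ancestral_orientation("slash", None, -1) == -1
        assert infer_ancestral_orientation("backslash", None, -1) == 1

    def test_unknown_when_no_information(self):
        assert infer_ancestral_orientation("slash", None, None) is None
        assert infer_ancestral_orientation("undetermined", None, 1) is None


class TestExtractSbs:
    def test_worked_example_window_statistics(self, fig3):
        ga, gb, fams = fig3
        blocks = extract_sbs(
            rewrite_in_tbs(ga.chromosomes[0], fams),
            rewrite_in_tbs(gb.chromosomes[0], fams),
            metric="DPD",
            gap_max=4,
            alpha=1.0,
        )
        big = max(blocks, key=lambda b: b.m)
        assert (big.m, big.l_a, big.l_b, big.max_gap) == (4, 6, 4, 2)

    def test_identity_genomes_single_full_diagonal(self):
        n = 12
        ga = Genome(
            "a", [Chromosome("c", [Gene(f"a{i}", 1) for i in range(n)])]
        )
        gb = Genome(
            "b", [Chromosome("c", [Gene(f"b{i}", 1) for i in range(n)])]
        )
        fams = FamilySet({f"F{i}": {f"a{i}", f"b{i}"} for i in range(n)})
        blocks = extract_sbs(
            rewrite_in_tbs(ga.chromosomes[0], fams),
            rewrite_in_tbs(gb.chromosomes[0], fams),
            metric="CD",
            gap_max=0,
            alpha=1.0,
        )
        assert len(blocks) == 1
        assert blocks[0].m == n and blocks[0].diag_type == "slash"

    def test_disjoint_families_no_blocks(self):
        ga = Genome("a", [Chromosome("c", [Gene("a1", 1)])])
        gb = Genome("b", [Chromosome("c", [Gene("b1", 1)])])
        fams = FamilySet({"F1": {"a1"}, "F2": {"b1"}})
        blocks = extract_sbs(
            rewrite_in_tbs(ga.chromosomes[0], fams),
            rewrite_in_tbs(gb.chromosomes[0], fams),
        )
        assert blocks == []

    def test_significant_block_survives_alpha(self, fig3):
        ga, gb, fams = fig3
        blocks = detect_synteny_blocks(
            ga, gb, fams, metric="DPD", gap_max=4, alpha=1e-3
        )
        assert [b.m for b in blocks] == [4]
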
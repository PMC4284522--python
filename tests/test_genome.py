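"""Structure bookkeeping: moves, candidate enumeration, invariants, layout IO."""

import numpy as np
import pytest

from proxiscaf.genome import (
    Bin,
    GenomeStructure,
    Mutation,
    MutationKind,
    MUTATION_KINDS,
    apply_mutation,
    enumerate_candidates,
    genomic_distance,
    n_contigs,
    read_layout,
    validate,
    write_layout,
)

from conftest import random_placed_pair


def chains(structure):
    return [[p.bin_id for p in sc.placed] for sc in structure.scaffolds]


class TestBin:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Bin(0, 0, 2)
        with pytest.raises(ValueError):
            Bin(0, 100, 0)

    def test_orientability_requires_two_fragments(self):
        assert not Bin(0, 100, 1).orientable
        assert Bin(0, 100, 2).orientable

    def test_single_fragment_bin_has_one_segment(self):
        assert len(Bin(0, 100, 1).segment_lengths) == 1
        assert sum(Bin(0, 100, 3).segment_lengths) == 100


class TestApplyMutation:
    def test_transpose_before(self, toy_bins):
        st = GenomeStructure.from_arrangement(toy_bins, [[(0, 1), (1, 1), (2, 1)]])
        out = apply_mutation(
            st, Mutation(MutationKind.TRANSPOSE_BEFORE_FWD, (2, 0), (0, 0))
        )
        assert chains(out) == [[2, 0, 1]]
        assert chains(st) == [[0, 1, 2]]  # input untouched

    def test_duplicate_after(self, toy_bins):
        st = GenomeStructure.from_arrangement(toy_bins, [[(0, 1), (1, 1), (2, 1)]])
        out = apply_mutation(
            st, Mutation(MutationKind.DUP_AFTER_FWD, (1, 0), (2, 0))
        )
        assert chains(out) == [[0, 1, 2, 1]]
        assert out.multiplicity[1] == 2
        assert out.scaffolds[0].placed[-1].copy_index == 1

    def test_reciprocal_translocation_four_bin_toy(self, toy_bins):
        # [A,B | C,D]: every orientation-consistent arm pairing is reachable,
        # and the exchange at junction bins B,D rejoins arms as [A,D | C,B]
        st = GenomeStructure.from_arrangement(
            toy_bins[:4], [[(0, 1), (1, 1)], [(2, 1), (3, 1)]]
        )
        out = apply_mutation(
            st, Mutation(MutationKind.TRANSLOC_EXCHANGE, (1, 0), (3, 0))
        )
        assert sorted(chains(out)) == [[0, 3], [2, 1]]
        # brute force: the four variants yield four distinct valid structures
        seen = set()
        for kind in (
            MutationKind.TRANSLOC_EXCHANGE,
            MutationKind.TRANSLOC_HEAD_HEAD,
            MutationKind.TRANSLOC_TAIL_HEAD,
            MutationKind.TRANSLOC_TAIL_TAIL,
        ):
            cand = apply_mutation(st, Mutation(kind, (1, 0), (3, 0)))
            assert validate(cand) == []
            seen.add(cand.canonical())
        assert len(seen) == 4

    def test_tail_head_concatenates_scaffolds(self, toy_structure):
        out = apply_mutation(
            toy_structure, Mutation(MutationKind.TRANSLOC_TAIL_HEAD, (2, 0), (3, 0))
        )
        assert chains(out) == [[0, 1, 2, 3, 4, 5]]

    def test_delete_last_copy_goes_unplaced(self, toy_structure):
        out = apply_mutation(toy_structure, Mutation(MutationKind.DELETE, (1, 0)))
        assert 1 in out.unplaced
        assert out.multiplicity[1] == 0
        assert chains(out) == [[0, 2], [3, 4, 5]]

    def test_unplaced_bin_can_reenter(self, toy_structure):
        gone = apply_mutation(toy_structure, Mutation(MutationKind.DELETE, (1, 0)))
        back = apply_mutation(
            gone, Mutation(MutationKind.TRANSPOSE_AFTER_FWD, (1, None), (0, 0))
        )
        assert 1 not in back.unplaced
        assert chains(back) == [[0, 1, 2], [3, 4, 5]]
        # copy index was never reused
        assert back.scaffolds[0].placed[1].copy_index == 1

    def test_eject_forms_singleton(self, toy_structure):
        out = apply_mutation(toy_structure, Mutation(MutationKind.EJECT, (1, 0)))
        assert sorted(chains(out)) == [[0, 2], [1], [3, 4, 5]]

    def test_unknown_placement_rejected(self, toy_structure):
        with pytest.raises(KeyError):
            apply_mutation(
                toy_structure, Mutation(MutationKind.DELETE, (1, 7))
            )

    def test_non_orientable_bin_never_flipped(self):
        bins = [Bin(0, 100, 1), Bin(1, 100, 2)]
        st = GenomeStructure.from_arrangement(bins, [[(0, 1), (1, 1)]])
        out = apply_mutation(
            st, Mutation(MutationKind.TRANSPOSE_AFTER_REV, (0, 0), (1, 0))
        )
        assert out.scaffolds[0].placed[-1].orientation == 1


class TestEnumerate:
    @pytest.mark.parametrize("m", [1, 3])
    def test_candidate_count_is_14m(self, toy_structure, m):
        partners = [(3, 0), (4, 0), (5, 0)][:m]
        cands = enumerate_candidates(toy_structure, (0, 0), partners)
        assert len(cands) == 14 * m

    def test_all_candidates_valid(self, toy_structure):
        partners = [(3, 0)]
        for mv, cand in enumerate_candidates(toy_structure, (0, 0), partners):
            assert validate(cand) == [], mv

    def test_empty_partner_list_rejected(self, toy_structure):
        with pytest.raises(ValueError):
            enumerate_candidates(toy_structure, (0, 0), [])

    def test_unplaced_bin_still_yields_14(self, toy_structure):
        gone = apply_mutation(toy_structure, Mutation(MutationKind.DELETE, (1, 0)))
        cands = enumerate_candidates(gone, (1, None), [(3, 0)])
        assert len(cands) == 14
        assert all(validate(c) == [] for _, c in cands)


class TestGeometry:
    def test_adjacent_bins(self, toy_structure):
        g = genomic_distance(toy_structure, (0, 0), (1, 0))
        assert not g.is_trans
        assert g.s == 10_000

    def test_self_distance_zero(self, toy_structure):
        assert genomic_distance(toy_structure, (0, 0), (0, 0)).s == 0

    def test_trans_flag(self, toy_structure):
        assert genomic_distance(toy_structure, (0, 0), (3, 0)).is_trans

    def test_strand_symmetry(self, toy_bins):
        fwd = GenomeStructure.from_arrangement(toy_bins, [[(0, 1), (1, 1), (2, 1)]])
        rev = GenomeStructure.from_arrangement(toy_bins, [[(2, -1), (1, -1), (0, -1)]])
        for a, b in [((0, 0), (2, 0)), ((1, 0), (2, 0))]:
            assert (
                genomic_distance(fwd, a, b).s == genomic_distance(rev, a, b).s
            )
        assert fwd.equivalent(rev)


class TestNContigs:
    def test_counts_scaffolds_only(self, toy_structure):
        assert n_contigs(toy_structure) == 2
        gone = apply_mutation(toy_structure, Mutation(MutationKind.DELETE, (1, 0)))
        assert n_contigs(gone) == 2  # unplaced pool not counted

    def test_split_increments(self, toy_structure):
        out = apply_mutation(
            toy_structure,
            Mutation(MutationKind.TRANSLOC_EXCHANGE, (1, 0), (2, 0)),
        )
        assert n_contigs(out) == 3


class TestValidate:
    def test_fresh_structure_clean(self, toy_structure):
        assert validate(toy_structure) == []

    def test_corrupted_multiplicity_reported(self, toy_bins):
        st = GenomeStructure.from_arrangement(toy_bins, [[(0, 1), (1, 1)]])
        # hand-corrupt: claim bin 0 unplaced although it is placed
        bad = GenomeStructure(st.bins, st.scaffolds, unplaced={0})
        msgs = validate(bad)
        assert any("unplaced" in m for m in msgs)

    def test_thousand_random_moves_stay_valid(self, toy_bins):
        rng = np.random.default_rng(5)
        st = GenomeStructure.from_arrangement(
            toy_bins, [[(i, 1) for i in range(6)]]
        )
        for _ in range(1000):
            placed = [
                (p.bin_id, p.copy_index)
                for sc in st.scaffolds
                for p in sc.placed
            ]
            if len(placed) < 2:
                break
            a, b = random_placed_pair(st, rng)
            kind = MUTATION_KINDS[rng.integers(14)]
            st = apply_mutation(st, Mutation(kind, a, b))
            assert validate(st) == []


class TestReversibility:
    def test_non_delete_moves_invertible(self, toy_bins):
        """Every non-delete move is undone by a single move found by brute
        force (duplications by deleting the new copy, splits by re-merging)."""
        base = GenomeStructure.from_arrangement(
            toy_bins, [[(0, 1), (1, 1), (2, 1), (3, 1)], [(4, 1), (5, 1)]]
        )

        def all_single_moves(st):
            placed = [
                (p.bin_id, p.copy_index) for sc in st.scaffolds for p in sc.placed
            ]
            for a in placed:
                for b in placed:
                    if a == b:
                        continue
                    for kind in MUTATION_KINDS:
                        yield Mutation(kind, a, b)

        target = base.canonical()
        for kind in MUTATION_KINDS:
            if kind is MutationKind.DELETE:
                continue
            step1 = apply_mutation(base, Mutation(kind, (1, 0), (4, 0)))
            if step1.canonical() == target:
                continue
            found = any(
                apply_mutation(step1, mv2).canonical() == target
                for mv2 in all_single_moves(step1)
            )
            assert found, f"{kind} not invertible by a single move"


class TestLayoutIO:
    def test_round_trip(self, toy_structure, tmp_path):
        gone = apply_mutation(toy_structure, Mutation(MutationKind.DELETE, (5, 0)))
        path = tmp_path / "layout.tsv"
        write_layout(gone, path)
        back = read_layout(path, gone.bins)
        assert back.canonical() == gone.canonical()
        assert back.unplaced == gone.unplaced
        # byte-identical on rewrite
        path2 = tmp_path / "layout2.tsv"
        write_layout(back, path2)
        assert path.read_text() == path2.read_text()
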
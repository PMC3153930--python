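"""Haplotype enumeration, genotype decomposition and Mendelian checking."""

import numpy as np
import pytest

from c4redvr.caller import C4DiploidGenotype
from c4redvr.pedigree import (
    C4Haplotype,
    Pedigree,
    PedigreeMember,
    check_mendelian,
    decompose_genotype,
    enumerate_haplotypes,
    read_pedigree_table,
    write_pedigree_table,
)


def brute_force_decompositions(g, max_copies=4):
    """Independent oracle: scan all unordered pairs over the full haplotype
    grid and keep those summing to the genotype."""
    haps = enumerate_haplotypes(max_copies)
    target = (g.nA - g.iA, g.iA, g.nB - g.iB, g.iB)
    found = set()
    for i, h1 in enumerate(haps):
        for h2 in haps[i:]:
            if tuple(a + b for a, b in zip(h1.counts, h2.counts)) == target:
                found.add(tuple(sorted((h1, h2))))
    return found


def random_valid_genotype(rng):
    while True:
        nA, nB = int(rng.integers(0, 9)), int(rng.integers(0, 9))
        if 2 <= nA + nB <= 8:
            return C4DiploidGenotype(
                nA, nB, int(rng.integers(0, nA + 1)), int(rng.integers(0, nB + 1))
            )


class TestEnumerateHaplotypes:
    @pytest.mark.parametrize("max_copies,expected", [(1, 4), (2, 14), (3, 34), (4, 69)])
    def test_counts(self, max_copies, expected):
        haps = enumerate_haplotypes(max_copies)
        assert len(haps) == expected
        assert len(set(haps)) == expected

    def test_every_haplotype_has_at_least_one_gene(self):
        assert all(1 <= h.total <= 4 for h in enumerate_haplotypes())

    def test_empty_chromosome_rejected(self):
        with pytest.raises(ValueError):
            C4Haplotype(0, 0, 0, 0)


class TestDecomposeGenotype:
    def test_symmetric_split_present(self):
        pairs = decompose_genotype(C4DiploidGenotype(2, 2, 0, 0))
        assert (C4Haplotype(1, 0, 1, 0), C4Haplotype(1, 0, 1, 0)) in pairs

    def test_empty_chromosome_pairs_excluded(self):
        pairs = decompose_genotype(C4DiploidGenotype(1, 1, 1, 0))
        # the only split puts one gene on each chromosome
        assert pairs == [tuple(sorted((C4Haplotype(0, 1, 0, 0), C4Haplotype(0, 0, 1, 0))))]

    def test_impossible_genotype_empty(self):
        g = C4DiploidGenotype(5, 0, 0, 0)
        assert decompose_genotype(g, max_copies=2) == []

    def test_matches_brute_force_grid_scan(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            g = random_valid_genotype(rng)
            assert set(decompose_genotype(g)) == brute_force_decompositions(g)

    def test_all_pairs_sum_to_genotype(self):
        g = C4DiploidGenotype(3, 2, 1, 1)
        target = (g.nA - g.iA, g.iA, g.nB - g.iB, g.iB)
        for h1, h2 in decompose_genotype(g):
            assert tuple(a + b for a, b in zip(h1.counts, h2.counts)) == target


def trio(father_g, mother_g, child_g):
    return Pedigree(
        (
            PedigreeMember("f", None, None, father_g),
            PedigreeMember("m", None, None, mother_g),
            PedigreeMember("c", "f", "m", child_g),
        )
    )


class TestCheckMendelian:
    def test_transmitted_insertion_consistent(self):
        ped = trio(
            C4DiploidGenotype(2, 2, 1, 0),
            C4DiploidGenotype(2, 2, 0, 0),
            C4DiploidGenotype(2, 2, 1, 0),
        )
        ok, witness = check_mendelian(ped)
        assert ok
        hf, hm = witness["c"]
        assert hf in witness["f"] and hm in witness["m"]
        assert hf.ai + hm.ai == 1

    def test_de_novo_insertion_inconsistent(self):
        ped = trio(
            C4DiploidGenotype(2, 2, 0, 0),
            C4DiploidGenotype(2, 2, 0, 0),
            C4DiploidGenotype(2, 2, 1, 0),
        )
        assert check_mendelian(ped) == (False, None)

    def test_ceu_like_trio_untyped_father(self):
        # mother and child both carry a C4A insertion; father untyped
        ped = Pedigree(
            (
                PedigreeMember("f", None, None, None),
                PedigreeMember("m", None, None, C4DiploidGenotype(2, 2, 1, 0)),
                PedigreeMember("c", "f", "m", C4DiploidGenotype(2, 2, 1, 0)),
            )
        )
        ok, witness = check_mendelian(ped)
        assert ok and witness["c"][1] in witness["m"]

    def test_all_wild_type_family_consistent(self):
        ped = Pedigree(
            (
                PedigreeMember("f", None, None, C4DiploidGenotype(2, 2, 0, 0)),
                PedigreeMember("m", None, None, C4DiploidGenotype(2, 2, 0, 0)),
                PedigreeMember("c1", "f", "m", C4DiploidGenotype(2, 2, 0, 0)),
                PedigreeMember("c2", "f", "m", C4DiploidGenotype(2, 2, 0, 0)),
            )
        )
        assert check_mendelian(ped)[0]

    def test_symmetric_under_parent_and_child_order(self):
        f = C4DiploidGenotype(3, 1, 1, 0)
        m = C4DiploidGenotype(2, 2, 0, 1)
        c1 = C4DiploidGenotype(3, 1, 1, 0)
        c2 = C4DiploidGenotype(2, 2, 0, 1)

        def build(fg, mg, children):
            members = [
                PedigreeMember("p1", None, None, fg),
                PedigreeMember("p2", None, None, mg),
            ] + [
                PedigreeMember(f"c{i}", "p1", "p2", cg)
                for i, cg in enumerate(children)
            ]
            return Pedigree(tuple(members))

        results = {
            check_mendelian(build(fg, mg, order))[0]
            for fg, mg in ((f, m), (m, f))
            for order in ((c1, c2), (c2, c1))
        }
        assert len(results) == 1

    def test_sibling_copy_number_conflict_detected(self):
        # parents can jointly supply at most 4 haplotypes; three children
        # requiring three distinct haplotypes from one parent must fail
        ped = Pedigree(
            (
                PedigreeMember("f", None, None, C4DiploidGenotype(1, 1, 0, 0)),
                PedigreeMember("m", None, None, C4DiploidGenotype(1, 1, 0, 0)),
                PedigreeMember("c", "f", "m", C4DiploidGenotype(4, 0, 0, 0)),
            )
        )
        assert not check_mendelian(ped)[0]

    def test_self_ancestor_rejected(self):
        with pytest.raises(ValueError):
            Pedigree(
                (
                    PedigreeMember("a", "b", None, None),
                    PedigreeMember("b", "a", None, None),
                )
            )


class TestPedigreeIO:
    def test_round_trip(self, tmp_path):
        ped = trio(
            C4DiploidGenotype(2, 2, 1, 0),
            C4DiploidGenotype(2, 2, 0, 0),
            C4DiploidGenotype(2, 2, 1, 0),
        )
        untyped = Pedigree(
            (
                PedigreeMember("x", None, None, None),
                PedigreeMember("y", None, None, C4DiploidGenotype(2, 2, 0, 0)),
                PedigreeMember("z", "x", "y", C4DiploidGenotype(2, 2, 0, 0), affected=True),
            ),
            family_id="FAM2",
        )
        path = tmp_path / "families.tsv"
        write_pedigree_table([ped, untyped], str(path))
        back = read_pedigree_table(str(path))
        assert [p.family_id for p in back] == ["FAM", "FAM2"]
        assert back[1].member("x").genotype is None
        assert back[1].member("z").affected
        assert back[0].member("c").genotype == C4DiploidGenotype(2, 2, 1, 0)
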
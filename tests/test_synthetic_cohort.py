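"""Cohort generator, fixtures and assay-readout round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import c4redvr as c4
from c4redvr.caller import C4DiploidGenotype
from c4redvr.pedigree import Pedigree, PedigreeMember
from c4redvr.synthetic_cohort import (
    CohortParams,
    SnpSpec,
    _SPAIN_HAPLOTYPES,
    _UK_HAPLOTYPES,
)


class TestFixtures:
    def test_uk_fixture_composition(self):
        fx = c4.load_fixture("UK")
        calls = fx.calls
        assert len(calls) == 719
        assert (calls["iA"] >= 1).sum() == 30
        assert (calls["iB"] >= 1).sum() == 0
        # per-class counts: 26 single / 2 double / 1 triple / 1 sole-copy
        assert ((calls.iA == 1) & (calls.nA >= 2)).sum() == 26
        assert ((calls.iA == 2) & (calls.nA == 3)).sum() == 2
        assert ((calls.iA == 3) & (calls.nA == 4)).sum() == 1
        assert ((calls.iA == 1) & (calls.nA == 1)).sum() == 1

    def test_spain_fixture_composition(self):
        fx = c4.load_fixture("Spain")
        calls = fx.calls
        assert len(calls) == 449
        assert (calls["iA"] >= 1).sum() == 8
        assert (calls["iB"] == 1).sum() == 1
        assert ((calls.iA == 1) & (calls.nA == 2)).sum() == 6
        assert ((calls.iA == 1) & (calls.nA == 3)).sum() == 1
        assert ((calls.iA == 1) & (calls.nA == 4)).sum() == 1

    def test_fixture_hla_counts(self):
        for label, typed, with13 in (("UK", 28, 23), ("Spain", 5, 3)):
            fx = c4.load_fixture(label)
            res = c4.drb1_cocarriage(fx.calls, fx.hla)
            assert (res.carriers_with_allele, res.carriers_typed) == (with13, typed)

    def test_fixture_regenerates_identically(self):
        for label in ("UK", "Spain"):
            a, b = c4.load_fixture(label), c4.load_fixture(label)
            assert a.calls.to_csv(index=False) == b.calls.to_csv(index=False)
            assert a.hla.to_csv(index=False) == b.hla.to_csv(index=False)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            c4.load_fixture("France")


class TestSimulateCohort:
    def test_zero_insertion_frequency_no_carriers(self):
        freqs = tuple(
            (h, f) for h, f in _UK_HAPLOTYPES if h.ai == 0
        )
        total = sum(f for _, f in freqs)
        freqs = tuple((h, f / total) for h, f in freqs)
        params = CohortParams(label="UK", n_individuals=200, haplotype_freqs=freqs)
        sim = c4.simulate_cohort(params)
        assert (sim.calls["iA"] == 0).all()

    def test_carrier_percentage_matches_binomial_expectation(self):
        # insertion haplotype frequency 0.0208 -> 1-(1-0.0208)^2 = 4.12%
        reps = 200
        pcts = []
        for seed in range(reps):
            params = c4.uk_cohort_params(seed=seed)
            params = CohortParams(
                label="UK",
                n_individuals=719,
                haplotype_freqs=params.haplotype_freqs,
                snp_specs=(),
                seed=seed,
            )
            sim = c4.simulate_cohort(params)
            pcts.append(c4.carrier_frequency(sim.calls, "C4A"))
        expect = 100 * (1 - (1 - 0.0208) ** 2)
        se = np.std(pcts, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(pcts) - expect) < 2 * se + 1e-9

    def test_haplotype_draws_respect_frequencies(self):
        params = CohortParams(
            label="UK", n_individuals=20_000, haplotype_freqs=_UK_HAPLOTYPES, seed=5
        )
        sim = c4.simulate_cohort(params)
        haps = [h for h, _ in _UK_HAPLOTYPES]
        freqs = np.array([f for _, f in _UK_HAPLOTYPES])
        counts = np.zeros(len(haps))
        index = {h: i for i, h in enumerate(haps)}
        for h1, h2 in sim.haplotypes:
            counts[index[h1]] += 1
            counts[index[h2]] += 1
        chi2 = stats.chisquare(counts, freqs * counts.sum())
        assert chi2.pvalue > 0.01

    def test_marker_hits_target_r2_at_large_n(self):
        params = CohortParams(
            label="UK",
            n_individuals=10_000,
            haplotype_freqs=_UK_HAPLOTYPES,
            snp_specs=(SnpSpec("m", 1, 0.4),),
            seed=3,
        )
        sim = c4.simulate_cohort(params)
        res = c4.snp_insertion_r2(sim.calls, sim.dosages)
        assert 0.35 <= res.loc[0, "r2"] <= 0.45

    def test_infeasible_target_r2_rejected(self):
        freqs = tuple((h, f) for h, f in _UK_HAPLOTYPES if h.ai == 0)
        total = sum(f for _, f in freqs)
        freqs = tuple((h, f / total) for h, f in freqs)
        params = CohortParams(
            label="UK",
            n_individuals=50,
            haplotype_freqs=freqs,
            snp_specs=(SnpSpec("m", 1, 0.4),),
        )
        with pytest.raises(ValueError, match="infeasible"):
            c4.simulate_cohort(params)

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortParams(
                label="x",
                n_individuals=10,
                haplotype_freqs=((c4.C4Haplotype(1, 0, 0, 0), 0.5),),
            )

    def test_deterministic_given_seed(self):
        a = c4.simulate_cohort(c4.uk_cohort_params(n_individuals=50, seed=9))
        b = c4.simulate_cohort(c4.uk_cohort_params(n_individuals=50, seed=9))
        pd.testing.assert_frame_equal(a.calls, b.calls)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)


class TestSimulatePedigrees:
    def test_generated_families_always_mendelian(self):
        peds = c4.simulate_pedigrees(25, c4.uk_cohort_params(seed=4), n_children=3)
        assert all(c4.check_mendelian(p)[0] for p in peds)

    def test_child_transmission_matches_enumeration(self):
        """Child genotypes of fixed parental haplotypes are exactly the four
        (hf, hm) combinations, each appearing for some seed."""
        params = c4.spain_cohort_params(seed=0)
        peds = c4.simulate_pedigrees(40, params, n_children=2)
        for ped in peds:
            father = ped.member(f"{ped.family_id}-father").genotype
            mother = ped.member(f"{ped.family_id}-mother").genotype
            f_dec = c4.decompose_genotype(father)
            m_dec = c4.decompose_genotype(mother)
            allowed = set()
            for fp in f_dec:
                for mp in m_dec:
                    for hf in fp:
                        for hm in mp:
                            g = (
                                hf.aw + hf.ai + hm.aw + hm.ai,
                                hf.bw + hf.bi + hm.bw + hm.bi,
                                hf.ai + hm.ai,
                                hf.bi + hm.bi,
                            )
                            allowed.add(g)
            for m in ped.members:
                if m.father_id:
                    g = m.genotype
                    assert (g.nA, g.nB, g.iA, g.iB) in allowed

    def test_corrupted_child_detected(self):
        peds = c4.simulate_pedigrees(30, c4.uk_cohort_params(seed=8), n_children=2)
        detected = False
        for ped in peds:
            child = ped.member(f"{ped.family_id}-child1")
            g = child.genotype
            if g.iA + 1 > g.nA:
                continue
            corrupted = C4DiploidGenotype(g.nA, g.nB, g.iA + 1, g.iB)
            members = tuple(
                PedigreeMember(m.id, m.father_id, m.mother_id, corrupted, m.affected)
                if m.id == child.id
                else m
                for m in ped.members
            )
            ok, _ = c4.check_mendelian(Pedigree(members, ped.family_id))
            parents_carry = any(
                ped.member(f"{ped.family_id}-{p}").genotype.iA > 0
                for p in ("father", "mother")
            )
            if not parents_carry:
                # insertion copy with no parental source must fail
                assert not ok
                detected = True
        assert detected


class TestGeneratePeakData:
    def test_noiseless_round_trip_on_fixture(self):
        fx = c4.load_fixture("Spain")
        q = c4.generate_peak_data(fx.calls, c4.NoiseModel(cv=0.0), seed=0)
        gcn = fx.calls.rename(columns={"nA": "C4A_GCN", "nB": "C4B_GCN"})[
            ["sample_id", "C4A_GCN", "C4B_GCN"]
        ]
        calls = c4.call_cohort(q, gcn)
        merged = calls.merge(fx.calls, on="sample_id", suffixes=("_c", "_t"))
        assert (merged.iA_c == merged.iA_t).all()
        assert (merged.iB_c == merged.iB_t).all()

    def test_concordance_degrades_with_noise(self):
        params = c4.uk_cohort_params(n_individuals=400, seed=21)
        sim = c4.simulate_cohort(params)
        gcn = sim.calls.rename(columns={"nA": "C4A_GCN", "nB": "C4B_GCN"})[
            ["sample_id", "C4A_GCN", "C4B_GCN"]
        ]
        conc = []
        for cv in (0.0, 0.2, 0.6):
            q = c4.generate_peak_data(sim.calls, c4.NoiseModel(cv=cv), seed=22)
            calls = c4.call_cohort(q, gcn)
            m = calls.merge(sim.calls, on="sample_id", suffixes=("_c", "_t"))
            conc.append(((m.iA_c == m.iA_t) & (m.iB_c == m.iB_t)).mean())
        assert conc[0] >= conc[1] >= conc[2]
        assert conc[0] == 1.0 and conc[2] < 1.0
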
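"""Synthetic cohorts, pedigrees and assay readouts for the C4 CT-insertion
pipeline, plus deterministic fixtures transcribing the reported composition
of the genotyped UK (N=719) and Spanish (N=449) control cohorts.

The generator draws two RCCX haplotypes per individual from a frequency
table over single-chromosome C4 configurations, calibrated so the UK-like
and Spain-like defaults approximately reproduce the reported gene copy
number moments (UK total GCN 3.89 +/- 0.76; Spain 4.13 +/- 1.02) and
carrier-chromosome frequencies (2.08% / 0.89%). The CT insertion rides an
A-bearing bimodular haplotype; a rare B-insertion haplotype in the
Spain-like table models the single observed C4B event (plausibly a gene
conversion). HLA-DRB1*13 tags attach preferentially to insertion
haplotypes (imperfect LD), and flanking SNP markers are placed on the
insertion background at a concordance solved to hit a requested r^2 with
the insertion copy number.

Marker assignment is stratified rather than i.i.d.: the concordance is
solved against the realized insertion haplotype count and exactly the
implied number of non-insertion haplotypes receive the marker allele
(randomized rounding). This keeps the realized r^2 tightly around its
target at cohort-scale sample sizes, where independent Bernoulli draws
would swamp the target in sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .caller import C4DiploidGenotype
from .electropherogram import (
    PGF_QUARTET,
    NoiseModel,
    PeakQuartet,
    integrate_peaks,
    mix_with_reference,
    simulate_trace,
)
from .pedigree import C4Haplotype, Pedigree, PedigreeMember
from .popstats import CohortTable

__all__ = [
    "SnpSpec",
    "CohortParams",
    "SimulatedCohort",
    "uk_cohort_params",
    "spain_cohort_params",
    "simulate_cohort",
    "simulate_pedigrees",
    "load_fixture",
    "generate_peak_data",
    "simulate_spikein_quartets",
]


@dataclass(frozen=True)
class SnpSpec:
    """A flanking marker to simulate: id, chromosomal position (bp) and the
    target squared correlation with the C4A insertion copy number."""

    marker: str
    position: int
    target_r2: float

    def __post_init__(self) -> None:
        if not 0 <= self.target_r2 <= 1:
            raise ValueError("target_r2 must lie in [0, 1]")


@dataclass(frozen=True)
class CohortParams:
    """Generative settings for one synthetic cohort."""

    label: str
    n_individuals: int
    haplotype_freqs: tuple  # ((C4Haplotype, frequency), ...)
    drb13_linkage: float = 0.85  # P(DRB1*13 tag | insertion haplotype)
    drb13_background: float = 0.088  # P(DRB1*13 tag | other haplotype)
    snp_specs: tuple = ()
    noise: NoiseModel = NoiseModel()
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.haplotype_freqs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if any(f < 0 for _, f in self.haplotype_freqs):
            raise ValueError("haplotype frequencies must be non-negative")

    @property
    def insertion_haplotype_frequency(self) -> float:
        """Frequency of haplotypes bearing a C4A insertion."""
        return sum(f for h, f in self.haplotype_freqs if h.ai > 0)


@dataclass
class SimulatedCohort(CohortTable):
    """A CohortTable plus the underlying per-individual haplotype pairs
    (ground truth for transmission and round-trip tests)."""

    haplotypes: tuple = ()


# Haplotype tables calibrated to the reported GCN moments and null-homozygote
# frequencies (see docs/methods.md for the calibration arithmetic).
_UK_HAPLOTYPES = (
    (C4Haplotype(1, 0, 0, 0), 0.1500),
    (C4Haplotype(0, 0, 1, 0), 0.0235),
    (C4Haplotype(2, 0, 0, 0), 0.0400),
    (C4Haplotype(0, 0, 2, 0), 0.0885),
    (C4Haplotype(1, 0, 1, 0), 0.5587),
    (C4Haplotype(0, 1, 1, 0), 0.0208),  # CT-insertion haplotype
    (C4Haplotype(2, 0, 1, 0), 0.0800),
    (C4Haplotype(1, 0, 2, 0), 0.0385),
)

_SPAIN_HAPLOTYPES = (
    (C4Haplotype(1, 0, 0, 0), 0.1250),
    (C4Haplotype(0, 0, 1, 0), 0.0550),
    (C4Haplotype(2, 0, 0, 0), 0.0350),
    (C4Haplotype(0, 0, 2, 0), 0.0500),
    (C4Haplotype(1, 0, 1, 0), 0.4950),
    (C4Haplotype(0, 1, 1, 0), 0.0089),  # C4A CT-insertion haplotype
    (C4Haplotype(1, 0, 0, 1), 0.0011),  # rare C4B insertion (gene conversion)
    (C4Haplotype(2, 0, 1, 0), 0.1200),
    (C4Haplotype(1, 0, 2, 0), 0.0700),
    (C4Haplotype(2, 0, 2, 0), 0.0400),
)

_UK_SNPS = (
    SnpSpec("rs2734331", 31_742_508, 0.43),
    SnpSpec("rs453098", 31_694_000, 0.20),
    SnpSpec("rs707915", 31_721_000, 0.20),
)

_SPAIN_SNPS = (
    SnpSpec("rs2228088", 31_575_000, 0.25),
    SnpSpec("rs6927077", 32_370_000, 0.25),
    SnpSpec("rs11964779", 31_721_500, 0.12),
)

_HLA_POOL_2DIGIT = ("01", "03", "04", "07", "11", "15")
_HLA_POOL_4DIGIT = ("01:01", "03:01", "04:01", "07:01", "11:01", "15:01")


def uk_cohort_params(n_individuals: int = 719, seed: int = 0) -> CohortParams:
    """UK-like generator defaults: insertion haplotype frequency 0.0208,
    DRB1*13 background 8.8% (overall allele frequency ~10.4%)."""
    return CohortParams(
        label="UK",
        n_individuals=n_individuals,
        haplotype_freqs=_UK_HAPLOTYPES,
        drb13_linkage=0.85,
        drb13_background=0.088,
        snp_specs=_UK_SNPS,
        seed=seed,
    )


def spain_cohort_params(n_individuals: int = 449, seed: int = 0) -> CohortParams:
    """Spain-like generator defaults: insertion haplotype frequencies
    0.0089 (C4A) and 0.0011 (C4B), DRB1*13 background 11.7% (overall
    ~12.3%)."""
    return CohortParams(
        label="Spain",
        n_individuals=n_individuals,
        haplotype_freqs=_SPAIN_HAPLOTYPES,
        drb13_linkage=0.85,
        drb13_background=0.117,
        snp_specs=_SPAIN_SNPS,
        seed=seed,
    )


def _solve_marker_concordance(target_r2: float, f: float) -> float:
    """Background marker frequency q0 such that a marker present on every
    insertion haplotype (q1 = 1) and on a fraction q0 of the others has
    haplotype-level r^2 = target with insertion status at insertion
    frequency f."""

    def r2(q0: float) -> float:
        p_m = f + (1 - f) * q0
        return f * (1 - f) * (1 - q0) ** 2 / (p_m * (1 - p_m))

    if target_r2 <= 0:
        return 0.3  # uncorrelated background marker
    if f <= 0 or f >= 1:
        raise ValueError(
            f"target r2={target_r2} is infeasible: insertion haplotype "
            f"frequency is {f}; the marker cannot correlate with an absent "
            "(or fixed) insertion"
        )
    if target_r2 >= 1:
        return 0.0
    return float(optimize.brentq(lambda q: r2(q) - target_r2, 0.0, 1 - 1e-12))


def _genotype_from(h1: C4Haplotype, h2: C4Haplotype) -> C4DiploidGenotype:
    return C4DiploidGenotype(
        nA=h1.aw + h1.ai + h2.aw + h2.ai,
        nB=h1.bw + h1.bi + h2.bw + h2.bi,
        iA=h1.ai + h2.ai,
        iB=h1.bi + h2.bi,
    )


def simulate_cohort(params: CohortParams) -> SimulatedCohort:
    """Draw a cohort: two haplotypes per individual from the frequency
    table, genotype as the componentwise sum, HLA-DRB1 tags and flanking
    markers placed on the haplotypes. Deterministic given ``params.seed``."""
    ss = np.random.SeedSequence(params.seed)
    rng_hap, rng_hla, rng_snp = (np.random.default_rng(s) for s in ss.spawn(3))

    haps = [h for h, _ in params.haplotype_freqs]
    freqs = np.array([f for _, f in params.haplotype_freqs])
    n = params.n_individuals
    draws = rng_hap.choice(len(haps), size=2 * n, p=freqs)
    pairs = draws.reshape(n, 2)

    prefix = "UK" if params.label.upper() == "UK" else params.label[:2].upper()
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    calls = pd.DataFrame(
        [
            {
                "sample_id": sid,
                **{
                    k: getattr(_genotype_from(haps[a], haps[b]), k)
                    for k in ("nA", "nB", "iA", "iB")
                },
            }
            for sid, (a, b) in zip(ids, pairs)
        ]
    )

    # HLA-DRB1 tags: preferential but imperfect linkage to the insertion.
    ins_hap = np.array([h.ai + h.bi > 0 for h in haps])
    tag_p = np.where(ins_hap[draws], params.drb13_linkage, params.drb13_background)
    tagged = rng_hla.random(2 * n) < tag_p
    four_digit = params.label.upper() != "UK"
    pool = _HLA_POOL_4DIGIT if four_digit else _HLA_POOL_2DIGIT
    drb13 = "13:02" if four_digit else "13"
    alleles = np.where(
        tagged, drb13, np.asarray(pool)[rng_hla.integers(0, len(pool), size=2 * n)]
    ).reshape(n, 2)
    hla = pd.DataFrame(
        {"sample_id": ids, "allele1": alleles[:, 0], "allele2": alleles[:, 1]}
    )

    # Flanking markers on the C4A-insertion background, stratified so the
    # realized haplotype-level r^2 matches the target (see module docstring).
    a_ins_hap = np.array([h.ai > 0 for h in haps])[draws]
    k_ins = int(a_ins_hap.sum())
    dosage_cols = {}
    positions = {}
    for spec in params.snp_specs:
        if spec.target_r2 > 0 and params.insertion_haplotype_frequency <= 0:
            raise ValueError(
                f"marker {spec.marker}: target r2={spec.target_r2} infeasible "
                "with zero insertion haplotype frequency"
            )
        marker = a_ins_hap.copy()
        non_ins = np.flatnonzero(~a_ins_hap)
        if spec.target_r2 <= 0:
            q0 = _solve_marker_concordance(0.0, 0.0)
            marker = rng_snp.random(2 * n) < q0
        elif k_ins == 0:
            marker = np.zeros(2 * n, bool)  # degenerate draw: no carriers
        else:
            q0 = _solve_marker_concordance(spec.target_r2, k_ins / (2 * n))
            m = int(round(q0 * len(non_ins)))
            if m > 0:
                marker[rng_snp.choice(non_ins, size=m, replace=False)] = True
        dosage_cols[spec.marker] = marker.reshape(n, 2).sum(axis=1)
        positions[spec.marker] = spec.position
    dosages = (
        pd.DataFrame(dosage_cols, index=pd.Index(ids, name="sample_id"))
        if dosage_cols
        else None
    )

    return SimulatedCohort(
        calls=calls,
        hla=hla,
        dosages=dosages,
        positions=positions or None,
        haplotypes=tuple((haps[a], haps[b]) for a, b in pairs),
    )


def simulate_pedigrees(
    n_families: int,
    params: CohortParams,
    n_children: int = 2,
) -> list[Pedigree]:
    """Nuclear families with founder haplotypes drawn from the cohort table
    and each child inheriting one haplotype from each parent uniformly. All
    generated families are Mendelian-consistent by construction."""
    ss = np.random.SeedSequence((params.seed, 0x9ED))
    rng = np.random.default_rng(ss)
    haps = [h for h, _ in params.haplotype_freqs]
    freqs = np.array([f for _, f in params.haplotype_freqs])
    peds = []
    for fam in range(n_families):
        f1, f2, m1, m2 = (haps[i] for i in rng.choice(len(haps), size=4, p=freqs))
        fid = f"FAM{fam + 1:03d}"
        members = [
            PedigreeMember(f"{fid}-father", None, None, _genotype_from(f1, f2)),
            PedigreeMember(f"{fid}-mother", None, None, _genotype_from(m1, m2)),
        ]
        for c in range(n_children):
            hf = (f1, f2)[rng.integers(2)]
            hm = (m1, m2)[rng.integers(2)]
            members.append(
                PedigreeMember(
                    f"{fid}-child{c + 1}",
                    f"{fid}-father",
                    f"{fid}-mother",
                    _genotype_from(hf, hm),
                    affected=(c == 0),
                )
            )
        peds.append(Pedigree(tuple(members), family_id=fid))
    return peds


def _fixture_uk() -> CohortTable:
    # Carrier classes as reported for the 719 UK subjects: 26 single
    # insertion + >=1 normal copy, 2 double + 1 normal, 1 triple + 1 normal,
    # 1 insertion in the sole C4A copy; no C4B insertions.
    genotypes = (
        [(2, 2, 1, 0)] * 26
        + [(3, 2, 2, 0)] * 2
        + [(4, 2, 3, 0)]
        + [(1, 2, 1, 0)]
        + [(2, 2, 0, 0)] * 689
    )
    ids = [f"UK{i + 1:04d}" for i in range(len(genotypes))]
    calls = pd.DataFrame(
        [
            {"sample_id": sid, "nA": g[0], "nB": g[1], "iA": g[2], "iB": g[3]}
            for sid, g in zip(ids, genotypes)
        ]
    )
    # 28 of the 30 carriers HLA-typed, 23 of them DRB1*13; the three
    # multi-copy carriers are typed and DRB1*13-negative.
    hla_rows: list[tuple] = []
    carrier_hla = (
        [("13", "07")] * 23  # singles 1..23
        + [("07", "03")]  # single 24, typed, no *13
        + [(None, None)] * 2  # singles 25..26 untyped
        + [("04", "07"), ("03", "15")]  # double-insertion carriers
        + [("01", "04")]  # triple-insertion carrier
        + [("07", "15")]  # sole-copy carrier
    )
    hla_rows.extend(carrier_hla)
    # 661/719 typed overall -> 633 typed non-carriers.
    pool = _HLA_POOL_2DIGIT
    for i in range(689):
        if i < 633:
            hla_rows.append((pool[i % len(pool)], pool[(i // len(pool)) % len(pool)]))
        else:
            hla_rows.append((None, None))
    hla = pd.DataFrame(
        {
            "sample_id": ids,
            "allele1": [a for a, _ in hla_rows],
            "allele2": [b for _, b in hla_rows],
        }
    )
    return CohortTable(calls=calls, hla=hla)


def _fixture_spain() -> CohortTable:
    # Post-QC Spanish cohort of 449: 8 C4A carriers (6 with one normal copy,
    # 1 with two, 1 with three) and a single C4B carrier with a functional
    # C4B copy.
    genotypes = (
        [(2, 2, 1, 0)] * 6
        + [(3, 2, 1, 0)]
        + [(4, 2, 1, 0)]
        + [(2, 2, 0, 1)]  # the C4B insertion carrier
        + [(2, 2, 0, 0)] * 440
    )
    ids = [f"ES{i + 1:04d}" for i in range(len(genotypes))]
    calls = pd.DataFrame(
        [
            {"sample_id": sid, "nA": g[0], "nB": g[1], "iA": g[2], "iB": g[3]}
            for sid, g in zip(ids, genotypes)
        ]
    )
    # 5 of the 9 carriers HLA-typed (4-digit), 3 of them DRB1*13.
    carrier_hla = (
        [("13:02", "07:01")] * 3
        + [("07:01", "03:01")]
        + [(None, None)] * 4
        + [("04:01", "11:01")]  # the C4B carrier, typed, no *13
    )
    hla_rows = list(carrier_hla)
    # 232/460 pre-QC subjects typed; keep 227 typed non-carriers post-QC.
    pool = _HLA_POOL_4DIGIT
    for i in range(440):
        if i < 227:
            hla_rows.append((pool[i % len(pool)], pool[(i // len(pool)) % len(pool)]))
        else:
            hla_rows.append((None, None))
    hla = pd.DataFrame(
        {
            "sample_id": ids,
            "allele1": [a for a, _ in hla_rows],
            "allele2": [b for _, b in hla_rows],
        }
    )
    return CohortTable(calls=calls, hla=hla)


def load_fixture(label: str) -> CohortTable:
    """Deterministic cohort table matching the reported per-class carrier
    and HLA counts; non-carriers filled as (nA=2, nB=2, iA=0, iB=0)."""
    key = label.strip().upper()
    if key == "UK":
        return _fixture_uk()
    if key in ("SPAIN", "ES"):
        return _fixture_spain()
    raise ValueError(f"unknown fixture label {label!r}; use 'UK' or 'Spain'")


def generate_peak_data(
    calls: pd.DataFrame,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a capillary run per sample (trace rendering followed by peak
    integration) and return the quartet table consumed by the caller."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(calls))
    rows = []
    for child, rec in zip(children, calls.itertuples(index=False)):
        genotype = C4DiploidGenotype(int(rec.nA), int(rec.nB), int(rec.iA), int(rec.iB))
        trace = simulate_trace(genotype, noise, seed=child)
        result = integrate_peaks(trace, peak_sigma=noise.peak_sigma)
        q = result.quartet
        rows.append(
            {
                "sample_id": rec.sample_id,
                "area_A_wt": q.area_A_wt,
                "area_A_ins": q.area_A_ins,
                "area_B_wt": q.area_B_wt,
                "area_B_ins": q.area_B_ins,
                "flags": ";".join(sorted(result.flags)),
            }
        )
    return pd.DataFrame(rows)


def simulate_spikein_quartets(
    quartets: pd.DataFrame,
    sample_ids: Sequence[str],
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Model the PGF spike-in re-run for selected samples: each observed
    quartet is mixed with the PGF reference post-PCR at sample share
    ``alpha``."""
    sub = quartets[quartets["sample_id"].isin(set(sample_ids))]
    rows = []
    for rec in sub.itertuples(index=False):
        q = PeakQuartet(rec.area_A_wt, rec.area_A_ins, rec.area_B_wt, rec.area_B_ins)
        mixed = mix_with_reference(q, PGF_QUARTET, alpha)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "area_A_wt": mixed.area_A_wt,
                "area_A_ins": mixed.area_A_ins,
                "area_B_wt": mixed.area_B_wt,
                "area_B_ins": mixed.area_B_ins,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "area_A_wt", "area_A_ins", "area_B_wt", "area_B_ins"],
    )
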
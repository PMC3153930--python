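"""Mendelian-consistency checking of C4 copy-number + insertion genotypes.

C4 genes sit inside RCCX cassettes, with one to four cassettes (hence one to
four C4 genes, each C4A or C4B, wild type or insertion-bearing) per
chromosome 6. An individual's unphased genotype (nA, nB, iA, iB) therefore
decomposes into unordered pairs of single-chromosome haplotypes, and a
nuclear family is Mendelian-consistent exactly when every member can be
assigned a haplotype pair such that each child inherits one haplotype from
each parent, unchanged (no recombination within the cassette is modelled --
faithful transmission is the hypothesis under test).

The haplotype space is small (69 haplotypes at the biological maximum of
four cassettes), so the check is an exhaustive search over decompositions
with light pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Optional

import pandas as pd

from .caller import C4DiploidGenotype

__all__ = [
    "C4Haplotype",
    "PedigreeMember",
    "Pedigree",
    "MAX_HAPLOTYPE_COPIES",
    "enumerate_haplotypes",
    "decompose_genotype",
    "check_mendelian",
    "read_pedigree_table",
    "write_pedigree_table",
]

#: Biological maximum of C4 genes on one chromosome 6 (quadri-modular RCCX).
MAX_HAPLOTYPE_COPIES = 4


@dataclass(frozen=True)
class C4Haplotype:
    """One chromosome's C4 content: wild-type/insertion counts of each
    paralog, plus an optional HLA-DRB1 tag used by the cohort simulator."""

    aw: int = 0  # wild-type C4A copies
    ai: int = 0  # insertion-bearing C4A copies
    bw: int = 0  # wild-type C4B copies
    bi: int = 0  # insertion-bearing C4B copies
    hla_tag: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if min(self.aw, self.ai, self.bw, self.bi) < 0:
            raise ValueError("haplotype copy counts must be non-negative")
        if not 1 <= self.total <= MAX_HAPLOTYPE_COPIES:
            raise ValueError(
                f"a chromosome carries 1..{MAX_HAPLOTYPE_COPIES} C4 genes"
            )

    @property
    def total(self) -> int:
        return self.aw + self.ai + self.bw + self.bi

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.aw, self.ai, self.bw, self.bi)

    def __lt__(self, other: "C4Haplotype") -> bool:
        return self.counts < other.counts


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    genotype: Optional[C4DiploidGenotype]
    affected: bool = False


@dataclass(frozen=True)
class Pedigree:
    members: tuple[PedigreeMember, ...]
    family_id: str = "FAM"

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate member ids")
        known = set(ids)
        parents = {}
        for m in self.members:
            for p in (m.father_id, m.mother_id):
                if p is not None and p not in known:
                    raise ValueError(f"unresolved parent reference {p!r}")
            parents[m.id] = tuple(p for p in (m.father_id, m.mother_id) if p)
        # no individual may be its own ancestor
        for start in ids:
            stack, seen = list(parents[start]), set()
            while stack:
                cur = stack.pop()
                if cur == start:
                    raise ValueError(f"{start} is its own ancestor")
                if cur in seen:
                    continue
                seen.add(cur)
                stack.extend(parents[cur])

    def member(self, mid: str) -> PedigreeMember:
        return next(m for m in self.members if m.id == mid)


def enumerate_haplotypes(max_copies: int = MAX_HAPLOTYPE_COPIES) -> list[C4Haplotype]:
    """Every composition of 1..max_copies C4 genes into the four states
    (wild-type/insertion x C4A/C4B), canonically sorted. 69 haplotypes at
    the default maximum of four."""
    if not 1 <= max_copies <= MAX_HAPLOTYPE_COPIES:
        raise ValueError(f"max_copies must lie in 1..{MAX_HAPLOTYPE_COPIES}")
    out = []
    for t in range(1, max_copies + 1):
        for aw in range(t + 1):
            for ai in range(t - aw + 1):
                for bw in range(t - aw - ai + 1):
                    out.append(C4Haplotype(aw, ai, bw, t - aw - ai - bw))
    return sorted(out)


def decompose_genotype(
    g: C4DiploidGenotype, max_copies: int = MAX_HAPLOTYPE_COPIES
) -> list[tuple[C4Haplotype, C4Haplotype]]:
    """All unordered haplotype pairs summing componentwise to the genotype
    (aw = nA - iA, ai = iA, bw = nB - iB, bi = iB). Empty when the genotype
    cannot be carried on two chromosomes of <= max_copies cassettes."""
    target = (g.nA - g.iA, g.iA, g.nB - g.iB, g.iB)
    pairs = set()
    for aw in range(target[0] + 1):
        for ai in range(target[1] + 1):
            for bw in range(target[2] + 1):
                for bi in range(target[3] + 1):
                    t1 = aw + ai + bw + bi
                    t2 = sum(target) - t1
                    if not (1 <= t1 <= max_copies and 1 <= t2 <= max_copies):
                        continue
                    h1 = C4Haplotype(aw, ai, bw, bi)
                    h2 = C4Haplotype(
                        target[0] - aw, target[1] - ai, target[2] - bw, target[3] - bi
                    )
                    pairs.add(tuple(sorted((h1, h2))))
    return sorted(pairs)


def _all_pairs(max_copies: int) -> list[tuple[C4Haplotype, C4Haplotype]]:
    haps = enumerate_haplotypes(max_copies)
    return list(combinations_with_replacement(haps, 2))


def check_mendelian(
    ped: Pedigree, max_copies: int = MAX_HAPLOTYPE_COPIES
) -> tuple[bool, Optional[dict[str, tuple[C4Haplotype, C4Haplotype]]]]:
    """Decide whether the pedigree admits a haplotype assignment in which
    every child draws exactly one haplotype from each parent.

    Members without a genotype (untyped relatives) are unconstrained
    wildcards. Returns (consistent, witness): the witness maps member id to
    an assigned haplotype pair when consistent, else None. Assumes nuclear
    families (founder couples and their children).
    """
    decomps: dict[str, Optional[list]] = {}
    for m in ped.members:
        if m.genotype is None:
            decomps[m.id] = None
        else:
            d = decompose_genotype(m.genotype, max_copies)
            if not d:
                return False, None  # genotype impossible on two chromosomes
            decomps[m.id] = d

    witness: dict[str, tuple[C4Haplotype, C4Haplotype]] = {}
    default_hap = C4Haplotype(1, 0, 0, 0)

    # Group children by parental couple; absent parents act as wildcards.
    couples: dict[tuple[Optional[str], Optional[str]], list[PedigreeMember]] = {}
    for m in ped.members:
        if m.father_id or m.mother_id:
            couples.setdefault((m.father_id, m.mother_id), []).append(m)

    def solve_couple(father_id, mother_id, children) -> bool:
        f_dec = decomps.get(father_id) if father_id else None
        m_dec = decomps.get(mother_id) if mother_id else None
        options = []
        for child in children:
            if decomps[child.id] is None:
                options.append([None])  # untyped child: no constraint
                continue
            opts = set()
            for h1, h2 in decomps[child.id]:
                opts.add((h1, h2))
                opts.add((h2, h1))
            options.append(sorted(opts))

        def feasible(needed: set, dec) -> bool:
            if len(needed) > 2:
                return False
            return dec is None or any(needed <= set(pair) for pair in dec)

        def pick_pair(needed: set, dec):
            if dec is not None:
                return next(pair for pair in dec if needed <= set(pair))
            pad = sorted(needed) + [default_hap, default_hap]
            return (pad[0], pad[1])

        def recurse(i, need_f, need_m, chosen):
            if i == len(children):
                fp, mp = pick_pair(need_f, f_dec), pick_pair(need_m, m_dec)
                if father_id:
                    witness[father_id] = fp
                if mother_id:
                    witness[mother_id] = mp
                for child, pick in zip(children, chosen):
                    witness[child.id] = pick if pick else (fp[0], mp[0])
                return True
            for opt in options[i]:
                if opt is None:
                    if recurse(i + 1, need_f, need_m, chosen + [None]):
                        return True
                    continue
                hf, hm = opt
                nf, nm = need_f | {hf}, need_m | {hm}
                if feasible(nf, f_dec) and feasible(nm, m_dec):
                    if recurse(i + 1, nf, nm, chosen + [opt]):
                        return True
            return False

        return recurse(0, set(), set(), [])

    for (fid, mid), children in couples.items():
        if not solve_couple(fid, mid, children):
            return False, None

    # Members untouched by any couple still need an assignment.
    for m in ped.members:
        if m.id not in witness:
            d = decomps[m.id]
            witness[m.id] = d[0] if d else (default_hap, default_hap)
    return True, witness


_PED_COLUMNS = [
    "family_id", "individual_id", "father_id", "mother_id",
    "sex", "affected", "nA", "nB", "iA", "iB", "missing",
]


def read_pedigree_table(path: str) -> list[Pedigree]:
    """Read a PED-like TSV (one row per individual, '0' for absent parents,
    missing=1 for untyped members) into one Pedigree per family."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    absent = lambda v: None if pd.isna(v) or str(v) in ("0", "") else str(v)
    peds = []
    for fam, sub in df.groupby("family_id", sort=False):
        members = []
        for r in sub.itertuples(index=False):
            if int(r.missing):
                geno = None
            else:
                geno = C4DiploidGenotype(int(r.nA), int(r.nB), int(r.iA), int(r.iB))
            members.append(
                PedigreeMember(
                    str(r.individual_id),
                    absent(r.father_id),
                    absent(r.mother_id),
                    geno,
                    affected=bool(int(r.affected)),
                )
            )
        peds.append(Pedigree(tuple(members), family_id=str(fam)))
    return peds


def write_pedigree_table(peds: list[Pedigree], path: str) -> None:
    rows = []
    for ped in peds:
        for m in ped.members:
            g = m.genotype
            rows.append(
                {
                    "family_id": ped.family_id,
                    "individual_id": m.id,
                    "father_id": m.father_id or "0",
                    "mother_id": m.mother_id or "0",
                    "sex": "0",
                    "affected": int(m.affected),
                    "nA": g.nA if g else 0,
                    "nB": g.nB if g else 0,
                    "iA": g.iA if g else 0,
                    "iB": g.iB if g else 0,
                    "missing": int(g is None),
                }
            )
    pd.DataFrame(rows, columns=_PED_COLUMNS).to_csv(path, sep="\t", index=False)
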
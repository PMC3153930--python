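"""Insertion copy-number calling from peak-area quartets plus PRT integers.

The paralog ratio test (PRT) supplies integer gene copy numbers per paralog
(nA, nB); those integers are treated as ground truth. For each paralog with
n > 0 copies, the within-paralog insertion area fraction

    f = area_ins / (area_ins + area_wt)

is snapped to the nearest point of the grid {0/n, 1/n, ..., n/n}; the grid
index k is the called number of insertion-bearing copies. Ties break toward
the smaller k (conservative: fewer mutant copies). A paralog showing
insertion signal but no wild-type signal (f ~ 1) cannot distinguish k = n
from an artifact, so the call is flagged ``needs_spikein`` and resolved by
re-reading the sample after post-PCR mixing with the PGF reference line
(two normal copies each of C4A and C4B): each candidate k's mixed quartet is
predicted through the forward mixing model and the best L1 fit wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .electropherogram import PGF_QUARTET, PeakQuartet, mix_with_reference

__all__ = [
    "C4DiploidGenotype",
    "CallResult",
    "call_insertion_copies",
    "resolve_with_spikein",
    "call_cohort",
    "enumerate_valid_genotypes",
]

logger = logging.getLogger(__name__)

MAX_DIPLOID_COPIES = 8


@dataclass(frozen=True)
class C4DiploidGenotype:
    """Per-individual integer copy numbers: total C4A/C4B copies (nA, nB)
    and how many of each carry the exon 29 CT insertion (iA, iB).

    A diploid genome carries 2-8 C4 genes (1-4 per chromosome).
    """

    nA: int
    nB: int
    iA: int = 0
    iB: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.iA <= self.nA <= MAX_DIPLOID_COPIES):
            raise ValueError(f"require 0 <= iA <= nA <= {MAX_DIPLOID_COPIES}")
        if not (0 <= self.iB <= self.nB <= MAX_DIPLOID_COPIES):
            raise ValueError(f"require 0 <= iB <= nB <= {MAX_DIPLOID_COPIES}")
        if not (2 <= self.nA + self.nB <= MAX_DIPLOID_COPIES):
            raise ValueError(f"total C4 copies must lie in [2, {MAX_DIPLOID_COPIES}]")

    @property
    def total(self) -> int:
        return self.nA + self.nB


@dataclass(frozen=True)
class CallResult:
    genotype: C4DiploidGenotype
    flags: frozenset
    residual: float

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


def _nearest_k(f: float, n: int) -> tuple[int, float]:
    # Ascending scan with strict improvement => ties resolve to smaller k.
    best_k, best_d = 0, abs(f)
    for k in range(1, n + 1):
        d = abs(f - k / n)
        if d < best_d:
            best_k, best_d = k, d
    return best_k, best_d


def call_insertion_copies(
    quartet: PeakQuartet,
    nA: int,
    nB: int,
    detection_floor: float = 0.02,
) -> CallResult:
    """Call (iA, iB) from one sample's peak-area quartet and its PRT copy
    numbers.

    detection_floor is the fraction of within-paralog area below which a
    peak counts as absent (the single-peak homozygote criterion); the same
    fraction of *total* area decides whether a paralog produced any usable
    signal at all.
    """
    arr = quartet.as_array()
    total = float(arr.sum())
    flags: set[str] = set()
    calls: list[int] = []
    residual = 0.0

    for n, wt, ins in ((nA, arr[0], arr[1]), (nB, arr[2], arr[3])):
        paralog_area = wt + ins
        if n == 0:
            if total > 0 and paralog_area > detection_floor * total:
                flags.add("inconsistent_ratio")
            calls.append(0)
            continue
        if total <= 0 or paralog_area <= detection_floor * total:
            flags.add("low_quality")
            calls.append(0)
            continue
        f = ins / paralog_area
        k, d = _nearest_k(f, n)
        if wt / paralog_area < detection_floor <= ins / paralog_area:
            # f ~ 1: homozygous/hemizygous insertion vs artifact is
            # unresolvable without the PGF spike-in.
            flags.add("needs_spikein")
        calls.append(k)
        residual += d

    genotype = C4DiploidGenotype(nA, nB, calls[0], calls[1])
    return CallResult(genotype, frozenset(flags), residual)


def resolve_with_spikein(
    unmixed: PeakQuartet,
    mixed: PeakQuartet,
    nA: int,
    nB: int,
    alpha: float = 0.5,
    detection_floor: float = 0.02,
) -> CallResult:
    """Resolve a needs_spikein call using the PGF-mixed re-run.

    For every candidate insertion count k of each flagged paralog, the
    mixed quartet is predicted via the forward model (candidate noise-free
    sample quartet mixed with PGF at the given alpha) and the candidate
    minimising the L1 distance to the observed mixed quartet is chosen;
    ties break toward fewer insertion copies.
    """
    base = call_insertion_copies(unmixed, nA, nB, detection_floor)
    if "needs_spikein" not in base.flags:
        return base

    mixed_arr = mixed.normalized().as_array() if mixed.total > 0 else None
    if mixed_arr is None or mixed.area_A_wt <= 0 or mixed.area_B_wt <= 0:
        # PGF contributes wild-type copies of both paralogs: their absence
        # post-mix means the mixing itself failed.
        return CallResult(base.genotype, base.flags | {"assay_failure"}, base.residual)

    arr = unmixed.as_array()
    a_flagged = nA > 0 and (arr[0] + arr[1]) > 0 and (
        arr[0] / (arr[0] + arr[1]) < detection_floor <= arr[1] / (arr[0] + arr[1])
    )
    b_flagged = nB > 0 and (arr[2] + arr[3]) > 0 and (
        arr[2] / (arr[2] + arr[3]) < detection_floor <= arr[3] / (arr[2] + arr[3])
    )
    ka_range = range(nA + 1) if a_flagged else [base.genotype.iA]
    kb_range = range(nB + 1) if b_flagged else [base.genotype.iB]

    best = None
    for ka in ka_range:
        for kb in kb_range:
            candidate = PeakQuartet(float(nA - ka), float(ka), float(nB - kb), float(kb))
            if candidate.total <= 0:
                continue
            pred = mix_with_reference(candidate, PGF_QUARTET, alpha).as_array()
            dist = float(np.abs(pred - mixed_arr).sum())
            key = (dist, ka + kb, ka)
            if best is None or key < best[0]:
                best = (key, ka, kb)
    assert best is not None
    (dist, _, _), ka, kb = best
    flags = (base.flags - {"needs_spikein"}) | {"spikein_resolved"}
    return CallResult(C4DiploidGenotype(nA, nB, ka, kb), frozenset(flags), dist)


def call_cohort(
    quartets: pd.DataFrame,
    gcn_table: pd.DataFrame,
    detection_floor: float = 0.02,
    spikein: pd.DataFrame | None = None,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Call every sample in a cohort.

    quartets: columns sample_id, area_A_wt, area_A_ins, area_B_wt, area_B_ins.
    gcn_table: columns sample_id, C4A_GCN, C4B_GCN (optionally total_GCN).
    spikein: optional quartet table of PGF-mixed re-runs, same columns as
    ``quartets``; samples flagged needs_spikein without a mixed run are
    reported unresolved.

    Returns a calls table: sample_id, nA, nB, iA, iB, flags (';'-joined),
    residual. Samples missing from the GCN table are skipped with a warning.
    A nA+nB mismatch against total_GCN is reported via the gcn_mismatch flag,
    never auto-corrected.
    """
    gcn = gcn_table.set_index("sample_id")
    mixed_by_id = (
        spikein.set_index("sample_id") if spikein is not None else pd.DataFrame()
    )
    rows = []
    flag_counts: dict[str, int] = {}
    area_cols = ["area_A_wt", "area_A_ins", "area_B_wt", "area_B_ins"]
    for rec in quartets.itertuples(index=False):
        sid = rec.sample_id
        if sid not in gcn.index:
            logger.warning("sample %s has no GCN record; skipped", sid)
            continue
        nA = int(gcn.at[sid, "C4A_GCN"])
        nB = int(gcn.at[sid, "C4B_GCN"])
        q = PeakQuartet(rec.area_A_wt, rec.area_A_ins, rec.area_B_wt, rec.area_B_ins)
        result = call_insertion_copies(q, nA, nB, detection_floor)
        if "needs_spikein" in result.flags:
            if sid in mixed_by_id.index:
                m = mixed_by_id.loc[sid, area_cols]
                result = resolve_with_spikein(
                    q, PeakQuartet(*m.to_numpy(float)), nA, nB, alpha, detection_floor
                )
            else:
                result = CallResult(
                    result.genotype, result.flags | {"unresolved"}, result.residual
                )
        flags = set(result.flags)
        if "total_GCN" in gcn.columns and not pd.isna(gcn.at[sid, "total_GCN"]):
            if int(gcn.at[sid, "total_GCN"]) != nA + nB:
                flags.add("gcn_mismatch")
        for fl in flags:
            flag_counts[fl] = flag_counts.get(fl, 0) + 1
        g = result.genotype
        rows.append(
            {
                "sample_id": sid,
                "nA": g.nA,
                "nB": g.nB,
                "iA": g.iA,
                "iB": g.iB,
                "flags": ";".join(sorted(flags)),
                "residual": result.residual,
            }
        )
    if flag_counts:
        logger.info(
            "call_cohort flags: %s",
            ", ".join(f"{k}={v}" for k, v in sorted(flag_counts.items())),
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "nA", "nB", "iA", "iB", "flags", "residual"]
    )


def enumerate_valid_genotypes(max_total: int = MAX_DIPLOID_COPIES):
    """All diploid genotypes (nA, nB, iA, iB) with 2 <= nA+nB <= max_total."""
    out = []
    for nA in range(0, max_total + 1):
        for nB in range(0, max_total + 1 - nA):
            if nA + nB < 2:
                continue
            for iA in range(nA + 1):
                for iB in range(nB + 1):
                    out.append(C4DiploidGenotype(nA, nB, iA, iB))
    return out
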
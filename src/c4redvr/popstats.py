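"""Population summaries of C4 CT-insertion genotype calls.

Covers the quantities reported for genotyped cohorts: per-class insertion
tables, carrier and chromosome frequencies, two-cohort proportion and mean
comparisons, HLA-DRB1*13 co-carriage among insertion carriers, and the
squared correlation (r^2) between flanking-marker dosages and insertion
integer copy number.

Chromosome (carrier-chromosome) frequency is computed under the minimal
cis-placement rule: an unphased carrier contributes the fewest chromosomes
consistent with at most four C4 genes per chromosome, so up to four
insertion copies count as a single carrier chromosome. Percentages are kept
as exact floats; any display rounding happens at the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .pedigree import MAX_HAPLOTYPE_COPIES

__all__ = [
    "CohortTable",
    "CocarriageResult",
    "class_table",
    "carrier_frequency",
    "chromosome_frequency",
    "compare_proportions",
    "drb1_cocarriage",
    "snp_insertion_r2",
    "summarize_gcn",
    "compare_means_from_summary",
    "summarize",
]

_PARALOG_COLS = {"C4A": ("iA", "nA"), "C4B": ("iB", "nB")}


@dataclass
class CohortTable:
    """Bundle of per-sample tables for one cohort.

    calls
        DataFrame with sample_id, nA, nB, iA, iB (genotype calls).
    hla
        Optional DataFrame with sample_id, allele1, allele2 (HLA-DRB1);
        missing alleles as NaN/empty.
    dosages
        Optional DataFrame indexed by sample_id, one column per marker,
        values in {0, 1, 2} or NaN.
    positions
        Optional mapping marker id -> chromosomal position (bp).
    """

    calls: pd.DataFrame
    hla: Optional[pd.DataFrame] = None
    dosages: Optional[pd.DataFrame] = None
    positions: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.calls["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in calls")

    @property
    def n(self) -> int:
        return len(self.calls)


def _ins_col(paralog: str) -> tuple[str, str]:
    try:
        return _PARALOG_COLS[paralog]
    except KeyError:
        raise ValueError("paralog must be 'C4A' or 'C4B'") from None


def class_table(calls: pd.DataFrame, paralog: str = "C4A") -> pd.DataFrame:
    """Bin individuals by (insertion copies, remaining normal copies) of one
    paralog. Counts sum to the cohort size; the zero-insertion class pools
    all non-carriers regardless of copy number."""
    icol, ncol = _ins_col(paralog)
    ins = calls[icol].astype(int)
    normal = (calls[ncol] - calls[icol]).astype(int)
    tab = (
        pd.DataFrame({"insertion_copies": ins, "normal_copies": normal.where(ins > 0, -1)})
        .groupby(["insertion_copies", "normal_copies"])
        .size()
        .reset_index(name="count")
    )
    tab.loc[tab["insertion_copies"] == 0, "normal_copies"] = pd.NA
    tab["percent"] = 100.0 * tab["count"] / len(calls)
    return tab


def carrier_frequency(calls: pd.DataFrame, paralog: str = "C4A") -> float:
    """Percentage of individuals carrying >= 1 insertion copy of the paralog."""
    icol, _ = _ins_col(paralog)
    return 100.0 * float((calls[icol] > 0).sum()) / len(calls)


def chromosome_frequency(calls: pd.DataFrame, paralog: str = "C4A") -> float:
    """Percentage of chromosomes bearing >= 1 insertion copy, minimal
    cis-placement: a carrier with i copies occupies ceil(i / 4) chromosomes."""
    icol, _ = _ins_col(paralog)
    i = calls[icol].to_numpy(int)
    chroms = np.ceil(i[i > 0] / MAX_HAPLOTYPE_COPIES).sum()
    return 100.0 * float(chroms) / (2 * len(calls))


def compare_proportions(
    x1: int, n1: int, x2: int, n2: int, method: str = "z_test"
) -> float:
    """Two-sided p-value for a difference of two proportions.

    z_test: pooled-variance two-proportion z test. fisher: Fisher's exact
    test on the 2x2 table.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("require 0 <= x <= n for both samples")
    if method == "z_test":
        _, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
        return float(p)
    if method == "fisher":
        _, p = stats.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])
        return float(p)
    raise ValueError("method must be 'z_test' or 'fisher'")


def _is_drb1_group(allele, group: str = "13") -> bool:
    if allele is None or (isinstance(allele, float) and np.isnan(allele)):
        return False
    s = str(allele).strip().upper()
    if s in ("", "NA", "NAN", "-", "0"):
        return False
    for prefix in ("HLA-DRB1*", "DRB1*", "*"):
        if s.startswith(prefix):
            s = s[len(prefix):]
    field = s.split(":")[0]
    if field.endswith(".0"):  # numeric round-trip through a TSV reader
        field = field[:-2]
    return field.lstrip("0") == group.lstrip("0") or field == group


def _hla_typed(row) -> bool:
    return any(
        not (a is None or (isinstance(a, float) and np.isnan(a)) or str(a).strip() in ("", "NA", "nan", "-", "0"))
        for a in (row.allele1, row.allele2)
    )


@dataclass(frozen=True)
class CocarriageResult:
    percent: float
    carriers_with_allele: int
    carriers_typed: int


def drb1_cocarriage(
    calls: pd.DataFrame, hla: pd.DataFrame, group: str = "13"
) -> CocarriageResult:
    """Percentage of insertion carriers (either paralog) with HLA data who
    carry at least one HLA-DRB1*13 allele. Matching is at 2-digit
    resolution, so any DRB1*13:xx counts as *13."""
    carriers = calls.loc[(calls["iA"] > 0) | (calls["iB"] > 0), "sample_id"]
    sub = hla[hla["sample_id"].isin(carriers)]
    typed = sub[[_hla_typed(r) for r in sub.itertuples(index=False)]]
    if len(typed) == 0:
        raise ValueError("no insertion carrier has HLA-DRB1 data")
    hits = sum(
        _is_drb1_group(r.allele1, group) or _is_drb1_group(r.allele2, group)
        for r in typed.itertuples(index=False)
    )
    return CocarriageResult(100.0 * hits / len(typed), int(hits), int(len(typed)))


def snp_insertion_r2(
    calls: pd.DataFrame,
    dosages: pd.DataFrame,
    positions: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-marker squared Pearson correlation between dosage (0/1/2, or an
    HLA allele count) and the C4A insertion integer copy number, with the
    regression p-value. Missing dosages are dropped pairwise."""
    iA = calls.set_index("sample_id")["iA"].astype(float)
    rows = []
    for marker in dosages.columns:
        d = dosages[marker].astype(float)
        joined = pd.concat([d, iA], axis=1, join="inner").dropna()
        if len(joined) < 3:
            raise ValueError(f"marker {marker}: fewer than 3 informative samples")
        x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r2, p = 0.0, 1.0
        else:
            res = stats.linregress(x, y)
            r2, p = float(res.rvalue**2), float(res.pvalue)
        rows.append(
            {
                "marker": marker,
                "position": (positions or {}).get(marker, np.nan),
                "r2": r2,
                "p": p,
                "n": len(joined),
            }
        )
    return pd.DataFrame(rows, columns=["marker", "position", "r2", "p", "n"])


def summarize_gcn(calls: pd.DataFrame) -> pd.Series:
    """Means and sample SDs of total/C4A/C4B gene copy number plus
    null-homozygote (zero-copy) percentages."""
    total = calls["nA"] + calls["nB"]
    out = {
        "mean_total_GCN": total.mean(),
        "sd_total_GCN": total.std(ddof=1),
        "mean_C4A_GCN": calls["nA"].mean(),
        "sd_C4A_GCN": calls["nA"].std(ddof=1),
        "mean_C4B_GCN": calls["nB"].mean(),
        "sd_C4B_GCN": calls["nB"].std(ddof=1),
        "pct_C4A_null_homozygotes": 100.0 * float((calls["nA"] == 0).sum()) / len(calls),
        "pct_C4B_null_homozygotes": 100.0 * float((calls["nB"] == 0).sum()) / len(calls),
        "n": float(len(calls)),
    }
    return pd.Series(out)


def compare_means_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Two-sided Welch t-test p-value from summary statistics."""
    _, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(p)


def summarize(cohort: CohortTable) -> dict:
    """One-stop cohort summary: carrier/chromosome frequencies and class
    tables for both paralogs, GCN moments, and DRB1*13 co-carriage when HLA
    data are attached."""
    out: dict = {"n": cohort.n}
    for paralog in ("C4A", "C4B"):
        out[f"{paralog}_carrier_pct"] = carrier_frequency(cohort.calls, paralog)
        out[f"{paralog}_chromosome_pct"] = chromosome_frequency(cohort.calls, paralog)
        out[f"{paralog}_class_table"] = class_table(cohort.calls, paralog)
    out["gcn"] = summarize_gcn(cohort.calls)
    if cohort.hla is not None:
        try:
            out["drb1_13_cocarriage"] = drb1_cocarriage(cohort.calls, cohort.hla)
        except ValueError:
            out["drb1_13_cocarriage"] = None
    return out
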
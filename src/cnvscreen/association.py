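"""Case-control association and cohort burden statistics.

The association statistic is the one-sided Fisher exact probability: the
hypergeometric tail in the direction of the observed enrichment, computed
by direct log-factorial summation with no normal approximation.  One test
per locus, no multiplicity correction by default (an optional
Benjamini-Hochberg adjustment can be switched on).

Burden statistics compare per-individual call counts and per-call sizes
between groups with the two-tailed Mann-Whitney U test: exact null
distribution when both groups have at most 50 observations, tie-corrected
normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CASE, CONTROL, AssociationResult, CnvCall, CnvLocus, SampleGroups

EXACT_MW_MAX_N = 50


def _log_hyper_pmf(k: int, N: int, K: int, n: int) -> float:
    """log P(X = k) for X ~ Hypergeometric(N, K, n)."""
    return (
        math.lgamma(K + 1) - math.lgamma(k + 1) - math.lgamma(K - k + 1)
        + math.lgamma(N - K + 1) - math.lgamma(n - k + 1) - math.lgamma(N - K - n + k + 1)
        - (math.lgamma(N + 1) - math.lgamma(n + 1) - math.lgamma(N - n + 1))
    )


def fisher_one_sided(a_carriers: int, a_total: int, b_carriers: int, b_total: int) -> float:
    """One-sided Fisher exact p in the direction of observed enrichment.

    With ``N`` samples overall and ``K`` carriers overall, the null
    carrier count ``X`` in group A is hypergeometric; returns
    ``P(X >= a_carriers)`` when group A is at least as enriched as group B,
    else ``P(X <= a_carriers)``.  Summation is carried out term by term in
    log space.
    """
    for v in (a_carriers, a_total, b_carriers, b_total):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    if a_carriers > a_total or b_carriers > b_total:
        raise ValueError("carriers cannot exceed group totals")
    if a_total == 0 or b_total == 0:
        raise ValueError("group totals must be > 0")
    N = a_total + b_total
    K = a_carriers + b_carriers
    lo = max(0, K - b_total)
    hi = min(K, a_total)
    if a_carriers / a_total >= b_carriers / b_total:
        ks = range(a_carriers, hi + 1)
    else:
        ks = range(lo, a_carriers + 1)
    p = sum(math.exp(_log_hyper_pmf(k, N, K, a_total)) for k in ks)
    return min(p, 1.0)


def fisher_two_sided(a_carriers: int, a_total: int, b_carriers: int, b_total: int) -> float:
    """Two-sided Fisher exact p: sum of all outcomes no more probable than
    the observed table."""
    N = a_total + b_total
    K = a_carriers + b_carriers
    lo = max(0, K - b_total)
    hi = min(K, a_total)
    log_obs = _log_hyper_pmf(a_carriers, N, K, a_total)
    p = sum(
        math.exp(lp)
        for k in range(lo, hi + 1)
        if (lp := _log_hyper_pmf(k, N, K, a_total)) <= log_obs + 1e-12
    )
    return min(p, 1.0)


def associate_loci(
    loci: Sequence[CnvLocus],
    groups: SampleGroups,
    alpha: float = 0.05,
    two_sided: bool = False,
    correction: str | None = None,
) -> list[AssociationResult]:
    """One Fisher exact test per locus against the post-QC denominators.

    ``significant`` is claimed only for common loci (rare loci are
    reported with their p-values but never flagged).  ``correction="bh"``
    applies a Benjamini-Hochberg adjustment before thresholding; the
    default applies none.
    """
    n_case, n_control = groups.n_case, groups.n_control
    if n_case == 0 or n_control == 0:
        raise ValueError("both groups must be non-empty")
    test = fisher_two_sided if two_sided else fisher_one_sided
    pvals = [
        test(l.carriers_case, n_case, l.carriers_control, n_control) for l in loci
    ]
    adjusted = (
        stats.false_discovery_control(pvals, method="bh") if correction == "bh" and pvals
        else pvals
    )
    results = []
    for locus, p_adj, p_raw in zip(loci, adjusted, pvals):
        direction = "risk" if locus.freq_case > locus.freq_control else "protective"
        results.append(
            AssociationResult(
                locus=locus,
                a_carriers=locus.carriers_case,
                a_noncarriers=n_case - locus.carriers_case,
                b_carriers=locus.carriers_control,
                b_noncarriers=n_control - locus.carriers_control,
                p_value=float(p_raw),
                direction=direction,
                significant=bool(p_adj < alpha and locus.rarity == "common"),
            )
        )
    return results


# ---------------------------------------------------------------------------
# burden statistics
# ---------------------------------------------------------------------------

@dataclass
class BurdenSummary:
    """Cohort-level burden: overall and per-CNV-type group comparisons."""

    overall: pd.DataFrame  # category, case, control, p_value
    by_type: pd.DataFrame  # cnv_type, metric, case, control, p_value
    counts_per_individual: pd.DataFrame  # sample_id, group, n_calls


def mann_whitney_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed Mann-Whitney U: exact for small tie-free groups,
    tie-corrected normal approximation otherwise."""
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    exact_ok = x.size <= EXACT_MW_MAX_N and y.size <= EXACT_MW_MAX_N
    method = "exact" if exact_ok else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _rng_str(values: np.ndarray, fmt: str = "{:g}") -> str:
    return f"{fmt.format(values.min())}-{fmt.format(values.max())}"


def burden_stats(calls: Sequence[CnvCall], groups: SampleGroups) -> BurdenSummary:
    """Per-group call burden (counts, lengths, marker spans) with
    between-group Mann-Whitney p-values.

    Individuals with zero calls still contribute zeros to per-individual
    counts; lengths are reported in kb (1 kb = 1,000 bp, length =
    end - start).
    """
    if groups.n_case == 0 or groups.n_control == 0:
        raise ValueError("both groups must be non-empty")
    rows = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "group": [groups[c.sample_id] for c in calls],
            "length_kb": [c.length / 1000.0 for c in calls],
            "num_snps": [c.num_snps for c in calls],
            "type": [
                "duplication" if c.copy_number > 2
                else ("hom_deletion" if c.copy_number == 0 else "het_deletion")
                for c in calls
            ],
        }
    )

    def per_individual_counts(sub: pd.DataFrame) -> pd.DataFrame:
        counts = sub.groupby("sample_id").size()
        recs = [
            {"sample_id": sid, "group": groups[sid], "n_calls": int(counts.get(sid, 0))}
            for sid in groups.sample_ids
        ]
        return pd.DataFrame(recs)

    counts = per_individual_counts(rows)
    case_counts = counts.loc[counts["group"] == CASE, "n_calls"].to_numpy()
    ctrl_counts = counts.loc[counts["group"] == CONTROL, "n_calls"].to_numpy()
    case_rows = rows[rows["group"] == CASE]
    ctrl_rows = rows[rows["group"] == CONTROL]

    def safe_mw(x, y):
        try:
            return mann_whitney_two_sided(x, y)
        except ValueError:
            return float("nan")

    overall = pd.DataFrame(
        [
            {
                "category": "total_calls",
                "case": len(case_rows),
                "control": len(ctrl_rows),
                "p_value": float("nan"),
            },
            {
                "category": "mean_calls_per_individual",
                "case": case_counts.mean(),
                "control": ctrl_counts.mean(),
                "p_value": safe_mw(case_counts, ctrl_counts),
            },
            {
                "category": "mean_length_kb",
                "case": case_rows["length_kb"].mean() if len(case_rows) else float("nan"),
                "control": ctrl_rows["length_kb"].mean() if len(ctrl_rows) else float("nan"),
                "p_value": safe_mw(case_rows["length_kb"], ctrl_rows["length_kb"])
                if len(case_rows) and len(ctrl_rows) else float("nan"),
            },
            {
                "category": "mean_snps_per_call",
                "case": case_rows["num_snps"].mean() if len(case_rows) else float("nan"),
                "control": ctrl_rows["num_snps"].mean() if len(ctrl_rows) else float("nan"),
                "p_value": safe_mw(case_rows["num_snps"], ctrl_rows["num_snps"])
                if len(case_rows) and len(ctrl_rows) else float("nan"),
            },
        ]
    )

    type_rows = []
    for cnv_type in ("duplication", "het_deletion", "hom_deletion"):
        sub = rows[rows["type"] == cnv_type]
        sub_counts = per_individual_counts(sub)
        t_case = sub_counts.loc[sub_counts["group"] == CASE, "n_calls"].to_numpy()
        t_ctrl = sub_counts.loc[sub_counts["group"] == CONTROL, "n_calls"].to_numpy()
        s_case = sub.loc[sub["group"] == CASE, "length_kb"].to_numpy()
        s_ctrl = sub.loc[sub["group"] == CONTROL, "length_kb"].to_numpy()
        type_rows += [
            {
                "cnv_type": cnv_type, "metric": "total",
                "case": len(s_case), "control": len(s_ctrl), "p_value": float("nan"),
            },
            {
                "cnv_type": cnv_type, "metric": "mean_per_individual",
                "case": t_case.mean(), "control": t_ctrl.mean(),
                "p_value": safe_mw(t_case, t_ctrl),
            },
            {
                "cnv_type": cnv_type, "metric": "median_size_kb",
                "case": float(np.median(s_case)) if s_case.size else float("nan"),
                "control": float(np.median(s_ctrl)) if s_ctrl.size else float("nan"),
                "p_value": safe_mw(s_case, s_ctrl)
                if s_case.size and s_ctrl.size else float("nan"),
            },
        ]
    return BurdenSummary(
        overall=overall,
        by_type=pd.DataFrame(type_rows),
        counts_per_individual=counts,
    )
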
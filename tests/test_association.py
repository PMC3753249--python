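"""Fisher exact association against exact-rational oracles, and burden
statistics against exhaustive rank-sum enumeration."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvscreen import (
    CnvLocus,
    SampleGroups,
    associate_loci,
    burden_stats,
    fisher_one_sided,
    fisher_two_sided,
    mann_whitney_two_sided,
)
from tests.conftest import make_call


# ---------------------------------------------------------------------------
# exact-rational oracle for the hypergeometric tail
# ---------------------------------------------------------------------------

def hyper_pmf(k, N, K, n) -> Fraction:
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def fisher_oracle(a, na, b, nb) -> float:
    N, K = na + nb, a + b
    lo, hi = max(0, K - nb), min(K, na)
    if a / na >= b / nb:
        ks = range(a, hi + 1)
    else:
        ks = range(lo, a + 1)
    return float(sum(hyper_pmf(k, N, K, na) for k in ks))


# one-sided Fisher on carrier counts at the post-QC denominators 114/106
REFERENCE_TABLES = [
    (2, 114, 11, 106, 0.0065024),   # protective loss, EPH-receptor region
    (14, 114, 2, 106, 0.0023976),   # kinase-gene duplication
    (21, 114, 2, 106, 2.94e-05),    # chr11 intergenic loss
    (15, 114, 2, 106, 0.001320),    # chr19 intergenic loss
    (8, 114, 0, 106, 0.0045992),    # HLA-class-I homozygous loss
    (12, 114, 2, 106, 0.0076187),   # DPYD duplication
    (1, 114, 6, 106, 0.0486939),    # chr15 protective loss
    (6, 114, 14, 106, 0.034200),    # TP63 protective loss
]


class TestFisherOneSided:
    @pytest.mark.parametrize("a,na,b,nb,expected", REFERENCE_TABLES)
    def test_reference_tables(self, a, na, b, nb, expected):
        assert fisher_one_sided(a, na, b, nb) == pytest.approx(expected, rel=5e-4)

    def test_no_carriers_gives_one(self):
        assert fisher_one_sided(0, 114, 0, 106) == 1.0

    @settings(deadline=None, max_examples=200)
    @given(data=st.data())
    def test_matches_exact_rational_oracle(self, data):
        na = data.draw(st.integers(1, 150))
        nb = data.draw(st.integers(1, 150))
        a = data.draw(st.integers(0, na))
        b = data.draw(st.integers(0, nb))
        p = fisher_one_sided(a, na, b, nb)
        expected = fisher_oracle(a, na, b, nb)
        assert p == pytest.approx(expected, rel=1e-11)

    @settings(deadline=None, max_examples=100)
    @given(data=st.data())
    def test_invariant_under_group_swap(self, data):
        na = data.draw(st.integers(1, 120))
        nb = data.draw(st.integers(1, 120))
        a = data.draw(st.integers(0, na))
        b = data.draw(st.integers(0, nb))
        assert fisher_one_sided(a, na, b, nb) == pytest.approx(
            fisher_one_sided(b, nb, a, na), rel=1e-12
        )

    def test_two_sided_bounded_below_by_one_sided(self):
        p1 = fisher_one_sided(8, 114, 0, 106)
        p2 = fisher_two_sided(8, 114, 0, 106)
        assert p1 <= p2 <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            fisher_one_sided(-1, 114, 0, 106)


# ---------------------------------------------------------------------------
# locus association
# ---------------------------------------------------------------------------

def locus_with_counts(a, b, n_case=114, n_control=106, rarity="common"):
    return CnvLocus(
        chrom="3",
        start=89_485_137,
        end=89_499_861,
        cnv_type="het_loss",
        member_calls=[],
        carriers_case=a,
        carriers_control=b,
        freq_case=a / n_case,
        freq_control=b / n_control,
        rarity=rarity,
    )


def cohort_groups(n_case=114, n_control=106):
    assign = {f"A{i}": "case" for i in range(n_case)}
    assign.update({f"C{i}": "control" for i in range(n_control)})
    return SampleGroups(assign)


class TestAssociateLoci:
    def test_protective_locus_flagged(self):
        res = associate_loci([locus_with_counts(2, 11)], cohort_groups())[0]
        assert res.direction == "protective" and res.significant
        assert res.p_value == pytest.approx(0.0065024, rel=5e-4)

    def test_risk_locus_flagged(self):
        res = associate_loci([locus_with_counts(21, 2)], cohort_groups())[0]
        assert res.direction == "risk" and res.significant

    def test_equal_frequencies_never_significant(self):
        # with zero carriers on both sides the upper tail is the whole mass
        res = associate_loci([locus_with_counts(0, 0)], cohort_groups())[0]
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant
        # at matched nonzero frequencies the tail contains the expectation
        res = associate_loci([locus_with_counts(10, 10, 100, 100)], cohort_groups(100, 100))[0]
        assert res.p_value >= 0.5
        assert not res.significant

    def test_rare_locus_never_claims_significance(self):
        res = associate_loci([locus_with_counts(4, 0, rarity="rare")], cohort_groups())[0]
        assert not res.significant  # reported, but no significance claim
        assert 0 < res.p_value < 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            associate_loci([locus_with_counts(1, 1)], SampleGroups({"A1": "case"}))

    def test_power_at_study_effect_size(self):
        """Planted 1.75% vs 10.38% carrier frequencies at n = 114/106 reach
        one-sided protective significance with probability >= 0.80.

        Power is computed exactly by enumerating the binomial carrier-count
        grid (tail mass beyond the grid < 1e-9), not by sampling."""
        from scipy import stats as ss

        power = 0.0
        for a in range(0, 21):
            pa = ss.binom.pmf(a, 114, 0.0175)
            for b in range(0, 51):
                pb = ss.binom.pmf(b, 106, 0.1038)
                if b / 106 > a / 114 and fisher_one_sided(a, 114, b, 106) < 0.05:
                    power += pa * pb
        assert power >= 0.80


# ---------------------------------------------------------------------------
# burden statistics
# ---------------------------------------------------------------------------

def rank_sum_oracle(x, y) -> float:
    """Exact two-tailed Mann-Whitney by enumerating all group assignments."""
    pooled = sorted(x + y)
    ranks = {}
    vals = np.array(x + y, float)
    order = vals.argsort()
    # midranks
    r = np.empty(len(vals))
    i = 0
    sorted_vals = vals[order]
    while i < len(vals):
        j = i
        while j + 1 < len(vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        r[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    n = len(x)
    obs = r[:n].sum()
    stats_all = [
        sum(r[list(idx)]) for idx in combinations(range(len(vals)), n)
    ]
    mean = np.mean(stats_all)
    extreme = sum(1 for s in stats_all if abs(s - mean) >= abs(obs - mean) - 1e-9)
    return extreme / len(stats_all)


class TestBurdenStats:
    def test_identical_counts_give_p_one(self):
        calls = [
            make_call(sample_id=s, start=10_000 * i + 1, end=10_000 * i + 5_000)
            for i, s in enumerate(["A0", "A1", "C0", "C1"])
        ]
        groups = cohort_groups(2, 2)
        summary = burden_stats(calls, groups)
        row = summary.overall.set_index("category").loc["mean_calls_per_individual"]
        assert row["p_value"] == pytest.approx(1.0)

    def test_mann_whitney_matches_exhaustive_enumeration(self):
        x, y = [3.0, 4.0, 5.0], [1.0, 1.0, 2.0]
        assert mann_whitney_two_sided(x, y) == pytest.approx(rank_sum_oracle(x, y))
        x2, y2 = [3.0, 5.0, 8.0, 9.0], [1.0, 2.0, 4.0]
        assert mann_whitney_two_sided(x2, y2) == pytest.approx(rank_sum_oracle(x2, y2))

    def test_median_and_mean_sizes(self):
        calls = [
            make_call(sample_id="A0", start=100_000 * i + 1, end=100_000 * i + 10_001)
            for i in range(10)
        ] + [make_call(sample_id="A0", start=5_000_001, end=5_100_001)]
        groups = cohort_groups(1, 1)
        calls.append(make_call(sample_id="C0", start=1, end=10_001))
        summary = burden_stats(calls, groups)
        by_type = summary.by_type.set_index(["cnv_type", "metric"])
        assert by_type.loc[("het_deletion", "median_size_kb"), "case"] == pytest.approx(10.0)
        mean_kb = summary.overall.set_index("category").loc["mean_length_kb", "case"]
        assert mean_kb == pytest.approx(18.2, abs=0.05)

    def test_zero_call_individuals_contribute_zeros(self):
        calls = [make_call(sample_id="A0")]
        groups = cohort_groups(3, 2)
        summary = burden_stats(calls, groups)
        counts = summary.counts_per_individual
        assert len(counts) == 5 and counts["n_calls"].sum() == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            burden_stats([make_call(sample_id="A0")], SampleGroups({"A0": "case"}))

    def test_totals_split_by_type(self):
        calls = [
            make_call(sample_id="A0", copy_number=3),
            make_call(sample_id="A0", copy_number=1, start=50_000, end=60_000),
            make_call(sample_id="C0", copy_number=0, start=90_000, end=99_000),
        ]
        summary = burden_stats(calls, cohort_groups(1, 1))
        by_type = summary.by_type.set_index(["cnv_type", "metric"])
        assert by_type.loc[("duplication", "total"), "case"] == 1
        assert by_type.loc[("het_deletion", "total"), "case"] == 1
        assert by_type.loc[("hom_deletion", "total"), "control"] == 1
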
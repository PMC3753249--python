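"""Locus definition: greedy intersection-core clustering against a
brute-force partition oracle, plus carrier accounting."""

import numpy as np
import pytest

from cnvscreen import LocusParams, SampleGroups, define_loci
from cnvscreen.loci import _greedy_cluster
from tests.conftest import make_call


def groups_for(calls, n_case=114, n_control=106):
    assign = {}
    for c in calls:
        assign[c.sample_id] = "case" if c.sample_id.startswith("A") else "control"
    # pad to the requested denominators
    for i in range(n_case - sum(1 for g in assign.values() if g == "case")):
        assign[f"Apad{i}"] = "case"
    for i in range(n_control - sum(1 for g in assign.values() if g == "control")):
        assign[f"Cpad{i}"] = "control"
    return SampleGroups(assign)


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate all set partitions into valid blocks
# ---------------------------------------------------------------------------

def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield part + [[first]]


def block_core(block):
    start = max(c.start for c in block)
    end = min(c.end for c in block)
    return start, end


def min_valid_blocks(calls, min_intersection):
    """Minimum number of blocks over all partitions whose every block has a
    common core of at least min_intersection bp."""
    best = None
    for part in set_partitions(list(calls)):
        if all(
            (lambda se: se[1] - se[0] >= min_intersection)(block_core(b)) for b in part
        ):
            best = len(part) if best is None else min(best, len(part))
    return best


class TestGreedyClustering:
    def test_identical_calls_form_single_locus_with_exact_bounds(self):
        calls = [
            make_call(sample_id="A1", start=89_485_137, end=89_499_861),
            make_call(sample_id="C1", start=89_485_137, end=89_499_861),
        ]
        loci = define_loci(calls, groups_for(calls))
        assert len(loci) == 1
        locus = loci[0]
        assert (locus.start, locus.end) == (89_485_137, 89_499_861)
        assert locus.carriers_case == 1 and locus.carriers_control == 1

    def test_999_bp_overlap_stays_two_loci(self):
        calls = [
            make_call(sample_id="A1", start=1, end=10_000),
            make_call(sample_id="A2", start=9_001, end=20_000),
        ]
        loci = define_loci(calls, groups_for(calls))
        assert len(loci) == 2

    def test_1000_bp_overlap_merges(self):
        calls = [
            make_call(sample_id="A1", start=1, end=10_000),
            make_call(sample_id="A2", start=9_000, end=20_000),
        ]
        loci = define_loci(calls, groups_for(calls))
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (9_000, 10_000)

    def test_chained_calls_resolve_like_the_exhaustive_oracle(self):
        a = make_call(sample_id="A1", start=1, end=5_000)
        b = make_call(sample_id="A2", start=3_000, end=9_000)
        c = make_call(sample_id="A3", start=7_500, end=12_000)
        groups = _greedy_cluster([a, b, c], 1000)
        assert len(groups) == min_valid_blocks([a, b, c], 1000) == 2
        members = sorted(frozenset(x.sample_id for x in g[2]) for g in groups)
        # longest call (B) seeds and admits A; C has no 1 kb core with them
        assert members == [frozenset({"A1", "A2"}), frozenset({"A3"})]

    def test_sample_with_two_member_calls_counts_once(self):
        calls = [
            make_call(sample_id="A1", start=1_000, end=10_000),
            make_call(sample_id="A1", start=2_000, end=9_000),
            make_call(sample_id="C1", start=1_500, end=9_500),
        ]
        loci = define_loci(calls, groups_for(calls))
        assert len(loci) == 1
        assert loci[0].carriers_case == 1 and loci[0].carriers_control == 1

    def test_gains_and_losses_cluster_separately(self):
        calls = [
            make_call(sample_id="A1", start=1_000, end=10_000, copy_number=1),
            make_call(sample_id="A2", start=1_000, end=10_000, copy_number=3),
        ]
        loci = define_loci(calls, groups_for(calls))
        assert sorted(l.cnv_type for l in loci) == ["gain", "het_loss"]

    def test_mixed_zygosity_records_counts(self):
        calls = [
            make_call(sample_id="A1", start=1_000, end=10_000, copy_number=0),
            make_call(sample_id="A2", start=1_000, end=10_000, copy_number=1),
            make_call(sample_id="A3", start=20_000, end=30_000, copy_number=0),
        ]
        loci = define_loci(calls, groups_for(calls))
        het = next(l for l in loci if l.start == 1_000)
        hom = next(l for l in loci if l.start == 20_000)
        assert het.cnv_type == "het_loss" and (het.n_het, het.n_hom) == (1, 1)
        assert hom.cnv_type == "hom_loss"

    def test_unknown_sample_rejected(self):
        calls = [make_call(sample_id="ghost")]
        with pytest.raises(ValueError, match="ghost"):
            define_loci(calls, SampleGroups({"A1": "case", "C1": "control"}))

    def test_frequencies_reproduce_printed_percentages(self):
        calls = [
            make_call(sample_id=f"A{i}", start=50_545_009, end=50_586_426)
            for i in range(21)
        ] + [
            make_call(sample_id=f"C{i}", start=50_545_009, end=50_586_426)
            for i in range(2)
        ]
        loci = define_loci(calls, groups_for(calls, 114, 106))
        locus = loci[0]
        assert round(100 * locus.freq_case, 2) == 18.42
        assert round(100 * locus.freq_control, 2) == 1.89
        assert locus.rarity == "common"

    def test_rare_flag_below_threshold(self):
        calls = [make_call(sample_id="A1"), make_call(sample_id="A2")]
        loci = define_loci(calls, groups_for(calls, 114, 106))
        assert loci[0].rarity == "rare"  # 2/114 < 5% in both groups

    @pytest.mark.parametrize("seed", range(12))
    def test_randomized_jittered_clusters_match_partition_oracle(self, seed):
        """Calls jittered around shared true loci (the regime the pipeline
        sees) partition exactly as the exhaustive minimum-block oracle."""
        rng = np.random.default_rng(seed)
        calls = []
        n_loci = rng.integers(1, 3)
        sid = 0
        for i in range(n_loci):
            start = 1 + i * 50_000 + int(rng.integers(0, 10_000))
            end = start + int(rng.integers(8_000, 20_000))
            for _ in range(int(rng.integers(1, 4))):
                j1, j2 = rng.integers(-2_000, 2_000, 2)
                calls.append(
                    make_call(
                        sample_id=f"A{sid}",
                        start=max(1, start + int(j1)),
                        end=end + int(j2),
                    )
                )
                sid += 1
        for _ in range(int(rng.integers(0, 3))):  # isolated calls
            start = 200_000 + int(rng.integers(0, 100_000))
            calls.append(
                make_call(sample_id=f"A{sid}", start=start, end=start + 5_000)
            )
            sid += 1
        calls = calls[:6]
        groups = _greedy_cluster(list(calls), 1000)
        # greedy partition is valid and attains the oracle block count
        for core_s, core_e, members in groups:
            assert core_e - core_s >= 1000
            for m in members:
                assert m.start <= core_s and m.end >= core_e
        assert len(groups) == min_valid_blocks(calls, 1000)
        assert sorted(id(c) for g in groups for c in g[2]) == sorted(map(id, calls))

    def test_every_member_contains_core(self):
        rng = np.random.default_rng(99)
        calls = []
        for i in range(20):
            start = int(rng.integers(1, 50_000))
            calls.append(
                make_call(
                    sample_id=f"A{i}", start=start, end=start + int(rng.integers(2_000, 30_000))
                )
            )
        loci = define_loci(calls, groups_for(calls))
        seen = 0
        for locus in loci:
            assert locus.end - locus.start >= 1000 or len(locus.member_calls) == 1
            for member in locus.member_calls:
                assert member.start <= locus.start and member.end >= locus.end
            seen += len(locus.member_calls)
        assert seen == len(calls)  # partition: every call in exactly one locus

    def test_param_validation(self):
        with pytest.raises(ValueError, match="min_intersection"):
            LocusParams(min_intersection=0)
        with pytest.raises(ValueError, match="rarity"):
            LocusParams(rarity_threshold=1.0)
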
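"""Population-level CNV locus definition.

Per-sample calls are collapsed into loci whose interval is the *common
intersected core* of their member calls: gains and losses cluster
separately per chromosome, and a call joins a locus only while its overlap
with the running core stays at or above ``min_intersection`` (default
1 kb).  Chaining without a shared core is resolved greedily: the longest
unassigned call seeds each locus, qualifying calls are admitted in a
deterministic order (longest first, then leftmost), and the core shrinks
to the intersection after every admission.  The guarantee that every
member contains the final core — hence any two members overlap by at
least the core length — follows by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .model import CASE, GAIN, HET_LOSS, HOM_LOSS, CnvCall, CnvLocus, SampleGroups


@dataclass
class LocusParams:
    min_intersection: int = 1000  # bp
    rarity_threshold: float = 0.05  # carrier-frequency split for common/rare

    def __post_init__(self):
        if self.min_intersection < 1:
            raise ValueError("min_intersection must be >= 1 bp")
        if not 0.0 < self.rarity_threshold < 1.0:
            raise ValueError("rarity_threshold must lie in (0, 1)")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return min(a_end, b_end) - max(a_start, b_start)


def _greedy_cluster(
    calls: list[CnvCall], min_intersection: int
) -> list[tuple[int, int, list[CnvCall]]]:
    """Greedy seeded clustering of same-chromosome, same-class calls.

    Returns (core_start, core_end, members) groups forming a partition of
    ``calls``.
    """
    # deterministic scan order: longest first, then leftmost, then sample id
    pool = sorted(calls, key=lambda c: (-c.length, c.start, c.end, c.sample_id))
    groups = []
    while pool:
        seed = pool.pop(0)
        core_s, core_e = seed.start, seed.end
        members = [seed]
        admitted = True
        while admitted:
            admitted = False
            for i, cand in enumerate(pool):
                if _overlap(core_s, core_e, cand.start, cand.end) >= min_intersection:
                    core_s = max(core_s, cand.start)
                    core_e = min(core_e, cand.end)
                    members.append(pool.pop(i))
                    admitted = True
                    break
        groups.append((core_s, core_e, members))
    return groups


def define_loci(
    calls: Sequence[CnvCall],
    groups: SampleGroups,
    params: LocusParams | None = None,
) -> list[CnvLocus]:
    """Collapse QC-passed calls into CNV loci with carrier statistics.

    Carriers are counted once per sample per locus; frequencies use the
    post-QC group sizes carried by ``groups``.  A locus is common when its
    carrier frequency exceeds the rarity threshold in either group.
    """
    params = params or LocusParams()
    for call in calls:
        if call.sample_id not in groups:
            raise ValueError(f"sample {call.sample_id!r} missing from group sheet")
    if groups.n_case == 0 or groups.n_control == 0:
        raise ValueError("both groups must be non-empty")

    loci: list[CnvLocus] = []
    by_key: dict[tuple[bool, str], list[CnvCall]] = {}
    for call in calls:
        by_key.setdefault((call.is_loss, call.chrom), []).append(call)

    for (is_loss, chrom), group_calls in by_key.items():
        for core_s, core_e, members in _greedy_cluster(
            group_calls, params.min_intersection
        ):
            carrier_ids = {c.sample_id for c in members}
            n_case_carr = sum(1 for s in carrier_ids if groups[s] == CASE)
            n_ctrl_carr = len(carrier_ids) - n_case_carr
            freq_case = n_case_carr / groups.n_case
            freq_ctrl = n_ctrl_carr / groups.n_control
            if is_loss:
                n_hom = sum(1 for c in members if c.copy_number == 0)
                n_het = len(members) - n_hom
                cnv_type = HOM_LOSS if n_het == 0 else HET_LOSS
            else:
                n_het = n_hom = 0
                cnv_type = GAIN
            loci.append(
                CnvLocus(
                    chrom=chrom,
                    start=core_s,
                    end=core_e,
                    cnv_type=cnv_type,
                    member_calls=members,
                    carriers_case=n_case_carr,
                    carriers_control=n_ctrl_carr,
                    freq_case=freq_case,
                    freq_control=freq_ctrl,
                    rarity="common"
                    if max(freq_case, freq_ctrl) > params.rarity_threshold
                    else "rare",
                    n_het=n_het,
                    n_hom=n_hom,
                )
            )
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.cnv_type))
    return loci


def annotate_loci(loci: Sequence[CnvLocus], gene_bed: pd.DataFrame) -> None:
    """Join loci against a gene/region table (1-based inclusive intervals)
    with any-overlap semantics, filling ``genes`` in place."""
    for locus in loci:
        sub = gene_bed[gene_bed["chrom"].astype(str) == str(locus.chrom)]
        hits = sub[(sub["start"] <= locus.end) & (sub["end"] >= locus.start)]
        locus.genes = list(dict.fromkeys(hits["name"]))
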
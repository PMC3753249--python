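"""Synthetic genotyping-array cohorts with known embedded CNV loci.

Generates a marker scaffold at OmniExpress-like density (~1 marker / 4 kb),
then per-sample LRR/BAF signals for a two-group cohort in which specified
loci are carried at specified per-group frequencies.  The emission model is
copy-number dependent: LRR is Gaussian around a per-copy-number mean with a
per-sample GC-coupled waviness term, and BAF follows the binomial genotype
mixture of :mod:`cnvscreen.baf`.  A truth table records every carrier
assignment so downstream stages can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .baf import sample_baf
from .model import (
    CASE,
    CONTROL,
    GAIN,
    HET_LOSS,
    HOM_LOSS,
    MarkerMap,
    SampleGroups,
    SampleSignal,
    chrom_sort_key,
)

#: copy number assigned to a carrier of each locus type (single-copy events;
#: hom_loss is the two-copy loss)
TYPE_TO_CN = {GAIN: 3, HET_LOSS: 1, HOM_LOSS: 0}

#: post-QC cohort of the study design this generator emulates
DEFAULT_N_CASE = 115
DEFAULT_N_CONTROL = 106


@dataclass
class EmissionModel:
    """Copy-number-dependent signal model for array LRR/BAF.

    LRR means are the canonical per-state values used by HMM-based array
    CNV callers (a full deletion leaves only background intensity, hence
    the large negative mean and inflated spread at cn=0); they are
    synthetic defaults, configurable per study.
    """

    lrr_mean: dict[int, float] = field(
        default_factory=lambda: {0: -3.5, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68}
    )
    lrr_sd: dict[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: 0.30, 2: 0.30, 3: 0.30, 4: 0.30}
    )
    baf_sd: float = 0.03
    waviness_sd: float = 0.3

    def __post_init__(self):
        means = [self.lrr_mean[cn] for cn in sorted(self.lrr_mean)]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ValueError("lrr_mean must be nondecreasing in copy number")
        if any(sd <= 0 for sd in self.lrr_sd.values()) or self.baf_sd <= 0:
            raise ValueError("all emission sd must be > 0")
        if self.waviness_sd < 0:
            raise ValueError("waviness_sd must be >= 0")


@dataclass
class EmbeddedLocusSpec:
    """A CNV locus to plant, with per-group carrier probabilities."""

    chrom: str
    start: int
    end: int
    cnv_type: str
    freq_case: float
    freq_control: float

    def __post_init__(self):
        self.chrom = str(self.chrom)
        if self.cnv_type not in TYPE_TO_CN:
            raise ValueError(f"unknown cnv_type {self.cnv_type!r}")
        for f in (self.freq_case, self.freq_control):
            if not 0.0 <= f <= 1.0:
                raise ValueError("carrier frequencies must lie in [0, 1]")
        if self.start >= self.end:
            raise ValueError("locus requires start < end")


class TruthTable:
    """Carrier assignments per sample x embedded locus."""

    def __init__(self, table: pd.DataFrame):
        self.table = table

    def carriers(self, locus_index: int) -> set[str]:
        t = self.table
        return set(t.loc[(t["locus"] == locus_index) & t["carrier"], "sample_id"])

    def carrier_counts(self, locus_index: int) -> tuple[int, int]:
        """(case carriers, control carriers) of one planted locus."""
        t = self.table
        sub = t[(t["locus"] == locus_index) & t["carrier"]]
        return (
            int((sub["group"] == CASE).sum()),
            int((sub["group"] == CONTROL).sum()),
        )

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def generate_marker_map(
    chrom_lengths: Mapping[str, int],
    mean_spacing_bp: float = 4000.0,
    seed: int = 0,
) -> MarkerMap:
    """Draw a marker scaffold with mean inter-marker gap ``mean_spacing_bp``.

    Gaps are uniform on [0.5, 1.5] x spacing; PFB is uniform on
    [0.05, 0.95]; GC is a smooth superposition of long-period sinusoids
    rescaled to [0.3, 0.7].
    """
    if mean_spacing_bp <= 0:
        raise ValueError("mean_spacing_bp must be > 0")
    if any(l <= 0 for l in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x4D41)))
    rows = []
    counter = 1
    items = sorted(chrom_lengths.items(), key=lambda kv: chrom_sort_key(kv[0]))
    for chrom, length in items:
        n_guess = int(2 * length / mean_spacing_bp) + 10
        gaps = rng.uniform(0.5 * mean_spacing_bp, 1.5 * mean_spacing_bp, size=n_guess)
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[pos <= length]
        pos = np.unique(pos)
        # smooth GC landscape: three sinusoids with Mb-scale periods
        periods = rng.uniform(5e5, 5e6, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        raw = sum(np.sin(2 * np.pi * pos / p + ph) for p, ph in zip(periods, phases)) / 3.0
        gc = np.clip(0.5 + 0.2 * raw, 0.3, 0.7)
        pfb = rng.uniform(0.05, 0.95, size=len(pos))
        for p, f, g in zip(pos, pfb, gc):
            rows.append((f"rs{counter}", str(chrom), int(p), float(f), float(g)))
            counter += 1
    return MarkerMap(pd.DataFrame(rows, columns=["name", "chrom", "pos", "pfb", "gc"]))


def simulate_cohort(
    marker_map: MarkerMap,
    n_case: int = DEFAULT_N_CASE,
    n_control: int = DEFAULT_N_CONTROL,
    locus_specs: Sequence[EmbeddedLocusSpec] = (),
    emission: EmissionModel | None = None,
    seed: int = 0,
) -> tuple[list[SampleSignal], TruthTable]:
    """Simulate a two-group cohort with the given loci planted.

    Each sample draws from its own deterministic substream (derived from
    ``seed`` and the sample index), so enlarging the cohort never perturbs
    existing samples.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("both group sizes must be > 0")
    emission = emission or EmissionModel()
    locus_markers = []
    for spec in locus_specs:
        idx = marker_map.markers_in(spec.chrom, spec.start, spec.end)
        if idx.size == 0:
            raise ValueError(
                f"locus {spec.chrom}:{spec.start}-{spec.end} spans no mapped marker"
            )
        locus_markers.append(idx)

    gc = marker_map.gc
    gc_centered = gc - gc.mean()
    pfb = marker_map.pfb
    n = len(marker_map)
    mean2, sd2 = emission.lrr_mean[2], emission.lrr_sd[2]

    signals: list[SampleSignal] = []
    truth_rows = []
    labels = [(f"ALS{i + 1}", CASE) for i in range(n_case)] + [
        (f"CTRL{i + 1}", CONTROL) for i in range(n_control)
    ]
    for s_idx, (sid, group) in enumerate(labels):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), s_idx)))
        lrr = rng.normal(mean2, sd2, size=n)
        w = rng.normal(0.0, emission.waviness_sd)
        baf = sample_baf(2, pfb, emission.baf_sd, rng)
        for l_idx, (spec, idx) in enumerate(zip(locus_specs, locus_markers)):
            freq = spec.freq_case if group == CASE else spec.freq_control
            carrier = bool(rng.random() < freq)
            cn = TYPE_TO_CN[spec.cnv_type]
            truth_rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "locus": l_idx,
                    "chrom": spec.chrom,
                    "start": spec.start,
                    "end": spec.end,
                    "carrier": carrier,
                    "copy_number": cn if carrier else 2,
                }
            )
            if carrier:
                lrr[idx] = rng.normal(
                    emission.lrr_mean[cn], emission.lrr_sd[cn], size=idx.size
                )
                baf[idx] = sample_baf(cn, pfb[idx], emission.baf_sd, rng)
        lrr += w * gc_centered  # per-sample GC waviness across the whole array
        signals.append(SampleSignal(sample_id=sid, group=group, lrr=lrr, baf=baf))
    truth = TruthTable(
        pd.DataFrame(
            truth_rows,
            columns=[
                "sample_id", "group", "locus", "chrom", "start", "end",
                "carrier", "copy_number",
            ],
        )
    )
    return signals, truth


def write_cohort(
    signals: Sequence[SampleSignal],
    truth: TruthTable,
    marker_map: MarkerMap,
    outdir,
) -> None:
    """Write a simulated cohort in the pipeline's on-disk dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sig_dir = outdir / "signals"
    sig_dir.mkdir(exist_ok=True)
    for sig in signals:
        cio.write_signal_file(sig, marker_map, sig_dir / f"{sig.sample_id}.txt")
    cio.write_sample_sheet(SampleGroups.from_signals(signals), outdir / "samples.tsv")
    cio.write_marker_map(marker_map, outdir / "markers.pfb", outdir / "markers.gcmodel")
    truth.write(outdir / "truth.tsv")
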
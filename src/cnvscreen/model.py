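"""Domain types shared by every pipeline stage.

Coordinate convention: all genomic intervals are 1-based inclusive
(matching the text dialect of array CNV callers and the coordinates this
kind of study prints), and a call's ``length`` is defined as ``end - start``
in bp.  BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

GAIN = "gain"
HET_LOSS = "het_loss"
HOM_LOSS = "hom_loss"

#: copy numbers a CNV call may carry (diploid cn=2 is never a call)
CNV_COPY_NUMBERS = (0, 1, 3, 4)


def chrom_sort_key(chrom: str) -> tuple:
    """Order autosomes numerically, then other labels lexicographically."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


class MarkerMap:
    """Ordered genome-wide marker scaffold all signals align to.

    Wraps a DataFrame with columns ``name, chrom, pos, pfb, gc``:
    marker identifier, chromosome label, 1-based bp position, population
    frequency of the B allele and GC fraction of the surrounding window
    (both fractions in [0, 1]).
    """

    COLUMNS = ("name", "chrom", "pos", "pfb", "gc")

    def __init__(self, table: pd.DataFrame):
        df = table.reset_index(drop=True).copy()
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"marker table missing columns: {sorted(missing)}")
        df["chrom"] = df["chrom"].astype(str)
        if df["name"].duplicated().any():
            dups = df.loc[df["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate marker name: {dups!r}")
        if (df["pos"] < 1).any():
            raise ValueError("marker positions must be >= 1")
        for col in ("pfb", "gc"):
            vals = df[col].to_numpy(float)
            if np.any((vals < 0) | (vals > 1) | ~np.isfinite(vals)):
                raise ValueError(f"{col} values must lie in [0, 1]")
        key = df["chrom"].map(chrom_sort_key)
        order = pd.DataFrame({"k": key, "pos": df["pos"]}).sort_values(["k", "pos"]).index
        if not np.array_equal(order.to_numpy(), np.arange(len(df))):
            raise ValueError("markers must be sorted by (chrom, pos)")
        per_chrom = df.groupby("chrom", sort=False)["pos"]
        if (per_chrom.apply(lambda s: s.duplicated().any())).any():
            raise ValueError("duplicate marker position on a chromosome")
        self._df = df
        self._index = {name: i for i, name in enumerate(df["name"])}

    # -- accessors ---------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def names(self) -> pd.Series:
        return self._df["name"]

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self._df["chrom"]))

    @property
    def pos(self) -> np.ndarray:
        return self._df["pos"].to_numpy()

    @property
    def pfb(self) -> np.ndarray:
        return self._df["pfb"].to_numpy(float)

    @property
    def gc(self) -> np.ndarray:
        return self._df["gc"].to_numpy(float)

    def index_of(self, name: str) -> int:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index range of one chromosome's markers."""
        idx = np.flatnonzero((self._df["chrom"] == str(chrom)).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def markers_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of markers with start <= pos <= end on chrom."""
        sl = self.chrom_slice(chrom)
        pos = self.pos[sl]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return np.arange(sl.start + lo, sl.start + hi)


@dataclass
class SampleSignal:
    """One individual's LRR/BAF vectors aligned to a :class:`MarkerMap`."""

    sample_id: str
    group: str
    lrr: np.ndarray
    baf: np.ndarray
    missing: np.ndarray = None

    def __post_init__(self):
        self.lrr = np.asarray(self.lrr, float)
        self.baf = np.asarray(self.baf, float)
        if self.missing is None:
            self.missing = np.zeros(self.lrr.shape, bool)
        self.missing = np.asarray(self.missing, bool)
        if not (len(self.lrr) == len(self.baf) == len(self.missing)):
            raise ValueError("lrr/baf/missing length mismatch")
        if self.group not in (CASE, CONTROL):
            raise ValueError(f"group must be {CASE!r} or {CONTROL!r}")
        ok = ~self.missing & np.isfinite(self.baf)
        if np.any((self.baf[ok] < 0) | (self.baf[ok] > 1)):
            raise ValueError("BAF outside [0, 1]")

    def check_aligned(self, marker_map: MarkerMap) -> None:
        if len(self.lrr) != len(marker_map):
            raise ValueError(
                f"signal of {self.sample_id} has {len(self.lrr)} markers, "
                f"map has {len(marker_map)}"
            )


@dataclass
class CnvCall:
    """One called copy-number segment in one sample.

    ``length`` is ``end - start`` bp; ``confidence`` is the log-likelihood
    ratio of the called state versus diploid over the segment (``None``
    when unknown, which any confidence filter treats as below threshold).
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    num_snps: int
    start_snp: str
    end_snp: str
    confidence: float | None = None

    def __post_init__(self):
        self.chrom = str(self.chrom)
        if self.copy_number not in CNV_COPY_NUMBERS:
            raise ValueError(f"copy_number must be one of {CNV_COPY_NUMBERS}")
        if not self.start < self.end:
            raise ValueError("call requires start < end")
        if self.num_snps < 3:
            raise ValueError("call requires num_snps >= 3")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_loss(self) -> bool:
        return self.copy_number < 2


@dataclass
class CnvLocus:
    """Population-level CNV region: the intersected core of member calls."""

    chrom: str
    start: int
    end: int
    cnv_type: str
    member_calls: list[CnvCall]
    carriers_case: int
    carriers_control: int
    freq_case: float
    freq_control: float
    rarity: str
    n_het: int = 0
    n_hom: int = 0
    genes: list[str] = field(default_factory=list)
    novel: bool | None = None

    @property
    def carrier_ids(self) -> set[str]:
        return {c.sample_id for c in self.member_calls}

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AssociationResult:
    locus: CnvLocus
    a_carriers: int
    a_noncarriers: int
    b_carriers: int
    b_noncarriers: int
    p_value: float
    direction: str  # "risk" | "protective"
    significant: bool


@dataclass
class ValidationReport:
    """Per-SNP LRR contrast around one locus and the resulting verdict."""

    locus: CnvLocus
    snps: pd.DataFrame  # marker, pos, in_region, mean_carrier, mean_noncarrier, p_t, p_u
    verdict: str  # "validated" | "not_validated" | "undeterminable"
    direction_consistent: bool
    n_carriers: int
    n_noncarrier_controls: int


class SampleGroups:
    """Case/control assignment with explicit group denominators.

    Denominators are the post-QC group sizes used for carrier frequencies
    and association tests; samples dropped by QC must be removed with
    :meth:`without_samples` before association.
    """

    def __init__(self, assignment: Mapping[str, str]):
        bad = {g for g in assignment.values() if g not in (CASE, CONTROL)}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self._assignment = dict(assignment)

    def __getitem__(self, sample_id: str) -> str:
        return self._assignment[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._assignment

    def __len__(self) -> int:
        return len(self._assignment)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._assignment)

    @property
    def n_case(self) -> int:
        return sum(1 for g in self._assignment.values() if g == CASE)

    @property
    def n_control(self) -> int:
        return sum(1 for g in self._assignment.values() if g == CONTROL)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self._assignment.items() if g == group]

    def without_samples(self, dropped: Iterable[str]) -> "SampleGroups":
        dropped = set(dropped)
        return SampleGroups(
            {s: g for s, g in self._assignment.items() if s not in dropped}
        )

    @classmethod
    def from_signals(cls, signals: Sequence[SampleSignal]) -> "SampleGroups":
        return cls({s.sample_id: s.group for s in signals})
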
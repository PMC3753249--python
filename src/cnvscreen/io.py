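"""Readers and writers for the text dialects the pipeline touches.

Supported formats:

* per-sample signal tables (tab-delimited, header-bearing; a subset of the
  Illumina final-report columns: marker name, Log R Ratio, B allele freq),
* PFB and GC-model marker companion files,
* the ``.rawcnv`` one-call-per-line dialect of array CNV callers,
* sample sheets (sample id + case/control label),
* association/loci TSV and BED exports.

All readers validate domain invariants and reject bad records instead of
coercing them.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    CASE,
    CONTROL,
    AssociationResult,
    CnvCall,
    CnvLocus,
    MarkerMap,
    SampleGroups,
    SampleSignal,
    chrom_sort_key,
)

log = logging.getLogger(__name__)

# state token <-> copy number in the .rawcnv dialect (state3/state4 are the
# diploid and copy-neutral states and never appear in a call file)
STATE_TO_CN = {"state1": 0, "state2": 1, "state5": 3, "state6": 4}
CN_TO_STATE = {v: k for k, v in STATE_TO_CN.items()}

_RAWCNV_RE = re.compile(
    r"^chr(?P<chrom>\S+):(?P<start>[\d,]+)-(?P<end>[\d,]+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+length=(?P<length>[\d,]+)\s+"
    r"(?P<state>state\d),cn=(?P<cn>\d)\s+(?P<sample>\S+)\s+"
    r"startsnp=(?P<startsnp>\S+)\s+endsnp=(?P<endsnp>\S+)"
    r"(?:\s+conf=(?P<conf>\S+))?\s*$"
)


def _toint(token: str) -> int:
    return int(token.replace(",", ""))


# ---------------------------------------------------------------------------
# marker map companions
# ---------------------------------------------------------------------------

def _read_marker_table(path, value_col: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=["name", "chrom", "pos", value_col],
        dtype={"name": str, "chrom": str},
        header=None,
        skiprows=_count_header_rows(path),
    )
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
        raise ValueError(f"{path}: duplicate marker name {dup!r}")
    key = df["chrom"].map(chrom_sort_key)
    order = pd.DataFrame({"k": key, "pos": df["pos"]}).sort_values(["k", "pos"]).index
    if not np.array_equal(order.to_numpy(), np.arange(len(df))):
        log.info("%s: input not sorted by (chrom, pos); sorting", path)
        df = df.loc[order].reset_index(drop=True)
    return df


def _count_header_rows(path) -> int:
    """Companion files may carry one header line (e.g. 'Name Chr Position PFB')."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.split()
            try:
                float(fields[2])
                return 0
            except (ValueError, IndexError):
                return 1
    return 0


def read_pfb(path) -> pd.DataFrame:
    """Read a PFB companion file: name, chrom, position, B-allele frequency."""
    df = _read_marker_table(path, "pfb")
    bad = df[(df["pfb"] < 0) | (df["pfb"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: pfb outside [0, 1] at marker {bad['name'].iloc[0]!r}")
    return df


def read_gc_model(path) -> pd.DataFrame:
    """Read a GC-model companion file; GC given as percentage (0-100) or
    fraction (0-1) is normalized to a fraction."""
    df = _read_marker_table(path, "gc")
    gc = df["gc"].to_numpy(float)
    if np.nanmax(gc) > 1.0:
        gc = gc / 100.0
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError(f"{path}: gc outside [0, 100]")
    df["gc"] = gc
    return df


def marker_map_from_tables(pfb: pd.DataFrame, gc: pd.DataFrame) -> MarkerMap:
    """Merge PFB and GC companions into one MarkerMap (inner join on name)."""
    merged = pfb.merge(gc[["name", "gc"]], on="name", how="inner")
    if len(merged) < len(pfb):
        log.info(
            "GC model covers %d of %d PFB markers; dropping the rest",
            len(merged), len(pfb),
        )
    return MarkerMap(merged)


def read_marker_map(pfb_path, gc_path) -> MarkerMap:
    return marker_map_from_tables(read_pfb(pfb_path), read_gc_model(gc_path))


def write_marker_map(marker_map: MarkerMap, pfb_path, gc_path) -> None:
    df = marker_map.table
    df[["name", "chrom", "pos", "pfb"]].to_csv(
        pfb_path, sep="\t", index=False, header=False
    )
    out = df[["name", "chrom", "pos"]].copy()
    out["gc"] = df["gc"] * 100.0
    out.to_csv(gc_path, sep="\t", index=False, header=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# signal tables
# ---------------------------------------------------------------------------

_NAME_PATTERNS = ("snp name", "name", "marker")
_LRR_PATTERNS = ("log r ratio", "lrr")
_BAF_PATTERNS = ("b allele freq", "baf")


def _find_column(columns: Sequence[str], patterns: Sequence[str], what: str) -> str:
    lowered = {c.lower(): c for c in columns}
    for pat in patterns:
        for low, orig in lowered.items():
            if pat in low:
                return orig
    raise ValueError(f"no column matching {what} among {list(columns)}")


def read_signal_file(
    path,
    marker_map: MarkerMap,
    group: str = CONTROL,
    sample_id: str | None = None,
    max_unresolved_frac: float = 0.05,
) -> SampleSignal:
    """Read one sample's tab-delimited LRR/BAF table, aligned to the map.

    Markers present in the map but absent from the file are flagged missing;
    file markers not resolvable against the map are tolerated up to
    ``max_unresolved_frac`` of file rows, beyond which this is a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    name_col = _find_column(df.columns, _NAME_PATTERNS, "marker name")
    lrr_col = _find_column(df.columns, _LRR_PATTERNS, "LRR")
    baf_col = _find_column(df.columns, _BAF_PATTERNS, "BAF")
    for col in (lrr_col, baf_col):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: malformed numeric field in {col!r} at line {line}")
        df[col] = vals

    resolved = df[name_col].map(lambda n: n in marker_map)
    n_unresolved = int((~resolved).sum())
    if len(df) and n_unresolved / len(df) > max_unresolved_frac:
        raise ValueError(
            f"{path}: {n_unresolved}/{len(df)} marker names not in map "
            f"(tolerance {max_unresolved_frac:.0%})"
        )
    df = df[resolved]

    n = len(marker_map)
    lrr = np.full(n, np.nan)
    baf = np.full(n, np.nan)
    missing = np.ones(n, bool)
    idx = df[name_col].map(marker_map.index_of).to_numpy(int)
    lrr[idx] = df[lrr_col].to_numpy(float)
    baf[idx] = df[baf_col].to_numpy(float)
    missing[idx] = False
    return SampleSignal(
        sample_id=sample_id or path.stem,
        group=group,
        lrr=lrr,
        baf=baf,
        missing=missing,
    )


def write_signal_file(signal: SampleSignal, marker_map: MarkerMap, path) -> None:
    keep = ~signal.missing
    out = pd.DataFrame(
        {
            "Name": marker_map.names[keep],
            "Chr": marker_map.table["chrom"][keep],
            "Position": marker_map.pos[keep],
            "Log R Ratio": signal.lrr[keep],
            "B Allele Freq": signal.baf[keep],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_sample_sheet(path) -> SampleGroups:
    """Read a two-column sample sheet: sample_id <TAB> case|control."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    sid = cols.get("sample_id") or cols.get("sample") or df.columns[0]
    grp = cols.get("group") or cols.get("status") or df.columns[1]
    if df[sid].duplicated().any():
        raise ValueError(f"{path}: duplicate sample id")
    return SampleGroups(dict(zip(df[sid], df[grp].str.lower())))


def write_sample_sheet(groups: SampleGroups, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid in groups.sample_ids:
            fh.write(f"{sid}\t{groups[sid]}\n")


# ---------------------------------------------------------------------------
# .rawcnv call files
# ---------------------------------------------------------------------------

def parse_rawcnv_line(line: str) -> CnvCall:
    m = _RAWCNV_RE.match(line.strip())
    if not m:
        raise ValueError(f"unparseable rawcnv line: {line.strip()!r}")
    state, cn = m["state"], int(m["cn"])
    if state not in STATE_TO_CN:
        raise ValueError(f"state token {state!r} is not a CNV state")
    if STATE_TO_CN[state] != cn:
        raise ValueError(f"inconsistent {state},cn={cn}")
    conf = m["conf"]
    return CnvCall(
        sample_id=m["sample"],
        chrom=m["chrom"],
        start=_toint(m["start"]),
        end=_toint(m["end"]),
        copy_number=cn,
        num_snps=_toint(m["numsnp"]),
        start_snp=m["startsnp"],
        end_snp=m["endsnp"],
        confidence=float(conf) if conf is not None else None,
    )


def read_rawcnv(path) -> list[CnvCall]:
    calls = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                calls.append(parse_rawcnv_line(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return calls


def format_rawcnv_line(call: CnvCall) -> str:
    conf = "" if call.confidence is None else f" conf={call.confidence:g}"
    return (
        f"chr{call.chrom}:{call.start}-{call.end} "
        f"numsnp={call.num_snps} length={call.length} "
        f"{CN_TO_STATE[call.copy_number]},cn={call.copy_number} "
        f"{call.sample_id} startsnp={call.start_snp} endsnp={call.end_snp}"
        f"{conf}"
    )


def write_rawcnv(calls: Iterable[CnvCall], path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for call in calls:
            fh.write(format_rawcnv_line(call) + "\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_CHANGE = {"gain": "gain", "het_loss": "loss", "hom_loss": "loss*"}

ASSOC_COLUMNS = [
    "Chr", "Start", "End", "Change",
    "ALS count", "ALS %", "Control count", "Control %",
    "p-value", "Region", "Gene",
]


def _locus_row(locus: CnvLocus) -> dict:
    return {
        "Chr": locus.chrom,
        "Start": locus.start,
        "End": locus.end,
        "Change": _CHANGE[locus.cnv_type],
        "ALS count": locus.carriers_case,
        "ALS %": f"{100 * locus.freq_case:.2f}",
        "Control count": locus.carriers_control,
        "Control %": f"{100 * locus.freq_control:.2f}",
        "Region": "intergenic" if not locus.genes else "gene",
        "Gene": ",".join(locus.genes),
    }


def write_association_table(
    results: Sequence[AssociationResult], path, header_lines: Sequence[str] = ()
) -> None:
    rows = []
    for res in results:
        row = _locus_row(res.locus)
        row["p-value"] = f"{res.p_value:.7g}"
        rows.append(row)
    _write_tsv(pd.DataFrame(rows, columns=ASSOC_COLUMNS), path, header_lines)


def write_rare_table(
    loci: Sequence[CnvLocus], path, header_lines: Sequence[str] = ()
) -> None:
    """Rare-locus table: association schema without the p-value column."""
    cols = [c for c in ASSOC_COLUMNS if c != "p-value"]
    rows = [_locus_row(l) for l in loci]
    _write_tsv(pd.DataFrame(rows, columns=cols), path, header_lines)


def write_loci_bed(loci: Sequence[CnvLocus], path, header_lines: Sequence[str] = ()) -> None:
    """Export loci as BED (0-based half-open): start-1, end."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for locus in loci:
            name = _CHANGE[locus.cnv_type]
            fh.write(f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t{name}\n")


def read_gene_bed(path) -> pd.DataFrame:
    """Read a gene/region annotation BED (chrom, start, end, name) into
    1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append(
                {
                    "chrom": f[0].removeprefix("chr"),
                    "start": int(f[1]) + 1,
                    "end": int(f[2]),
                    "name": f[3].strip() if len(f) > 3 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _write_tsv(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
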
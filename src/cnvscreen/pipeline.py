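"""End-to-end orchestration: simulate or load a cohort, adjust signals,
call CNVs, filter, define loci, test association, and validate candidate
loci — with one config, one seed, and deterministic outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as cio
from .association import associate_loci, burden_stats
from .calling import CallerParams, adjust_gc, call_cnvs
from .loci import LocusParams, annotate_loci, define_loci
from .model import MarkerMap, SampleGroups, SampleSignal
from .qc import QcParams, filter_calls
from .simulate import (
    DEFAULT_N_CASE,
    DEFAULT_N_CONTROL,
    EmbeddedLocusSpec,
    EmissionModel,
    generate_marker_map,
    simulate_cohort,
    write_cohort,
)
from .validation import ValidationParams, validate_locus, write_validation_report

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # simulate | analyze
    outdir: str = "cnvscreen_out"
    seed: int = 0
    alpha: float = 0.05
    validate_all: bool = False

    # analyze-mode inputs
    signals_dir: str | None = None
    pfb: str | None = None
    gc_model: str | None = None
    sample_sheet: str | None = None
    rawcnv: str | None = None
    gene_bed: str | None = None

    # simulate-mode cohort
    chrom_lengths: dict = field(default_factory=lambda: {"1": 20_000_000})
    mean_spacing_bp: float = 4000.0
    n_case: int = DEFAULT_N_CASE
    n_control: int = DEFAULT_N_CONTROL
    planted_loci: list = field(default_factory=list)  # dicts for EmbeddedLocusSpec
    emission: dict = field(default_factory=dict)  # EmissionModel overrides

    # stage parameters
    caller: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    locus: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def emission_model(self) -> EmissionModel:
        kw = dict(self.emission)
        for key in ("lrr_mean", "lrr_sd"):
            if key in kw:
                kw[key] = {int(k): float(v) for k, v in kw[key].items()}
        return EmissionModel(**kw)

    def caller_params(self) -> CallerParams:
        return CallerParams(emission=self.emission_model(), **self.caller)

    def qc_params(self) -> QcParams:
        return QcParams(**self.qc)

    def locus_params(self) -> LocusParams:
        return LocusParams(**self.locus)

    def validation_params(self) -> ValidationParams:
        return ValidationParams(**self.validation)


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    """Return (marker_map, signals or None, groups, calls or None)."""
    if cfg.mode == "simulate":
        marker_map = generate_marker_map(
            cfg.chrom_lengths, cfg.mean_spacing_bp, seed=cfg.seed
        )
        specs = [EmbeddedLocusSpec(**d) for d in cfg.planted_loci]
        signals, truth = simulate_cohort(
            marker_map,
            n_case=cfg.n_case,
            n_control=cfg.n_control,
            locus_specs=specs,
            emission=cfg.emission_model(),
            seed=cfg.seed,
        )
        write_cohort(signals, truth, marker_map, outdir / "sim")
        groups = SampleGroups.from_signals(signals)
        return marker_map, signals, groups, None
    if cfg.mode != "analyze":
        raise ValueError(f"unknown mode {cfg.mode!r}")
    for name in ("pfb", "gc_model", "sample_sheet"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"analyze mode requires existing path for {name!r}")
    marker_map = cio.read_marker_map(cfg.pfb, cfg.gc_model)
    groups = cio.read_sample_sheet(cfg.sample_sheet)
    signals = None
    if cfg.signals_dir:
        signals = []
        for sid in groups.sample_ids:
            path = Path(cfg.signals_dir) / f"{sid}.txt"
            if not path.exists():
                raise FileNotFoundError(f"no signal file for sample {sid!r}: {path}")
            signals.append(
                cio.read_signal_file(path, marker_map, group=groups[sid], sample_id=sid)
            )
    calls = cio.read_rawcnv(cfg.rawcnv) if cfg.rawcnv else None
    return marker_map, signals, groups, calls


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the machine-readable run summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"seed={cfg.seed}", f"config={cfg.config_hash()}"]
    summary: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash(), "stages": {}}

    marker_map, signals, groups, provided_calls = _load_inputs(cfg, outdir)
    summary["n_markers"] = len(marker_map)
    summary["n_samples"] = len(groups)

    if provided_calls is None:
        if signals is None:
            raise ValueError("analyze mode needs either signals_dir or rawcnv")
        params = cfg.caller_params()
        adjusted = [adjust_gc(s, marker_map, params.gc_window_bp) for s in signals]
        signals = adjusted
        calls = []
        for sig in signals:
            calls.extend(call_cnvs(sig, marker_map, params))
        cio.write_rawcnv(calls, outdir / "calls.rawcnv", header_lines=header)
    else:
        calls = provided_calls
        log.info("using %d externally provided calls; calling stage skipped", len(calls))
    summary["stages"]["calling"] = {"calls": len(calls)}

    kept, report = filter_calls(calls, cfg.qc_params())
    assert report.n_input == report.n_kept + report.n_dropped_sample_filter + report.n_dropped_confidence
    cio._write_tsv(report.to_frame(), outdir / "qc_report.tsv", header_lines=header)
    groups_qc = groups.without_samples(report.excluded_samples)
    summary["stages"]["qc"] = {
        "calls_in": report.n_input,
        "calls_kept": report.n_kept,
        "calls_dropped_sample_filter": report.n_dropped_sample_filter,
        "calls_dropped_confidence": report.n_dropped_confidence,
        "samples_excluded": report.excluded_samples,
        "n_case": groups_qc.n_case,
        "n_control": groups_qc.n_control,
    }

    loci = define_loci(kept, groups_qc, cfg.locus_params())
    if cfg.gene_bed:
        annotate_loci(loci, cio.read_gene_bed(cfg.gene_bed))
    cio.write_loci_bed(loci, outdir / "loci.bed", header_lines=header)
    common = [l for l in loci if l.rarity == "common"]
    rare = [l for l in loci if l.rarity == "rare"]
    summary["stages"]["loci"] = {
        "n_loci": len(loci), "n_common": len(common), "n_rare": len(rare),
    }

    results = associate_loci(loci, groups_qc, alpha=cfg.alpha)
    results.sort(key=lambda r: r.p_value)
    common_results = [r for r in results if r.locus.rarity == "common"]
    cio.write_association_table(common_results, outdir / "association.tsv", header)
    cio.write_rare_table(rare, outdir / "rare_loci.tsv", header)
    significant = [r for r in common_results if r.significant]
    summary["stages"]["association"] = {
        "n_tested": len(results),
        "n_significant_common": len(significant),
    }

    if kept:
        burden = burden_stats(kept, groups_qc)
        cio._write_tsv(burden.overall, outdir / "burden_overall.tsv", header)
        cio._write_tsv(burden.by_type, outdir / "burden_by_type.tsv", header)

    validations = []
    if signals is not None:
        to_validate = [r.locus for r in (results if cfg.validate_all else significant)]
        sig_by_id = {s.sample_id: s for s in signals}
        vparams = cfg.validation_params()
        for i, locus in enumerate(to_validate):
            rep = validate_locus(locus, sig_by_id, groups_qc, marker_map, vparams)
            write_validation_report(
                rep, outdir / f"validation_{i}_{locus.chrom}_{locus.start}.tsv", header
            )
            validations.append(
                {
                    "locus": f"{locus.chrom}:{locus.start}-{locus.end}",
                    "cnv_type": locus.cnv_type,
                    "verdict": rep.verdict,
                    "direction_consistent": rep.direction_consistent,
                }
            )
    else:
        log.info("no per-sample signals available; LRR validation skipped")
    summary["stages"]["validation"] = validations

    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
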
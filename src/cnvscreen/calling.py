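"""Signal adjustment and segmental copy-number calling.

``adjust_gc`` removes per-sample GC waviness by regressing LRR on
window-averaged GC content.  ``call_cnvs`` is a five-state (cn 0-4)
hidden-Markov segmenter over the joint LRR + BAF emission model, decoding
each chromosome by Viterbi and emitting maximal non-diploid runs as calls
with a log-likelihood-ratio confidence against the diploid state.  It is a
self-contained stand-in for the external HMM callers used on real array
data, producing interchangeable ``.rawcnv`` output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .baf import baf_loglik
from .model import CnvCall, MarkerMap, SampleSignal
from .simulate import EmissionModel

STATES = (0, 1, 2, 3, 4)
DIPLOID = 2  # index of cn=2 in STATES


@dataclass
class CallerParams:
    emission: EmissionModel = field(default_factory=EmissionModel)
    p_stay: float = 0.999
    min_snps: int = 3
    gc_window_bp: int = 1_000_000
    max_nonfinite_frac: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.p_stay < 1.0:
            raise ValueError("p_stay must lie in (0, 1)")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


def window_gc(marker_map: MarkerMap, window_bp: int) -> np.ndarray:
    """Per-marker GC averaged over markers within +/- window/2 bp."""
    gc = marker_map.gc
    out = np.empty(len(marker_map))
    half = window_bp / 2.0
    csum = None
    for chrom in marker_map.chroms:
        sl = marker_map.chrom_slice(chrom)
        pos = marker_map.pos[sl].astype(float)
        g = gc[sl]
        cs = np.concatenate([[0.0], np.cumsum(g)])
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        out[sl] = (cs[hi] - cs[lo]) / (hi - lo)
    return out


def adjust_gc(
    signal: SampleSignal, marker_map: MarkerMap, gc_window_bp: int = 1_000_000
) -> SampleSignal:
    """Regress LRR on window-averaged GC and subtract the fitted waviness.

    The returned LRR is the OLS residual re-centred at the sample's own
    mean level (equivalently: residual plus intercept of the regression on
    centred GC).  A degenerate regressor (constant GC) leaves the signal
    untouched.  BAF is never modified.
    """
    signal.check_aligned(marker_map)
    ok = ~signal.missing & np.isfinite(signal.lrr)
    if not ok.any():
        raise ValueError(f"sample {signal.sample_id}: no usable LRR values")
    gcw = window_gc(marker_map, gc_window_bp)
    x = gcw[ok] - gcw[ok].mean()
    y = signal.lrr[ok]
    ssx = float(np.dot(x, x))
    slope = float(np.dot(x, y) / ssx) if ssx > 1e-12 else 0.0
    lrr = signal.lrr.copy()
    lrr[ok] = y - slope * x
    return SampleSignal(
        sample_id=signal.sample_id,
        group=signal.group,
        lrr=lrr,
        baf=signal.baf,
        missing=signal.missing,
    )


def _emission_loglik(
    lrr: np.ndarray, baf: np.ndarray, pfb: np.ndarray, emission: EmissionModel
) -> np.ndarray:
    """Per-marker log-likelihood under each copy-number state, shape (n, 5)."""
    ll = np.empty((len(lrr), len(STATES)))
    for j, cn in enumerate(STATES):
        ll[:, j] = stats.norm.logpdf(
            lrr, loc=emission.lrr_mean[cn], scale=emission.lrr_sd[cn]
        ) + baf_loglik(baf, cn, pfb, emission.baf_sd)
    return ll


def _viterbi(loglik: np.ndarray, p_stay: float) -> np.ndarray:
    """Decode the max-likelihood state path; ties resolve to the lower state."""
    n, k = loglik.shape
    log_stay = np.log(p_stay)
    log_move = np.log((1.0 - p_stay) / (k - 1))
    trans = np.full((k, k), log_move)
    np.fill_diagonal(trans, log_stay)
    # start from the diploid state's transition row
    delta = trans[DIPLOID] + loglik[0]
    back = np.zeros((n, k), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + trans  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # first max -> lowest state on ties
        delta = cand[back[t], np.arange(k)] + loglik[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def call_cnvs(
    signal: SampleSignal, marker_map: MarkerMap, params: CallerParams | None = None
) -> list[CnvCall]:
    """Segment one sample's signal into copy-number calls.

    Missing markers are skipped (the chain runs over observed markers
    only); a fraction of non-finite LRR above ``max_nonfinite_frac`` of
    observed markers is an error.
    """
    params = params or CallerParams()
    signal.check_aligned(marker_map)
    observed = ~signal.missing
    nonfinite = observed & ~np.isfinite(signal.lrr)
    if observed.sum() and nonfinite.sum() / observed.sum() > params.max_nonfinite_frac:
        raise ValueError(
            f"sample {signal.sample_id}: {int(nonfinite.sum())} non-finite LRR values"
        )
    usable = observed & np.isfinite(signal.lrr) & np.isfinite(signal.baf)

    calls: list[CnvCall] = []
    names = marker_map.names.to_numpy()
    for chrom in marker_map.chroms:
        sl = marker_map.chrom_slice(chrom)
        idx = np.flatnonzero(usable[sl]) + sl.start
        if idx.size == 0:
            continue
        ll = _emission_loglik(
            signal.lrr[idx], signal.baf[idx], marker_map.pfb[idx], params.emission
        )
        path = _viterbi(ll, params.p_stay)
        # maximal runs of identical non-diploid states
        change = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(path)]])
        for s, e in zip(starts, ends):
            state = int(path[s])
            if state == DIPLOID or (e - s) < params.min_snps:
                continue
            run = idx[s:e]
            conf = float(np.sum(ll[s:e, state] - ll[s:e, DIPLOID]))
            calls.append(
                CnvCall(
                    sample_id=signal.sample_id,
                    chrom=chrom,
                    start=int(marker_map.pos[run[0]]),
                    end=int(marker_map.pos[run[-1]]),
                    copy_number=STATES[state],
                    num_snps=int(e - s),
                    start_snp=str(names[run[0]]),
                    end_snp=str(names[run[-1]]),
                    confidence=conf,
                )
            )
    return calls
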
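"""Post-calling quality control.

Two filters, applied in a fixed order: (1) samples with an excessive
number of calls — a signature of residual waviness or poor-quality arrays
— are dropped entirely; (2) remaining calls below the confidence threshold
are dropped.  A call whose confidence is unknown counts as below any
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .model import CnvCall


@dataclass
class QcParams:
    #: keep calls with confidence >= this ("10 or larger" passes at 10.0)
    min_confidence: float = 10.0
    #: drop whole samples carrying more calls than this (100 calls keeps)
    max_calls_per_sample: int = 100

    def __post_init__(self):
        if not self.min_confidence == self.min_confidence:  # NaN guard
            raise ValueError("min_confidence must be finite")
        if self.max_calls_per_sample < 1:
            raise ValueError("max_calls_per_sample must be >= 1")


@dataclass
class QcReport:
    n_input: int = 0
    excluded_samples: list[str] = field(default_factory=list)
    n_dropped_sample_filter: int = 0
    n_dropped_confidence: int = 0
    n_kept: int = 0
    calls_per_sample: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "calls_in",
                    "samples_excluded",
                    "calls_dropped_sample_filter",
                    "calls_dropped_confidence",
                    "calls_kept",
                ],
                "value": [
                    self.n_input,
                    len(self.excluded_samples),
                    self.n_dropped_sample_filter,
                    self.n_dropped_confidence,
                    self.n_kept,
                ],
            }
        )


def filter_calls(
    calls: Sequence[CnvCall], qc: QcParams | None = None
) -> tuple[list[CnvCall], QcReport]:
    """Apply sample-level then call-level QC; input calls are never modified.

    Returns the kept calls (input order preserved) and a report listing
    excluded samples and counts dropped at each step.  Idempotent.
    """
    qc = qc or QcParams()
    report = QcReport(n_input=len(calls))
    counts: dict[str, int] = {}
    for call in calls:
        counts[call.sample_id] = counts.get(call.sample_id, 0) + 1
    report.calls_per_sample = counts
    report.excluded_samples = sorted(
        s for s, n in counts.items() if n > qc.max_calls_per_sample
    )
    excluded = set(report.excluded_samples)

    kept: list[CnvCall] = []
    for call in calls:
        if call.sample_id in excluded:
            report.n_dropped_sample_filter += 1
        elif call.confidence is None or call.confidence < qc.min_confidence:
            report.n_dropped_confidence += 1
        else:
            kept.append(call)
    report.n_kept = len(kept)
    return kept, report
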
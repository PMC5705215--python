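"""Run reports: configuration echo, provenance counters and the verdict."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from .match import MatchConfig, MatchResult
from .sketch import FilterReport, Sketch


@dataclass
class RunReport:
    """Everything a user needs to audit one matching run.

    Counter conservation holds by construction: every read is either
    passing or dropped by exactly one filter, and every base at a panel
    position becomes an observation, an error-discard or a duplicate.
    """

    config: dict
    reads_in: int
    reads_pass_qc: int
    dropped_quality: int
    dropped_multi: int
    bases_at_panel: int
    bases_error: int
    bases_duplicate: int
    observations_used: int
    error_fraction: float
    verdict: str
    best_sample_id: str
    best_posterior: float
    best_n_intersected: int
    best_n_mismatch: int
    n_matched: int
    elapsed_data_seconds: Optional[float] = None

    @classmethod
    def build(
        cls,
        config: MatchConfig,
        filter_report: FilterReport,
        sketch: Sketch,
        result: MatchResult,
    ) -> "RunReport":
        elapsed = (
            max(o.timestamp for o in sketch.observations)
            if sketch.observations
            else None
        )
        best = result.best
        return cls(
            config=asdict(config),
            reads_in=filter_report.total,
            reads_pass_qc=filter_report.kept,
            dropped_quality=filter_report.dropped_quality,
            dropped_multi=filter_report.dropped_multi,
            bases_at_panel=sketch.bases_at_panel,
            bases_error=sketch.bases_error,
            bases_duplicate=sketch.bases_duplicate,
            observations_used=len(sketch.observations),
            error_fraction=sketch.error_fraction,
            verdict=result.verdict,
            best_sample_id=best.sample_id,
            best_posterior=best.posterior,
            best_n_intersected=best.n_intersected,
            best_n_mismatch=best.n_mismatch,
            n_matched=len(result.matched),
            elapsed_data_seconds=elapsed,
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
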
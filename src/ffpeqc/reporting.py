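"""Cohort-level sequencing success-rate bookkeeping.

Samples pass through a two-stage funnel: (1) extracted RNA is successfully
prepared for library prep; (2) the library has a sufficient amount of
non-ribosomal RNA.  A sample can pass stage 2 only if it passed stage 1,
so the overall success rate is the product of the stage rates.  Rates are
reported both as exact fractions and as rounded whole percents (the
rounded numbers can otherwise be ambiguous: stage rates of 86% and 94%
compose to 80.84%, which rounds to 81%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .models import SUCCESS_STAGES, StageOutcome

__all__ = ["StageRates", "summarize_success", "compose_success_rates"]


@dataclass
class StageRates:
    """Per-stage and overall success rates of a sequencing cohort."""

    n_total: int
    n_pass_stage1: int
    n_pass_stage2: int
    stage1_rate: float
    stage2_rate: float  # conditional on passing stage 1
    overall_rate: float

    @property
    def stage1_percent(self) -> int:
        return round(self.stage1_rate * 100)

    @property
    def stage2_percent(self) -> int:
        return round(self.stage2_rate * 100)

    @property
    def overall_percent(self) -> int:
        return round(self.overall_rate * 100)

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_pass_stage1": self.n_pass_stage1,
            "n_pass_stage2": self.n_pass_stage2,
            "stage1_rate": self.stage1_rate,
            "stage2_rate": self.stage2_rate,
            "overall_rate": self.overall_rate,
            "stage1_percent": self.stage1_percent,
            "stage2_percent": self.stage2_percent,
            "overall_percent": self.overall_percent,
        }


def summarize_success(outcomes: Iterable[StageOutcome]) -> StageRates:
    """Per-stage pass rates and the overall rate from per-sample outcomes.

    Stage 2's rate is conditional on passing stage 1, so the overall rate
    (stage-2 passes over all samples) is exactly the product of the two
    stage rates.  Violations of the funnel invariant (a sample passing
    stage 2 without passing stage 1) raise an error.
    """
    stage1: dict[str, bool] = {}
    stage2: dict[str, bool] = {}
    for o in outcomes:
        target = stage1 if o.stage == SUCCESS_STAGES[0] else stage2
        if o.sample_id in target:
            raise ValueError(f"duplicate outcome for {o.sample_id!r} at {o.stage}")
        target[o.sample_id] = o.passed
    if not stage1:
        raise ValueError("empty cohort")
    for sid, passed in stage2.items():
        if passed and not stage1.get(sid, False):
            raise ValueError(
                f"sample {sid!r} passed {SUCCESS_STAGES[1]} without passing "
                f"{SUCCESS_STAGES[0]}"
            )
    n_total = len(stage1)
    n1 = sum(stage1.values())
    n2 = sum(1 for sid, p in stage2.items() if p)
    stage1_rate = n1 / n_total
    stage2_rate = n2 / n1 if n1 else 0.0
    return StageRates(
        n_total=n_total,
        n_pass_stage1=n1,
        n_pass_stage2=n2,
        stage1_rate=stage1_rate,
        stage2_rate=stage2_rate,
        overall_rate=n2 / n_total,
    )


def compose_success_rates(stage_rates: Sequence[float]) -> tuple[float, int]:
    """Compose per-stage success rates into the overall rate.

    Returns the exact product and its rounded whole percent; e.g. stage
    rates 0.86 and 0.94 compose to 0.8084, reported as 81%.
    """
    if not stage_rates:
        raise ValueError("no stage rates supplied")
    overall = 1.0
    for r in stage_rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {r} outside [0, 1]")
        overall *= r
    return overall, round(overall * 100)
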
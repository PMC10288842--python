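"""Volumetric treatment-response classification after two therapy cycles.

The relative MTV change between the baseline and the interim scan is
classified with the volumetric criteria of Ohlendorf and colleagues:
a reduction of more than 73% is a partial response (PR), an increase of
more than 63% is progressive disease (PD), anything between is stable
disease (SD).  "More than" makes both boundaries inclusive to SD.
PR and SD count as response; PD defines a non-responder.
"""

from __future__ import annotations

import math
from enum import Enum

__all__ = [
    "ResponseClass",
    "PR_THRESHOLD_PCT",
    "PD_THRESHOLD_PCT",
    "percent_change",
    "classify_response",
    "is_responder",
]

PR_THRESHOLD_PCT = -73.0
PD_THRESHOLD_PCT = 63.0


class ResponseClass(str, Enum):
    PR = "PR"
    SD = "SD"
    PD = "PD"


class ZeroBaselineError(ValueError):
    """Relative change is undefined for a zero baseline MTV."""


def percent_change(baseline_mtv_ml: float, interim_mtv_ml: float) -> float:
    """Relative MTV change in percent: ``100 * (interim - baseline) / baseline``."""
    if baseline_mtv_ml <= 0:
        raise ZeroBaselineError(
            f"baseline MTV must be > 0 (got {baseline_mtv_ml}); "
            "zero-baseline patients must be handled explicitly"
        )
    if interim_mtv_ml < 0:
        raise ValueError("interim MTV must be >= 0")
    return 100.0 * (interim_mtv_ml - baseline_mtv_ml) / baseline_mtv_ml


def classify_response(
    pct_change: float,
    pr_threshold: float = PR_THRESHOLD_PCT,
    pd_threshold: float = PD_THRESHOLD_PCT,
) -> ResponseClass:
    """Map a percent MTV change to PR / SD / PD.

    PR iff change < pr_threshold (default -73), PD iff change >
    pd_threshold (default +63), SD otherwise; the thresholds themselves
    classify as SD.
    """
    if not math.isfinite(pct_change):
        raise ValueError(f"pct_change must be finite, got {pct_change}")
    if not pr_threshold < 0 < pd_threshold:
        raise ValueError("require pr_threshold < 0 < pd_threshold")
    if pct_change < pr_threshold:
        return ResponseClass.PR
    if pct_change > pd_threshold:
        return ResponseClass.PD
    return ResponseClass.SD


def is_responder(cls: ResponseClass) -> bool:
    """PR and SD are responders; PD is the non-responder class."""
    return cls is not ResponseClass.PD
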
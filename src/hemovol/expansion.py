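"""Serial-scan comparison and the hematoma-expansion (HE) conjunction rule.

Hematoma expansion is called when the follow-up volume exceeds baseline by
at least 6 cc *and* at least 33% — both criteria in conjunction, the
stricter of the definitions in circulation, chosen for specificity.
Growth is signed positive (``abs_diff_cc = followup - baseline``), so
shrinkage on follow-up appears as a negative difference and is reported
as-is ("negative expansion"), never clamped.

Percent change is relative to the baseline of the same measurement
modality, so automated percent change uses the automated baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import CohortError

__all__ = ["ExpansionCriteria", "SerialComparison", "compare_serial", "classify_cohort"]

logger = logging.getLogger(__name__)

#: Baseline volumes below this floor (cc) are outside the rule's domain:
#: percent change explodes and such lesions sit below the detection limit.
BASELINE_FLOOR_CC = 1.0


@dataclass(frozen=True)
class ExpansionCriteria:
    """Thresholds of the conjunction rule, both inclusive (>=)."""

    abs_threshold_cc: float = 6.0
    pct_threshold: float = 33.0


@dataclass(frozen=True)
class SerialComparison:
    """Baseline/follow-up volumes and the resulting HE classification."""

    baseline_cc: float
    followup_cc: float
    abs_diff_cc: float
    pct_diff: float
    he_positive: bool
    criteria: ExpansionCriteria


def compare_serial(
    baseline_cc: float,
    followup_cc: float,
    criteria: ExpansionCriteria = ExpansionCriteria(),
    baseline_floor_cc: float = BASELINE_FLOOR_CC,
) -> SerialComparison:
    """Classify one baseline/follow-up volume pair.

    ``he_positive`` is true iff ``abs_diff_cc >= abs_threshold_cc`` AND
    ``pct_diff >= pct_threshold``; both thresholds inclusive.

    Raises
    ------
    ValueError
        If ``baseline_cc`` is below the floor (default 1 cc): percent
        change is not meaningfully defined there.
    """
    if baseline_cc < baseline_floor_cc:
        raise ValueError(
            f"baseline volume {baseline_cc:g} cc is below the {baseline_floor_cc:g} cc "
            "floor; percent change is undefined for sub-detection-limit lesions"
        )
    if followup_cc < 0:
        raise ValueError("followup volume must be >= 0")
    abs_diff = followup_cc - baseline_cc
    pct_diff = 100.0 * abs_diff / baseline_cc
    positive = (abs_diff >= criteria.abs_threshold_cc) and (pct_diff >= criteria.pct_threshold)
    return SerialComparison(
        baseline_cc=float(baseline_cc),
        followup_cc=float(followup_cc),
        abs_diff_cc=float(abs_diff),
        pct_diff=float(pct_diff),
        he_positive=bool(positive),
        criteria=criteria,
    )


def classify_cohort(
    rows: Iterable[Sequence],
    criteria: ExpansionCriteria = ExpansionCriteria(),
) -> list[tuple[str, SerialComparison]]:
    """Classify every (id, baseline_cc, followup_cc) row of a cohort.

    Deterministic; duplicate ids or malformed rows raise
    :class:`~hemovol.errors.CohortError` naming the offender. Summary
    counts are logged at INFO.
    """
    seen: set[str] = set()
    out: list[tuple[str, SerialComparison]] = []
    for row in rows:
        try:
            rid, baseline, followup = row
            rid = str(rid)
            baseline = float(baseline)
            followup = float(followup)
        except (TypeError, ValueError) as exc:
            raise CohortError(f"malformed cohort row {row!r}: {exc}") from exc
        if rid in seen:
            raise CohortError(f"duplicate cohort id {rid!r}")
        seen.add(rid)
        try:
            out.append((rid, compare_serial(baseline, followup, criteria)))
        except ValueError as exc:
            raise CohortError(f"row {rid!r}: {exc}") from exc
    n_pos = sum(1 for _, c in out if c.he_positive)
    logger.info("classified %d pairs: %d HE-positive, %d HE-negative", len(out), n_pos, len(out) - n_pos)
    return out
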
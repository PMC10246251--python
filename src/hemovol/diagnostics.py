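"""Diagnostic accuracy of a binary test against a reference standard.

Given paired reference/test calls (here: radiologist vs automated
hematoma-expansion detection) this module builds the 2x2 confusion table
and reports sensitivity, specificity, PPV, NPV and accuracy as percentages
with exact Clopper-Pearson 95% confidence intervals, and the positive and
negative likelihood ratios with log-method (Simel) intervals:

    LR+ = sens / (1 - spec),     LR- = (1 - sens) / spec
    CI: exp( ln LR +/- z * SE ),  SE(ln LR+) = sqrt(1/tp - 1/(tp+fn)
                                               + 1/fp - 1/(fp+tn))

Clopper-Pearson bounds come from beta-distribution quantiles; they are
exact (conservative), with the conventional closures ci_low = 0 at k = 0
and ci_high = 100 at k = n. Rounding happens only at report formatting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError

__all__ = [
    "ConfusionTable",
    "EstimateWithCI",
    "DiagnosticSummary",
    "build_confusion",
    "clopper_pearson",
    "likelihood_ratios",
    "summarize",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts; reference standard on rows, test under evaluation on columns."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("confusion table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EstimateWithCI:
    """A point estimate with its 95% confidence bounds.

    Proportions are on the 0-100 percent scale; likelihood ratios are
    unitless ratios.
    """

    point: float
    ci_low: float
    ci_high: float
    method: str

    def __str__(self) -> str:
        return f"{self.point:.2f} (CI: {self.ci_low:.2f}-{self.ci_high:.2f})"


@dataclass(frozen=True)
class DiagnosticSummary:
    """The seven test-performance metrics, each with a 95% CI.

    ``lr_pos``/``lr_neg`` are ``None`` when undefined for the table's cell
    pattern; the reason is then recorded in ``errors``.
    """

    table: ConfusionTable
    sensitivity: EstimateWithCI
    specificity: EstimateWithCI
    ppv: EstimateWithCI
    npv: EstimateWithCI
    accuracy: EstimateWithCI
    lr_pos: EstimateWithCI | None
    lr_neg: EstimateWithCI | None
    errors: dict[str, str]

    def to_dict(self) -> dict:
        def est(e: EstimateWithCI | None) -> dict | None:
            if e is None:
                return None
            return {"point": e.point, "ci_low": e.ci_low, "ci_high": e.ci_high, "method": e.method}

        return {
            "table": {"tp": self.table.tp, "fp": self.table.fp, "fn": self.table.fn, "tn": self.table.tn, "n": self.table.n},
            "sensitivity": est(self.sensitivity),
            "specificity": est(self.specificity),
            "ppv": est(self.ppv),
            "npv": est(self.npv),
            "accuracy": est(self.accuracy),
            "lr_pos": est(self.lr_pos),
            "lr_neg": est(self.lr_neg),
            "errors": self.errors,
        }


def build_confusion(pairs: Iterable[Sequence]) -> ConfusionTable:
    """Tally (reference_label, test_label) pairs into a 2x2 table.

    Labels must be binary; accepted truthy/falsy encodings are bool, 0/1,
    and the strings ``"positive"``/``"negative"`` (case-insensitive).
    """

    def as_bool(label, which: str) -> bool:
        if isinstance(label, (bool, np.bool_)):
            return bool(label)
        if isinstance(label, (int, np.integer)) and label in (0, 1):
            return bool(label)
        if isinstance(label, str):
            s = label.strip().lower()
            if s in ("positive", "pos", "1", "true", "growth"):
                return True
            if s in ("negative", "neg", "0", "false", "non-growth", "nongrowth"):
                return False
        raise ValueError(f"non-binary {which} label {label!r}")

    tp = fp = fn = tn = 0
    for pair in pairs:
        ref, test = pair
        r = as_bool(ref, "reference")
        t = as_bool(test, "test")
        if r and t:
            tp += 1
        elif r and not t:
            fn += 1
        elif not r and t:
            fp += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> EstimateWithCI:
    """Exact binomial proportion CI, on the percent scale.

    ``ci_low = 100 * Beta(alpha/2; k, n-k+1)`` quantile and
    ``ci_high = 100 * Beta(1-alpha/2; k+1, n-k)``, with the conventional
    closures at k = 0 and k = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, {n}], got {k}")
    point = 100.0 * k / n
    low = 0.0 if k == 0 else 100.0 * float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 100.0 if k == n else 100.0 * float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return EstimateWithCI(point=point, ci_low=low, ci_high=high, method="clopper_pearson")


def likelihood_ratios(
    table: ConfusionTable, alpha: float = 0.05
) -> tuple[EstimateWithCI, EstimateWithCI]:
    """Positive and negative likelihood ratios with log-method 95% CIs.

    Raises :class:`~hemovol.errors.UndefinedStatisticError` naming the
    offending cell when a zero cell makes a ratio undefined; no continuity
    correction is ever applied silently.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    if tp + fn == 0:
        raise UndefinedStatisticError("likelihood ratios undefined: tp + fn = 0 (no reference positives)")
    if fp + tn == 0:
        raise UndefinedStatisticError("likelihood ratios undefined: fp + tn = 0 (no reference negatives)")
    if fp == 0:
        raise UndefinedStatisticError("LR+ undefined: fp = 0 (false-positive rate is zero)")
    if tn == 0:
        raise UndefinedStatisticError("LR- undefined: tn = 0 (specificity is zero)")
    if tp == 0:
        raise UndefinedStatisticError("LR+ undefined: tp = 0 (sensitivity is zero)")
    if fn == 0:
        raise UndefinedStatisticError("LR- undefined: fn = 0 (no false negatives)")

    z = float(stats.norm.ppf(1 - alpha / 2))
    sens = tp / (tp + fn)
    fpr = fp / (fp + tn)
    lr_pos = sens / fpr
    se_pos = np.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
    pos = EstimateWithCI(
        point=float(lr_pos),
        ci_low=float(np.exp(np.log(lr_pos) - z * se_pos)),
        ci_high=float(np.exp(np.log(lr_pos) + z * se_pos)),
        method="log_lr",
    )

    fnr = fn / (tp + fn)
    spec = tn / (fp + tn)
    lr_neg = fnr / spec
    se_neg = np.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
    neg = EstimateWithCI(
        point=float(lr_neg),
        ci_low=float(np.exp(np.log(lr_neg) - z * se_neg)),
        ci_high=float(np.exp(np.log(lr_neg) + z * se_neg)),
        method="log_lr",
    )
    return pos, neg


def summarize(table: ConfusionTable, alpha: float = 0.05) -> DiagnosticSummary:
    """All seven metrics with 95% CIs for one confusion table.

    Proportion metrics use Clopper-Pearson on their natural numerator /
    denominator (accuracy on ``tp + tn`` of ``n``). An undefined
    proportion (zero denominator) or likelihood ratio is surfaced
    per-metric in ``errors`` while the rest are still reported.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    errors: dict[str, str] = {}

    def prop(k: int, n: int, name: str) -> EstimateWithCI | None:
        if n == 0:
            errors[name] = f"{name} undefined: denominator is zero"
            return None
        return clopper_pearson(k, n, alpha)

    sens = prop(tp, tp + fn, "sensitivity")
    spec = prop(tn, tn + fp, "specificity")
    ppv = prop(tp, tp + fp, "ppv")
    npv = prop(tn, tn + fn, "npv")
    acc = clopper_pearson(tp + tn, table.n, alpha)

    lr_pos: EstimateWithCI | None
    lr_neg: EstimateWithCI | None
    try:
        lr_pos, lr_neg = likelihood_ratios(table, alpha)
    except UndefinedStatisticError as exc:
        lr_pos = lr_neg = None
        errors["likelihood_ratios"] = str(exc)

    return DiagnosticSummary(
        table=table,
        sensitivity=sens,  # type: ignore[arg-type]
        specificity=spec,  # type: ignore[arg-type]
        ppv=ppv,  # type: ignore[arg-type]
        npv=npv,  # type: ignore[arg-type]
        accuracy=acc,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        errors=errors,
    )
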
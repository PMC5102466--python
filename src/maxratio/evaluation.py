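"""Rater consensus, diagnostic performance, agreement statistics, efficiency.

Conventions
-----------
* Reported metric values are rounded half-up (so 13 639/13 824 prints as
  0.987); the exact rational values are used internally.
* Metrics with a zero denominator are undefined and reported as ``None``.
* Cohen's kappa comes with a large-sample 95% confidence interval; Fleiss'
  kappa with a normal-approximation p-value for H0: kappa = 0.
* Agreement bands follow the conventional ladder: slight (0-0.20), fair
  (0.21-0.40), moderate (0.41-0.60), substantial (0.61-0.80), almost
  perfect (0.81-1); band edges are inclusive at the upper printed decimal,
  so kappa = 0.20 is slight and 0.205 is fair.  Negative kappa is reported
  as "poor (below slight)".
* Amplification efficiency from a dilution-series regression slope s (cycles
  per log10 template unit) is E = 10^(-1/s) - 1, i.e. E = 1 for perfect
  per-cycle doubling (s = -1/log10 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.stats import linregress, norm

__all__ = [
    "ConfusionTable",
    "PerformanceMetrics",
    "AgreementResult",
    "StandardCurveFit",
    "round_half_up",
    "consensus_call",
    "confusion",
    "metrics",
    "cohen_kappa",
    "fleiss_kappa",
    "agreement_category",
    "fit_standard_curve",
]


def round_half_up(value: float, decimals: int = 3) -> float:
    """Round the shortest decimal representation of ``value`` half-up."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts with the reference classification as truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Diagnostic statistics; ``None`` marks an undefined (0/0) ratio."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def _ratio(num: int, den: int) -> Fraction | None:
    return None if den == 0 else Fraction(num, den)


def exact_metrics(table: ConfusionTable) -> dict[str, Fraction | None]:
    """The five diagnostic ratios in exact rational arithmetic."""
    t = table
    return {
        "accuracy": _ratio(t.tp + t.tn, t.total),
        "sensitivity": _ratio(t.tp, t.tp + t.fn),
        "specificity": _ratio(t.tn, t.tn + t.fp),
        "ppv": _ratio(t.tp, t.tp + t.fp),
        "npv": _ratio(t.tn, t.tn + t.fn),
    }


def metrics(table: ConfusionTable, decimals: int = 3) -> PerformanceMetrics:
    """Accuracy, sensitivity, specificity, PPV and NPV, rounded half-up."""
    exact = exact_metrics(table)
    rounded = {
        k: None if v is None else round_half_up(float(v), decimals)
        for k, v in exact.items()
    }
    return PerformanceMetrics(**rounded)


def consensus_call(calls: Sequence[int], tie_positive: bool = True) -> int:
    """Median (majority) of binary rater calls.

    An even split has no majority; the default policy resolves it as
    positive — the screening posture of ruling cases in — and emits a
    warning.  Set ``tie_positive=False`` to resolve ties as negative.
    """
    if len(calls) == 0:
        raise ValueError("no rater calls")
    if any(c not in (0, 1) for c in calls):
        raise ValueError("rater calls must be binary")
    pos = sum(calls)
    neg = len(calls) - pos
    if pos > neg:
        return 1
    if pos < neg:
        return 0
    warnings.warn(
        f"tied rater calls ({pos} vs {neg}); resolving as "
        + ("positive" if tie_positive else "negative"),
        stacklevel=2,
    )
    return 1 if tie_positive else 0


def confusion(calls: Sequence[int], reference: Sequence[int]) -> ConfusionTable:
    """Cross-tabulate binary calls against a binary reference truth."""
    calls = np.asarray(calls, dtype=int)
    reference = np.asarray(reference, dtype=int)
    if calls.shape != reference.shape:
        raise ValueError(
            f"length mismatch: {calls.size} calls vs {reference.size} reference"
        )
    return ConfusionTable(
        tp=int(np.sum((calls == 1) & (reference == 1))),
        fp=int(np.sum((calls == 1) & (reference == 0))),
        fn=int(np.sum((calls == 0) & (reference == 1))),
        tn=int(np.sum((calls == 0) & (reference == 0))),
    )


@dataclass
class AgreementResult:
    """Chance-corrected agreement; CI for Cohen, p-value for Fleiss."""

    kappa: float | None
    category: str | None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None


def agreement_category(kappa: float) -> str:
    """Verbal band for a kappa value (upper band edges inclusive)."""
    if kappa > 1:
        raise ValueError(f"kappa cannot exceed 1, got {kappa}")
    if kappa < 0:
        return "poor (below slight)"
    for edge, name in [
        (0.20, "slight"),
        (0.40, "fair"),
        (0.60, "moderate"),
        (0.80, "substantial"),
    ]:
        if kappa <= edge:
            return name
    return "almost perfect"


def cohen_kappa(
    calls_a: Sequence[int], calls_b: Sequence[int], ci_level: float = 0.95
) -> AgreementResult:
    """Unweighted Cohen's kappa between two raters with a large-sample CI.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product chance agreement;
    the CI uses the simple large-sample standard error
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)) and normal quantiles.  Undefined
    (kappa None) when p_e = 1, i.e. both raters are constant.
    """
    a = np.asarray(calls_a, dtype=int)
    b = np.asarray(calls_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("call sequences must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired calls")
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for cat in (0, 1):
        p_e += float(np.mean(a == cat)) * float(np.mean(b == cat))
    if p_e >= 1.0:
        return AgreementResult(kappa=None, category=None)
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    zq = float(norm.ppf(0.5 + ci_level / 2.0))
    return AgreementResult(
        kappa=kappa,
        category=agreement_category(kappa),
        ci_low=kappa - zq * se,
        ci_high=min(kappa + zq * se, 1.0),
    )


def fleiss_kappa(calls: np.ndarray) -> AgreementResult:
    """Fleiss' kappa for an items x raters matrix of binary calls.

    Every item must be rated by every rater.  The p-value tests H0:
    kappa = 0 with the classic large-sample standard error.  Note the m = 2
    case is the Fleiss formula at two raters, which differs in general from
    Cohen's kappa (per-rater marginals are pooled).  Undefined when all
    calls fall in a single category.
    """
    mat = np.asarray(calls, dtype=int)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need an items x raters matrix with >= 2 raters")
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("calls must be binary")
    n_items, m = mat.shape
    # counts per item per category
    pos = mat.sum(axis=1)
    counts = np.stack([m - pos, pos], axis=1)  # columns: category 0, 1
    p_j = counts.sum(axis=0) / (n_items * m)
    if p_j.max() == 1.0:
        return AgreementResult(kappa=None, category=None)
    p_i = ((counts**2).sum(axis=1) - m) / (m * (m - 1))
    p_bar = float(p_i.mean())
    p_e = float((p_j**2).sum())
    kappa = (p_bar - p_e) / (1.0 - p_e)
    # Large-sample SE under H0 (Fleiss 1971)
    q_j = 1.0 - p_j
    s = float((p_j * q_j).sum())
    se0 = np.sqrt(2.0 / (n_items * m * (m - 1))) * np.sqrt(
        s**2 - float((p_j * q_j * (q_j - p_j)).sum())
    ) / s
    z = kappa / se0
    p_value = float(2.0 * norm.sf(abs(z)))
    return AgreementResult(
        kappa=float(kappa),
        category=agreement_category(float(kappa)),
        p_value=p_value,
    )


@dataclass
class StandardCurveFit:
    """Dilution-series regression and derived amplification efficiency."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float | None


def fit_standard_curve(
    log10_quantity: Sequence[float], cycles: Sequence[float]
) -> StandardCurveFit:
    """Ordinary least-squares standard curve and efficiency estimate.

    ``log10_quantity`` is the log10 relative template quantity (e.g. the
    log10 reciprocal dilution factor); ``cycles`` the matching Cq or FCN
    values.  E = 10^(-1/s) - 1; undefined when the slope is zero.
    """
    x = np.asarray(log10_quantity, dtype=float)
    y = np.asarray(cycles, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.unique(x).size < 2:
        raise ValueError("all log10 quantities are equal; cannot fit a slope")
    fit = linregress(x, y)
    slope = float(fit.slope)
    efficiency = None if slope == 0 else float(10.0 ** (-1.0 / slope) - 1.0)
    return StandardCurveFit(
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=efficiency,
    )
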
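"""Learning and applying the two-cutoff MR filter.

Training reactions (each an (MR, FCN) pair with a consensus label) define
two regions of the FCN-MR plane, split at the *watershed*: the lowest FCN
among the positive training reactions.  Early-cycle fluorescence transients
produce high MR at low FCN without amplification, so the early region
(FCN < watershed) gets an inflated cut-off — the maximum training MR seen
there, scaled by 1.5 (the moderate-outlier whisker multiplier).  The late
region gets a cut-off learned without operator assumptions: a two-component
Gaussian mixture is fitted to the training MR values by EM, candidate
cut-offs bracketing the gap between the two component means are derived,
and the candidate minimizing misclassifications (FP + FN) against the
training labels is selected — ties prefer the mid-point.

Classification of a query reaction then only asks on which side of the
watershed its FCN falls and whether its MR reaches the applicable cut-off
(boundary inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import norm

from .core import MaxRatioResult

__all__ = [
    "DegenerateDataError",
    "TrainingError",
    "MixtureFit",
    "CutoffCandidates",
    "CutoffModel",
    "LabelledResult",
    "split_train_query",
    "fit_em_mixture",
    "derive_cutoff_candidates",
    "select_cutoff",
    "train_cutoff_model",
    "classify",
    "save_model",
    "load_model",
]

DEFAULT_MULTIPLIER = 1.5
DEFAULT_Z = 3.0


class DegenerateDataError(ValueError):
    """The MR sample cannot support a two-component mixture fit."""


class TrainingError(ValueError):
    """The labelled training set cannot define the two-cutoff model."""


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian mixture (means ascending)."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    loglik: float
    n_iter: int
    converged: bool


@dataclass(frozen=True)
class CutoffCandidates:
    lower: float
    upper: float

    @property
    def mid(self) -> float:
        return (self.lower + self.upper) / 2.0

    def __post_init__(self) -> None:
        if not (self.lower <= self.upper):
            raise ValueError("candidate cutoffs out of order")

    def as_dict(self) -> dict[str, float]:
        return {"lower": self.lower, "mid": self.mid, "upper": self.upper}


@dataclass
class CutoffModel:
    """Trained two-cutoff classifier in the FCN-MR plane."""

    fcn_watershed: float
    early_cutoff: float
    late_cutoff: float
    multiplier: float
    z: float
    candidates: CutoffCandidates
    selection: str  # which candidate became the late cutoff


@dataclass(frozen=True)
class LabelledResult:
    """An (MR, FCN) result paired with its binary consensus label."""

    result: MaxRatioResult
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def split_train_query(
    dataset: Sequence, fraction: float = 0.122, seed: int | None = None
) -> tuple[list, list]:
    """Random split without replacement into (training, query) subsets.

    Training size is round(fraction * n) (half-up); the split is exhaustive,
    disjoint and reproducible for a fixed seed.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    n_train = int(math.floor(fraction * n + 0.5))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"fraction {fraction} leaves an empty training or query set (n={n})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = set(order[:n_train].tolist())
    training = [dataset[i] for i in sorted(train_idx)]
    query = [dataset[i] for i in range(n) if i not in train_idx]
    return training, query


def fit_em_mixture(
    values: Iterable[float],
    k: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
) -> MixtureFit:
    """Fit a two-component univariate Gaussian mixture by EM.

    Deterministic quantile initialization: component means at the 25th and
    75th percentiles, both SDs at the pooled sample SD, equal weights.
    Iterates E/M steps until the relative log-likelihood change drops below
    ``tol``.  ``seed`` is accepted for interface symmetry; the fit itself is
    deterministic.
    """
    if k != 2:
        raise NotImplementedError("only k=2 is supported")
    x = np.asarray(list(values), dtype=float)
    if x.size < 10:
        raise ValueError(f"need >= 10 values for a mixture fit, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite MR value")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all MR values are identical")

    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    if mu[0] == mu[1]:
        mu = np.array([x.min(), x.max()], dtype=float)
    pooled = x.std(ddof=0)
    sd_floor = max(1e-12, 1e-9 * pooled)
    sd = np.array([pooled, pooled], dtype=float)
    w = np.array([0.5, 0.5])

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step: responsibilities in log space
        log_comp = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None], sd[:, None])
        log_total = logsumexp(log_comp, axis=0)
        ll = float(log_total.sum())
        resp = np.exp(log_comp - log_total[None, :])
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        mu = (resp * x[None, :]).sum(axis=1) / nk
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
        sd = np.maximum(np.sqrt(var), sd_floor)
        w = nk / x.size
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(ll):
            converged = True
            break
        prev_ll = ll

    order = np.argsort(mu)
    return MixtureFit(
        means=(float(mu[order[0]]), float(mu[order[1]])),
        sds=(float(sd[order[0]]), float(sd[order[1]])),
        weights=(float(w[order[0]]), float(w[order[1]])),
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
    )


def _posterior_crossing(fit: MixtureFit) -> float:
    """MR value where the two components are equally probable a posteriori."""
    (m1, m2), (s1, s2), (w1, w2) = fit.means, fit.sds, fit.weights

    def logdiff(t: float) -> float:
        return (math.log(w1) + norm.logpdf(t, m1, s1)) - (
            math.log(w2) + norm.logpdf(t, m2, s2)
        )

    a, b = m1, m2
    try:
        fa, fb = logdiff(a), logdiff(b)
        if fa == 0:
            return a
        if fb == 0:
            return b
        if fa * fb < 0:
            return float(brentq(logdiff, a, b))
    except (ValueError, OverflowError):
        pass
    # no sign change between the means (heavy overlap): dense scan fallback
    grid = np.linspace(a, b, 20001)
    vals = np.array([abs(logdiff(t)) for t in grid])
    return float(grid[int(np.argmin(vals))])


def derive_cutoff_candidates(fit: MixtureFit, z: float = DEFAULT_Z) -> CutoffCandidates:
    """Candidate late cut-offs bracketing the gap between the two components.

    lower = mu_low + z*sd_low, upper = mu_high - z*sd_high.  If the
    components overlap so much that lower > upper, both collapse to the
    equal-posterior crossing point.  The mid candidate is always their
    midpoint.
    """
    m1, m2 = fit.means
    s1, s2 = fit.sds
    if not (
        math.isfinite(m1) and math.isfinite(m2) and math.isfinite(s1) and math.isfinite(s2)
    ):
        raise ValueError("non-finite mixture parameters")
    if not m1 < m2:
        raise ValueError("component means must be strictly ordered")
    lower = m1 + z * s1
    upper = m2 - z * s2
    if lower > upper:
        crossing = _posterior_crossing(fit)
        lower = upper = crossing
    return CutoffCandidates(lower=lower, upper=upper)


def _count_errors(
    cutoff: float, late: Sequence[LabelledResult]
) -> tuple[int, int]:
    fp = sum(1 for r in late if r.label == 0 and r.result.mr >= cutoff)
    fn = sum(1 for r in late if r.label == 1 and r.result.mr < cutoff)
    return fp, fn


def select_cutoff(
    candidates: CutoffCandidates,
    training: Sequence[LabelledResult],
    watershed: float,
) -> str:
    """Pick the candidate minimizing FP + FN on the late training region.

    Evaluated on training reactions with FCN >= watershed; ties prefer
    ``mid``, then ``lower``.
    """
    late = [r for r in training if r.result.fcn >= watershed]
    if not late:
        raise TrainingError("no training reactions at or above the watershed")
    tie_order = {"mid": 0, "lower": 1, "upper": 2}
    best = None
    for name, value in candidates.as_dict().items():
        fp, fn = _count_errors(value, late)
        key = (fp + fn, tie_order[name])
        if best is None or key < best[0]:
            best = (key, name)
    return best[1]


def train_cutoff_model(
    training: Sequence[LabelledResult],
    multiplier: float = DEFAULT_MULTIPLIER,
    z: float = DEFAULT_Z,
    em_tol: float = 1e-8,
    em_max_iter: int = 1000,
    seed: int | None = None,
) -> CutoffModel:
    """Learn the full two-cutoff model from a labelled training set.

    watershed  = lowest FCN among training positives;
    early_cutoff = multiplier x (max training MR with FCN < watershed),
    defaulting to the late cutoff when no reaction lies below the watershed;
    late_cutoff  = EM-derived candidate selected on the late region.
    """
    positives = [r for r in training if r.label == 1]
    if not positives:
        raise TrainingError("training set contains no positive reactions")
    watershed = min(r.result.fcn for r in positives)
    late = [r for r in training if r.result.fcn >= watershed]
    early = [r for r in training if r.result.fcn < watershed]
    fit = fit_em_mixture(
        [r.result.mr for r in late], tol=em_tol, max_iter=em_max_iter, seed=seed
    )
    candidates = derive_cutoff_candidates(fit, z=z)
    selection = select_cutoff(candidates, training, watershed)
    late_cutoff = candidates.as_dict()[selection]
    if early:
        early_cutoff = multiplier * max(r.result.mr for r in early)
    else:
        early_cutoff = late_cutoff
    return CutoffModel(
        fcn_watershed=watershed,
        early_cutoff=early_cutoff,
        late_cutoff=late_cutoff,
        multiplier=multiplier,
        z=z,
        candidates=candidates,
        selection=selection,
    )


def classify(result: MaxRatioResult, model: CutoffModel) -> int:
    """Binary call for one reaction: 1 = positive, 0 = negative.

    Early region (FCN strictly below the watershed) uses the inflated early
    cutoff; the watershed itself — a positive's FCN — and everything above
    use the late cutoff.  The boundary is inclusive: MR equal to the cutoff
    is positive.
    """
    cutoff = (
        model.early_cutoff if result.fcn < model.fcn_watershed else model.late_cutoff
    )
    return 1 if result.mr >= cutoff else 0


_MODEL_FIELDS = [
    "fcn_watershed",
    "early_cutoff",
    "late_cutoff",
    "multiplier",
    "z",
    "candidate_lower",
    "candidate_mid",
    "candidate_upper",
    "selection",
]


def save_model(model: CutoffModel, path: str | Path) -> None:
    """Serialize a model as a flat, diffable key = value text file."""
    lines = {
        "fcn_watershed": repr(model.fcn_watershed),
        "early_cutoff": repr(model.early_cutoff),
        "late_cutoff": repr(model.late_cutoff),
        "multiplier": repr(model.multiplier),
        "z": repr(model.z),
        "candidate_lower": repr(model.candidates.lower),
        "candidate_mid": repr(model.candidates.mid),
        "candidate_upper": repr(model.candidates.upper),
        "selection": model.selection,
    }
    with open(path, "wt", encoding="utf-8") as fh:
        for key in _MODEL_FIELDS:
            fh.write(f"{key} = {lines[key]}\n")


def load_model(path: str | Path) -> CutoffModel:
    entries: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            entries[key.strip()] = value.strip()
    missing = [k for k in _MODEL_FIELDS if k not in entries]
    if missing:
        raise ValueError(f"model file {path} is missing fields: {missing}")
    return CutoffModel(
        fcn_watershed=float(entries["fcn_watershed"]),
        early_cutoff=float(entries["early_cutoff"]),
        late_cutoff=float(entries["late_cutoff"]),
        multiplier=float(entries["multiplier"]),
        z=float(entries["z"]),
        candidates=CutoffCandidates(
            lower=float(entries["candidate_lower"]),
            upper=float(entries["candidate_upper"]),
        ),
        selection=entries["selection"],
    )
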
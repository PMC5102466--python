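"""Seeded generator of synthetic amplification curves and labelled plates.

Real high-throughput plates show a small vocabulary of recurring profile
shapes, and the generator emulates exactly those classes:

``clear_positive``
    A full sigmoid: baseline, exponential rise, plateau.
``weak_positive``
    A genuine but weak sigmoid whose plateau is only a few times the CT
    threshold — easily under-called by eye and by fixed thresholds.
``slow_riser``
    A slow, non-sigmoid drift upward that can creep across the CT
    threshold late in the run without genuine exponential amplification;
    the canonical CT false positive.
``transient_negative``
    A flat curve with a spurious fluorescence spike in the earliest
    cycles, yielding a high MR at a low FCN (the early-transient artefact
    the watershed cutoff exists for).
``flat_negative``
    Baseline plus noise only.

Curves are built as baseline + linear drift + a four-parameter logistic +
an optional Gaussian transient bump + Gaussian noise, clamped to stay
strictly positive; every draw is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .plate_io import AmplificationCurve

__all__ = [
    "PROFILE_CLASSES",
    "POSITIVE_CLASSES",
    "CurveSpec",
    "SyntheticPlate",
    "generate_curve",
    "generate_plate",
]

PROFILE_CLASSES = (
    "clear_positive",
    "weak_positive",
    "slow_riser",
    "transient_negative",
    "flat_negative",
)
#: Classes whose truth label is positive.
POSITIVE_CLASSES = frozenset({"clear_positive", "weak_positive"})

#: Fraction of clamped cycles above which a spec is rejected as unrealistic.
MAX_CLAMP_FRACTION = 0.10

DEFAULT_NOISE_SD = 0.005
DEFAULT_N_CYCLES = 45


@dataclass
class CurveSpec:
    """Parameters of one synthetic amplification curve.

    rn(c) = b0 + d*c + A / (1 + exp(-k (c - m))) + transient bump + noise
    """

    profile_class: str
    seed: int
    n_cycles: int = DEFAULT_N_CYCLES
    b0: float = 1.0  # baseline fluorescence level, > 0
    drift: float = 0.0  # linear drift per cycle
    amplitude: float = 0.0  # logistic amplitude A, >= 0
    midpoint: float = 25.0  # logistic midpoint m, cycles
    steepness: float = 0.8  # logistic rate k per cycle, > 0
    noise_sd: float = DEFAULT_NOISE_SD
    transient: tuple[float, float, float] | None = None  # (position, height, width)

    def __post_init__(self) -> None:
        if self.profile_class not in PROFILE_CLASSES:
            raise ValueError(f"unknown profile class {self.profile_class!r}")
        if self.b0 <= 0 or self.amplitude < 0 or self.steepness <= 0:
            raise ValueError("b0 must be > 0, amplitude >= 0, steepness > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cycles < 5:
            raise ValueError("need at least 5 cycles")


@dataclass
class SyntheticPlate:
    """A labelled set of synthetic curves with its generating bookkeeping."""

    curves: list[AmplificationCurve]
    truth: dict[str, int]  # well_id -> binary label
    classes: dict[str, str]  # well_id -> profile class
    class_mix: dict[str, int]
    master_seed: int
    plate_id: str = "SIM1"


def generate_curve(spec: CurveSpec, plate_id: str = "SIM1", well_id: str = "W0001",
                   target: str = "T1", sample_id: str = "S1") -> AmplificationCurve:
    """Deterministically generate one curve from its spec.

    Values are clamped at b0/100 to keep the fluorescence strictly positive;
    a spec that forces clamping on 10% or more of the cycles is rejected.
    """
    rng = np.random.default_rng(spec.seed)
    c = np.arange(1, spec.n_cycles + 1, dtype=float)
    rn = spec.b0 + spec.drift * c
    rn = rn + spec.amplitude / (1.0 + np.exp(-spec.steepness * (c - spec.midpoint)))
    if spec.transient is not None:
        pos, height, width = spec.transient
        if width <= 0:
            raise ValueError("transient width must be positive")
        rn = rn + height * np.exp(-0.5 * ((c - pos) / width) ** 2)
    if spec.noise_sd > 0:
        rn = rn + rng.normal(0.0, spec.noise_sd, size=rn.size)
    floor = spec.b0 / 100.0
    clamped = rn < floor
    if clamped.mean() >= MAX_CLAMP_FRACTION:
        raise ValueError(
            f"spec forces clamping on {int(clamped.sum())}/{rn.size} cycles;"
            " parameters are unrealistic"
        )
    rn = np.maximum(rn, floor)
    return AmplificationCurve(plate_id, well_id, target, sample_id, rn)


def _draw_spec(
    profile_class: str, rng: np.random.Generator, n_cycles: int, noise_sd: float
) -> CurveSpec:
    """Class-conditional parameter draw (uniform ranges, documented defaults)."""
    seed = int(rng.integers(0, 2**31 - 1))
    b0 = float(rng.uniform(0.9, 1.1))
    drift = float(rng.uniform(0.0, 0.002))
    common = dict(n_cycles=n_cycles, b0=b0, drift=drift, noise_sd=noise_sd, seed=seed)
    if profile_class == "clear_positive":
        return CurveSpec(
            profile_class,
            amplitude=float(rng.uniform(2.0, 4.0)),
            steepness=float(rng.uniform(0.6, 1.0)),
            midpoint=float(rng.uniform(18.0, 35.0)),
            **common,
        )
    if profile_class == "weak_positive":
        # plateau only ~3x the 0.2-unit CT threshold
        return CurveSpec(
            profile_class,
            amplitude=float(rng.uniform(0.55, 0.8)),
            steepness=float(rng.uniform(0.5, 0.9)),
            midpoint=float(rng.uniform(28.0, 38.0)),
            **common,
        )
    if profile_class == "slow_riser":
        # quasi-linear creep: midpoint beyond the run, tiny rate constant
        return CurveSpec(
            profile_class,
            amplitude=float(rng.uniform(0.8, 1.4)),
            steepness=float(rng.uniform(0.045, 0.075)),
            midpoint=float(rng.uniform(46.0, 54.0)),
            **common,
        )
    if profile_class == "transient_negative":
        return CurveSpec(
            profile_class,
            amplitude=0.0,
            transient=(
                float(rng.uniform(2.0, 4.0)),
                float(rng.uniform(0.03, 0.08)),
                float(rng.uniform(0.6, 1.2)),
            ),
            **common,
        )
    if profile_class == "flat_negative":
        return CurveSpec(profile_class, amplitude=0.0, **common)
    raise ValueError(f"unknown profile class {profile_class!r}")


def generate_plate(
    class_mix: Mapping[str, int],
    master_seed: int,
    n_cycles: int = DEFAULT_N_CYCLES,
    noise_sd: float = DEFAULT_NOISE_SD,
    plate_id: str = "SIM1",
) -> SyntheticPlate:
    """Generate a labelled plate from per-class well counts.

    Wells are named W0001, W0002, ... in class order (classes iterated in
    the canonical order of :data:`PROFILE_CLASSES`); every draw flows from
    ``master_seed``, so identical seeds give identical plates.
    """
    unknown = set(class_mix) - set(PROFILE_CLASSES)
    if unknown:
        raise ValueError(f"unknown profile classes: {sorted(unknown)}")
    total = sum(int(v) for v in class_mix.values())
    if total < 1:
        raise ValueError("class mix is empty")
    rng = np.random.default_rng(master_seed)
    curves: list[AmplificationCurve] = []
    truth: dict[str, int] = {}
    classes: dict[str, str] = {}
    idx = 0
    for profile_class in PROFILE_CLASSES:
        for _ in range(int(class_mix.get(profile_class, 0))):
            idx += 1
            well_id = f"W{idx:04d}"
            spec = _draw_spec(profile_class, rng, n_cycles, noise_sd)
            curves.append(
                generate_curve(
                    spec,
                    plate_id=plate_id,
                    well_id=well_id,
                    target="T1",
                    sample_id=f"S{idx:04d}",
                )
            )
            truth[well_id] = 1 if profile_class in POSITIVE_CLASSES else 0
            classes[well_id] = profile_class
    return SyntheticPlate(
        curves=curves,
        truth=truth,
        classes=classes,
        class_mix={k: int(v) for k, v in class_mix.items() if int(v)},
        master_seed=master_seed,
        plate_id=plate_id,
    )
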
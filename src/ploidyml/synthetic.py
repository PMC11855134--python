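"""Synthetic oryzalin dose-response outcome generator.

Emulates a 26-treatment tetraploid-induction experiment on nodal explants:
concentration x exposure treatments, 4 replicates x 4 explants each, with
ploidy outcomes (diploid / mixoploid / tetraploid) drawn from an analytic
three-class dose-response model.

Model structure
---------------
A latent "escape-from-diploid" score

    s(C, t) = b0 + b1 * ln(1 + C) + b2 * t + b3 * ln(1 + C) * t

drives the diploid probability P(diploid) = 1 / (1 + exp(s / tau)): at low
dose every cell stays diploid, and escape rises with dose, time and their
interaction.  Conversion to a uniform tetraploid requires both enough dose
and enough exposure near an optimum; the tetraploid share of the non-diploid
mass is a unimodal bump

    B(C, t) = exp(-[(|C - Cp| / wC)^p + (|t - tp| / wt)^p])

peaking at (Cp, tp) = (33 µM, 18 h), with a stretched exponent p = 0.5
(fast decay near the peak, heavy tails far away) and a much shorter width on
the short-exposure side: brief pulses of even extreme doses convert only
part of the meristem and yield chimeric mixoploids.  Mixoploid takes the
remainder, with a floor fraction of converted explants staying chimeric
even at the optimum:

    P(tetraploid) = (1 - P(diploid)) * (1 - floor) * B(C, t)
    P(mixoploid)  = 1 - P(diploid) - P(tetraploid)

The probabilities sum to one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral

import numpy as np
from scipy.special import expit

from .errors import DataError, DomainError
from .preprocess import CLASSES, PloidyDataset

CONCENTRATION_MAX = 100.0  # µM
EXPOSURE_MAX = 48.0  # h


@dataclass(frozen=True)
class Treatment:
    """One (oryzalin concentration µM, exposure time h) condition."""

    concentration: float
    exposure: float

    def __post_init__(self):
        c, t = float(self.concentration), float(self.exposure)
        if not (0.0 <= c <= CONCENTRATION_MAX) or not np.isfinite(c):
            raise DomainError(f"concentration {c} outside [0, {CONCENTRATION_MAX}] µM")
        if not (0.0 <= t <= EXPOSURE_MAX) or not np.isfinite(t):
            raise DomainError(f"exposure {t} outside [0, {EXPOSURE_MAX}] h")
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "exposure", t)


@dataclass(frozen=True)
class DoseResponseParams:
    """Parameters of the three-class dose-response model.

    score_* are the dimensionless coefficients of the latent escape score;
    (peak_concentration, peak_exposure) locate the tetraploid optimum; the
    width parameters are e-folding distances of the stretched-exponential
    bump (separate short-/long-side exposure widths); diploid_scale divides
    the score (logistic steepness); mixoploid_floor is the chimeric fraction
    of converted explants that persists even at the optimum.
    """

    score_intercept: float = -21.74
    score_log_dose: float = 5.5
    score_time: float = 0.0
    score_interaction: float = 0.1
    peak_concentration: float = 33.0  # µM
    peak_exposure: float = 18.0  # h
    conc_width: float = 680.0  # µM (e-folding distance, p = 0.5)
    exposure_width_short: float = 16.0  # h, side t < peak
    exposure_width_long: float = 1740.0  # h, side t > peak
    bump_exponent: float = 0.5
    diploid_scale: float = 1.0
    mixoploid_floor: float = 0.02

    def __post_init__(self):
        for name in ("conc_width", "exposure_width_short", "exposure_width_long"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.bump_exponent <= 0:
            raise DomainError("bump_exponent must be > 0")
        if self.diploid_scale <= 0:
            raise DomainError("diploid_scale must be > 0")
        if not 0.0 <= self.mixoploid_floor < 1.0:
            raise DomainError("mixoploid_floor must be in [0, 1)")


DEFAULT_PARAMS = DoseResponseParams()

#: Default 26-treatment design.  The concentration levels are the ten tested
#: ones; each named (concentration, exposure) pair from the study is present,
#: and remaining cells fill in the low-dose / short-time region.
_DEFAULT_GRID: tuple[tuple[float, float], ...] = (
    (0, 12), (0, 24),
    (2, 12), (2, 24),
    (5, 12), (5, 24),
    (8, 12), (8, 24),
    (10, 12), (10, 24),
    (20, 12), (20, 18), (20, 24),
    (40, 12), (40, 18), (40, 24), (40, 36),
    (60, 18), (60, 24), (60, 36),
    (80, 18), (80, 24), (80, 36),
    (100, 10), (100, 12), (100, 18),
)


def default_treatment_grid() -> list[Treatment]:
    """The 26 default (concentration, exposure) treatments."""
    return [Treatment(c, t) for c, t in _DEFAULT_GRID]


def _as_treatment(t) -> Treatment:
    if isinstance(t, Treatment):
        return t
    c, e = t
    return Treatment(float(c), float(e))


def class_probabilities(
    t, params: DoseResponseParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Analytic (diploid, mixoploid, tetraploid) probabilities for a treatment.

    Returns a length-3 probability vector in the fixed class order; sums to
    one exactly by construction.
    """
    t = _as_treatment(t)
    c, h = t.concentration, t.exposure
    u = np.log1p(c)
    s = (
        params.score_intercept
        + params.score_log_dose * u
        + params.score_time * h
        + params.score_interaction * u * h
    ) / params.diploid_scale
    p_dip = float(expit(-s))
    non_dip = 1.0 - p_dip
    dc = abs(c - params.peak_concentration)
    dt = h - params.peak_exposure
    wt = params.exposure_width_short if dt < 0 else params.exposure_width_long
    q = (dc / params.conc_width) ** params.bump_exponent + (
        abs(dt) / wt
    ) ** params.bump_exponent
    p_tet = non_dip * (1.0 - params.mixoploid_floor) * float(np.exp(-q))
    p_mix = 1.0 - p_dip - p_tet
    return np.array([p_dip, p_mix, p_tet])


@dataclass(frozen=True)
class ExperimentRecord:
    """One explant: its treatment, observed ploidy class and design indices."""

    treatment: Treatment
    ploidy: str
    replicate: int
    explant: int

    def __post_init__(self):
        if self.ploidy not in CLASSES:
            raise DataError(f"unknown ploidy label {self.ploidy!r}")


def simulate_experiment(
    grid=None,
    replicates: int = 4,
    explants: int = 4,
    params: DoseResponseParams = DEFAULT_PARAMS,
    seed: int = 0,
) -> list[ExperimentRecord]:
    """Draw every explant's ploidy class independently from the model.

    Returns |grid| * replicates * explants records; identical seeds yield
    identical outcomes.
    """
    if grid is None:
        grid = default_treatment_grid()
    if replicates < 1 or explants < 1:
        raise DomainError("replicates and explants must be >= 1")
    if not isinstance(seed, Integral) or isinstance(seed, bool):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    rng = np.random.default_rng(int(seed))
    records: list[ExperimentRecord] = []
    for t in grid:
        t = _as_treatment(t)
        probs = class_probabilities(t, params)
        draws = rng.choice(3, size=replicates * explants, p=probs)
        for rep in range(replicates):
            for ex in range(explants):
                records.append(
                    ExperimentRecord(
                        treatment=t,
                        ploidy=CLASSES[draws[rep * explants + ex]],
                        replicate=rep + 1,
                        explant=ex + 1,
                    )
                )
    return records


def records_to_dataset(records) -> PloidyDataset:
    """Flatten experiment records into a labeled feature table."""
    X = np.array(
        [[r.treatment.concentration, r.treatment.exposure] for r in records],
        dtype=float,
    ).reshape(-1, 2)
    y = np.array([r.ploidy for r in records], dtype=object)
    return PloidyDataset(X, y)


def assemble_balanced_dataset(
    records, per_class: int = 24, seed: int = 0
) -> PloidyDataset:
    """Subsample records to an equal per-class dataset (default 3 x 24 = 72).

    Each class is subsampled without replacement using the seed; a class
    with fewer than per_class records raises and names the deficient class.
    """
    if per_class < 0:
        raise DomainError("per_class must be >= 0")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {c: [] for c in CLASSES}
    for i, r in enumerate(records):
        by_class[r.ploidy].append(i)
    chosen: list[int] = []
    for c in CLASSES:
        idx = by_class[c]
        if len(idx) < per_class:
            raise DataError(
                f"class {c!r} has only {len(idx)} records; needs >= {per_class}"
            )
        pick = rng.choice(len(idx), size=per_class, replace=False)
        chosen.extend(sorted(idx[i] for i in pick))
    sub = [records[i] for i in chosen]
    if not sub:
        return PloidyDataset(np.empty((0, 2)), np.empty((0,), dtype=object))
    return records_to_dataset(sub)
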
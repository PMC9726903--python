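"""Kalman-filter Bayesian observer for serial duration discrimination.

The observer encodes each interval on a logarithmic scale with Gaussian
sensory noise, ``x_m = ln(d) + n_m``, and maintains a single Gaussian
prior over log duration that is updated by *every* measurement, in
presentation order, within a subject (a dynamic prior carried across
trials).  Each update follows the one-dimensional Kalman filter

    k_n   = (p_{n-1} + q) / (p_{n-1} + q + r)
    p_n   = k_n * r
    mu_n  = (1 - k_n) * mu_{n-1} + k_n * x_{m,n}

where ``r`` is the variance of the current measurement noise and ``q`` a
process variance controlling how quickly the prior forgets.  The percept
of a stimulus is the posterior mean after its update; the observer
responds "comparison longer" when the comparison percept exceeds the
standard percept.

The noise law distinguishes the two roles an interval can play.  The
*first* interval must be encoded and held across the ISI; its log-scale
SD is ``sigma_subject * (1 + noise_floor_ms / d)``, a sub-scalar law in
which very short intervals are encoded disproportionately poorly (the
Weber fraction rises sharply below ~100 ms).  The *second* interval is
judged online; its SD is ``sigma_subject`` scaled by an ISI-indexed
preparation multiplier.  On top of this, time-order errors are injected
through asymmetric standardized noise shapes (see
:class:`ObserverParams`):

1. the second interval is noisier at short inter-stimulus intervals
   (the ISI multiplier is non-increasing in ISI);
2. the second interval's standardized noise is drawn from one of two
   shape distributions depending on whether the trial's *longer*
   interval comes first or second; both are shifted low (the second
   interval tends to be under-measured), more strongly so on
   longer-second trials;
3. on the weakest discriminations (step Δ = 20 ms) in which the *first*
   interval is the shorter one, the first interval's standardized noise
   is drawn from a positively truncated normal, so a short unpredictable
   first interval is systematically expanded.

With the floor at zero, unit multipliers and standard-normal shapes the
noise is symmetric in log duration and no order-dependent bias emerges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .design import DesignSpec, Group, Trial, build_design, label_longer_first

LN_120 = math.log(120.0)


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(loc, scale²) truncated to [lower, upper].

    Used both for between-subject parameter draws (in SD units) and for
    standardized per-measurement noise shapes (unitless; the measurement
    SD multiplies the draw).  ``scale == 0`` degenerates to the constant
    ``loc``.
    """

    loc: float = 0.0
    scale: float = 1.0
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("scale must be non-negative")
        if self.lower >= self.upper:
            raise ValueError("empty truncation interval")

    def draw(self, rng: np.random.Generator, size: int | None = None):
        if self.scale == 0.0:
            out = np.full(size or 1, self.loc)
            return float(out[0]) if size is None else out
        a = ndtr((self.lower - self.loc) / self.scale)
        b = ndtr((self.upper - self.loc) / self.scale)
        u = rng.uniform(a, b, size=size)
        x = self.loc + self.scale * ndtri(u)
        return float(x) if size is None else x

    @property
    def mean(self) -> float:
        """Analytic mean of the truncated distribution."""
        if self.scale == 0.0:
            return self.loc
        a = (self.lower - self.loc) / self.scale
        b = (self.upper - self.loc) / self.scale
        phi = lambda z: math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
        num = (phi(a) if math.isfinite(a) else 0.0) - (phi(b) if math.isfinite(b) else 0.0)
        den = ndtr(b) - ndtr(a)
        return self.loc + self.scale * num / den


STANDARD_NORMAL = TruncatedNormal(0.0, 1.0)


@dataclass(frozen=True)
class Measurement:
    """A noisy internal log-duration representation of a physical interval."""

    x_m: float
    d: float
    sigma_m2: float


@dataclass(frozen=True)
class ObserverState:
    """The evolving Gaussian prior over log duration (mean, variance)."""

    mu_p: float = LN_120
    p: float = 10.0
    n_updates: int = 0


@dataclass(frozen=True)
class StimulusNoise:
    """Resolved noise for one measurement: an SD and a standardized shape.

    The realized noise is ``sigma * Z`` with ``Z`` drawn from ``shape``;
    an asymmetric (truncated) shape therefore carries a mean bias that
    scales with the SD.
    """

    sigma: float
    shape: TruncatedNormal = STANDARD_NORMAL

    @property
    def variance(self) -> float:
        return self.sigma**2


@dataclass(frozen=True)
class ObserverParams:
    """All free parameters of the Bayesian observer.

    Defaults mirror the packaged configuration file
    (``serialtoe/data/default_params.yml``); prefer loading that file via
    :func:`serialtoe.config.default_params` so the provenance of every
    number stays in one place.
    """

    q: float = 1.5
    sigma_subject: TruncatedNormal = TruncatedNormal(0.25, 0.05, 0.1, 0.5)
    noise_floor_ms: float = 0.0
    isi_noise: Mapping[float, float] = field(
        default_factory=lambda: {400.0: 1.0, 800.0: 1.0, 1600.0: 1.0, 2000.0: 1.0}
    )
    longer_first_noise: TruncatedNormal = STANDARD_NORMAL
    longer_second_noise: TruncatedNormal = STANDARD_NORMAL
    weak_level_noise: TruncatedNormal = STANDARD_NORMAL
    weak_delta: float = 20.0
    prior_mean0: float = LN_120
    prior_var0: float = 10.0
    prior_carryover: bool = True

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("process variance q must be non-negative")
        mults = [m for _, m in sorted(self.isi_noise.items())]
        if any(m <= 0 for m in mults):
            raise ValueError("ISI noise multipliers must be positive")
        if any(b > a for a, b in zip(mults, mults[1:])):
            raise ValueError("ISI noise multipliers must be non-increasing in ISI")

    def initial_state(self) -> ObserverState:
        return ObserverState(mu_p=self.prior_mean0, p=self.prior_var0, n_updates=0)


@dataclass(frozen=True)
class ResponseRecord:
    """One binary judgement: 1 = "comparison longer", 0 = "standard longer"."""

    trial: Trial
    response: int
    correct: bool
    subject_id: int = 0


def measure(d: float, sigma_m: float, rng: np.random.Generator) -> Measurement:
    """Encode duration ``d`` (ms) as ``ln(d)`` plus N(0, sigma_m²) noise."""
    if d <= 0:
        raise ValueError("physical duration must be positive")
    if sigma_m < 0:
        raise ValueError("measurement noise SD must be non-negative")
    noise = rng.normal(0.0, sigma_m) if sigma_m > 0 else 0.0
    return Measurement(x_m=math.log(d) + noise, d=d, sigma_m2=sigma_m**2)


def kalman_gain(p_prev: float, q: float, r: float) -> float:
    """Weight of the current measurement: (p+q)/(p+q+r), in (0, 1)."""
    if r <= 0:
        raise ValueError("likelihood variance r must be positive")
    if p_prev < 0 or q < 0:
        raise ValueError("variances must be non-negative")
    if p_prev + q <= 0:
        raise ValueError("p_prev + q must be positive")
    return (p_prev + q) / (p_prev + q + r)


def update_state(
    state: ObserverState, x_m: float, r: float, q: float
) -> tuple[ObserverState, float]:
    """One Kalman update; returns the new state and the percept (posterior mean)."""
    k = kalman_gain(state.p, q, r)
    # a convex combination of equal points is that point; keep it exact
    mu = state.mu_p if x_m == state.mu_p else (1.0 - k) * state.mu_p + k * x_m
    new = ObserverState(mu_p=mu, p=k * r, n_updates=state.n_updates + 1)
    return new, mu


def steady_state_variance(q: float, r: float) -> float:
    """Fixed point of the variance recursion p = r(p+q)/(p+q+r).

    Solves the quadratic p² + q·p − q·r = 0 for its positive root; the
    iterated prior variance converges here from any start.
    """
    if r <= 0 or q < 0:
        raise ValueError("require r > 0 and q >= 0")
    if q == 0:
        return 0.0
    return (-q + math.sqrt(q * q + 4.0 * q * r)) / 2.0


def _weak_level_applies(trial: Trial, params: ObserverParams) -> bool:
    """Weak-step trials whose first interval is the shorter one.

    For group SC (standard first) these are the +Δ20 trials; for CS
    (comparison first) the −Δ20 trials.
    """
    if trial.delta_level != params.weak_delta:
        return False
    return not label_longer_first(trial)


def resolve_noise(
    trial: Trial,
    stimulus_position: Literal["first", "second"],
    params: ObserverParams,
    sigma_subject: float,
) -> StimulusNoise:
    """Compose the noise model for one measurement of one trial.

    The SD composes the subject's base noise with the first-interval
    encoding floor or, for the second interval, the ISI preparation
    multiplier.  The standardized shape encodes the asymmetric
    assumptions: the second interval draws from the position-specific
    distribution selected by where the trial's longer interval sits, and
    on weak-step trials a shorter first interval draws from the
    positively truncated weak-level distribution.
    """
    if stimulus_position not in ("first", "second"):
        raise ValueError(f"unknown position {stimulus_position!r}")
    if stimulus_position == "first":
        # the first interval must be encoded and held across the ISI;
        # its log-scale SD carries a sub-scalar floor term that grows as
        # the interval shrinks (the Weber fraction rises at short
        # durations).  noise_floor_ms = 0 recovers scalar encoding.
        d = trial.first_duration
        sigma = sigma_subject * (1.0 + params.noise_floor_ms / d)
    else:
        # the second interval is judged online; its noise is scalar but
        # scaled by the preparation (ISI) multiplier
        try:
            sigma = sigma_subject * params.isi_noise[trial.isi]
        except KeyError:
            raise KeyError(f"no ISI noise multiplier configured for {trial.isi} ms")
    if trial.c_duration == trial.s_duration:
        # catch trials with no longer interval: plain symmetric noise
        shape = STANDARD_NORMAL
    elif stimulus_position == "second":
        # the second interval's standardized noise depends on where the
        # trial's longer interval sits: longer-second trials draw from a
        # more strongly low-shifted distribution (the second interval is
        # under-measured, most of all when it is the longer one)
        shape = (
            params.longer_first_noise
            if label_longer_first(trial)
            else params.longer_second_noise
        )
    elif _weak_level_applies(trial, params):
        shape = params.weak_level_noise
    else:
        shape = STANDARD_NORMAL
    return StimulusNoise(sigma=sigma, shape=shape)


def _measure_with(
    d: float, noise: StimulusNoise, rng: np.random.Generator
) -> Measurement:
    z = noise.shape.draw(rng)
    return Measurement(x_m=math.log(d) + noise.sigma * z, d=d, sigma_m2=noise.variance)


def run_trial(
    trial: Trial,
    state: ObserverState,
    params: ObserverParams,
    rng: np.random.Generator,
    *,
    sigma_subject: float | None = None,
) -> tuple[ResponseRecord, ObserverState]:
    """Simulate one trial: measure both intervals in order, update the
    shared prior after each, compare the two percepts.

    ``sigma_subject`` is the realized base noise SD of the simulated
    subject; when omitted, the location of the between-subject
    distribution is used.  Exact percept ties (possible in degenerate
    noiseless configurations) are broken by a fair coin from ``rng``.
    """
    if sigma_subject is None:
        sigma_subject = params.sigma_subject.loc
    order = ("S", "C") if trial.group == "SC" else ("C", "S")
    percepts: dict[str, float] = {}
    for position, stim in zip(("first", "second"), order):
        d = trial.s_duration if stim == "S" else trial.c_duration
        noise = resolve_noise(trial, position, params, sigma_subject)
        m = _measure_with(d, noise, rng)
        if m.sigma_m2 == 0.0:
            # noiseless limit of the Kalman update (k -> 1): trust the
            # measurement outright, collapse the prior onto it
            percept = m.x_m
            state = ObserverState(mu_p=m.x_m, p=0.0, n_updates=state.n_updates + 1)
        else:
            state, percept = update_state(state, m.x_m, m.sigma_m2, params.q)
        percepts[stim] = percept
    if percepts["C"] > percepts["S"]:
        response = 1
    elif percepts["C"] < percepts["S"]:
        response = 0
    else:
        response = int(rng.integers(2))
    correct = (response == 1) == (trial.c_duration > trial.s_duration)
    return ResponseRecord(trial=trial, response=response, correct=correct), state


def simulate_subject(
    subject_id: int,
    spec: DesignSpec,
    group: Group,
    params: ObserverParams,
    rng: np.random.Generator,
    *,
    sigma_subject: float | None = None,
) -> list[ResponseRecord]:
    """One subject's full session; the prior persists across trials and,
    when ``params.prior_carryover`` is set, across ISI blocks."""
    if sigma_subject is None:
        sigma_subject = params.sigma_subject.draw(rng)
    trials = build_design(spec, group, rng)
    state = params.initial_state()
    records: list[ResponseRecord] = []
    current_block = None
    for trial in trials:
        if not params.prior_carryover and trial.block_index != current_block:
            state = params.initial_state()
        current_block = trial.block_index
        rec, state = run_trial(
            trial, state, params, rng, sigma_subject=sigma_subject
        )
        records.append(replace(rec, subject_id=subject_id))
    return records


def simulate_cohort(
    n_subjects: int,
    spec: DesignSpec,
    group: Group,
    params: ObserverParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate ``n_subjects`` independent sessions and return a tidy table.

    Each subject draws a base noise SD from the between-subject
    distribution, gets a freshly randomized design, and starts from the
    initial prior.  Columns: subject_id, group, block_index, trial_index,
    isi_ms, s_ms, c_ms, delta_level, delta_sign, longer_first, response,
    correct.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rows = []
    for sid in range(n_subjects):
        for rec in simulate_subject(sid, spec, group, params, rng):
            t = rec.trial
            rows.append(
                (
                    rec.subject_id,
                    t.group,
                    t.block_index,
                    t.trial_index,
                    t.isi,
                    t.s_duration,
                    t.c_duration,
                    t.delta_level,
                    t.delta_sign,
                    label_longer_first(t),
                    rec.response,
                    rec.correct,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "block_index",
            "trial_index",
            "isi_ms",
            "s_ms",
            "c_ms",
            "delta_level",
            "delta_sign",
            "longer_first",
            "response",
            "correct",
        ],
    )
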
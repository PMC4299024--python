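"""Seeded generator of multi-day labeled triaxial accelerometer recordings.

Each day is a concatenation of activity episodes.  An activity owns one or
more motion *regimes* — a per-axis mean orientation (gravity component), a
per-axis noise level, and an optional sinusoidal component standing in for
rhythmic movement (walking cadence, vehicle vibration).  A fragmented
activity (the "commute by bus or on foot" situation) owns several regimes
and draws one per episode, so a single label covers kinematically distinct
behaviour.  Idle stretches are never labeled, and a fraction of genuine
activity episodes have their labels withheld; both end up in the catch-all
``not_tagged`` class, as they would in a real self-annotated deployment.
The true activity and regime of every episode are retained in a trace so
that fragment recovery can be checked up to label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ActivityLabeling, LabeledInterval, TriaxialRecording

IDLE = "idle"
DEFAULT_SAMPLING_RATE = 20.0  # Hz
DEFAULT_DAY_LENGTH_S = 3600.0
DEFAULT_UNTAGGED_FRACTION = 0.05  # per-episode label withholding probability
DAY_START_S = 9 * 3600.0  # recordings nominally start at 09:00


@dataclass
class Regime:
    """One motion regime: Gaussian noise around a mean, plus optional sinusoid.

    The oscillation models rhythmic movement (arm swing, scrubbing, vehicle
    vibration) as a one-dimensional motion along a fixed direction in the
    sensor frame: a single sinusoid with a random per-episode phase is
    projected onto the axes through ``osc_dir``, so the inter-axis
    correlation pattern is a stable signature of the regime rather than an
    artifact of independent per-axis phases.
    """

    weight: float
    mean: tuple[float, float, float]
    std: tuple[float, float, float]
    osc_freq: float | None = None  # Hz
    osc_amp: float = 0.0  # g
    osc_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass
class ActivitySpec:
    """Durations (seconds) and regime mixture of one activity class."""

    name: str
    min_duration: float
    max_duration: float
    regimes: list[Regime]
    fragmented: bool = False

    def __post_init__(self) -> None:
        if self.min_duration > self.max_duration:
            raise ValueError("min_duration exceeds max_duration")
        if not self.regimes:
            raise ValueError("at least one regime required")
        total = sum(r.weight for r in self.regimes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("regime weights must sum to 1")


@dataclass
class Episode:
    activity: str
    duration_s: float
    tagged: bool


@dataclass
class DayPlan:
    """Schedule of one day: ordered episodes plus generation parameters."""

    seed: int
    schedule: list[Episode]
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    untagged_fraction: float = DEFAULT_UNTAGGED_FRACTION
    start_time_s: float = DAY_START_S


@dataclass
class EpisodeTrace:
    """Ground truth retained for every episode, labeled or not."""

    activity: str
    regime_index: int
    start_s: float
    end_s: float
    tagged: bool


@dataclass
class SyntheticDay:
    run_id: str
    recording: TriaxialRecording
    labeling: ActivityLabeling
    trace: list[EpisodeTrace] = field(default_factory=list)


def default_activity_specs() -> list[ActivitySpec]:
    """The default 6-way scenario: a dominant sedentary class, short
    hygiene/meal/exercise classes, a deliberately fragmented commute
    (walk vs. vehicle regimes), and an idle regime that is never labeled."""
    return [
        ActivitySpec(
            "working", 300, 600,
            [Regime(1.0, (-0.05, -0.30, 0.95), (0.03, 0.03, 0.03))],
        ),
        ActivitySpec(
            "meal", 120, 240,
            [Regime(1.0, (0.55, -0.60, 0.45), (0.08, 0.08, 0.08),
                    0.4, 0.05, (0.6, -0.8, 0.0))],
        ),
        ActivitySpec(
            "hygiene", 60, 120,
            [Regime(1.0, (0.70, 0.45, 0.25), (0.18, 0.20, 0.18),
                    1.3, 0.35, (-0.5, 0.7, 0.5))],
        ),
        ActivitySpec(
            "exercise", 120, 300,
            [Regime(1.0, (0.05, 0.85, 0.10), (0.20, 0.25, 0.20),
                    1.0, 0.50, (0.2, 0.9, -0.4))],
        ),
        ActivitySpec(
            "commute", 120, 300,
            [
                Regime(0.5, (0.35, 0.55, 0.40), (0.12, 0.14, 0.12),
                       0.9, 0.35, (0.7, 0.5, 0.5)),
                Regime(0.5, (0.80, 0.05, 0.45), (0.07, 0.07, 0.07),
                       0.4, 0.04, (0.3, 0.3, 0.9)),
            ],
            fragmented=True,
        ),
        ActivitySpec(
            IDLE, 240, 480,
            [Regime(1.0, (0.90, 0.00, 0.40), (0.10, 0.10, 0.10))],
        ),
    ]


#: Episode-draw weight of each default activity (idle is always untagged).
DEFAULT_DRAW_WEIGHTS = {
    "working": 0.24,
    IDLE: 0.37,
    "commute": 0.13,
    "exercise": 0.10,
    "meal": 0.09,
    "hygiene": 0.07,
}


def expected_time_shares(
    specs: list[ActivitySpec], draw_weights: dict[str, float]
) -> dict[str, float]:
    """Expected share of recorded time per activity under the draw weights.

    Episodes are drawn with no immediate repeats, so the episode frequency
    of activity i is the stationary distribution of the chain
    ``P(next=i | prev=j) = w_i / (1 - w_j)`` for i != j, found by fixed-point
    iteration; time shares then weight frequencies by mean episode duration.
    """
    names = list(draw_weights)
    w = np.array([draw_weights[n] for n in names], dtype=float)
    w = w / w.sum()
    f = w.copy()
    for _ in range(200):
        c = f / (1.0 - w)
        f_new = w * (c.sum() - c)
        f_new /= f_new.sum()
        if np.abs(f_new - f).max() < 1e-12:
            f = f_new
            break
        f = f_new
    mean_dur = {s.name: 0.5 * (s.min_duration + s.max_duration) for s in specs}
    raw = {n: fi * mean_dur[n] for n, fi in zip(names, f)}
    total = sum(raw.values())
    return {n: v / total for n, v in raw.items()}


def make_day_plan(
    specs: list[ActivitySpec],
    draw_weights: dict[str, float],
    day_length_s: float,
    untagged_fraction: float,
    seed: int,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    start_time_s: float = DAY_START_S,
) -> DayPlan:
    """Random schedule: weighted activity draws without immediate repeats,
    uniform durations within each activity's bounds, until the day is full."""
    rng = np.random.default_rng(seed)
    by_name = {s.name: s for s in specs}
    names = np.array(list(draw_weights))
    weights = np.array([draw_weights[str(n)] for n in names], dtype=float)
    schedule: list[Episode] = []
    t = 0.0
    prev = None
    while True:
        remaining = day_length_s - t
        # draw among activities that still fit; avoid immediate repeats when
        # any alternative fits
        fits = np.array([by_name[str(n)].min_duration <= remaining for n in names])
        if fits.sum() > 1 and prev is not None:
            fits &= names != prev
        if not fits.any():
            break
        p = weights * fits
        name = str(rng.choice(names, p=p / p.sum()))
        spec = by_name[name]
        dur = float(rng.uniform(spec.min_duration, min(spec.max_duration, remaining)))
        tagged = (name != IDLE) and (rng.random() >= untagged_fraction)
        schedule.append(Episode(name, dur, tagged))
        t += dur
        prev = name
    return DayPlan(
        seed=seed,
        schedule=schedule,
        sampling_rate=sampling_rate,
        untagged_fraction=untagged_fraction,
        start_time_s=start_time_s,
    )


def _regime_signal(regime: Regime, n: int, rate: float, rng) -> np.ndarray:
    """(3, n) signal of one regime: noise around the mean plus a sinusoid
    with a random phase projected onto the regime's movement direction."""
    tt = np.arange(n) / rate
    osc = np.zeros(n)
    if regime.osc_freq is not None and regime.osc_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        osc = regime.osc_amp * np.sin(2 * np.pi * regime.osc_freq * tt + phase)
    direction = np.asarray(regime.osc_dir, dtype=float)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else direction
    return np.stack(
        [
            regime.mean[axis]
            + regime.std[axis] * rng.standard_normal(n)
            + direction[axis] * osc
            for axis in range(3)
        ]
    )


def generate_day(
    specs: list[ActivitySpec],
    plan: DayPlan,
    seed: int,
    run_id: str = "day",
    gesture_rate_per_min: float = 0.5,
    gesture_duration_s: tuple[float, float] = (3.0, 8.0),
) -> SyntheticDay:
    """Emit one day's signal from a plan; deterministic given the seed.

    Besides the episode regimes, short *gesture bursts* are injected at
    ``gesture_rate_per_min`` (Poisson): for a few seconds the signal follows
    a regime of some other activity (a reach, a scratch, a brief walk to the
    printer) while the ground-truth label stays that of the episode.  These
    transients are what make unconstrained decoding emit spurious short
    segments — the failure mode the minimum-run-length constraint targets.
    """
    rng = np.random.default_rng(seed)
    by_name = {s.name: s for s in specs}
    rate = plan.sampling_rate
    xs, ys, zs = [], [], []
    intervals: list[LabeledInterval] = []
    trace: list[EpisodeTrace] = []
    t0 = plan.start_time_s
    for ep in plan.schedule:
        spec = by_name[ep.activity]
        weights = np.array([r.weight for r in spec.regimes])
        ridx = int(rng.choice(len(spec.regimes), p=weights / weights.sum()))
        regime = spec.regimes[ridx]
        n = int(round(ep.duration_s * rate))
        if n < 1:
            raise ValueError(f"episode too short for the sampling rate: {ep}")
        sig = _regime_signal(regime, n, rate, rng)
        foreign = [r for s in specs if s.name != ep.activity for r in s.regimes]
        if foreign and gesture_rate_per_min > 0:
            n_bursts = rng.poisson(ep.duration_s / 60.0 * gesture_rate_per_min)
            for _ in range(n_bursts):
                lo, hi = gesture_duration_s
                bn = int(round(rng.uniform(lo, hi) * rate))
                bn = min(bn, n)
                if bn < 1:
                    continue
                b0 = int(rng.integers(0, n - bn + 1))
                burst = foreign[int(rng.integers(len(foreign)))]
                sig[:, b0 : b0 + bn] = _regime_signal(burst, bn, rate, rng)
        xs.append(sig[0]); ys.append(sig[1]); zs.append(sig[2])
        end = t0 + n / rate
        if ep.tagged:
            intervals.append(LabeledInterval(t0, end, ep.activity))
        trace.append(EpisodeTrace(ep.activity, ridx, t0, end, ep.tagged))
        t0 = end
    if not xs:
        raise ValueError("empty schedule")
    x = np.concatenate(xs); y = np.concatenate(ys); z = np.concatenate(zs)
    timestamps = plan.start_time_s + np.arange(len(x)) / rate
    recording = TriaxialRecording(run_id, timestamps, x, y, z)
    return SyntheticDay(run_id, recording, ActivityLabeling(intervals), trace)


def default_scenario(
    n_days: int,
    seed: int,
    day_length_s: float = DEFAULT_DAY_LENGTH_S,
    untagged_fraction: float = DEFAULT_UNTAGGED_FRACTION,
) -> list[SyntheticDay]:
    """Multi-day default scenario; one seeded recording per day."""
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    specs = default_activity_specs()
    root = np.random.SeedSequence(seed)
    days = []
    for d, child in enumerate(root.spawn(n_days)):
        sub = child.generate_state(2)
        plan = make_day_plan(
            specs,
            DEFAULT_DRAW_WEIGHTS,
            day_length_s,
            untagged_fraction,
            seed=int(sub[0] % (2**31)),
        )
        days.append(generate_day(specs, plan, seed=int(sub[1] % (2**31)), run_id=f"day{d:02d}"))
    return days
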
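"""Synthetic telemetry and feeding-trial data with known ground truth.

The simulators emulate the structure of the field data the pipeline
consumes: GPS tracks sampled every 15 or 30 min over tens to hundreds of
hours within a bounded home range, and marker-spore excretion counts
observed on a staged scat-collection schedule (4-hourly for 48 h, then
6-hourly for 36 h, then 12-hourly for 24 h).

Movement models
---------------
``ou``
    Per-axis discrete-time Ornstein–Uhlenbeck process — the standard
    home-range model: positions revert to a centre with autocorrelation
    time ``tau`` and stationary standard deviation ``sigma`` per axis,
    using the exact transition
    ``x_{i+1} = x_i e^{-dt/tau} + sigma sqrt(1 - e^{-2 dt/tau}) z``.
``constant_velocity``
    Straight-line motion at a fixed speed — the analytically tractable
    scenario whose kernel quantiles have a closed form.
``stationary``
    No movement; every kernel collapses to a point mass at zero.

Excretion times are drawn from the logistic distribution with location
``t50`` and scale ``s`` truncated to the collection schedule, matching the
family fitted by :mod:`sporekernel.gut_passage` so parameter recovery is
well-posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .gut_passage import ExcretionObservation, logistic_cdf
from .telemetry import METERS_PER_DEGREE, Track

#: default scat-collection schedule: (start, end) hours since dosing
DEFAULT_SCHEDULE: tuple[tuple[float, float], ...] = tuple(
    [(float(a), float(a + 4)) for a in range(0, 48, 4)]
    + [(float(a), float(a + 6)) for a in range(48, 84, 6)]
    + [(float(a), float(a + 12)) for a in range(84, 108, 12)]
)

_EPOCH = np.datetime64("2016-07-01T00:00:00", "ns")


@dataclass
class MovementSimConfig:
    """Configuration for one simulated tracking period."""

    model: str = "ou"  # ou | constant_velocity | stationary
    home_center: tuple[float, float] = (-30.4, 151.6)  # (lat, lon) degrees
    sigma: float = 300.0  # OU stationary SD per axis, metres
    tau: float = 12.0  # OU autocorrelation time, hours
    speed: float = 100.0  # constant-velocity speed, m/h
    fix_interval_min: float = 15.0
    duration_hours: float = 200.0
    dropout_prob: float = 0.0
    seed: int = 0
    animal_id: str = "sim"
    period_id: str = "p1"
    start_time: np.datetime64 = _EPOCH

    def __post_init__(self) -> None:
        if self.model not in ("ou", "constant_velocity", "stationary"):
            raise ValueError(f"unknown movement model {self.model!r}")
        if self.sigma <= 0 or self.tau <= 0 or self.speed < 0:
            raise ValueError("sigma, tau must be positive; speed nonnegative")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.duration_hours <= 0 or self.fix_interval_min <= 0:
            raise ValueError("duration and fix interval must be positive")


@dataclass
class GutSimConfig:
    """Configuration for one simulated marker-spore feeding trial."""

    t50: float = 24.0  # hours to 50% cumulative excretion
    s: float = 5.0  # logistic scale, hours
    n_spores: int = 10_000
    schedule: tuple[tuple[float, float], ...] = DEFAULT_SCHEDULE
    seed: int = 0
    trial_animal_id: str = "trial"

    def __post_init__(self) -> None:
        if self.s <= 0 or self.n_spores < 1:
            raise ValueError("s must be positive and n_spores >= 1")
        prev_end = None
        for a, b in self.schedule:
            if b <= a or (prev_end is not None and abs(a - prev_end) > 1e-9):
                raise ValueError("schedule intervals must be contiguous and increasing")
            prev_end = b


def simulate_track(config: MovementSimConfig) -> Track:
    """Simulate one tracking period; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    dt_h = config.fix_interval_min / 60.0
    n = int(math.floor(config.duration_hours / dt_h)) + 1
    t_hours = np.arange(n) * dt_h

    if config.model == "stationary":
        x = np.zeros(n)
        y = np.zeros(n)
    elif config.model == "constant_velocity":
        x = config.speed * t_hours
        y = np.zeros(n)
    else:  # ou
        rho = math.exp(-dt_h / config.tau)
        innov_sd = config.sigma * math.sqrt(1.0 - rho * rho)
        z = rng.standard_normal((n, 2))
        xy = np.empty((n, 2))
        xy[0] = config.sigma * z[0]  # start from the stationary law
        for i in range(1, n):
            xy[i] = rho * xy[i - 1] + innov_sd * z[i]
        x, y = xy[:, 0], xy[:, 1]

    keep = np.ones(n, dtype=bool)
    if config.dropout_prob > 0:
        keep = rng.random(n) >= config.dropout_prob
        keep[0] = True  # anchor the period start
        if keep.sum() < 2:
            keep[-1] = True

    lat0, lon0 = config.home_center
    lat = lat0 + y / METERS_PER_DEGREE
    lon = lon0 + x / (METERS_PER_DEGREE * math.cos(math.radians(lat0)))
    times = config.start_time + (t_hours * 3.6e12).astype("timedelta64[ns]")
    return Track(
        animal_id=config.animal_id,
        period_id=config.period_id,
        times=times[keep],
        lat=lat[keep],
        lon=lon[keep],
        crs="geographic",
    )


def simulate_gut_passage(config: GutSimConfig) -> list[ExcretionObservation]:
    """Simulate marker-spore counts per collection interval.

    Each spore's excretion time is drawn from the logistic(t50, s)
    distribution truncated to [0, schedule end] (inverse-CDF sampling), and
    the spores are tallied into the collection intervals.  Total count
    across intervals equals ``n_spores``.
    """
    rng = np.random.default_rng(config.seed)
    end = config.schedule[-1][1]
    f_lo = logistic_cdf(0.0, config.t50, config.s)
    f_hi = logistic_cdf(end, config.t50, config.s)
    u = f_lo + (f_hi - f_lo) * rng.random(config.n_spores)
    times = config.t50 + config.s * np.log(u / (1.0 - u))
    times = np.clip(times, 0.0, end)
    edges = np.array([config.schedule[0][0]] + [b for _, b in config.schedule])
    counts, _ = np.histogram(times, bins=edges)
    return [
        ExcretionObservation(
            trial_animal_id=config.trial_animal_id,
            interval_start=a,
            interval_end=b,
            marker_amount=float(c),
        )
        for (a, b), c in zip(config.schedule, counts)
    ]


def closed_form_quantile(
    speed: float,
    t50: float,
    s: float,
    q: float,
    window_hours: float = 69.0,
    asymptote: float = 1.0,
) -> float:
    """Analytic kernel quantile for straight-line motion at ``speed``.

    With constant speed and dense fixes, the distance travelled by the
    defecation time is speed * t where t solves the window-renormalised
    cumulative curve C~(t) = (C(t) - C(0)) / (C(W) - C(0)) = q.  Inverted by
    bisection to 1e-9 h.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be inside (0, 1)")
    if speed == 0.0:
        return 0.0
    c0 = logistic_cdf(0.0, t50, s, asymptote)
    cw = logistic_cdf(window_hours, t50, s, asymptote)

    def f(t: float) -> float:
        return (logistic_cdf(t, t50, s, asymptote) - c0) / (cw - c0) - q

    t_q = brentq(f, 0.0, window_hours, xtol=1e-9)
    return speed * t_q


# ---------------------------------------------------------------------------
# a full synthetic study


@dataclass
class StudyConfig:
    """A synthetic study mirroring the field campaign's shape: six tracked
    animals over nine tracking periods (two animals retracked, period
    spans 85-544 h summing to ~1,808 h, fixes every 15 or 30 min) and two
    feeding-trial animals with distinct gut-retention curves."""

    seed: int = 0
    movement_model: str = "ou"
    sigma: float = 300.0
    tau: float = 12.0
    n_spores: int = 2_000
    #: (animal, period, duration h, fix interval min)
    periods: tuple = (
        ("w1", "p1", 165.0, 15.0),
        ("w1", "p2", 85.0, 30.0),
        ("w1", "p3", 110.0, 15.0),
        ("w2", "p4", 544.0, 30.0),
        ("w2", "p5", 127.0, 15.0),
        ("w3", "p6", 180.0, 15.0),
        ("w4", "p7", 300.0, 30.0),
        ("w5", "p8", 157.0, 15.0),
        ("w6", "p9", 139.0, 30.0),
    )
    #: (trial animal, t50 h, s h) — one faster, one slower passage
    trials: tuple = (("trialA", 24.0, 5.0), ("trialB", 40.0, 7.0))


def simulate_study(config: StudyConfig) -> tuple[list[Track], list[ExcretionObservation]]:
    """Generate the full synthetic study; deterministic given the seed."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(len(config.periods) + len(config.trials)) % (2**31)
    tracks = []
    for (animal, period, dur, dt), seed in zip(config.periods, seeds):
        tracks.append(
            simulate_track(
                MovementSimConfig(
                    model=config.movement_model,
                    sigma=config.sigma,
                    tau=config.tau,
                    fix_interval_min=dt,
                    duration_hours=dur,
                    seed=int(seed),
                    animal_id=animal,
                    period_id=period,
                )
            )
        )
    observations: list[ExcretionObservation] = []
    for (trial, t50, s), seed in zip(config.trials, seeds[len(config.periods):]):
        observations.extend(
            simulate_gut_passage(
                GutSimConfig(
                    t50=t50, s=s, n_spores=config.n_spores,
                    seed=int(seed), trial_animal_id=trial,
                )
            )
        )
    return tracks, observations


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    """Telemetry CSV dialect consumed by :func:`sporekernel.telemetry.read_tracks`."""
    rows = []
    for t in tracks:
        for i in range(len(t)):
            rows.append({
                "animal_id": t.animal_id,
                "period_id": t.period_id,
                "timestamp": pd.Timestamp(t.times[i]).isoformat(),
                "lat": t.lat[i],
                "lon": t.lon[i],
            })
    return pd.DataFrame(rows)


def observations_to_frame(observations: Sequence[ExcretionObservation]) -> pd.DataFrame:
    """Excretion CSV dialect consumed by :func:`sporekernel.gut_passage.read_excretion_csv`."""
    return pd.DataFrame([
        {
            "trial_animal_id": o.trial_animal_id,
            "interval_start_h": o.interval_start,
            "interval_end_h": o.interval_end,
            "marker_amount": o.marker_amount,
        }
        for o in observations
    ])
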
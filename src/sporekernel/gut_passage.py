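"""Gut-retention curves: cumulative spore excretion and its logistic fit.

A marker-spore feeding trial yields, per trial animal, counts of marker
spores in scats collected over a fixed schedule of intervals after dosing.
Normalising the running total by the grand total gives the *cumulative
excretion curve* — the proportion of recovered spores defecated by each
time.  A two-parameter logistic

    C(t) = A / (1 + exp(-(t - t50) / s))

is fitted to that curve by nonlinear least squares: ``t50`` is the time of
50% cumulative defecation (hours) and ``s`` a scale (hours) controlling how
spread out excretion is.  The asymptote ``A`` is fixed at 1 by default
because the curve is normalised to the total spores observed.

The fitted curve converts a sequence of telemetry fix times (hours since a
hypothetical ingestion) into defecation-probability masses — the increment
of C between consecutive fixes — which weight the animal's displacements in
the dispersal kernel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)


class GutPassageError(ValueError):
    """Invalid excretion observations or curve."""


class FitConvergenceError(RuntimeError):
    """Least-squares fit failed; carries the best parameters found."""

    def __init__(self, message: str, params: dict, rss: float):
        super().__init__(message)
        self.params = params
        self.rss = rss


@dataclass(frozen=True)
class ExcretionObservation:
    """Marker-spore amount recovered in one scat-collection interval."""

    trial_animal_id: str
    interval_start: float  # hours since dosing
    interval_end: float
    marker_amount: float  # count or proportion, nonnegative

    def __post_init__(self) -> None:
        if not (0 <= self.interval_start < self.interval_end):
            raise GutPassageError(
                f"bad interval [{self.interval_start}, {self.interval_end})"
            )
        if self.marker_amount < 0:
            raise GutPassageError("marker_amount must be nonnegative")


@dataclass
class CumulativeExcretionCurve:
    """Cumulative proportion of marker spores defecated, by interval midpoint.

    ``times`` are collection-interval midpoints (the conventional estimate of
    individual excretion times); ``cum_prop`` is the running total of marker
    divided by the grand total, so the final value is exactly 1.
    ``interval_ends`` is retained when the curve was built from interval
    observations: the cumulative count through interval k is the proportion
    excreted by that interval's *end*, which is where the logistic fit
    evaluates the model unless told otherwise.
    """

    trial_animal_id: str
    times: np.ndarray  # hours, strictly increasing (interval midpoints)
    cum_prop: np.ndarray  # nondecreasing, final value 1
    interval_ends: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cum_prop = np.asarray(self.cum_prop, dtype=float)
        if self.times.size != self.cum_prop.size or self.times.size < 3:
            raise GutPassageError("curve needs >= 3 (time, cum_prop) points")
        if np.any(np.diff(self.times) <= 0):
            raise GutPassageError("curve times must be strictly increasing")
        if np.any(np.diff(self.cum_prop) < -1e-12):
            raise GutPassageError("cum_prop must be nondecreasing")
        if abs(self.cum_prop[-1] - 1.0) > 1e-9:
            raise GutPassageError("final cumulative proportion must be 1")
        if self.interval_ends is not None:
            self.interval_ends = np.asarray(self.interval_ends, dtype=float)
            if self.interval_ends.size != self.times.size:
                raise GutPassageError("interval_ends length mismatch")


def build_curve(observations: Sequence[ExcretionObservation]) -> CumulativeExcretionCurve:
    """Turn interval observations into a cumulative excretion curve.

    Intervals are sorted by start time and must not overlap.  Midpoints
    become the curve's times; the running marker total divided by the grand
    total becomes ``cum_prop``.
    """
    obs = sorted(observations, key=lambda o: o.interval_start)
    if len(obs) < 3:
        raise GutPassageError("need at least 3 observations")
    ids = {o.trial_animal_id for o in obs}
    if len(ids) != 1:
        raise GutPassageError(f"observations mix trial animals: {sorted(ids)}")
    for a, b in zip(obs, obs[1:]):
        if b.interval_start < a.interval_end - 1e-12:
            raise GutPassageError(
                f"overlapping intervals [{a.interval_start}, {a.interval_end}) "
                f"and [{b.interval_start}, {b.interval_end})"
            )
    amounts = np.array([o.marker_amount for o in obs], dtype=float)
    total = amounts.sum()
    if total <= 0:
        raise GutPassageError("total marker amount is zero")
    cum = np.cumsum(amounts) / total
    cum[-1] = 1.0  # exact by construction
    return CumulativeExcretionCurve(
        trial_animal_id=obs[0].trial_animal_id,
        times=np.array([(o.interval_start + o.interval_end) / 2.0 for o in obs]),
        cum_prop=cum,
        interval_ends=np.array([o.interval_end for o in obs]),
    )


def read_excretion_csv(path_or_df) -> dict[str, list[ExcretionObservation]]:
    """Read excretion observations, grouped by trial animal.

    Expected columns: trial_animal_id, interval_start_h, interval_end_h,
    marker_amount.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    required = ["trial_animal_id", "interval_start_h", "interval_end_h", "marker_amount"]
    for c in required:
        if c not in df.columns:
            raise GutPassageError(f"required column {c!r} not found in excretion input")
    out: dict[str, list[ExcretionObservation]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["trial_animal_id"]), []).append(
            ExcretionObservation(
                trial_animal_id=str(row["trial_animal_id"]),
                interval_start=float(row["interval_start_h"]),
                interval_end=float(row["interval_end_h"]),
                marker_amount=float(row["marker_amount"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# logistic model


def logistic_cdf(t, t50: float, s: float, asymptote: float = 1.0):
    """Cumulative defecation probability A / (1 + exp(-(t - t50)/s))."""
    if s <= 0:
        raise GutPassageError("scale s must be positive")
    if not (0 < asymptote <= 1.0):
        raise GutPassageError("asymptote must be in (0, 1]")
    t = np.asarray(t, dtype=float)
    # numerically safe on both tails
    z = (t - t50) / s
    out = asymptote * 0.5 * (1.0 + np.tanh(z / 2.0))
    return float(out) if out.ndim == 0 else out


class GutPassageModel:
    """Logistic gut-passage model for one cumulative excretion curve.

    Parameters
    ----------
    curve : CumulativeExcretionCurve
        Cumulative proportion of marker spores defecated over time.
    window_hours : float
        Upper support bound used downstream when weighting displacements
        (the maximum observed ingestion-to-defecation time).

    ``fit`` returns a :class:`GutPassageResults`.
    """

    #: restart jitter applied to the initial values on failed convergence
    N_RESTARTS = 5

    def __init__(self, curve: CumulativeExcretionCurve, window_hours: float = 69.0):
        self.curve = curve
        self.window_hours = float(window_hours)

    @classmethod
    def from_observations(
        cls, observations: Sequence[ExcretionObservation], window_hours: float = 69.0
    ) -> "GutPassageModel":
        return cls(build_curve(observations), window_hours=window_hours)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, trial_animal_id: str | None = None,
                       window_hours: float = 69.0) -> "GutPassageModel":
        groups = read_excretion_csv(df)
        if trial_animal_id is None:
            if len(groups) != 1:
                raise GutPassageError(
                    f"dataframe holds {len(groups)} trial animals; pass trial_animal_id"
                )
            trial_animal_id = next(iter(groups))
        return cls.from_observations(groups[trial_animal_id], window_hours=window_hours)

    # -- initialisation ----------------------------------------------------

    def _initial_values(self, rng: np.random.Generator | None = None) -> tuple[float, float]:
        t = self.curve.times
        c = self.curve.cum_prop
        t50 = _crossing_time(t, c, 0.5)
        t25 = _crossing_time(t, c, 0.25)
        t75 = _crossing_time(t, c, 0.75)
        s = max((t75 - t25) / (2.0 * np.log(3.0)), 1e-3)
        if rng is not None:
            t50 = t50 * rng.uniform(0.7, 1.3)
            s = s * rng.uniform(0.5, 2.0)
        return float(t50), float(s)

    # -- fitting -----------------------------------------------------------

    def fit(self, fix_asymptote: bool = True, time_basis: str = "auto") -> "GutPassageResults":
        """Nonlinear least squares on the cumulative proportions.

        time_basis : {"auto", "midpoint", "interval_end"}
            Where the model is evaluated.  Curves built from interval
            observations carry interval ends; the cumulative count through
            interval k measures C at that interval's end, so "auto" uses the
            ends when available (removing the half-interval discretisation
            bias of the midpoint convention) and the stated times otherwise.
        """
        if time_basis not in ("auto", "midpoint", "interval_end"):
            raise ValueError(f"unknown time_basis {time_basis!r}")
        if time_basis == "interval_end" and self.curve.interval_ends is None:
            raise GutPassageError("curve has no interval ends")
        if time_basis == "auto":
            time_basis = "interval_end" if self.curve.interval_ends is not None else "midpoint"
        t = (self.curve.interval_ends if time_basis == "interval_end"
             else self.curve.times)
        y = self.curve.cum_prop
        if np.unique(y).size < 3:
            raise GutPassageError("need >= 3 distinct cumulative values to fit")

        def resid(theta):
            if fix_asymptote:
                t50, s = theta
                a = 1.0
            else:
                t50, s, a = theta
            return logistic_cdf(t, t50, s, a) - y

        lo = [0.0, 1e-6] + ([] if fix_asymptote else [1e-6])
        hi = [10.0 * self.window_hours, 10.0 * self.window_hours] + ([] if fix_asymptote else [1.0])

        rng = np.random.default_rng(0)
        best = None
        for attempt in range(1 + self.N_RESTARTS):
            t50_0, s_0 = self._initial_values(rng if attempt else None)
            x0 = [min(max(t50_0, lo[0]), hi[0]), min(max(s_0, lo[1]), hi[1])]
            if not fix_asymptote:
                x0.append(1.0 - 1e-9)
            try:
                res = least_squares(resid, x0, bounds=(lo, hi), method="trf")
            except Exception:  # pragma: no cover - scipy internal failure
                continue
            rss = float(2.0 * res.cost)
            if best is None or rss < best[0]:
                best = (rss, res)
            if res.success and rss <= best[0] + 1e-15:
                break
        if best is None or not best[1].success:
            params = {} if best is None else _unpack(best[1].x, fix_asymptote)
            raise FitConvergenceError(
                f"logistic fit did not converge for {self.curve.trial_animal_id}",
                params=params,
                rss=float("inf") if best is None else best[0],
            )
        rss, res = best
        params = _unpack(res.x, fix_asymptote)
        bse = _standard_errors(res, len(y))
        return GutPassageResults(
            model=self,
            t50=params["t50"],
            s=params["s"],
            asymptote=params.get("asymptote", 1.0),
            rss=rss,
            converged=bool(res.success),
            bse=bse,
            time_basis=time_basis,
            nobs=len(y),
        )


def _unpack(x, fix_asymptote: bool) -> dict:
    d = {"t50": float(x[0]), "s": float(x[1])}
    if not fix_asymptote:
        d["asymptote"] = float(x[2])
    return d


def _standard_errors(res, nobs: int) -> dict:
    """Asymptotic SEs from the least-squares Jacobian; NaN when singular."""
    p = res.x.size
    names = ["t50", "s", "asymptote"][:p]
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * (2.0 * res.cost) / max(nobs - p, 1)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, (float(v) for v in se)))


def _crossing_time(t: np.ndarray, c: np.ndarray, level: float) -> float:
    """Linearly interpolated first crossing of cum_prop = level."""
    above = np.nonzero(c >= level)[0]
    if above.size == 0:
        return float(t[-1])
    i = int(above[0])
    if i == 0 or c[i] == c[i - 1]:
        return float(t[i])
    w = (level - c[i - 1]) / (c[i] - c[i - 1])
    return float(t[i - 1] + w * (t[i] - t[i - 1]))


@dataclass
class GutPassageResults:
    """Fitted logistic gut-passage curve and its diagnostics."""

    model: GutPassageModel
    t50: float  # hours to 50% cumulative defecation
    s: float  # logistic scale, hours
    asymptote: float
    rss: float
    converged: bool
    bse: dict
    time_basis: str
    nobs: int

    @property
    def params(self) -> dict:
        return {"t50": self.t50, "s": self.s, "asymptote": self.asymptote}

    @property
    def window_hours(self) -> float:
        return self.model.window_hours

    @property
    def trial_animal_id(self) -> str:
        return self.model.curve.trial_animal_id

    def predict(self, t) -> np.ndarray | float:
        """Cumulative defecation probability C(t)."""
        return logistic_cdf(t, self.t50, self.s, self.asymptote)

    def summary(self) -> str:
        lines = [
            "Logistic gut-passage fit",
            "=" * 40,
            f"trial animal:       {self.trial_animal_id}",
            f"n points:           {self.nobs}",
            f"time basis:         {self.time_basis}",
            f"converged:          {self.converged}",
            f"RSS:                {self.rss:.6g}",
            "-" * 40,
            f"t50 (h):            {self.t50:.4f}  (SE {self.bse.get('t50', float('nan')):.4f})",
            f"s (h):              {self.s:.4f}  (SE {self.bse.get('s', float('nan')):.4f})",
            f"asymptote:          {self.asymptote:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "trial_animal_id": self.trial_animal_id,
            "t50_h": self.t50,
            "s_h": self.s,
            "asymptote": self.asymptote,
            "rss": self.rss,
            "converged": self.converged,
            "bse": self.bse,
            "time_basis": self.time_basis,
            "nobs": self.nobs,
            "window_hours": self.window_hours,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "GutPassageResults":
        """Rebuild a results object from :meth:`to_dict` output (no curve)."""
        curve = CumulativeExcretionCurve(
            trial_animal_id=d["trial_animal_id"],
            times=np.array([0.0, d["t50_h"], 2 * d["t50_h"] + 1.0]),
            cum_prop=np.array([0.0, 0.5, 1.0]),
        )
        model = GutPassageModel(curve, window_hours=d.get("window_hours", 69.0))
        return cls(
            model=model, t50=d["t50_h"], s=d["s_h"],
            asymptote=d.get("asymptote", 1.0), rss=d.get("rss", float("nan")),
            converged=d.get("converged", True), bse=d.get("bse", {}),
            time_basis=d.get("time_basis", "interval_end"), nobs=d.get("nobs", 0),
        )


# ---------------------------------------------------------------------------
# defecation weights


def defecation_weights(
    results,
    offsets: np.ndarray,
    renormalize: bool = True,
    residual: str = "renormalize",
    weighting: str = "increment",
) -> np.ndarray:
    """Defecation-probability mass at each fix offset.

    The weight at offset_i is the increment C(offset_i) - C(offset_{i-1}) of
    the fitted cumulative curve, with the value before the first offset taken
    as C(0): spores are treated as excreted at the observed fix times.  With
    ``renormalize`` the weights are scaled to total exactly 1 within the
    window (the default); ``residual="assign_endpoints"`` instead adds the
    mass before the first offset to the first weight and the mass beyond the
    last offset to the last.  ``weighting="cumulative"`` is a diagnostic mode
    using the cumulative value itself (renormalised) rather than its
    increment.

    ``results`` may be a :class:`GutPassageResults` or any object with
    ``predict`` and ``window_hours``.
    """
    offsets = np.asarray(offsets, dtype=float)
    if offsets.size == 0:
        raise GutPassageError("offsets must be nonempty")
    if np.any(np.diff(offsets) <= 0):
        raise GutPassageError("offsets must be strictly increasing")
    w_max = getattr(results, "window_hours", None)
    if w_max is not None and (offsets[0] < -1e-9 or offsets[-1] > w_max + 1e-9):
        raise GutPassageError(
            f"offsets must lie within [0, {w_max}] h; got "
            f"[{offsets[0]}, {offsets[-1]}]"
        )
    c = np.asarray(results.predict(offsets), dtype=float).reshape(-1)
    if weighting == "cumulative":
        w = c.copy()
    elif weighting == "increment":
        prev = np.concatenate(([float(results.predict(0.0))], c[:-1]))
        w = c - prev
        if residual == "assign_endpoints":
            w[0] += float(results.predict(0.0))
            w[-1] += results.asymptote - c[-1]
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = np.maximum(w, 0.0)
    if renormalize:
        total = w.sum()
        if total <= 0:
            # degenerate window (no probability mass moves within it):
            # spread the unit mass uniformly over the observed fixes
            return np.full(offsets.size, 1.0 / offsets.size)
        w = w / total
    return w
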
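"""Dispersal distance kernels: weighted distance distributions and summaries.

A dispersal kernel here is a discrete probability distribution over
straight-line distances from the point of spore ingestion: a *support* of
distances (metres) with matching probability *masses* summing to 1.  One
kernel arises per (ingestion window, gut-passage model) pair — the window's
displacements weighted by the model's defecation-probability masses — and
kernels are aggregated by equal-weight mixing: the two trial animals' gut
models are averaged within each window, windows are averaged within each
tracked animal, and animals are averaged into the overall kernel (each
animal contributing 1/n regardless of how many windows it has).

Quantiles use the lower weighted-empirical convention: the smallest support
value whose cumulative mass reaches the requested probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gut_passage import defecation_weights
from .telemetry import IngestionWindow

#: tolerance on probability-mass sums and CDF comparisons
MASS_TOL = 1e-9


class KernelError(ValueError):
    """Invalid kernel construction or aggregation."""


class DispersalKernel:
    """Weighted sample of dispersal distances.

    Parameters
    ----------
    support : array of distances, metres, finite and nonnegative
    mass : matching array of probabilities, nonnegative, summing to 1
    label : provenance tag (window / animal / overall identifier)
    """

    def __init__(self, support, mass, label: str = ""):
        support = np.asarray(support, dtype=float)
        mass = np.asarray(mass, dtype=float)
        if support.size == 0 or support.size != mass.size:
            raise KernelError("support and mass must be nonempty and equal length")
        if not np.all(np.isfinite(support)) or np.any(support < 0):
            raise KernelError("support must be finite and nonnegative")
        if np.any(mass < -MASS_TOL):
            raise KernelError("masses must be nonnegative")
        total = float(mass.sum())
        if abs(total - 1.0) > MASS_TOL:
            raise KernelError(f"masses sum to {total!r}, not 1")
        order = np.argsort(support, kind="mergesort")
        self.support = support[order]
        self.mass = np.maximum(mass[order], 0.0)
        self.label = label
        self._cum = np.cumsum(self.mass)

    def __len__(self) -> int:
        return int(self.support.size)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"DispersalKernel(label={self.label!r}, n={len(self)}, "
                f"median={self.quantile(0.5):.1f} m)")

    # -- summaries ---------------------------------------------------------

    def quantile(self, q: float) -> float:
        """Smallest distance d with CDF(d) >= q (lower convention)."""
        if not (0.0 < q < 1.0):
            raise ValueError("q must be strictly inside (0, 1)")
        idx = int(np.searchsorted(self._cum, q - MASS_TOL, side="left"))
        idx = min(idx, len(self) - 1)
        return float(self.support[idx])

    def quantiles(self, probs: Sequence[float]) -> np.ndarray:
        return np.array([self.quantile(q) for q in probs])

    def cdf(self, d) -> np.ndarray | float:
        """P(distance <= d), evaluated at scalar or array d."""
        d = np.asarray(d, dtype=float)
        idx = np.searchsorted(self.support, d, side="right")
        cum = np.concatenate(([0.0], self._cum))
        out = cum[idx]
        return float(out) if out.ndim == 0 else out

    def max_distance(self, mass_floor: float = 0.0) -> float:
        """Largest support value carrying mass above ``mass_floor``."""
        carrying = self.mass > mass_floor
        if not carrying.any():
            raise KernelError("no support point carries mass above the floor")
        return float(self.support[np.nonzero(carrying)[0][-1]])

    def binned_density(self, bin_width: float = 25.0) -> pd.DataFrame:
        """Masses aggregated into half-open bins [k*w, (k+1)*w).

        Returns a DataFrame with bin_left, bin_center and probability
        columns; probabilities sum to 1 and empty interior bins are kept so
        the table forms a regular grid.
        """
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        k = np.floor(self.support / bin_width).astype(int)
        n_bins = int(k.max()) + 1
        probs = np.bincount(k, weights=self.mass, minlength=n_bins)
        left = np.arange(n_bins) * bin_width
        return pd.DataFrame({
            "bin_left": left,
            "bin_center": left + bin_width / 2.0,
            "probability": probs,
        })

    def compress(self) -> "DispersalKernel":
        """Merge duplicate support values (CDF-preserving)."""
        uniq, inv = np.unique(self.support, return_inverse=True)
        mass = np.bincount(inv, weights=self.mass)
        return DispersalKernel(uniq, mass, label=self.label)

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_m": self.support, "mass": self.mass})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "DispersalKernel":
        df = pd.read_csv(path)
        if "distance_m" not in df.columns or "mass" not in df.columns:
            raise KernelError(f"kernel file {path} lacks distance_m/mass columns")
        return cls(df["distance_m"].to_numpy(), df["mass"].to_numpy(), label=label)

    @classmethod
    def point_mass(cls, distance: float, label: str = "") -> "DispersalKernel":
        return cls([distance], [1.0], label=label)


@dataclass(frozen=True)
class KernelSummary:
    """Quantiles and extremes of a dispersal kernel."""

    quantiles: dict  # probability -> metres
    max_distance: float
    n_windows: int
    n_animals: int

    def __post_init__(self) -> None:
        qs = [self.quantiles[p] for p in sorted(self.quantiles)]
        if any(b < a for a, b in zip(qs, qs[1:])):
            raise KernelError("quantiles must be nondecreasing in probability")

    def to_dict(self) -> dict:
        return {
            "quantiles_m": {f"{p:g}": v for p, v in sorted(self.quantiles.items())},
            "max_distance_m": self.max_distance,
            "n_windows": self.n_windows,
            "n_animals": self.n_animals,
        }


# ---------------------------------------------------------------------------
# construction and aggregation


def window_kernel(
    window: IngestionWindow,
    gut_results,
    renormalize: bool = True,
    residual: str = "renormalize",
    weighting: str = "increment",
) -> DispersalKernel:
    """Kernel for one ingestion window under one gut-passage model.

    Support is the window's displacement at each fix; mass is the fitted
    cumulative curve's defecation-probability increment between consecutive
    fixes (renormalised within the window by default).
    """
    mass = defecation_weights(
        gut_results, window.offsets, renormalize=renormalize,
        residual=residual, weighting=weighting,
    )
    if not renormalize:
        total = mass.sum()
        if total <= 0:
            raise KernelError("window carries no defecation mass")
        mass = mass / total
    label = (f"window:{window.animal_id}/{window.period_id}"
             f"@{np.datetime_as_string(window.anchor_time, unit='m')}"
             f"|gut:{getattr(gut_results, 'trial_animal_id', '?')}")
    return DispersalKernel(window.distances, mass, label=label)


def mix_kernels(
    kernels: Sequence[DispersalKernel],
    weights: Sequence[float] | None = None,
    label: str = "mixture",
) -> DispersalKernel:
    """Finite mixture of kernels (equal weights unless supplied)."""
    if len(kernels) == 0:
        raise KernelError("need at least one kernel to mix")
    if weights is None:
        weights = np.full(len(kernels), 1.0 / len(kernels))
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.size != len(kernels):
            raise KernelError("weight count does not match kernel count")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise KernelError("mixture weights must be nonnegative, not all zero")
        weights = weights / weights.sum()
    support = np.concatenate([k.support for k in kernels])
    mass = np.concatenate([w * k.mass for w, k in zip(weights, kernels)])
    return DispersalKernel(support, mass, label=label)


def animal_kernel(
    windows: Sequence[IngestionWindow],
    gut_models: Sequence,
    animal_id: str | None = None,
    **window_kw,
) -> DispersalKernel:
    """Per-animal kernel: gut models mixed within each window, windows mixed
    with equal weight across the animal's tracking periods."""
    if len(windows) == 0:
        raise KernelError("animal has no admissible ingestion windows")
    if len(gut_models) == 0:
        raise KernelError("need at least one gut-passage model")
    if animal_id is None:
        animal_id = windows[0].animal_id
    per_window = [
        mix_kernels([window_kernel(w, g, **window_kw) for g in gut_models],
                    label=f"window-mean:{w.animal_id}/{w.period_id}")
        for w in windows
    ]
    mixed = mix_kernels(per_window, label=f"animal:{animal_id}")
    return mixed


def overall_kernel(animal_kernels: Sequence[DispersalKernel]) -> DispersalKernel:
    """Equal-weight mixture across animals (1/n each, regardless of window
    counts), matching a mean over tracked individuals."""
    return mix_kernels(list(animal_kernels), label="overall")


def kernel_max(kernels: Iterable[DispersalKernel], mass_floor: float = 0.0) -> float:
    """Maximum distance carrying mass above the floor, across kernels."""
    kernels = list(kernels)
    if not kernels:
        raise KernelError("need at least one kernel")
    return max(k.max_distance(mass_floor) for k in kernels)


def across_animal_band(
    animal_kernels: Sequence[DispersalKernel],
    level: float = 0.50,
    bin_width: float = 25.0,
) -> pd.DataFrame:
    """Mean and central-``level`` envelope of per-animal binned densities.

    The per-animal kernels are binned on a common distance grid; at each bin
    the mean probability across animals is reported together with the lower
    and upper quantiles of the animal values (outward-rounding empirical
    quantiles, so with two animals the band spans both values).
    """
    if len(animal_kernels) < 2:
        raise KernelError("band needs at least two animal kernels")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be inside (0, 1)")
    tables = [k.binned_density(bin_width) for k in animal_kernels]
    n_bins = max(len(t) for t in tables)
    probs = np.zeros((len(tables), n_bins))
    for i, t in enumerate(tables):
        probs[i, : len(t)] = t["probability"].to_numpy()
    left = np.arange(n_bins) * bin_width
    lo_q, hi_q = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    mean = probs.mean(axis=0)
    # the envelope always brackets the mean curve, even when the animal
    # values are skewed enough that the mean falls outside the raw
    # interquantile range
    lower = np.minimum(np.quantile(probs, lo_q, axis=0, method="lower"), mean)
    upper = np.maximum(np.quantile(probs, hi_q, axis=0, method="higher"), mean)
    return pd.DataFrame({
        "bin_left": left,
        "bin_center": left + bin_width / 2.0,
        "mean": mean,
        "lower": lower,
        "upper": upper,
    })
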
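"""End-to-end spore-dispersal model: telemetry + gut passage -> kernel.

:class:`SporeDispersalModel` holds the cleaned tracks and the fitted
gut-passage curves; :meth:`SporeDispersalModel.fit` extracts every
admissible ingestion window, builds per-animal and overall dispersal
kernels, and returns a :class:`SporeDispersalResults` carrying the kernels,
their quantile summaries and diagnostics.

Procedure (per tracking period): discard the first 60 min after handling,
take every fix with at least 69 h of track remaining as a hypothetical
ingestion point, compute straight-line displacement from that point at each
subsequent fix, weight each displacement by the fitted probability of
defecation in the interval ending at that fix, average the two trial
animals' gut curves per window, average windows per tracked animal, and
average animals into the overall kernel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import telemetry as tlm
from .gut_passage import (
    GutPassageModel,
    GutPassageResults,
    read_excretion_csv,
)
from .kernel import (
    DispersalKernel,
    KernelSummary,
    across_animal_band,
    animal_kernel,
    kernel_max,
    mix_kernels,
    window_kernel,
)

logger = logging.getLogger(__name__)

DEFAULT_QUANTILES = (0.25, 0.50, 0.75, 0.95)


class SporeDispersalModel:
    """Dispersal-kernel model for spores carried by a tracked mycophagist.

    Parameters
    ----------
    tracks : sequence of Track
        Raw telemetry, one per tracking period.
    gut_results : sequence of GutPassageResults
        Fitted gut-passage curves (one per feeding-trial animal); their
        predictions are averaged per window.
    window_hours : float
        Maximum ingestion-to-defecation time; displacements beyond it carry
        no spore mass.
    warmup_min : float
        Post-handling minutes discarded from the start of each period.
    min_span_fraction : float
        Fraction of ``window_hours`` a track must extend past an anchor fix
        for the window to be admitted.
    weighting, renormalize, residual
        Passed to the window-kernel construction (see
        :func:`sporekernel.gut_passage.defecation_weights`).
    """

    def __init__(
        self,
        tracks: Sequence[tlm.Track],
        gut_results: Sequence[GutPassageResults],
        window_hours: float = 69.0,
        warmup_min: float = 60.0,
        min_span_fraction: float = 1.0,
        weighting: str = "increment",
        renormalize: bool = True,
        residual: str = "renormalize",
    ):
        if not tracks:
            raise ValueError("need at least one track")
        if not gut_results:
            raise ValueError("need at least one fitted gut-passage model")
        self.tracks = list(tracks)
        self.gut_results = list(gut_results)
        self.window_hours = float(window_hours)
        self.warmup_min = float(warmup_min)
        self.min_span_fraction = float(min_span_fraction)
        self.weighting = weighting
        self.renormalize = renormalize
        self.residual = residual

    @classmethod
    def from_csv(
        cls,
        telemetry_path,
        excretion_path,
        column_map: Mapping[str, str] | None = None,
        fix_asymptote: bool = True,
        **kwargs,
    ) -> "SporeDispersalModel":
        """Build the model from a telemetry CSV and an excretion CSV,
        fitting one logistic gut-passage curve per trial animal."""
        tracks = tlm.read_tracks(telemetry_path, column_map=column_map)
        window_hours = float(kwargs.get("window_hours", 69.0))
        groups = read_excretion_csv(excretion_path)
        gut = [
            GutPassageModel.from_observations(obs, window_hours=window_hours)
            .fit(fix_asymptote=fix_asymptote)
            for obs in groups.values()
        ]
        return cls(tracks, gut, **kwargs)

    # ------------------------------------------------------------------

    def fit(self) -> "SporeDispersalResults":
        """Run the pipeline and return the fitted kernels."""
        window_kw = dict(
            renormalize=self.renormalize,
            residual=self.residual,
            weighting=self.weighting,
        )
        windows_by_animal: dict[str, list] = {}
        windows_by_period: dict[tuple[str, str], int] = {}
        cleaned: list[tlm.Track] = []
        for track in self.tracks:
            try:
                ct = tlm.clean_track(track, warmup_min=self.warmup_min)
            except tlm.EmptyTrackError:
                logger.warning(
                    "period %s/%s skipped: empty after warm-up",
                    track.animal_id, track.period_id,
                )
                continue
            cleaned.append(ct)
            wins = tlm.extract_windows(
                ct, window_hours=self.window_hours,
                min_span_fraction=self.min_span_fraction,
            )
            windows_by_period[(ct.animal_id, ct.period_id)] = len(wins)
            if not wins:
                logger.warning(
                    "period %s/%s too short for any %g-h window",
                    ct.animal_id, ct.period_id, self.window_hours,
                )
                continue
            windows_by_animal.setdefault(ct.animal_id, []).extend(wins)

        if not windows_by_animal:
            raise ValueError("no admissible ingestion windows in any track")

        animal_kernels: dict[str, DispersalKernel] = {}
        window_kernels: list[DispersalKernel] = []
        for animal, wins in sorted(windows_by_animal.items()):
            animal_kernels[animal] = animal_kernel(
                wins, self.gut_results, animal_id=animal, **window_kw
            )
            for w in wins:
                for g in self.gut_results:
                    window_kernels.append(window_kernel(w, g, **window_kw))

        overall = mix_kernels(
            [animal_kernels[a] for a in sorted(animal_kernels)], label="overall"
        ).compress()

        return SporeDispersalResults(
            model=self,
            overall=overall,
            animal_kernels=animal_kernels,
            window_kernels=window_kernels,
            windows_per_period=windows_by_period,
            cleaned_tracks=cleaned,
        )


@dataclass
class SporeDispersalResults:
    """Fitted dispersal kernels with summaries and diagnostics."""

    model: SporeDispersalModel
    overall: DispersalKernel
    animal_kernels: dict
    window_kernels: list
    windows_per_period: dict
    cleaned_tracks: list

    @property
    def n_windows(self) -> int:
        return int(sum(self.windows_per_period.values()))

    @property
    def n_animals(self) -> int:
        return len(self.animal_kernels)

    def quantile(self, q: float) -> float:
        """Overall-kernel distance quantile (metres, lower convention)."""
        return self.overall.quantile(q)

    def quantiles(self, probs: Sequence[float] = DEFAULT_QUANTILES) -> dict:
        return {float(p): self.overall.quantile(p) for p in probs}

    def max_distance(self, mass_floor: float = 0.0) -> float:
        """Maximum predicted dispersal distance across all windows."""
        return kernel_max(self.window_kernels, mass_floor=mass_floor)

    def summary_stats(self, probs: Sequence[float] = DEFAULT_QUANTILES) -> KernelSummary:
        return KernelSummary(
            quantiles=self.quantiles(probs),
            max_distance=self.max_distance(),
            n_windows=self.n_windows,
            n_animals=self.n_animals,
        )

    def band(self, level: float = 0.50, bin_width: float = 25.0) -> pd.DataFrame:
        """Across-animal mean density with a central-``level`` envelope."""
        kernels = [self.animal_kernels[a] for a in sorted(self.animal_kernels)]
        return across_animal_band(kernels, level=level, bin_width=bin_width)

    def mean_displacement_curve(self) -> pd.DataFrame:
        """Diagnostic: defecation-weighted mean displacement per animal.

        Collapses each animal's kernel to its expected distance — a single
        number, not the kernel — mirroring a literal mean-displacement
        reading of the aggregation.
        """
        rows = [
            {"animal_id": a,
             "mean_weighted_displacement_m": float((k.support * k.mass).sum())}
            for a, k in sorted(self.animal_kernels.items())
        ]
        return pd.DataFrame(rows)

    def summary(self, probs: Sequence[float] = DEFAULT_QUANTILES) -> str:
        s = self.summary_stats(probs)
        lines = [
            "Spore dispersal kernel",
            "=" * 46,
            f"animals:                 {s.n_animals}",
            f"tracking periods:        {len(self.windows_per_period)}",
            f"ingestion windows:       {s.n_windows}",
            f"gut-passage curves:      {len(self.model.gut_results)}",
            f"window length (h):       {self.model.window_hours:g}",
            "-" * 46,
        ]
        for p in sorted(s.quantiles):
            lines.append(f"{100 * p:5.1f}% of spores within   {s.quantiles[p]:10.1f} m")
        lines.append(f"maximum distance:        {s.max_distance:10.1f} m")
        return "\n".join(lines)

    # -- output ---------------------------------------------------------

    def save(self, outdir, bin_width: float = 25.0,
             probs: Sequence[float] = DEFAULT_QUANTILES) -> None:
        """Write kernels, summary, density, CDF and band tables to a dir."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.overall.to_csv(out / "overall_kernel.csv")
        for a, k in sorted(self.animal_kernels.items()):
            k.compress().to_csv(out / f"kernel_animal_{a}.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary_stats(probs).to_dict(), fh, indent=2)
        self.overall.binned_density(bin_width).to_csv(
            out / "overall_density.csv", index=False
        )
        cdf = self.overall.to_frame()
        cdf["cdf"] = np.cumsum(cdf["mass"].to_numpy())
        cdf.to_csv(out / "overall_cdf.csv", index=False)
        if self.n_animals >= 2:
            self.band(bin_width=bin_width).to_csv(out / "band.csv", index=False)

    def plot_density(self, ax=None, bin_width: float = 25.0):
        from .plotting import plot_density

        return plot_density(self, ax=ax, bin_width=bin_width)

    def plot_cdf(self, ax=None, probs: Sequence[float] = DEFAULT_QUANTILES):
        from .plotting import plot_cdf

        return plot_cdf(self, ax=ax, probs=probs)
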
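"""Monte-Carlo population viability analysis (depletion risk).

Starting each population at the average density observed at its location,
trajectories are stepped forward with the fitted stochastic map for a fixed
horizon.  Because the locations are open to immigration, falling below a
threshold is a (possibly temporary) *depletion*, not an absorbing
extinction: runs continue after crossing and only the first crossing is
recorded.  For each threshold c the depletion probability is the fraction
of runs whose density fell below c at least once, and the expected time to
depletion is the mean first-crossing year over those runs (undefined when
no run crossed).  A run that starts at or below the threshold is depleted
at time 0 by definition.

Two ensemble modes combine the top-m models of a ranking:
``average`` (default) steps with the AICc-weighted mean deterministic map
and the weighted-mean σ; ``sample`` draws one member model per run with
probability equal to its renormalized weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import FitResult
from .forms import _det_step
from .inference import ModelRanking, top_models

__all__ = ["PVAConfig", "PVAResult", "run_pva", "default_threshold_grid"]


def default_threshold_grid(n: int = 25) -> np.ndarray:
    """Logarithmic grid of depletion thresholds, 1e-4 to 1e-1 ind./m²."""
    return np.logspace(-4, -1, n)


@dataclass
class PVAConfig:
    """Settings for a viability analysis.

    ``ensemble`` is either a single :class:`FitResult` or a
    :class:`ModelRanking` (the ``top_m`` best members are averaged).
    ``initial_density`` maps each location to its starting density
    (typically the mean of the observed annual means).
    """

    ensemble: FitResult | ModelRanking
    initial_density: Mapping[str, float]
    thresholds: np.ndarray = field(default_factory=default_threshold_grid)
    horizon: int = 100
    n_sims: int = 100_000
    top_m: int = 3
    mode: str = "average"  # or "sample"
    seed: int | None = 0

    def members(self) -> list[tuple[FitResult, float]]:
        if isinstance(self.ensemble, ModelRanking):
            return top_models(self.ensemble, self.top_m)
        return [(self.ensemble, 1.0)]

    def validate(self) -> None:
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.size == 0:
            raise ValueError("threshold grid is empty")
        if np.any(thr < 0) or np.any(np.diff(thr) <= 0):
            raise ValueError("thresholds must be non-negative and strictly increasing")
        if self.horizon < 1 or self.n_sims < 1:
            raise ValueError("horizon and n_sims must be >= 1")
        if self.mode not in ("average", "sample"):
            raise ValueError(f"unknown ensemble mode {self.mode!r}")
        locs = set(self.members()[0][0].config.locations)
        missing = set(self.initial_density) - locs
        if missing:
            raise ValueError(f"ensemble does not cover location(s) {sorted(missing)}")


@dataclass
class PVAResult:
    """Depletion probability and conditional expected time per threshold."""

    frame: pd.DataFrame  # location, threshold, probability, expected_time, n_depleted
    n_sims: int
    horizon: int
    seed: int | None

    def probability(self, location: str) -> pd.Series:
        sub = self.frame[self.frame["location"] == location]
        return sub.set_index("threshold")["probability"]

    def expected_time(self, location: str) -> pd.Series:
        sub = self.frame[self.frame["location"] == location]
        return sub.set_index("threshold")["expected_time"]

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["n_sims"] = self.n_sims
        out["seed"] = self.seed
        out.to_csv(path, index=False)


def _location_members(members, location):
    """Per-member (form, params, sigma, weight) tuples for one location."""
    out = []
    for fit, w in members:
        out.append(
            (
                fit.config.form_at(location),
                fit.location_params(location),
                fit.sigma(location),
                w,
            )
        )
    return out


def run_pva(config: PVAConfig) -> PVAResult:
    """Run the Monte-Carlo viability analysis. Deterministic given ``seed``."""
    config.validate()
    thr = np.asarray(config.thresholds, dtype=float)
    members = config.members()
    rng = np.random.default_rng(config.seed)
    records = []
    for location in sorted(config.initial_density):
        n0 = float(config.initial_density[location])
        if n0 < 0:
            raise ValueError(f"negative initial density at {location!r}")
        parts = _location_members(members, location)
        n = np.full(config.n_sims, n0)
        if config.mode == "sample":
            member_of_run = rng.choice(
                len(parts), size=config.n_sims, p=[w for *_, w in parts]
            )
        # first-crossing time per (threshold, run); -1 = not yet crossed
        first = np.full((len(thr), config.n_sims), -1, dtype=np.int32)
        first[thr >= n0, :] = 0  # at/below threshold from the start
        for t in range(1, config.horizon + 1):
            if config.mode == "average":
                pred = np.zeros_like(n)
                sig = 0.0
                for form, params, sigma, w in parts:
                    pred += w * _det_step(form, params, n)
                    sig += w * sigma
                n = np.maximum(0.0, pred + rng.normal(0.0, sig, size=n.shape))
            else:
                pred = np.empty_like(n)
                sig = np.empty_like(n)
                for j, (form, params, sigma, _) in enumerate(parts):
                    mask = member_of_run == j
                    if mask.any():
                        pred[mask] = _det_step(form, params, n[mask])
                        sig[mask] = sigma
                n = np.maximum(0.0, pred + sig * rng.normal(size=n.shape))
            newly = (first < 0) & (n[None, :] < thr[:, None])
            first[newly] = t
        depleted = first >= 0
        n_dep = depleted.sum(axis=1)
        prob = n_dep / config.n_sims
        with np.errstate(invalid="ignore"):
            exp_time = np.array(
                [
                    float(np.mean(first[i][depleted[i]])) if n_dep[i] else np.nan
                    for i in range(len(thr))
                ]
            )
        for i, c in enumerate(thr):
            records.append(
                {
                    "location": location,
                    "threshold": float(c),
                    "probability": float(prob[i]),
                    "expected_time": exp_time[i],
                    "n_depleted": int(n_dep[i]),
                }
            )
    return PVAResult(
        frame=pd.DataFrame(records),
        n_sims=config.n_sims,
        horizon=config.horizon,
        seed=config.seed,
    )
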
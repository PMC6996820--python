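"""Stratified bootstrap of transects for parameter uncertainty.

Each (location, year) stratum is resampled with replacement at its own
size, independently of the other strata; the resampled survey is aggregated
to annual means and the model refitted.  Repeating B times yields an
empirical distribution per parameter that folds census error and local
spatial variability into the estimates.  Central tendency is reported as
the median (less sensitive than the mean to the extreme refits bootstrap
can produce); spread as SD, IQR and the empirical 5th–95th percentile 90%
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import fit_config
from .data import SurveyDataset, annual_means
from .model_space import ModelConfig

__all__ = ["BootstrapDistribution", "stratified_resample", "bootstrap_fit"]


def stratified_resample(
    data: SurveyDataset, rng: np.random.Generator | int | None = None
) -> SurveyDataset:
    """Resample transects with replacement within every (location, year) stratum.

    Each stratum keeps its original size; strata are independent.
    Resampled rows get fresh transect ids (``b0``, ``b1``, ...) so the
    uniqueness invariant holds even when a transect is drawn twice.
    Deterministic given ``rng``.
    """
    gen = np.random.default_rng(rng)
    frames = []
    for (loc, year), dens in data.strata():
        m = len(dens)
        pick = gen.integers(0, m, size=m)
        frames.append(
            pd.DataFrame(
                {
                    "location": loc,
                    "year": year,
                    "transect_id": [f"b{i}" for i in range(m)],
                    "density": dens[pick],
                }
            )
        )
    return SurveyDataset(pd.concat(frames, ignore_index=True))


@dataclass
class BootstrapDistribution:
    """Empirical bootstrap distribution of a config's parameter estimates."""

    config: ModelConfig
    samples: dict[str, np.ndarray]
    n_failed: int = 0
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def B(self) -> int:
        return len(next(iter(self.samples.values())))

    def summary(self) -> pd.DataFrame:
        """Per-parameter mean ± SD, median, IQR and 90% CI (5th–95th pct)."""
        rows = {}
        for name, s in self.samples.items():
            q5, q25, med, q75, q95 = np.percentile(s, [5, 25, 50, 75, 95])
            rows[name] = {
                "mean": float(np.mean(s)),
                "sd": float(np.std(s, ddof=1)) if len(s) > 1 else 0.0,
                "median": float(med),
                "iqr": float(q75 - q25),
                "ci90_low": float(q5),
                "ci90_high": float(q95),
            }
        return pd.DataFrame(rows).T

    def ci90(self, name: str) -> tuple[float, float]:
        lo, hi = np.percentile(self.samples[name], [5, 95])
        return float(lo), float(hi)

    def to_frame(self) -> pd.DataFrame:
        """Long table (replicate, parameter, estimate)."""
        recs = []
        for name, s in self.samples.items():
            for b, v in enumerate(s):
                recs.append({"replicate": b, "parameter": name, "estimate": v})
        return pd.DataFrame(recs)


def bootstrap_fit(
    data: SurveyDataset,
    config: ModelConfig,
    B: int = 1000,
    seed: int | None = 0,
    n_starts: int = 4,
    max_failure_rate: float = 0.10,
    reselect_among: list[ModelConfig] | None = None,
) -> BootstrapDistribution:
    """Refit ``config`` to ``B`` stratified resamples of the survey.

    Failed refits are dropped and counted; more than
    ``max_failure_rate · B`` failures raises (an ill-posed config/data
    combination should not be summarized silently).

    ``reselect_among`` enables a sensitivity analysis of model *selection*:
    when given, every candidate config is also refitted per replicate and
    the AICc winner's id recorded under ``extras["selected_config_ids"]``.
    Parameter samples still summarize ``config`` itself, so the returned
    distribution keeps a single interpretation.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    gen = np.random.default_rng(seed)
    names = config.free_parameters
    collected: dict[str, list[float]] = {name: [] for name in names}
    selected_ids: list[str] = []
    n_failed = 0
    for _ in range(B):
        resampled = stratified_resample(data, gen)
        series = annual_means(resampled)
        try:
            fit = fit_config(
                config,
                series,
                n_starts=n_starts,
                seed=int(gen.integers(2**31)),
                polish=False,
            )
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        for name in names:
            collected[name].append(fit.params[name])
        if reselect_among:
            best_id, best_aicc = None, np.inf
            for cand in reselect_among:
                try:
                    cf = fit_config(
                        cand,
                        series,
                        n_starts=n_starts,
                        seed=int(gen.integers(2**31)),
                        polish=False,
                    )
                except (ValueError, RuntimeError):
                    continue
                if np.isfinite(cf.aicc) and cf.aicc < best_aicc:
                    best_id, best_aicc = cand.config_id, cf.aicc
            selected_ids.append(best_id if best_id is not None else "")
    if n_failed > max_failure_rate * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap refits failed (> {max_failure_rate:.0%}); "
            f"config {config.config_id} appears ill-posed for these data"
        )
    samples = {name: np.asarray(vals) for name, vals in collected.items()}
    extras = {"selected_config_ids": selected_ids} if reselect_among else {}
    return BootstrapDistribution(
        config=config, samples=samples, n_failed=n_failed, seed=seed, extras=extras
    )
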
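"""AICc ranking, Akaike weights, evidence sums and multi-model averaging.

The Akaike weight of model i in a candidate set is
w_i = exp(−Δ_i/2) / Σ_k exp(−Δ_k/2) with Δ_i = AICc_i − AICc_min, and is
interpreted as the relative strength of evidence for that model.  Evidence
for a hypothesis (e.g. "density dependence at the protected location") is
the sum of the weights of the models satisfying it, after excluding
unreliable forms (by default the theta-logistic, whose β–θ trade-off makes
its fits non-robust on short census series) and renormalizing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import FitResult
from .forms import FORMS, _det_step
from .model_space import ModelConfig

__all__ = [
    "ModelRanking",
    "rank_models",
    "evidence_sum",
    "form_evidence_table",
    "form_at",
    "density_dependent_at",
    "shared_dynamics",
    "shared_beta",
    "multimodel_predict",
    "top_models",
]

DEFAULT_EXCLUDED_FORMS = ("theta_logistic",)


@dataclass
class ModelRanking:
    """Fits sorted ascending by AICc with ΔAICc and Akaike weights."""

    fits: list[FitResult]
    delta: np.ndarray
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.fits)

    @property
    def best(self) -> FitResult:
        return self.fits[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "config_id": [f.config.config_id for f in self.fits],
                "k": [f.k for f in self.fits],
                "n": [f.n for f in self.fits],
                "nll": [f.nll for f in self.fits],
                "aicc": [f.aicc for f in self.fits],
                "delta_aicc": self.delta,
                "weight": self.weights,
            }
        )


def akaike_weights(delta: np.ndarray) -> np.ndarray:
    rel = np.exp(-0.5 * np.asarray(delta, dtype=float))
    return rel / rel.sum()


def rank_models(fits: Iterable[FitResult]) -> ModelRanking:
    """Sort fits by AICc (ties broken by the deterministic config order)."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    bad = [f.config.config_id for f in fits if not np.isfinite(f.aicc)]
    if bad:
        raise ValueError(
            f"AICc undefined (n <= k + 1) for config(s) {bad[:3]}; "
            "such fits cannot be ranked"
        )
    fits = sorted(fits, key=lambda f: (f.aicc, f.config.sort_key()))
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs[0]
    return ModelRanking(fits=fits, delta=delta, weights=akaike_weights(delta))


# -- hypothesis predicates -------------------------------------------------


def form_at(location: str, form: str) -> Callable[[ModelConfig], bool]:
    """Predicate: the config assigns ``form`` to ``location``."""
    return lambda cfg: cfg.form_at(location) == form


def density_dependent_at(location: str) -> Callable[[ModelConfig], bool]:
    """Predicate: a density-dependent form at ``location``.

    Evaluated over the usual evidence set (theta-logistic excluded), this is
    Ricker ∪ Gompertz; keeping the exclusion in ``evidence_sum`` keeps the
    density-dependent and density-independent halves of the set balanced.
    """
    from .forms import DENSITY_DEPENDENT_FORMS

    return lambda cfg: cfg.form_at(location) in DENSITY_DEPENDENT_FORMS


def shared_dynamics(locations: Sequence[str]) -> Callable[[ModelConfig], bool]:
    """Predicate: the locations share model structure and parameter values."""
    locs = sorted(locations)

    def _pred(cfg: ModelConfig) -> bool:
        forms = {cfg.form_at(l) for l in locs}
        if len(forms) != 1:
            return False
        for _, part in cfg.sharing:
            relevant = [b for b in part if any(l in b for l in locs)]
            if not relevant:
                continue
            if not any(set(locs) <= set(b) for b in part):
                return False
        return True

    return _pred


def shared_beta(locations: Sequence[str]) -> Callable[[ModelConfig], bool]:
    """Predicate: the locations share the density-dependence parameter β
    (same form, same β, λ free)."""
    locs = set(locations)

    def _pred(cfg: ModelConfig) -> bool:
        sharing = cfg.sharing_map
        if "beta" not in sharing:
            return False
        return any(locs <= set(b) for b in sharing["beta"])

    return _pred


# -- evidence --------------------------------------------------------------


def _excluded(cfg: ModelConfig, excluded_forms: Sequence[str]) -> bool:
    return any(f in excluded_forms for _, f in cfg.forms)


def evidence_sum(
    ranking: ModelRanking,
    predicate: Callable[[ModelConfig], bool],
    excluded_forms: Sequence[str] = DEFAULT_EXCLUDED_FORMS,
) -> float:
    """Summed Akaike weight (percent) of the models satisfying ``predicate``.

    Models using any excluded form at any location are dropped and the
    remaining weights renormalized before summing.
    """
    keep = np.array([not _excluded(f.config, excluded_forms) for f in ranking.fits])
    if not keep.any():
        raise ValueError("every model is excluded from the evidence set")
    w = ranking.weights[keep]
    w = w / w.sum()
    hit = np.array([predicate(f.config) for f, k in zip(ranking.fits, keep) if k])
    return float(100.0 * w[hit].sum())


def form_evidence_table(
    ranking: ModelRanking,
    locations: Sequence[str] | None = None,
    excluded_forms: Sequence[str] = DEFAULT_EXCLUDED_FORMS,
) -> pd.DataFrame:
    """Form-by-location table of evidence percentages.

    Each column sums to 100 over the non-excluded forms: the strength of
    evidence that the given form drives the dynamics at that location.
    """
    if locations is None:
        locations = ranking.best.config.locations
    forms = [f for f in FORMS if f not in excluded_forms]
    table = {
        loc: [evidence_sum(ranking, form_at(loc, f), excluded_forms) for f in forms]
        for loc in locations
    }
    return pd.DataFrame(table, index=forms)


# -- multi-model averaging -------------------------------------------------


def top_models(ranking: ModelRanking, top_m: int = 3) -> list[tuple[FitResult, float]]:
    """The ``top_m`` best fits with weights renormalized to sum to 1."""
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    m = min(top_m, len(ranking))
    w = ranking.weights[:m]
    w = w / w.sum()
    return list(zip(ranking.fits[:m], (float(x) for x in w)))


def multimodel_predict(
    ranking: ModelRanking, location: str, n_t, top_m: int = 3
):
    """AICc-weighted average one-step prediction at ``location``.

    The weights of the ``top_m`` best models are renormalized to 1 and each
    member predicts with its own form and parameter estimates.
    """
    arr = np.asarray(n_t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("density must be non-negative")
    out = np.zeros_like(arr, dtype=float)
    for fit, w in top_models(ranking, top_m):
        form = fit.config.form_at(location)
        if form == "gompertz" and np.any(arr == 0):
            raise ValueError("gompertz member model undefined at density 0")
        out = out + w * _det_step(form, fit.location_params(location), arr)
    return out if isinstance(n_t, np.ndarray) else float(out)
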
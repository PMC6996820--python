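"""Discrete-time demographic maps for unstructured populations.

Five one-step functional forms commonly contrasted when testing for density
dependence in census time series:

==================  ============================================  ==========
name                deterministic map  f(N)                       parameters
==================  ============================================  ==========
``random_walk``     N                                             —
``exponential``     λN                                            λ
``ricker``          λN·exp(−βN)                                   λ, β
``gompertz``        λN·exp(−β·ln N)                               λ, β
``theta_logistic``  λN·exp(−β·N^θ)                                λ, β, θ
==================  ============================================  ==========

λ is the finite (multiplicative, per year-step) growth rate in the
density-independent limit, β measures the strength of density dependence
(its units depend on the form) and θ allows a nonlinear scaling of density
dependence.  The stochastic version of each map adds a Gaussian error term
ε_t ~ N(0, σ_ε²) *on the density scale* (additive, not log-additive), which
can also absorb net exchange of individuals with the surroundings; simulated
densities are clamped at zero.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

__all__ = [
    "FORM_PARAMS",
    "FORMS",
    "DENSITY_DEPENDENT_FORMS",
    "DENSITY_INDEPENDENT_FORMS",
    "THETA_MAX",
    "predict_next",
    "simulate_trajectory",
    "trajectory_frame",
    "equilibrium_density",
]

#: dynamic parameters of each form, in canonical order
FORM_PARAMS: dict[str, tuple[str, ...]] = {
    "random_walk": (),
    "exponential": ("lambda",),
    "ricker": ("lambda", "beta"),
    "gompertz": ("lambda", "beta"),
    "theta_logistic": ("lambda", "beta", "theta"),
}

FORMS: tuple[str, ...] = tuple(FORM_PARAMS)
DENSITY_DEPENDENT_FORMS = frozenset({"ricker", "gompertz", "theta_logistic"})
DENSITY_INDEPENDENT_FORMS = frozenset({"random_walk", "exponential"})

#: upper bound for the θ exponent during fitting; the β–θ trade-off makes an
#: unbounded theta-logistic fit non-robust on short series.
THETA_MAX = 5.0


def _check_form(form: str) -> None:
    if form not in FORM_PARAMS:
        raise ValueError(f"unknown model form {form!r}; expected one of {FORMS}")


def _get_params(form: str, params: Mapping[str, float]) -> tuple[float, ...]:
    try:
        return tuple(float(params[p]) for p in FORM_PARAMS[form])
    except KeyError as exc:
        raise ValueError(f"form {form!r} requires parameter {exc.args[0]!r}") from exc


def _det_step(form: str, params: Mapping[str, float], n):
    """Deterministic part of the map, vectorized, with ``gompertz(0) = 0``.

    Internal: used by the simulator, where a population clamped at zero must
    still be steppable (a positive noise draw can rescue it).
    """
    n = np.asarray(n, dtype=float)
    if form == "random_walk":
        return n.copy()
    if form == "exponential":
        (lam,) = _get_params(form, params)
        return lam * n
    if form == "ricker":
        lam, beta = _get_params(form, params)
        return lam * n * np.exp(-beta * n)
    if form == "gompertz":
        lam, beta = _get_params(form, params)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = lam * n * np.exp(-beta * np.log(n))
        return np.where(n > 0, out, 0.0)
    if form == "theta_logistic":
        lam, beta, theta = _get_params(form, params)
        return lam * n * np.exp(-beta * n**theta)
    _check_form(form)
    raise AssertionError("unreachable")


def predict_next(form: str, params: Mapping[str, float], n_t):
    """One-step deterministic prediction N̂_{t+1} = f(N_t).

    Parameters
    ----------
    form
        One of :data:`FORMS`.
    params
        Mapping with the form's dynamic parameters (``lambda``, ``beta``,
        ``theta`` as applicable).  Extra keys are ignored.
    n_t
        Current density (individuals/m²), scalar or array, ≥ 0.
        The Gompertz map is undefined at 0 (log of zero).

    Returns
    -------
    Predicted density, same shape as ``n_t``.
    """
    _check_form(form)
    arr = np.asarray(n_t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("density must be non-negative")
    if form == "gompertz" and np.any(arr == 0):
        raise ValueError("gompertz map is undefined at density 0")
    out = _det_step(form, params, arr)
    return out if isinstance(n_t, np.ndarray) else float(out)


def simulate_trajectory(
    form: str,
    params: Mapping[str, float],
    sigma_eps: float,
    n0: float,
    horizon: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate ``N_{t+1} = max(0, f(N_t) + ε_t)`` for ``horizon`` steps.

    ε_t ~ N(0, sigma_eps²) i.i.d.  Negative post-noise densities are clamped
    to zero; because the noise is additive on the density scale, a population
    at zero can recover through a positive draw (the locations are open to
    immigration).  Returns an array of length ``horizon + 1`` starting at
    ``n0``.  Deterministic for a given ``rng`` seed.
    """
    _check_form(form)
    if sigma_eps < 0:
        raise ValueError("sigma_eps must be non-negative")
    if n0 < 0:
        raise ValueError("initial density must be non-negative")
    if horizon < 1:
        raise ValueError("horizon must be at least 1 year")
    gen = np.random.default_rng(rng)
    traj = np.empty(horizon + 1)
    traj[0] = n0
    eps = gen.normal(0.0, sigma_eps, size=horizon) if sigma_eps > 0 else np.zeros(horizon)
    n = float(n0)
    for t in range(horizon):
        n = max(0.0, float(_det_step(form, params, n)) + eps[t])
        traj[t + 1] = n
    return traj


def trajectory_frame(trajectories, start_year: int = 0):
    """Long-format (replicate, year, density) table of simulated trajectories.

    ``trajectories`` is one trajectory (1-D) or a stack of replicates
    (2-D, replicates × years); ``year`` counts from ``start_year``.
    """
    import pandas as pd

    arr = np.atleast_2d(np.asarray(trajectories, dtype=float))
    reps, steps = arr.shape
    return pd.DataFrame(
        {
            "replicate": np.repeat(np.arange(reps), steps),
            "year": np.tile(start_year + np.arange(steps), reps),
            "density": arr.ravel(),
        }
    )


def equilibrium_density(form: str, params: Mapping[str, float]) -> float | None:
    """Positive fixed point of the deterministic map, or ``None``.

    ricker: ln(λ)/β; gompertz: exp(ln(λ)/β); theta_logistic: (ln(λ)/β)^{1/θ}.
    The density-independent forms have no isolated positive equilibrium
    (for the random walk every density is an equilibrium; for exponential
    growth none is unless λ = 1), so ``None`` is returned, as it is for any
    parameter combination without a positive fixed point.
    """
    _check_form(form)
    if form in DENSITY_INDEPENDENT_FORMS:
        return None
    vals = dict(params)
    lam = float(vals["lambda"])
    beta = float(vals["beta"])
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if form == "ricker":
        if beta == 0:
            return None
        nstar = np.log(lam) / beta
        return float(nstar) if nstar > 0 else None
    if form == "gompertz":
        if beta == 0:
            return None
        return float(np.exp(np.log(lam) / beta))
    # theta_logistic
    theta = float(vals["theta"])
    if beta == 0 or theta <= 0:
        return None
    x = np.log(lam) / beta
    return float(x ** (1.0 / theta)) if x > 0 else None
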
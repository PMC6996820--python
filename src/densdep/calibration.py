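"""Maximum-likelihood calibration of multi-location demographic models.

The observation model: for each location i and each consecutive-year
transition N_{i,t} → N_{i,t+1}, the prediction error is

    ε_{i,t} = N_{i,t+1} − f_i(N_{i,t})

with f_i the deterministic map assigned to location i, and ε_{i,t} Gaussian
with mean 0 and a standard deviation σ_ε shared within the location's
σ group.  The negative log-likelihood

    L = −Σ_{i,t} ln φ(ε_{i,t}; 0, σ²)

is minimized over the config's free parameters.  Because the errors are
Gaussian, σ for each group can be profiled out in closed form
(σ̂² = mean of squared residuals), so the numerical search runs only over
the dynamic parameters, on transformed scales (log for λ, a scaled logit
for θ, untransformed for β), with a multi-start simplex search followed by
a tight polish.  Joint and profiled optimization have the same optimum.

Model selection uses the small-sample corrected information criterion

    AICc = 2L + 2k + 2k(k+1)/(n − k − 1)

with k the free-parameter count (dynamic blocks + σ groups) and n the total
number of transitions pooled over the config's locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import minimize, root
from scipy.special import expit, logit

from .data import AnnualSeries
from .forms import THETA_MAX, _det_step
from .model_space import ModelConfig

__all__ = [
    "SIGMA_FLOOR",
    "FitResult",
    "DynamicsModel",
    "negative_log_likelihood",
    "fit_config",
    "aicc",
]

#: lower bound on σ_ε (individuals/m²); keeps the likelihood finite on
#: degenerate (noise-free) inputs.
SIGMA_FLOOR = 1e-8

_LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e300


def aicc(nll: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    Raises ``ValueError`` when ``n <= k + 1`` (the correction term's
    denominator vanishes or turns negative).
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return 2.0 * nll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one :class:`ModelConfig`.

    Attributes
    ----------
    config : ModelConfig
    params : dict
        Estimates, one entry per free-parameter slot (natural scale).
    nll : float
        Minimized negative log-likelihood L.
    n : int
        Number of transitions pooled over the config's locations.
    k : int
        Free-parameter count (dynamic blocks + σ groups).
    aicc : float
        NaN when the criterion is undefined (n ≤ k + 1).
    diagnostics : dict
        Multi-start bookkeeping (starts, winning start, function evals).
    """

    config: ModelConfig
    params: dict[str, float]
    nll: float
    n: int
    k: int
    aicc: float
    diagnostics: dict = field(default_factory=dict)

    def get(self, param: str, location: str) -> float:
        """Estimate of ``param`` ("lambda", "beta", "theta", "sigma") at a location."""
        return self.params[self.config.slot_for(param, location)]

    def location_params(self, location: str) -> dict[str, float]:
        """Dynamic parameters feeding the map at ``location``."""
        from .forms import FORM_PARAMS

        form = self.config.form_at(location)
        return {p: self.get(p, location) for p in FORM_PARAMS[form]}

    def sigma(self, location: str) -> float:
        return self.get("sigma", location)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "params": dict(self.params),
            "nll": self.nll,
            "n": self.n,
            "k": self.k,
            "aicc": self.aicc,
            "diagnostics": dict(self.diagnostics),
        }

    def summary(self) -> str:
        lines = [
            "Model fit",
            "=" * 56,
            f"config:  {self.config.config_id}",
            f"n transitions: {self.n:>5d}    k: {self.k}",
            f"-log L: {self.nll:>12.6f}    AICc: {self.aicc:.6f}",
            "-" * 56,
            f"{'parameter':<28s}{'estimate':>14s}",
        ]
        for name, val in self.params.items():
            lines.append(f"{name:<28s}{val:>14.6g}")
        lines.append("=" * 56)
        return "\n".join(lines)


class DynamicsModel:
    """Multi-location stochastic demographic model bound to annual series.

    Parameters
    ----------
    series
        Mapping location → :class:`AnnualSeries`; must cover every location
        of ``config`` with at least one consecutive-year transition.
    config
        The functional forms and parameter-sharing structure to calibrate.

    ``fit()`` returns a :class:`FitResult`.
    """

    def __init__(self, series: Mapping[str, AnnualSeries], config: ModelConfig):
        self.config = config
        self._locs = config.locations
        self._trans: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for loc in self._locs:
            if loc not in series:
                raise ValueError(f"no series for location {loc!r}")
            n_from, n_to = series[loc].transitions()
            if len(n_from) == 0:
                raise ValueError(
                    f"location {loc!r} has no consecutive-year transitions"
                )
            if config.form_at(loc) == "gompertz" and np.any(n_from == 0):
                raise ValueError(
                    f"gompertz at {loc!r}: zero density in the series "
                    "(log of zero undefined)"
                )
            self._trans[loc] = (n_from, n_to)
        self.n = int(sum(len(v[0]) for v in self._trans.values()))
        self.k = config.k
        # index free dynamic slots
        self._dyn = list(config.dynamic_slots)  # (param, block)
        self._slot_names = [config.slot_name(p, b) for p, b in self._dyn]
        self._sigma_groups = config.sigma_groups
        self._sigma_names = [config.slot_name("sigma", g) for g in self._sigma_groups]
        # per-location mapping param -> dyn index
        self._loc_param_idx: dict[str, dict[str, int]] = {loc: {} for loc in self._locs}
        for j, (p, block) in enumerate(self._dyn):
            for loc in block:
                self._loc_param_idx[loc][p] = j

    # -- likelihood --------------------------------------------------------

    def _residuals(self, dyn_values: np.ndarray) -> dict[str, np.ndarray] | None:
        """Prediction errors per location, or None if parameters blow up."""
        out = {}
        for loc in self._locs:
            form = self.config.form_at(loc)
            params = {p: dyn_values[j] for p, j in self._loc_param_idx[loc].items()}
            n_from, n_to = self._trans[loc]
            with np.errstate(over="ignore", invalid="ignore"):
                pred = _det_step(form, params, n_from)
            if not np.all(np.isfinite(pred)):
                return None
            out[loc] = n_to - pred
        return out

    def _group_residuals(self, res: dict[str, np.ndarray]) -> list[np.ndarray]:
        return [
            np.concatenate([res[loc] for loc in group]) for group in self._sigma_groups
        ]

    def profiled_nll(self, dyn_values: np.ndarray) -> float:
        """Negative log-likelihood with each group's σ at its closed-form MLE."""
        res = self._residuals(np.asarray(dyn_values, dtype=float))
        if res is None:
            return _BIG
        total = 0.0
        with np.errstate(over="ignore", invalid="ignore"):
            for eps in self._group_residuals(res):
                m = len(eps)
                s2 = max(float(np.mean(eps**2)), SIGMA_FLOOR**2)
                if not math.isfinite(s2):
                    return _BIG
                total += 0.5 * m * (_LOG2PI + math.log(s2)) + float(
                    np.sum(eps**2)
                ) / (2 * s2)
        return total if math.isfinite(total) else _BIG

    def profiled_sigmas(self, dyn_values: np.ndarray) -> list[float]:
        res = self._residuals(np.asarray(dyn_values, dtype=float))
        if res is None:
            raise ValueError("non-finite predictions at the given parameters")
        return [
            max(float(np.sqrt(np.mean(eps**2))), SIGMA_FLOOR)
            for eps in self._group_residuals(res)
        ]

    def nll(self, params: Mapping[str, float]) -> float:
        """Full negative log-likelihood at explicit parameter values.

        ``params`` must contain every free slot named by
        ``config.free_parameters`` (dynamic slots and σ groups).
        """
        dyn = np.array([params[name] for name in self._slot_names], dtype=float)
        res = self._residuals(dyn)
        if res is None:
            return _BIG
        total = 0.0
        with np.errstate(over="ignore", invalid="ignore"):
            for name, eps in zip(self._sigma_names, self._group_residuals(res)):
                s = float(params[name])
                if s <= 0:
                    raise ValueError(f"{name} must be positive")
                total += 0.5 * len(eps) * (_LOG2PI + 2 * math.log(s)) + float(
                    np.sum(eps**2)
                ) / (2 * s**2)
        return total if math.isfinite(total) else _BIG

    # -- parameter transforms ---------------------------------------------

    def _to_internal(self, natural: np.ndarray) -> np.ndarray:
        x = np.array(natural, dtype=float)
        for j, (p, _) in enumerate(self._dyn):
            if p == "lambda":
                x[j] = math.log(max(x[j], 1e-12))
            elif p == "theta":
                frac = min(max(x[j] / THETA_MAX, 1e-9), 1 - 1e-9)
                x[j] = logit(frac)
        return x

    def _to_natural(self, internal: np.ndarray) -> np.ndarray:
        v = np.array(internal, dtype=float)
        for j, (p, _) in enumerate(self._dyn):
            if p == "lambda":
                v[j] = math.exp(min(v[j], 500.0))
            elif p == "theta":
                v[j] = THETA_MAX * expit(v[j])
        return v

    def _objective(self, x: np.ndarray) -> float:
        return self.profiled_nll(self._to_natural(x))

    def _objective_grad(self, x: np.ndarray) -> np.ndarray | None:
        """Analytic gradient of the σ-profiled NLL w.r.t. internal coords.

        dL/dp = Σ_g (1/σ̂_g²) Σ_t ε_t · (−∂pred_t/∂p).  Returns ``None``
        when any group's σ̂ sits on its floor (clipped objective is not
        differentiable there) or predictions blow up.
        """
        natural = self._to_natural(x)
        res = self._residuals(natural)
        if res is None:
            return None
        inv_s2: dict[str, float] = {}
        for group in self._sigma_groups:
            eps = np.concatenate([res[loc] for loc in group])
            with np.errstate(over="ignore"):
                s2 = float(np.mean(eps**2))
            if not math.isfinite(s2) or s2 <= SIGMA_FLOOR**2:
                return None
            for loc in group:
                inv_s2[loc] = 1.0 / s2
        grad = np.zeros(len(self._dyn))
        for loc in self._locs:
            form = self.config.form_at(loc)
            idx = self._loc_param_idx[loc]
            params = {p: natural[j] for p, j in idx.items()}
            n_from, _ = self._trans[loc]
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                pred = _det_step(form, params, n_from)
                for p, j in idx.items():
                    if p == "lambda":
                        dpred = pred / params["lambda"]
                    elif p == "beta":
                        if form == "gompertz":
                            dpred = -pred * np.log(n_from)
                        elif form == "theta_logistic":
                            dpred = -pred * n_from ** params["theta"]
                        else:  # ricker
                            dpred = -pred * n_from
                    else:  # theta
                        with np.errstate(invalid="ignore"):
                            term = np.where(
                                n_from > 0,
                                n_from ** params["theta"] * np.log(n_from),
                                0.0,
                            )
                        dpred = -pred * params["beta"] * term
                    if not np.all(np.isfinite(dpred)):
                        return None
                    grad[j] += inv_s2[loc] * float(np.sum(res[loc] * (-dpred)))
        # chain rule through the internal-coordinate transforms
        for j, (p, _) in enumerate(self._dyn):
            if p == "lambda":
                grad[j] *= natural[j]  # dλ/du = λ for u = ln λ
            elif p == "theta":
                grad[j] *= natural[j] * (1.0 - natural[j] / THETA_MAX)
        return grad if np.all(np.isfinite(grad)) else None

    # -- starting values ---------------------------------------------------

    def _moment_start(self) -> np.ndarray:
        """Moment-based start: λ from the origin slope, β from a crude
        log-growth regression, θ = 1."""
        start = np.empty(len(self._dyn))
        lam0_by_block: dict = {}
        for j, (p, block) in enumerate(self._dyn):
            nf = np.concatenate([self._trans[l][0] for l in block])
            nt = np.concatenate([self._trans[l][1] for l in block])
            if p == "lambda":
                denom = float(np.sum(nf**2))
                lam0 = float(np.sum(nf * nt)) / denom if denom > 0 else 1.0
                lam0 = min(max(lam0, 1e-3), 1e3)
                lam0_by_block[block] = lam0
                start[j] = lam0
            elif p == "beta":
                form = self.config.form_at(block[0])
                ok = (nf > 0) & (nt > 0)
                beta0 = None
                if np.count_nonzero(ok) >= 3:
                    y = np.log(nt[ok] / nf[ok])
                    x = np.log(nf[ok]) if form == "gompertz" else nf[ok]
                    if np.ptp(x) > 0:
                        slope = np.polyfit(x, y, 1)[0]
                        if np.isfinite(slope):
                            beta0 = -slope
                if beta0 is None or not np.isfinite(beta0):
                    mean_n = float(np.mean(nf[nf > 0])) if np.any(nf > 0) else 1.0
                    beta0 = 1.0 if form == "gompertz" else math.log(2.0) / mean_n
                start[j] = min(max(beta0, -1e4), 1e4)
            else:  # theta
                start[j] = 1.0
        return start

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        n_starts: int = 10,
        seed: int | None = 0,
        tol: float = 1e-10,
        polish: bool = True,
    ) -> FitResult:
        """Minimize the (σ-profiled) negative log-likelihood.

        One deterministic moment-based start plus ``n_starts - 1`` jittered
        starts; derivative-free simplex descent per start, then a tight
        polish of the best point (skippable with ``polish=False`` when many
        approximate refits are needed, as in the bootstrap).  Deterministic
        given ``seed``.
        """
        d = len(self._dyn)
        if d == 0:
            best_x = np.empty(0)
            nfev = 0
            best_f = self.profiled_nll(best_x)
            n_used = 0
        else:
            rng = np.random.default_rng(seed)
            x0 = self._to_internal(self._moment_start())
            scales = np.array(
                [
                    0.5 if p == "lambda" else (1.0 if p == "theta" else 0.5 * max(1.0, abs(x0[j])))
                    for j, (p, _) in enumerate(self._dyn)
                ]
            )
            starts = [x0]
            for _ in range(max(0, n_starts - 1)):
                starts.append(x0 + rng.normal(0.0, scales))
            best_x, best_f, nfev, n_used = None, np.inf, 0, 0
            for s in starts:
                r = minimize(
                    self._objective,
                    s,
                    method="Nelder-Mead",
                    options={
                        "xatol": 1e-8,
                        "fatol": max(tol, 1e-12),
                        "maxiter": 400 * (d + 2),
                        "maxfev": 400 * (d + 2),
                    },
                )
                nfev += r.nfev
                if np.isfinite(r.fun):
                    n_used += 1
                if r.fun < best_f:
                    best_f, best_x = r.fun, r.x
            if best_x is None or not math.isfinite(best_f) or best_f >= _BIG:
                raise RuntimeError(
                    f"all {len(starts)} starts failed to converge for "
                    f"{self.config.config_id}"
                )
            if polish:
                # Stationarity polish: solve ∇L = 0 on the analytic
                # gradient.  Near the optimum the objective is flat to
                # machine precision, so derivative-free descent floors out
                # around 1e-9 in the parameters while the gradient retains
                # full relative accuracy.
                if self._objective_grad(best_x) is not None:

                    def _grad(x: np.ndarray) -> np.ndarray:
                        g = self._objective_grad(x)
                        return g if g is not None else np.full(d, np.nan)

                    sol = root(_grad, best_x, method="hybr")
                    nfev += int(sol.nfev)
                    if sol.success:
                        f_at = self._objective(sol.x)
                        tol_f = 1e-10 * (1.0 + abs(best_f))
                        if np.isfinite(f_at) and f_at <= best_f + tol_f:
                            best_f, best_x = f_at, sol.x
                else:
                    # σ on its floor (noise-free input): the profiled
                    # objective is clipped and not differentiable, fall back
                    # to a tight simplex pass
                    pol = minimize(
                        self._objective,
                        best_x,
                        method="Nelder-Mead",
                        options={
                            "xatol": 1e-13,
                            "fatol": 1e-13,
                            "maxiter": 4000 * (d + 1),
                            "maxfev": 4000 * (d + 1),
                        },
                    )
                    nfev += pol.nfev
                    if pol.fun <= best_f:
                        best_f, best_x = pol.fun, pol.x

        dyn_nat = self._to_natural(best_x)
        sigmas = self.profiled_sigmas(dyn_nat)
        params = dict(zip(self._slot_names, (float(v) for v in dyn_nat)))
        params.update(zip(self._sigma_names, sigmas))
        nll = self.nll(params)
        # the criterion is undefined when n <= k + 1; the fit itself stands
        crit = aicc(nll, self.k, self.n) if self.n > self.k + 1 else math.nan
        return FitResult(
            config=self.config,
            params=params,
            nll=float(nll),
            n=self.n,
            k=self.k,
            aicc=crit,
            diagnostics={
                "n_starts": n_starts if d else 0,
                "n_starts_converged": n_used,
                "nfev": int(nfev),
            },
        )


def negative_log_likelihood(
    config: ModelConfig,
    params: Mapping[str, float],
    series: Mapping[str, AnnualSeries],
) -> float:
    """L = −Σ ln φ(ε_{i,t}) at explicit parameter values (no fitting)."""
    return DynamicsModel(series, config).nll(params)


def fit_config(
    config: ModelConfig,
    series: Mapping[str, AnnualSeries],
    n_starts: int = 10,
    seed: int | None = 0,
    tol: float = 1e-10,
    polish: bool = True,
) -> FitResult:
    """Fit ``config`` to ``series`` by maximum likelihood (see :class:`DynamicsModel`)."""
    return DynamicsModel(series, config).fit(
        n_starts=n_starts, seed=seed, tol=tol, polish=polish
    )
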
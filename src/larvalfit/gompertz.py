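"""Gompertz growth model with treatment-structured rates and AICc selection.

The growth curve for container-mean total length is

    Y(t) = S0 * exp[(gamma/alpha) * (1 - e^(-alpha t))]

where S0 is initial size (mm) at the start of treatments, gamma (1/day) the
maximum size-specific growth rate (dY/dt = gamma e^(-alpha t) Y) and alpha
(1/day) the exponential decay rate of that size-specific rate. The asymptote
is S0 * exp(gamma/alpha).

Treatment structure enters through linear predictors for log(gamma) and
log(alpha) built from the experiment's factors — location, salinity and
density (a 3-level factor) — under treatment (dummy) coding with reference
cell (coastal, fresh, density 2). The log link keeps both rates positive for
any coefficient vector. Every candidate model shares a single S0 and a single
residual standard deviation sigma (i.i.d. Gaussian errors on the cup mean).

The candidate set crosses four effect structures {L+S+D, L*S+D, L+S*D,
L*S*D} on gamma and alpha (16 models) plus the single no-effects model:
17 parameterizations, compared by small-sample-corrected AIC (AICc) and
Akaike weights.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy

logger = logging.getLogger(__name__)

# formula vocabulary used in all reports, mapped to patsy model formulas
NULL_FORMULA = "1"
_FACTOR_EXPR = {
    "Location": 'C(location, levels=("coastal", "inland"))',
    "Salinity": 'C(salinity, levels=("fresh", "salt4ppt"))',
    "Density": "C(density, levels=(2, 4, 8))",
}
EFFECT_FORMULAS = (
    "Location + Salinity + Density",
    "Location * Salinity + Density",
    "Location + Salinity * Density",
    "Location * Salinity * Density",
)
FORMULA_VOCABULARY = EFFECT_FORMULAS + (NULL_FORMULA,)


def _to_patsy(label: str) -> str:
    if label == NULL_FORMULA:
        return "1"
    out = label
    for name, expr in _FACTOR_EXPR.items():
        out = out.replace(name, expr)
    return out


class UnknownFactorLevelError(ValueError):
    """A unit carries a factor level outside the design's vocabulary."""


@dataclass(frozen=True)
class GompertzParams:
    """Parameter vector of one treatment cell's growth curve."""

    S0: float
    gamma: float
    alpha: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.S0 <= 0 or self.gamma <= 0 or self.alpha <= 0 or self.sigma < 0:
            raise ValueError(
                "require S0 > 0, gamma > 0, alpha > 0, sigma >= 0; got "
                f"S0={self.S0}, gamma={self.gamma}, alpha={self.alpha}, "
                f"sigma={self.sigma}")

    @property
    def asymptote(self) -> float:
        return self.S0 * math.exp(self.gamma / self.alpha)


def gompertz_length(t, S0: float, gamma: float, alpha: float):
    """Expected total length (mm) at time t (days since treatment start).

    Stable for small alpha via expm1; the alpha -> 0 limit is exponential
    growth S0 * e^(gamma t). Accepts scalars or arrays; t must be >= 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if alpha == 0.0:
        expo = gamma * t_arr
    else:
        expo = gamma * (-np.expm1(-alpha * t_arr)) / alpha
    out = S0 * np.exp(expo)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def gompertz_predict(params: GompertzParams, t):
    """Curve evaluation with a validated parameter vector."""
    return gompertz_length(t, params.S0, params.gamma, params.alpha)


# ---------------------------------------------------------------------------
# Candidate models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which effect structure applies to gamma and to alpha (S0 is shared)."""

    gamma_formula: str
    alpha_formula: str

    def __post_init__(self) -> None:
        for f in (self.gamma_formula, self.alpha_formula):
            if f not in FORMULA_VOCABULARY:
                raise ValueError(f"unknown formula {f!r}")
        null = (self.gamma_formula == NULL_FORMULA,
                self.alpha_formula == NULL_FORMULA)
        if any(null) and not all(null):
            raise ValueError(
                "the null structure is only used in the single no-effects model")

    @property
    def is_null(self) -> bool:
        return self.gamma_formula == NULL_FORMULA

    @property
    def label(self) -> str:
        return f"gamma: {self.gamma_formula} | alpha: {self.alpha_formula}"


def enumerate_model_specs() -> list[ModelSpec]:
    """All 17 candidate parameterizations, in stable enumeration order.

    The 16 non-null combinations come first (gamma-major over the four effect
    structures), the no-effects model last. Ties in AICc ranking are broken
    by this order.
    """
    specs = [ModelSpec(g, a)
             for g, a in itertools.product(EFFECT_FORMULAS, EFFECT_FORMULAS)]
    specs.append(ModelSpec(NULL_FORMULA, NULL_FORMULA))
    return specs


def _validate_levels(units: pd.DataFrame) -> None:
    allowed = {"location": {"coastal", "inland"},
               "salinity": {"fresh", "salt4ppt"},
               "density": {2, 4, 8}}
    for col, levels in allowed.items():
        bad = set(units[col]) - levels
        if bad:
            raise UnknownFactorLevelError(
                f"unknown {col} level(s) {sorted(map(str, bad))}; "
                f"allowed: {sorted(map(str, levels))}")


def _units_frame(units) -> pd.DataFrame:
    if isinstance(units, pd.DataFrame):
        return units
    from .simulate import units_to_frame
    return units_to_frame(units)


def build_design_matrices(spec: ModelSpec, units) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment-coded model matrices for gamma and alpha, one row per unit.

    Reference levels: coastal, fresh, density 2; density contributes two
    dummy columns as a main effect. Returned as DataFrames indexed like the
    unit table, with patsy column names.
    """
    frame = _units_frame(units)
    _validate_levels(frame)
    Xg = patsy.dmatrix(_to_patsy(spec.gamma_formula), frame,
                       return_type="dataframe")
    Xa = patsy.dmatrix(_to_patsy(spec.alpha_formula), frame,
                       return_type="dataframe")
    return Xg, Xa


def count_parameters(spec: ModelSpec) -> int:
    """Total estimated parameters: shared S0 and sigma plus both matrices'
    columns (this is the df column of the model-comparison table)."""
    from .simulate import all_cells
    cells = pd.DataFrame([{"location": c.location, "salinity": c.salinity,
                           "density": c.density} for c in all_cells()])
    Xg, Xa = build_design_matrices(spec, cells)
    return 2 + Xg.shape[1] + Xa.shape[1]


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

@dataclass
class _GrowthProblem:
    """Preprocessed growth data aligned with a spec's design matrices."""

    spec: ModelSpec
    Xg: np.ndarray          # (n_units, pg)
    Xa: np.ndarray          # (n_units, pa)
    unit_idx: np.ndarray    # growth row -> unit row
    t: np.ndarray
    y: np.ndarray
    gamma_names: list[str]
    alpha_names: list[str]

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def k(self) -> int:
        return 2 + self.Xg.shape[1] + self.Xa.shape[1]


def _prepare(spec: ModelSpec, growth: pd.DataFrame, units) -> _GrowthProblem:
    frame = _units_frame(units).reset_index(drop=True)
    if growth.empty:
        raise ValueError("growth data must be non-empty")
    Xg, Xa = build_design_matrices(spec, frame)
    pos = {uid: i for i, uid in enumerate(frame["unit_id"])}
    missing = set(growth["unit_id"]) - set(pos)
    if missing:
        raise ValueError(f"growth references unknown unit_id(s): {sorted(missing)[:5]}")
    return _GrowthProblem(
        spec=spec,
        Xg=np.asarray(Xg, dtype=float),
        Xa=np.asarray(Xa, dtype=float),
        unit_idx=growth["unit_id"].map(pos).to_numpy(),
        t=growth["day"].to_numpy(dtype=float),
        y=growth["mean_total_length_mm"].to_numpy(dtype=float),
        gamma_names=list(Xg.columns),
        alpha_names=list(Xa.columns),
    )


def _nll_grad(theta: np.ndarray, prob: _GrowthProblem):
    """Gaussian negative log-likelihood and its analytic gradient.

    theta packs [S0, gamma coefficients (log link), alpha coefficients
    (log link), log sigma].
    """
    pg, pa = prob.Xg.shape[1], prob.Xa.shape[1]
    S0 = theta[0]
    bg = theta[1:1 + pg]
    ba = theta[1 + pg:1 + pg + pa]
    log_sigma = theta[-1]
    n = prob.n_obs

    if S0 <= 0 or not np.all(np.isfinite(theta)):
        return np.inf, np.zeros_like(theta)

    gamma_u = np.exp(np.clip(prob.Xg @ bg, -30.0, 10.0))
    alpha_u = np.exp(np.clip(prob.Xa @ ba, -30.0, 10.0))
    g = gamma_u[prob.unit_idx]
    a = alpha_u[prob.unit_idx]
    t = prob.t

    E = np.exp(-a * t)
    one_mE = -np.expm1(-a * t)
    expo = np.clip(g * one_mE / a, -100.0, 100.0)
    pred = S0 * np.exp(expo)
    resid = prob.y - pred

    sigma = math.exp(log_sigma)
    inv_s2 = math.exp(-2.0 * log_sigma)
    rss = float(resid @ resid)
    nll = n * (log_sigma + 0.5 * math.log(2.0 * math.pi)) + 0.5 * rss * inv_s2
    if not np.isfinite(nll):
        return np.inf, np.zeros_like(theta)

    # chain rule through the curve and the log links
    dl_dpred = -resid * inv_s2
    dpred_dgamma = pred * one_mE / a
    dpred_dalpha = pred * (g / a) * (t * E - one_mE / a)

    grad = np.empty_like(theta)
    grad[0] = float(dl_dpred @ (pred / S0))
    wg = dl_dpred * dpred_dgamma * g
    wa = dl_dpred * dpred_dalpha * a
    grad[1:1 + pg] = np.bincount(prob.unit_idx, weights=wg,
                                 minlength=prob.Xg.shape[0]) @ prob.Xg
    grad[1 + pg:1 + pg + pa] = np.bincount(prob.unit_idx, weights=wa,
                                           minlength=prob.Xa.shape[0]) @ prob.Xa
    grad[-1] = n - rss * inv_s2
    return nll, grad


def negative_log_likelihood(theta: Sequence[float], spec: ModelSpec,
                            growth: pd.DataFrame, units) -> float:
    """Gaussian NLL of cup-mean lengths for a packed coefficient vector.

    ``theta`` packs [S0, gamma coefficients, alpha coefficients, log sigma];
    the rate coefficients act on the log scale. Non-finite predictions yield
    +inf (optimizer-safe).
    """
    prob = _prepare(spec, growth, units)
    theta = np.asarray(theta, dtype=float)
    expected = 1 + prob.Xg.shape[1] + prob.Xa.shape[1] + 1
    if theta.size != expected:
        raise ValueError(f"theta has {theta.size} entries, spec needs {expected}")
    nll, _ = _nll_grad(theta, prob)
    return float(nll)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Optimizer settings for one maximum-likelihood fit."""

    n_restarts: int = 10
    seed: int = 0
    gtol: float = 1e-8
    maxiter: int = 1000
    # natural-scale bounds on the reference-cell rates
    rate_lower: float = 1e-4
    rate_upper: float = 5.0


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate parameterization."""

    spec: ModelSpec
    coefficients: dict[str, float]
    log_likelihood: float
    k: int
    n_obs: int
    aicc: float
    converged: bool
    n_restarts_used: int
    theta: np.ndarray = field(repr=False, default=None)

    def cell_rates(self) -> pd.DataFrame:
        """Natural-scale fitted gamma and alpha for each of the 12 cells."""
        from .simulate import all_cells
        cells = pd.DataFrame([{"location": c.location, "salinity": c.salinity,
                               "density": c.density} for c in all_cells()])
        Xg, Xa = build_design_matrices(self.spec, cells)
        pg = Xg.shape[1]
        bg = self.theta[1:1 + pg]
        ba = self.theta[1 + pg:1 + pg + Xa.shape[1]]
        cells["gamma"] = np.exp(np.asarray(Xg) @ bg)
        cells["alpha"] = np.exp(np.asarray(Xa) @ ba)
        return cells


class FitError(RuntimeError):
    """All optimizer restarts failed; carries the best partial result."""

    def __init__(self, message: str, partial: FitResult | None = None):
        super().__init__(message)
        self.partial = partial


def _moment_starts(prob: _GrowthProblem, cfg: FitConfig) -> list[np.ndarray]:
    """Coarse method-of-moments starting points.

    S0 from the first-measurement mean, the asymptote from the last-week
    mean, alpha from a grid of plausible curve half-lives.
    """
    t, y = prob.t, prob.y
    s0 = max(float(np.mean(y[t == t.min()])), 0.5)
    a_end = max(float(np.mean(y[t == t.max()])), s0 * 1.1)
    r0 = max(math.log(a_end / s0), 0.05)
    sigma0 = max(0.05, float(np.std(y - np.interp(t, np.sort(np.unique(t)),
                 [np.mean(y[t == d]) for d in np.sort(np.unique(t))]))))
    pg, pa = prob.Xg.shape[1], prob.Xa.shape[1]
    starts = []
    for alpha0 in (0.02, 0.05, 0.10):
        theta = np.zeros(2 + pg + pa)
        theta[0] = s0
        theta[1] = math.log(max(r0 * alpha0, 1.5 * cfg.rate_lower))
        theta[1 + pg] = math.log(alpha0)
        theta[-1] = math.log(sigma0)
        starts.append(theta)
    return starts


def fit_gompertz(spec: ModelSpec, growth: pd.DataFrame, units,
                 fit_config: FitConfig | None = None) -> FitResult:
    """Multi-start bounded quasi-Newton ML fit of one parameterization."""
    from scipy.optimize import minimize

    cfg = fit_config or FitConfig()
    prob = _prepare(spec, growth, units)
    if prob.n_obs < prob.k + 1:
        raise ValueError(
            f"under-determined: {prob.n_obs} observations for k={prob.k}")

    pg, pa = prob.Xg.shape[1], prob.Xa.shape[1]
    lo_rate, hi_rate = math.log(cfg.rate_lower), math.log(cfg.rate_upper)
    bounds = ([(1e-3, 1e3)]
              + [(lo_rate, hi_rate)] + [(-6.0, 6.0)] * (pg - 1)
              + [(lo_rate, hi_rate)] + [(-6.0, 6.0)] * (pa - 1)
              + [(-12.0, 6.0)])

    rng = np.random.default_rng(cfg.seed)
    base_starts = _moment_starts(prob, cfg)
    starts = list(base_starts)
    while len(starts) < cfg.n_restarts:
        theta = base_starts[len(starts) % len(base_starts)].copy()
        theta[0] *= math.exp(rng.normal(0.0, 0.15))
        theta[1:-1] += rng.normal(0.0, 0.3, size=theta.size - 2)
        theta[-1] += rng.normal(0.0, 0.3)
        starts.append(theta)
    starts = starts[:max(cfg.n_restarts, 1)]

    best = None
    n_used = 0
    for i, theta0 in enumerate(starts):
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = minimize(_nll_grad, theta0, args=(prob,), jac=True,
                           method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": cfg.maxiter, "ftol": cfg.gtol,
                                    "gtol": cfg.gtol})
        except Exception as exc:  # pragma: no cover - optimizer crash
            logger.debug("restart %d failed: %s", i, exc)
            continue
        n_used += 1
        logger.debug("restart %d: nll=%.6f success=%s", i, res.fun, res.success)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res

    if best is None:
        raise FitError(f"all {len(starts)} restarts failed for {spec.label}")

    theta = best.x
    names = (["S0"] + [f"gamma:{n}" for n in prob.gamma_names]
             + [f"alpha:{n}" for n in prob.alpha_names] + ["sigma"])
    values = list(theta[:-1]) + [math.exp(theta[-1])]
    ll = -float(best.fun)
    result = FitResult(
        spec=spec,
        coefficients=dict(zip(names, map(float, values))),
        log_likelihood=ll,
        k=prob.k,
        n_obs=prob.n_obs,
        aicc=aicc(ll, prob.k, prob.n_obs),
        converged=bool(best.success),
        n_restarts_used=n_used,
        theta=theta,
    )
    logger.info("fit %s: logLik=%.3f k=%d AICc=%.3f converged=%s",
                spec.label, ll, result.k, result.aicc, result.converged)
    return result


# ---------------------------------------------------------------------------
# Information criteria and model table
# ---------------------------------------------------------------------------

def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: -2l + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(delta_aicc: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-d_i/2) / sum_j exp(-d_j/2), order-preserving."""
    deltas = np.asarray(delta_aicc, dtype=float)
    if deltas.size == 0:
        raise ValueError("empty delta list")
    if np.any(deltas < -1e-9) or abs(deltas.min()) > 1e-9:
        raise ValueError("deltas must be >= 0 with min exactly 0")
    rel = np.exp(-0.5 * deltas)
    return rel / rel.sum()


@dataclass
class ModelTable:
    """Ranked AICc comparison across all candidate parameterizations."""

    frame: pd.DataFrame
    fits: list[FitResult]  # in enumeration order

    @property
    def best(self) -> FitResult:
        return self.fits[int(self.frame.iloc[0]["spec_index"])]

    def to_csv(self, path) -> None:
        cols = ["rank", "gamma_formula", "alpha_formula", "logLik", "k", "n",
                "AICc", "dAICc", "weight", "converged"]
        self.frame[cols].to_csv(path, index=False, float_format="%.6f")


def rank_fit_records(rows: pd.DataFrame) -> pd.DataFrame:
    """Sort fit records by AICc (ties broken by ``spec_index``), attach rank,
    dAICc and Akaike weights."""
    if "spec_index" not in rows.columns:
        rows = rows.assign(spec_index=np.arange(len(rows)))
    rows = rows.sort_values(["AICc", "spec_index"], kind="mergesort")
    rows["rank"] = np.arange(1, len(rows) + 1)
    rows["dAICc"] = rows["AICc"] - rows["AICc"].iloc[0]
    rows["weight"] = akaike_weights(rows["dAICc"].to_numpy())
    return rows.reset_index(drop=True)


def build_model_table(growth: pd.DataFrame, units,
                      fit_config: FitConfig | None = None) -> ModelTable:
    """Fit all 17 parameterizations and rank them by AICc.

    Non-convergent fits are retained and flagged in the ``converged`` column,
    never dropped. Ties are broken by enumeration order.
    """
    cfg = fit_config or FitConfig()
    specs = enumerate_model_specs()
    fits = []
    for i, spec in enumerate(specs):
        spec_cfg = FitConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * i})
        fits.append(fit_gompertz(spec, growth, units, spec_cfg))

    rows = pd.DataFrame({
        "spec_index": range(len(specs)),
        "gamma_formula": [s.gamma_formula for s in specs],
        "alpha_formula": [s.alpha_formula for s in specs],
        "logLik": [f.log_likelihood for f in fits],
        "k": [f.k for f in fits],
        "n": [f.n_obs for f in fits],
        "AICc": [f.aicc for f in fits],
        "converged": [f.converged for f in fits],
    })
    rows = rank_fit_records(rows)
    if not rows["converged"].all():
        bad = rows.loc[~rows["converged"],
                       ["gamma_formula", "alpha_formula"]].to_records(index=False)
        logger.warning("non-convergent fits retained in table: %s", list(bad))
    return ModelTable(frame=rows, fits=fits)
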
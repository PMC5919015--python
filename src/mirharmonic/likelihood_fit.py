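"""Maximum-likelihood fitting of harmonic MIR curves with multiplicative error.

Observed MIR percentages scatter multiplicatively around the periodic mean
curve, so the residual is taken on the log scale.  With the error variance
concentrated out, the objective to minimize is

    -2 ln L(theta) = n * [ ln( 2*pi * S(theta) / n ) + 1 ],
    S(theta) = sum_i ( ln psi_obs_i - ln psi_exp_i(theta) )^2,

where ``n`` is the observation count entering the fit (twice the sample size
when the two-period replication convention is on) and the implicit error
variance is ``sigma^2 = S/n``.  Because ``-2 ln L`` is a strictly increasing
function of ``S``, maximizing the likelihood is exactly a nonlinear
least-squares problem in the log residuals; the optimizer is a trust-region
Gauss-Newton method with an analytic Jacobian, run from multiple starts
because the likelihood is multimodal in the phase/period directions.  The
period ``gamma`` is a free parameter throughout — annual periodicity is a
conclusion, never an assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .harmonic_models import N_FREE, HarmonicParams, predict
from .mir_core import MIRDataset, replicate_two_periods

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateFitError",
    "FitFailureError",
    "InsufficientDataError",
    "FitConfig",
    "FitResult",
    "neg2_log_likelihood",
    "fit",
]

#: smooth positivity floor for predicted MIR inside the optimizer
_PSI_FLOOR = 1e-3


class DegenerateFitError(ValueError):
    """All residuals vanished: the concentrated likelihood is unbounded."""


class FitFailureError(RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[dict] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class InsufficientDataError(ValueError):
    """Fewer observations than free parameters."""


def neg2_log_likelihood(data: MIRDataset, params: HarmonicParams) -> float:
    """Concentrated ``-2 ln L`` of the dataset under the given curve.

    ``n`` is the dataset's effective observation count (doubled if the
    two-period replication has been applied).  Any non-positive predicted
    MIR at an observation time yields ``+inf`` (log-scale residual
    undefined); a perfect fit (all residuals zero) raises
    :class:`DegenerateFitError` since the concentrated objective diverges
    to ``-inf``.
    """
    t = data.times
    psi_o = data.mir
    n = t.size
    if n == 0:
        raise InsufficientDataError("empty dataset")
    psi_e = np.asarray(predict(params, t), dtype=float)
    if np.any(psi_e <= 0) or not np.all(np.isfinite(psi_e)):
        logger.debug("non-positive predicted MIR; objective set to +inf")
        return float("inf")
    s = float(np.sum((np.log(psi_o) - np.log(psi_e)) ** 2))
    if s == 0.0:
        raise DegenerateFitError(
            "all log-residuals are exactly zero; -2lnL is unbounded below"
        )
    return n * (np.log(2.0 * np.pi * s / n) + 1.0)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit`.

    ``replicate=True`` applies the two-period convention before fitting
    (skipped if the dataset is already replicated).  ``gamma_bounds``
    defaults to ``(2, 2*period_unit)``, wide enough to let the data choose
    the period while excluding sub-Nyquist aliases of monthly sampling.
    ``n_starts`` caps the multi-start budget: harmonic-regression starts on
    ``gamma_grid``, phase rotations of the best of those, then seeded
    jittered copies.  Ties within ``tie_tol`` objective units resolve to
    the candidate whose period is nearest ``period_unit``.
    """

    replicate: bool = True
    n_starts: int = 16
    gamma_grid: tuple[float, ...] = (10.0, 11.0, 12.0, 13.0, 14.0)
    gamma_bounds: tuple[float, float] | None = None
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-10
    tie_tol: float = 1e-6
    seed: int = 0
    squared_trig: bool = False


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``neg2lnL`` is the minimized objective; ``n_used`` the observation count
    that entered it; ``start_values`` the initial parameter vectors tried,
    aligned with ``start_objectives`` (``inf`` for non-converged starts).
    """

    params: HarmonicParams
    neg2lnL: float
    n_used: int
    converged: bool
    n_starts: int
    start_values: tuple[tuple[float, ...], ...]
    start_objectives: tuple[float, ...]
    config: FitConfig
    sigma_log: float = field(default=float("nan"))

    @property
    def order(self) -> int:
        return self.params.order


def _design(t: np.ndarray, gamma: float, order: int, squared: bool) -> np.ndarray:
    w = 2.0 * np.pi * t / gamma
    cols = [np.ones_like(t), np.sin(w), np.cos(w)]
    if order == 2:
        if squared:
            cols += [np.sin(w) ** 2, np.cos(w) ** 2]
        else:
            cols += [np.sin(2.0 * w), np.cos(2.0 * w)]
    return np.column_stack(cols)


def _soft_floor(psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smooth positive surrogate for psi and its derivative w.r.t. psi.

    Below ``_PSI_FLOOR`` the prediction is mapped onto a positive
    exponential tail (C1-continuous at the floor) so log residuals stay
    finite and the trust-region step keeps a usable gradient.
    """
    low = psi <= _PSI_FLOOR
    # exponent computed from min(psi, floor) so it never overflows; clamped
    # below so the surrogate (and its log) stays finite
    expfac = np.exp(np.maximum(np.minimum(psi, _PSI_FLOOR) / _PSI_FLOOR - 1.0, -60.0))
    safe = np.where(low, _PSI_FLOOR * expfac, psi)
    dsafe = np.where(low, expfac, 1.0)
    return safe, dsafe


def _residuals_and_jac(
    x: np.ndarray,
    t: np.ndarray,
    log_psi_o: np.ndarray,
    order: int,
    squared: bool,
    free_mask: np.ndarray,
    full_template: np.ndarray,
):
    """Log residuals and Jacobian for the free subset of parameters.

    ``full_template`` carries fixed values (profiling); ``free_mask`` marks
    which of the ``N_FREE[order]`` parameters are optimized.
    """
    full = full_template.copy()
    full[free_mask] = x
    gamma = full[-1]
    betas = full[:-1]
    w = 2.0 * np.pi * t / gamma
    X = _design(t, gamma, order, squared)
    psi = X @ betas
    safe, dsafe = _soft_floor(psi)
    r = log_psi_o - np.log(safe)

    # d r / d theta = -(dsafe/dpsi) * (d psi / d theta) / safe
    dpsi_dbeta = X
    dpsi_dgamma = (betas[1] * np.cos(w) - betas[2] * np.sin(w)) * (-w / gamma)
    if order == 2:
        if squared:
            dpsi_dgamma += (betas[3] - betas[4]) * np.sin(2.0 * w) * (-w / gamma)
        else:
            dpsi_dgamma += (
                2.0 * betas[3] * np.cos(2.0 * w) - 2.0 * betas[4] * np.sin(2.0 * w)
            ) * (-w / gamma)
    J_full = np.column_stack([dpsi_dbeta, dpsi_dgamma])
    J = -(dsafe / safe)[:, None] * J_full[:, free_mask]
    return r, J


def _harmonic_ols_start(
    t: np.ndarray, psi_o: np.ndarray, gamma: float, order: int, squared: bool
) -> np.ndarray:
    """Linear harmonic regression of raw MIR on the basis at fixed gamma.

    Order-2 starts keep the second-harmonic betas at zero: the restricted
    optimum is an excellent, basin-safe initial point for the full model.
    """
    X = _design(t, gamma, order=1, squared=False)
    beta, *_ = np.linalg.lstsq(X, psi_o, rcond=None)
    if order == 1:
        return np.array([*beta, gamma])
    return np.array([*beta, 0.0, 0.0, gamma])


def _phase_rotations(start: np.ndarray, angles_deg: Sequence[float]) -> list[np.ndarray]:
    out = []
    for a in angles_deg:
        th = np.deg2rad(a)
        b1, b2 = start[1], start[2]
        rot = start.copy()
        rot[1] = b1 * np.cos(th) - b2 * np.sin(th)
        rot[2] = b1 * np.sin(th) + b2 * np.cos(th)
        out.append(rot)
    return out


def _build_starts(
    t: np.ndarray, psi_o: np.ndarray, order: int, cfg: FitConfig, period_unit: float
) -> list[np.ndarray]:
    starts = [
        _harmonic_ols_start(t, psi_o, g, order, cfg.squared_trig)
        for g in cfg.gamma_grid
    ]
    nearest = min(starts, key=lambda s: abs(s[-1] - period_unit))
    starts += _phase_rotations(nearest, (90.0, 180.0, 270.0))
    rng = np.random.default_rng(cfg.seed)
    scale = np.abs(nearest) + 1.0
    while len(starts) < cfg.n_starts:
        jitter = nearest + rng.normal(0.0, 0.15, size=nearest.size) * scale
        jitter[-1] = np.clip(jitter[-1], *_gamma_bounds(cfg, period_unit))
        starts.append(jitter)
    return starts[: max(cfg.n_starts, 1)]


def _gamma_bounds(cfg: FitConfig, period_unit: float) -> tuple[float, float]:
    if cfg.gamma_bounds is not None:
        return cfg.gamma_bounds
    return (2.0, 2.0 * period_unit)


def _objective_from_s(s: float, n: int) -> float:
    if s <= 0:
        raise DegenerateFitError("zero residual sum during optimization")
    return n * (np.log(2.0 * np.pi * s / n) + 1.0)


def minimize_s(
    t: np.ndarray,
    psi_o: np.ndarray,
    order: int,
    start_full: np.ndarray,
    cfg: FitConfig,
    period_unit: float,
    fixed: Mapping[int, float] | None = None,
):
    """One trust-region Gauss-Newton run; returns (full_vector, S, success).

    ``fixed`` maps parameter indices (position in the full vector, gamma
    last) to pinned values — the workhorse of profile likelihood.
    """
    k = N_FREE[order]
    free_mask = np.ones(k, dtype=bool)
    template = np.asarray(start_full, dtype=float).copy()
    if fixed:
        for idx, val in fixed.items():
            free_mask[idx] = False
            template[idx] = val
    x0 = template[free_mask]
    lo = np.full(k, -np.inf)
    hi = np.full(k, np.inf)
    lo[-1], hi[-1] = _gamma_bounds(cfg, period_unit)
    x0[-1] = np.clip(x0[-1], lo[-1] + 1e-9, hi[-1] - 1e-9) if free_mask[-1] else x0[-1]
    log_psi_o = np.log(psi_o)
    res = least_squares(
        lambda x: _residuals_and_jac(
            x, t, log_psi_o, order, cfg.squared_trig, free_mask, template
        )[0],
        x0,
        jac=lambda x: _residuals_and_jac(
            x, t, log_psi_o, order, cfg.squared_trig, free_mask, template
        )[1],
        bounds=(lo[free_mask], hi[free_mask]),
        method="trf",
        ftol=cfg.ftol,
        xtol=cfg.xtol,
        gtol=cfg.gtol,
        max_nfev=2000,
    )
    full = template.copy()
    full[free_mask] = res.x
    s = float(2.0 * res.cost)
    return full, s, bool(res.success)


def fit(
    data: MIRDataset,
    order: int,
    config: FitConfig | None = None,
    *,
    fixed: Mapping[str, float] | None = None,
    extra_starts: Sequence[np.ndarray] = (),
) -> FitResult:
    """Maximum-likelihood fit of an order-1 or order-2 harmonic curve.

    Applies two-period replication (unless disabled or already applied),
    runs the multi-start optimizer, and returns the best converged optimum.
    ``fixed`` pins named parameters (e.g. ``{"gamma": 11.5}``) and optimizes
    the rest — used by profile likelihood.  ``extra_starts`` prepends known
    good full-parameter vectors to the start list.

    Raises
    ------
    InsufficientDataError
        If the effective observation count does not exceed the free
        parameter count.
    FitFailureError
        If no start converges.
    """
    cfg = config or FitConfig()
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    work = data
    if cfg.replicate and not data.is_replicated:
        work = replicate_two_periods(data)
    t = work.times
    psi_o = work.mir
    n = t.size
    n_free = N_FREE[order] - (len(fixed) if fixed else 0)
    if n <= n_free:
        raise InsufficientDataError(
            f"{n} observation(s) cannot identify {n_free} free parameter(s)"
        )

    name_to_idx = {
        name: i
        for i, name in enumerate(
            HarmonicParams.from_vector(
                order, [0, 0, 0, 12] if order == 1 else [0, 0, 0, 0, 0, 12]
            ).names
        )
    }
    fixed_idx = {name_to_idx[k]: v for k, v in (fixed or {}).items()}

    starts = [np.asarray(s, dtype=float) for s in extra_starts]
    starts += _build_starts(t, psi_o, order, cfg, work.period_unit)

    candidates: list[tuple[np.ndarray, float, bool]] = []
    diagnostics: list[dict] = []
    for s0 in starts:
        try:
            full, s, ok = minimize_s(t, psi_o, order, s0, cfg, work.period_unit, fixed_idx)
        except DegenerateFitError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append({"start": s0.tolist(), "error": repr(exc)})
            continue
        obj = _objective_from_s(s, n)
        candidates.append((full, obj, ok))
        diagnostics.append({"start": s0.tolist(), "objective": obj, "converged": ok})

    converged = [(v, o) for v, o, ok in candidates if ok and np.isfinite(o)]
    if not converged:
        raise FitFailureError("no optimizer start converged", diagnostics)

    best_obj = min(o for _, o in converged)
    tied = [(v, o) for v, o in converged if o - best_obj < cfg.tie_tol]
    if len(tied) > 1:
        logger.info(
            "%d co-optimal starts within %.1e; keeping gamma nearest %.1f",
            len(tied),
            cfg.tie_tol,
            work.period_unit,
        )
    best_vec, best_obj = min(
        tied, key=lambda vo: (abs(vo[0][-1] - work.period_unit), vo[1])
    )

    params = HarmonicParams.from_vector(order, best_vec, squared_trig=cfg.squared_trig)
    s_best = float(
        np.sum((np.log(psi_o) - np.log(np.asarray(predict(params, t)))) ** 2)
    )
    return FitResult(
        params=params,
        neg2lnL=float(best_obj),
        n_used=n,
        converged=True,
        n_starts=len(starts),
        start_values=tuple(tuple(s) for s in starts),
        start_objectives=tuple(o for _, o, _ok in candidates),
        config=cfg,
        sigma_log=float(np.sqrt(s_best / n)),
    )


def hessian(data: MIRDataset, fit_result: FitResult, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of ``-2 ln L`` at the fitted optimum.

    Steps are scaled per parameter (``step * max(|theta|, 1)``).  Used to
    size the profile-likelihood search grid via Wald standard errors.
    """
    work = data
    if fit_result.config.replicate and not data.is_replicated:
        work = replicate_two_periods(data)
    vec = fit_result.params.to_vector()
    k = vec.size
    h = step * np.maximum(np.abs(vec), 1.0)

    def f(v: np.ndarray) -> float:
        p = HarmonicParams.from_vector(
            fit_result.order, v, squared_trig=fit_result.config.squared_trig
        )
        return neg2_log_likelihood(work, p)

    H = np.empty((k, k))
    f0 = f(vec)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(vec + ei) - 2.0 * f0 + f(vec - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(vec + ei + ej) - f(vec + ei - ej) - f(vec - ei + ej) + f(vec - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def wald_se(data: MIRDataset, fit_result: FitResult) -> np.ndarray:
    """Asymptotic standard errors from the inverse half-Hessian of -2lnL.

    Falls back to a crude curvature-based scale for any direction in which
    the Hessian is not positive definite.
    """
    H = hessian(data, fit_result)
    try:
        cov = np.linalg.inv(0.5 * H)
        se = np.sqrt(np.diag(cov))
        if np.all(np.isfinite(se)) and np.all(se > 0):
            return se
    except np.linalg.LinAlgError:
        pass
    diag = np.diag(H)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(diag > 0, 2.0 / diag, np.nan))
    se = np.where(np.isfinite(se), se, np.maximum(np.abs(fit_result.params.to_vector()), 1.0) * 0.1)
    return se


def fit_report(fit_result: FitResult) -> dict:
    """JSON-serializable fit report: params, objective, convergence, config."""
    p = fit_result.params
    return {
        "model": f"H{p.order}",
        "params": dict(zip(p.names, p.to_vector().tolist())),
        "neg2lnL": fit_result.neg2lnL,
        "sigma_log": fit_result.sigma_log,
        "n_used": fit_result.n_used,
        "n_free_params": p.n_free,
        "converged": fit_result.converged,
        "n_starts": fit_result.n_starts,
        "config": {
            "replicate": fit_result.config.replicate,
            "n_starts": fit_result.config.n_starts,
            "gamma_grid": list(fit_result.config.gamma_grid),
            "gamma_bounds": fit_result.config.gamma_bounds,
            "seed": fit_result.config.seed,
            "squared_trig": fit_result.config.squared_trig,
        },
    }
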
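"""Single- and second-order harmonic (Fourier) mean curves for MIR data.

The expected MIR at month ``t`` is modelled as a truncated Fourier series
with an *estimated* period ``gamma`` (months per cycle):

order 1 (H1, symmetric)::

    psi(t) = b0 + b1*sin(2*pi*t/gamma) + b2*cos(2*pi*t/gamma)

order 2 (H2, can be asymmetric)::

    psi(t) = H1(t) + b3*sin(4*pi*t/gamma) + b4*cos(4*pi*t/gamma)

``gamma`` close to 12 on monthly data indicates annual band deposition.  The
second harmonic lets the curve rise and fall at different rates, capturing
e.g. a rapid band-formation phase followed by a plateau.  Angles are in
radians; ``t`` stays on the natural month scale (no re-scaling of the data).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["HarmonicParams", "predict", "curve_extremes", "export_curve"]

#: free parameters per model order (betas + gamma)
N_FREE = {1: 4, 2: 6}


@dataclass(frozen=True)
class HarmonicParams:
    """Coefficients of an order-1 or order-2 harmonic mean curve.

    ``beta0`` is the cycle-average MIR level (%), ``beta1``/``beta2`` the
    first-harmonic amplitudes, ``beta3``/``beta4`` the second-harmonic
    amplitudes (order 2 only), and ``gamma`` the period in months (> 0).

    ``squared_trig`` switches the order-2 extra terms to the literal
    squared-sinusoid basis ``b3*sin^2 + b4*cos^2``.  That basis is linearly
    reducible to a constant plus a second harmonic (it confounds ``beta0``),
    and is provided only for cross-checking the Fourier reading.
    """

    order: int
    beta0: float
    beta1: float
    beta2: float
    gamma: float
    beta3: float | None = None
    beta4: float | None = None
    squared_trig: bool = False

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError(f"order must be 1 or 2, got {self.order}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.order == 1 and not (self.beta3 is None and self.beta4 is None):
            raise ValueError("order-1 model must not carry second-harmonic betas")
        if self.order == 2 and (self.beta3 is None or self.beta4 is None):
            raise ValueError("order-2 model requires beta3 and beta4")

    @property
    def n_free(self) -> int:
        """Free-parameter count: 4 for order 1, 6 for order 2."""
        return N_FREE[self.order]

    @property
    def names(self) -> tuple[str, ...]:
        if self.order == 1:
            return ("beta0", "beta1", "beta2", "gamma")
        return ("beta0", "beta1", "beta2", "beta3", "beta4", "gamma")

    def to_vector(self) -> np.ndarray:
        """Free parameters as an array, betas first then gamma."""
        if self.order == 1:
            return np.array([self.beta0, self.beta1, self.beta2, self.gamma])
        return np.array(
            [self.beta0, self.beta1, self.beta2, self.beta3, self.beta4, self.gamma]
        )

    @classmethod
    def from_vector(
        cls, order: int, vec: Iterable[float], *, squared_trig: bool = False
    ) -> "HarmonicParams":
        v = [float(x) for x in vec]
        if order == 1:
            b0, b1, b2, g = v
            return cls(1, b0, b1, b2, g, squared_trig=squared_trig)
        b0, b1, b2, b3, b4, g = v
        return cls(2, b0, b1, b2, g, beta3=b3, beta4=b4, squared_trig=squared_trig)


def predict(params: HarmonicParams, t: float | np.ndarray) -> float | np.ndarray:
    """Expected MIR at month(s) ``t`` under the harmonic curve.

    Periodic with period ``gamma``: ``predict(t + k*gamma) == predict(t)``.
    """
    t = np.asarray(t, dtype=float)
    w = 2.0 * np.pi * t / params.gamma
    out = params.beta0 + params.beta1 * np.sin(w) + params.beta2 * np.cos(w)
    if params.order == 2:
        if params.squared_trig:
            out = out + params.beta3 * np.sin(w) ** 2 + params.beta4 * np.cos(w) ** 2
        else:
            out = out + params.beta3 * np.sin(2.0 * w) + params.beta4 * np.cos(2.0 * w)
    return out if out.ndim else float(out)


def curve_extremes(
    params: HarmonicParams, resolution: float = None  # type: ignore[assignment]
) -> tuple[float, float, float, float]:
    """Global maximum and minimum of the curve over one period ``[0, gamma)``.

    A dense grid scan (default 10,000 points per period) brackets each
    extreme; bounded golden-section refinement then locates it to ~1e-8 in
    ``t``.  Returns ``(t_max, psi_max, t_min, psi_min)``.
    """
    if resolution is None:
        resolution = params.gamma / 10_000
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    n = max(int(np.ceil(params.gamma / resolution)), 8)
    grid = np.linspace(0.0, params.gamma, n, endpoint=False)
    vals = predict(params, grid)
    step = params.gamma / n

    def _refine(i: int, sign: float) -> tuple[float, float]:
        lo, hi = grid[i] - step, grid[i] + step
        res = minimize_scalar(
            lambda t: sign * predict(params, t),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-9},
        )
        return float(res.x) % params.gamma, float(sign * res.fun)

    t_max, psi_max = _refine(int(np.argmax(vals)), -1.0)
    t_min, psi_min = _refine(int(np.argmin(vals)), 1.0)
    return t_max, psi_max, t_min, psi_min


def export_curve(
    params: HarmonicParams, t: Iterable[float] | None = None, n: int = 241
) -> pd.DataFrame:
    """Evaluation table ``(t, psi_e)`` for plotting; one period by default."""
    if t is None:
        t = np.linspace(0.0, params.gamma, n)
    t = np.asarray(list(t), dtype=float)
    return pd.DataFrame({"t": t, "psi_e": predict(params, t)})


def strip_second_harmonic(params: HarmonicParams) -> HarmonicParams:
    """The nested order-1 model sharing ``beta0..beta2`` and ``gamma``."""
    if params.order == 1:
        return params
    return HarmonicParams(1, params.beta0, params.beta1, params.beta2, params.gamma)


def widen_to_second_order(params: HarmonicParams) -> HarmonicParams:
    """Embed an order-1 model in the order-2 family with zero extra betas."""
    if params.order == 2:
        return params
    return replace(params, order=2, beta3=0.0, beta4=0.0)
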
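"""Age-invariance check for growth-increment proportions.

The MIR approach assumes that successive growth bands keep a roughly
constant proportion across an animal's life, so that the marginal ratio is
comparable between young and old individuals.  The check: for each measured
individual, compute the growth-increment ratio at age i,

    IR_i = GI_i / GI_{i-1} * 100,

the size of the band laid down at age i relative to the previous band;
average IR within each age class; and regress mean IR on age by ordinary
least squares.  A slope indistinguishable from zero (F test, alpha = 0.05)
supports age-invariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mir_core import InvalidMeasurementError

__all__ = [
    "IncrementSeries",
    "RegressionSummary",
    "increment_ratio",
    "mean_ir_by_age",
    "regress_ir_on_age",
    "read_increment_series",
]


@dataclass(frozen=True)
class IncrementSeries:
    """One individual's growth-increment sizes ordered by age.

    ``increments[k]`` is the band deposited at ``first_age + k``; sizes may
    be absolute lengths or relative units (IR is scale-invariant).
    """

    sample_id: str
    increments: tuple[float, ...]
    first_age: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "increments", tuple(float(g) for g in self.increments))
        if any(g <= 0 or not np.isfinite(g) for g in self.increments):
            raise InvalidMeasurementError(
                f"sample {self.sample_id!r}: growth increments must be finite and > 0"
            )


@dataclass(frozen=True)
class RegressionSummary:
    """OLS summary for mean IR against age.

    ``r_squared`` is the plain coefficient of determination;
    ``r_squared_adj`` the adjusted version (may be negative for a
    non-informative fit).  ``f_stat`` tests the zero-slope null on
    ``(df_num, df_den) = (1, k - 2)`` for k age classes.
    """

    slope: float
    intercept: float
    r_squared: float
    r_squared_adj: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "r_squared_adj": self.r_squared_adj,
            "f_stat": self.f_stat,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
        }


def increment_ratio(series: IncrementSeries) -> list[tuple[int, float]]:
    """Per-age increment ratios ``(age_i, 100 * GI_i / GI_{i-1})``.

    The output has one entry per consecutive pair, starting at the series'
    second age.  Constant band sizes give IR = 100 everywhere; geometric
    shrinkage by factor r gives IR = 100 r.
    """
    g = series.increments
    if len(g) < 2:
        raise ValueError(
            f"sample {series.sample_id!r}: need at least 2 increments, got {len(g)}"
        )
    return [
        (series.first_age + i, 100.0 * g[i] / g[i - 1]) for i in range(1, len(g))
    ]


def mean_ir_by_age(
    series: Iterable[IncrementSeries], min_age: int | None = None
) -> pd.DataFrame:
    """Average IR within each age class across individuals.

    ``min_age`` drops age classes younger than the youngest individual used
    in the periodicity modelling (so both analyses cover the same ages).
    """
    rows: list[tuple[int, float]] = []
    for s in series:
        rows.extend(increment_ratio(s))
    df = pd.DataFrame(rows, columns=["age", "ir"])
    if min_age is not None:
        df = df[df["age"] >= min_age]
    out = df.groupby("age", as_index=False).agg(mean_ir=("ir", "mean"), n=("ir", "size"))
    return out


def regress_ir_on_age(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    min_age: int | None = None,
) -> RegressionSummary:
    """OLS of mean IR per age class on age, with the zero-slope F test.

    ``points`` is either ``(age, mean IR)`` pairs or the frame produced by
    :func:`mean_ir_by_age`.  For simple regression the slope F statistic is
    the squared slope t statistic, with df (1, k-2).
    """
    if isinstance(points, pd.DataFrame):
        pts = list(zip(points["age"], points["mean_ir"]))
    else:
        pts = [(float(a), float(y)) for a, y in points]
    if min_age is not None:
        pts = [(a, y) for a, y in pts if a >= min_age]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 age classes, got {len(pts)}")
    age = np.array([a for a, _ in pts])
    ir = np.array([y for _, y in pts])
    k = len(pts)
    if np.ptp(ir) == 0:
        # exactly flat response: zero slope, no explained variance
        return RegressionSummary(0.0, float(ir[0]), 0.0, 0.0, 0.0, 1, k - 2, 1.0)
    res = stats.linregress(age, ir)
    r2 = float(res.rvalue**2)
    r2_adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
    # F for the slope in simple OLS is t^2; guard the exact-fit case where
    # stderr is 0 and t is undefined
    if res.stderr == 0:
        f = 0.0 if res.slope == 0 else float("inf")
        p = 1.0 if res.slope == 0 else 0.0
    else:
        tstat = res.slope / res.stderr
        f = float(tstat**2)
        p = float(res.pvalue)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        r_squared_adj=float(r2_adj),
        f_stat=f,
        df_num=1,
        df_den=k - 2,
        p_value=p,
    )


def read_increment_series(path: str | Path) -> list[IncrementSeries]:
    """Read long-format increment data: columns ``sample_id, age, increment``.

    Rows are grouped by individual and sorted by age; each individual's ages
    must be consecutive.
    """
    df = pd.read_csv(path)
    df = df.rename(columns={c: str(c).strip().lower() for c in df.columns})
    needed = {"sample_id", "age", "increment"}
    if not needed <= set(df.columns):
        raise KeyError(f"{Path(path).name}: need columns {sorted(needed)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy()
        if len(ages) > 1 and not np.all(np.diff(ages) == 1):
            raise ValueError(f"sample {sid!r}: ages must be consecutive")
        out.append(
            IncrementSeries(
                sample_id=str(sid),
                increments=tuple(grp["increment"].astype(float)),
                first_age=int(ages[0]),
            )
        )
    return out
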
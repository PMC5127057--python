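"""Relative-activity profiles and first-order inactivation half-lives.

Inactivation is modelled as a single exponential A(t) = 100*exp(-k*t);
k comes from a log-linear regression and t1/2 = ln(2)/k. Series that
barely decay inside the observation window are reported as censored
lower bounds (the "> t_max" convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .assay_io import DecaySeries
from .errors import DegenerateDataError, InputError

__all__ = ["ActivityProfile", "HalfLifeResult", "normalize_profile", "fit_half_life"]

#: residual activities below this percent sit at the detection floor and
#: are excluded from the log-linear fit
DEFAULT_ACTIVITY_FLOOR_PCT = 5.0

#: a series whose last observed activity is above this percent has not
#: decayed past one half-life and is reported censored
CENSOR_THRESHOLD_PCT = 50.0


@dataclass
class ActivityProfile:
    condition_kind: str
    conditions: list[float]
    relative_inhibition: list[float]  # percent, max == 100


@dataclass
class HalfLifeResult:
    condition_kind: str
    condition_value: float
    k_inact: float  # min^-1
    t_half: float  # minutes; lower bound when censored
    censored: bool
    r_squared: float

    @property
    def label(self) -> str:
        if self.censored:
            return f">{self.t_half:g}"
        return f"{self.t_half:g}"


def normalize_profile(
    raw: Sequence[tuple[float, float]], condition_kind: str = "temperature"
) -> ActivityProfile:
    """Scale inhibition values so the optimum condition reads 100%."""
    if len(raw) < 2:
        raise InputError(f"need >= 2 conditions, got {len(raw)}")
    values = [float(v) for _, v in raw]
    peak = max(values)
    if peak <= 0:
        raise DegenerateDataError("all inhibition values are zero")
    return ActivityProfile(
        condition_kind=condition_kind,
        conditions=[float(c) for c, _ in raw],
        relative_inhibition=[100.0 * v / peak for v in values],
    )


def fit_half_life(
    decay: DecaySeries,
    activity_floor_pct: float = DEFAULT_ACTIVITY_FLOOR_PCT,
    nonlinear: bool = False,
) -> HalfLifeResult:
    """First-order inactivation rate and half-life for one condition.

    Uses a variance-weighted log-linear regression of ln(activity) on
    time over points above the detection floor (weights A^2, the
    inverse-variance weights for additive activity noise pushed through
    the log transform); ``nonlinear=True`` instead refines the rate by
    nonlinear least squares on the raw (untransformed) activities.

    When the final observed activity is still above 50%, the half-life
    cannot be bracketed by the data and the result is censored with
    t_half reported as the observation-window lower bound.
    """
    t = decay.times
    a = decay.residual_activity
    if t.size < 3 or t[0] != 0:
        raise InputError(
            f"{decay.label}: need >= 3 time points including t=0, got {t.size}"
        )
    if a[-1] > a[0]:
        warnings.warn(
            f"{decay.label}: activity increases over time; "
            f"first-order decay model violated",
            stacklevel=2,
        )

    mask = a > activity_floor_pct
    if mask.sum() < 2:
        raise InputError(f"{decay.label}: fewer than 2 points above the detection floor")
    # Weighted log-linear regression: additive noise on A becomes
    # heteroscedastic after the log transform (var(ln A) ~ sigma^2/A^2),
    # so weights proportional to A^2 restore inverse-variance weighting.
    tm, am = t[mask], a[mask]
    y = np.log(am)
    w = am**2
    wsum = w.sum()
    tbar = (w * tm).sum() / wsum
    ybar = (w * y).sum() / wsum
    sxx = (w * (tm - tbar) ** 2).sum()
    sxy = (w * (tm - tbar) * (y - ybar)).sum()
    slope = sxy / sxx
    k = -float(slope)
    ss_res = (w * (y - ybar - slope * (tm - tbar)) ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0

    if nonlinear and k > 0:
        a0 = float(a[0])

        def residuals(p):
            return p[0] * np.exp(-p[1] * t[mask]) - a[mask]

        sol = optimize.least_squares(residuals, [a0, k], max_nfev=10_000)
        k = float(sol.x[1])
        ss_res = float(np.sum(sol.fun**2))
        ss_tot = float(np.sum((a[mask] - a[mask].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    censored = bool(a[-1] > CENSOR_THRESHOLD_PCT)
    if censored:
        t_half = float(t[-1])  # lower bound: still above half activity at t_max
    else:
        if k <= 0:
            raise DegenerateDataError(f"{decay.label}: non-positive decay rate fitted")
        t_half = math.log(2.0) / k

    return HalfLifeResult(
        condition_kind=decay.condition_kind,
        condition_value=decay.condition_value,
        k_inact=k,
        t_half=t_half,
        censored=censored,
        r_squared=r2,
    )
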
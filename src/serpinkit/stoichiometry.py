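"""Stoichiometry of inhibition from fractional-activity titrations.

The stoichiometry of inhibition (SI) is the x-intercept of the linear
regression of fractional activity against the inhibitor:enzyme molar
ratio, restricted to the linear (pre-plateau) regime.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .assay_io import TitrationSeries
from .errors import DomainError, InputError, NonInhibitoryError

__all__ = ["SIResult", "fractional_activity", "fit_si"]

#: fractional activities at or below this value are treated as the
#: post-intercept plateau and excluded from the regression
DEFAULT_ACTIVITY_FLOOR = 0.05


@dataclass
class SIResult:
    si: float
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def fractional_activity(v_inhibited: float, v_uninhibited: float) -> float:
    """Ratio of inhibited to uninhibited reaction velocity."""
    if v_uninhibited <= 0:
        raise DomainError(f"uninhibited velocity must be > 0, got {v_uninhibited}")
    return v_inhibited / v_uninhibited


def fit_si(
    series: TitrationSeries,
    fit_range: tuple[float, float] | None = None,
    activity_floor: float = DEFAULT_ACTIVITY_FLOOR,
) -> SIResult:
    """X-intercept linear regression of a fractional-activity titration.

    Parameters
    ----------
    series:
        Titration points (ratio, fractional activity).
    fit_range:
        Optional (min_ratio, max_ratio) window; points outside it are
        dropped before fitting.
    activity_floor:
        Points with fractional activity <= this are excluded — past the
        x-intercept the curve plateaus near zero and breaks linearity.
    """
    pts = series.points
    if fit_range is not None:
        lo, hi = fit_range
        pts = [(r, a) for r, a in pts if lo <= r <= hi]
    pts = [(r, a) for r, a in pts if a > activity_floor]
    if len(pts) < 3:
        raise InputError(
            f"titration {series.protease_id!r}: need >= 3 usable points above the "
            f"activity floor, got {len(pts)}"
        )
    ratios = [r for r, _ in pts]
    acts = [a for _, a in pts]
    res = stats.linregress(ratios, acts)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope >= 0:
        raise NonInhibitoryError(
            f"titration {series.protease_id!r}: activity does not decrease with "
            f"inhibitor ratio (slope={slope:.3g})"
        )
    return SIResult(
        si=-intercept / slope,
        slope=slope,
        intercept=intercept,
        r_squared=float(res.rvalue**2),
        n_points=len(pts),
    )
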
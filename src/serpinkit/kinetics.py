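"""Progress-curve kinetics of irreversible inhibition.

Pipeline: each trace is fitted to the single-exponential product model

    P(t) = (v0 / kobs) * (1 - exp(-kobs * t))           (+ optional baseline)

giving a pseudo-first-order rate kobs per inhibitor concentration; kobs
vs [I] is fitted by ordinary least squares, whose slope k'app is then
corrected for competition by the reporter substrate,

    ka = k'app * (1 + [S] / Km),

yielding the second-order association rate constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .assay_io import ProgressCurve
from .errors import DegenerateDataError, DomainError, InputError

__all__ = [
    "ProgressFit",
    "AssociationFit",
    "irreversible_progress",
    "fit_progress_curve",
    "fit_kobs_vs_inhibitor",
    "correct_association_constant",
    "run_association_pipeline",
]

MIN_CURVE_POINTS = 5


@dataclass
class ProgressFit:
    """Per-curve nonlinear fit result."""

    curve_id: str
    v0: float
    kobs: float
    baseline: float
    rss: float
    converged: bool

    @property
    def plateau(self) -> float:
        """Asymptotic signal above baseline, v0/kobs (inf when kobs == 0)."""
        return self.v0 / self.kobs if self.kobs > 0 else float("inf")


@dataclass
class AssociationFit:
    """kobs-vs-[I] regression plus the competition-corrected ka.

    Concentrations here are molar (M); ka and kapp_prime are M^-1 s^-1.
    """

    kapp_prime: float
    intercept: float
    r_squared: float
    substrate_conc: float
    km: float
    ka: float = field(init=False)
    points: list[tuple[float, float]] = field(default_factory=list)
    curve_fits: list[ProgressFit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ka = correct_association_constant(self.kapp_prime, self.substrate_conc, self.km)


def irreversible_progress(
    t: np.ndarray, v0: float, kobs: float, baseline: float = 0.0
) -> np.ndarray:
    """Product signal under pseudo-first-order enzyme loss.

    Continuous at kobs -> 0, where the model degenerates to baseline + v0*t.
    """
    t = np.asarray(t, dtype=float)
    if kobs == 0.0:
        return baseline + v0 * t
    # -expm1 keeps full precision for small kobs*t
    return baseline + (v0 / kobs) * (-np.expm1(-kobs * t))


def _initial_guess(times: np.ndarray, signal: np.ndarray, baseline: float):
    n = times.size
    head = max(2, int(np.ceil(0.1 * n)))
    v0 = float(np.polyfit(times[:head], signal[:head], 1)[0])
    span = float(np.max(signal) - baseline)
    if v0 <= 0:
        v0 = max(span / max(times[-1], 1.0), 1e-12)
    # log-linear fit of the residual approach to plateau
    resid = span - (signal - baseline)
    mask = resid > 1e-3 * max(span, 1e-300)
    kobs = 1.0 / max(times[-1], 1.0)
    if mask.sum() >= 2:
        slope = np.polyfit(times[mask], np.log(resid[mask]), 1)[0]
        if slope < 0:
            kobs = -float(slope)
    return v0, kobs


def fit_progress_curve(
    curve: ProgressCurve,
    fit_baseline: bool | None = None,
    max_iter: int = 10_000,
) -> ProgressFit:
    """Nonlinear least-squares fit of (v0, kobs) to one progress curve.

    A baseline offset is co-estimated when the t=0 signal is materially
    nonzero (|signal[0]| above 5% of the signal range) or when
    ``fit_baseline=True`` is forced.
    """
    t, y = curve.times, curve.signal
    if t.size < MIN_CURVE_POINTS:
        raise InputError(
            f"curve {curve.curve_id!r}: need >= {MIN_CURVE_POINTS} points, got {t.size}"
        )
    span = float(np.ptp(y))
    if span == 0.0:
        raise DegenerateDataError(f"curve {curve.curve_id!r}: signal is constant")
    if fit_baseline is None:
        fit_baseline = abs(float(y[0])) > 0.05 * span

    b0 = float(y[0]) if fit_baseline else 0.0
    v0_init, kobs_init = _initial_guess(t, y, b0)

    if fit_baseline:
        def residuals(p):
            return irreversible_progress(t, p[0], p[1], p[2]) - y

        x0 = [v0_init, kobs_init, b0]
        lower = [0.0, 0.0, -np.inf]
        upper = [np.inf, np.inf, np.inf]
    else:
        def residuals(p):
            return irreversible_progress(t, p[0], p[1]) - y

        x0 = [v0_init, kobs_init]
        lower = [0.0, 0.0]
        upper = [np.inf, np.inf]

    sol = optimize.least_squares(
        residuals,
        x0,
        bounds=(lower, upper),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_iter,
    )
    v0, kobs = float(sol.x[0]), float(sol.x[1])
    baseline = float(sol.x[2]) if fit_baseline else 0.0
    return ProgressFit(
        curve_id=curve.curve_id,
        v0=v0,
        kobs=kobs,
        baseline=baseline,
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
    )


def fit_kobs_vs_inhibitor(
    points: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """Ordinary least-squares line through (inhibitor concentration, kobs).

    Returns (slope, intercept, r_squared); the slope is the apparent
    second-order constant k'app when [I] is molar and kobs is s^-1.
    """
    pts = [(float(i), float(k)) for i, k in points]
    if len(pts) < 3:
        raise InputError(f"need >= 3 (inhibitor, kobs) points, got {len(pts)}")
    conc = np.array([i for i, _ in pts])
    kobs = np.array([k for _, k in pts])
    if np.unique(conc).size < 3:
        raise InputError("need >= 3 distinct inhibitor concentrations")
    res = stats.linregress(conc, kobs)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def correct_association_constant(
    kapp_prime: float, substrate_conc: float, km: float
) -> float:
    """Substrate-competition correction: ka = k'app * (1 + [S]/Km).

    substrate_conc and km must share units; ka inherits the units of
    kapp_prime.
    """
    if km <= 0:
        raise DomainError(f"Km must be > 0, got {km}")
    if substrate_conc < 0:
        raise DomainError(f"substrate concentration must be >= 0, got {substrate_conc}")
    return kapp_prime * (1.0 + substrate_conc / km)


def run_association_pipeline(
    curves: Sequence[ProgressCurve],
    km: float,
    fit_baseline: bool | None = None,
) -> AssociationFit:
    """Full trace-to-ka pipeline over one inhibitor dilution series.

    ``km`` is molar. Curve concentrations (µM, per the canonical table
    units) are converted to molar internally. Curves at [I]=0 are
    excluded from the kobs regression.
    """
    if not curves:
        raise InputError("no progress curves supplied")
    sub_um = {round(c.substrate_conc, 9) for c in curves}
    if len(sub_um) != 1:
        raise InputError(f"curves mix substrate concentrations: {sorted(sub_um)}")
    substrate_m = curves[0].substrate_conc * 1e-6

    fits: list[ProgressFit] = []
    points: list[tuple[float, float]] = []
    for curve in curves:
        if curve.inhibitor_conc <= 0:
            continue
        if curve.enzyme_conc > 0 and curve.inhibitor_conc / curve.enzyme_conc < 1.0:
            warnings.warn(
                f"curve {curve.curve_id!r}: [I]/[E] = "
                f"{curve.inhibitor_conc / curve.enzyme_conc:.2f} < 1; "
                f"pseudo-first-order assumption strained",
                stacklevel=2,
            )
        fit = fit_progress_curve(curve, fit_baseline=fit_baseline)
        fits.append(fit)
        points.append((curve.inhibitor_conc * 1e-6, fit.kobs))

    if len({round(i, 15) for i, _ in points}) < 3:
        raise InputError("need >= 3 distinct nonzero inhibitor concentrations")

    slope, intercept, r2 = fit_kobs_vs_inhibitor(points)
    return AssociationFit(
        kapp_prime=slope,
        intercept=intercept,
        r_squared=r2,
        substrate_conc=substrate_m,
        km=km,
        points=points,
        curve_fits=fits,
    )
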
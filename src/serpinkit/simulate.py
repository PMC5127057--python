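"""Synthetic-assay generator.

Emits every table the analysis pipeline consumes, with the statistical
structure the fits assume: exponential product-accumulation curves under
pseudo-first-order inhibition with substrate competition, clipped-linear
stoichiometry titrations, first-order inactivation decays, and
group-structured activity panels.

Randomness: one global integer seed per scenario; every sub-series draws
from ``numpy.random.default_rng([seed, counter])`` so adding a series
never shifts the noise of the others, and a fixed seed fixes every byte
of output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assay_io import ActivityMeasurement, DecaySeries, ProgressCurve, TitrationSeries
from .errors import ValidationError

__all__ = [
    "KineticScenario",
    "simulate_progress_curves",
    "simulate_titration",
    "simulate_decay",
    "simulate_fecal_assay",
]

LN2 = np.log(2.0)


@dataclass
class KineticScenario:
    """Generating parameters for one inhibitor dilution series.

    All concentrations are molar; ka_true is M^-1 s^-1.
    """

    ka_true: float
    km: float
    substrate_conc: float
    enzyme_conc: float
    inhibitor_concs: Sequence[float]
    v_max_signal: float = 1e-3
    duration: float = 1200.0
    n_timepoints: int = 61
    noise_sd_frac: float = 0.0
    si_true: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ka_true", "km", "substrate_conc", "enzyme_conc", "v_max_signal", "duration"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"scenario field {name} must be > 0")
        if self.si_true < 1:
            raise ValidationError("si_true must be >= 1")
        if self.n_timepoints < 2:
            raise ValidationError("n_timepoints must be >= 2")
        if self.noise_sd_frac < 0:
            raise ValidationError("noise_sd_frac must be >= 0")
        if not self.inhibitor_concs or any(i <= 0 for i in self.inhibitor_concs):
            raise ValidationError("inhibitor_concs must be non-empty and positive")

    @property
    def competition_factor(self) -> float:
        return 1.0 + self.substrate_conc / self.km

    def kobs(self, inhibitor_conc: float) -> float:
        """Pseudo-first-order rate at one inhibitor concentration."""
        return self.ka_true * inhibitor_conc / self.competition_factor

    @property
    def v0(self) -> float:
        """Uninhibited hydrolysis velocity at the scenario substrate level."""
        return self.v_max_signal * self.substrate_conc / (self.km + self.substrate_conc)


def _rng(seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(counter)])


def simulate_progress_curves(
    s: KineticScenario, mode: str = "closed_form"
) -> list[ProgressCurve]:
    """One progress curve per inhibitor concentration.

    ``mode='closed_form'`` draws from the exponential product model the
    fitter assumes; ``mode='ode'`` integrates the branched
    suicide-substrate mechanism (association consumes inhibitor; a
    fraction 1/SI of encounters traps the enzyme, the rest release it
    with cleaved inhibitor) and is meant for stress-testing the fits.
    """
    if mode not in ("closed_form", "ode"):
        raise ValidationError(f"unknown simulation mode {mode!r}")
    t = np.linspace(0.0, s.duration, s.n_timepoints)
    curves = []
    for i, inhib in enumerate(s.inhibitor_concs):
        if mode == "closed_form":
            kobs = s.kobs(inhib)
            clean = (s.v0 / kobs) * (-np.expm1(-kobs * t))
            plateau = s.v0 / kobs
        else:
            clean = _integrate_suicide_mechanism(s, inhib, t)
            plateau = max(float(clean[-1]), s.v0 / s.kobs(inhib))
        signal = clean
        if s.noise_sd_frac > 0:
            signal = clean + _rng(s.seed, i).normal(0.0, s.noise_sd_frac * plateau, t.size)
        curves.append(
            ProgressCurve(
                curve_id=f"sim_I{i}",
                times=t,
                signal=signal,
                inhibitor_conc=inhib * 1e6,
                enzyme_conc=s.enzyme_conc * 1e6,
                substrate_conc=s.substrate_conc * 1e6,
                signal_kind="absorbance",
            )
        )
    return curves


def _integrate_suicide_mechanism(
    s: KineticScenario, inhibitor_conc: float, t: np.ndarray
) -> np.ndarray:
    """Branched-pathway ODE: d[I]/dt = -k'[E][I], d[E]/dt = -k'[E][I]/SI.

    k' is the substrate-attenuated association rate; product accumulates
    at v0 scaled by the surviving enzyme fraction.
    """
    from scipy.integrate import solve_ivp

    k_prime = s.ka_true / s.competition_factor

    def rhs(_t, y):
        e, i, _p = y
        assoc = k_prime * e * i
        return [-assoc / s.si_true, -assoc, s.v0 * e / s.enzyme_conc]

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [s.enzyme_conc, inhibitor_conc, 0.0],
        t_eval=t,
        rtol=1e-10,
        atol=1e-14,
        method="LSODA",
    )
    return sol.y[2]


def simulate_titration(
    si_true: float,
    ratios: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    protease_id: str = "sim",
    enzyme_conc: float = 0.2,
) -> TitrationSeries:
    """Clipped-linear titration a(r) = max(0, 1 - r/SI) + Gaussian noise."""
    if si_true < 1:
        raise ValidationError("si_true must be >= 1")
    r = np.asarray(list(ratios), dtype=float)
    a = np.clip(1.0 - r / si_true, 0.0, None)
    if noise_sd > 0:
        a = a + _rng(seed, 0).normal(0.0, noise_sd, r.size)
    return TitrationSeries(
        protease_id=protease_id,
        enzyme_conc=enzyme_conc,
        points=list(zip(r.tolist(), a.tolist())),
    )


def simulate_decay(
    t_half_true: float,
    times: Sequence[float],
    noise_sd_pct: float = 0.0,
    seed: int = 0,
    condition_kind: str = "temperature",
    condition_value: float = 60.0,
) -> DecaySeries:
    """First-order decay A(t) = 100*2^(-t/t_half) + noise, floored at 0.

    ``noise_sd_pct`` is an absolute sd in percentage points.
    """
    if t_half_true <= 0:
        raise ValidationError("t_half_true must be > 0")
    t = np.asarray(list(times), dtype=float)
    a = 100.0 * np.exp(-LN2 * t / t_half_true)
    if noise_sd_pct > 0:
        a = np.clip(a + _rng(seed, 0).normal(0.0, noise_sd_pct, t.size), 0.0, None)
    return DecaySeries(
        condition_kind=condition_kind,
        condition_value=condition_value,
        times=t,
        residual_activity=a,
    )


def simulate_fecal_assay(
    control_mean: float,
    fold_dss: float,
    inhibition_pct_by_siropin: Mapping[str, float],
    n_per_group: int = 8,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[ActivityMeasurement]:
    """Group-structured activity panel: control, challenge, challenge+inhibitor.

    Groups are PBS (mean ``control_mean``), DSS (control * ``fold_dss``)
    and DSS+<name> (DSS mean reduced by the stated inhibition percent).
    Replicate noise is lognormal with the requested coefficient of
    variation, preserving each group mean.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if control_mean <= 0 or fold_dss <= 0:
        raise ValidationError("control_mean and fold_dss must be > 0")
    dss_mean = control_mean * fold_dss
    means = {"PBS": control_mean, "DSS": dss_mean}
    for name, pct in inhibition_pct_by_siropin.items():
        means[f"DSS+{name}"] = dss_mean * (1.0 - pct / 100.0)

    out = []
    for gi, (label, mean) in enumerate(means.items()):
        if noise_cv > 0:
            sigma2 = np.log1p(noise_cv**2)
            draws = _rng(seed, gi).lognormal(
                np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2), n_per_group
            )
        else:
            draws = np.full(n_per_group, mean)
        for j, val in enumerate(draws):
            out.append(ActivityMeasurement(label, f"{label}_r{j + 1}", float(val)))
    return out
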
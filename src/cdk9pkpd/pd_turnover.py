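"""Inhibitory indirect-response (turnover) model of mRNA suppression.

The biomarker PD is MYC or MCL1 mRNA in whole blood, expressed as percent of
the pre-dose baseline. Drug concentration inhibits the zero-order formation
of the transcript:

    dPD/dt = k_in · (1 − C(t)ⁿ / (IC50ⁿ + C(t)ⁿ)) − k_out · PD,   PD(0) = 100

with k_out fixed by homeostasis at k_in / PD_initial (PD_initial = 100 %), so
100 % is the drug-free steady state. k_in (%·h⁻¹) is the transcript formation
rate, IC50 (µg/L, total plasma) the concentration giving half-maximal
inhibition, and n the Hill coefficient. Full inhibition is attainable
(Imax = 1). Because the drug acts on production, the biomarker nadir lags
the concentration peak and a constant concentration C drives PD to the
steady state 100·(1 − Cⁿ/(IC50ⁿ + Cⁿ)).

Fitting is sequential: plasma PK is estimated first (``pk_core``); the fitted
population concentration curve then drives a pooled least-squares fit of
(k_in, IC50, n) with the baseline fixed at 100. IC50 is additionally reported
as an unbound molar concentration (× fu_plasma, then to nmol/L) when binding
constants are supplied, the scale on which in-vitro potencies are compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from .pk_core import (
    BindingConstants,
    DoseEvent,
    OneCompartmentParams,
    concentration_at,
    mass_to_molar,
    to_unbound,
)

__all__ = [
    "TurnoverParams",
    "BiomarkerTimeCourse",
    "TurnoverFitResult",
    "simulate_turnover",
    "fit_turnover",
    "max_inhibition",
    "washout_pulse",
]

ODE_RTOL = 1e-8
ODE_ATOL = 1e-10


@dataclass(frozen=True)
class TurnoverParams:
    """Indirect-response parameters; k_out is derived from homeostasis."""

    k_in: float            # %·h⁻¹ transcript formation rate
    ic50: float            # µg/L total plasma concentration at 50 % inhibition
    hill_n: float = 1.0
    baseline: float = 100.0

    def __post_init__(self) -> None:
        for name in ("k_in", "ic50", "hill_n", "baseline"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def k_out(self) -> float:
        """Loss rate constant (1/h): k_in / baseline, the homeostasis value."""
        return self.k_in / self.baseline

    def inhibition(self, conc: float | np.ndarray) -> float | np.ndarray:
        """Fractional inhibition of k_in: Cⁿ/(IC50ⁿ + Cⁿ)."""
        c = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(c > 0, (c / self.ic50) ** self.hill_n, 0.0)
        out = ratio / (1.0 + ratio)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BiomarkerTimeCourse:
    """One subject's biomarker trajectory in % of baseline."""

    subject_id: str
    analyte: str           # "MYC" or "MCL1"
    times: np.ndarray      # h; a baseline observation exists at or before 0
    pd_values: np.ndarray  # % of baseline, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.pd_values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and pd_values must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("pd_values must be nonnegative")
        if t.size == 0 or t[0] > 0:
            raise ValueError("a baseline observation at or before t = 0 is required")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pd_values", v)


def simulate_turnover(
    params: TurnoverParams,
    conc_fn: Callable[[float], float],
    times: Sequence[float] | np.ndarray,
    rtol: float = ODE_RTOL,
    atol: float = ODE_ATOL,
    breakpoints: Sequence[float] | None = None,
) -> np.ndarray:
    """Integrate the turnover ODE and return PD (%) at the requested times.

    Integration starts at ``times[0]`` from the baseline value (100 %). If
    ``conc_fn`` has jump discontinuities (square washout pulses), pass their
    locations via ``breakpoints`` — or attach a ``breakpoints`` attribute to
    the function, as :func:`washout_pulse` does — so the adaptive solver is
    restarted at each jump instead of stepping across it.
    """
    t_eval = np.asarray(times, dtype=float)
    if t_eval.ndim != 1 or t_eval.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(np.diff(t_eval) <= 0):
        raise ValueError("times must be strictly increasing")

    brk = set(breakpoints or ())
    brk.update(getattr(conc_fn, "breakpoints", ()))
    t0, t_end = float(t_eval[0]), float(t_eval[-1])
    edges = sorted({t0, t_end, *(b for b in brk if t0 < b < t_end)})

    def rhs(t: float, y: np.ndarray) -> list[float]:
        inhib = params.inhibition(float(conc_fn(t)))
        return [params.k_in * (1.0 - inhib) - params.k_out * y[0]]

    pd_out = np.empty_like(t_eval)
    pd_out[0] = params.baseline  # PD(t0) = baseline exactly
    y = params.baseline
    if t0 == t_end:
        return pd_out
    for a, b in zip(edges[:-1], edges[1:]):
        seg_mask = (t_eval > a) & (t_eval <= b)
        seg_times = t_eval[seg_mask]
        # always integrate through to b so the next segment starts correctly
        pts = seg_times if seg_times.size and seg_times[-1] == b else np.append(seg_times, b)
        sol = solve_ivp(
            rhs, (a, b), [y], method="LSODA", t_eval=pts,
            rtol=rtol, atol=atol, max_step=max((b - a) / 4.0, 1e-3),
        )
        if not sol.success:
            raise RuntimeError(f"turnover ODE solver failed on [{a}, {b}]: {sol.message}")
        pd_out[np.flatnonzero(seg_mask)] = sol.y[0][: seg_times.size]
        y = float(sol.y[0, -1])
    return pd_out


def washout_pulse(conc_level: float, duration: float = 4.0) -> Callable[[float], float]:
    """Square-pulse exposure: C(t) = conc_level for 0 <= t < duration, else 0.

    Models the in-vitro washout design (fixed-duration drug incubation, then
    drug-free medium). The returned function carries a ``breakpoints``
    attribute so :func:`simulate_turnover` restarts integration at the jump.
    """
    if conc_level < 0:
        raise ValueError("conc_level must be >= 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")

    def conc_fn(t: float) -> float:
        return conc_level if 0.0 <= t < duration else 0.0

    conc_fn.breakpoints = (0.0, duration)  # type: ignore[attr-defined]
    return conc_fn


def max_inhibition(
    tc: BiomarkerTimeCourse | tuple[Sequence[float], Sequence[float]],
) -> tuple[float, float]:
    """Maximal percent inhibition from baseline and the time of the nadir.

    Accepts a :class:`BiomarkerTimeCourse` or a ``(times, pd_values)`` pair;
    only post-dose observations (t > 0) are considered. Returns
    ``(100 − min PD, earliest time attaining the minimum)``.
    """
    if isinstance(tc, BiomarkerTimeCourse):
        times, values = tc.times, tc.pd_values
    else:
        times, values = (np.asarray(a, dtype=float) for a in tc)
    post = times > 0
    if not np.any(post):
        raise ValueError("no post-dose observations")
    t_post, v_post = times[post], values[post]
    i_min = int(np.argmin(v_post))  # argmin returns the earliest minimum
    return float(100.0 - v_post[i_min]), float(t_post[i_min])


@dataclass
class TurnoverFitResult:
    """Pooled turnover fit: estimates, precision and unbound-IC50 report."""

    params: TurnoverParams
    cv_percent: dict[str, float]
    objective: float
    converged: bool
    n_obs: int
    ic50_unbound_nmol: float | None = None
    message: str = ""


def _initial_turnover(
    t_all: np.ndarray, pd_all: np.ndarray, conc_fn: Callable[[float], float]
) -> tuple[float, float, float]:
    """Heuristic starting values.

    k_in from an assumed transcript half-life of ~1 h (k_out = ln 2, so
    k_in = 100·ln 2); IC50 from the model concentration at the observation
    nearest half-maximal observed inhibition; Hill n = 1.
    """
    k_in0 = 100.0 * math.log(2.0)
    pd_min = float(pd_all.min())
    target = (100.0 + pd_min) / 2.0
    post = t_all > 0
    if np.any(post):
        i = int(np.argmin(np.abs(pd_all[post] - target)))
        c_half = float(conc_fn(float(t_all[post][i])))
    else:
        c_half = 0.0
    if not c_half > 0:
        c_half = max(float(conc_fn(1.0)), 1.0)
    return k_in0, c_half, 1.0


def fit_turnover(
    data: Iterable[BiomarkerTimeCourse],
    pk: OneCompartmentParams,
    dose: DoseEvent,
    binding: BindingConstants | None = None,
    weighting: str = "uniform",
    fix_hill: float | None = None,
    initial: tuple[float, float, float] | None = None,
) -> TurnoverFitResult:
    """Pooled least-squares fit of the turnover model (baseline fixed at 100).

    The concentration input is the analytic curve of the previously fitted
    one-compartment model (sequential PK→PD estimation). All observations of
    all supplied time courses are pooled and a single (k_in, IC50, n) vector
    is estimated on the log scale; ``fix_hill`` freezes the Hill coefficient.
    ``weighting`` is ``"uniform"`` (default: PD is already scale-normalised)
    or ``"proportional"``. CV% per parameter derives from the Jacobian-based
    covariance of the log-parameters.

    When ``binding`` is given, the fitted IC50 (total plasma µg/L) is also
    reported as unbound nmol/L (× fu_plasma, / molecular weight).
    """
    data = list(data)
    if weighting not in ("uniform", "proportional"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if not data:
        raise ValueError("no biomarker time courses supplied")

    t_all = np.concatenate([tc.times for tc in data])
    pd_all = np.concatenate([tc.pd_values for tc in data])
    if np.ptp(pd_all) < 1.0:
        import warnings

        warnings.warn(
            "biomarker shows almost no dynamic range; expect very wide CVs",
            stacklevel=2,
        )

    def conc_fn(t: float) -> float:
        return concentration_at(pk, dose, t) if t >= 0 else 0.0

    # pooled prediction needs each unique observation time once
    u_times, inv = np.unique(t_all, return_inverse=True)
    sim_times = u_times if u_times[0] <= 0 else np.concatenate([[0.0], u_times])
    sim_keep = slice(1, None) if u_times[0] > 0 else slice(None)
    tinf = dose.start_time + dose.infusion_h

    if initial is None:
        initial = _initial_turnover(t_all, pd_all, conc_fn)
    if fix_hill is not None:
        x0 = np.log([initial[0], initial[1]])
    else:
        x0 = np.log(np.asarray(initial, dtype=float))

    def unpack(x: np.ndarray) -> TurnoverParams:
        n = fix_hill if fix_hill is not None else math.exp(x[2])
        return TurnoverParams(k_in=math.exp(x[0]), ic50=math.exp(x[1]), hill_n=n)

    def residuals(x: np.ndarray) -> np.ndarray:
        par = unpack(x)
        sim = simulate_turnover(
            par, conc_fn, sim_times, breakpoints=(dose.start_time, tinf)
        )[sim_keep]
        pred = np.where(u_times <= 0, 100.0, sim)[inv]
        if weighting == "proportional":
            return (pd_all - pred) / np.maximum(pred, 1e-9)
        return pd_all - pred

    sol = optimize.least_squares(
        residuals, x0, method="trf", ftol=1e-10, xtol=1e-10, gtol=1e-10,
        max_nfev=2000,
    )
    params = unpack(sol.x)
    objective = float(np.sum(sol.fun**2))
    names = ["k_in", "ic50"] + ([] if fix_hill is not None else ["hill_n"])
    cv = {n: float("nan") for n in ["k_in", "ic50", "hill_n"]}
    n_obs, p = t_all.size, len(names)
    if n_obs > p:
        sigma2 = objective / (n_obs - p)
        try:
            cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
            se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
            for name, se in zip(names, se_log):
                cv[name] = 100.0 * se
        except np.linalg.LinAlgError:
            pass
    ic50_unbound = None
    if binding is not None:
        ic50_unbound = mass_to_molar(
            to_unbound(params.ic50, binding.fu_plasma), binding.molecular_weight
        )
    return TurnoverFitResult(
        params=params,
        cv_percent=cv,
        objective=objective,
        converged=bool(sol.success),
        n_obs=int(n_obs),
        ic50_unbound_nmol=ic50_unbound,
        message=sol.message,
    )
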
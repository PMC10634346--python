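"""Noncompartmental analysis (NCA) of concentration–time profiles.

Model-free PK parameter estimation: observed Cmax/tmax, trapezoidal AUC and
AUMC (linear or linear-up/log-down), terminal log-linear regression for the
elimination rate constant λz with automatic best-fit tail selection, and the
derived parameters AUC0–∞, t½, CL, MRT and Vss. The conventions follow
standard plasma NCA for an IV infusion:

    AUC0–∞  = AUC0–t + Clast/λz
    AUMC0–∞ = AUMC0–t + Clast·tlast/λz + Clast/λz²
    CL      = dose/AUC0–∞
    MRT     = AUMC0–∞/AUC0–∞ − Tinf/2     (infusion correction)
    Vss     = CL·MRT

When the terminal phase cannot be identified (fewer than 3 usable points, or
a nonnegative terminal slope), λz-dependent quantities are reported as NaN
while Cmax, tmax and AUC0–t remain available — mirroring the "—" cells of a
clinical PK table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pk_core import ConcentrationProfile

__all__ = [
    "NcaResult",
    "LambdaZResult",
    "auc_trapezoid",
    "fit_lambda_z",
    "run_nca",
    "write_nca_csv",
]


@dataclass(frozen=True)
class NcaResult:
    """Noncompartmental parameter set for one profile (NaN where undefined)."""

    subject_id: str
    cmax: float           # µg/L
    tmax: float           # h
    auc_last: float       # µg·h/L
    auc_inf: float        # µg·h/L
    lambda_z: float       # 1/h
    t_half: float         # h
    clearance: float      # L/h
    vss: float            # L
    mrt: float            # h
    n_lambda_points: int
    lambda_r2_adj: float


@dataclass(frozen=True)
class LambdaZResult:
    lambda_z: float
    n_points: int
    r2_adj: float
    intercept: float      # log-scale intercept at t = 0
    success: bool


def _segment_areas(t1, t2, c1, c2, method: str) -> tuple[float, float]:
    """(AUC, AUMC) of one interval.

    linear-up/log-down uses the logarithmic trapezoid when both endpoints
    are positive and the concentration declines; otherwise linear.
    """
    dt = t2 - t1
    log_down = method == "linuplogdown" and c1 > 0 and c2 > 0 and c2 < c1
    if log_down:
        k = math.log(c1 / c2) / dt
        auc = (c1 - c2) / k
        aumc = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
    else:
        auc = dt * (c1 + c2) / 2.0
        aumc = dt * (t1 * c1 + t2 * c2) / 2.0
    return auc, aumc


def _auc_aumc(times: np.ndarray, concs: np.ndarray, method: str) -> tuple[float, float]:
    auc = aumc = 0.0
    for i in range(times.size - 1):
        a, m = _segment_areas(times[i], times[i + 1], concs[i], concs[i + 1], method)
        auc += a
        aumc += m
    return auc, aumc


def auc_trapezoid(
    times: Sequence[float] | np.ndarray,
    concs: Sequence[float] | np.ndarray,
    method: str = "linuplogdown",
) -> float:
    """Trapezoidal AUC (µg·h/L) over the sampled interval.

    ``method`` is ``"linear"`` or ``"linuplogdown"`` (linear while rising or
    at a zero endpoint, logarithmic while declining between positive points).
    Requires at least two points, strictly increasing times and nonnegative
    concentrations.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points for AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    if method not in ("linear", "linuplogdown"):
        raise ValueError(f"unknown AUC method {method!r}")
    return _auc_aumc(t, c, method)[0]


def fit_lambda_z(
    times: Sequence[float] | np.ndarray,
    concs: Sequence[float] | np.ndarray,
    selection: str = "best-fit",
    indices: Sequence[int] | None = None,
) -> LambdaZResult:
    """Terminal elimination rate constant by log-linear regression.

    ``best-fit`` selection evaluates every candidate tail of >= 3 positive
    concentrations strictly after tmax and keeps the one with the largest
    adjusted R² (ties broken toward more points).  ``manual`` regression uses
    the caller-supplied sample ``indices``.  A nonpositive slope (no decline)
    yields ``success=False``.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    failed = LambdaZResult(float("nan"), 0, float("nan"), float("nan"), False)

    if selection == "manual":
        if indices is None:
            raise ValueError("manual selection requires indices")
        sel_t, sel_c = t[list(indices)], c[list(indices)]
        if sel_t.size < 3 or np.any(sel_c <= 0):
            return failed
        return _loglinear(sel_t, sel_c)
    if selection != "best-fit":
        raise ValueError(f"unknown selection {selection!r}")

    i_tmax = int(np.argmax(c))
    tail_mask = (np.arange(t.size) > i_tmax) & (c > 0)
    tt, cc = t[tail_mask], c[tail_mask]
    if tt.size < 3:
        return failed
    best: LambdaZResult | None = None
    # longest tail first, so a strict improvement is required to prefer fewer points
    for start in range(tt.size - 2):
        cand = _loglinear(tt[start:], cc[start:])
        if not cand.success:
            continue
        if best is None or cand.r2_adj > best.r2_adj + 1e-12:
            best = cand
    return best if best is not None else failed


def _loglinear(t: np.ndarray, c: np.ndarray) -> LambdaZResult:
    slope, intercept = np.polyfit(t, np.log(c), 1)
    lam = -slope
    n = t.size
    ss_res = float(np.sum((np.log(c) - (slope * t + intercept)) ** 2))
    ss_tot = float(np.sum((np.log(c) - np.log(c).mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    # a numerically-zero slope (flat tail) is no decline at all
    return LambdaZResult(float(lam), int(n), float(r2_adj), float(intercept), lam > 1e-12)


def run_nca(
    profile: ConcentrationProfile,
    method: str = "linuplogdown",
    blq: str = "exclude",
    bolus: bool = False,
    auc_cut: str = "last-positive",
) -> NcaResult:
    """Full noncompartmental analysis of one profile.

    ``blq`` governs zero concentrations ("below the limit of quantification"):
    ``"exclude"`` drops them (treated as missing), ``"zero"`` keeps them as
    true zeros.  ``auc_cut`` selects whether AUC0–t runs to the last positive
    concentration (default) or the last observation.  ``bolus=True`` skips
    the −Tinf/2 infusion correction of MRT.
    """
    if blq not in ("exclude", "zero"):
        raise ValueError(f"unknown blq policy {blq!r}")
    if auc_cut not in ("last-positive", "last-observation"):
        raise ValueError(f"unknown auc_cut {auc_cut!r}")
    t = profile.times
    c = profile.concentrations
    keep = np.isfinite(c)
    if blq == "exclude":
        keep &= c > 0
    t, c = t[keep], c[keep]
    if t.size < 2:
        raise ValueError("NCA needs at least 2 usable samples")
    if not np.any(c > 0):
        raise ValueError("NCA needs at least one positive concentration")

    i_cmax = int(np.argmax(c))
    cmax = float(c[i_cmax])
    tmax = float(t[i_cmax])

    if auc_cut == "last-positive":
        i_last = int(np.max(np.nonzero(c > 0)[0]))
    else:
        i_last = t.size - 1
    tl, cl_ = t[: i_last + 1], c[: i_last + 1]
    if tl.size >= 2:
        auc_last, aumc_last = _auc_aumc(tl, cl_, method)
    else:
        auc_last = aumc_last = 0.0
    clast, tlast = float(cl_[-1]), float(tl[-1])

    lam = fit_lambda_z(t, c)
    nan = float("nan")
    if lam.success:
        lz = lam.lambda_z
        auc_inf = auc_last + clast / lz
        aumc_inf = aumc_last + clast * tlast / lz + clast / lz**2
        t_half = math.log(2.0) / lz
        clearance = profile.dose.dose_ug / auc_inf
        mrt = aumc_inf / auc_inf - (0.0 if bolus else profile.dose.infusion_h / 2.0)
        vss = clearance * mrt
    else:
        lz = auc_inf = t_half = clearance = mrt = vss = nan

    return NcaResult(
        subject_id=profile.subject_id,
        cmax=cmax,
        tmax=tmax,
        auc_last=float(auc_last),
        auc_inf=float(auc_inf),
        lambda_z=float(lz),
        t_half=float(t_half),
        clearance=float(clearance),
        vss=float(vss),
        mrt=float(mrt),
        n_lambda_points=lam.n_points,
        lambda_r2_adj=lam.r2_adj,
    )


#: Output column names mirroring a clinical PK table.
NCA_CSV_COLUMNS = {
    "subject_id": "Subject",
    "cmax": "Cmax",
    "tmax": "tmax",
    "auc_last": "AUC0-t",
    "auc_inf": "AUC0-inf",
    "t_half": "t1/2",
    "clearance": "CL",
    "vss": "Vss",
    "mrt": "MRT",
    "lambda_z": "lambda_z",
    "n_lambda_points": "n_lambda",
    "lambda_r2_adj": "r2_adj",
}


def write_nca_csv(results: Iterable[NcaResult], path) -> None:
    df = pd.DataFrame([vars(r) for r in results])[list(NCA_CSV_COLUMNS)]
    df = df.rename(columns=NCA_CSV_COLUMNS)
    df.to_csv(path, index=False)
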
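"""Seeded generators of synthetic PK/PD study data.

The study's patient-level data are not publicly deposited, so every stage of
the analysis is exercised on synthetic data with the statistical structure
the estimators assume:

* plasma profiles from the one-compartment IV-infusion model with log-normal
  between-subject variability on CL and V and proportional (log-normal)
  residual error;
* biomarker (% of baseline mRNA) trajectories from the inhibitory turnover
  model driven by each subject's own concentration curve, with additive
  Gaussian noise truncated at 0;
* in-vitro washout panels (4-h square drug pulse, then drug-free follow-up)
  sampled on the experimental grid;
* cohort tables assembled by running NCA on the synthetic profiles.

Defaults mirror the clinical study conditions: 15 subjects, 30 mg over a
0.5-h infusion, typical CL/V at the cohort NCA means (10.3 L/h, 67.1 L), and
PD truth calibrated so unbound IC50s land near the reported clinical ranges
(MYC ≈ 20 nmol/L, MCL1 ≈ 65 nmol/L on the unbound molar scale). Residual
error magnitudes are package choices (the study reports none): 20 %
proportional CV for PK, 5 percentage points additive SD for PD.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded
from ``SyntheticConfig.seed``; a fixed seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nca as nca_mod
from .cohort import COHORT_COLUMNS, CohortTable
from .pk_core import (
    BindingConstants,
    ConcentrationProfile,
    DoseEvent,
    OneCompartmentParams,
    concentration_at,
    molar_to_mass,
)
from .pd_turnover import BiomarkerTimeCourse, TurnoverParams, simulate_turnover, washout_pulse

__all__ = [
    "SyntheticConfig",
    "WASHOUT_GRID",
    "generate_pk_profiles",
    "generate_pd_timecourses",
    "generate_washout_panel",
    "generate_cohort_table",
]

#: In-vitro washout sampling grid (hours relative to washout): pre-treatment
#: (−4), end of the 4-h pulse (0), then follow-up to 48 h.
WASHOUT_GRID: tuple[float, ...] = (-4.0, 0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0, 48.0)

#: Clinical biomarker sampling pattern: pre-dose then 1–24 h post-dose.
CLINICAL_PD_GRID: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 24.0)

#: Rich plasma sampling grid for a 0.5-h infusion (hours).
CLINICAL_PK_GRID: tuple[float, ...] = (
    0.25, 0.5, 0.583, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0
)


def _default_pd_truth() -> dict[str, TurnoverParams]:
    # IC50s in total plasma µg/L; on the unbound molar scale
    # (× fu 0.0665, / MW 404.4 × 1000) these are ≈ 20 and ≈ 65 nmol/L.
    # k_in = 140 %·h⁻¹ ⇒ k_out ≈ 1.4 1/h, a ~30-min transcript half-life,
    # which places the biomarker nadir 2–3 h after a 0.5-h infusion.
    return {
        "MYC": TurnoverParams(k_in=140.0, ic50=121.6, hill_n=1.5),
        "MCL1": TurnoverParams(k_in=140.0, ic50=395.3, hill_n=1.0),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Truth parameters, design and noise model of the synthetic study."""

    seed: int = 0
    n_subjects: int = 15
    pk_truth: OneCompartmentParams = field(
        default_factory=lambda: OneCompartmentParams(clearance=10.3, volume=67.1)
    )
    pk_bsv_cv: tuple[float, float] = (0.3, 0.3)   # between-subject CV of (CL, V)
    pd_truth: dict[str, TurnoverParams] = field(default_factory=_default_pd_truth)
    sampling_times_pk: tuple[float, ...] = CLINICAL_PK_GRID
    sampling_times_pd: tuple[float, ...] = CLINICAL_PD_GRID
    pk_proportional_cv: float = 0.2
    pd_additive_sd: float = 5.0                    # percentage points
    dose: DoseEvent = field(default_factory=lambda: DoseEvent(dose_mg=30.0, infusion_h=0.5))

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for cv in (*self.pk_bsv_cv, self.pk_proportional_cv):
            if cv < 0:
                raise ValueError("CVs must be >= 0")
        if self.pd_additive_sd < 0:
            raise ValueError("pd_additive_sd must be >= 0")


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per generator stage
    return np.random.default_rng([cfg.seed, stream])


def _lognormal_sigma(cv: float) -> float:
    """σ of a log-normal with the requested coefficient of variation."""
    return math.sqrt(math.log1p(cv**2))


def generate_pk_profiles(
    cfg: SyntheticConfig,
) -> tuple[list[ConcentrationProfile], dict]:
    """Simulate per-subject plasma profiles plus the generating truth.

    Individual (CL_i, V_i) are log-normal around the typical values with the
    configured between-subject CVs (median-preserving: the log-mean is the
    log of the typical value). Observations are the analytic model at the
    sampling grid times a log-normal proportional residual with CV
    ``pk_proportional_cv``. Returns ``(profiles, truth)`` where ``truth``
    records the typical and individual parameters for recovery tests.
    """
    rng = _rng(cfg, 1)
    times = np.asarray(cfg.sampling_times_pk, dtype=float)
    s_cl, s_v = (_lognormal_sigma(cv) for cv in cfg.pk_bsv_cv)
    s_res = _lognormal_sigma(cfg.pk_proportional_cv)
    profiles: list[ConcentrationProfile] = []
    individual: list[OneCompartmentParams] = []
    for i in range(cfg.n_subjects):
        cl_i = cfg.pk_truth.clearance * math.exp(rng.normal(0.0, s_cl)) if s_cl else cfg.pk_truth.clearance
        v_i = cfg.pk_truth.volume * math.exp(rng.normal(0.0, s_v)) if s_v else cfg.pk_truth.volume
        par_i = OneCompartmentParams(cl_i, v_i)
        pred = concentration_at(par_i, cfg.dose, times)
        eps = rng.normal(0.0, s_res, size=times.size) if s_res else np.zeros(times.size)
        conc = pred * np.exp(eps)
        profiles.append(
            ConcentrationProfile(f"SYN{i + 1:03d}", cfg.dose, times, conc)
        )
        individual.append(par_i)
    truth = {
        "typical": cfg.pk_truth,
        "individual": individual,
        "pk_proportional_cv": cfg.pk_proportional_cv,
    }
    return profiles, truth


def generate_pd_timecourses(
    cfg: SyntheticConfig,
    pk_truth: dict | None = None,
    analytes: tuple[str, ...] = ("MYC", "MCL1"),
) -> tuple[list[BiomarkerTimeCourse], dict]:
    """Simulate biomarker trajectories for each subject and analyte.

    Each subject's own (true) concentration curve drives the turnover model
    at the PD sampling grid; additive Gaussian noise (SD ``pd_additive_sd``
    points) is applied post-dose, clamped at 0, and the pre-dose value is
    pinned to 100 %. Pass the ``truth`` record of
    :func:`generate_pk_profiles` to reuse its individual PK parameters;
    otherwise fresh ones are drawn.
    """
    if pk_truth is None:
        _, pk_truth = generate_pk_profiles(cfg)
    individual: list[OneCompartmentParams] = pk_truth["individual"]
    rng = _rng(cfg, 2)
    times = np.asarray(cfg.sampling_times_pd, dtype=float)
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
    tinf = cfg.dose.start_time + cfg.dose.infusion_h
    courses: list[BiomarkerTimeCourse] = []
    for analyte in analytes:
        par = cfg.pd_truth[analyte]
        for i, pk_i in enumerate(individual):
            def conc_fn(t: float, _pk=pk_i) -> float:
                return concentration_at(_pk, cfg.dose, t) if t >= 0 else 0.0

            pd_clean = simulate_turnover(par, conc_fn, times, breakpoints=(tinf,))
            noise = rng.normal(0.0, cfg.pd_additive_sd, size=times.size) if cfg.pd_additive_sd else 0.0
            pd_obs = np.clip(pd_clean + noise, 0.0, None)
            pd_obs[times <= 0] = 100.0
            courses.append(
                BiomarkerTimeCourse(f"SYN{i + 1:03d}", analyte, times, pd_obs)
            )
    truth = {"pd_truth": {a: cfg.pd_truth[a] for a in analytes}}
    return courses, truth


def generate_washout_panel(
    levels_nmol: tuple[float, ...] = (250.0, 1000.0),
    binding: BindingConstants | None = None,
    pd_truth: TurnoverParams | None = None,
    analyte: str = "MYC",
    duration_h: float = 4.0,
    grid: tuple[float, ...] = WASHOUT_GRID,
) -> pd.DataFrame:
    """Noise-free in-vitro washout scenario table.

    For each nominal media concentration (nmol/L) a ``duration_h`` square
    pulse is applied starting at −``duration_h`` (time 0 is the washout, as
    in the experimental design) and the turnover model is simulated on the
    sampling grid. The media concentration is reduced to its unbound level
    (× fu_media) and expressed as the plasma-equivalent total concentration
    the model's IC50 is calibrated against (converted to µg/L, ÷ fu_plasma).
    Returns a tidy frame (analyte, level_nmol, time_h, pd_percent).
    """
    binding = binding or BindingConstants()
    if pd_truth is None:
        pd_truth = _default_pd_truth()[analyte]
    if any(level < 0 for level in levels_nmol):
        raise ValueError("levels must be >= 0")
    t_grid = np.asarray(grid, dtype=float)
    rows = []
    for level in levels_nmol:
        unbound_nmol = level * binding.fu_media
        conc_ug = molar_to_mass(unbound_nmol, binding.molecular_weight) / binding.fu_plasma
        pulse = washout_pulse(conc_ug, duration_h)

        def conc_fn(t: float) -> float:
            return pulse(t + duration_h)  # pulse runs from −duration_h to 0

        pd_vals = simulate_turnover(
            pd_truth, conc_fn, t_grid, breakpoints=(-duration_h, 0.0)
        )
        for t, v in zip(t_grid, pd_vals):
            rows.append({"analyte": analyte, "level_nmol": level, "time_h": t, "pd_percent": v})
    return pd.DataFrame(rows)


def generate_cohort_table(cfg: SyntheticConfig) -> CohortTable:
    """Assemble a clinical-style cohort table from synthetic profiles.

    Two dosing occasions per subject (first dose and a later dose with fresh
    residual noise — no accumulation, as the half-life is short relative to
    weekly dosing) are run through NCA. A random minority of subjects lack
    the multiple-dose occasion, and occasional rows carry exclusion flags,
    mimicking the missing-data pattern of a real table.
    """
    profiles_sd, truth = generate_pk_profiles(cfg)
    rng = _rng(cfg, 3)
    times = np.asarray(cfg.sampling_times_pk, dtype=float)
    s_res = _lognormal_sigma(cfg.pk_proportional_cv)
    rows = []
    for i, (prof_sd, pk_i) in enumerate(zip(profiles_sd, truth["individual"])):
        res_sd = nca_mod.run_nca(prof_sd)
        has_md = rng.random() < 11.0 / 15.0
        md = {k: np.nan for k in ("cmax", "tmax", "auc_last", "t_half")}
        if has_md:
            pred = concentration_at(pk_i, cfg.dose, times)
            eps = rng.normal(0.0, s_res, size=times.size) if s_res else 0.0
            prof_md = ConcentrationProfile(prof_sd.subject_id, cfg.dose, times, pred * np.exp(eps))
            res_md = nca_mod.run_nca(prof_md)
            md = {
                "cmax": res_md.cmax, "tmax": res_md.tmax,
                "auc_last": res_md.auc_last, "t_half": res_md.t_half,
            }
        rows.append({
            "subject": prof_sd.subject_id,
            "indication": "synthetic",
            "cohort": "DH-DLBCL" if i < (2 * cfg.n_subjects) // 3 else "Other NHL",
            "sd_cmax_ug_L": res_sd.cmax,
            "sd_tmax_h": res_sd.tmax,
            "sd_auc_last_ug_h_L": res_sd.auc_last,
            "sd_cl_L_h": res_sd.clearance,
            "sd_vss_L": res_sd.vss,
            "sd_thalf_h": res_sd.t_half,
            "md_cmax_ug_L": md["cmax"],
            "md_tmax_h": md["tmax"],
            "md_auc_last_ug_h_L": md["auc_last"],
            "md_thalf_h": md["t_half"],
            "response": "Not evaluable",
            "duration_weeks": np.nan,
            "exclude_single_sample": bool(rng.random() < 0.07),
            "exclude_multiple_from_summary": bool(has_md and rng.random() < 0.1),
        })
    if not rows:
        df = pd.DataFrame(columns=COHORT_COLUMNS)
        return CohortTable(df)
    return CohortTable(pd.DataFrame(rows))
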
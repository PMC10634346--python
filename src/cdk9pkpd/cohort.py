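"""Cohort-level PK parameter tables and their summaries.

Holds per-subject noncompartmental parameters for the single-dose (first
infusion) and multiple-dose (third weekly infusion) occasions of the 15
patient MYC+ lymphoma cohort, in the shape of a clinical PK table: missing
cells ("—") are representable, each column may have its own summary n, and
two per-row exclusion flags capture the study's footnotes —

* ``exclude_single_sample``: an implausible single sample was excluded from
  that subject's NCA (metadata only; it does not alter table summaries);
* ``exclude_multiple_from_summary``: the subject's dose was reduced, so the
  multiple-dose row is left out of multiple-dose means/SDs (the single-dose
  values remain included).

Summaries are the arithmetic mean and the n−1 sample SD of the non-missing,
non-excluded values; rounding to the printed precision is display-only.
A transcription of the study's observed table ships as a package fixture
(:func:`table1`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .pk_core import BindingConstants, mass_to_molar, to_unbound

__all__ = [
    "CohortTable",
    "COHORT_COLUMNS",
    "summarize",
    "summarize_all",
    "unbound_cmax_range",
    "load_cohort",
    "write_cohort",
    "write_summary",
    "table1",
]

#: Column order of the cohort CSV.
COHORT_COLUMNS = [
    "subject", "indication", "cohort",
    "sd_cmax_ug_L", "sd_tmax_h", "sd_auc_last_ug_h_L",
    "sd_cl_L_h", "sd_vss_L", "sd_thalf_h",
    "md_cmax_ug_L", "md_tmax_h", "md_auc_last_ug_h_L", "md_thalf_h",
    "response", "duration_weeks",
    "exclude_single_sample", "exclude_multiple_from_summary",
]

_NUMERIC = [c for c in COHORT_COLUMNS if c.startswith(("sd_", "md_"))] + ["duration_weeks"]
_FLAGS = ["exclude_single_sample", "exclude_multiple_from_summary"]

#: Short parameter names accepted by :func:`summarize`, per phase.
PHASE_COLUMNS = {
    "single": {
        "cmax": "sd_cmax_ug_L", "tmax": "sd_tmax_h", "auc_last": "sd_auc_last_ug_h_L",
        "cl": "sd_cl_L_h", "vss": "sd_vss_L", "t_half": "sd_thalf_h",
    },
    "multiple": {
        "cmax": "md_cmax_ug_L", "tmax": "md_tmax_h",
        "auc_last": "md_auc_last_ug_h_L", "t_half": "md_thalf_h",
    },
}


@dataclass(frozen=True)
class CohortTable:
    """Per-subject PK record set with exclusion flags."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        df = df[COHORT_COLUMNS].copy()
        for c in _NUMERIC:
            df[c] = pd.to_numeric(df[c].replace({"—": np.nan, "": np.nan}), errors="raise")
        for c in _FLAGS:
            df[c] = df[c].map(_to_bool)
        object.__setattr__(self, "rows", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.rows)


def _to_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer, float)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", "", "nan"):
        return False
    raise ValueError(f"cannot interpret flag value {v!r}")


def _included_values(table: CohortTable, column: str, phase: str) -> np.ndarray:
    if phase not in PHASE_COLUMNS:
        raise ValueError(f"phase must be 'single' or 'multiple', got {phase!r}")
    col = PHASE_COLUMNS[phase].get(column, column)
    if col not in table.rows.columns:
        raise ValueError(f"unknown column {column!r}")
    df = table.rows
    if phase == "multiple":
        df = df[~df["exclude_multiple_from_summary"]]
    return df[col].dropna().to_numpy(float)


def summarize(table: CohortTable, column: str, phase: str) -> tuple[float, float, int]:
    """Mean, sample (n−1) SD and n of one parameter column.

    ``column`` is a short name ("cmax", "tmax", "auc_last", "cl", "vss",
    "t_half") or a raw column name; ``phase`` selects the single- or
    multiple-dose occasion. Missing cells are dropped; for the multiple-dose
    phase, rows flagged ``exclude_multiple_from_summary`` are dropped too.
    """
    vals = _included_values(table, column, phase)
    if vals.size == 0:
        raise ValueError(f"no usable values for {column!r} ({phase} dose)")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd, int(vals.size)


def summarize_all(table: CohortTable) -> pd.DataFrame:
    """Mean/SD/n for every parameter column of both phases (tidy frame)."""
    rows = []
    for phase, cols in PHASE_COLUMNS.items():
        for short in cols:
            mean, sd, n = summarize(table, short, phase)
            rows.append({"phase": phase, "parameter": short, "mean": mean, "sd": sd, "n": n})
    return pd.DataFrame(rows)


def unbound_cmax_range(
    table: CohortTable, phase: str, binding: BindingConstants | None = None
) -> tuple[float, float]:
    """Range of unbound Cmax in nmol/L across included subjects.

    Each included Cmax (µg/L total) is multiplied by fu_plasma and converted
    to molar units; returns (min, max). This is the exposure scale on which
    clinical Cmax is compared with in-vitro potency.
    """
    binding = binding or BindingConstants()
    cmax = _included_values(table, "cmax", phase)
    if cmax.size == 0:
        raise ValueError(f"no Cmax values for {phase} dose")
    unbound = mass_to_molar(to_unbound(cmax, binding.fu_plasma), binding.molecular_weight)
    return float(np.min(unbound)), float(np.max(unbound))


def load_cohort(path) -> CohortTable:
    """Read a cohort CSV (missing cells empty or "—"; flags True/False)."""
    df = pd.read_csv(path, dtype={"subject": str}, keep_default_na=False, na_values=[""])
    if df.empty:
        raise ValueError(f"cohort file {path} contains no rows")
    try:
        return CohortTable(df)
    except ValueError as exc:
        raise ValueError(f"malformed cohort file {path}: {exc}") from exc


def write_cohort(table: CohortTable, path) -> None:
    table.rows.to_csv(path, index=False)


def write_summary(table: CohortTable, path) -> None:
    summarize_all(table).to_csv(path, index=False)


def table1() -> CohortTable:
    """The packaged transcription of the observed 15-patient PK table."""
    with resources.files("cdk9pkpd.data").joinpath("table1.csv").open() as fh:
        return load_cohort(fh)
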
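"""CSF A/T biomarker classification and analysis-sample selection.

Amyloid positivity (A+) is defined by the CSF Abeta42/Abeta40 ratio falling
strictly below a cutoff (default 0.046); tau positivity (T+) by CSF p-Tau181
at or above a cutoff (default 24.8 pg/mL). Participants are assigned one of
four A/T cells; A-T+ falls outside the amyloid-first AD continuum and is
excluded from analysis, as are cognitively impaired participants without
amyloid positivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

AT_CELLS = ("A-T-", "A+T-", "A+T+", "A-T+")
DIAGNOSES = ("CU", "MCI", "AD")

__all__ = [
    "AT_CELLS",
    "DIAGNOSES",
    "CutoffConfig",
    "classify_at",
    "classify_at_table",
    "select_analysis_sample",
]


@dataclass(frozen=True)
class CutoffConfig:
    """Positivity cutoffs for the CSF analytes.

    abeta_ratio_cutoff : Abeta42/Abeta40 ratio; A+ iff ratio < cutoff (strict).
    ptau_cutoff        : p-Tau181 concentration; T+ iff value >= cutoff.

    Boundary semantics are taken literally (strict ``<`` for the ratio,
    ``>=`` for p-Tau) and are configurable for sensitivity analyses.
    """

    abeta_ratio_cutoff: float = 0.046
    ptau_cutoff: float = 24.8

    def __post_init__(self) -> None:
        if not (self.abeta_ratio_cutoff > 0 and self.ptau_cutoff > 0):
            raise ValueError("cutoffs must be positive")


def classify_at(
    abeta42: float,
    abeta40: float,
    ptau: float,
    cutoffs: CutoffConfig | None = None,
) -> str:
    """Assign an A/T cell from the three CSF analytes.

    Returns one of ``"A-T-"``, ``"A+T-"``, ``"A+T+"``, ``"A-T+"``.
    A status depends only on the Abeta42/Abeta40 ratio, so it is invariant
    to a joint rescaling of the two amyloid analytes.
    """
    cutoffs = cutoffs or CutoffConfig()
    for name, value in (("abeta42", abeta42), ("abeta40", abeta40), ("ptau", ptau)):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"missing CSF analyte: {name}")
        if not math.isfinite(value):
            raise ValueError(f"non-finite CSF analyte: {name}")
    if abeta40 <= 0:
        raise ValueError("abeta40 must be positive: Abeta42/Abeta40 ratio undefined")
    a = "A+" if (abeta42 / abeta40) < cutoffs.abeta_ratio_cutoff else "A-"
    t = "T+" if ptau >= cutoffs.ptau_cutoff else "T-"
    return a + t


def classify_at_table(
    participants: pd.DataFrame, cutoffs: CutoffConfig | None = None
) -> pd.Series:
    """Vectorised :func:`classify_at` over a participant table.

    Expects columns ``abeta42``, ``abeta40``, ``ptau``; returns a Series of
    A/T cells aligned with the input index.
    """
    cutoffs = cutoffs or CutoffConfig()
    for col in ("abeta42", "abeta40", "ptau"):
        if col not in participants.columns:
            raise ValueError(f"missing CSF column: {col}")
        vals = participants[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            bad = participants.index[np.isnan(vals)].tolist()
            raise ValueError(f"missing CSF analyte {col} for rows {bad}")
        if not np.isfinite(vals).all():
            raise ValueError(f"non-finite CSF analyte in column {col}")
    ab40 = participants["abeta40"].to_numpy(dtype=float)
    if (ab40 <= 0).any():
        bad = participants.index[ab40 <= 0].tolist()
        raise ValueError(f"abeta40 <= 0 (ratio undefined) for rows {bad}")
    ratio = participants["abeta42"].to_numpy(dtype=float) / ab40
    a = np.where(ratio < cutoffs.abeta_ratio_cutoff, "A+", "A-")
    t = np.where(
        participants["ptau"].to_numpy(dtype=float) >= cutoffs.ptau_cutoff, "T+", "T-"
    )
    return pd.Series(np.char.add(a.astype("U2"), t.astype("U2")),
                     index=participants.index, name="at_status")


# Reason codes attached to the exclusion ledger.
REASON_AT_MINUS_T_PLUS = "A-T+ outside AD A/T criteria"
REASON_IMPAIRED_AMYLOID_NEG = "impaired without amyloid positivity"


def select_analysis_sample(
    participants: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study's analysis-sample filter.

    Retains CU participants in A-T-/A+T-/A+T+ and MCI/AD participants only if
    amyloid positive (A+T- or A+T+). Returns ``(retained, ledger)`` where
    ``ledger`` lists every dropped participant with a reason code; the two
    frames partition the input.
    """
    required = {"participant_id", "diagnosis", "at_status"}
    missing = required - set(participants.columns)
    if missing:
        raise ValueError(f"participant table missing columns: {sorted(missing)}")
    unknown_dx = set(participants["diagnosis"]) - set(DIAGNOSES)
    if unknown_dx:
        raise ValueError(f"unknown diagnosis labels: {sorted(unknown_dx)}")
    unknown_at = set(participants["at_status"]) - set(AT_CELLS)
    if unknown_at:
        raise ValueError(f"unknown A/T status labels: {sorted(unknown_at)}")

    dx = participants["diagnosis"]
    at = participants["at_status"]
    is_cu = dx == "CU"
    keep = (is_cu & (at != "A-T+")) | (~is_cu & at.isin(["A+T-", "A+T+"]))

    ledger = participants.loc[~keep, ["participant_id", "diagnosis", "at_status"]].copy()
    ledger["reason"] = np.where(
        ledger["at_status"] == "A-T+",
        REASON_AT_MINUS_T_PLUS,
        REASON_IMPAIRED_AMYLOID_NEG,
    )
    return participants.loc[keep].copy(), ledger.reset_index(drop=True)
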
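"""Robust age/sex-adjusted normative z-scoring of ROI-level NODDI metrics.

The normative reference is the cognitively unimpaired, CSF amyloid- and
tau-negative (A-T-) group. For every (ROI, metric) cell an ordinary
least-squares regression predicts the metric from centered age and sex
(0 = male, 1 = female):

    predicted = b0 + b_age * (age - age_center) + b_sex * sex
    z         = (observed - predicted) / RMSE

Participants whose initial z falls 1.5 or more standard deviations BELOW
expectation in any cell are removed once, the regressions are refit on the
reduced set, and the frozen coefficients and RMSE are used to z-score every
participant (normative or not). The exclusion is deliberately one-sided:
only low values signal neurodegeneration-like abnormality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MetricRegression",
    "NormativeModel",
    "fit_metric_regression",
    "compute_zscores",
    "flag_outliers",
    "build_norms",
]

MIN_FIT_N = 10


@dataclass(frozen=True)
class MetricRegression:
    """OLS fit for one (ROI, metric) cell: coefficients in metric units."""

    b0: float
    b_age: float     # per year
    b_sex: float     # female minus male
    rmse: float
    n_fit: int


@dataclass
class NormativeModel:
    """Frozen normative regressions plus the exclusion audit trail.

    regressions are keyed ``(roi_name, metric, tissue_class)``; age_center is
    the centering constant (years) frozen at fit time; excluded carries, per
    excluded participant, the (roi, metric, z) triples that triggered removal.
    """

    regressions: dict[tuple[str, str, str], MetricRegression]
    age_center: float
    exclusion_threshold: float = 1.5
    rmse_denominator: str = "n-3"
    excluded: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    normative_ids_initial: list[str] = field(default_factory=list)
    normative_ids_final: list[str] = field(default_factory=list)

    # -- JSON persistence so norms can be applied to new cohorts -------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "age_center": self.age_center,
            "exclusion_threshold": self.exclusion_threshold,
            "rmse_denominator": self.rmse_denominator,
            "regressions": [
                {"roi_name": roi, "metric": m, "tissue_class": t,
                 "b0": r.b0, "b_age": r.b_age, "b_sex": r.b_sex,
                 "rmse": r.rmse, "n_fit": r.n_fit}
                for (roi, m, t), r in sorted(self.regressions.items())
            ],
            "excluded": {pid: [list(tr) for tr in triggers]
                         for pid, triggers in sorted(self.excluded.items())},
            "normative_ids_initial": self.normative_ids_initial,
            "normative_ids_final": self.normative_ids_final,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NormativeModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        regs = {
            (r["roi_name"], r["metric"], r["tissue_class"]): MetricRegression(
                b0=r["b0"], b_age=r["b_age"], b_sex=r["b_sex"],
                rmse=r["rmse"], n_fit=r["n_fit"])
            for r in payload["regressions"]
        }
        return cls(
            regressions=regs,
            age_center=payload["age_center"],
            exclusion_threshold=payload["exclusion_threshold"],
            rmse_denominator=payload.get("rmse_denominator", "n-3"),
            excluded={pid: [tuple(tr) for tr in triggers]
                      for pid, triggers in payload.get("excluded", {}).items()},
            normative_ids_initial=payload.get("normative_ids_initial", []),
            normative_ids_final=payload.get("normative_ids_final", []),
        )


def fit_metric_regression(
    values: np.ndarray,
    ages: np.ndarray,
    sexes: np.ndarray,
    age_center: float,
    rmse_denominator: str = "n-3",
) -> MetricRegression:
    """OLS of a metric on centered age and sex.

    RMSE is the residual root-mean-square; the default denominator n-3
    accounts for the three estimated coefficients (a plain 1/n denominator is
    available via ``rmse_denominator="n"``).
    """
    values = np.asarray(values, float)
    ages = np.asarray(ages, float)
    sexes = np.asarray(sexes, float)
    n = len(values)
    if n < MIN_FIT_N:
        raise ValueError(f"need at least {MIN_FIT_N} observations, got {n}")
    if len(set(np.unique(sexes)) - {0.0, 1.0}) > 0:
        raise ValueError("sex must be coded 0 (male) / 1 (female)")
    if np.unique(sexes).size < 2:
        raise ValueError("both sexes must be represented: b_sex unidentifiable")
    X = np.column_stack([np.ones(n), ages - age_center, sexes])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (constant age and single sex)")
    beta, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    ss = float(resid @ resid)
    denom = n if rmse_denominator == "n" else n - 3
    rmse = float(np.sqrt(ss / denom))
    return MetricRegression(b0=float(beta[0]), b_age=float(beta[1]),
                            b_sex=float(beta[2]), rmse=rmse, n_fit=n)


def _demographics(participants: pd.DataFrame) -> pd.DataFrame:
    for col in ("participant_id", "age", "sex"):
        if col not in participants.columns:
            raise ValueError(f"participants missing column {col!r}")
    bad = participants[participants["age"].isna() | participants["sex"].isna()]
    if not bad.empty:
        raise ValueError(
            f"participants missing age/sex: {bad['participant_id'].tolist()}")
    return participants.set_index("participant_id")


def compute_zscores(
    model: NormativeModel,
    roi_table: pd.DataFrame,
    participants: pd.DataFrame,
) -> pd.DataFrame:
    """Apply frozen norms to every row of an ROI table.

    Returns one row per (participant, roi, metric) with the robust z-score.
    """
    demo = _demographics(participants)
    out = roi_table.copy()
    missing_pid = set(out["participant_id"]) - set(demo.index)
    if missing_pid:
        raise ValueError(f"ROI rows reference unknown participants: "
                         f"{sorted(missing_pid)}")
    age_c = demo.loc[out["participant_id"], "age"].to_numpy(float) - model.age_center
    sex = demo.loc[out["participant_id"], "sex"].to_numpy(float)

    keys = list(zip(out["roi_name"], out["metric"], out["tissue_class"]))
    missing_models = {k for k in keys if k not in model.regressions}
    if missing_models:
        raise ValueError(f"no normative model for cells: {sorted(missing_models)}")
    b0 = np.array([model.regressions[k].b0 for k in keys])
    b_age = np.array([model.regressions[k].b_age for k in keys])
    b_sex = np.array([model.regressions[k].b_sex for k in keys])
    rmse = np.array([model.regressions[k].rmse for k in keys])
    if (rmse <= 0).any():
        raise ValueError("degenerate normative model: RMSE must be positive")

    predicted = b0 + b_age * age_c + b_sex * sex
    out["z"] = (out["value"].to_numpy(float) - predicted) / rmse
    return out[["participant_id", "roi_name", "metric", "tissue_class", "z"]]


def flag_outliers(
    ztable: pd.DataFrame, threshold: float = 1.5
) -> dict[str, list[tuple[str, str, float]]]:
    """Participants with z <= -threshold in ANY (roi, metric) cell.

    One-sided by design: only scores below expectation count, and the
    boundary is inclusive ("1.5 or more standard deviations below").
    Returns participant_id -> list of (roi, metric, z) triggers.
    """
    hits = ztable[ztable["z"] <= -threshold]
    flagged: dict[str, list[tuple[str, str, float]]] = {}
    for pid, grp in hits.groupby("participant_id", sort=True):
        flagged[str(pid)] = [
            (row.roi_name, row.metric, float(row.z))
            for row in grp.itertuples()
        ]
    return flagged


def _fit_all_cells(
    roi_table: pd.DataFrame, demo: pd.DataFrame, age_center: float,
    rmse_denominator: str,
) -> dict[tuple[str, str, str], MetricRegression]:
    regs = {}
    for (roi, metric, tissue), grp in roi_table.groupby(
            ["roi_name", "metric", "tissue_class"], sort=True):
        ages = demo.loc[grp["participant_id"], "age"].to_numpy(float)
        sexes = demo.loc[grp["participant_id"], "sex"].to_numpy(float)
        regs[(roi, metric, tissue)] = fit_metric_regression(
            grp["value"].to_numpy(float), ages, sexes, age_center,
            rmse_denominator=rmse_denominator)
    return regs


def build_norms(
    roi_table: pd.DataFrame,
    participants: pd.DataFrame,
    exclusion_threshold: float = 1.5,
    rmse_denominator: str = "n-3",
    iterate: bool = False,
    min_final_n: int = MIN_FIT_N,
) -> tuple[NormativeModel, pd.DataFrame]:
    """Run the full robust-norms procedure and z-score all participants.

    1. Normative set := CU participants with A-T- CSF status.
    2. Fit age+sex OLS per (ROI, metric) on that set.
    3. Compute initial z-scores for the normative set.
    4. Remove (once) anyone with z <= -threshold in any cell.
    5. Refit on the reduced set; freeze coefficients, RMSE and age center.
    6. Z-score every participant in the input with the frozen model.

    Returns ``(model, ztable)``. With ``iterate=True`` step 4-5 repeats until
    no further exclusions (off by default; the reference procedure is a
    single pass).
    """
    for col in ("diagnosis", "at_status"):
        if col not in participants.columns:
            raise ValueError(f"participants missing column {col!r}")
    norm_mask = (participants["diagnosis"] == "CU") & \
                (participants["at_status"] == "A-T-")
    normative = participants[norm_mask]
    if normative.empty:
        raise ValueError("no CU A-T- participants: cannot build norms")

    demo = _demographics(participants)
    norm_ids = normative["participant_id"].tolist()
    norm_roi = roi_table[roi_table["participant_id"].isin(norm_ids)]
    age_center = float(normative["age"].mean())

    current_ids = list(norm_ids)
    excluded: dict[str, list[tuple[str, str, float]]] = {}
    while True:
        subset = norm_roi[norm_roi["participant_id"].isin(current_ids)]
        regs = _fit_all_cells(subset, demo, age_center, rmse_denominator)
        model = NormativeModel(regressions=regs, age_center=age_center,
                               exclusion_threshold=exclusion_threshold,
                               rmse_denominator=rmse_denominator)
        ztable = compute_zscores(
            model, subset, participants[participants["participant_id"].isin(current_ids)])
        newly = flag_outliers(ztable, exclusion_threshold)
        newly = {pid: trig for pid, trig in newly.items() if pid not in excluded}
        if not newly:
            break
        excluded.update(newly)
        current_ids = [pid for pid in current_ids if pid not in excluded]
        if len(current_ids) < min_final_n:
            raise ValueError(
                f"normative set reduced to {len(current_ids)} < {min_final_n}; "
                "a larger normative sample is required")
        # Refit on the reduced set.
        subset = norm_roi[norm_roi["participant_id"].isin(current_ids)]
        regs = _fit_all_cells(subset, demo, age_center, rmse_denominator)
        model = NormativeModel(regressions=regs, age_center=age_center,
                               exclusion_threshold=exclusion_threshold,
                               rmse_denominator=rmse_denominator)
        if not iterate:
            break

    model.excluded = excluded
    model.normative_ids_initial = norm_ids
    model.normative_ids_final = current_ids
    if len(model.regressions) == 0:
        warnings.warn("no (ROI, metric) cells fitted", stacklevel=2)

    ztable_all = compute_zscores(model, roi_table, participants)
    return model, ztable_all
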
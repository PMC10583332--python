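"""Synthetic cohort generator for ROI-level NODDI normative analyses.

Generates participant tables (demographics, CSF amyloid/tau analytes, A/T
status) and ROI-level bilateral-mean NDI/ODI values with the statistical
structure the downstream analysis assumes: linear age and sex effects, group
shifts expressed in residual-SD units, and Gaussian residual noise. Default
cell counts mirror a 296-participant observational cohort (CU 231/26/28 across
A-T-/A+T-/A+T+, MCI 0/1/5, AD 0/1/4); CSF analytes are drawn from log-normal
distributions truncated to the cutoff side of the assigned cell so that
classification from the generated analytes reproduces the assigned cell with
probability one.

The generator also returns the planted effect map so that recovery tests can
compare fitted models against known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atclass import AT_CELLS, DIAGNOSES, CutoffConfig, classify_at_table

METRICS = ("NDI", "ODI")

GM_ROIS = (
    "superior_frontal_gyrus",
    "parahippocampus",
    "hippocampus",
    "inferior_temporal",
    "posterior_cingulate_gyrus",
    "inferior_parietal_precuneus",
)
WM_ROIS = (
    "cingulum_cingulate",
    "cingulum_hippocampus",
    "superior_longitudinal_fasciculus",
    "inferior_longitudinal_fasciculus",
    "uncinate_fasciculus",
    "forceps_major",
)
ALL_ROIS = GM_ROIS + WM_ROIS

ROI_TISSUE = {**{r: "GM" for r in GM_ROIS}, **{r: "WM" for r in WM_ROIS}}

AGE_RANGE = (45.0, 95.0)


def _default_counts() -> dict[tuple[str, str], int]:
    return {
        ("CU", "A-T-"): 231, ("CU", "A+T-"): 26, ("CU", "A+T+"): 28,
        ("MCI", "A-T-"): 0, ("MCI", "A+T-"): 1, ("MCI", "A+T+"): 5,
        ("AD", "A-T-"): 0, ("AD", "A+T-"): 1, ("AD", "A+T+"): 4,
    }


def _default_baselines() -> dict[tuple[str, str], float]:
    gm_ndi = dict(zip(GM_ROIS, (0.42, 0.40, 0.38, 0.43, 0.44, 0.45)))
    gm_odi = dict(zip(GM_ROIS, (0.47, 0.50, 0.52, 0.48, 0.46, 0.45)))
    wm_ndi = dict(zip(WM_ROIS, (0.60, 0.55, 0.62, 0.58, 0.56, 0.65)))
    wm_odi = dict(zip(WM_ROIS, (0.22, 0.28, 0.25, 0.24, 0.26, 0.18)))
    out: dict[tuple[str, str], float] = {}
    for roi in GM_ROIS:
        out[(roi, "NDI")] = gm_ndi[roi]
        out[(roi, "ODI")] = gm_odi[roi]
    for roi in WM_ROIS:
        out[(roi, "NDI")] = wm_ndi[roi]
        out[(roi, "ODI")] = wm_odi[roi]
    return out


def _default_group_effects() -> dict[tuple[str, str, str], float]:
    """Planted shifts in residual-SD units, keyed (group, roi, metric).

    ``group`` is a diagnosis (MCI/AD) or an A/T cell label; shifts for all
    matching keys add. The defaults plant lower GM dispersion and density and
    lower WM density in the impaired groups, with a bidirectional WM ODI
    pattern (uncinate and cingulum-hippocampus raised, ILF lowered), and a
    milder posterior dispersion reduction in cognitively unimpaired A+T+.
    """
    eff: dict[tuple[str, str, str], float] = {}
    for dx in ("MCI", "AD"):
        for roi in GM_ROIS:
            eff[(dx, roi, "ODI")] = -1.0
        for roi in ("hippocampus", "parahippocampus", "posterior_cingulate_gyrus"):
            eff[(dx, roi, "NDI")] = -0.9
        for roi in ("inferior_longitudinal_fasciculus", "cingulum_hippocampus",
                    "cingulum_cingulate"):
            eff[(dx, roi, "NDI")] = -0.9
        eff[(dx, "uncinate_fasciculus", "ODI")] = 1.0
        eff[(dx, "cingulum_hippocampus", "ODI")] = 0.9
        eff[(dx, "inferior_longitudinal_fasciculus", "ODI")] = -0.8
    # Preclinical effects confined to the CU A+T+ cell (matched by A/T label).
    eff[("A+T+", "posterior_cingulate_gyrus", "ODI")] = -0.45
    eff[("A+T+", "inferior_parietal_precuneus", "ODI")] = -0.45
    eff[("A+T+", "forceps_major", "ODI")] = -0.5
    return eff


@dataclass
class CSFParams:
    """Log-normal location (median) and log-scale per analyte, conditional on
    the A/T cell; sampling truncates each draw to the cutoff side of the cell.
    Concentrations carry pg/mL semantics; the amyloid ratio is dimensionless.
    """

    ratio_neg_median: float = 0.070
    ratio_neg_sigma: float = 0.22
    ratio_pos_median: float = 0.034
    ratio_pos_sigma: float = 0.20
    ptau_neg_median: float = 16.5
    ptau_neg_sigma: float = 0.28
    ptau_pos_median: float = 33.0
    ptau_pos_sigma: float = 0.28
    abeta40_median: float = 15000.0
    abeta40_sigma: float = 0.25


@dataclass
class CohortConfig:
    """Full parameterisation of the synthetic cohort.

    n_per_group maps (diagnosis, A/T cell) to a count; cells absent from the
    mapping contribute zero participants. A-T+ participants (excluded by the
    analysis-sample filter) are generated only if explicitly given a count.
    """

    n_per_group: dict[tuple[str, str], int] = field(default_factory=_default_counts)
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"CU": 65.10, "MCI": 71.77, "AD": 71.36})
    age_sd: dict[str, float] = field(
        default_factory=lambda: {"CU": 7.81, "MCI": 9.73, "AD": 2.52})
    female_fraction: dict[str, float] = field(
        default_factory=lambda: {"CU": 0.65, "MCI": 0.83, "AD": 0.40})
    csf_params: CSFParams = field(default_factory=CSFParams)
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    roi_baselines: dict[tuple[str, str], float] = field(default_factory=_default_baselines)
    # Linear effects keyed (tissue_class, metric): metric units per year / per
    # sex level (female minus male).
    age_slope: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("GM", "NDI"): -0.0015, ("GM", "ODI"): 0.0005,
        ("WM", "NDI"): -0.0010, ("WM", "ODI"): 0.0008,
    })
    sex_effect: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("GM", "NDI"): 0.005, ("GM", "ODI"): -0.004,
        ("WM", "NDI"): 0.006, ("WM", "ODI"): -0.003,
    })
    group_effects: dict[tuple[str, str, str], float] = field(
        default_factory=_default_group_effects)
    residual_sd: float | dict[tuple[str, str], float] = 0.03
    # Share of residual variance carried by a participant-level component
    # common to all (ROI, metric) cells; emulates the strong within-person
    # correlation of microstructure metrics across regions. Marginal per-cell
    # residual SD stays residual_sd.
    residual_correlation: float = 0.6
    age_reference: float = 65.0  # centering constant of the generative model
    seed: int = 0

    def residual_sd_for(self, roi: str, metric: str) -> float:
        if isinstance(self.residual_sd, dict):
            return self.residual_sd[(roi, metric)]
        return float(self.residual_sd)

    def validate(self) -> None:
        for (dx, cell), n in self.n_per_group.items():
            if dx not in DIAGNOSES:
                raise ValueError(f"n_per_group: unknown diagnosis {dx!r}")
            if cell not in AT_CELLS:
                raise ValueError(f"n_per_group: unknown A/T cell {cell!r}")
            if n < 0:
                raise ValueError(f"n_per_group[{dx}, {cell}] is negative")
        for dx in {k[0] for k in self.n_per_group}:
            if self.age_sd.get(dx, 1.0) <= 0:
                raise ValueError(f"age_sd[{dx}] must be positive")
            ff = self.female_fraction.get(dx, 0.5)
            if not 0 <= ff <= 1:
                raise ValueError(f"female_fraction[{dx}] outside [0, 1]")
        for f in dataclasses.fields(CSFParams):
            if getattr(self.csf_params, f.name) <= 0:
                raise ValueError(f"csf_params.{f.name} must be positive")
        rsds = (self.residual_sd.values() if isinstance(self.residual_sd, dict)
                else [self.residual_sd])
        if any(s <= 0 for s in rsds):
            raise ValueError("residual_sd must be positive")
        if not 0 <= self.residual_correlation < 1:
            raise ValueError("residual_correlation must lie in [0, 1)")
        for (roi, metric), b in self.roi_baselines.items():
            if not 0 < b < 1:
                raise ValueError(f"roi_baselines[{roi}, {metric}] outside (0, 1)")


def _truncated_lognormal(
    rng: np.random.Generator, n: int, median: float, sigma: float,
    lower: float | None = None, upper: float | None = None,
) -> np.ndarray:
    """Sample log-normal(log median, sigma) restricted to (lower, upper) by
    inverse-CDF sampling, so the bound holds for every draw."""
    mu = np.log(median)
    lo = 0.0 if lower is None else stats.norm.cdf((np.log(lower) - mu) / sigma)
    hi = 1.0 if upper is None else stats.norm.cdf((np.log(upper) - mu) / sigma)
    u = rng.uniform(lo, hi, size=n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def generate_participants(config: CohortConfig) -> pd.DataFrame:
    """Draw the participant table: demographics, CSF analytes, A/T status.

    Cell counts are honoured exactly; sex is Bernoulli per participant at the
    group's female fraction; age is normal truncated to [45, 95] years; CSF
    analytes are log-normal truncated to the cutoff side of the assigned cell.
    The same seed yields a byte-identical table.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 11])
    csf = config.csf_params
    cut = config.cutoffs

    frames: list[pd.DataFrame] = []
    next_id = 0
    for (dx, cell) in sorted(config.n_per_group):
        n = config.n_per_group[(dx, cell)]
        if n == 0:
            continue
        mean, sd = config.age_mean[dx], config.age_sd[dx]
        a, b = (AGE_RANGE[0] - mean) / sd, (AGE_RANGE[1] - mean) / sd
        age = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        sex = (rng.random(n) < config.female_fraction[dx]).astype(int)

        amyloid_pos = cell.startswith("A+")
        tau_pos = cell.endswith("T+")
        abeta40 = _truncated_lognormal(rng, n, csf.abeta40_median, csf.abeta40_sigma)
        if amyloid_pos:
            ratio = _truncated_lognormal(rng, n, csf.ratio_pos_median,
                                         csf.ratio_pos_sigma,
                                         upper=cut.abeta_ratio_cutoff)
        else:
            ratio = _truncated_lognormal(rng, n, csf.ratio_neg_median,
                                         csf.ratio_neg_sigma,
                                         lower=cut.abeta_ratio_cutoff)
        if tau_pos:
            ptau = _truncated_lognormal(rng, n, csf.ptau_pos_median,
                                        csf.ptau_pos_sigma, lower=cut.ptau_cutoff)
        else:
            ptau = _truncated_lognormal(rng, n, csf.ptau_neg_median,
                                        csf.ptau_neg_sigma, upper=cut.ptau_cutoff)

        frames.append(pd.DataFrame({
            "participant_id": [f"P{next_id + i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "diagnosis": dx,
            "abeta42": ratio * abeta40,
            "abeta40": abeta40,
            "ptau": ptau,
            "at_status": cell,
        }))
        next_id += n

    if not frames:
        return pd.DataFrame(columns=["participant_id", "age", "sex", "diagnosis",
                                     "abeta42", "abeta40", "ptau", "at_status"])
    table = pd.concat(frames, ignore_index=True)
    derived = classify_at_table(table, cut)
    if not (derived == table["at_status"]).all():
        raise RuntimeError("generated CSF values inconsistent with assigned A/T cell")
    return table


def generate_roi_values(
    participants: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ROI-level bilateral-mean NDI/ODI values for every participant.

    value = baseline + b_age * (age - age_reference) + b_sex * sex
            + (sum of matching group shifts) * residual_sd + N(0, residual_sd),
    clipped to the open unit interval. Returns ``(roi_table, truth)`` where
    ``truth`` carries the noise-free expectation and the planted shift (in
    residual-SD units) for every cell, for parameter-recovery tests.
    """
    if participants.empty:
        raise ValueError("participants table is empty")
    for col in ("participant_id", "age", "sex", "diagnosis", "at_status"):
        if col not in participants.columns:
            raise ValueError(f"participants missing column {col!r}")
    bad = participants[participants["age"].isna() | participants["sex"].isna()]
    if not bad.empty:
        raise ValueError(
            f"participants missing demographics: {bad['participant_id'].tolist()}")

    rng = np.random.default_rng([int(config.seed), 23])
    age_c = participants["age"].to_numpy(float) - config.age_reference
    sex = participants["sex"].to_numpy(float)
    pid = participants["participant_id"].to_numpy()
    n = len(participants)

    # Per-participant planted shift for each (roi, metric): sum over keys
    # matching the diagnosis or the A/T cell.
    shift = {rm: np.zeros(n) for rm in config.roi_baselines}
    dx = participants["diagnosis"].to_numpy()
    at = participants["at_status"].to_numpy()
    for (group, roi, metric), s in config.group_effects.items():
        mask = (dx == group) | (at == group)
        if (roi, metric) in shift:
            shift[(roi, metric)][mask] += s

    rho = config.residual_correlation
    shared = rng.normal(0.0, 1.0, size=n)  # participant-level component

    rows, truth_rows = [], []
    for roi in ALL_ROIS:
        tissue = ROI_TISSUE[roi]
        for metric in METRICS:
            if (roi, metric) not in config.roi_baselines:
                continue
            sd = config.residual_sd_for(roi, metric)
            expected = (config.roi_baselines[(roi, metric)]
                        + config.age_slope[(tissue, metric)] * age_c
                        + config.sex_effect[(tissue, metric)] * sex
                        + shift[(roi, metric)] * sd)
            noise = sd * (np.sqrt(rho) * shared
                          + np.sqrt(1.0 - rho) * rng.normal(0.0, 1.0, size=n))
            value = np.clip(expected + noise, 1e-6, 1 - 1e-6)
            rows.append(pd.DataFrame({
                "participant_id": pid, "roi_name": roi, "metric": metric,
                "tissue_class": tissue, "value": value,
            }))
            truth_rows.append(pd.DataFrame({
                "participant_id": pid, "roi_name": roi, "metric": metric,
                "tissue_class": tissue, "expected": expected,
                "shift_sd": shift[(roi, metric)], "residual_sd": sd,
            }))
    return (pd.concat(rows, ignore_index=True),
            pd.concat(truth_rows, ignore_index=True))


# ---------------------------------------------------------------------------
# CSV round-trip (UTF-8, header row, one row per record, full float precision)

PARTICIPANT_COLUMNS = ["participant_id", "age", "sex", "diagnosis",
                       "abeta42", "abeta40", "ptau", "at_status"]
ROI_COLUMNS = ["participant_id", "roi_name", "metric", "tissue_class", "value"]


def write_cohort(
    participants: pd.DataFrame, roi_table: pd.DataFrame, outdir: str | Path,
    seed: int | None = None,
) -> None:
    """Write participants.csv, roi_values.csv and a provenance sidecar.

    Floats are written with ``repr`` round-trip precision so reading the files
    back reproduces the tables exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants[PARTICIPANT_COLUMNS].to_csv(
        outdir / "participants.csv", index=False, float_format="%.17g")
    roi_table[ROI_COLUMNS].to_csv(
        outdir / "roi_values.csv", index=False, float_format="%.17g")
    provenance = {"seed": seed, "n_participants": int(len(participants)),
                  "format": "noddinorms cohort CSV v1"}
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read and validate a participants CSV; errors carry file line numbers
    (header is line 1)."""
    df = pd.read_csv(path)
    missing = set(PARTICIPANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"participants file missing columns: {sorted(missing)}")
    dup = df["participant_id"][df["participant_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate participant_id: {dup.iloc[0]!r} "
                         f"(line {dup.index[0] + 2})")
    for col in ("age", "abeta42", "abeta40", "ptau"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(f"non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    if (df["age"] <= 0).any():
        line = int(df.index[df["age"] <= 0][0]) + 2
        raise ValueError(f"non-positive age at line {line}")
    if not df["sex"].isin([0, 1]).all():
        line = int(df.index[~df["sex"].isin([0, 1])][0]) + 2
        raise ValueError(f"sex must be 0 (male) or 1 (female); bad value at line {line}")
    return df


def read_roi_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an ROI-values CSV; values must lie in (0, 1)."""
    df = pd.read_csv(path)
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI file missing columns: {sorted(missing)}")
    coerced = pd.to_numeric(df["value"], errors="coerce")
    bad = coerced.isna() & df["value"].notna()
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"non-numeric ROI value at line {line}")
    df["value"] = coerced
    out_of_range = (df["value"] <= 0) | (df["value"] >= 1)
    if out_of_range.any():
        line = int(df.index[out_of_range][0]) + 2
        raise ValueError(f"ROI value outside (0, 1) at line {line}")
    dup = df.duplicated(subset=["participant_id", "roi_name", "metric"])
    if dup.any():
        row = df.loc[df.index[dup][0]]
        raise ValueError(
            f"duplicate ROI row for participant {row['participant_id']!r}, "
            f"{row['roi_name']}/{row['metric']} (line {int(df.index[dup][0]) + 2})")
    return df
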
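"""Firth-penalized logistic regression model-comparison suite.

Ten models predict clinical status (cognitively unimpaired vs impaired), all
controlling for age and sex: a base model, CSF A/T status as a single ordinal
covariate (1 = A-T-, 2 = A+T-, 3 = A+T+), four models adding the six raw
bilateral ROI means of one metric x tissue-class block, and four combining
A/T status with each block. Each fit reports the in-sample ROC AUC with a
DeLong 95% CI, AIC from the penalized log-likelihood, and a penalized
log-likelihood ratio (PLR) against a configurable reference model.

Firth's correction penalizes the likelihood by the Jeffreys prior,
l*(b) = l(b) + 0.5 * log det I(b), which keeps estimates finite under
complete separation and reduces small-sample bias — essential here, where
the impaired class is small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import GM_ROIS, WM_ROIS

__all__ = [
    "FirthFit",
    "fit_firth_logistic",
    "roc_auc",
    "delong_auc_ci",
    "model_fit_stats",
    "run_model_suite",
    "MODEL_SPECS",
]


@dataclass
class FirthFit:
    """Result of a Firth-penalized logistic fit."""

    coef: np.ndarray              # per design column
    se: np.ndarray                # Wald standard errors from the Fisher info
    ci_low: np.ndarray
    ci_high: np.ndarray
    penalized_loglik: float       # nats
    loglik: float                 # unpenalized, at the penalized optimum
    converged: bool
    iterations: int
    score_norm: float             # penalized-score norm at the final estimate
    fitted: np.ndarray = field(repr=False, default=None)
    max_hat: float = float("nan")

    @property
    def k(self) -> int:
        return len(self.coef)


def _penalized_parts(X: np.ndarray, y: np.ndarray, beta: np.ndarray):
    eta = X @ beta
    p = expit(eta)
    w = p * (1.0 - p)
    Xw = X * w[:, None]
    info = X.T @ Xw
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return p, w, info, -np.inf, -np.inf
    # Log-likelihood written to stay finite for extreme eta.
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return p, w, info, ll, ll + 0.5 * logdet


def fit_firth_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
    ci_level: float = 0.95,
) -> FirthFit:
    """Maximize the Jeffreys-penalized logistic likelihood.

    Uses modified-score Newton iterations: the score is augmented with the
    hat-value correction h_i * (1/2 - p_i), and steps are halved (up to 10
    times) whenever the penalized likelihood would decrease. Convergence is
    declared when the penalized-score norm falls below ``tol``. The design
    matrix must include its own intercept column if one is wanted.
    """
    X_raw = np.asarray(X, float)
    y = np.asarray(y, float)
    if X_raw.ndim == 1:
        X_raw = X_raw[:, None]
    n, k = X_raw.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.linalg.matrix_rank(X_raw) < k:
        raise ValueError("design matrix is rank deficient")

    # Rescale columns to unit spread for the iterations: the penalized
    # objective is equivariant under column scaling (the Jeffreys term shifts
    # by a constant), and the Newton steps are far better conditioned when
    # age in years and unit-interval metrics share a scale.
    col_sd = X_raw.std(axis=0)
    scale = np.where(col_sd > 0, col_sd, 1.0)
    X = X_raw / scale

    beta = np.zeros(k)
    p, w, info, ll, pll = _penalized_parts(X, y, beta)
    score_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        info_inv = np.linalg.inv(info)
        # hat diagonal of the weighted design: h_i = w_i x_i' I^{-1} x_i
        h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        score_norm = float(np.linalg.norm(score))
        if score_norm < tol:
            break
        step = info_inv @ score
        # Step-halving on the penalized likelihood; the acceptance test
        # tolerates float-level decreases so Newton steps near the optimum
        # (where the gain is below double precision) are not rejected.
        for _ in range(11):
            cand = beta + step
            p_c, w_c, info_c, ll_c, pll_c = _penalized_parts(X, y, cand)
            if pll_c >= pll - 1e-10 * (1.0 + abs(pll)) or np.allclose(step, 0):
                break
            step = step / 2.0
        beta, p, w, info, ll, pll = cand, p_c, w_c, info_c, ll_c, pll_c

    converged = score_norm < tol
    if not converged:
        # The modified-score Newton uses the Fisher information as Hessian,
        # which drops the penalty's curvature; when the penalty dominates
        # (tiny n, heavy separation) the iteration is only linearly
        # convergent. Polish with BFGS on the penalized objective — the
        # modified score is its exact gradient.
        from scipy.optimize import minimize

        def neg_pll(b):
            return -_penalized_parts(X, y, b)[4]

        def neg_grad(b):
            p_b, w_b, info_b, _, pll_b = _penalized_parts(X, y, b)
            if not np.isfinite(pll_b):
                return np.full(k, np.nan)
            inv_b = np.linalg.inv(info_b)
            h_b = w_b * np.einsum("ij,jk,ik->i", X, inv_b, X)
            return -(X.T @ (y - p_b + h_b * (0.5 - p_b)))

        res = minimize(neg_pll, beta, jac=neg_grad, method="BFGS",
                       options={"gtol": tol / 10, "maxiter": 500})
        cand_norm = float(np.linalg.norm(res.jac))
        if cand_norm < score_norm:
            beta = res.x
            p, w, info, ll, pll = _penalized_parts(X, y, beta)
            score_norm = cand_norm
        converged = score_norm < tol
    if not converged:
        warnings.warn(
            f"Firth fit did not converge in {max_iter} iterations "
            f"(score norm {score_norm:.2e}); returning last iterate",
            stacklevel=2)
    info_inv = np.linalg.inv(info)
    h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
    # Map back to the raw parameterisation; the reported penalized
    # log-likelihood uses the raw design so AIC/PLR are comparable across
    # models regardless of internal scaling.
    beta_raw = beta / scale
    se_raw = np.sqrt(np.diag(info_inv)) / scale
    _, _, _, ll_raw, pll_raw = _penalized_parts(X_raw, y, beta_raw)
    zq = stats.norm.ppf(0.5 + ci_level / 2)
    return FirthFit(
        coef=beta_raw, se=se_raw,
        ci_low=beta_raw - zq * se_raw, ci_high=beta_raw + zq * se_raw,
        penalized_loglik=float(pll_raw), loglik=float(ll_raw),
        converged=converged, iterations=it, score_norm=score_norm,
        fitted=p, max_hat=float(h.max()),
    )


def roc_auc(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formula; ties count one half."""
    s = np.asarray(scores, float)
    lab = np.asarray(labels)
    if set(np.unique(lab)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n1 = int(np.sum(lab == 1))
    n0 = int(np.sum(lab == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present: AUC undefined")
    ranks = stats.rankdata(s)
    return float((ranks[lab == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_ci(
    scores, labels, level: float = 0.95
) -> tuple[float, float]:
    """DeLong structural-components CI for the AUC of one score vector.

    Normal-approximation interval truncated to [0, 1]; under perfect
    separation the variance degenerates and a zero-width interval at the AUC
    is returned with a warning.
    """
    s = np.asarray(scores, float)
    lab = np.asarray(labels)
    pos = s[lab == 1]
    neg = s[lab == 0]
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise ValueError("need at least 2 members per class")
    auc = roc_auc(s, lab)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    # Structural components: v10 over positives, v01 over negatives.
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    if var <= 0:
        warnings.warn("degenerate DeLong variance (perfect separation); "
                      "returning zero-width interval", stacklevel=2)
        return auc, auc
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(var)
    return max(auc - half, 0.0), min(auc + half, 1.0)


def model_fit_stats(fit: FirthFit, reference: FirthFit | None) -> tuple[float, float]:
    """(AIC, PLR) for a Firth fit.

    AIC = -2 * penalized log-likelihood + 2k. PLR = 2 * (pll_fit - pll_ref);
    positive when the fit improves on the reference. With no reference the
    PLR is NaN.
    """
    aic = -2.0 * fit.penalized_loglik + 2.0 * fit.k
    if reference is None:
        return float(aic), float("nan")
    plr = 2.0 * (fit.penalized_loglik - reference.penalized_loglik)
    return float(aic), float(plr)


# Covariate blocks per model id; age and sex are always included.
MODEL_SPECS: dict[int, tuple[str, ...]] = {
    0: (),
    1: ("at",),
    2: ("wm_ndi",),
    3: ("wm_odi",),
    4: ("gm_ndi",),
    5: ("gm_odi",),
    6: ("at", "wm_ndi"),
    7: ("at", "wm_odi"),
    8: ("at", "gm_ndi"),
    9: ("at", "gm_odi"),
}

MODEL_LABELS = {
    0: "age + sex only",
    1: "CSF A/T status",
    2: "WM NDI", 3: "WM ODI", 4: "GM NDI", 5: "GM ODI",
    6: "CSF A/T status + WM NDI", 7: "CSF A/T status + WM ODI",
    8: "CSF A/T status + GM NDI", 9: "CSF A/T status + GM ODI",
}

_AT_ORDINAL = {"A-T-": 1.0, "A+T-": 2.0, "A+T+": 3.0}

_BLOCK_ROIS = {
    "wm_ndi": (WM_ROIS, "NDI"), "wm_odi": (WM_ROIS, "ODI"),
    "gm_ndi": (GM_ROIS, "NDI"), "gm_odi": (GM_ROIS, "ODI"),
}


def _design_columns(
    participants: pd.DataFrame, wide: pd.DataFrame, blocks: tuple[str, ...],
    at_coding: str,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(participants)),
            participants["age"].to_numpy(float),
            participants["sex"].to_numpy(float)]
    names = ["intercept", "age", "sex"]
    for block in blocks:
        if block == "at":
            at = participants["at_status"].map(_AT_ORDINAL)
            if at.isna().any():
                bad = participants.loc[at.isna(), "at_status"].unique()
                raise ValueError(f"A/T status outside the 1/2/3 coding: {bad}")
            if at_coding == "ordinal":
                cols.append(at.to_numpy(float))
                names.append("at_status")
            else:  # dummy coding with A-T- as reference
                for cell in ("A+T-", "A+T+"):
                    cols.append((participants["at_status"] == cell)
                                .to_numpy(float))
                    names.append(f"at_{cell}")
        else:
            rois, metric = _BLOCK_ROIS[block]
            for roi in rois:
                key = (roi, metric)
                if key not in wide.columns:
                    raise ValueError(f"ROI table missing {roi}/{metric}")
                cols.append(wide.loc[participants["participant_id"], key]
                            .to_numpy(float))
                names.append(f"{roi}_{metric}")
    return np.column_stack(cols), names


def run_model_suite(
    participants: pd.DataFrame,
    roi_table: pd.DataFrame,
    outcome: tuple[tuple[str, ...], tuple[str, ...]] = (("CU",), ("MCI", "AD")),
    plr_reference: int = 0,
    at_coding: str = "ordinal",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[pd.DataFrame, dict[int, FirthFit]]:
    """Fit models 0-9 and report AUC (DeLong CI), AIC and PLR per model.

    ``outcome`` is a pair of diagnosis tuples: first coded 0, second coded 1;
    participants with other diagnoses are dropped. ROI covariates are the RAW
    bilateral means. Returns the results table and the fits keyed by model id.
    """
    neg, pos = outcome
    sel = participants[participants["diagnosis"].isin(neg + pos)].copy()
    y = sel["diagnosis"].isin(pos).to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("fewer than 2 outcome classes after selection")

    wide = roi_table.pivot_table(index="participant_id",
                                 columns=["roi_name", "metric"],
                                 values="value")
    missing = set(sel["participant_id"]) - set(wide.index)
    if missing:
        raise ValueError(f"participants without ROI values: {sorted(missing)}")

    fits: dict[int, FirthFit] = {}
    designs: dict[int, list[str]] = {}
    for mid, blocks in MODEL_SPECS.items():
        X, names = _design_columns(sel, wide, blocks, at_coding)
        fits[mid] = fit_firth_logistic(X, y, tol=tol, max_iter=max_iter)
        designs[mid] = names

    ref = fits.get(plr_reference)
    rows = []
    for mid, fit in fits.items():
        auc = roc_auc(fit.fitted, y)
        lo, hi = delong_auc_ci(fit.fitted, y)
        aic, plr = model_fit_stats(fit, None if mid == plr_reference else ref)
        rows.append({
            "model_id": mid, "model": MODEL_LABELS[mid],
            "n_covariates": fit.k, "auc": auc,
            "auc_ci_low": lo, "auc_ci_high": hi,
            "aic": aic, "plr_vs_reference": plr,
            "penalized_loglik": fit.penalized_loglik,
            "converged": fit.converged, "n": int(len(y)),
        })
    return pd.DataFrame(rows), fits
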
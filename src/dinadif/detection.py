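"""The three DIF detection statistics: Mantel-Haenszel, logistic regression,
and the Wald test of DINA item-parameter invariance.

All three flag an item at level ``alpha`` (default 0.05, no multiple-testing
adjustment — the study reports raw per-item rejection rates):

* Mantel-Haenszel — examinees are stratified by number-correct total score
  (the studied item included in the matching score, no purification loop);
  per stratum a 2x2 table (group x correct/incorrect) contributes to the
  classical continuity-corrected MH chi-square on 1 df.  Score-based; never
  reads the Q-matrix.
* Logistic regression — for the studied item, the score-only binary-response
  model M0: logit P = b0 + b1*score is tested against M1 adding group and
  group x score; the 2-df likelihood-ratio statistic jointly targets uniform
  and nonuniform DIF.  Score-based; never reads the Q-matrix.
* Wald — a two-group DINA model is fitted by EM with the studied item's
  (s, g) group-specific and everything else shared; W = d' V^-1 d with
  d = (g_F - g_R, s_F - s_R) and V the OPG covariance of d, on 2 df.
  Conditions on the analysis Q-matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .dina import QMatrix, ResponseMatrix
from .estimation import (
    EstimationError,
    FitOptions,
    FittedDina,
    MultiGroupFit,
    em_fit,
    multigroup_em_fit,
    studied_item_covariance,
)

__all__ = [
    "DifTestResult",
    "DetectionError",
    "mantel_haenszel_test",
    "mantel_haenszel_from_tables",
    "logistic_regression_test",
    "wald_dif_test",
    "run_all_methods",
]

METHODS = ("mh", "logistic", "wald")


class DetectionError(RuntimeError):
    """Raised when a DIF statistic cannot be computed on the given data."""


@dataclass(frozen=True)
class DifTestResult:
    """One item x method decision."""

    item_id: int
    method: str
    statistic: float
    df: int
    p_value: float
    flagged: bool
    alpha: float = 0.05
    note: str = ""


def _as_matrix(x: ResponseMatrix | np.ndarray) -> np.ndarray:
    return x.responses if isinstance(x, ResponseMatrix) else np.asarray(x)


# --------------------------------------------------------------------------
# Mantel-Haenszel
# --------------------------------------------------------------------------


def mantel_haenszel_from_tables(
    tables: np.ndarray, continuity_correction: bool = True
) -> tuple[float, float]:
    """MH chi-square and common odds ratio from stratified 2x2 tables.

    ``tables`` has shape (S, 2, 2) with rows = group (reference, focal) and
    columns = (correct, incorrect).  Strata with a zero margin contribute
    nothing (their variance term is zero) and are effectively dropped.
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim != 3 or t.shape[1:] != (2, 2):
        raise ValueError("tables must have shape (S, 2, 2)")
    a = t[:, 0, 0]  # reference correct
    n1 = t[:, 0, :].sum(axis=1)  # reference total
    n2 = t[:, 1, :].sum(axis=1)  # focal total
    m1 = t[:, :, 0].sum(axis=1)  # correct total
    m0 = t[:, :, 1].sum(axis=1)  # incorrect total
    tot = n1 + n2
    usable = tot >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        expect = np.where(usable, n1 * m1 / np.maximum(tot, 1), 0.0)
        var = np.where(
            usable,
            n1 * n2 * m1 * m0 / np.maximum(tot * tot * (tot - 1.0), 1.0),
            0.0,
        )
    denom = var.sum()
    if denom <= 0:
        raise DetectionError("no usable strata: every score stratum has zero variance")
    num = abs(a.sum() - expect.sum())
    if continuity_correction:
        num = max(num - 0.5, 0.0)
    stat = num * num / denom
    # Mantel-Haenszel common odds ratio (reference odds over focal odds)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(tot > 0, t[:, 0, 0] * t[:, 1, 1] / np.maximum(tot, 1), 0.0)
        s_ = np.where(tot > 0, t[:, 0, 1] * t[:, 1, 0] / np.maximum(tot, 1), 0.0)
    odds = r.sum() / s_.sum() if s_.sum() > 0 else np.inf
    return float(stat), float(odds)


def _score_strata(x_ref: np.ndarray, x_foc: np.ndarray):
    """Per-stratum 2x2 counts for every item at once: (S, 2, 2, J)."""
    j = x_ref.shape[1]
    scores_r = x_ref.sum(axis=1)
    scores_f = x_foc.sum(axis=1)
    n_strata = j + 1  # total scores 0..J
    onehot_r = np.zeros((x_ref.shape[0], n_strata))
    onehot_r[np.arange(x_ref.shape[0]), scores_r] = 1.0
    onehot_f = np.zeros((x_foc.shape[0], n_strata))
    onehot_f[np.arange(x_foc.shape[0]), scores_f] = 1.0
    corr_r = onehot_r.T @ x_ref  # (S, J) reference correct per stratum
    corr_f = onehot_f.T @ x_foc
    tot_r = onehot_r.sum(axis=0)  # (S,)
    tot_f = onehot_f.sum(axis=0)
    tables = np.empty((n_strata, 2, 2, j))
    tables[:, 0, 0, :] = corr_r
    tables[:, 0, 1, :] = tot_r[:, None] - corr_r
    tables[:, 1, 0, :] = corr_f
    tables[:, 1, 1, :] = tot_f[:, None] - corr_f
    return tables


def mantel_haenszel_test(
    x_ref: ResponseMatrix | np.ndarray,
    x_foc: ResponseMatrix | np.ndarray,
    item: int,
    alpha: float = 0.05,
    continuity_correction: bool = True,
) -> DifTestResult:
    """Mantel-Haenszel DIF test for one item, matching on total score."""
    xr, xf = _as_matrix(x_ref), _as_matrix(x_foc)
    if xr.shape[1] != xf.shape[1]:
        raise ValueError("groups must share the same items")
    jidx = item - 1
    if not (0 <= jidx < xr.shape[1]):
        raise KeyError(f"unknown item id {item}")
    tables = _score_strata(xr, xf)[:, :, :, jidx]
    stat, _ = mantel_haenszel_from_tables(tables, continuity_correction)
    p = float(chi2.sf(stat, 1))
    return DifTestResult(item, "mh", stat, 1, p, p < alpha, alpha)


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------


def _logistic_lr_statistic(
    score: np.ndarray, group: np.ndarray, succ: np.ndarray, tot: np.ndarray
) -> float:
    """2-df LR statistic from counts collapsed by (score, group) cell."""
    endog = np.column_stack([succ, tot - succ])
    x0 = np.column_stack([np.ones_like(score), score])
    x1 = np.column_stack([np.ones_like(score), score, group, group * score])
    fam = sm.families.Binomial()
    m0 = sm.GLM(endog, x0, family=fam).fit()
    m1 = sm.GLM(endog, x1, family=fam).fit()
    if not (np.isfinite(m0.llf) and np.isfinite(m1.llf)):
        raise DetectionError("logistic model log-likelihood not finite")
    return max(2.0 * (m1.llf - m0.llf), 0.0)


def logistic_regression_test(
    x_ref: ResponseMatrix | np.ndarray,
    x_foc: ResponseMatrix | np.ndarray,
    item: int,
    alpha: float = 0.05,
) -> DifTestResult:
    """Joint uniform + nonuniform logistic-regression DIF test (2 df).

    The studied item's responses are modelled against total score (M0) and
    against score + group + group x score (M1); responses are collapsed to
    binomial counts per (score, group) cell before fitting.  Separation or
    non-convergence is reported via DetectionError so callers can mark the
    replication invalid rather than mis-flag.
    """
    xr, xf = _as_matrix(x_ref), _as_matrix(x_foc)
    if xr.shape[1] != xf.shape[1]:
        raise ValueError("groups must share the same items")
    jidx = item - 1
    if not (0 <= jidx < xr.shape[1]):
        raise KeyError(f"unknown item id {item}")
    score = np.concatenate([xr.sum(axis=1), xf.sum(axis=1)])
    group = np.concatenate([np.zeros(xr.shape[0]), np.ones(xf.shape[0])])
    y = np.concatenate([xr[:, jidx], xf[:, jidx]])
    cells = pd.DataFrame({"score": score, "group": group, "y": y})
    agg = cells.groupby(["score", "group"], as_index=False).agg(
        succ=("y", "sum"), tot=("y", "size")
    )
    try:
        stat = _logistic_lr_statistic(
            agg["score"].to_numpy(float),
            agg["group"].to_numpy(float),
            agg["succ"].to_numpy(float),
            agg["tot"].to_numpy(float),
        )
    except (np.linalg.LinAlgError, ValueError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise DetectionError(f"logistic fit failed for item {item}: {exc}") from exc
    p = float(chi2.sf(stat, 2))
    return DifTestResult(item, "logistic", stat, 2, p, p < alpha, alpha)


# --------------------------------------------------------------------------
# Wald
# --------------------------------------------------------------------------


def wald_dif_test(
    x_ref: ResponseMatrix | np.ndarray,
    x_foc: ResponseMatrix | np.ndarray,
    q: QMatrix,
    item: int,
    alpha: float = 0.05,
    options: FitOptions | None = None,
    init: FittedDina | MultiGroupFit | None = None,
    information: str = "item_block",
) -> DifTestResult:
    """Wald test of item-parameter invariance for one item (2 df).

    Fits the two-group DINA with the studied item freed, forms
    d = (g_F - g_R, s_F - s_R) and W = d' V^-1 d with V from the OPG
    covariance of the joint fit (item-wise information block by default, the
    convention of the standard implementations; ``information='full'`` for
    the complete-information variant).  ``init`` may carry a warm start (a
    pooled single-group fit or the fully shared two-group fit).
    """
    fit = multigroup_em_fit(x_ref, x_foc, q, item, options=options, init=init)
    cov4 = studied_item_covariance(fit, information)  # (s_R, g_R, s_F, g_F)
    est = fit.studied_estimates()
    d = np.array([est[3] - est[1], est[2] - est[0]])  # (g_F - g_R, s_F - s_R)
    contrast = np.array([[0.0, -1.0, 0.0, 1.0], [-1.0, 0.0, 1.0, 0.0]])
    v = contrast @ cov4 @ contrast.T
    try:
        w = float(d @ np.linalg.solve(v, d))
    except np.linalg.LinAlgError as exc:
        raise DetectionError(
            f"singular covariance of the parameter differences for item {item}"
        ) from exc
    if not np.isfinite(w):
        raise DetectionError(f"non-finite Wald statistic for item {item}")
    w = max(w, 0.0)
    note = "" if fit.converged else "multigroup EM hit max_iter"
    p = float(chi2.sf(w, 2))
    return DifTestResult(item, "wald", w, 2, p, p < alpha, alpha, note)


# --------------------------------------------------------------------------
# all methods, all items
# --------------------------------------------------------------------------


def run_all_methods(
    x_ref: ResponseMatrix | np.ndarray,
    x_foc: ResponseMatrix | np.ndarray,
    q: QMatrix,
    alpha: float = 0.05,
    methods: tuple[str, ...] = METHODS,
    fit_options: FitOptions | None = None,
) -> pd.DataFrame:
    """Apply the requested DIF tests to every item.

    Returns a tidy frame with one row per item x method (statistic, df, p,
    flagged, note).  MH and logistic never read Q; Wald conditions on the
    analysis Q.  Per-item failures are recorded in the ``note`` column with
    ``flagged`` left missing, never raised.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    xr, xf = _as_matrix(x_ref), _as_matrix(x_foc)
    if xr.shape[1] != q.n_items:
        raise ValueError("response columns must match Q-matrix rows")
    rows: list[dict] = []

    def record(res: DifTestResult) -> None:
        rows.append(
            {
                "item_id": res.item_id,
                "method": res.method,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "flagged": res.flagged,
                "note": res.note,
            }
        )

    def record_failure(item: int, method: str, exc: Exception) -> None:
        rows.append(
            {
                "item_id": item,
                "method": method,
                "statistic": np.nan,
                "df": pd.NA,
                "p_value": np.nan,
                "flagged": pd.NA,
                "note": str(exc),
            }
        )

    if "mh" in methods:
        tables = _score_strata(xr, xf)
        for item in q.item_ids:
            try:
                stat, _ = mantel_haenszel_from_tables(tables[:, :, :, item - 1])
                p = float(chi2.sf(stat, 1))
                record(DifTestResult(item, "mh", stat, 1, p, p < alpha, alpha))
            except DetectionError as exc:
                record_failure(item, "mh", exc)
    if "logistic" in methods:
        for item in q.item_ids:
            try:
                record(logistic_regression_test(xr, xf, item, alpha))
            except DetectionError as exc:
                record_failure(item, "logistic", exc)
    if "wald" in methods:
        # one fully shared two-group fit warm-starts every per-item fit
        base = multigroup_em_fit(xr, xf, q, None, options=fit_options)
        for item in q.item_ids:
            try:
                record(
                    wald_dif_test(
                        xr, xf, q, item, alpha, options=fit_options, init=base
                    )
                )
            except (DetectionError, EstimationError) as exc:
                record_failure(item, "wald", exc)
    out = pd.DataFrame(rows)
    out["flagged"] = out["flagged"].astype("boolean")
    return out
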
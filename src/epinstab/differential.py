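"""Per-CpG supervised differential methylation analysis.

Each probe's beta value is regressed on a binary disease status plus
optional covariates (age, bisulfite-control intensity, chip as a
categorical batch term). The status coefficient gives the adjusted
mean beta difference; its t statistic and two-sided p-value form the
per-CpG result. Hyper- and hypomethylation call lists come from a raw
p-value threshold with the direction read off the effect sign, and the
skew between the two list sizes is assessed with an exact two-sided
binomial test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .beta_matrix import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "fit_cpg_models",
    "call_differential",
    "binomial_skew",
    "write_results",
]

RESULT_COLUMNS = ["t_stat", "p_value", "effect", "n_used"]


def _design_matrix(samples: pd.DataFrame, status: pd.Series, covariates) -> pd.DataFrame:
    """Intercept + status + covariates; categoricals dummy-coded."""
    cols = {"intercept": np.ones(len(status)), "status": status.astype(float).to_numpy()}
    X = pd.DataFrame(cols, index=status.index)
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"covariate {cov!r} not found in sample annotations")
        col = samples.loc[status.index, cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = col.astype(float).to_numpy()
    return X


def fit_cpg_models(
    bm: BetaMatrix,
    status,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Fit beta ~ status + covariates by OLS for every probe.

    Parameters
    ----------
    bm
        QC-passed beta matrix.
    status
        Binary per-sample indicator (0 = control, 1 = case), as a Series
        aligned to sample ids or an array in sample order. Positive
        effects mean higher methylation in cases.
    covariates
        Annotation columns to adjust for; string-valued columns (e.g.
        ``chip``) enter as dummy-coded categoricals.

    Returns
    -------
    DataFrame indexed by probe_id with t_stat, p_value, effect (adjusted
    beta difference, cases minus controls) and n_used. Probes whose
    design becomes rank-deficient on their non-missing samples yield NA
    rows with a logged reason.
    """
    covariates = covariates or []
    if not isinstance(status, pd.Series):
        status = pd.Series(np.asarray(status), index=bm.values.columns)
    status = status.loc[bm.values.columns]
    levels = set(status.dropna().unique())
    if not levels <= {0, 1}:
        raise ValueError(f"status must be binary 0/1, got levels {sorted(levels)}")
    counts = status.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need both status classes with >= 2 samples each")

    X = _design_matrix(bm.samples, status, covariates)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    Xv = X.to_numpy(dtype=float)
    Y = bm.values.to_numpy(dtype=float)
    n, k = Xv.shape
    j = list(X.columns).index("status")

    out = np.full((bm.n_probes, 4), np.nan)
    complete = ~np.isnan(Y).any(axis=1)

    # fast path: probes with no missing values share one design factorisation
    if complete.any() and n > k:
        XtX_inv = np.linalg.inv(Xv.T @ Xv)
        H = XtX_inv @ Xv.T
        B = Y[complete] @ H.T                      # probes x k coefficients
        resid = Y[complete] - B @ Xv.T
        df = n - k
        sigma2 = (resid ** 2).sum(axis=1) / df
        se = np.sqrt(sigma2 * XtX_inv[j, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = B[:, j] / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        idx = np.flatnonzero(complete)
        out[idx, 0] = t
        out[idx, 1] = p
        out[idx, 2] = B[:, j]
        out[idx, 3] = n

    for i in np.flatnonzero(~complete):
        row = Y[i]
        mask = ~np.isnan(row)
        Xi, yi = Xv[mask], row[mask]
        ni = int(mask.sum())
        if ni <= k or np.linalg.matrix_rank(Xi) < k:
            logger.warning("probe %s: unusable design on %d complete samples",
                           bm.values.index[i], ni)
            continue
        XtX_inv = np.linalg.inv(Xi.T @ Xi)
        b = XtX_inv @ Xi.T @ yi
        resid = yi - Xi @ b
        df = ni - k
        sigma2 = float(resid @ resid) / df
        se = np.sqrt(sigma2 * XtX_inv[j, j])
        t = b[j] / se if se > 0 else np.nan
        out[i] = [t, 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan, b[j], ni]

    res = pd.DataFrame(out, index=bm.values.index, columns=RESULT_COLUMNS)
    res["n_used"] = res["n_used"].astype("Int64")
    # numerically exact-zero p-values are floored so p stays in (0, 1]
    res["p_value"] = res["p_value"].clip(lower=np.finfo(float).tiny)
    return res


def call_differential(results: pd.DataFrame, p_threshold: float) -> tuple[list, list]:
    """Split significant probes into hyper- and hypomethylated lists.

    hyper: p < threshold and effect > 0; hypo: p < threshold and
    effect < 0. Raw p-values are used; no multiplicity correction.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    sig = results["p_value"] < p_threshold
    hyper = results.index[sig & (results["effect"] > 0)].tolist()
    hypo = results.index[sig & (results["effect"] < 0)].tolist()
    return hyper, hypo


def binomial_skew(n_hyper: int, n_hypo: int) -> float:
    """Exact two-sided binomial test of hyper/hypo balance against 0.5.

    Returns the two-sided p-value for observing ``n_hyper`` successes in
    ``n_hyper + n_hypo`` trials under a fair-coin null.
    """
    n = n_hyper + n_hypo
    if n < 1:
        raise ValueError("binomial skew undefined with zero calls in both lists")
    return float(stats.binomtest(n_hyper, n, 0.5, alternative="two-sided").pvalue)


def write_results(results: pd.DataFrame, path) -> None:
    """Write per-probe results as TSV: probe_id, t_stat, p_value, effect, n_used."""
    results.rename_axis("probe_id").to_csv(path, sep="\t")
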
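"""Clinical outcome analysis of the instability indices.

Covers the downstream associations: Kaplan-Meier comparison of index
tertiles, uni/multivariate Cox proportional-hazards fits, the primary
vs metastasis rank-sum shift test, the rank-based ROC/AUC for
discriminating metastases, and the enrichment of MESC loci among CpGs
whose methylation anti-correlates with TET demethylase expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .beta_matrix import BetaMatrix
from .enrichment import EnrichmentResult, fisher_enrichment
from .locus_sets import LocusSet

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalResult",
    "tertile_groups",
    "cox_fit",
    "screen_covariates",
    "km_curves",
    "stage_shift_test",
    "roc_auc",
    "tet_anticorrelation",
]


@dataclass
class SurvivalResult:
    """Cox model summary for the index coefficient."""

    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    covariates: list = field(default_factory=list)
    standardized: bool = True

    def __post_init__(self) -> None:
        if not self.ci_low <= self.hr <= self.ci_high:
            raise ValueError("CI must bracket the hazard ratio")


def tertile_groups(index: pd.Series) -> pd.Series:
    """Assign samples to lower/middle/upper tertiles of an index.

    Uses empirical tertiles of the non-missing values; ties at a
    cut-point are resolved by stable sample order so group sizes are as
    equal as possible and the assignment is deterministic. The middle
    tertile is retained in the labels but conventionally excluded from
    the two-group survival comparison.
    """
    x = index.dropna()
    if len(x) < 3:
        raise ValueError("tertiles need >= 3 non-missing values")
    if x.nunique() == 1:
        raise ValueError("index is constant; tertiles undefined")
    order = np.argsort(x.to_numpy(), kind="stable")
    n = len(x)
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for name, size in zip(("lower", "middle", "upper"), sizes):
        labels[order[start:start + size]] = name
        start += size
    out = pd.Series(labels, index=x.index, name="tertile")
    counts = out.value_counts().to_dict()
    logger.info("tertile sizes: %s", counts)
    return out.reindex(index.index)


def cox_fit(
    time,
    event,
    index,
    covariates: pd.DataFrame | None = None,
    standardize: bool = True,
) -> SurvivalResult:
    """Proportional-hazards fit of survival on an instability index.

    The hazard ratio is reported per unit of the index, or per standard
    deviation when ``standardize`` is on (the default, making HRs
    comparable across indices). Extra covariates enter untransformed;
    rows with any missing value are dropped.
    """
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=float),
                       "index": np.asarray(index, dtype=float)})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        for c in cov.columns:
            if cov[c].dtype == object or isinstance(cov[c].dtype, pd.CategoricalDtype):
                cov = pd.concat([cov.drop(columns=c),
                                 pd.get_dummies(cov[c], prefix=c, drop_first=True, dtype=float)],
                                axis=1)
        df = pd.concat([df, cov], axis=1)
    df = df.dropna()
    if df["event"].sum() < 1:
        raise ValueError("no events observed; Cox model undefined")
    if df["index"].nunique() <= 1:
        raise ValueError("index is constant")
    if standardize:
        df["index"] = (df["index"] - df["index"].mean()) / df["index"].std(ddof=1)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    s = cph.summary.loc["index"]
    return SurvivalResult(
        hr=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        n=len(df),
        covariates=[c for c in df.columns if c not in ("time", "event", "index")],
        standardized=standardize,
    )


def screen_covariates(time, event, candidates: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Select covariates univariately associated with survival.

    Each candidate is fit alone in a univariate Cox model; those with
    p < alpha are returned (and logged) for inclusion in the
    multivariate model.
    """
    keep = []
    for c in candidates.columns:
        try:
            res = cox_fit(time, event, candidates[c], standardize=False)
        except (ValueError, RuntimeError) as exc:
            logger.warning("covariate screen: %s skipped (%s)", c, exc)
            continue
        logger.info("covariate screen: %s p=%.4g", c, res.p_value)
        if res.p_value < alpha:
            keep.append(c)
    return keep


def km_curves(time, event, groups) -> tuple[dict, float | None]:
    """Kaplan-Meier curves per group plus a two-sided log-rank test.

    Returns ``(curves, p)`` where curves maps group label to the fitted
    survival function (DataFrame) and p is the log-rank p-value, or
    None when fewer than two groups are present.
    """
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=float),
                       "group": np.asarray(groups, dtype=object)}).dropna()
    curves = {}
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[g] = kmf.survival_function_
    if df["group"].nunique() < 2:
        return curves, None
    lr = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return curves, float(lr.p_value)


def stage_shift_test(a, b, exact_max_n: int = 25) -> float:
    """One-tailed Wilcoxon rank-sum p for b stochastically larger than a.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations (and no ties), otherwise the normal
    approximation with continuity correction. When every value is tied
    across both groups the test carries no information and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        logger.warning("stage shift test: all values tied; p = 1")
        return 1.0
    small = len(a) <= exact_max_n and len(b) <= exact_max_n
    method = "exact" if small else "asymptotic"
    res = stats.mannwhitneyu(b, a, alternative="greater", method=method)
    return float(res.pvalue)


def roc_auc(index, labels, positive=1, ci: str = "delong") -> tuple[float, tuple[float, float]]:
    """Rank-based AUC for discriminating the positive class, with 95% CI.

    The AUC equals the Mann-Whitney probability that a positive sample
    scores above a negative one (ties count half). The CI is DeLong's
    (default) or a stratified bootstrap (``ci='bootstrap'``); the
    interval is clipped to [0, 1].
    """
    x = np.asarray(index, dtype=float)
    y = np.asarray(labels)
    pos = x[y == positive]
    neg = x[y != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    m, n = len(pos), len(neg)
    # midrank formulation (DeLong)
    all_x = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_x)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    if ci == "delong":
        v10 = (r_all[:m] - r_pos) / n
        v01 = 1.0 - (r_all[m:] - r_neg) / m
        var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
              (np.var(v01, ddof=1) / n if n > 1 else 0.0)
        half = 1.96 * np.sqrt(var)
        lo, hi = auc - half, auc + half
    elif ci == "bootstrap":
        rng = np.random.default_rng(0)
        reps = []
        for _ in range(2000):
            p = rng.choice(pos, m, replace=True)
            q = rng.choice(neg, n, replace=True)
            rr = stats.rankdata(np.concatenate([p, q]))
            reps.append((rr[:m].sum() - m * (m + 1) / 2) / (m * n))
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ValueError("ci must be 'delong' or 'bootstrap'")
    return float(auc), (float(max(lo, 0.0)), float(min(hi, 1.0)))


def tet_anticorrelation(
    bm_tumours: BetaMatrix,
    hypo_probes,
    tet_expr: pd.Series,
    mesc: LocusSet,
    alpha: float = 0.05,
    method: str = "spearman",
) -> tuple[pd.DataFrame, EnrichmentResult]:
    """MESC enrichment among CpGs anti-correlated with TET expression.

    For every hypomethylated probe, correlates its beta values with TET
    (e.g. TET3) expression across tumour samples. A probe is
    "significantly anti-correlated" when rho < 0 and p < alpha. The
    returned table is rank-ordered from most to least anti-correlated
    (heatmap-ready); the enrichment result tests MESC membership among
    the significant probes against the remaining hypomethylated probes.
    """
    tet = tet_expr.reindex(bm_tumours.values.columns)
    usable = tet.notna()
    if usable.sum() < 5:
        raise ValueError("need >= 5 tumour samples with TET expression")
    if tet[usable].nunique() <= 1:
        raise ValueError("TET expression is constant")
    hypo_probes = [p for p in hypo_probes if p in bm_tumours.values.index]
    if not hypo_probes:
        raise ValueError("no hypomethylated probes present in the beta matrix")
    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    samples = bm_tumours.values.columns[usable]
    tvals = tet[samples].to_numpy(dtype=float)
    for p in hypo_probes:
        beta = bm_tumours.values.loc[p, samples].to_numpy(dtype=float)
        mask = ~np.isnan(beta)
        if mask.sum() < 5 or np.unique(beta[mask]).size == 1:
            rows.append((p, np.nan, np.nan, False))
            continue
        rho, pval = corr_fn(beta[mask], tvals[mask])
        rows.append((p, float(rho), float(pval), rho < 0 and pval < alpha))
    table = pd.DataFrame(rows, columns=["probe_id", "rho", "p_value", "anti_correlated"])
    table["is_mesc"] = table["probe_id"].isin(mesc.members)
    table = table.sort_values(["rho", "probe_id"], na_position="last").reset_index(drop=True)
    significant = set(table.loc[table["anti_correlated"], "probe_id"])
    universe = set(table["probe_id"])
    enr = fisher_enrichment(significant, mesc, universe)
    return table, enr
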
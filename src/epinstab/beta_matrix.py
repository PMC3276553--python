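"""Beta-value matrices: computation from intensities, IO, and quality control.

The Infinium assay reports two background-corrected intensities per CpG,
for the methylated (M) and unmethylated (U) allele. The methylation
fraction estimate is

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + 100)

which lies in [0, 1). Sample-level QC removes arrays with poor bisulfite
conversion (control intensity below 4000) and flags total-intensity
outliers; probe-level QC drops CpGs not reliably detected above
background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "QCRecord",
    "compute_beta",
    "read_beta_table",
    "read_sample_annotations",
    "qc_filter_samples",
    "qc_filter_probes",
    "bimodality_score",
]

GROUPS = ("normal", "bdy_control", "bdy_case", "dysplasia", "cancer", "metastasis")


def compute_beta(M, U):
    """Beta value from background-corrected allele intensities.

    Accepts scalars or arrays; negative intensities are clamped to zero
    and the +100 offset in the denominator regularises low-intensity
    probes, so the result is always in [0, 1).
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise ValueError("intensities must be finite")
    m = np.maximum(M, 0.0)
    u = np.maximum(U, 0.0)
    beta = m / (m + u + 100.0)
    return float(beta) if beta.ndim == 0 else beta


@dataclass
class QCRecord:
    """One QC exclusion or flag: sample or probe id plus a reason."""

    item: str
    reason: str
    detail: str = ""


@dataclass
class BetaMatrix:
    """Probes x samples beta values with per-sample annotations.

    Attributes
    ----------
    values
        DataFrame of beta values, probes as rows, samples as columns.
        Non-missing entries lie in [0, 1]; NaN marks missing.
    samples
        DataFrame indexed by sample_id, aligned with ``values`` columns.
        Recognised columns: group, age, chip, bs_intensity, surv_time,
        surv_event; extra covariates are carried through untouched.
    detection_p
        Optional matrix of detection p-values parallel to ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    qc_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples.index.is_unique:
            raise ValueError("sample ids must be unique")
        if list(self.values.columns) != list(self.samples.index):
            self.samples = self.samples.loc[self.values.columns]
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 1))
        if bad:
            raise ValueError(f"{int(bad)} beta values outside [0, 1]")
        if "surv_event" in self.samples.columns and "surv_time" not in self.samples.columns:
            raise ValueError("surv_event requires surv_time")
        if self.detection_p is not None and self.detection_p.shape != self.values.shape:
            raise ValueError("detection_p must be parallel to values")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        ids = list(sample_ids)
        det = self.detection_p[ids] if self.detection_p is not None else None
        return BetaMatrix(self.values[ids], self.samples.loc[ids], det, list(self.qc_log))

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        ids = list(probe_ids)
        det = self.detection_p.loc[ids] if self.detection_p is not None else None
        return BetaMatrix(self.values.loc[ids], self.samples, det, list(self.qc_log))

    def by_group(self, *groups) -> "BetaMatrix":
        keep = self.samples.index[self.samples["group"].isin(groups)]
        return self.subset_samples(keep)


def read_beta_table(path) -> pd.DataFrame:
    """Read a TSV beta matrix (probes x samples, first column probe_id).

    GEO series-matrix-style files are accepted: lines starting with '!'
    are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="!", index_col=0)
    return df.astype(float)


def read_sample_annotations(path) -> pd.DataFrame:
    """Read a sample-annotation CSV keyed by sample_id."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: annotation file needs a sample_id column")
    return df.set_index("sample_id")


def qc_filter_samples(
    bm: BetaMatrix,
    bs_threshold: float = 4000.0,
    intensity: pd.Series | None = None,
    drop_intensity_outliers: bool = False,
) -> tuple[BetaMatrix, list[QCRecord]]:
    """Remove samples failing bisulfite-conversion QC.

    Samples with bisulfite-control intensity strictly below
    ``bs_threshold`` are excluded (a value of exactly 4000 is retained).
    When per-sample total intensities (median of U+M) are supplied,
    samples outside median +/- 3 IQR are flagged as outliers and, only if
    ``drop_intensity_outliers`` is set, excluded as well. The report
    lists every exclusion and flag with its reason.
    """
    report: list[QCRecord] = []
    excluded: set = set()
    if "bs_intensity" in bm.samples.columns and bm.samples["bs_intensity"].notna().any():
        bs = bm.samples["bs_intensity"]
        for sid, val in bs.items():
            if pd.notna(val) and val < bs_threshold:
                excluded.add(sid)
                report.append(QCRecord(sid, "bs_control", f"bs_intensity={val} < {bs_threshold}"))
    else:
        warnings.warn("no bs_intensity annotation present; BS QC skipped", stacklevel=2)
    if intensity is not None:
        med = float(intensity.median())
        q1, q3 = intensity.quantile([0.25, 0.75])
        iqr = float(q3 - q1)
        lo, hi = med - 3 * iqr, med + 3 * iqr
        for sid, val in intensity.items():
            if val < lo or val > hi:
                report.append(QCRecord(sid, "total_intensity_outlier",
                                       f"median I={val:.1f} outside [{lo:.1f}, {hi:.1f}]"))
                if drop_intensity_outliers:
                    excluded.add(sid)
    keep = [s for s in bm.values.columns if s not in excluded]
    if not keep:
        raise ValueError("sample QC excluded every sample")
    out = bm.subset_samples(keep)
    out.qc_log = bm.qc_log + report
    logger.info("sample QC: %d excluded, %d retained", len(excluded), len(keep))
    return out, report


def qc_filter_probes(
    bm: BetaMatrix,
    detection_alpha: float = 0.05,
    min_fraction_detected: float = 0.95,
    strict: bool = False,
) -> BetaMatrix:
    """Drop probes not reliably detected above background.

    A probe is retained when its detection p-value is below
    ``detection_alpha`` in at least ``min_fraction_detected`` of samples.
    Without a detection matrix the input passes through (or errors in
    strict mode).
    """
    if bm.detection_p is None:
        if strict:
            raise ValueError("no detection p-value matrix available")
        warnings.warn("no detection p-values; probe QC skipped", stacklevel=2)
        return bm
    detected = (bm.detection_p.to_numpy() < detection_alpha).mean(axis=1)
    keep = bm.values.index[detected >= min_fraction_detected]
    n_drop = bm.n_probes - len(keep)
    if len(keep) == 0:
        raise ValueError("probe QC dropped every probe")
    if n_drop:
        logger.info("probe QC: dropped %d of %d probes", n_drop, bm.n_probes)
    return bm.subset_probes(keep)


def bimodality_score(bm: BetaMatrix) -> pd.Series:
    """Per-sample bimodality of the beta histogram (reported, never filtered on).

    Uses the bimodality coefficient (skewness^2 + 1) / kurtosis, where a
    value above ~0.55 indicates the two-mode shape expected of a healthy
    methylation array. Visual histogram screening cannot be automated
    faithfully, so this is diagnostic output only.
    """
    from scipy import stats

    out = {}
    for sid in bm.values.columns:
        x = bm.values[sid].dropna().to_numpy()
        if len(x) < 4:
            out[sid] = np.nan
            continue
        g = stats.skew(x)
        k = stats.kurtosis(x, fisher=False)
        out[sid] = (g * g + 1.0) / k if k > 0 else np.nan
    return pd.Series(out, name="bimodality")
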
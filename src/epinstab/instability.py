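"""Epigenetic instability indices.

Beta values are discretized into three methylation states:

    0 (unmethylated)   beta < 0.25
    1 (hemimethylated) 0.25 <= beta <= 0.70
    2 (methylated)     beta > 0.70

A CpG is *stable* when its discretized state is identical in every
normal reference sample. For each tumour, the fraction of stable CpGs
undergoing each of four state transitions is an Epigenetic Instability
Index (EpI):

    0 -> 1/2   gain from unmethylated
    1 -> 2     gain from hemimethylated
    1 -> 0     loss from hemimethylated
    2 -> 0/1   loss from methylated  (the Demethylation Instability
               Index, DeMI)

A transition is only called when the tumour beta additionally differs
from the normal-tissue mean beta by at least a 10% buffer, so that
trivially small shifts across a state threshold do not count. Indices
can be restricted to a locus set (PCGT, MESC); the combined DeMI pools
the two demethylation transitions (1->0 and 2->0/1) at MESC loci into
a single fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beta_matrix import BetaMatrix
from .locus_sets import LocusSet

logger = logging.getLogger(__name__)

__all__ = [
    "STATE_THRESHOLDS",
    "TRANSITIONS",
    "discretize",
    "find_stable",
    "transitions",
    "epi_indices",
    "indices_for_cohort",
    "combined_demi",
    "hypo_frequency",
]

STATE_THRESHOLDS = (0.25, 0.70)

#: index name -> (baseline state, set of qualifying tumour states)
TRANSITIONS = {
    "f_0_gain": (0, {1, 2}),   # 0 -> 1/2
    "f_1_gain": (1, {2}),      # 1 -> 2
    "f_1_loss": (1, {0}),      # 1 -> 0
    "f_2_loss": (2, {0, 1}),   # 2 -> 0/1, the DeMI
}


def discretize(beta, lower: float = STATE_THRESHOLDS[0], upper: float = STATE_THRESHOLDS[1]):
    """Map beta values to methylation states 0/1/2 (boundaries belong to state 1).

    Accepts scalars or arrays; NaN propagates as NaN.
    """
    b = np.asarray(beta, dtype=float)
    state = np.where(b < lower, 0.0, np.where(b <= upper, 1.0, 2.0))
    state = np.where(np.isnan(b), np.nan, state)
    return float(state) if state.ndim == 0 else state


def find_stable(bm_normals: BetaMatrix, min_normals: int = 2) -> pd.DataFrame:
    """Probes with one discretized state across all normal samples.

    Each probe is assessed on its non-missing normals; at least
    ``min_normals`` observations are required. Returns a DataFrame
    indexed by probe_id with columns stable_state, normal_mean_beta and
    n_normals.
    """
    if bm_normals.n_samples < min_normals:
        raise ValueError(
            f"stability needs >= {min_normals} normal samples, got {bm_normals.n_samples}"
        )
    vals = bm_normals.values.to_numpy(dtype=float)
    states = discretize(vals)
    n_obs = (~np.isnan(states)).sum(axis=1)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        smin = np.nanmin(states, axis=1)
        smax = np.nanmax(states, axis=1)
        mean_beta = np.nanmean(vals, axis=1)
    stable = (n_obs >= min_normals) & (smin == smax)
    out = pd.DataFrame(
        {
            "stable_state": smin,
            "normal_mean_beta": mean_beta,
            "n_normals": n_obs,
        },
        index=bm_normals.values.index,
    )[stable]
    out["stable_state"] = out["stable_state"].astype(int)
    logger.info("stable set: %d of %d probes", len(out), bm_normals.n_probes)
    return out


def transitions(sample_beta: pd.Series, stable: pd.DataFrame, buffer: float = 0.10) -> pd.Series:
    """Per-probe transition labels for one tumour sample.

    A stable probe transitions when (i) its tumour state differs from
    the stable normal state and (ii) the tumour beta differs from the
    normal mean beta by at least ``buffer``. Returns a Series over the
    stable probes with values among {'', '0->1/2', '1->2', '1->0',
    '2->0/1'}; probes with a missing tumour beta are absent (and must be
    removed from index denominators by the caller).
    """
    if not 0.0 <= buffer < 1.0:
        raise ValueError("buffer must be in [0, 1)")
    beta = sample_beta.reindex(stable.index)
    present = beta.notna()
    beta = beta[present]
    st = stable.loc[present.index[present]]
    tumour_state = discretize(beta.to_numpy())
    base_state = st["stable_state"].to_numpy()
    delta_ok = np.abs(beta.to_numpy() - st["normal_mean_beta"].to_numpy()) >= buffer
    changed = (tumour_state != base_state) & delta_ok
    labels = np.full(len(beta), "", dtype=object)
    labels[changed & (base_state == 0)] = "0->1/2"
    labels[changed & (base_state == 1) & (tumour_state == 2)] = "1->2"
    labels[changed & (base_state == 1) & (tumour_state == 0)] = "1->0"
    labels[changed & (base_state == 2)] = "2->0/1"
    return pd.Series(labels, index=beta.index)


@dataclass
class SampleIndices:
    """The four transition fractions for one tumour sample.

    Fractions are NaN (undefined) when the corresponding baseline-state
    denominator is zero; denominators count stable probes of that state
    with a non-missing tumour beta.
    """

    fractions: dict
    denominators: dict

    @property
    def demi(self) -> float:
        return self.fractions["f_2_loss"]


def epi_indices(
    sample_beta: pd.Series,
    stable: pd.DataFrame,
    locus_set: LocusSet | None = None,
    buffer: float = 0.10,
) -> SampleIndices:
    """Compute the four instability indices for one tumour sample.

    Optionally restricts the stable set to ``locus_set`` members first
    (giving e.g. the MESC DeMI). Each index is the number of qualifying
    transitions of its type divided by the number of stable probes in
    the corresponding baseline state that are non-missing in this
    sample; zero-denominator indices are NaN, never 0.
    """
    st = stable
    if locus_set is not None:
        st = st[st.index.isin(locus_set.members)]
        if st.empty:
            logger.warning("no stable probes in locus set %s", locus_set.name)
    lab = transitions(sample_beta, st, buffer=buffer)
    base = st.loc[lab.index, "stable_state"]
    fractions, denominators = {}, {}
    for name, (state, _) in TRANSITIONS.items():
        denom = int((base == state).sum())
        count = {"f_0_gain": "0->1/2", "f_1_gain": "1->2",
                 "f_1_loss": "1->0", "f_2_loss": "2->0/1"}[name]
        num = int((lab == count).sum())
        denominators[name] = denom
        fractions[name] = num / denom if denom else np.nan
    return SampleIndices(fractions, denominators)


def combined_demi(
    sample_beta: pd.Series,
    stable: pd.DataFrame,
    mesc: LocusSet,
    buffer: float = 0.10,
) -> float:
    """Pooled MESC demethylation fraction (micro-average of 1->0 and 2->0/1).

    Counts qualifying 1->0 plus 2->0/1 transitions at stable MESC loci
    and divides by the pooled number of stable MESC probes with baseline
    state 1 or 2 (non-missing in the sample). NaN when that pooled
    denominator is zero.
    """
    st = stable[stable.index.isin(mesc.members)]
    lab = transitions(sample_beta, st, buffer=buffer)
    base = st.loc[lab.index, "stable_state"]
    denom = int(base.isin([1, 2]).sum())
    if denom == 0:
        return np.nan
    num = int(lab.isin(["1->0", "2->0/1"]).sum())
    return num / denom


def indices_for_cohort(
    bm_tumours: BetaMatrix,
    stable: pd.DataFrame,
    pcgt: LocusSet | None = None,
    mesc: LocusSet | None = None,
    buffer: float = 0.10,
) -> pd.DataFrame:
    """Per-sample index table for a tumour cohort.

    Columns: the four genome-wide fractions and their denominators,
    ``demi`` (alias of f_2_loss), and when locus sets are given the
    stem-cell restricted indices pcgt_gain (PCGT 0->1/2), mesc_1_loss,
    mesc_demi (MESC 2->0/1) and combined_demi.
    """
    rows = {}
    for sid in bm_tumours.values.columns:
        beta = bm_tumours.values[sid]
        si = epi_indices(beta, stable, buffer=buffer)
        row = dict(si.fractions)
        row.update({f"n_{k}": v for k, v in si.denominators.items()})
        row["demi"] = si.fractions["f_2_loss"]
        if pcgt is not None:
            row["pcgt_gain"] = epi_indices(beta, stable, pcgt, buffer).fractions["f_0_gain"]
        if mesc is not None:
            mi = epi_indices(beta, stable, mesc, buffer)
            row["mesc_1_loss"] = mi.fractions["f_1_loss"]
            row["mesc_demi"] = mi.fractions["f_2_loss"]
            row["combined_demi"] = combined_demi(beta, stable, mesc, buffer)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def hypo_frequency(
    bm_tumours: BetaMatrix,
    stable: pd.DataFrame,
    mesc: LocusSet,
    buffer: float = 0.10,
) -> pd.Series:
    """Per-probe fraction of tumours with a qualifying demethylation transition.

    Considers stable MESC probes with baseline state 2; a tumour counts
    when the probe undergoes a 2->0/1 transition there. The result is
    sorted descending with ties broken by probe id, matching a
    deterministic ranking of the most frequently hypomethylated loci.
    """
    if bm_tumours.n_samples < 1:
        raise ValueError("need at least one tumour sample")
    st = stable[stable.index.isin(mesc.members) & (stable["stable_state"] == 2)]
    counts = pd.Series(0, index=st.index, dtype=float)
    denom = pd.Series(0, index=st.index, dtype=float)
    for sid in bm_tumours.values.columns:
        lab = transitions(bm_tumours.values[sid], st, buffer=buffer)
        denom.loc[lab.index] += 1
        counts.loc[lab.index[lab == "2->0/1"]] += 1
    with np.errstate(invalid="ignore"):
        freq = counts / denom.replace(0, np.nan)
    freq = freq.fillna(0.0)
    order = sorted(freq.index, key=lambda p: (-freq[p], str(p)))
    return freq.loc[order].rename("hypo_frequency")
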
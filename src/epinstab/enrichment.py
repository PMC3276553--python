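"""Fisher enrichment of locus classes among differentially methylated CpGs.

The basic question: among a selected CpG list (e.g. probes
hypomethylated in cancer), is a locus class (MESC, PCGT) over- or
under-represented relative to a reference universe (by default all
QC-passing probes on the array)? Answered with a two-tailed Fisher
exact test; the odds ratio is the sample cross-product ratio with a
Woolf log-OR normal-approximation 95% CI (Haldane-Anscombe 0.5
correction on zero cells).

Two baseline-aware variants control for the methylation level in
normal tissue: ``baseline_matched_enrichment`` restricts the universe
to probes that start unmethylated (hypermethylation direction) or
methylated (hypomethylation direction) in normals, and
``control_matched_enrichment`` compares the target class against
non-target probes whose normal-tissue mean beta lies in the same band,
so enrichment cannot be an artifact of baseline level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .beta_matrix import BetaMatrix
from .locus_sets import LocusSet

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "baseline_matched_enrichment",
    "control_matched_enrichment",
]


@dataclass
class EnrichmentResult:
    """A 2x2 enrichment table with OR, 95% CI and two-tailed Fisher p.

    Table layout: a = selected & in set, b = selected & not in set,
    c = not selected & in set, d = not selected & not in set.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float | None = None
    degenerate: bool = False
    haldane_corrected: bool = False
    name: str = ""

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def _enrichment_from_table(a: int, b: int, c: int, d: int, name: str = "") -> EnrichmentResult:
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if (a + b) == 0 or (a + c) == 0 or (c + d) == 0 or (b + d) == 0:
        # an empty margin: no selection, no target in the universe, no
        # unselected rest, or no non-target probes -> no contrast to test
        return EnrichmentResult(a, b, c, d, degenerate=True, name=name)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if b * c > 0:
        oratio = (a * d) / (b * c)
    else:
        oratio = np.inf if a * d > 0 else np.nan
    corrected = min(a, b, c, d) == 0
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = np.log((aa * dd) / (bb * cc))
    lo, hi = np.exp(log_or - 1.96 * se), np.exp(log_or + 1.96 * se)
    return EnrichmentResult(a, b, c, d, oratio, float(lo), float(hi), p,
                            degenerate=False, haldane_corrected=corrected, name=name)


def fisher_enrichment(selected, target: LocusSet, universe) -> EnrichmentResult:
    """Two-tailed Fisher enrichment of ``target`` membership in ``selected``.

    ``selected`` must be a subset of ``universe``; the target set is
    intersected with the universe before tabulation. Degenerate inputs
    (empty selection, or no target member in the universe) return a
    flagged result with no p-value.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected probes must be a subset of the universe")
    tgt = target.members & universe
    a = len(selected & tgt)
    b = len(selected - tgt)
    c = len(tgt - selected)
    d = len(universe) - a - b - c
    res = _enrichment_from_table(a, b, c, d, name=target.name)
    if res.degenerate:
        logger.warning("degenerate enrichment table for %s: (%d,%d,%d,%d)",
                       target.name, a, b, c, d)
    return res


def _normal_means(bm_normals: BetaMatrix) -> pd.Series:
    return bm_normals.values.mean(axis=1, skipna=True)


def baseline_matched_enrichment(
    bm_normals: BetaMatrix,
    case_means: pd.Series,
    target: LocusSet,
    direction: str,
    baseline_cut: float | None = None,
    significant: set | None = None,
) -> EnrichmentResult:
    """Enrichment among probes moving away from their normal-tissue baseline.

    direction='hyper': the universe is probes unmethylated in normals
    (mean beta < baseline_cut, default 0.2) and the selection is those
    whose case mean beta is strictly higher. direction='hypo': universe
    is probes methylated in normals (mean beta > cut, default 0.4),
    selection those whose case mean is strictly lower. When a
    significance list is supplied the selection is additionally
    intersected with it.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    nm = _normal_means(bm_normals)
    case_means = case_means.reindex(nm.index)
    if direction == "hyper":
        cut = 0.2 if baseline_cut is None else baseline_cut
        universe = nm.index[nm < cut]
        moved = case_means.loc[universe] > nm.loc[universe]
    else:
        cut = 0.4 if baseline_cut is None else baseline_cut
        universe = nm.index[nm > cut]
        moved = case_means.loc[universe] < nm.loc[universe]
    selected = set(universe[moved.fillna(False)])
    if significant is not None:
        selected &= set(significant)
    if len(universe) == 0:
        return EnrichmentResult(0, 0, 0, 0, degenerate=True, name=target.name)
    return fisher_enrichment(selected, target, set(universe))


def control_matched_enrichment(
    bm_normals: BetaMatrix,
    case_means: pd.Series,
    target: LocusSet,
    direction: str,
    baseline_band: tuple[float, float],
    significant: set | None = None,
) -> EnrichmentResult:
    """Enrichment against control probes with matched baseline methylation.

    The universe is target probes plus the non-target probes whose
    normal-tissue mean beta lies inside ``baseline_band`` (open
    interval), so any enrichment is independent of the starting
    methylation level. Target probes outside the band are also dropped,
    keeping target and controls on the same footing.
    """
    lo, hi = baseline_band
    if not lo < hi:
        raise ValueError("baseline_band must satisfy low < high")
    nm = _normal_means(bm_normals)
    in_band = (nm > lo) & (nm < hi)
    controls = nm.index[in_band & ~nm.index.isin(target.members)]
    targets = nm.index[in_band & nm.index.isin(target.members)]
    if len(controls) == 0:
        raise ValueError(
            f"no control probes with normal mean beta in ({lo}, {hi}); widen the band"
        )
    universe = targets.append(controls)
    case_means = case_means.reindex(universe)
    if direction == "hyper":
        moved = case_means > nm.loc[universe]
    elif direction == "hypo":
        moved = case_means < nm.loc[universe]
    else:
        raise ValueError("direction must be 'hyper' or 'hypo'")
    selected = set(universe[moved.fillna(False)])
    if significant is not None:
        selected &= set(significant)
    return fisher_enrichment(selected, LocusSet(target.name, set(targets)), set(universe))
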
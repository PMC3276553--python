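"""Stem-cell locus sets and probe-manifest annotation.

Two locus classes drive the analysis:

* **MESC** CpGs — sites heavily methylated in human embryonic stem cells,
  derived here from strand-resolved whole-genome bisulfite read counts
  (Lister-style tables): a site qualifies when it has sufficient read
  coverage and an overall mean methylation level above 80%.
* **PCGT** CpGs — Polycomb group target loci (SUZ12/EED occupancy or
  H3K27me3 in hESC), consumed as an annotation table.

Partially methylated domains (PMDs) are consumed as BED-style intervals
and intersected with probe coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WGBSSiteCounts",
    "LocusSet",
    "UndefinedMethylationLevel",
    "site_methylation_level",
    "derive_mesc",
    "read_wgbs_counts",
    "load_locus_table",
    "load_pmd_intervals",
    "read_manifest",
    "annotate_manifest",
]

WGBS_COLUMNS = ["chrom", "pos", "fwd_c", "fwd_t", "rev_c", "rev_t"]


class UndefinedMethylationLevel(ValueError):
    """Raised when a CpG site has zero read coverage on both strands."""


@dataclass(frozen=True)
class WGBSSiteCounts:
    """Strand-resolved bisulfite read counts at a single CpG site."""

    chrom: str
    pos: int
    fwd_c: int
    fwd_t: int
    rev_c: int
    rev_t: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based (got {self.pos})")
        for name in ("fwd_c", "fwd_t", "rev_c", "rev_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative read count {name}={getattr(self, name)}")

    @property
    def total_reads(self) -> int:
        return self.fwd_c + self.fwd_t + self.rev_c + self.rev_t


@dataclass
class LocusSet:
    """A named set of probe/CpG identifiers with provenance."""

    name: str
    members: set = field(default_factory=set)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, probe_id) -> bool:
        return probe_id in self.members


def site_methylation_level(counts: WGBSSiteCounts) -> tuple[float, float, float]:
    """Per-strand and overall methylation level of one CpG site.

    The level of a strand is C/(C+T) over the reads covering it; the
    overall level is the mean of the two strand levels, or the covered
    strand's level when only one strand has reads.

    Returns
    -------
    (fwd_level, rev_level, overall) — strand levels are NaN when that
    strand has no coverage.

    Raises
    ------
    UndefinedMethylationLevel
        If both strands have zero coverage.
    """
    fwd_n = counts.fwd_c + counts.fwd_t
    rev_n = counts.rev_c + counts.rev_t
    if fwd_n == 0 and rev_n == 0:
        raise UndefinedMethylationLevel(
            f"no reads at {counts.chrom}:{counts.pos} on either strand"
        )
    fwd = counts.fwd_c / fwd_n if fwd_n else np.nan
    rev = counts.rev_c / rev_n if rev_n else np.nan
    defined = [x for x in (fwd, rev) if not np.isnan(x)]
    return fwd, rev, float(np.mean(defined))


def derive_mesc(
    sites,
    coverage_min: int = 5,
    level_min: float = 0.8,
    per_strand_coverage: bool = False,
    name: str = "MESC",
) -> LocusSet:
    """Select CpG sites methylated in embryonic stem cells.

    A site is included when it passes the coverage rule and its overall
    mean methylation level is strictly greater than ``level_min``.

    Parameters
    ----------
    sites
        Iterable of :class:`WGBSSiteCounts`.
    coverage_min
        Minimum read count. By default the rule is applied to the total
        C+T reads summed over both strands; with
        ``per_strand_coverage=True`` each strand must individually reach
        ``coverage_min``.
    level_min
        Overall mean methylation level must exceed this (strict).

    Members are keyed as ``"chrom:pos"``.
    """
    if coverage_min < 1:
        raise ValueError("coverage_min must be >= 1")
    if not 0.0 < level_min < 1.0:
        raise ValueError("level_min must be in (0, 1)")
    members: set = set()
    n_seen = 0
    for site in sites:
        n_seen += 1
        if per_strand_coverage:
            ok = (
                site.fwd_c + site.fwd_t >= coverage_min
                and site.rev_c + site.rev_t >= coverage_min
            )
        else:
            ok = site.total_reads >= coverage_min
        if not ok:
            continue
        _, _, overall = site_methylation_level(site)
        if overall > level_min:
            members.add(f"{site.chrom}:{site.pos}")
    if n_seen == 0:
        warnings.warn("derive_mesc called on an empty site collection", stacklevel=2)
    prov = (
        f"derived from {n_seen} WGBS sites; coverage_min={coverage_min} "
        f"({'per-strand' if per_strand_coverage else 'total'}), level_min={level_min}"
    )
    return LocusSet(name=name, members=members, provenance=prov)


def read_wgbs_counts(path) -> list[WGBSSiteCounts]:
    """Read a tab-delimited strand-resolved CpG count table.

    Expected header: chrom, pos, fwd_c, fwd_t, rev_c, rev_t.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WGBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"WGBS count table {path} is missing columns: {missing}")
    return [
        WGBSSiteCounts(str(r.chrom), int(r.pos), int(r.fwd_c), int(r.fwd_t),
                       int(r.rev_c), int(r.rev_t))
        for r in df.itertuples(index=False)
    ]


def load_locus_table(path, id_column: str = "IlluminaID", name: str | None = None) -> LocusSet:
    """Load a locus-membership table (IlluminaID, geneID, symbol, MapInfo, chromosome).

    Duplicate probe ids collapse to one member; the number of duplicate
    rows is logged.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    if id_column not in df.columns:
        raise ValueError(
            f"locus table {path} has no column {id_column!r}; found {list(df.columns)}"
        )
    ids = df[id_column].astype(str)
    members = set(ids)
    n_dup = len(ids) - len(members)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate probe id rows", path, n_dup)
    return LocusSet(name=name or str(path), members=members, provenance=f"loaded from {path}")


def load_pmd_intervals(path) -> pd.DataFrame:
    """Read BED-style (chrom, start, end) PMD intervals; 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest CSV (probe_id, gene, chromosome, position).

    Returns a DataFrame indexed by probe_id with locus-class flag columns
    initialised to False.
    """
    df = pd.read_csv(path)
    required = {"probe_id", "gene", "chromosome", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise ValueError("manifest probe_id values are not unique")
    df = df.set_index("probe_id")
    df["chromosome"] = df["chromosome"].astype(str)
    for flag in ("is_pcgt", "is_mesc", "is_pmd"):
        if flag not in df.columns:
            df[flag] = False
    return df


def annotate_manifest(
    manifest: pd.DataFrame,
    pcgt: LocusSet | None = None,
    mesc: LocusSet | None = None,
    pmd: pd.DataFrame | LocusSet | None = None,
) -> pd.DataFrame:
    """Flag manifest probes by locus class.

    PCGT and MESC sets match on probe id. PMD membership may be given
    either as a probe-id set or as a BED-interval DataFrame, in which
    case a probe is inside a PMD when its coordinate lies within a
    half-open [start, end) interval on the same chromosome.

    Idempotent: flags are recomputed, not accumulated.
    """
    out = manifest.copy()
    for set_, flag in ((pcgt, "is_pcgt"), (mesc, "is_mesc")):
        if set_ is None:
            continue
        hit = out.index.isin(set_.members)
        if not hit.any():
            warnings.warn(
                f"{set_.name}: no members match the manifest probe ids "
                "(possible id-space mismatch)",
                stacklevel=2,
            )
        out[flag] = hit
        logger.info("%s: %d/%d manifest probes flagged", flag, int(hit.sum()), len(out))
    if pmd is not None:
        if isinstance(pmd, LocusSet):
            hit = out.index.isin(pmd.members)
        else:
            hit = _in_intervals(out["chromosome"].to_numpy(),
                                out["position"].to_numpy(), pmd)
        if not hit.any():
            warnings.warn("PMD annotation overlaps no manifest probe", stacklevel=2)
        out["is_pmd"] = hit
        logger.info("is_pmd: %d/%d manifest probes flagged", int(hit.sum()), len(out))
    return out


def _in_intervals(chroms: np.ndarray, positions: np.ndarray, bed: pd.DataFrame) -> np.ndarray:
    """Half-open [start, end) interval membership for 1-based probe positions."""
    hit = np.zeros(len(chroms), dtype=bool)
    for chrom, sub in bed.groupby("chrom"):
        mask = chroms == chrom
        if not mask.any():
            continue
        # convert the 1-based probe coordinate to 0-based before the BED test
        pos0 = positions[mask] - 1
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        inside = ((pos0[:, None] >= starts[None, :]) & (pos0[:, None] < ends[None, :])).any(axis=1)
        hit[np.flatnonzero(mask)] = inside
    return hit
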
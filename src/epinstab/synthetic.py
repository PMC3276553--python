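"""Synthetic Infinium-27k-style data with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a probe manifest with PCGT, MESC and PMD locus classes, where PCGT
  probes carry low baseline methylation (typically unmethylated in
  normal tissue) and MESC probes high baseline methylation;
* per-cohort beta matrices in which case samples gain methylation at
  PCGT loci and lose it at MESC loci with stage-dependent
  probabilities that increase from "before dysplasia" through
  dysplasia and invasive cancer to metastasis;
* per-sample heterogeneity in the demethylation propensity, which
  makes the demethylation instability index (DeMI) vary across
  tumours and ties it to simulated survival and TET expression;
* chip batch effects on the logit-beta scale;
* exponential survival with log-hazard linear in standardized DeMI;
* strand-resolved bisulfite read counts with known true methylation
  levels.

Every planted change moves beta across a discretization threshold by
more than the transition-calling buffer, so the emitted truth table is
exactly recoverable by the instability module when noise is small.
All outputs are deterministic functions of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beta_matrix import BetaMatrix
from .locus_sets import LocusSet, WGBSSiteCounts

__all__ = [
    "STAGES",
    "SimConfig",
    "SimulatedCohort",
    "simulate_manifest",
    "simulate_cohort",
    "simulate_survival",
    "simulate_wgbs_counts",
    "simulate_tet",
]

STAGES = ("bdy", "dysplasia", "cancer", "metastasis")


def _check_probs(name, d):
    for k, v in d.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}[{k}] = {v} is not a probability")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Stage sample counts default to the cohort sizes of the cervical
    carcinogenesis design (152 cytologically normal samples of which 75
    later progress; 30 normals vs 18 dysplasias; 15 normal tissues vs
    48 invasive cancers) plus a metastasis arm. The MESC loss
    probability rises monotonically across stages
    (0.05/0.10/0.20/0.35), mirroring progressive hypomethylation, while
    the PCGT gain probability jumps before dysplasia and then stays
    roughly constant.
    """

    seed: int
    n_probes: int = 2000
    frac_pcgt: float = 0.15
    frac_mesc: float = 0.25
    frac_pmd: float = 0.20
    stage_samples: dict = field(default_factory=lambda: {
        "bdy": (77, 75), "dysplasia": (30, 18), "cancer": (15, 48), "metastasis": (15, 17),
    })
    mesc_loss_prob: dict = field(default_factory=lambda: {
        "bdy": 0.05, "dysplasia": 0.10, "cancer": 0.20, "metastasis": 0.35,
    })
    pcgt_gain_prob: dict = field(default_factory=lambda: {
        "bdy": 0.08, "dysplasia": 0.12, "cancer": 0.12, "metastasis": 0.12,
    })
    concentration: float = 100.0          # Beta-noise concentration around each probe mean
    sample_heterogeneity: float = 50.0    # per-sample effect-prob Beta concentration
    probe_susceptibility: float | None = 0.6   # per-probe weight spread; None = homogeneous
    samples_per_chip: int = 12
    chip_shift_sd: float = 0.05           # logit-scale per-chip shift
    confound_chips: bool = False          # assign cases and controls to separate chips
    baseline_hazard: float = 0.1
    hr_per_sd: float = 1.8
    censoring_ratio: float = 0.5          # censoring rate relative to baseline hazard
    tet_slope: float = 5.0
    tet_noise_sd: float = 1.0
    n_wgbs_sites: int = 500
    wgbs_mean_coverage: float = 20.0
    buffer: float = 0.10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for f in (self.frac_pcgt, self.frac_mesc, self.frac_pmd):
            if not 0.0 <= f <= 1.0:
                raise ValueError("locus-class fractions must be in [0, 1]")
        if self.frac_pcgt + self.frac_mesc > 1.0:
            raise ValueError("frac_pcgt + frac_mesc exceeds 1 (classes are disjoint)")
        _check_probs("mesc_loss_prob", self.mesc_loss_prob)
        _check_probs("pcgt_gain_prob", self.pcgt_gain_prob)
        losses = [self.mesc_loss_prob[s] for s in STAGES if s in self.mesc_loss_prob]
        if any(b < a for a, b in zip(losses, losses[1:])):
            raise ValueError("mesc_loss_prob must be non-decreasing across stages")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def simulate_manifest(cfg: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Probe manifest with locus-class flags and per-probe baseline betas.

    Returns ``(manifest, locus_sets)`` where locus_sets maps 'pcgt',
    'mesc', 'pmd' to :class:`LocusSet`. The extra ``baseline_beta``
    column is the generator's per-probe normal-tissue mean: low
    (0.04-0.12) for PCGT probes, high (0.80-0.92) for MESC probes, and
    a low/mid/high mixture elsewhere.
    """
    rng = _rng(cfg, 0)
    n = cfg.n_probes
    probe_ids = np.array([f"cg{i:07d}" for i in range(n)])
    n_pcgt = int(round(cfg.frac_pcgt * n))
    n_mesc = int(round(cfg.frac_mesc * n))
    perm = rng.permutation(n)
    pcgt_idx = perm[:n_pcgt]
    mesc_idx = perm[n_pcgt:n_pcgt + n_mesc]
    is_pcgt = np.zeros(n, bool); is_pcgt[pcgt_idx] = True
    is_mesc = np.zeros(n, bool); is_mesc[mesc_idx] = True
    is_pmd = rng.random(n) < cfg.frac_pmd

    baseline = np.empty(n)
    baseline[is_pcgt] = rng.uniform(0.04, 0.12, is_pcgt.sum())
    baseline[is_mesc] = rng.uniform(0.80, 0.92, is_mesc.sum())
    rest = ~(is_pcgt | is_mesc)
    kind = rng.choice(3, rest.sum(), p=[0.40, 0.25, 0.35])
    rb = np.empty(rest.sum())
    rb[kind == 0] = rng.uniform(0.04, 0.18, (kind == 0).sum())
    rb[kind == 1] = rng.uniform(0.35, 0.60, (kind == 1).sum())
    rb[kind == 2] = rng.uniform(0.78, 0.92, (kind == 2).sum())
    baseline[rest] = rb

    # per-probe susceptibility weights: some loci are altered in most
    # tumours, others rarely. Weights are renormalised to mean exactly 1
    # within each locus class so the planted per-sample alteration rate
    # stays the nominal stage probability.
    if cfg.probe_susceptibility is not None:
        a = cfg.probe_susceptibility
        suscept = 2.0 * rng.beta(a, a, n)
        for cls in (is_mesc, is_pcgt):
            if cls.any() and suscept[cls].mean() > 0:
                suscept[cls] /= suscept[cls].mean()
    else:
        suscept = np.ones(n)

    manifest = pd.DataFrame({
        "gene": [f"GENE{i // 2}" for i in range(n)],
        "chromosome": [str(1 + i % 22) for i in range(n)],
        "position": 1000 + 500 * np.arange(n),
        "is_pcgt": is_pcgt,
        "is_mesc": is_mesc,
        "is_pmd": is_pmd,
        "baseline_beta": baseline,
        "susceptibility": suscept,
    }, index=pd.Index(probe_ids, name="probe_id"))
    sets = {
        "pcgt": LocusSet("PCGT", set(probe_ids[is_pcgt]), "simulated"),
        "mesc": LocusSet("MESC", set(probe_ids[is_mesc]), "simulated"),
        "pmd": LocusSet("PMD", set(probe_ids[is_pmd]), "simulated"),
    }
    return manifest, sets


@dataclass
class SimulatedCohort:
    """One simulated stage: beta matrix, truth table and planted burdens."""

    bm: BetaMatrix
    truth: pd.DataFrame              # sample_id, probe_id, transition
    case_loss_prob: pd.Series        # per-case planted MESC loss probability
    case_burden: pd.Series           # realised fraction of MESC probes demethylated
    stage: str


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(cfg: SimConfig, stage: str, manifest: pd.DataFrame | None = None) -> SimulatedCohort:
    """Simulate normals plus cases for one carcinogenesis stage.

    Normal betas are Beta-distributed around each probe's baseline with
    concentration ``cfg.concentration``. Each case draws a personal
    effect probability from a Beta distribution centred on the stage's
    gain/loss probability (concentration ``cfg.sample_heterogeneity``),
    then flips each susceptible probe independently: MESC probes drop
    to a low beta (full demethylation), PCGT probes rise into the hemi-
    or fully-methylated range. Chip shifts are added on the logit
    scale. The truth table records every planted flip.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    if manifest is None:
        manifest, _ = simulate_manifest(cfg)
    n_norm, n_case = cfg.stage_samples[stage]
    if n_norm + n_case == 0:
        raise ValueError("zero samples requested")
    rng = _rng(cfg, 1 + STAGES.index(stage))
    n = len(manifest)
    baseline = manifest["baseline_beta"].to_numpy()
    is_mesc = manifest["is_mesc"].to_numpy()
    is_pcgt = manifest["is_pcgt"].to_numpy()
    s = cfg.concentration

    normal_group = "bdy_control" if stage == "bdy" else "normal"
    case_group = "bdy_case" if stage == "bdy" else stage
    sample_ids = [f"{stage}_N{i:03d}" for i in range(n_norm)] + \
                 [f"{stage}_C{i:03d}" for i in range(n_case)]

    # per-sample target means; cases start from the shared baselines
    means = np.tile(baseline, (n_norm + n_case, 1))

    q_loss = cfg.mesc_loss_prob[stage]
    q_gain = cfg.pcgt_gain_prob[stage]
    kappa = cfg.sample_heterogeneity
    suscept = manifest["susceptibility"].to_numpy() if "susceptibility" in manifest else np.ones(n)
    loss_probs = np.zeros(n_case)
    truth_rows = []
    burdens = np.zeros(n_case)
    for ci in range(n_case):
        row = n_norm + ci
        qi = rng.beta(q_loss * kappa, (1 - q_loss) * kappa) if 0 < q_loss < 1 else q_loss
        gi = rng.beta(q_gain * kappa, (1 - q_gain) * kappa) if 0 < q_gain < 1 else q_gain
        loss_probs[ci] = qi
        sid = sample_ids[row]
        lose = is_mesc & (rng.random(n) < np.clip(qi * suscept, 0.0, 1.0))
        means[row, lose] = rng.uniform(0.03, 0.14, lose.sum())
        gain = is_pcgt & (rng.random(n) < np.clip(gi * suscept, 0.0, 1.0))
        means[row, gain] = rng.uniform(0.45, 0.85, gain.sum())
        burdens[ci] = lose.sum() / max(int(is_mesc.sum()), 1)
        for p in manifest.index[lose]:
            truth_rows.append((sid, p, "2->0/1"))
        for p in manifest.index[gain]:
            truth_rows.append((sid, p, "0->1/2"))

    # Beta noise around each target mean
    a = means * s
    b = (1 - means) * s
    beta = rng.beta(a, b)

    # chip assignment and logit-scale batch shifts
    n_samples = n_norm + n_case
    if cfg.confound_chips:
        order = np.arange(n_samples)          # normals fill the first chips
    else:
        order = rng.permutation(n_samples)
    chip_of = np.empty(n_samples, dtype=int)
    chip_of[order] = np.arange(n_samples) // cfg.samples_per_chip
    n_chips = chip_of.max() + 1
    shifts = rng.normal(0.0, cfg.chip_shift_sd, n_chips)
    if cfg.chip_shift_sd > 0:
        eps = 1e-6
        clipped = np.clip(beta, eps, 1 - eps)
        beta = _expit(_logit(clipped) + shifts[chip_of][:, None])

    values = pd.DataFrame(beta.T, index=manifest.index, columns=sample_ids)
    ages = rng.uniform(25, 70, n_samples).round(1)
    samples = pd.DataFrame({
        "group": [normal_group] * n_norm + [case_group] * n_case,
        "age": ages,
        "chip": [f"chip{c:02d}" for c in chip_of],
        "bs_intensity": rng.normal(6000, 500, n_samples).round(0),
    }, index=pd.Index(sample_ids, name="sample_id"))
    bm = BetaMatrix(values, samples)
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "probe_id", "transition"])
    case_ids = sample_ids[n_norm:]
    return SimulatedCohort(
        bm=bm,
        truth=truth,
        case_loss_prob=pd.Series(loss_probs, index=case_ids, name="loss_prob"),
        case_burden=pd.Series(burdens, index=case_ids, name="burden"),
        stage=stage,
    )


def simulate_survival(cfg: SimConfig, demi: pd.Series, stream: int = 17) -> pd.DataFrame:
    """Exponential survival with log-hazard linear in standardized DeMI.

    hazard_i = baseline_hazard * hr_per_sd ** z_i where z is the
    standardized index; censoring is independent exponential with rate
    ``baseline_hazard * censoring_ratio``. Returns a DataFrame with
    time and event (1 = death observed) indexed like ``demi``.
    """
    if cfg.baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    rng = _rng(cfg, stream)
    x = demi.to_numpy(dtype=float)
    sd = x.std(ddof=1)
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    lam = cfg.baseline_hazard * np.power(cfg.hr_per_sd, z)
    t_event = rng.exponential(1.0 / lam)
    if cfg.censoring_ratio > 0:
        t_cens = rng.exponential(1.0 / (cfg.baseline_hazard * cfg.censoring_ratio),
                                 size=len(x))
    else:
        t_cens = np.full(len(x), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=demi.index)


def simulate_wgbs_counts(cfg: SimConfig) -> tuple[list[WGBSSiteCounts], pd.DataFrame]:
    """Strand-resolved CpG read counts with known true methylation levels.

    True levels follow a bimodal Beta mixture (half heavily methylated,
    half lowly methylated); per-strand coverage is Poisson with mean
    half of ``wgbs_mean_coverage``; methylated-read counts are binomial
    at the true level. Returns the site list plus a truth table.
    """
    if cfg.wgbs_mean_coverage <= 0:
        raise ValueError("wgbs_mean_coverage must be positive")
    rng = _rng(cfg, 23)
    n = cfg.n_wgbs_sites
    high = rng.random(n) < 0.5
    level = np.where(high, rng.beta(20, 2, n), rng.beta(2, 20, n))
    sites = []
    rows = []
    for i in range(n):
        fwd_n = rng.poisson(cfg.wgbs_mean_coverage / 2)
        rev_n = rng.poisson(cfg.wgbs_mean_coverage / 2)
        fwd_c = rng.binomial(fwd_n, level[i]) if fwd_n else 0
        rev_c = rng.binomial(rev_n, level[i]) if rev_n else 0
        pos = 100 + 50 * i
        sites.append(WGBSSiteCounts("chr1", pos, fwd_c, fwd_n - fwd_c, rev_c, rev_n - rev_c))
        rows.append(("chr1", pos, level[i]))
    truth = pd.DataFrame(rows, columns=["chrom", "pos", "true_level"])
    return sites, truth


def simulate_tet(cfg: SimConfig, burden: pd.Series, stream: int = 29) -> pd.Series:
    """TET expression linked to each sample's demethylation burden.

    expression = tet_slope * burden + Gaussian noise, so beta values at
    planted-demethylation loci anti-correlate with expression across
    samples.
    """
    if not np.isfinite(cfg.tet_slope):
        raise ValueError("tet_slope must be finite")
    rng = _rng(cfg, stream)
    expr = cfg.tet_slope * burden.to_numpy(dtype=float) + \
        rng.normal(0.0, cfg.tet_noise_sd, len(burden))
    return pd.Series(expr, index=burden.index, name="tet_expression")
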
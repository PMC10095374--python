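"""Synthetic paired GWAS summary statistics with known ground truth.

The generator emulates the study design this package analyses: a very large
linear-model GWAS of a binary drug-use exposure (UK-Biobank scale, n ~ 463k,
case fraction ~2.5%) paired with a smaller case-control outcome GWAS
(n ~ 58k, case fraction ~25%) on the log-odds scale.  For SNP j with minor
allele frequency f_j:

* true exposure effect  beta_X,j = g_j * sqrt(h2 * var_x / (2 f_j (1-f_j))),
  g_j ~ N(0,1), so the mean per-SNP variance explained is ``exposure_h2_per_snp``;
* exposure SE          se_X,j = sqrt(var_x) / sqrt(2 f_j (1-f_j) n_exp)
  (linear model on a 0/1 trait with variance var_x = mu_x(1-mu_x));
* pleiotropy           alpha_j per the scenario law (none / balanced /
  directional / correlated, the last tying alpha to beta_X and thereby
  violating the InSIDE assumption);
* true outcome effect  beta_Y,j = theta * beta_X,j + alpha_j, with logistic
  SE se_Y,j = 1 / sqrt(2 f_j (1-f_j) n_out mu_y (1-mu_y));
* observed betas are drawn from N(true, SE); p-values are two-sided normal.

Planted outliers receive an additional gross pleiotropic shift of
``outlier_scale`` outcome-SEs, so their residuals dwarf the others'.
A configurable fraction of SNPs get palindromic (A/T or C/G) allele pairs,
and the outcome record's allele orientation/strand is randomly scrambled, so
harmonization has real work to do on every synthetic dataset.

Randomness uses one root seed with per-SNP counter substreams: adding or
reordering SNPs never perturbs the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InfeasibleScenarioError
from .harmonize import COMPLEMENT
from .sumstats_io import GwasRecord

__all__ = [
    "PleiotropyLaw",
    "SimScenario",
    "SimTruth",
    "simulate_pair",
    "simulate_significant_instruments",
]

GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class PleiotropyLaw:
    """Per-SNP direct (horizontal) effect law.

    ``none``: alpha = 0.  ``balanced``: alpha ~ N(0, sd) (InSIDE holds, IVW
    remains consistent).  ``directional``: alpha ~ N(mean, sd) oriented to
    the exposure-increasing allele (biases IVW, detectable by the Egger
    intercept).  ``correlated``: alpha = strength*beta_X + N(0, sd)
    (violates InSIDE; even Egger is biased).
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    strength: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "balanced", "directional", "correlated"):
            raise ValueError(f"unknown pleiotropy law {self.kind!r}")

    @classmethod
    def none(cls) -> "PleiotropyLaw":
        return cls("none")

    @classmethod
    def balanced(cls, sd: float) -> "PleiotropyLaw":
        return cls("balanced", sd=sd)

    @classmethod
    def directional(cls, mean: float, sd: float) -> "PleiotropyLaw":
        return cls("directional", mean=mean, sd=sd)

    @classmethod
    def correlated(cls, strength: float, sd: float = 0.0) -> "PleiotropyLaw":
        return cls("correlated", strength=strength, sd=sd)


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one synthetic two-sample dataset.

    Defaults mirror the metformin/RA study design: 32 instruments, exposure
    GWAS of 462,933 (11,552 cases), outcome GWAS of 58,284 (14,361 cases),
    mean per-SNP exposure variance explained 1.4e-4 (per-SNP F ~ 64 at the
    exposure sample size), and a strongly protective causal effect
    theta = -3.76 log-odds per unit of exposure.
    """

    j_snps: int = 32
    n_exp: int = 462_933
    n_out: int = 58_284
    theta: float = -3.76
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2_per_snp: float = 1.4e-4
    pleiotropy: PleiotropyLaw = field(default_factory=PleiotropyLaw.none)
    n_outliers: int = 0
    outlier_scale: float = 10.0
    case_frac_exp: float = 11_552 / 462_933
    case_frac_out: float = 14_361 / 58_284
    palindromic_frac: float = 0.2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0 < lo < hi <= 0.5, got {self.maf_range}")
        if self.j_snps < 0:
            raise ConfigurationError("j_snps must be >= 0")
        if not math.isfinite(self.theta):
            raise ConfigurationError("theta must be finite")
        if not (0 <= self.palindromic_frac <= 1):
            raise ConfigurationError("palindromic_frac must lie in [0, 1]")
        if self.n_outliers > self.j_snps:
            raise ConfigurationError("n_outliers cannot exceed j_snps")


@dataclass
class SimTruth:
    """Ground truth accompanying one synthetic dataset."""

    theta: float
    beta_x_true: dict
    alpha: dict
    outlier_ids: list

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "beta_x_true": self.beta_x_true,
            "alpha": self.alpha,
            "outlier_ids": self.outlier_ids,
        }


_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                         ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _two_sided_p(beta: float, se: float) -> float:
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return max(p, 5e-324)  # keep within (0, 1]


def _draw_snp(sc: SimScenario, index: int, seed: int):
    """One SNP's true parameters, observed records and bookkeeping.

    ``index`` keys the substream, so draws are independent of how many other
    SNPs exist and of their order.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))
    lo, hi = sc.maf_range
    maf = float(rng.uniform(lo, hi))
    var_x = sc.case_frac_exp * (1 - sc.case_frac_exp)
    var_geno = 2 * maf * (1 - maf)
    beta_x = float(rng.standard_normal() * math.sqrt(sc.exposure_h2_per_snp * var_x / var_geno))
    se_x = math.sqrt(var_x) / math.sqrt(var_geno * sc.n_exp)
    se_y = 1.0 / math.sqrt(var_geno * sc.n_out * sc.case_frac_out * (1 - sc.case_frac_out))

    law = sc.pleiotropy
    if law.kind == "none":
        alpha = 0.0
    elif law.kind == "balanced":
        alpha = float(rng.normal(0.0, law.sd))
    elif law.kind == "directional":
        # directional with respect to the exposure-increasing allele, so the
        # mean survives the orientation step of Egger regression
        alpha = float(rng.normal(law.mean, law.sd)) * (1.0 if beta_x >= 0 else -1.0)
    else:  # correlated: tied to instrument strength, violating InSIDE
        alpha = float(law.strength * beta_x + (rng.normal(0.0, law.sd) if law.sd > 0 else 0.0))

    # alleles: exposure orientation, with a palindromic fraction
    if rng.uniform() < sc.palindromic_frac:
        ea, oa = _PALINDROMIC_PAIRS[int(rng.integers(len(_PALINDROMIC_PAIRS)))]
    else:
        ea, oa = _NONPALINDROMIC_PAIRS[int(rng.integers(len(_NONPALINDROMIC_PAIRS)))]

    return {
        "rng": rng, "maf": maf, "beta_x": beta_x, "se_x": se_x, "se_y": se_y,
        "alpha": alpha, "ea": ea, "oa": oa,
    }


def _emit_records(sc: SimScenario, draws: list[dict], outlier_idx: set[int]):
    exp_records, out_records = [], []
    truth_bx, truth_alpha, outlier_ids = {}, {}, []
    for k, d in enumerate(draws):
        rng = d["rng"]
        snp_id = f"sim{k:05d}"
        alpha = d["alpha"]
        if k in outlier_idx:
            alpha += sc.outlier_scale * d["se_y"] * (1.0 if rng.uniform() < 0.5 else -1.0)
            outlier_ids.append(snp_id)
        beta_y = sc.theta * d["beta_x"] + alpha
        obs_bx = float(rng.normal(d["beta_x"], d["se_x"]))
        obs_by = float(rng.normal(beta_y, d["se_y"]))
        eaf_out = float(np.clip(d["maf"] + rng.normal(0.0, 0.005), 0.001, 0.999))

        exp_records.append(
            GwasRecord(
                snp_id=snp_id, chrom=str(1 + k % 22), effect_allele=d["ea"], other_allele=d["oa"],
                beta=obs_bx, se=d["se_x"], pvalue=_two_sided_p(obs_bx, d["se_x"]),
                eaf=d["maf"], n=sc.n_exp, pos=1_000_000 + 10_000_000 * (k // 22),
            )
        )
        # outcome record in a random orientation: possibly allele-swapped
        # and/or reported on the opposite strand
        ea, oa, b, eaf = d["ea"], d["oa"], obs_by, eaf_out
        if rng.uniform() < 0.3:
            ea, oa, b, eaf = oa, ea, -b, 1.0 - eaf
        if rng.uniform() < 0.2:
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        out_records.append(
            GwasRecord(
                snp_id=snp_id, chrom=str(1 + k % 22), effect_allele=ea, other_allele=oa,
                beta=b, se=d["se_y"], pvalue=_two_sided_p(b, d["se_y"]),
                eaf=eaf, n=sc.n_out, pos=1_000_000 + 10_000_000 * (k // 22),
            )
        )
        truth_bx[snp_id] = d["beta_x"]
        truth_alpha[snp_id] = alpha
    truth = SimTruth(theta=sc.theta, beta_x_true=truth_bx, alpha=truth_alpha, outlier_ids=outlier_ids)
    return exp_records, out_records, truth


def simulate_pair(sc: SimScenario):
    """Generate one paired exposure/outcome dataset.

    Returns ``(exposure_records, outcome_records, truth)``.  No selection is
    applied: weak and strong SNPs alike are emitted.
    """
    draws = [_draw_snp(sc, k, sc.seed) for k in range(sc.j_snps)]
    outlier_idx = set(range(sc.n_outliers))  # first SNPs by construction; ids recorded in truth
    return _emit_records(sc, draws, outlier_idx)


def simulate_significant_instruments(sc: SimScenario):
    """Generate instruments that pass genome-wide significance by design.

    Candidate SNPs are rejection-sampled until ``j_snps`` have a *true*
    exposure association exceeding the genome-wide threshold (two-sided
    p < 5e-8 on the true effect), emulating the instrument-selection step
    without winner's curse: acceptance looks only at true effects, so the
    observed betas of accepted SNPs remain unbiased.  Returns the same
    triple as :func:`simulate_pair`.
    """
    if sc.j_snps == 0:
        return [], [], SimTruth(theta=sc.theta, beta_x_true={}, alpha={}, outlier_ids=[])
    z_thr = float(stats.norm.isf(GENOME_WIDE_P / 2.0))
    # acceptance probability: z_true = g * sqrt(h2 * n_exp), g ~ N(0,1)
    z_scale = math.sqrt(sc.exposure_h2_per_snp * sc.n_exp)
    p_accept = float(2 * stats.norm.sf(z_thr / z_scale))
    if p_accept < 1e-6:
        raise InfeasibleScenarioError(
            f"expected significance probability {p_accept:.2e} < 1e-6; "
            "increase n_exp or exposure_h2_per_snp"
        )
    draws = []
    index = 0
    max_candidates = int(max(1000, 50 * sc.j_snps / p_accept))
    while len(draws) < sc.j_snps:
        if index >= max_candidates:
            raise InfeasibleScenarioError(
                f"only {len(draws)}/{sc.j_snps} significant SNPs after {index} candidates"
            )
        d = _draw_snp(sc, index, sc.seed)
        index += 1
        if abs(d["beta_x"]) / d["se_x"] > z_thr:
            draws.append(d)
    outlier_idx = set(range(sc.n_outliers))
    return _emit_records(sc, draws, outlier_idx)
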
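"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a harmonized instrument set and return the causal
effect of the exposure on the outcome on the log-odds scale, with the odds
ratio and Wald 95% CI derived by exponentiation (never by averaging ORs).

Per-SNP building block is the Wald ratio  r_j = beta_out_j / beta_exp_j with
first-order delta-method standard error  se_j = se_out_j / |beta_exp_j|
(ignoring exposure-side noise; a second-order option adds the
beta_out² se_exp² / beta_exp⁴ term).  On top of the ratios:

``ivw``             inverse-variance-weighted mean, weights 1/se_j²; the
                    multiplicative random-effects variant scales the SE by
                    max(1, sqrt(Q/(J-1))).
``egger``           weighted regression of outcome betas on exposure betas
                    *with* an intercept; the slope is the causal estimate and
                    the intercept the average directional pleiotropy.
``weighted_median`` interpolated 50th weighted percentile of the ordered
                    ratios; consistent when >=50% of the weight is valid.
``mode_estimate``   kernel-density argmax of the ratios (simple = unweighted,
                    weighted = inverse-variance weights); consistent when the
                    largest group of SNPs shares the true effect (ZEMPA).

Median and mode standard errors come from a seeded parametric bootstrap
resampling both betas from their reported normal sampling distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInstrumentError, InsufficientInstrumentsError
from .sumstats_io import HarmonizedInstrument, InstrumentSet

__all__ = [
    "Z_CI",
    "RatioEstimate",
    "MrResult",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "to_or",
]

#: normal 97.5th percentile used for all Wald confidence intervals
Z_CI = 1.959964


@dataclass(frozen=True)
class RatioEstimate:
    """One SNP's Wald ratio with its delta-method SE and IVW weight."""

    snp_id: str
    ratio: float
    se_ratio: float

    def __post_init__(self):
        if not math.isfinite(self.ratio):
            raise ValueError(f"{self.snp_id}: non-finite Wald ratio")
        if not (self.se_ratio > 0 and math.isfinite(self.se_ratio)):
            raise ValueError(f"{self.snp_id}: se_ratio must be positive and finite")

    @property
    def weight(self) -> float:
        return 1.0 / self.se_ratio**2


@dataclass
class MrResult:
    """One estimator's pooled output on the log-odds scale, with OR transform."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.or_, self.ci_low, self.ci_high = to_or(self.beta, self.se)


def to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its Wald 95% CI."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return math.exp(beta), math.exp(beta - Z_CI * se), math.exp(beta + Z_CI * se)


def wald_ratio(instr: HarmonizedInstrument, *, second_order: bool = False) -> RatioEstimate:
    """Per-SNP causal estimate beta_out/beta_exp with delta-method SE."""
    if instr.beta_exp == 0:
        raise DegenerateInstrumentError(f"{instr.snp_id}: beta_exp is zero")
    ratio = instr.beta_out / instr.beta_exp
    var = instr.se_out**2 / instr.beta_exp**2
    if second_order:
        var += instr.beta_out**2 * instr.se_exp**2 / instr.beta_exp**4
    return RatioEstimate(instr.snp_id, ratio, math.sqrt(var))


def _as_instruments(instrs) -> list[HarmonizedInstrument]:
    if isinstance(instrs, InstrumentSet):
        return list(instrs.instruments)
    return list(instrs)


def _ratio_arrays(insts, second_order: bool = False):
    est = [wald_ratio(i, second_order=second_order) for i in insts]
    r = np.array([e.ratio for e in est])
    se = np.array([e.se_ratio for e in est])
    return r, se


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return 2.0 * stats.norm.sf(abs(beta / se))


def _ivw_core(r: np.ndarray, se: np.ndarray) -> tuple[float, float, float]:
    w = 1.0 / se**2
    theta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - theta) ** 2))
    return theta, se_fixed, q


def ivw(instrs, effects: str = "fixed", *, second_order: bool = False) -> MrResult:
    """Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios.

    ``effects="fixed"`` (default) uses SE = (sum of weights)^(-1/2);
    ``effects="random_multiplicative"`` inflates it by max(1, sqrt(Q/(J-1))),
    the multiplicative overdispersion model, never crediting underdispersion.
    """
    insts = _as_instruments(instrs)
    if len(insts) < 2:
        raise InsufficientInstrumentsError(
            f"IVW needs >= 2 instruments, got {len(insts)}; use wald_ratio for a single SNP"
        )
    if effects not in ("fixed", "random_multiplicative"):
        raise ValueError(f"unknown effects model {effects!r}")
    r, se_r = _ratio_arrays(insts, second_order)
    theta, se_fixed, q = _ivw_core(r, se_r)
    scale = 1.0
    if effects == "random_multiplicative":
        scale = max(1.0, math.sqrt(q / (len(insts) - 1)))
    se = se_fixed * scale
    return MrResult(
        method=f"ivw_{'fixed' if effects == 'fixed' else 'random'}",
        beta=theta,
        se=se,
        pvalue=_normal_p(theta, se),
        n_snps=len(insts),
        extras={"q_stat": q, "q_df": len(insts) - 1, "re_scale": scale},
    )


def egger(instrs) -> MrResult:
    """MR-Egger: weighted regression of outcome betas on exposure betas with
    an intercept, instruments oriented so every exposure beta is positive.

    Weights are 1/se_out².  Coefficient SEs are divided by
    min(weighted residual SD, 1): overdispersion widens them, underdispersion
    earns no credit.  p-values use Student's t with J-2 df.  The intercept
    triple lands in ``extras`` (``intercept``, ``intercept_se``,
    ``intercept_p``); a non-zero intercept estimates the average directional
    pleiotropic effect.
    """
    insts = _as_instruments(instrs)
    j = len(insts)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {j}")
    bx = np.array([i.beta_exp for i in insts])
    by = np.array([i.beta_out for i in insts])
    sy = np.array([i.se_out for i in insts])
    if np.any(bx == 0):
        raise DegenerateInstrumentError("zero exposure beta cannot be oriented")
    sgn = np.sign(bx)
    bx, by = bx * sgn, by * sgn
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    xtw = x.T * w
    xtwx_inv = np.linalg.inv(xtw @ x)
    coef = xtwx_inv @ (xtw @ by)
    resid = by - x @ coef
    sigma2 = float(np.sum(w * resid**2) / (j - 2))
    se_coef = np.sqrt(np.diag(xtwx_inv) * sigma2) / min(1.0, math.sqrt(sigma2))
    tvals = coef / se_coef
    pvals = 2.0 * stats.t.sf(np.abs(tvals), j - 2)
    return MrResult(
        method="egger",
        beta=float(coef[1]),
        se=float(se_coef[1]),
        pvalue=float(pvals[1]),
        n_snps=j,
        extras={
            "intercept": float(coef[0]),
            "intercept_se": float(se_coef[0]),
            "intercept_p": float(pvals[0]),
            "residual_sd": math.sqrt(sigma2),
        },
    )


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r, w = r[order], w[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, r))


def _bootstrap_se(insts, statistic, n_boot: int, seed) -> float:
    """Parametric bootstrap: redraw both betas from their reported normals."""
    rng = np.random.default_rng(seed)
    bx = np.array([i.beta_exp for i in insts])
    sx = np.array([i.se_exp for i in insts])
    by = np.array([i.beta_out for i in insts])
    sy = np.array([i.se_out for i in insts])
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = np.finfo(float).tiny  # measure-zero guard
        draws[b] = statistic(bys / bxs, sy / np.abs(bxs))
    return float(np.std(draws, ddof=1))


def weighted_median(instrs, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Weighted-median estimator: the interpolated 50th percentile of the
    ordered Wald ratios under cumulative normalized inverse-variance weights.

    The point estimate is deterministic; the SE comes from a parametric
    bootstrap with ``n_boot`` draws under ``seed`` (set ``n_boot=0`` to skip,
    yielding NaN SE/p).
    """
    insts = _as_instruments(instrs)
    if len(insts) < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 instruments, got {len(insts)}")
    r, se_r = _ratio_arrays(insts)
    theta = _weighted_median_point(r, 1.0 / se_r**2)
    if n_boot > 0:
        se = _bootstrap_se(insts, lambda rr, ss: _weighted_median_point(rr, 1.0 / ss**2), n_boot, seed)
    else:
        se = float("nan")
    return MrResult(
        method="weighted_median",
        beta=theta,
        se=se,
        pvalue=_normal_p(theta, se) if math.isfinite(se) else float("nan"),
        n_snps=len(insts),
        extras={"n_boot": n_boot, "seed": seed},
    )


def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    # modified Silverman rule over the ratio sample
    mad = 1.4826 * np.median(np.abs(r - np.median(r)))
    return float(phi * 0.9 * min(np.std(r, ddof=1), mad) * len(r) ** (-0.2))


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float, grid_points: int = 512) -> float | None:
    h = _mode_bandwidth(r, phi)
    if h == 0 or not math.isfinite(h):
        return None
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, grid_points)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ (w / w.sum())
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    instrs,
    variant: str = "weighted",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrResult:
    """Mode-based estimator: argmax of a Gaussian kernel density over the
    Wald ratios, evaluated on a 512-point grid spanning the ratio range
    padded by three bandwidths.

    ``variant="weighted"`` weights each kernel by the normalized inverse
    ratio variance; ``"simple"`` weights uniformly.  Bandwidth follows the
    modified Silverman rule  phi * 0.9 * min(sd, 1.4826*MAD) * J^(-1/5).
    If the bandwidth degenerates to zero (all ratios identical) the common
    ratio is returned with the IVW standard error.
    """
    if variant not in ("simple", "weighted"):
        raise ValueError(f"unknown mode variant {variant!r}")
    insts = _as_instruments(instrs)
    if len(insts) < 3:
        raise InsufficientInstrumentsError(f"mode estimator needs >= 3 instruments, got {len(insts)}")
    r, se_r = _ratio_arrays(insts)

    def weights(rr, ss):
        return 1.0 / ss**2 if variant == "weighted" else np.ones_like(rr)

    theta = _mode_point(r, weights(r, se_r), phi)
    if theta is None:  # degenerate: zero spread
        pooled = ivw(insts)
        return MrResult(
            method=f"{variant}_mode",
            beta=float(r[0]),
            se=pooled.se,
            pvalue=_normal_p(float(r[0]), pooled.se),
            n_snps=len(insts),
            extras={"phi": phi, "degenerate": True, "n_boot": n_boot, "seed": seed},
        )

    def statistic(rr, ss):
        point = _mode_point(rr, weights(rr, ss), phi)
        return point if point is not None else float(rr[0])

    if n_boot > 0:
        se = _bootstrap_se(insts, statistic, n_boot, seed)
    else:
        se = float("nan")
    return MrResult(
        method=f"{variant}_mode",
        beta=theta,
        se=se,
        pvalue=_normal_p(theta, se) if math.isfinite(se) else float("nan"),
        n_snps=len(insts),
        extras={"phi": phi, "bandwidth": _mode_bandwidth(r, phi), "n_boot": n_boot, "seed": seed},
    )
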
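"""Heterogeneity, pleiotropy and influence diagnostics for an MR analysis.

The causal estimate is only as credible as its instruments, so every MR
analysis here travels with four diagnostics:

* **Cochran's Q** — weighted squared deviation of the per-SNP Wald ratios
  about the fixed-effect IVW centre; excess Q signals heterogeneity, often a
  symptom of pleiotropy.
* **Egger intercept test** — the intercept of the MR-Egger regression, an
  estimate of average directional pleiotropy.
* **MR-PRESSO** — a Monte-Carlo test on the leave-one-out weighted residual
  sum of squares, with per-SNP outlier tests (Bonferroni-corrected) and a
  distortion test comparing estimates with and without flagged outliers.
* **leave-one-out** — the fixed-effect IVW re-estimated with each SNP
  removed in turn, to expose single-variant leverage.

The module also emits plot-ready scatter / funnel / forest / leave-one-out
tables (data only; no rendering).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import MrResult, Z_CI, _as_instruments, _ivw_core, _ratio_arrays, egger, ivw, wald_ratio
from .sumstats_io import InstrumentSet

__all__ = [
    "PressoResult",
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "sensitivity_report",
    "export_plot_tables",
]


def cochran_q(instrs) -> tuple[float, int, float]:
    """Cochran's Q about the fixed-effect IVW estimate, with df and p.

    Q = sum_j w_j (r_j - theta_IVW)^2, w_j = 1/se_ratio_j^2; p is the
    chi-square upper tail at J-1 df.  This is the single source of truth for
    Q: the multiplicative random-effects scale in ``ivw`` is sqrt(Q/(J-1))
    with the same Q.
    """
    insts = _as_instruments(instrs)
    if len(insts) < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 instruments, got {len(insts)}")
    r, se_r = _ratio_arrays(insts)
    _, _, q = _ivw_core(r, se_r)
    df = len(insts) - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(instrs) -> tuple[float, float, float]:
    """(intercept, SE, p) of the MR-Egger regression — directional pleiotropy."""
    res = egger(instrs)
    return res.extras["intercept"], res.extras["intercept_se"], res.extras["intercept_p"]


@dataclass
class PressoResult:
    """MR-PRESSO output: global RSS test, per-SNP outlier tests, distortion."""

    rss_obs: float
    global_p: float
    outlier_p: dict
    outliers: list
    distortion_p: float | None
    n_sim: int
    seed: int

    @property
    def global_p_label(self) -> str:
        """Printable global p; Monte-Carlo floor reported as an upper bound."""
        floor = 1.0 / (1 + self.n_sim)
        return f"<{floor:.3g}" if self.global_p <= floor else f"{self.global_p:.3g}"


def _snp_rng(seed: int, snp_id: str) -> np.random.Generator:
    # substream keyed by (root seed, stable hash of rsID): results do not
    # depend on instrument order
    key = int.from_bytes(hashlib.sha256(snp_id.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def mr_presso(instrs, n_sim: int = 1000, outlier_alpha: float = 0.05, seed: int = 0) -> PressoResult:
    """MR-PRESSO: Monte-Carlo residual-sum-of-squares test for pleiotropy.

    Observed statistic: for each SNP j, the IVW estimate excluding j predicts
    j's outcome effect; d_j is the prediction residual and
    RSS = sum_j d_j²/se_out_j².  Null replicates redraw
    beta_exp* ~ N(beta_exp, se_exp) and beta_out* ~ N(theta_{-j}·beta_exp_j,
    se_out) and recompute RSS the same way.  Monte-Carlo p-values use the
    (1+k)/(1+n) estimator, so they are never zero.  SNPs whose per-SNP
    residual p falls below ``outlier_alpha/J`` (Bonferroni) are flagged; when
    any are flagged, the distortion test compares the estimate shift caused
    by removing them against random same-size removals.
    """
    insts = _as_instruments(instrs)
    j = len(insts)
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {j}")
    bx = np.array([i.beta_exp for i in insts])
    sx = np.array([i.se_exp for i in insts])
    by = np.array([i.beta_out for i in insts])
    sy = np.array([i.se_out for i in insts])
    ids = [i.snp_id for i in insts]

    def loo_residuals(bx_, by_):
        # leave-one-out IVW slope per SNP via sum subtraction, then residual
        sy_ = sy if bx_.ndim == 1 else sy[:, None]
        w = (bx_ / sy_) ** 2         # ratio-space weights = bx²/se_out²
        r = by_ / bx_
        s_w, s_wr = w.sum(axis=0), (w * r).sum(axis=0)
        theta_loo = (s_wr - w * r) / (s_w - w)
        return by_ - theta_loo * bx_

    d_obs = loo_residuals(bx, by)
    w_out = 1.0 / sy**2
    rss_obs = float(np.sum(w_out * d_obs**2))
    theta_loo_obs = (by - d_obs) / bx  # recover theta_{-j}: d = by - theta_loo*bx

    # simulated replicates: per-SNP substreams keyed by rsID
    bx_sim = np.empty((j, n_sim))
    by_sim = np.empty((j, n_sim))
    for k, snp in enumerate(ids):
        rng = _snp_rng(seed, snp)
        bx_sim[k] = rng.normal(bx[k], sx[k], size=n_sim)
        by_sim[k] = rng.normal(theta_loo_obs[k] * bx[k], sy[k], size=n_sim)
    bx_sim[bx_sim == 0] = np.finfo(float).tiny
    d_sim = loo_residuals(bx_sim, by_sim)
    rss_sim = np.sum(w_out[:, None] * d_sim**2, axis=0)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    per_snp = (1 + np.sum(d_sim**2 >= (d_obs**2)[:, None], axis=1)) / (1 + n_sim)
    outlier_p = dict(zip(ids, per_snp.astype(float)))
    outliers = [s for s, p in outlier_p.items() if p < outlier_alpha / j]

    distortion_p = None
    if outliers and j - len(outliers) >= 2:
        keep = [i for i in insts if i.snp_id not in outliers]
        theta_all = ivw(insts).beta
        theta_no_out = ivw(keep).beta
        d_stat = (theta_all - theta_no_out) / abs(theta_no_out)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD157]))
        n_out = len(outliers)
        draws = np.empty(n_sim)
        r, se_r = _ratio_arrays(insts)
        w = 1.0 / se_r**2
        theta_full = float(np.sum(w * r) / np.sum(w))
        for b in range(n_sim):
            drop_idx = rng.choice(j, size=n_out, replace=False)
            mask = np.ones(j, bool)
            mask[drop_idx] = False
            theta_b = float(np.sum(w[mask] * r[mask]) / np.sum(w[mask]))
            draws[b] = (theta_full - theta_b) / abs(theta_b)
        distortion_p = float((1 + np.sum(np.abs(draws) >= abs(d_stat))) / (1 + n_sim))

    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=outliers,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(instrs) -> pd.DataFrame:
    """Fixed-effect IVW re-estimated leaving each SNP out in turn.

    Returns one row per left-out SNP (in instrument order) plus a final
    ``"All"`` reference row, with columns snp_id / beta / se / pvalue / or_ /
    ci_low / ci_high.
    """
    insts = _as_instruments(instrs)
    if len(insts) < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 3 instruments, got {len(insts)}")
    rows = []
    for k, left_out in enumerate(insts):
        subset = insts[:k] + insts[k + 1:]
        res = ivw(subset)
        rows.append(
            {"snp_id": left_out.snp_id, "beta": res.beta, "se": res.se, "pvalue": res.pvalue,
             "or_": res.or_, "ci_low": res.ci_low, "ci_high": res.ci_high}
        )
    full = ivw(insts)
    rows.append(
        {"snp_id": "All", "beta": full.beta, "se": full.se, "pvalue": full.pvalue,
         "or_": full.or_, "ci_low": full.ci_low, "ci_high": full.ci_high}
    )
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Bundle of every diagnostic plus plot-ready per-SNP tables."""

    q_stat: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso: PressoResult
    loo: pd.DataFrame
    funnel_rows: pd.DataFrame
    scatter_rows: pd.DataFrame
    forest_rows: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "cochran_q": {"q": self.q_stat, "df": self.q_df, "p": self.q_p},
            "egger_intercept": {
                "estimate": self.egger_intercept,
                "se": self.egger_intercept_se,
                "p": self.egger_intercept_p,
            },
            "mr_presso": {
                "rss_obs": self.presso.rss_obs,
                "global_p": self.presso.global_p,
                "outliers": self.presso.outliers,
                "distortion_p": self.presso.distortion_p,
                "n_sim": self.presso.n_sim,
                "seed": self.presso.seed,
            },
            "leave_one_out": self.loo.to_dict(orient="records"),
        }


def sensitivity_report(instrs, n_sim: int = 1000, seed: int = 0) -> SensitivityReport:
    """Run the full diagnostic battery on one instrument set."""
    insts = _as_instruments(instrs)
    q, df, qp = cochran_q(insts)
    icpt, icpt_se, icpt_p = egger_intercept_test(insts)
    presso = mr_presso(insts, n_sim=n_sim, seed=seed)
    loo = leave_one_out(insts)
    ratios = [wald_ratio(i) for i in insts]
    funnel = pd.DataFrame(
        {"snp_id": [e.snp_id for e in ratios],
         "ratio": [e.ratio for e in ratios],
         "precision": [1.0 / e.se_ratio for e in ratios]}
    )
    scatter = pd.DataFrame(
        {"snp_id": [i.snp_id for i in insts],
         "beta_exp": [i.beta_exp for i in insts],
         "beta_out": [i.beta_out for i in insts],
         "se_exp": [i.se_exp for i in insts],
         "se_out": [i.se_out for i in insts]}
    )
    forest = pd.DataFrame(
        {"snp_id": [e.snp_id for e in ratios],
         "beta": [e.ratio for e in ratios],
         "ci_low": [e.ratio - Z_CI * e.se_ratio for e in ratios],
         "ci_high": [e.ratio + Z_CI * e.se_ratio for e in ratios]}
    )
    pooled = ivw(insts)
    forest.loc[len(forest)] = ["All (IVW fixed)", pooled.beta,
                               pooled.beta - Z_CI * pooled.se, pooled.beta + Z_CI * pooled.se]
    return SensitivityReport(
        q_stat=q, q_df=df, q_p=qp,
        egger_intercept=icpt, egger_intercept_se=icpt_se, egger_intercept_p=icpt_p,
        presso=presso, loo=loo,
        funnel_rows=funnel, scatter_rows=scatter, forest_rows=forest,
    )


def export_plot_tables(report: SensitivityReport, out_dir) -> list[Path]:
    """Write scatter.tsv, funnel.tsv, forest.tsv and loo.tsv under ``out_dir``.

    Data only — rendering is left to the caller's plotting tool of choice.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in (
        ("scatter.tsv", report.scatter_rows),
        ("funnel.tsv", report.funnel_rows),
        ("forest.tsv", report.forest_rows),
        ("loo.tsv", report.loo),
    ):
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    return written
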
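#!/usr/bin/env python
"""Pipeline validation on synthetic data with known ground truth.

Simulates a study-scale dataset (32 genome-wide-significant instruments,
UKB-sized exposure GWAS, theta = -3.76), pushes it through the full
selection-harmonization-estimation pipeline, and repeats under directional
pleiotropy and with a planted outlier.  Finding: IVW recovers theta within
2 SE on clean data; directional pleiotropy shifts the Egger intercept to its
generative mean while biasing IVW; MR-PRESSO pinpoints the planted outlier.
"""

import argparse
from pathlib import Path

import pandas as pd

from metformin_ra_mr import (
    PleiotropyLaw,
    SimScenario,
    egger,
    filter_weak,
    harmonize_all,
    ivw,
    mr_presso,
    simulate_significant_instruments,
    steiger_filter,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def run_pipeline(sc: SimScenario):
    exp, out, truth = simulate_significant_instruments(sc)
    instr = harmonize_all(exp, out, exposure_name="synthetic exposure", outcome_name="synthetic outcome")
    instr = steiger_filter(instr, n_exp=sc.n_exp, n_out=sc.n_out)
    instr = filter_weak(instr)
    return instr, truth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2026)
    args = ap.parse_args()
    rows = []

    # clean data: theta recovered
    sc = SimScenario(j_snps=32, theta=-3.76, seed=args.seed)
    instr, truth = run_pipeline(sc)
    res = ivw(instr)
    rows.append({"scenario": "clean", "n_instruments": len(instr), "truth_theta": truth.theta,
                 "ivw_beta": res.beta, "ivw_se": res.se,
                 "recovered_within_2se": abs(res.beta - truth.theta) < 2 * res.se})
    print(f"clean: IVW {res.beta:.3f} +/- {res.se:.3f} vs truth {truth.theta} "
          f"({len(instr)} instruments after harmonization/filters)")

    # directional pleiotropy: Egger intercept finds it, IVW is misled
    sc = SimScenario(j_snps=60, theta=-2.0, seed=args.seed + 1,
                     pleiotropy=PleiotropyLaw.directional(0.02, 0.002))
    instr, truth = run_pipeline(sc)
    eg, res = egger(instr), ivw(instr)
    rows.append({"scenario": "directional_pleiotropy", "n_instruments": len(instr),
                 "truth_theta": truth.theta, "ivw_beta": res.beta, "ivw_se": res.se,
                 "egger_intercept": eg.extras["intercept"]})
    print(f"directional pleiotropy (mean 0.02): Egger intercept {eg.extras['intercept']:.4f}, "
          f"IVW {res.beta:.2f} (truth {truth.theta}) -- IVW is biased, the intercept flags why")

    # planted outlier: MR-PRESSO finds it.  Note the filters interact: a
    # 10-sigma pleiotropic SNP explains more outcome than exposure variance,
    # so the Steiger filter alone already removes it; to exercise MR-PRESSO
    # we run it on the harmonized set before Steiger filtering.
    sc = SimScenario(j_snps=30, theta=-2.0, n_outliers=1, outlier_scale=10, seed=args.seed + 2)
    exp, out, truth = simulate_significant_instruments(sc)
    instr = harmonize_all(exp, out)
    pres = mr_presso(instr, n_sim=1000, seed=args.seed)
    steigered = steiger_filter(instr, n_exp=sc.n_exp, n_out=sc.n_out)
    steiger_caught = set(truth.outlier_ids) - set(steigered.snp_ids)
    rows.append({"scenario": "planted_outlier", "n_instruments": len(instr),
                 "truth_theta": truth.theta, "planted": ",".join(truth.outlier_ids),
                 "flagged": ",".join(pres.outliers), "presso_global_p": pres.global_p,
                 "also_removed_by_steiger": ",".join(sorted(steiger_caught))})
    print(f"planted outlier {truth.outlier_ids}: MR-PRESSO flagged {pres.outliers} "
          f"(global p {pres.global_p_label}); Steiger independently removed {sorted(steiger_caught)}")

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "synthetic_validation.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"wrote {OUT / 'synthetic_validation.tsv'}")


if __name__ == "__main__":
    main()
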
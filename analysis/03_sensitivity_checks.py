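#!/usr/bin/env python
"""Sensitivity battery for the metformin/RA causal estimate.

Cochran's Q heterogeneity test, the MR-Egger intercept (directional
pleiotropy), MR-PRESSO (global pleiotropy + per-SNP outliers) and the
leave-one-out analysis, plus plot-ready scatter / funnel / forest / LOO
tables.  Finding: no heterogeneity (Q ~ 40.8 on 31 df, p ~ 0.11), no
directional pleiotropy (intercept ~ 0.0066, p ~ 0.51), no MR-PRESSO
outliers (global p ~ 0.12), and no single SNP flips the sign of the effect.
"""

import argparse
import json
from pathlib import Path

from metformin_ra_mr import export_plot_tables, load_metformin_ra_instruments, sensitivity_report

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--presso-sims", type=int, default=1000)
    args = ap.parse_args()

    instr = load_metformin_ra_instruments()
    report = sensitivity_report(instr, n_sim=args.presso_sims, seed=args.seed)
    OUT.mkdir(exist_ok=True)
    export_plot_tables(report, OUT)
    (OUT / "sensitivity.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")

    print(f"Cochran's Q: {report.q_stat:.3f} on {report.q_df} df (p = {report.q_p:.3f})")
    print(f"Egger intercept: {report.egger_intercept:.4f} "
          f"(SE {report.egger_intercept_se:.4f}, p {report.egger_intercept_p:.3f})")
    print(f"MR-PRESSO global p: {report.presso.global_p_label} "
          f"({report.presso.n_sim} simulations); outliers: {report.presso.outliers or 'none'}")
    sign_stable = (report.loo.beta[:-1] < 0).all()
    print(f"leave-one-out: {len(report.loo) - 1} reduced-set estimates, "
          f"all negative: {bool(sign_stable)}")
    print(f"wrote plot tables + sensitivity.json under {OUT}")


if __name__ == "__main__":
    main()
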
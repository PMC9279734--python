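"""Stage 2 — fit the beta-binomial positivity law to the nodal cohort.

Fits (alpha, beta) to node-positive patients with at least two nodes
examined, both with the plain beta-binomial likelihood and with the
zero-truncated likelihood that conditions on detection.  Reports percentile
bootstrap confidence intervals (patient-level resampling with per-replicate
refits) and a Pearson chi-square goodness-of-fit test.  The truncated fit
is the generative-consistent one: on a cohort drawn at Beta(2.50, 6.21) it
recovers the parameters, while the untruncated fit is biased upward because
the substrate is condition-on-detection.
"""

import argparse
import json
from pathlib import Path

from occultln import bootstrap_ci, fit_mle, goodness_of_fit, read_nodal_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--bootstrap-replicates", type=int, default=500)
    args = ap.parse_args()

    cohort = read_nodal_csv(args.out_dir / "nodal_cohort.csv")
    report = {}
    for truncated in (True, False):
        fit = fit_mle(cohort, truncated=truncated)
        ci_a = bootstrap_ci(cohort, "alpha", n_replicates=args.bootstrap_replicates,
                            seed=args.seed, truncated=truncated)
        ci_b = bootstrap_ci(cohort, "beta", n_replicates=args.bootstrap_replicates,
                            seed=args.seed, truncated=truncated)
        gof = goodness_of_fit(cohort, fit.params)
        label = "truncated" if truncated else "untruncated"
        report[label] = {
            "alpha": fit.params.alpha,
            "alpha_ci": [ci_a.ci_lower, ci_a.ci_upper],
            "beta": fit.params.beta,
            "beta_ci": [ci_b.ci_lower, ci_b.ci_upper],
            "log_likelihood": fit.log_likelihood,
            "n_used": fit.n_used,
            "gof_statistic": gof.statistic,
            "gof_df": gof.df,
            "gof_p": gof.p_value,
        }
        print(
            f"{label:12s} fit (n={fit.n_used}): "
            f"alpha = {fit.params.alpha:.2f} "
            f"(95% CI {ci_a.ci_lower:.2f}-{ci_a.ci_upper:.2f}), "
            f"beta = {fit.params.beta:.2f} "
            f"(95% CI {ci_b.ci_lower:.2f}-{ci_b.ci_upper:.2f}), "
            f"GOF p = {gof.p_value:.3f}"
        )

    (args.out_dir / "fit_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
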
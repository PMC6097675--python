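"""Asymptotic vs MCMC uncertainty on one fitted configuration.

Fits the 49-parameter F-free configuration with estimated natural
mortality, then compares delta-approximation standard deviations (inverse
Hessian) with Metropolis-Hastings posterior SDs at desk scale, and runs
the full chain diagnostics (Heidelberger-Welch, Geweke, ESS).
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from krillassess.config import preset
from krillassess.estimation import run_replicates
from krillassess.io import load_bundle
from krillassess.synth import default_scenario, observe, simulate_truth
from krillassess.uncertainty import asymptotic_intervals, diagnose, mcmc_sample

import numpy as np


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--config", default="cfgII")
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--samples", type=int, default=40_000)
    ap.add_argument("--thin", type=int, default=10)
    ap.add_argument("--out", type=Path, default=Path("results/uncertainty"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    if args.data.exists():
        bundle = load_bundle(args.data)
    else:
        sc = default_scenario(seed=args.seed)
        rng = np.random.default_rng(args.seed)
        truth, traj = simulate_truth(sc, rng)
        bundle = observe(traj, sc, rng)

    fits, summary = run_replicates(
        preset(args.config), bundle, n_replicates=1, seed=args.seed
    )
    fit = fits[summary.best_index]
    print(f"{args.config}: nll={fit.nll:.2f}, max|g|={fit.max_gradient:.1e}, "
          f"converged={fit.converged}")

    asym = asymptotic_intervals(fit)
    asym.to_csv(args.out / "asymptotic_intervals.csv", index=False)

    res = mcmc_sample(fit, n_total=args.samples, thin=args.thin, rng=args.seed + 17)
    res.to_frame().to_csv(args.out / "chains.csv", index=False)
    print(f"MCMC acceptance rate: {res.acceptance_rate:.2f}; "
          f"{res.n_saved} saved samples of {len(res.labels)} quantities")

    report = diagnose(res)
    report.rows.to_csv(args.out / "diagnostics.csv", index=False)
    print(report.rows.to_string(index=False))
    print(f"overall diagnostics pass: {report.overall_pass}")

    # MCMC vs asymptotic SDs for the monitored scalar parameters
    rows = []
    for j, label in enumerate(res.labels):
        match = asym[asym.name == label]
        if len(match):
            rows.append(
                {
                    "quantity": label,
                    "sd_mcmc": res.chains[:, j].std(),
                    "sd_asymptotic": float(match.iloc[0].sd),
                }
            )
    cmp = pd.DataFrame(rows)
    cmp["ratio"] = cmp.sd_mcmc / cmp.sd_asymptotic
    cmp.to_csv(args.out / "sd_comparison.csv", index=False)
    print(cmp.to_string(index=False))

    fig, axes = plt.subplots(
        min(4, len(res.labels)), 1, figsize=(8, 9), sharex=True
    )
    for ax, j in zip(np.atleast_1d(axes), range(len(res.labels))):
        ax.plot(res.chains[:, j], lw=0.4)
        ax.set_ylabel(res.labels[j])
    plt.xlabel("saved sample")
    plt.tight_layout()
    plt.savefig(args.out / "trace_plots.png", dpi=120)
    print(f"wrote outputs to {args.out}")


if __name__ == "__main__":
    main()
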
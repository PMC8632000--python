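#!/usr/bin/env python
"""Evaluate the final model: GOF table, bootstrap, visual predictive check.

Reduced replicate counts (100 bootstrap / 200 VPC simulations) keep this
driver quick; the package supports the full 1,000 / 500 via arguments.
Writes the GOF table, bootstrap summary, VPC bands and the two figures.
"""

from pathlib import Path

from vancopk.datasets import read_dataset
from vancopk.estimation import fit_model
from vancopk.evaluation import bootstrap_run, gof_tables, vpc_run
from vancopk.model import final_model_spec
from vancopk.plots import plot_gof, plot_vpc

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20210721


def main() -> None:
    ds = read_dataset(OUT / "cohort.csv")
    fit = fit_model(final_model_spec(), ds)
    print(f"final model OFV {fit.ofv:.1f}")

    gof = gof_tables(fit, ds)
    gof.to_csv(OUT / "gof_table.csv", index=False)
    frac = (gof["CWRES"].abs() <= 2).mean()
    print(f"GOF: {len(gof)} rows; {100 * frac:.1f}% of CWRES within [-2, 2]")
    plot_gof(gof, OUT / "gof_panels.png")

    boot = bootstrap_run(final_model_spec(), ds, n=100, seed=SEED + 1, original_fit=fit)
    boot.table.to_csv(OUT / "bootstrap_table.csv", index=False)
    print(f"\nbootstrap ({boot.n_converged}/{boot.n_replicates} replicates converged):")
    print(boot.table.to_string(index=False))

    vpc = vpc_run(fit, ds, n_sim=200, seed=SEED + 2)
    vpc.bins.to_csv(OUT / "vpc_bands.csv", index=False)
    obs = ds.frame[ds.frame["EVID"] == 0]
    plot_vpc(vpc, obs, OUT / "vpc.png")
    inside = (
        (vpc.bins["obs_p50"] >= vpc.bins["sim_p50_lo"])
        & (vpc.bins["obs_p50"] <= vpc.bins["sim_p50_hi"])
    ).mean()
    print(f"\nVPC: observed median inside its 90% band in {100 * inside:.0f}% of bins")


if __name__ == "__main__":
    main()
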
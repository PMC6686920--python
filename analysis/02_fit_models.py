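"""Fit all base models to one simulated trait and estimate heritabilities.

Reads a replicate written by 01_simulate.py, fits the six base models on
the full genotyped generation, and tabulates variance components
(V_A, V_D, h2, d2, H2) against the parametric values — the simulated-data
analogue of the study's variance-component comparison, where marker-only
BayesA gives the least biased estimates and pedigree models overestimate.

Run:  python analysis/02_fit_models.py [--arch oligogenic_medium]
      [--n-iter 10000] (100,000 reproduces the full-length chains)
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from forestgs import io
from forestgs.kinship import additive_relationship, dominance_relationship
from forestgs.models import ModelConfig, build_kernels, fit_bayesa, \
    fit_pedigree, fit_rkhs
from forestgs.evaluation import variance_components


def main() -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--arch", default="oligogenic_medium")
    parser.add_argument("--n-iter", type=int, default=10_000)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--sim-dir", type=Path,
                        default=Path("results/simulated"))
    parser.add_argument("--out", type=Path,
                        default=Path("results/variance_components.csv"))
    args = parser.parse_args()

    sim = args.sim_dir / args.arch
    if not sim.exists():
        print(f"run 01_simulate.py first ({sim} missing)")
        return 1
    codings, ped, y = io.read_inputs(sim / "genotypes.tsv",
                                     sim / "pedigree.csv",
                                     sim / "trait.csv")
    trait = pd.read_csv(sim / "trait.csv")
    y = trait["phenotype"].to_numpy()
    vp = np.var(y)
    true_h2 = np.var(trait["BV"]) / vp
    true_d2 = np.var(trait["DD"]) / vp

    A_full = additive_relationship(ped)
    rows = ped.index[ped["id"].isin(trait["id"])].to_numpy()
    A = A_full[np.ix_(rows, rows)]
    D = dominance_relationship(ped, A_full)[np.ix_(rows, rows)]

    cfg = ModelConfig(n_iter=args.n_iter,
                      burn_in=max(1000, args.n_iter // 5),
                      thin=3, seed=args.seed)
    X = codings.X.astype(float)
    W = codings.W.astype(float)
    fits = {
        "bayesa-a": fit_bayesa(y, X, config=cfg),
        "bayesa-ad": fit_bayesa(y, X, W, config=cfg),
        "rkhs-ka": fit_rkhs(y, build_kernels(X), config=cfg),
        "rkhs-kakd": fit_rkhs(y, build_kernels(X, W), config=cfg),
        "ped-a": fit_pedigree(y, A, config=cfg),
        "ped-ad": fit_pedigree(y, A, D=D, config=cfg),
    }
    rows_out = [{"model": "parametric", "h2": true_h2, "d2": true_d2,
                 "H2": true_h2 + true_d2}]
    for name, fit in fits.items():
        vc = variance_components(fit, codings.p, codings.q)
        rows_out.append({"model": name, "V_A": vc.V_A, "V_D": vc.V_D,
                         "sigma_e2": vc.sigma_e2, "h2": vc.h2,
                         "d2": vc.d2, "H2": vc.H2})
        print(f"{name:10s} h2={vc.h2:.3f} d2={vc.d2:.3f} H2={vc.H2:.3f}")
    print(f"parametric h2={true_h2:.3f} d2={true_d2:.3f}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    out = pd.DataFrame(rows_out).round(4)
    io.write_results(args.out, out, {"arch": args.arch, "seed": args.seed,
                                     "n_iter": args.n_iter})
    print(f"written {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
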
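#!/usr/bin/env python
"""Quantify the bias that intra-block recombination induces in MCL estimates.

The composite-likelihood model assumes blocks are non-recombining; real
64-site blocks spanning up to 128 bp recombine at the local map rate
(around 2 cM/Mb in these chromosomes).  This script simulates blocks with
recombination switched on, refits the recombination-free model, and reports
the relative bias per parameter.  The bias is reported, never subtracted.
"""

import argparse
import json
import os

from warblerdiv.experiments import RECOVERY_TRUTH
from warblerdiv.inference import LikelihoodOptions, MutationModel
from warblerdiv.model_selection import recombination_bias


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--rates", type=float, nargs="+", default=[0.0, 2.04],
                    help="recombination rates in cM/Mb (chromosome 1 uses 2.04)")
    ap.add_argument("--n-blocks", type=int, default=20_000)
    ap.add_argument("--n-genealogies", type=int, default=4000)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    mut = MutationModel()
    reports = []
    for rate in args.rates:
        rep = recombination_bias(
            RECOVERY_TRUTH, rate, n_blocks=args.n_blocks, mut=mut,
            opts=LikelihoodOptions(args.n_genealogies, 0), seed=args.seed,
            max_iter=1000,
        )
        reports.append(rep.to_dict())
        print(f"rate {rate} cM/Mb: T bias {rep.bias_percent['T']:+.1f}%  "
              f"N_anc bias {rep.bias_percent['N_anc']:+.1f}%")

    os.makedirs(args.out_dir, exist_ok=True)
    with open(os.path.join(args.out_dir, "recombination_bias.json"), "w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
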
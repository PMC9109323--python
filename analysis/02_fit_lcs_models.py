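#!/usr/bin/env python
"""Fit the three latent change score parameterizations to the simulated cohort.

Although the generator contains no breastfeeding effect on child IQ, the
adjusted models (forward and backward) both estimate a positive
breastfeeding effect on the latent change while the unadjusted model
estimates a negative one — the regression-to-the-mean artefact. Each fit is
checked against the closed-form population oracle and written with Wald
intervals.
"""

import argparse
from pathlib import Path

import pandas as pd

from lcsiq import (
    DGPConfig,
    MODELS,
    expected_model_coefficients,
    fit_lcs,
    generate_cohort,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = DGPConfig(seed=args.seed)
    cohort = generate_cohort(cfg)
    rows = []
    for model in MODELS:
        fit = fit_lcs(cohort, model, se="delta")
        oracle = expected_model_coefficients(cfg, model)
        lo, hi = fit.ci["bf_effect"]
        rows.append({
            "model": model,
            "bf_effect": fit.bf_effect,
            "se": fit.se["bf_effect"],
            "ci_low": lo, "ci_high": hi,
            "iq_effect": fit.iq_effect,
            "oracle_bf_effect": oracle.bf_effect,
        })
        print(f"{model:>14}: BF effect {fit.bf_effect:+.2f} "
              f"({lo:.2f}; {hi:.2f})  [oracle {oracle.bf_effect:+.2f}]")
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "simulation_fits.csv", index=False)
    signs = "".join("+" if b > 0 else "-" for b in table["bf_effect"])
    print(f"\nsign pattern (forward_adj, backward_adj, forward_noadj): ({', '.join(signs)})")
    print("no causal breastfeeding effect exists in the generator: the "
          "pattern is regression to the mean, not causation")


if __name__ == "__main__":
    main()
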
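#!/usr/bin/env python
"""Decompose the adjusted breastfeeding effects into direct and total effects.

The omitted-variable identity total = direct + (BF-group IQ difference) x
(IQ slope) reconciles the apparently contradictory models: on shared
moments the forward-adjusted total equals the unadjusted effect exactly,
and the backward-adjusted total equals its negative. The published
first-child coefficients are run through the same rule as a worked example.
"""

import argparse
from pathlib import Path

import pandas as pd

from lcsiq import (
    DGPConfig,
    coefficients_from_moments,
    decompose_fit,
    fiml_moments,
    generate_cohort,
    total_effect,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    print("worked examples from the published first-child coefficients:")
    t_fwd = total_effect(2.67, -0.648, 12.0)
    t_bwd = total_effect(8.09, -0.429, 6.91)
    print(f"  forward:  2.67 + 12.0 x -0.648 = {t_fwd:.2f}")
    print(f"  backward: 8.09 + 6.91 x -0.429 = {t_bwd:.2f}")

    cohort = generate_cohort(DGPConfig(seed=args.seed))
    moments, _ = fiml_moments(cohort)
    noadj = coefficients_from_moments(moments, "forward_noadj")
    rows = []
    for model, flip in (("forward_adj", 1), ("backward_adj", -1)):
        fit = coefficients_from_moments(moments, model)
        dec = decompose_fit(fit, moments)
        rows.append({
            "model": model, "direct": dec.direct,
            "conditioning_coef": dec.conditioning_coef,
            "group_mean_diff": dec.group_mean_diff, "total": dec.total,
            "unadjusted_effect": noadj.bf_effect,
            "identity_gap": dec.total - flip * noadj.bf_effect,
        })
        print(f"\n{model} on the simulated cohort:")
        print(f"  direct {dec.direct:+.3f}, slope {dec.conditioning_coef:+.3f}, "
              f"group diff {dec.group_mean_diff:+.3f} -> total {dec.total:+.3f}")
        print(f"  unadjusted effect {flip * noadj.bf_effect:+.3f} "
              f"(identity gap {rows[-1]['identity_gap']:.2e})")
    pd.DataFrame(rows).to_csv(args.out / "decomposition.csv", index=False)
    print(f"\nthe published -5.11 vs -5.13 gap is rounding of printed inputs; "
          "on shared moments the identity is exact")


if __name__ == "__main__":
    main()
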
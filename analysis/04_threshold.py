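"""Threshold (headroom) analysis: the maximum per-decision SDM delivery
cost at which each effect scenario stays cost-effective at the Dutch
willingness-to-pay thresholds.

Writes results/threshold.csv.  A negative value means the scenario is
not cost-effective even with free delivery; "not_achievable" means it
gains no QALYs.
"""

import argparse
from pathlib import Path

import pandas as pd

import mscea
from mscea.analysis import effect_profiles, threshold_sdm_cost


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20260101)
    ap.add_argument("--params", type=Path, default=None)
    ap.add_argument("--wtp", type=float, nargs="+", default=[20_000.0, 50_000.0])
    ap.add_argument("--out", type=Path, default=Path("results/threshold.csv"))
    args = ap.parse_args()

    if args.params is not None:
        params = mscea.load_parameter_set(args.params)
    else:
        params = mscea.generate_parameter_set(mscea.GeneratorConfig(seed=args.seed))
    cau, sdm = params.strategies["CAU"], params.strategies["SDM"]

    rows = []
    for name, profile in effect_profiles(cau, sdm).items():
        for wtp in args.wtp:
            c_star = threshold_sdm_cost(cau, profile, params, wtp)
            rows.append({"effect": name, "wtp": wtp, "max_sdm_cost": c_star})
            shown = c_star if isinstance(c_star, str) else f"{c_star:,.2f}"
            print(f"effect '{name}' at WTP {wtp:,.0f}: max delivery cost {shown}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
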
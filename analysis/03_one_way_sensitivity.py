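"""One-way sensitivity analysis of the combined-effects comparison.

Re-runs the SDM-vs-usual-care comparison under the standard scenario
registry (drug costs, progression relative risks, SDM delivery cost,
discount rates, perspectives, demographics, entry distribution,
initial/second-choice variants, transition probabilities) and writes
results/one_way_sensitivity.csv.
"""

import argparse
from pathlib import Path

import mscea
from mscea.analysis import one_way_sensitivity, table4_registry


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20260101)
    ap.add_argument("--params", type=Path, default=None)
    ap.add_argument("--out", type=Path, default=Path("results/one_way_sensitivity.csv"))
    args = ap.parse_args()

    if args.params is not None:
        params = mscea.load_parameter_set(args.params)
    else:
        params = mscea.generate_parameter_set(mscea.GeneratorConfig(seed=args.seed))
    cau, sdm = params.strategies["CAU"], params.strategies["SDM"]

    table = one_way_sensitivity(table4_registry(params), params, cau, sdm)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)

    base = table.set_index("scenario").loc["base_case"]
    print(f"base case: dCost {base['delta_cost']:+,.0f}, "
          f"dQALY {base['delta_qaly']:+.3f}, ICER {base['icer']:,.0f}")
    with_icer = table.dropna(subset=["icer"])
    lo = with_icer.loc[with_icer["icer"].idxmin()]
    hi = with_icer.loc[with_icer["icer"].idxmax()]
    print(f"most favourable scenario: {lo['scenario']} (ICER {lo['icer']:,.0f})")
    print(f"least favourable scenario: {hi['scenario']} (ICER {hi['icer']:,.0f})")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
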
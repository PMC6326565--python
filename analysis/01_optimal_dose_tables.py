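#!/usr/bin/env python
"""Enumerate how many doses of each discrete scheme are "optimal".

Two geometric questions are answered before any trial is simulated:

1. How many doses of each scheme fall inside the optimal MTD interval
   (true MTD +/- 15% of its value), for true MTDs 0.2/0.4/0.6/0.8?
2. How many doses have a true DLT probability inside theta +/- 0.10,
   for each of the four calibrated truth shapes?

The headline finding: the coarse schemes D0.125 and D0.25 contain *no*
optimal dose at all for several scenarios (e.g. no D0.25 dose lies in
(0.34, 0.46) when the true MTD is 0.4), so no amount of sampling can
rescue them there — the dose grid itself caps the achievable operating
characteristics.

Writes results/table1.csv and results/table2.csv.
"""

from pathlib import Path

from dosegrid.oc import optimal_mtd_table, optimal_toxicity_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)

    t1 = optimal_mtd_table(delta=0.15)
    t1.to_csv(OUT / "table1.csv", index=False)
    print("Optimal-MTD-interval enumeration (delta = 0.15):")
    print(t1.to_string(index=False), "\n")

    t2 = optimal_toxicity_table(band=0.10)
    t2.to_csv(OUT / "table2.csv", index=False)
    print("Optimal-toxicity-interval enumeration (theta +/- 0.10):")
    print(t2.to_string(index=False), "\n")

    empty = (
        t2[[c for c in t2.columns if c.endswith("_count")]].eq(0).sum(axis=1)
    )
    n_empty = int((empty > 0).sum())
    print(
        f"{n_empty} of {len(t2)} (shape, MTD) scenarios leave at least one "
        "scheme with zero optimal doses."
    )

    narrow = optimal_toxicity_table(band=0.05, shapes=(("logistic", 0.0),))
    count_cols = [c for c in narrow.columns if c.endswith("_count")]
    same = narrow[count_cols].to_numpy().tolist() == t1[count_cols].to_numpy().tolist()
    print(
        "Narrowing the toxicity band to theta +/- 0.05 makes the logistic "
        f"counts coincide with the MTD-interval counts: {same}"
    )


if __name__ == "__main__":
    main()
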
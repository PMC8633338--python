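#!/usr/bin/env python
"""Allelic-balance testing across the index family.

Reads the family's per-individual allelic depths, computes each typed
member's allelic ratio and exact binomial balance test against the 50/50
heterozygous expectation, and calls carrier states.  In the index family
the proband's 18/19 reads give a balanced ratio of 0.51 (p = 1.0) while
the grandmother's 22/6 reads give 0.21 (p = 0.0037): a mosaic candidate.
"""

import argparse
from pathlib import Path

import pandas as pd

from mhscreen.mosaicism import (
    AllelicDepth,
    BalanceConfig,
    Genotype,
    classify_carrier_state,
    write_states_tsv,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--alpha", type=float, default=0.01)
    parser.add_argument("--out", type=Path, default=Path("results/family"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    depths = pd.read_csv(args.sim / "family" / "allelic_depths.tsv", sep="\t")
    config = BalanceConfig(alpha=args.alpha)
    states = []
    for row in depths.itertuples(index=False):
        depth = AllelicDepth(str(row.individual), int(row.ref_reads),
                             int(row.alt_reads))
        state = classify_carrier_state(Genotype(row.genotype), depth, config)
        states.append(state)
        if state.test is not None:
            print(f"{state.individual:>6}: ratio "
                  f"{state.test.ratio:.2f} ({depth.alt_reads}/{depth.total} "
                  f"reads), p = {state.test.p_two_sided:.4f} "
                  f"-> {state.state.value}")
        else:
            print(f"{state.individual:>6}: {depth.alt_reads}/{depth.total} "
                  f"alt reads -> {state.state.value}")
    write_states_tsv(states, args.out / "carrier_states.tsv")
    print(f"wrote {args.out / 'carrier_states.tsv'}")


if __name__ == "__main__":
    main()
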
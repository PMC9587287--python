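#!/usr/bin/env python
"""Headline landscape shares, formatted by the reporting convention.

Prints the results/headline_shares.tsv table from analysis/02 with the
mixed rounding convention (integer percent at >= 10%, one decimal below).
"""
import argparse
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    from ndtrials.pipeline import read_table

    shares = read_table(args.results / "headline_shares.tsv")
    print(f"{'metric':38s} {'share':>7s}   numerator/denominator")
    for row in shares.itertuples(index=False):
        print(f"{row.metric:38s} {row.share_pct:>6g}%   "
              f"{row.numerator:.0f}/{row.denominator:.0f}")


if __name__ == "__main__":
    main()
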
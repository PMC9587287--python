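#!/usr/bin/env python
"""Generate the synthetic trial registry used by the downstream analyses.

Writes the registry (per-record XML plus a TSV mirror), the curated lookup
tables, the stage-cue sidecar and the ground-truth sidecar under
scratch/registry/. The registry emulates the two-decade neurodegenerative-
disease landscape: ~160 launches/year from 2000 through a three-month slice
of 2020, with the documented sector/class/stage mixtures and temporal
drifts baked into the generator defaults.
"""
import argparse
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path,
                        default=ROOT / "scratch" / "registry")
    args = parser.parse_args()

    from ndtrials.synthetic import (GeneratorConfig, generate_registry,
                                    write_generated)

    config = GeneratorConfig(seed=args.seed)
    result = generate_registry(config)
    write_generated(result, args.outdir)

    truth = result.truth
    print(f"registry: {len(result.records)} records -> {args.outdir}")
    print(f"  launch years {truth.year.min()}-{truth.year.max()}, "
          f"final year is a 3-month slice")
    print("  cohorts:", truth.cohort.value_counts().to_dict())
    included = truth[truth.included == 1]
    print("  included classes:",
          included.trial_class.value_counts().to_dict())
    print(f"  drug pool: {len(result.lookups.drug_info)} canonical entities,"
          f" {len(result.lookups.associations)} gene-disease associations")


if __name__ == "__main__":
    main()
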
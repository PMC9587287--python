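#!/usr/bin/env python
"""Screen and annotate the registry; report the inclusion funnel.

Runs the rule engine (arm classification, standard-of-care placebo
reassignment, screening flowchart, criteria counting, score-window
extraction, stage-cue mapping, 7-category drug taxonomy) over the registry
from analysis/01 and writes results/annotations.tsv plus the run manifest.
"""
import argparse
import json
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--registry", type=Path,
                        default=ROOT / "scratch" / "registry")
    parser.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    from ndtrials.pipeline import PipelineConfig, run_pipeline

    outdir = run_pipeline(PipelineConfig(
        registry=args.registry / "records.tsv",
        lookup_dir=args.registry / "lookups",
        cues_path=args.registry / "stage_cues.tsv",
        outdir=args.outdir))

    manifest = json.loads((outdir / "manifest.json").read_text())
    print(f"screened {manifest['n_records']} records "
          f"-> {manifest['n_included']} included")
    for reason, n in manifest["exclusions"].items():
        if n:
            print(f"  excluded {n:>4d}  {reason}")
    print(f"tables in {outdir}")


if __name__ == "__main__":
    main()
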
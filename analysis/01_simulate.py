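"""Generate the synthetic study inputs: guild-structured metabolite profiles
with planted commensal/pathogenic labels, drug-target tables with planted
pathogen-selective drugs, category annotations with one planted enriched
category, and a homology-hit table for the druggability survey.

Writes everything under results/run/simulate/ in the TSV dialects the later
stages consume, plus JSON sidecars recording parameters and ground truth.
"""

import argparse
import json
from pathlib import Path

from micropharm.pipeline import PipelineConfig, run_stage


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    config = PipelineConfig.from_dict({"out_dir": str(args.out), "seed": args.seed})
    outputs = run_stage("simulate", config)
    sidecar = json.loads((args.out / "simulate" / "profile_scenario.json").read_text())
    screen = json.loads((args.out / "simulate" / "screen_scenario.json").read_text())
    print(f"simulated community: {6 * 15} microbes in 6 guilds, seed {args.seed}")
    print(f"observed labels: {24} of 90 ({sidecar['params']['labeled_fraction']:.0%} per guild)")
    print(
        f"planted selective drugs: {len(screen['planted_inh_not_inh'])} typed / "
        f"{len(screen['planted_selective'])} untyped among {screen['params']['n_drugs']}"
    )
    for name, path in outputs.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
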
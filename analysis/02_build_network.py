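"""Infer the signed, directed microbe-microbe interaction network from the
simulated metabolite profiles, attach the observed health labels, and report
its structure: edge counts by sign, the relationship-type census of the
strongly connected core, and the per-microbe metabolite-count distributions.
"""

import argparse
from collections import Counter
from itertools import combinations
from pathlib import Path

from micropharm import (
    classify_relationship,
    largest_strongly_connected_component,
    profile_summary,
    read_profiles,
)
from micropharm.network import SignedNetwork
from micropharm.pipeline import PipelineConfig, run_stage


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    config = PipelineConfig.from_dict({"out_dir": str(args.out), "seed": args.seed})
    outputs = run_stage("build-network", config)
    network = SignedNetwork.from_graphml(outputs["graphml"])

    n_pos = sum(1 for e in network.edges if e.weight > 0)
    n_neg = sum(1 for e in network.edges if e.weight < 0)
    print(f"network: {len(network.nodes)} nodes, {network.number_of_edges()} edges "
          f"({n_pos} positive, {n_neg} negative)")

    core = largest_strongly_connected_component(network)
    print(f"largest strongly connected component: {len(core.nodes)} nodes")

    census = Counter(
        classify_relationship(core, u, v).value
        for u, v in combinations(sorted(core.nodes), 2)
    )
    print("relationship census of the core:")
    for rel, count in census.most_common():
        print(f"  {rel:13s} {count}")

    profiles = read_profiles(args.out / "simulate" / "profiles.tsv")
    per_microbe, per_metabolite = profile_summary(profiles)
    per_microbe.to_csv(args.out / "build-network" / "per_microbe_counts.tsv", sep="\t", index=False)
    per_metabolite.to_csv(
        args.out / "build-network" / "per_metabolite_counts.tsv", sep="\t", index=False
    )
    print(
        f"profiles: median {per_microbe['n_consumed'].median():.0f} consumed / "
        f"{per_microbe['n_produced'].median():.0f} produced metabolites per microbe; "
        f"{len(per_metabolite)} metabolites in play"
    )


if __name__ == "__main__":
    main()
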
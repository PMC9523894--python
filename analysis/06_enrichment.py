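"""Test the study item set for overrepresented categories with the
hypergeometric upper tail and Bonferroni / Benjamini-Hochberg /
Benjamini-Yekutieli corrections, and check that the planted enriched
category tops the table.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from micropharm.pipeline import PipelineConfig, run_stage


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    config = PipelineConfig.from_dict({"out_dir": str(args.out), "seed": args.seed})
    outputs = run_stage("enrich", config)

    table = pd.read_csv(outputs["table"], sep="\t")
    sig = pd.read_csv(outputs["significant"], sep="\t")
    planted = json.loads(
        (args.out / "simulate" / "annotation_scenario.json").read_text()
    )["planted_category"]
    top = table.iloc[0]
    print(f"{len(table)} categories tested; {len(sig)} significant at alpha 0.05")
    print(
        f"top category: {top['category']} (k/K = {top['k']}/{top['K']}, "
        f"p_raw = {top['p_raw']:.2e}, Bonferroni = {top['p_bonferroni']:.2e})"
    )
    print(f"planted category {planted} "
          + ("tops the table" if top["category"] == planted else "does NOT top the table"))


if __name__ == "__main__":
    main()
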
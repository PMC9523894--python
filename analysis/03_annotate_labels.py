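"""Propagate the observed commensal/pathogenic labels over the signed network
with the signed random walk (beta = gamma = 0.5, restart 0.15), predict a
label for every unannotated microbe, and validate the rule by leave-one-out
cross-validation against the planted truth.
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
    run_stage("annotate", config)
    run_stage("loocv", config)

    summary = json.loads((args.out / "annotate" / "prediction_summary.json").read_text())
    print(
        f"annotated {summary['n_predicted_commensal'] + summary['n_predicted_pathogenic']} "
        f"unlabeled microbes: {summary['n_predicted_commensal']} predicted commensal, "
        f"{summary['n_predicted_pathogenic']} predicted pathogenic"
    )

    report = json.loads((args.out / "loocv" / "loocv.json").read_text())
    print(
        "LOOCV on the observed labels: "
        f"precision+/recall+ = {report['precision_pos']:.3f}/{report['recall_pos']:.3f}, "
        f"precision-/recall- = {report['precision_neg']:.3f}/{report['recall_neg']:.3f}, "
        f"macro F1 = {report['macro_f1']:.3f}"
    )

    # how well do the predictions agree with the planted (hidden) truth?
    truth = pd.read_csv(args.out / "simulate" / "labels_true.tsv", sep="\t")
    truth_map = dict(zip(truth["microbe_id"], truth["label"]))
    preds = pd.read_csv(args.out / "annotate" / "predictions.tsv", sep="\t", comment="#")
    agree = sum(
        truth_map[row.microbe_id] == row.predicted_label for row in preds.itertuples()
    )
    print(f"agreement with planted truth: {agree}/{len(preds)} "
          f"({agree / len(preds):.1%}) of unlabeled microbes")


if __name__ == "__main__":
    main()
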
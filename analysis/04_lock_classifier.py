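"""Lock the final classifier and evaluate it on training and validation.

Recursive feature elimination reduces the candidate set to a 7-marker
logistic panel on log2 concentrations; the decision cutoff is fixed at the
score reaching 91% specificity among training controls and then applied,
frozen, to the independent validation cohort.  Writes the locked model JSON,
the Wilson-CI performance table, and the full cutoff table (every distinct
training score with its training and validation operating characteristics).
"""

import argparse
from pathlib import Path

import pandas as pd

from evpanel import PanelSchema, read_cohort
from evpanel.diagnostic_metrics import bootstrap_auc_ci, confusion_summary, roc_curve
from evpanel.model_development import apply_classifier, fit_locked_classifier, recursive_feature_elimination
from evpanel.reporting import _cutoff_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-features", type=int, default=7)
    ap.add_argument("--target-specificity", type=float, default=0.91)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    schema = PanelSchema.from_yaml(args.data / "panel_schema.yaml")
    train = read_cohort(args.data / "train_patients.csv",
                        args.data / "train_measurements.csv", schema)
    val = read_cohort(args.data / "val_patients.csv",
                      args.data / "val_measurements.csv", schema)
    candidates = list((args.out / "candidate_features.txt").read_text().split())

    selected = recursive_feature_elimination(train, candidates, args.n_features)
    print(f"RFE panel ({args.n_features} features): {', '.join(selected)}")
    model = fit_locked_classifier(train, selected, args.target_specificity)
    model.to_json(args.out / "locked_model.json")
    print(f"locked cutoff: {model.cutoff:.6g} (target specificity {args.target_specificity:.0%})")

    rows = []
    score_sets = {}
    for name, cohort in (("training", train), ("validation", val)):
        scores, calls = apply_classifier(model, cohort)
        score_sets[name] = (scores, cohort.labels)
        auc = bootstrap_auc_ci(scores, cohort.labels, n_reps=2000, seed=args.seed)
        summary = confusion_summary(calls, cohort.labels, cohort.stages).to_frame()
        summary.insert(0, "cohort", name)
        rows.append(summary)
        print(f"\n{name}: AUC {auc.auc:.3f} (95% CI {auc.lower:.3f}-{auc.upper:.3f}, "
              f"2000 bootstrap reps)")
        for _, r in summary.iterrows():
            print(f"  {r['metric']:22s} {r['successes']:3d}/{r['n']:3d} = {r['percent']:5.1f}% "
                  f"(95% CI {r['ci_lower']:.1f}-{r['ci_upper']:.1f})")

    pd.concat(rows, ignore_index=True).to_csv(args.out / "performance.csv", index=False)
    ts, tl = score_sets["training"]
    vs, vl = score_sets["validation"]
    _cutoff_table(model, ts, tl, vs, vl).to_csv(args.out / "cutoff_table.csv", index=False)
    print(f"\nwrote locked_model.json, performance.csv, cutoff_table.csv under {args.out}")


if __name__ == "__main__":
    main()
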
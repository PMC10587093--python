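"""Apply the two pre-modelling filters to the training cohort and report the
candidate-feature narrative (panel -> reliably measured -> non-redundant).

Reliability: keep biomarkers with <=50% of patients imputed to the LLoD.
Redundancy: resolve |Pearson r| > 0.9 pairs by the two-sample KS test
against case/control status, dropping the weaker member of each pair.
"""

import argparse
from pathlib import Path

from evpanel import PanelSchema, read_cohort
from evpanel.feature_filters import FilterConfig, FilterReport, correlation_ks_filter, imputation_rate_filter


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--max-imputed", type=float, default=0.5)
    ap.add_argument("--max-corr", type=float, default=0.9)
    args = ap.parse_args()

    schema = PanelSchema.from_yaml(args.data / "panel_schema.yaml")
    cohort = read_cohort(args.data / "train_patients.csv",
                         args.data / "train_measurements.csv", schema)
    cfg = FilterConfig(max_imputed_fraction=args.max_imputed, max_abs_correlation=args.max_corr)
    report = FilterReport()
    kept = imputation_rate_filter(cohort, cfg, report)
    n0 = schema.n_biomarkers
    print(f"{n0} biomarkers -> {len(kept)} reliably measured "
          f"(<= {args.max_imputed:.0%} of patients imputed)")
    kept, removals = correlation_ks_filter(cohort, kept, cohort.labels, cfg, report)
    for rm in removals:
        print(f"  removed {rm.biomarker}: {rm.reason} "
              f"(KS p {rm.ks_p_removed:.3g} vs partner {rm.ks_p_partner:.3g})")
    print(f"-> {len(kept)} candidate features after the correlation-KS filter")
    args.out.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.out / "filter_report.csv")
    (args.out / "candidate_features.txt").write_text("\n".join(kept) + "\n")
    print(f"wrote {args.out / 'filter_report.csv'} and candidate_features.txt")


if __name__ == "__main__":
    main()
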
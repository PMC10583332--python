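#!/usr/bin/env python
"""Fit the ten Firth-penalized logistic models of clinical status.

All models control for age and sex; model 1 adds ordinal CSF A/T status,
models 2-5 add the six raw bilateral ROI means of one metric x tissue block,
models 6-9 combine both. Reports in-sample AUC with DeLong 95% CI, AIC from
the penalized log-likelihood, and the PLR against the age+sex base model.
"""


from noddinorms.cohort import read_participants, read_roi_table
from noddinorms.models import run_model_suite

from paths import RESULTS, SCRATCH


def main() -> None:
    participants = read_participants(SCRATCH / "analysis_sample.csv")
    roi = read_roi_table(SCRATCH / "cohort" / "roi_values.csv")
    roi = roi[roi["participant_id"].isin(participants["participant_id"])]

    results, fits = run_model_suite(participants, roi)
    results.to_csv(RESULTS / "model_suite.csv", index=False,
                   float_format="%.6g")
    show = results[["model_id", "model", "auc", "auc_ci_low", "auc_ci_high",
                    "aic", "plr_vs_reference"]].round(3)
    print(show.to_string(index=False))
    best = results.loc[results["model_id"].isin([6, 7, 8, 9])] \
        .sort_values("aic").iloc[0]
    print(f"\nbest combined model by AIC: {best['model']} "
          f"(AUC {best['auc']:.3f}, AIC {best['aic']:.1f})")


if __name__ == "__main__":
    main()
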
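#!/usr/bin/env python
"""Compare robust z-scores across clinical status and A/T status groups.

Kruskal-Wallis omnibus with BH-FDR within each metric x tissue block, gated
pairwise follow-up, and Cliff's delta with 95% CI. Two contrasts: CU vs
MCI/AD (all participants) and A-T- vs A+T- vs A+T+ within CU.
"""


from noddinorms.cohort import read_participants
from noddinorms.compare import compare_groups

from paths import RESULTS, SCRATCH


def main() -> None:
    import pandas as pd
    participants = read_participants(SCRATCH / "analysis_sample.csv")
    ztable = pd.read_csv(SCRATCH / "zscores.csv")
    demo = participants.set_index("participant_id")

    clinical = demo["diagnosis"].map(lambda d: "CU" if d == "CU" else "MCI/AD")
    comp = compare_groups(ztable, clinical, alpha=0.05)
    comp.to_csv(RESULTS / "comparisons_clinical.csv", index=False,
                float_format="%.6g")
    omnibus = comp[comp["contrast"] == "omnibus"]
    sig = omnibus[omnibus["p_fdr"] < 0.05]
    print(f"CU vs MCI/AD: {len(sig)}/{len(omnibus)} cells significant "
          "after FDR; significant cells:")
    print(sig[["roi_name", "metric", "p_fdr"]].to_string(index=False))

    cu = demo[demo["diagnosis"] == "CU"]
    comp_at = compare_groups(ztable[ztable["participant_id"].isin(cu.index)],
                             cu["at_status"], alpha=0.05)
    comp_at.to_csv(RESULTS / "comparisons_at.csv", index=False,
                   float_format="%.6g")
    omnibus_at = comp_at[comp_at["contrast"] == "omnibus"]
    sig_at = omnibus_at[omnibus_at["p_fdr"] < 0.05]
    print(f"\nA/T status within CU: {len(sig_at)}/{len(omnibus_at)} cells "
          "significant after FDR")
    if not sig_at.empty:
        print(sig_at[["roi_name", "metric", "p_fdr"]].to_string(index=False))


if __name__ == "__main__":
    main()
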
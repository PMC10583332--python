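#!/usr/bin/env python
"""Classify CSF A/T status and apply the analysis-sample filter.

Verifies that classification from the generated analytes reproduces the
assigned cells, and writes the exclusion ledger (A-T+ participants and
impaired participants without amyloid positivity are dropped).
"""


from noddinorms.atclass import classify_at_table, select_analysis_sample
from noddinorms.cohort import read_participants

from paths import RESULTS, SCRATCH


def main() -> None:
    participants = read_participants(SCRATCH / "cohort" / "participants.csv")
    derived = classify_at_table(participants)
    agree = (derived == participants["at_status"]).mean()
    print(f"A/T classification agrees with assigned cells for {agree:.1%} of "
          f"{len(participants)} participants")

    retained, ledger = select_analysis_sample(participants)
    retained.to_csv(SCRATCH / "analysis_sample.csv", index=False,
                    float_format="%.17g")
    ledger.to_csv(RESULTS / "exclusion_ledger.csv", index=False)
    print(f"retained {len(retained)}, excluded {len(ledger)}")
    if not ledger.empty:
        print(ledger["reason"].value_counts().to_string())


if __name__ == "__main__":
    main()
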
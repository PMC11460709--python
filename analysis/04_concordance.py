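#!/usr/bin/env python
"""Score descriptor-outcome concordance over the reference cohort.

For every patient the four binary risk descriptors of the implanted
configuration (low velocity, recirculation, high ECAP, high adhesion) are
compared with the clinical outcome: a descriptor agrees when it raises for
a DRT patient or stays quiet for a control.  Writes
results/concordance.json.
"""

import json
from pathlib import Path

from laao_dpm import tables
from laao_dpm.report import RiskRow, concordance

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    risk = tables.load_risk_descriptors()
    rows, outcomes = {}, {}
    for r in risk.itertuples():
        rows[int(r.patient)] = RiskRow(
            r.low_vel_post == "YES", r.recirc_post == "YES",
            r.ecap_post == "YES", r.adhesion_post == "YES")
        outcomes[int(r.patient)] = r.outcome
    result = concordance(rows, outcomes)

    out = RESULTS / "concordance.json"
    RESULTS.mkdir(exist_ok=True)
    out.write_text(json.dumps(result, indent=1))

    t = result["tallies"]
    full = sorted(p for p, v in result["per_patient"].items() if v == 4)
    print(f"{t['complete']} patients with 4/4 descriptor-outcome agreement "
          f"(patients {full}); {t['at_least_three']} with >= 3/4")
    zero = sorted(p for p, v in result["per_patient"].items()
                  if v == 0 and outcomes[p] == "DRT")
    print(f"DRT patients missed by every descriptor: {zero}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
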
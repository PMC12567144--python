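#!/usr/bin/env python
"""Validate the PBPK simulations against observed clinical PK.

Extracts Cmax/AUC0-t/AUC0-inf from the simulated plasma profiles by NCA
and scores Cmax and AUC0-inf against the observed clinical means with the
±20% prediction-error gate.  The simulation is accepted for lung-dose
estimation only if every metric passes.
"""

import sys
from pathlib import Path

from tbinhale import pipeline

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    OUT.mkdir(exist_ok=True)
    report = pipeline.run_dose_translation()
    print(report.pk_table.round(3).to_string())
    print()
    print(report.validation.to_text())
    report.pk_table.to_csv(OUT / "pk_table.csv")
    report.validation.table.to_csv(OUT / "validation.csv", index=False)
    (OUT / "validation.txt").write_text(report.validation.to_text() + "\n")
    return report.exit_status


if __name__ == "__main__":
    sys.exit(main())
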
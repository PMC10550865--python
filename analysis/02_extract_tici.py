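#!/usr/bin/env python
"""Step 1: rule-based TICI extraction from the radiology reports.

Mines TICI grades from each report, binarizes grade 3 vs the rest, routes
reports with no or conflicting mentions to the manual-label queue, and
checks agreement of the automatic labels against the planted truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from bccstrat.simulate import read_cohort_csv, read_reports_jsonl
from bccstrat.tici import extract_corpus

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    reports = read_reports_jsonl(str(args.results / "reports.jsonl"))
    labels = extract_corpus(reports)
    labels.to_csv(args.results / "tici_labels.csv", index=False)

    counts = labels["status"].value_counts()
    print(f"{len(labels)} reports: {counts.get('unique', 0)} with a unique grade, "
          f"{counts.get('none', 0)} without a mention, "
          f"{counts.get('multiple', 0)} with conflicting grades "
          f"-> {int((labels['outcome'] == 'needs_manual').sum())} need manual labeling")

    cohort = read_cohort_csv(str(args.results / "cohort.csv"))
    truth = json.loads((args.results / "planted_truth.json").read_text())
    merged = labels.merge(cohort[["patient_id", "recanalization"]], on="patient_id")
    merged["planted"] = merged["patient_id"].map(truth["report_labels"])
    clean = merged[merged["planted"] == "clean"]
    agree = (clean["outcome"] == clean["recanalization"]).mean()
    print(f"agreement with planted labels on clean reports: {100 * agree:.1f}% "
          f"({len(clean)} reports)")
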
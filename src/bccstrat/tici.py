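"""Rule-based extraction of TICI reperfusion grades from radiology report text.

The TICI (Thrombolysis In Cerebral Infarction) scale grades angiographic
reperfusion after thrombectomy as 0, 1, 2a, 2b, 2c or 3.  The study outcome
dichotomizes it: grade 3 is successful recanalization, everything else
(0, 1, 2a, 2b, 2c) is unsuccessful.  Reports with no TICI mention, or with
more than one distinct grade, are routed to manual labeling.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

VALID_GRADES = ("0", "1", "2a", "2b", "2c", "3")

# "TICI", "eTICI" or "mTICI" (any case), optionally followed by whitespace,
# hyphen or colon, then a grade token.  Bare "2" is not in the study's grade
# set and is deliberately not matched.
_TICI_RE = re.compile(
    r"\b[em]?tici\b[\s:\-]*(2a|2b|2c|[013])\b",
    re.IGNORECASE,
)


class GradeError(ValueError):
    """Raised for a token outside the TICI grade set."""


@dataclass
class TICIExtraction:
    """Grades found in one report, with triage status and binarized outcome."""

    patient_id: str
    grades_found: list[str]
    status: str  # unique | none | multiple
    outcome: str  # success | failure | needs_manual


def binarize(grade: str) -> str:
    """Map a TICI grade to the dichotomous study outcome (success iff 3)."""
    g = str(grade).lower()
    if g not in VALID_GRADES:
        raise GradeError(f"unknown TICI grade {grade!r}")
    return "success" if g == "3" else "failure"


def extract_tici(text: str, patient_id: str = "") -> TICIExtraction:
    """Extract TICI grades from one report.

    Repeated identical mentions count as a single grade; more than one
    *distinct* grade (or no mention at all) routes the report to manual
    labeling.
    """
    if text is None:
        text = ""
    raw = [m.group(1).lower() for m in _TICI_RE.finditer(text)]
    grades: list[str] = []
    for g in raw:
        if g not in grades:
            grades.append(g)
    if len(raw) > len(grades):
        logger.debug(
            "report %s: repeated identical TICI mentions collapsed to one "
            "(alternative reading would triage any repeat)",
            patient_id,
        )
    if len(grades) == 1:
        status, outcome = "unique", binarize(grades[0])
    elif not grades:
        status, outcome = "none", "needs_manual"
    else:
        status, outcome = "multiple", "needs_manual"
    return TICIExtraction(patient_id, grades, status, outcome)


def extract_corpus(reports: list[dict[str, str]]) -> pd.DataFrame:
    """Run extraction over ``{"patient_id", "text"}`` records.

    Returns a table with columns patient_id, grades (semicolon-joined),
    status, outcome.
    """
    rows = [extract_tici(rec.get("text", ""), str(rec.get("patient_id", ""))) for rec in reports]
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "grades": [";".join(r.grades_found) for r in rows],
            "status": [r.status for r in rows],
            "outcome": [r.outcome for r in rows],
        }
    )
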
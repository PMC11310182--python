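"""Worked example: an excerpt of a lung-cancer treatment log.

Two complete patient cases with day-granularity timestamps, using the
abbreviated activity labels common in such logs (GPE = General Physical
Examination, CTC = CT Chest, LiB = Liver Biopsy, Cal/Cre/Glu/Mag = lab
tests, ChX = Chest X-ray, Spi = Spirometry, Elc = Electrocardiogram,
ELB = Excision of Lung and Bronchus, CAS = Computer Aided Surgery,
ONOP = Other Non-Operative Procedure). Case 47777 shows the canonical
same-day collision pattern: six examinations on one day form a six-way
parallel group, and ONOP is executed twice on one day.
"""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path

from .event_log import Event, EventLog, build_log
from .sequentializer import Pattern, Rule

#: (case id, activity, category, day) — day-granularity clinical events.
EXCERPT_ROWS: tuple[tuple[str, str, str | None, str], ...] = (
    ("25480", "GPE", None, "15/05/2017"),
    ("25480", "Cre", "Examination", "15/05/2017"),
    ("25480", "Cal", "Examination", "15/05/2017"),
    ("25480", "Glu", "Examination", "15/05/2017"),
    ("25480", "Mag", "Examination", "15/05/2017"),
    ("25480", "ChX", "Examination", "15/05/2017"),
    ("25480", "Spi", "Examination", "25/05/2017"),
    ("25480", "GPE", None, "01/06/2017"),
    ("47777", "GPE", None, "17/07/2017"),
    ("47777", "CTC", "Examination", "25/07/2017"),
    ("47777", "Cal", "Examination", "25/07/2017"),
    ("47777", "Glu", "Examination", "25/07/2017"),
    ("47777", "Mag", "Examination", "25/07/2017"),
    ("47777", "Cre", "Examination", "25/07/2017"),
    ("47777", "LiB", "Examination", "25/07/2017"),
    ("47777", "Elc", "Examination", "18/08/2017"),
    ("47777", "Spi", "Examination", "18/08/2017"),
    ("47777", "ELB", "Surgery", "01/09/2017"),
    ("47777", "CAS", "Surgery", "01/09/2017"),
    ("47777", "ONOP", "Treatment", "10/09/2017"),
    ("47777", "ONOP", "Treatment", "10/09/2017"),
    ("47777", "GPE", None, "15/09/2017"),
    ("47777", "Cal", "Examination", "15/09/2017"),
    ("47777", "Glu", "Examination", "15/09/2017"),
    ("47777", "Mag", "Examination", "15/09/2017"),
    ("47777", "Cre", "Examination", "15/09/2017"),
)


def excerpt_log() -> EventLog:
    """The two-case excerpt as an in-memory event log."""
    events = [
        Event(
            case_id=case_id,
            activity=label,
            timestamp=dt.datetime.strptime(day, "%d/%m/%Y").date(),
            category=category,
        )
        for case_id, label, category, day in EXCERPT_ROWS
    ]
    return build_log(events)


def write_excerpt_csv(path: str | Path) -> None:
    """Write the excerpt in the canonical CSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Case ID", "Activity label", "Activity category", "Timestamp"])
        for case_id, label, category, day in EXCERPT_ROWS:
            writer.writerow([case_id, label, category or "-", day])


def ct_before_liver_biopsy_rule() -> Rule:
    """A chest CT scan is taken before a liver biopsy.

    Source: any parallel group containing CTC and LiB (wildcard remainder).
    Target: CTC sequentially before LiB, remainder kept parallel.
    """
    return Rule(
        name="ct-chest-before-liver-biopsy",
        source=Pattern.parse("+( 'CTC', 'LiB', ... )"),
        target=Pattern.parse("+( ->( 'CTC', 'LiB' ), ... )"),
    )
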
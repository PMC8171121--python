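"""Small bundled reference datasets used by the examples, tests and the
acceptance report: an eight-subject two-group cohort and the categorical
qPCR outcomes of a 20 + 20 candidate validation experiment."""

from __future__ import annotations

import pandas as pd

from .diffexpr import DERecord, QpcrOutcome

__all__ = ["example_cohort", "example_validation"]


def example_cohort() -> pd.DataFrame:
    """Eight orthopedic-surgery subjects, four per group, with demographics,
    comorbidities and surgery duration."""
    rows = [
        # subject, age, gender, bmi, duration, chd, cvd, hypertension, dm, group
        (1, 84, "woman", 27.5, 140, "no", "no", "no", "no", "case"),
        (2, 81, "woman", 26.7, 100, "no", "no", "no", "no", "control"),
        (3, 83, "man", 25.7, 155, "no", "yes", "no", "no", "case"),
        (4, 81, "man", 23.4, 170, "no", "no", "yes", "no", "control"),
        (5, 93, "woman", 23.7, 190, "yes", "yes", "yes", "yes", "case"),
        (6, 87, "woman", 19.5, 70, "no", "no", "no", "no", "control"),
        (7, 93, "woman", 20.8, 80, "no", "yes", "no", "no", "case"),
        (8, 86, "woman", 18.7, 120, "no", "yes", "yes", "yes", "control"),
    ]
    return pd.DataFrame(
        rows,
        columns=["subject", "age", "gender", "bmi", "surgery_duration",
                 "chd", "cvd", "hypertension", "dm", "group"],
    )


def example_validation(biotype: str) -> tuple[list[DERecord], list[QpcrOutcome]]:
    """Twenty validation candidates (10 up, 10 down) per biotype with their
    categorical qPCR outcomes.

    lncRNA panel: 7 of 10 up and 7 of 10 down confirmed, 6 unchanged.
    mRNA panel: 8 of 10 up and 6 of 10 down confirmed, 6 unchanged.
    """
    if biotype == "lncRNA":
        confirmed_up, confirmed_down = 7, 7
    elif biotype == "mRNA":
        confirmed_up, confirmed_down = 8, 6
    else:
        raise ValueError(f"unknown biotype {biotype!r}")
    candidates: list[DERecord] = []
    outcomes: list[QpcrOutcome] = []
    for direction, confirmed in (("up", confirmed_up), ("down", confirmed_down)):
        for i in range(10):
            fid = f"{biotype}_{direction}_{i + 1:02d}"
            mean_case, mean_ctrl = (3000.0, 1000.0) if direction == "up" else (1000.0, 3000.0)
            candidates.append(
                DERecord(
                    feature_id=fid,
                    biotype=biotype,
                    mean_case=mean_case,
                    mean_control=mean_ctrl,
                    fold_change=3.0,
                    direction=direction,
                    t_statistic=5.0 if direction == "up" else -5.0,
                    p_value=0.01,
                    raw_intensity=3000.0,
                    is_de=True,
                )
            )
            call = direction if i < confirmed else "unchanged"
            outcomes.append(QpcrOutcome(fid, call))
    return candidates, outcomes
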
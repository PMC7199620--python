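"""Median-split categorization of patients on clinical covariates.

Patients (SCA group) are split into low/high subgroups on reticulocyte
count, platelet count, and the death-risk severity score. The split value
defaults to the in-group median (midpoint of the central order statistics
for even n) but can be overridden with the published study cuts
(400, 450, 0.670). A value strictly above the cut is "high"; a value at
or below it is "low" — with all values distinct and even n, exactly half
the subjects land on each side.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from typing import Optional

from .core_data import COVARIATES, CohortTable


@dataclass
class SubgroupAssignment:
    covariate: str
    cut: float
    labels: dict[str, str]  # subject_id -> "low" | "high"

    def ids(self, level: str) -> list[str]:
        if level not in ("low", "high"):
            raise KeyError(f"level must be low/high, got {level!r}")
        return [sid for sid, lab in self.labels.items() if lab == level]


def median_split(
    table: CohortTable,
    covariate: str,
    group: str = "SCA",
    cut: Optional[float] = None,
) -> SubgroupAssignment:
    """Label every subject of ``group`` with a non-missing ``covariate``
    as low (value <= cut) or high (value > cut).

    With ``cut`` omitted it is the median of the group's non-missing
    values. All-identical values are all labeled low, with a warning.
    """
    if covariate not in COVARIATES:
        raise KeyError(f"unknown covariate {covariate!r}")
    usable = [
        (s.subject_id, s.covariate(covariate))
        for s in table.subjects_in(group)
        if s.covariate(covariate) is not None
    ]
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 {group} subjects with non-missing {covariate}, "
            f"found {len(usable)}"
        )
    values = [v for _, v in usable]
    if cut is None:
        cut = float(statistics.median(values))
    if len(set(values)) == 1:
        warnings.warn(
            f"all {covariate} values identical ({values[0]}); "
            "every subject labeled 'low'",
            stacklevel=2,
        )
    labels = {sid: ("high" if v > cut else "low") for sid, v in usable}
    return SubgroupAssignment(covariate=covariate, cut=float(cut), labels=labels)


def assign_all_subgroups(
    table: CohortTable,
    cuts: Optional[dict[str, float]] = None,
    group: str = "SCA",
) -> list[SubgroupAssignment]:
    """Reticulocyte, platelet and severity assignments for the patient
    group. ``cuts`` overrides the in-data medians per covariate (e.g.
    ``{"reticulocytes": 400, "platelets": 450, "severity": 0.670}``)."""
    cuts = cuts or {}
    return [
        median_split(table, cov, group=group, cut=cuts.get(cov))
        for cov in COVARIATES
    ]
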
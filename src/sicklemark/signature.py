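"""Global-median ascendant biomarker signatures and Venn partition.

The signature analysis converts continuous panel measurements into a
categorical profile: for each biomarker the median over the *whole
universe* of subjects (all groups pooled) is the cut-off; each subject is
classified high (value strictly above the cut-off) or low. A group's
ascendant signature lists biomarkers by the percentage of its subjects
classified high, sorted ascending; biomarkers with more than 50% of
subjects high form the group's selected set. Selected sets across groups
or subgroups are partitioned with exact Venn set algebra into biomarkers
common to all sets, selective to one, or shared by some.

For tie-free pooled data with even total n, every biomarker's pooled
frequency-above is exactly 50% — group-level departures from 50% are the
signal this analysis surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import CohortTable

SELECTION_THRESHOLD = 50.0  # percent of subjects, strictly above


@dataclass
class SignatureProfile:
    group: str
    #: (biomarker, % of subjects above cut-off), ascending; ties broken
    #: lexicographically by name
    entries: list[tuple[str, float]]
    #: biomarkers with freq_above strictly greater than 50%
    selected: set[str]


@dataclass
class VennPartition:
    input_sets: dict[str, set[str]]
    common_all: set[str]
    selective: dict[str, set[str]]
    #: remaining membership patterns: frozenset of set names -> biomarkers
    other_regions: dict[frozenset, set[str]]

    def regions(self) -> dict[frozenset, set[str]]:
        """Every nonempty region (disjoint; union = union of the inputs)."""
        out = {k: set(v) for k, v in self.other_regions.items() if v}
        if self.common_all:
            out[frozenset(self.input_sets)] = set(self.common_all)
        for name, members in self.selective.items():
            if members:
                out[frozenset({name})] = set(members)
        return out


def global_median_cutoffs(
    table: CohortTable,
    biomarkers: Optional[Sequence[str]] = None,
) -> dict[str, float]:
    """Per-biomarker median over all subjects pooled (the global cut-off)."""
    biomarkers = list(biomarkers) if biomarkers else table.biomarker_names
    out = {}
    for bm in biomarkers:
        values = table.values(bm)
        if len(values) < 2:
            raise ValueError(
                f"{bm}: need >= 2 non-missing values to define a cut-off, "
                f"found {len(values)}"
            )
        out[bm] = float(np.median(values))
    return out


def categorize_subjects(
    table: CohortTable, cutoffs: Mapping[str, float]
) -> pd.DataFrame:
    """Subjects x biomarkers matrix of "low"/"high" (NaN where missing).

    High means strictly above the cut-off; a value equal to the cut-off
    counts as low (it is not *above* the edge).
    """
    df = table.to_dataframe()[list(cutoffs)]
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=object)
    for bm, cut in cutoffs.items():
        col = df[bm]
        out[bm] = np.where(
            col.isna(), None, np.where(col > cut, "high", "low")
        )
    return out


def ascendant_signature(
    table: CohortTable,
    cutoffs: Mapping[str, float],
    group: Optional[str] = None,
    subject_ids: Optional[Iterable[str]] = None,
    label: Optional[str] = None,
) -> SignatureProfile:
    """Ascendant signature of a group (or an explicit subject selection).

    freq_above per biomarker = 100 x (#high / #non-missing) within the
    selection; biomarkers with no non-missing value in the selection are
    omitted; the selected set applies the strict >50% rule.
    """
    if (group is None) == (subject_ids is None):
        raise ValueError("give exactly one of group / subject_ids")
    if group is not None:
        ids = [s.subject_id for s in table.subjects_in(group)]
        label = label or group
    else:
        ids = list(subject_ids)
        label = label or "selection"
    if not ids:
        raise ValueError("empty subject selection")
    cats = categorize_subjects(table, cutoffs).loc[ids]
    entries = []
    for bm in cats.columns:
        col = cats[bm].dropna()
        if len(col) == 0:
            continue
        freq = 100.0 * (col == "high").sum() / len(col)
        entries.append((bm, float(freq)))
    entries.sort(key=lambda e: (e[1], e[0]))
    selected = {bm for bm, f in entries if f > SELECTION_THRESHOLD}
    return SignatureProfile(group=label, entries=entries, selected=selected)


def venn_partition(sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Exact set algebra over the nonempty membership patterns.

    Returns the intersection of all sets (``common_all``), the per-set
    exclusive regions (``selective``), and every other intersection cell.
    Regions are disjoint and their union equals the union of the inputs.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 named sets")
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    as_sets = {name: set(sets[name]) for name in names}
    membership: dict[str, frozenset] = {}
    for name, members in as_sets.items():
        for m in members:
            membership[m] = membership.get(m, frozenset()) | {name}
    regions: dict[frozenset, set[str]] = {}
    for m, pattern in membership.items():
        regions.setdefault(pattern, set()).add(m)
    all_names = frozenset(names)
    common_all = regions.pop(all_names, set())
    selective = {
        name: regions.pop(frozenset({name}), set()) for name in names
    }
    return VennPartition(
        input_sets=as_sets,
        common_all=common_all,
        selective=selective,
        other_regions=regions,
    )


def write_signature_tsv(profiles: Sequence[SignatureProfile], path) -> None:
    """TSV export: group, biomarker, freq_above, selected."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\tbiomarker\tfreq_above\tselected\n")
        for prof in profiles:
            for bm, freq in prof.entries:
                fh.write(
                    f"{prof.group}\t{bm}\t{freq!r}\t{bm in prof.selected}\n"
                )


def write_venn_tsv(partition: VennPartition, path) -> None:
    """TSV export: biomarker, membership pattern (sorted, '+'-joined)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("biomarker\tmembership\n")
        for pattern, members in sorted(
            partition.regions().items(), key=lambda kv: sorted(kv[0])
        ):
            tag = "+".join(sorted(pattern))
            for m in sorted(members):
                fh.write(f"{m}\t{tag}\n")
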
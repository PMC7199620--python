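"""Cohort data model, the multiplex panel registry, and delimited-text I/O.

The package analyses case/control multiplex immunology panels: each subject
belongs to a group — sickle cell anemia patients at steady state (``SCA``)
or healthy blood donors (``HD``) — and carries clinical covariates
(reticulocyte count, platelet count, death-risk severity score) plus
measurements of biomarkers in three unit classes:

* ``percent`` — gated cell-phenotype frequencies, bounded in [0, 100];
* ``mfi`` — receptor expression as mean fluorescence intensity;
* ``pg_per_ml`` — serum analyte concentrations from a bead-based
  immunoassay, each with a limit of detection (LOD) below which values
  are censored.

:class:`CohortTable` is the universal currency passed between every
analysis stage.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

GROUPS = ("HD", "SCA")

CATEGORIES = (
    "cell_phenotype",
    "tlr_expression",
    "adhesion_expression",
    "cytokine",
    "chemokine",
    "growth_factor",
)

UNITS = ("percent", "mfi", "pg_per_ml")

COVARIATES = ("reticulocytes", "platelets", "severity")

#: Greek-letter and typographic variants accepted on input, mapped to the
#: canonical ASCII names used everywhere inside the package.
ALIASES = {
    "IL-1β": "IL-1b",
    "IL-1ß": "IL-1b",
    "TNF-α": "TNF-a",
    "IFN-γ": "IFN-g",
    "MIP-1α": "MIP-1a",
    "MIP-1β": "MIP-1b",
}


def canonical_name(name: str) -> str:
    """Map a biomarker name to its canonical ASCII form."""
    return ALIASES.get(name.strip(), name.strip())


class CohortValidationError(ValueError):
    """Raised when a cohort file or table violates the data model."""


@dataclass(frozen=True)
class BiomarkerDescriptor:
    """One panel analyte or cell phenotype.

    ``lod`` (limit of detection, pg/mL) is present exactly for serum
    analytes (``unit == "pg_per_ml"``).
    """

    name: str
    category: str
    unit: str
    subcategory: Optional[str] = None
    lod: Optional[float] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.unit == "pg_per_ml") != (self.lod is not None):
            raise ValueError(
                f"{self.name}: lod must be present iff unit is pg_per_ml"
            )
        if self.lod is not None and self.lod < 0:
            raise ValueError(f"{self.name}: negative lod")


@dataclass(frozen=True)
class Measurement:
    value: float
    censored: bool = False


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    sex: Optional[str] = None
    age: Optional[float] = None
    reticulocytes: Optional[float] = None
    platelets: Optional[float] = None
    severity: Optional[float] = None
    measurements: dict[str, Measurement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortValidationError(
                f"{self.subject_id}: group must be one of {GROUPS}, "
                f"got {self.group!r}"
            )
        if self.severity is not None and not 0.0 <= self.severity <= 1.0:
            raise CohortValidationError(
                f"{self.subject_id}: severity {self.severity} outside [0, 1]"
            )

    def covariate(self, name: str) -> Optional[float]:
        if name not in COVARIATES:
            raise KeyError(f"unknown covariate {name!r}")
        return getattr(self, name)


@dataclass
class CohortTable:
    """Subjects × biomarkers with group labels and clinical covariates."""

    registry: list[BiomarkerDescriptor]
    subjects: list[SubjectRecord]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        names = [d.name for d in self.registry]
        if len(set(names)) != len(names):
            raise CohortValidationError("duplicate biomarker names in registry")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject_id: {dupes}")
        by_name = self.registry_by_name
        for s in self.subjects:
            for bm, m in s.measurements.items():
                if bm not in by_name:
                    raise CohortValidationError(
                        f"{s.subject_id}: biomarker {bm!r} not in registry"
                    )
                if m.value < 0 or not math.isfinite(m.value):
                    raise CohortValidationError(
                        f"{s.subject_id}: invalid value {m.value} for {bm}"
                    )
                desc = by_name[bm]
                if desc.unit == "percent" and not 0.0 <= m.value <= 100.0:
                    raise CohortValidationError(
                        f"{s.subject_id}: percent value {m.value} for {bm} "
                        "outside [0, 100]"
                    )
                if m.censored and desc.unit != "pg_per_ml":
                    raise CohortValidationError(
                        f"{s.subject_id}: censored flag on non-serum "
                        f"biomarker {bm}"
                    )

    # -- convenience accessors -------------------------------------------

    @property
    def registry_by_name(self) -> dict[str, BiomarkerDescriptor]:
        return {d.name: d for d in self.registry}

    @property
    def biomarker_names(self) -> list[str]:
        return [d.name for d in self.registry]

    def subjects_in(self, group: str) -> list[SubjectRecord]:
        if group not in GROUPS:
            raise KeyError(f"unknown group {group!r}")
        return [s for s in self.subjects if s.group == group]

    def values(
        self, biomarker: str, subject_ids: Optional[Iterable[str]] = None
    ) -> list[float]:
        """Non-missing values of one biomarker, optionally restricted."""
        keep = None if subject_ids is None else set(subject_ids)
        out = []
        for s in self.subjects:
            if keep is not None and s.subject_id not in keep:
                continue
            m = s.measurements.get(biomarker)
            if m is not None:
                out.append(m.value)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Subjects × biomarkers value matrix (NaN = missing), indexed by
        subject_id, with group and covariates as leading columns."""
        rows = {}
        for s in self.subjects:
            row: dict[str, object] = {
                "group": s.group,
                "reticulocytes": s.reticulocytes,
                "platelets": s.platelets,
                "severity": s.severity,
            }
            for bm in self.biomarker_names:
                m = s.measurements.get(bm)
                row[bm] = math.nan if m is None else m.value
            rows[s.subject_id] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "subject_id"
        return df


# ---------------------------------------------------------------------------
# Built-in panel
# ---------------------------------------------------------------------------

# 23 serum analytes with the assay's limits of detection (pg/mL).
_SERUM_PANEL = [
    # (name, category, subcategory, lod)
    ("IL-1b", "cytokine", "inflammatory", 8.608),
    ("IL-6", "cytokine", "inflammatory", 37.680),
    ("TNF-a", "cytokine", "inflammatory", 64.803),
    ("IL-12", "cytokine", "Th1", 37.684),
    ("IFN-g", "cytokine", "Th1", 25.411),
    ("IL-2", "cytokine", "Th1", 18.297),
    ("IL-7", "cytokine", None, 16.593),
    ("IL-4", "cytokine", "Th2", 4.789),
    ("IL-5", "cytokine", "Th2", 23.105),
    ("IL-13", "cytokine", "Th2", 8.090),
    ("IL-17", "cytokine", "Th17", 28.850),
    ("IL-10", "cytokine", "regulatory", 35.170),
    ("IL-8", "chemokine", None, 42.150),
    ("IP-10", "chemokine", None, 31.236),
    ("MIP-1a", "chemokine", None, 960.0),
    ("MIP-1b", "chemokine", None, 11.233),
    ("MCP-1", "chemokine", None, 24.282),
    ("RANTES", "chemokine", None, 16.533),
    ("VEGF", "growth_factor", None, 29.464),
    ("FGF-basic", "growth_factor", None, 16.046),
    ("PDGF", "growth_factor", None, 24.721),
    ("GM-CSF", "growth_factor", None, 12.844),
    ("G-CSF", "growth_factor", None, 40.049),
]

# Gated cell-phenotype frequencies (%).
_CELL_PANEL = [
    "NEU",            # neutrophils
    "CD11b+NEU",      # activated (Mac-1+) neutrophils
    "MON",            # total monocytes
    "CD14+CD16+MON",  # activated inflammatory monocytes
    "mDC",
    "pDC",
    "NK",
    "NKT",
    "LYM",
    "CD4+T",
    "CD8+T",
    "CD4+CD69+",
    "CD8+CD69+",
    "Treg",           # CD4+CD25+FoxP3+
    "B",              # CD5-CD19+
    "B1",             # CD5+CD19+
]

# Receptor expression (MFI): Toll-like receptors on monocytes/neutrophils.
_TLR_PANEL = [
    "TLR2MON", "TLR2NEU", "TLR4MON", "TLR4NEU", "TLR9MON", "TLR9NEU",
]

# Adhesion molecule expression (MFI): Mac-1 (CD11b) and VLA-4 (CD49d) on
# T-cell subsets.
_ADHESION_PANEL = [
    "CD4+CD11b+", "CD8+CD11b+", "CD4+CD49d+", "CD8+CD49d+",
]


def builtin_panel_registry() -> list[BiomarkerDescriptor]:
    """The study panel: 23 serum analytes with LODs plus the cell-phenotype
    and receptor/adhesion-expression markers."""
    out = [
        BiomarkerDescriptor(n, cat, "pg_per_ml", sub, lod)
        for n, cat, sub, lod in _SERUM_PANEL
    ]
    out += [
        BiomarkerDescriptor(n, "cell_phenotype", "percent")
        for n in _CELL_PANEL
    ]
    out += [BiomarkerDescriptor(n, "tlr_expression", "mfi") for n in _TLR_PANEL]
    out += [
        BiomarkerDescriptor(n, "adhesion_expression", "mfi")
        for n in _ADHESION_PANEL
    ]
    return out


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = ("subject_id", "group", "sex", "age") + COVARIATES


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort as UTF-8 CSV, one row per subject, full-precision
    decimals; ``read_cohort`` of the output reproduces the table."""
    header = list(_META_COLUMNS) + table.biomarker_names
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for s in table.subjects:
            row = [
                s.subject_id,
                s.group,
                s.sex or "",
                _fmt(s.age),
                _fmt(s.reticulocytes),
                _fmt(s.platelets),
                _fmt(s.severity),
            ]
            for bm in table.biomarker_names:
                m = s.measurements.get(bm)
                row.append("" if m is None else _fmt(m.value))
            w.writerow(row)


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else repr(float(x))


def read_cohort(
    path: str | Path,
    registry: Optional[Sequence[BiomarkerDescriptor]] = None,
) -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-made in
    the same dialect) and validate it against ``registry`` (built-in panel
    by default).

    Censoring flags are re-derived from the registry: a serum value at or
    below its LOD is flagged censored.
    """
    registry = list(registry) if registry is not None else builtin_panel_registry()
    by_name = {d.name: d for d in registry}

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortValidationError(f"{path}: empty file") from None
        header = [canonical_name(h) for h in header]
        if header[: len(_META_COLUMNS)] != list(_META_COLUMNS):
            raise CohortValidationError(
                f"{path}: header must start with {', '.join(_META_COLUMNS)}"
            )
        bm_cols = header[len(_META_COLUMNS):]
        unknown = [c for c in bm_cols if c not in by_name]
        if unknown:
            raise CohortValidationError(
                f"{path}: unknown biomarker column(s): {', '.join(unknown)}"
            )
        subjects = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            meta = dict(zip(_META_COLUMNS, row))
            measurements: dict[str, Measurement] = {}
            for bm, cell in zip(bm_cols, row[len(_META_COLUMNS):]):
                if cell == "":
                    continue
                value = float(cell)
                if value < 0:
                    raise CohortValidationError(
                        f"{path}:{lineno}: negative measurement {value} "
                        f"for {bm}"
                    )
                desc = by_name[bm]
                censored = desc.lod is not None and value <= desc.lod
                measurements[bm] = Measurement(value, censored)
            subjects.append(
                SubjectRecord(
                    subject_id=meta["subject_id"],
                    group=meta["group"],
                    sex=meta["sex"] or None,
                    age=_opt_float(meta["age"]),
                    reticulocytes=_opt_float(meta["reticulocytes"]),
                    platelets=_opt_float(meta["platelets"]),
                    severity=_opt_float(meta["severity"]),
                    measurements=measurements,
                )
            )
    return CohortTable(registry=registry, subjects=subjects)


def _opt_float(cell: str) -> Optional[float]:
    return None if cell == "" else float(cell)


def write_registry(
    registry: Sequence[BiomarkerDescriptor], path: str | Path
) -> None:
    """Export a registry as CSV (name, category, subcategory, unit, lod)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "category", "subcategory", "unit", "lod"])
        for d in registry:
            w.writerow(
                [d.name, d.category, d.subcategory or "", d.unit, _fmt(d.lod)]
            )
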
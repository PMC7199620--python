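"""Nonparametric group comparisons and healthy-donor reference intervals.

Patients vs healthy donors are compared per biomarker with the two-tailed
Mann-Whitney U test; low/high patient subgroups against the donor group
with Kruskal-Wallis followed by Dunn's pairwise post-hoc test (Bonferroni
over the pairs within one family). Significance is per-biomarker at
alpha = 0.05, with no correction across biomarkers (an optional
Benjamini-Hochberg FDR flag exists but is off by default). Healthy-donor
interquartile ranges serve as the reference band against which patient
levels are called above/below/within.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_data import COVARIATES, CohortTable
from .stratify import median_split

ALPHA = 0.05


@dataclass
class ComparisonResult:
    biomarker: str
    contrast: str
    statistic: float  # U (two groups) or H (omnibus)
    p: float
    significant: bool
    pairwise: Optional[list[tuple[tuple[str, str], float, float]]] = None
    direction: Optional[str] = None  # above | below | within HD reference


@dataclass(frozen=True)
class ReferenceInterval:
    biomarker: str
    q25: float
    q75: float


def mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    U counts (x_i, y_j) pairs with x_i > y_j plus half the tied pairs.
    The p-value is exact (full enumeration over rank assignments) for
    tie-free samples with combined N <= 12, otherwise the normal
    approximation with tie and continuity corrections.
    """
    x, y = list(x), list(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = x + y
    tie_free = len(set(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(pooled) <= 12) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H on midranks with tie correction; p from the
    chi-square approximation with k-1 degrees of freedom."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 values")
    flat = [v for g in groups for v in g]
    if len(set(flat)) == 1:  # scipy rejects all-identical data
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjust: str = "bonferroni",
    names: Optional[Sequence[str]] = None,
) -> list[tuple[tuple[str, str], float, float]]:
    """Dunn's rank-based pairwise post-hoc test after Kruskal-Wallis.

    For each pair (i, j):
        z = (rbar_i - rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))
    with tie term T = sum(t^3 - t) / (12 (N - 1)). Two-tailed normal p,
    multiplied by the number of pairs under ``bonferroni`` (capped at 1).
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 values")
    names = list(names) if names is not None else [
        f"g{i + 1}" for i in range(len(groups))
    ]
    sizes = [len(g) for g in groups]
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = len(flat)
    ranks = stats.rankdata(flat)
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    _, counts = np.unique(flat, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, n_pairs * p)
        out.append(((names[i], names[j]), float(z), float(p)))
    return out


def hd_reference_interval(
    table: CohortTable, biomarker: str
) -> ReferenceInterval:
    """Healthy-donor interquartile range (25th-75th percentile, linear
    interpolation between order statistics)."""
    values = table.values(
        biomarker, (s.subject_id for s in table.subjects_in("HD"))
    )
    if len(values) < 4:
        raise ValueError(
            f"need >= 4 HD values for {biomarker}, found {len(values)}"
        )
    q25, q75 = np.quantile(values, [0.25, 0.75])
    return ReferenceInterval(biomarker, float(q25), float(q75))


def _direction(values: Sequence[float], ref: ReferenceInterval) -> str:
    med = float(np.median(values))
    if med > ref.q75:
        return "above"
    if med < ref.q25:
        return "below"
    return "within"


def compare_all(
    table: CohortTable,
    scheme: str = "hd_vs_sca",
    alpha: float = ALPHA,
    cuts: Optional[dict[str, float]] = None,
    fdr: bool = False,
) -> list[ComparisonResult]:
    """Run the full comparison battery over every biomarker.

    ``hd_vs_sca``: Mann-Whitney per biomarker (U for HD-over-SCA pairs).
    ``subgroups``: per clinical covariate, Kruskal-Wallis over
    (HD, patient-low, patient-high) followed by Dunn's post-hoc;
    covariates without data are skipped. ``fdr=True`` replaces the raw
    significance calls with Benjamini-Hochberg-adjusted ones across the
    biomarkers of each contrast.
    """
    if scheme not in ("hd_vs_sca", "subgroups"):
        raise ValueError(f"unknown scheme {scheme!r}")
    hd_ids = [s.subject_id for s in table.subjects_in("HD")]
    sca_ids = [s.subject_id for s in table.subjects_in("SCA")]
    if not hd_ids or not sca_ids:
        raise ValueError("both HD and SCA subjects are required")

    results: list[ComparisonResult] = []
    if scheme == "hd_vs_sca":
        for bm in table.biomarker_names:
            hd = table.values(bm, hd_ids)
            sca = table.values(bm, sca_ids)
            u, p = mann_whitney(hd, sca)
            direction = None
            if len(hd) >= 4:
                direction = _direction(sca, hd_reference_interval(table, bm))
            results.append(
                ComparisonResult(
                    bm, "HD vs SCA", u, p, p < alpha, direction=direction
                )
            )
    else:
        assignments = []
        for cov in COVARIATES:
            usable = sum(
                s.covariate(cov) is not None for s in table.subjects_in("SCA")
            )
            if usable >= 2:
                assignments.append(
                    median_split(table, cov, cut=(cuts or {}).get(cov))
                )
        if not assignments:
            raise ValueError("no usable covariates for subgroup comparisons")
        for assignment in assignments:
            low_ids = assignment.ids("low")
            high_ids = assignment.ids("high")
            contrast = (
                f"HD vs {assignment.covariate}-low "
                f"vs {assignment.covariate}-high"
            )
            for bm in table.biomarker_names:
                groups = [
                    table.values(bm, hd_ids),
                    table.values(bm, low_ids),
                    table.values(bm, high_ids),
                ]
                h, p = kruskal_wallis(groups)
                pairwise = dunn_posthoc(
                    groups, names=("HD", "low", "high")
                )
                results.append(
                    ComparisonResult(bm, contrast, h, p, p < alpha, pairwise)
                )
    if fdr:
        _apply_fdr(results, alpha)
    return results


def _apply_fdr(results: list[ComparisonResult], alpha: float) -> None:
    from statsmodels.stats.multitest import multipletests

    by_contrast: dict[str, list[ComparisonResult]] = {}
    for r in results:
        by_contrast.setdefault(r.contrast, []).append(r)
    for rs in by_contrast.values():
        reject, _, _, _ = multipletests(
            [r.p for r in rs], alpha=alpha, method="fdr_bh"
        )
        for r, rej in zip(rs, reject):
            r.significant = bool(rej)


def write_results_tsv(results: Sequence[ComparisonResult], path) -> None:
    """TSV export: biomarker, contrast, statistic, p, significant,
    direction relative to the HD reference interval."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("biomarker\tcontrast\tstatistic\tp\tsignificant\tdirection\n")
        for r in results:
            fh.write(
                f"{r.biomarker}\t{r.contrast}\t{r.statistic!r}\t{r.p!r}\t"
                f"{r.significant}\t{r.direction or ''}\n"
            )
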
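"""Spearman correlation networks with Taylor strength categories.

Every unordered biomarker pair within a subject selection is tested with
Spearman's rank correlation; pairs significant at p < alpha (0.05, raw —
no correction across pairs) become undirected edges. Each edge carries the
sign of r and a strength class on |r| with cut-points 0.36 and 0.68
(weak < 0.36 <= moderate <= 0.68 < strong). Missing values are deleted
pairwise, with the number of complete pairs recorded per edge.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .core_data import CohortTable

log = logging.getLogger(__name__)

ALPHA = 0.05

#: |r| cut-points of the Taylor strength classes.
MODERATE_MIN = 0.36
STRONG_MIN = 0.68  # strong is strictly above this


class UndefinedCorrelationError(ValueError):
    """Raised when either variable has zero rank variance."""


@dataclass(frozen=True)
class CorrelationEdge:
    pair: tuple[str, str]
    r: float
    p: float
    n: int
    sign: str       # positive | negative
    strength: str   # weak | moderate | strong


@dataclass
class BiomarkerNetwork:
    group: str
    nodes: list[str]
    edges: list[CorrelationEdge]

    def __post_init__(self) -> None:
        seen = set()
        node_set = set(self.nodes)
        for e in self.edges:
            key = frozenset(e.pair)
            if len(key) != 2:
                raise ValueError(f"self-edge on {e.pair[0]}")
            if key in seen:
                raise ValueError(f"duplicate edge {e.pair}")
            seen.add(key)
            if not key <= node_set:
                raise ValueError(f"edge endpoint outside nodes: {e.pair}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(group=self.group)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                *e.pair, r=e.r, p=e.p, n=e.n, sign=e.sign, strength=e.strength
            )
        return g


# ---------------------------------------------------------------------------
# Spearman correlation with an exact small-sample p
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _exact_rho_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique Spearman rho values over all n! rank permutations,
    with their counts (null distribution for tie-free samples)."""
    base = np.arange(1, n + 1, dtype=float)
    rhos = [
        _rank_pearson(base, np.asarray(perm, dtype=float))
        for perm in itertools.permutations(base)
    ]
    values, counts = np.unique(np.round(rhos, 12), return_counts=True)
    return values, counts


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, int]:
    """Spearman rank correlation with two-tailed p.

    Missing values (NaN/None) are removed pairwise; at least 3 complete
    pairs are required. r is the Pearson correlation of midranks. The p is
    exact (full permutation enumeration) for tie-free samples with
    n <= 8, otherwise the t-approximation with n - 2 degrees of freedom.
    """
    xa = np.asarray([math.nan if v is None else v for v in x], dtype=float)
    ya = np.asarray([math.nan if v is None else v for v in y], dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = len(xa)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, found {n}")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise UndefinedCorrelationError(
            "zero variance: Spearman correlation undefined"
        )
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    r = _rank_pearson(rx, ry)

    tie_free = len(set(xa)) == n and len(set(ya)) == n
    if tie_free and n <= 8:
        values, counts = _exact_rho_distribution(n)
        # two-tailed: mass at least as extreme as |r| (tolerant comparison)
        mask = np.abs(values) >= abs(r) - 1e-9
        p = float(counts[mask].sum() / counts.sum())
    else:
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p, n


def taylor_category(r: float) -> tuple[str, str]:
    """(sign, strength) of a correlation coefficient.

    Sign is negative for r < 0. Strength on |r|: weak below 0.36,
    moderate in the closed band [0.36, 0.68], strong strictly above 0.68.
    """
    if not -1.0 <= r <= 1.0 or math.isnan(r):
        raise ValueError(f"r must lie in [-1, 1], got {r}")
    sign = "negative" if r < 0 else "positive"
    a = abs(r)
    if a > STRONG_MIN:
        strength = "strong"
    elif a >= MODERATE_MIN:
        strength = "moderate"
    else:
        strength = "weak"
    return sign, strength


# ---------------------------------------------------------------------------
# Network assembly and summaries
# ---------------------------------------------------------------------------

def build_network(
    table: CohortTable,
    subject_ids: Iterable[str],
    biomarkers: Optional[Sequence[str]] = None,
    alpha: float = ALPHA,
    group: str = "",
) -> BiomarkerNetwork:
    """Correlation network over a subject selection.

    All unordered pairs of ``biomarkers`` (default: the whole registry)
    are tested; edges are retained iff p < alpha and categorized by
    :func:`taylor_category`. Pairs with undefined correlations or fewer
    than 3 complete pairs are skipped with a logged warning.
    """
    ids = list(subject_ids)
    if len(ids) < 3:
        raise ValueError(f"need >= 3 subjects, found {len(ids)}")
    biomarkers = list(biomarkers) if biomarkers else table.biomarker_names
    df = table.to_dataframe().loc[ids, biomarkers]
    edges = []
    for b1, b2 in itertools.combinations(biomarkers, 2):
        try:
            r, p, n = spearman(df[b1].to_numpy(), df[b2].to_numpy())
        except (UndefinedCorrelationError, ValueError) as exc:
            log.warning("skipping pair %s~%s: %s", b1, b2, exc)
            continue
        if p < alpha:
            sign, strength = taylor_category(r)
            edges.append(CorrelationEdge((b1, b2), r, p, n, sign, strength))
    return BiomarkerNetwork(group=group, nodes=biomarkers, edges=edges)


def build_group_network(
    table: CohortTable,
    group: str,
    biomarkers: Optional[Sequence[str]] = None,
    alpha: float = ALPHA,
) -> BiomarkerNetwork:
    """Network for one whole group (HD or SCA)."""
    ids = [s.subject_id for s in table.subjects_in(group)]
    return build_network(table, ids, biomarkers, alpha, group=group)


def network_summary(net: BiomarkerNetwork) -> dict:
    """Edge counts by sign x strength, node degrees, component count."""
    counts = {
        f"{sign}_{strength}": 0
        for sign in ("positive", "negative")
        for strength in ("weak", "moderate", "strong")
    }
    for e in net.edges:
        counts[f"{e.sign}_{e.strength}"] += 1
    g = net.to_networkx()
    return {
        "group": net.group,
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "edge_counts": counts,
        "degrees": dict(g.degree()),
        "n_components": nx.number_connected_components(g) if net.nodes else 0,
    }


def find_triads(net: BiomarkerNetwork) -> list[dict]:
    """All 3-cliques (triads), each annotated with its edge signs."""
    g = net.to_networkx()
    triads = []
    for clique in nx.enumerate_all_cliques(g):
        if len(clique) > 3:
            break
        if len(clique) != 3:
            continue
        trio = tuple(sorted(clique))
        signs = {
            (a, b): g.edges[a, b]["sign"]
            for a, b in itertools.combinations(trio, 2)
        }
        triads.append({"nodes": trio, "signs": signs})
    return triads


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_TSV_HEADER = "source\ttarget\tr\tp\tn\tsign\tstrength\n"


def export_edge_list(net: BiomarkerNetwork, path, format: str = "tsv") -> None:
    """Write the edge list for downstream graph tools.

    ``sif``: lines ``source sign_strength target``;
    ``tsv``: columns source, target, r, p, n, sign, strength;
    ``graphml``: GraphML with the same edge attributes.
    """
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for e in net.edges:
                fh.write(f"{e.pair[0]} {e.sign}_{e.strength} {e.pair[1]}\n")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_TSV_HEADER)
            for e in net.edges:
                fh.write(
                    f"{e.pair[0]}\t{e.pair[1]}\t{e.r!r}\t{e.p!r}\t{e.n}\t"
                    f"{e.sign}\t{e.strength}\n"
                )
    elif format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_edge_list_tsv(path, group: str = "") -> BiomarkerNetwork:
    """Re-read a TSV edge list written by :func:`export_edge_list`."""
    edges = []
    nodes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header != _TSV_HEADER:
            raise ValueError(f"{path}: not an edge-list TSV")
        for line in fh:
            s, t, r, p, n, sign, strength = line.rstrip("\n").split("\t")
            edges.append(
                CorrelationEdge(
                    (s, t), float(r), float(p), int(n), sign, strength
                )
            )
            for node in (s, t):
                if node not in nodes:
                    nodes.append(node)
    return BiomarkerNetwork(group=group, nodes=nodes, edges=edges)
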
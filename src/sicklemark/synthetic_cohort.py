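"""Synthetic cohort generator with known ground truth.

Real panel data for this study design are not publicly deposited, so the
generator reproduces the *structure* the analysis assumes and provides the
ground truth that recovery tests need:

* two groups (healthy donors and SCA patients, default 70 vs 30);
* positive marginals — log-normal for concentrations (pg/mL) and receptor
  expression (MFI), logit-normal for bounded cell frequencies (%);
* directional group effects as fold changes on the location (median);
* injectable pairwise Spearman correlations via a Gaussian copula, using
  the latent-Pearson map rho_lat = 2*sin(pi*rho_s/6) so that requested
  rank correlations are met under the monotone marginal transforms;
* clinical covariates (reticulocytes, platelets, severity) with medians at
  the study's split points (400, 450, 0.670);
* limit-of-detection censoring of serum analytes through the same policy
  the analysis applies.

Identical config (including seed) always yields an identical cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .core_data import (
    BiomarkerDescriptor,
    CohortTable,
    Measurement,
    SubjectRecord,
    builtin_panel_registry,
)
from .luminex_quant import DEFAULT_CENSORING_POLICY, apply_lod_censoring


class InfeasibleCorrelationError(ValueError):
    """The requested correlation specs do not form a valid (positive
    definite) latent correlation matrix."""


@dataclass(frozen=True)
class Selector:
    """A subject-set condition: a group, optionally restricted to the
    low/high subgroup of a covariate (subgroup labels are re-derived by a
    median split within the generated group)."""

    group: str
    covariate: Optional[str] = None
    level: Optional[str] = None  # "low" | "high"

    def __post_init__(self) -> None:
        if (self.covariate is None) != (self.level is None):
            raise ValueError("covariate and level must be given together")
        if self.level is not None and self.level not in ("low", "high"):
            raise ValueError(f"level must be low/high, got {self.level!r}")


@dataclass(frozen=True)
class EffectSpec:
    """Multiplies the location (median) of one biomarker within a selector."""

    biomarker: str
    selector: Selector
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


@dataclass(frozen=True)
class CorrelationSpec:
    """Target Spearman correlation between two biomarkers within a group."""

    pair: tuple[str, str]
    selector: Selector
    rho: float

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if self.pair[0] == self.pair[1]:
            raise ValueError("pair must name two distinct biomarkers")


@dataclass(frozen=True)
class Baseline:
    """Marginal distribution of one biomarker (or covariate).

    ``location`` is the median on the natural scale; ``cv`` the coefficient
    of variation on the natural scale (log-normal: sigma = sqrt(ln(1+cv^2));
    logit-normal: latent sigma ~ cv/(1-p) by the delta method, capped at
    2.5 so extreme medians stay usable).
    """

    family: str  # "lognormal" | "logitnormal"
    location: float
    cv: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "logitnormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.location <= 0 or self.cv <= 0:
            raise ValueError("location and cv must be positive")


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic cohort."""

    n_hd: int = 70
    n_sca: int = 30
    seed: int = 0
    registry: list[BiomarkerDescriptor] = field(
        default_factory=builtin_panel_registry
    )
    baselines: dict[str, Baseline] = field(default_factory=dict)
    effects: list[EffectSpec] = field(default_factory=list)
    correlations: list[CorrelationSpec] = field(default_factory=list)
    #: covariate -> group -> Baseline (severity's logit-normal lives on (0,1))
    covariates: dict[str, dict[str, Baseline]] = field(default_factory=dict)
    censoring_policy: str = DEFAULT_CENSORING_POLICY

    def __post_init__(self) -> None:
        if self.n_hd < 2 or self.n_sca < 2:
            raise ValueError("need at least 2 subjects per group")
        names = {d.name for d in self.registry}
        if not self.baselines:
            self.baselines = default_baselines(self.registry)
        for bm in self.baselines:
            if bm not in names:
                raise ValueError(f"baseline for unknown biomarker {bm!r}")
        for e in self.effects:
            if e.biomarker not in names:
                raise ValueError(f"effect on unknown biomarker {e.biomarker!r}")
        for c in self.correlations:
            for bm in c.pair:
                if bm not in names:
                    raise ValueError(
                        f"correlation on unknown biomarker {bm!r}"
                    )

    # -- structured-text round trip --------------------------------------

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        raw = json.loads(text)
        raw["registry"] = [BiomarkerDescriptor(**d) for d in raw["registry"]]
        raw["baselines"] = {
            k: Baseline(**v) for k, v in raw["baselines"].items()
        }
        raw["effects"] = [
            EffectSpec(e["biomarker"], Selector(**e["selector"]),
                       e["fold_change"])
            for e in raw["effects"]
        ]
        raw["correlations"] = [
            CorrelationSpec(tuple(c["pair"]), Selector(**c["selector"]),
                            c["rho"])
            for c in raw["correlations"]
        ]
        raw["covariates"] = {
            cov: {g: Baseline(**b) for g, b in per_group.items()}
            for cov, per_group in raw["covariates"].items()
        }
        return cls(**raw)


# ---------------------------------------------------------------------------
# Defaults: the study conditions
# ---------------------------------------------------------------------------

# Plausible healthy-donor medians for gated cell frequencies (% of the
# parent population under each gating strategy).
_CELL_MEDIANS = {
    "NEU": 55.0, "CD11b+NEU": 8.0, "MON": 6.0, "CD14+CD16+MON": 4.0,
    "mDC": 0.5, "pDC": 0.4, "NK": 10.0, "NKT": 4.0, "LYM": 30.0,
    "CD4+T": 40.0, "CD8+T": 25.0, "CD4+CD69+": 2.0, "CD8+CD69+": 2.0,
    "Treg": 3.0, "B": 10.0, "B1": 1.5,
}

_DEFAULT_MFI_MEDIAN = 300.0
_SERUM_LOCATION_PER_LOD = 3.0  # healthy-donor median as a multiple of LOD

# Biomarkers reported higher in SCA patients than healthy donors.
_UP_IN_SCA_SERUM = (
    "IL-1b", "IL-6", "IL-12", "IFN-g", "IL-4", "IL-17", "IL-10",
    "IL-8", "IP-10", "MIP-1a", "MIP-1b", "RANTES",
    "VEGF", "FGF-basic", "GM-CSF",
)
_UP_IN_SCA_CELL = (
    "CD14+CD16+MON", "B1", "B", "LYM", "CD4+CD69+", "CD8+CD69+",
    "TLR9MON", "TLR9NEU", "CD4+CD11b+",
)
# Biomarkers reported lower in SCA patients.
_DOWN_IN_SCA_SERUM = ("IL-2", "IL-13")
_DOWN_IN_SCA_CELL = (
    "CD4+T", "CD8+T", "NEU", "NK", "NKT", "mDC", "pDC", "CD8+CD11b+",
)

_SERUM_FOLD_UP = 2.0
_SERUM_FOLD_DOWN = 0.5
_CELL_FOLD_UP = 1.5
_CELL_FOLD_DOWN = 0.6

# Correlation pairs consistently reported in the patient networks.
_SCA_CORRELATIONS = (
    (("IL-17", "MIP-1b"), 0.7),
    (("IL-12", "VEGF"), 0.7),
    (("IL-10", "IP-10"), 0.7),
)


def default_baselines(
    registry: Sequence[BiomarkerDescriptor],
) -> dict[str, Baseline]:
    """Healthy-donor marginals for a registry: log-normal at 3x LOD for
    serum analytes, log-normal MFI for receptor expression, logit-normal
    frequencies for cell phenotypes."""
    out: dict[str, Baseline] = {}
    for d in registry:
        if d.unit == "pg_per_ml":
            out[d.name] = Baseline(
                "lognormal", _SERUM_LOCATION_PER_LOD * max(d.lod, 1e-9)
            )
        elif d.unit == "percent":
            out[d.name] = Baseline(
                "logitnormal", _CELL_MEDIANS.get(d.name, 5.0)
            )
        else:
            out[d.name] = Baseline("lognormal", _DEFAULT_MFI_MEDIAN)
    return out


def default_sca_config(seed: int = 0) -> SyntheticConfig:
    """The study conditions: 70 healthy donors vs 30 SCA patients, the
    reported direction of every group effect, the three recurrent patient
    correlation pairs, and covariate medians at the split points
    (reticulocytes 400, platelets 450, severity 0.670)."""
    registry = builtin_panel_registry()
    sca = Selector("SCA")
    effects = (
        [EffectSpec(b, sca, _SERUM_FOLD_UP) for b in _UP_IN_SCA_SERUM]
        + [EffectSpec(b, sca, _SERUM_FOLD_DOWN) for b in _DOWN_IN_SCA_SERUM]
        + [EffectSpec(b, sca, _CELL_FOLD_UP) for b in _UP_IN_SCA_CELL]
        + [EffectSpec(b, sca, _CELL_FOLD_DOWN) for b in _DOWN_IN_SCA_CELL]
    )
    correlations = [
        CorrelationSpec(pair, sca, rho) for pair, rho in _SCA_CORRELATIONS
    ]
    covariates = {
        "reticulocytes": {"SCA": Baseline("lognormal", 400.0, 0.4)},
        "platelets": {
            "SCA": Baseline("lognormal", 450.0, 0.4),
            "HD": Baseline("lognormal", 246.0, 0.25),
        },
        "severity": {"SCA": Baseline("logitnormal", 0.670, 0.3)},
    }
    return SyntheticConfig(
        n_hd=70,
        n_sca=30,
        seed=seed,
        registry=registry,
        effects=effects,
        correlations=correlations,
        covariates=covariates,
    )


def null_config(
    n_biomarkers: int,
    n_hd: int = 70,
    n_sca: int = 30,
    seed: int = 0,
    location: float = 100.0,
    cv: float = 0.5,
) -> SyntheticConfig:
    """A no-effect, no-correlation cohort of generic uncensored biomarkers
    (MFI-like log-normal marginals) for calibration studies."""
    registry = [
        BiomarkerDescriptor(f"M{i:04d}", "cytokine", "mfi")
        for i in range(n_biomarkers)
    ]
    baselines = {d.name: Baseline("lognormal", location, cv) for d in registry}
    return SyntheticConfig(
        n_hd=n_hd, n_sca=n_sca, seed=seed,
        registry=registry, baselines=baselines, covariates={},
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _latent_correlation_matrix(
    names: Sequence[str],
    specs: Sequence[CorrelationSpec],
) -> np.ndarray:
    """Latent Pearson matrix realizing the requested Spearman values,
    rho_lat = 2*sin(pi*rho_s/6) (the Gaussian-copula rank map)."""
    idx = {n: i for i, n in enumerate(names)}
    k = len(names)
    mat = np.eye(k)
    for s in specs:
        i, j = idx[s.pair[0]], idx[s.pair[1]]
        lat = 2.0 * math.sin(math.pi * s.rho / 6.0)
        mat[i, j] = mat[j, i] = lat
    return mat


def _cholesky_or_raise(
    mat: np.ndarray, specs: Sequence[CorrelationSpec]
) -> np.ndarray:
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        detail = ", ".join(
            f"{s.pair[0]}~{s.pair[1]} (rho={s.rho})" for s in specs
        )
        raise InfeasibleCorrelationError(
            "requested correlations do not form a positive-definite latent "
            f"matrix: {detail}"
        ) from None


def _marginal(
    baseline: Baseline, z: np.ndarray, location: np.ndarray, upper: float
) -> np.ndarray:
    """Transform standard-normal latents to the marginal with the given
    per-subject location (median). ``upper`` bounds logit-normal output."""
    if baseline.family == "lognormal":
        return location * np.exp(_lognormal_sigma(baseline.cv) * z)
    # logit-normal on (0, upper); clip the shifted median into the support
    p = np.clip(location / upper, 1e-4, 1.0 - 1e-4)
    sigma = np.minimum(baseline.cv / (1.0 - p), 2.5)
    return upper * _expit(np.log(p / (1.0 - p)) + sigma * z)


def _draw_covariates(
    config: SyntheticConfig, group: str, n: int, rng: np.random.Generator
) -> dict[str, Optional[np.ndarray]]:
    out: dict[str, Optional[np.ndarray]] = {}
    for cov in ("reticulocytes", "platelets", "severity"):
        spec = config.covariates.get(cov, {}).get(group)
        if spec is None:
            out[cov] = None
            continue
        z = rng.standard_normal(n)
        upper = 1.0 if cov == "severity" else math.inf
        if spec.family == "lognormal":
            vals = spec.location * np.exp(_lognormal_sigma(spec.cv) * z)
        else:
            vals = _marginal(spec, z, np.full(n, spec.location), upper)
        out[cov] = vals
    return out


def _subgroup_labels(values: Optional[np.ndarray]) -> Optional[np.ndarray]:
    """Within-group median split; ties at the cut go to 'low'."""
    if values is None:
        return None
    cut = float(np.median(values))
    return np.where(values > cut, "high", "low")


def _fold_for_subject(
    effects: Sequence[EffectSpec],
    biomarker: str,
    group: str,
    i: int,
    labels: dict[str, Optional[np.ndarray]],
) -> float:
    fold = 1.0
    for e in effects:
        if e.biomarker != biomarker or e.selector.group != group:
            continue
        if e.selector.covariate is not None:
            lab = labels.get(e.selector.covariate)
            if lab is None or lab[i] != e.selector.level:
                continue
        fold *= e.fold_change
    return fold


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw a cohort from the configured recipe.

    Within each group, biomarkers come from a Gaussian copula with the
    requested latent correlations; marginal locations are multiplied by
    every applicable fold change; serum analytes then pass through the
    LOD-censoring policy with the registry LODs.
    """
    rng = np.random.default_rng(config.seed)
    names = [d.name for d in config.registry if d.name in config.baselines]
    by_name = {d.name: d for d in config.registry}
    subjects: list[SubjectRecord] = []

    for group, n in (("HD", config.n_hd), ("SCA", config.n_sca)):
        group_specs = [
            c for c in config.correlations if c.selector.group == group
        ]
        chol = _cholesky_or_raise(
            _latent_correlation_matrix(names, group_specs), group_specs
        )
        z = rng.standard_normal((n, len(names))) @ chol.T
        covs = _draw_covariates(config, group, n, rng)
        labels = {c: _subgroup_labels(v) for c, v in covs.items()}

        values = np.empty((n, len(names)))
        for j, bm in enumerate(names):
            base = config.baselines[bm]
            loc = np.array(
                [
                    base.location
                    * _fold_for_subject(config.effects, bm, group, i, labels)
                    for i in range(n)
                ]
            )
            upper = 100.0 if by_name[bm].unit == "percent" else math.inf
            values[:, j] = _marginal(base, z[:, j], loc, upper)

        for i in range(n):
            measurements: dict[str, Measurement] = {}
            for j, bm in enumerate(names):
                desc = by_name[bm]
                v = float(values[i, j])
                if desc.lod is not None:
                    v, cens = apply_lod_censoring(
                        v, desc.lod, config.censoring_policy
                    )
                else:
                    cens = False
                measurements[bm] = Measurement(v, cens)
            subjects.append(
                SubjectRecord(
                    subject_id=f"{group}{i + 1:03d}",
                    group=group,
                    reticulocytes=_at(covs["reticulocytes"], i),
                    platelets=_at(covs["platelets"], i),
                    severity=_at(covs["severity"], i),
                    measurements=measurements,
                )
            )
    return CohortTable(registry=list(config.registry), subjects=subjects)


def _at(arr: Optional[np.ndarray], i: int) -> Optional[float]:
    return None if arr is None else float(arr[i])
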
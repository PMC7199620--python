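"""Five-parameter logistic (5PL) standard-curve model and LOD censoring.

Bead-based immunoassays convert a fluorescence response to a concentration
through an asymmetric sigmoid standard curve

    f(x) = d + (a - d) / (1 + (x / c)^b)^g

where ``a`` is the response at zero concentration, ``d`` the response at
infinite concentration, ``c`` a scale concentration (pg/mL), ``b`` the
slope factor and ``g`` the asymmetry factor (g = 1 recovers the symmetric
4PL). Quantification inverts the curve in closed form. Curve *fitting* is
out of scope: the pipeline consumes a fitted curve per analyte.

Values below an analyte's limit of detection (LOD) are censored; the
default single-imputation policy substitutes LOD/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

CENSORING_POLICIES = ("substitute_lod", "substitute_half_lod", "keep")

DEFAULT_CENSORING_POLICY = "substitute_half_lod"


@dataclass(frozen=True)
class FiveParameterCurve:
    """Fitted 5PL standard-curve parameters for one analyte."""

    a: float  # asymptotic response at zero concentration
    d: float  # asymptotic response at infinite concentration
    c: float  # inflection-scale concentration, pg/mL, > 0
    b: float  # slope factor, != 0
    g: float  # asymmetry factor, > 0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.g <= 0:
            raise ValueError("g must be > 0")
        if self.b == 0:
            raise ValueError("b must be nonzero")
        if self.a == self.d:
            raise ValueError("a and d must differ")

    @property
    def response_interval(self) -> Tuple[float, float]:
        """Open interval of invertible responses, (min(a,d), max(a,d))."""
        return (min(self.a, self.d), max(self.a, self.d))


def logistic5_response(curve: FiveParameterCurve, conc: float) -> float:
    """Response at concentration ``conc`` (>= 0).

    ``conc == 0`` returns the zero-concentration asymptote ``a`` by the
    parameter's definition (blank well response).
    """
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    if conc == 0:
        return curve.a
    ratio = conc / curve.c
    return curve.d + (curve.a - curve.d) / (1.0 + ratio ** curve.b) ** curve.g


def logistic5_inverse(curve: FiveParameterCurve, response: float) -> float:
    """Concentration producing ``response``, by closed-form inversion.

    ``response`` must lie strictly between the asymptotes; values at or
    outside them correspond to blank or saturated wells and raise.
    """
    lo, hi = curve.response_interval
    if not lo < response < hi:
        raise ValueError(
            f"response {response} outside open interval ({lo}, {hi}); "
            "well is blank or saturated"
        )
    inner = ((curve.a - curve.d) / (response - curve.d)) ** (1.0 / curve.g)
    return curve.c * (inner - 1.0) ** (1.0 / curve.b)


def apply_lod_censoring(
    value: float,
    lod: float,
    policy: str = DEFAULT_CENSORING_POLICY,
) -> Tuple[float, bool]:
    """Censor a concentration below the limit of detection.

    Returns ``(value, censored)``. Values >= lod pass through unflagged;
    values < lod are flagged and replaced according to ``policy``:
    ``substitute_lod`` -> lod, ``substitute_half_lod`` -> lod/2,
    ``keep`` -> unchanged.
    """
    if lod < 0:
        raise ValueError("lod must be non-negative")
    if policy not in CENSORING_POLICIES:
        raise ValueError(
            f"unknown policy {policy!r}; expected one of {CENSORING_POLICIES}"
        )
    if value >= lod:
        return value, False
    if policy == "substitute_lod":
        return lod, True
    if policy == "substitute_half_lod":
        return lod / 2.0, True
    return value, True
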
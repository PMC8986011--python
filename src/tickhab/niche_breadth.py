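"""Niche-breadth (amplitude) statistics for a use profile.

Shannon and Levins families measure evenness of use across all k habitats
(zero-use habitats stay in the normalization); the Ivlev amplitude variant
sums absolute electivities and is inverted — 0 marks the broadest niche.
Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .availability_use import AvailabilityVector
from .preference import ivlev
from .survey_model import SurveyDataError, UseProfile

__all__ = [
    "BreadthReport",
    "shannon_breadth",
    "levins_family",
    "ivlev_amplitude",
    "breadth_report",
]


@dataclass(frozen=True)
class BreadthReport:
    group: str
    season: str
    H: float  # Shannon diversity of use, nats
    H_std: float  # H / ln k, in [0, 1]
    B: float  # Levins 1/sum r^2, in [1, k]
    B_std: float  # (B - 1)/(k - 1), in [0, 1]
    B_mod: float  # B/k, in [1/k, 1]
    ivlev_amp: Optional[float]  # sum |E_i|; None when no availability given


def _as_r(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if abs(r.sum() - 1.0) > 1e-9:
        raise SurveyDataError("use proportions must sum to 1")
    if (r < 0).any():
        raise SurveyDataError("negative use proportion")
    return r


def shannon_breadth(r, k: Optional[int] = None) -> tuple[float, float]:
    """Shannon diversity H = -sum r ln r and its normalization H/ln k.

    Zero components contribute 0; k counts every habitat, used or not.
    """
    r = _as_r(r)
    k = k if k is not None else len(r)
    if k < 2:
        raise SurveyDataError("breadth needs at least 2 habitats")
    pos = r[r > 0]
    H = float(-np.sum(pos * np.log(pos)))
    return H, H / np.log(k)


def levins_family(r, k: Optional[int] = None) -> tuple[float, float, float]:
    """Levins B = 1/sum r^2 with standardized (B-1)/(k-1) and modified B/k forms."""
    r = _as_r(r)
    k = k if k is not None else len(r)
    if k < 2:
        raise SurveyDataError("breadth needs at least 2 habitats")
    B = float(1.0 / np.sum(r**2))
    return B, (B - 1) / (k - 1), B / k


def ivlev_amplitude(r, p) -> float:
    """Sum of absolute electivities over all habitats (0 = broadest niche)."""
    return float(np.abs(ivlev(r, p)).sum())


def breadth_report(
    profile: UseProfile, p: Optional[AvailabilityVector] = None
) -> BreadthReport:
    """The five amplitude statistics for one group-season profile."""
    r = profile.r
    k = len(r)
    H, H_std = shannon_breadth(r, k)
    B, B_std, B_mod = levins_family(r, k)
    amp = None
    if p is not None:
        if profile.names != p.names:
            raise SurveyDataError("profile and availability habitats differ")
        amp = ivlev_amplitude(r, p)
    return BreadthReport(
        group=profile.group,
        season=profile.season,
        H=H,
        H_std=H_std,
        B=B,
        B_std=B_std,
        B_mod=B_mod,
        ivlev_amp=amp,
    )
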
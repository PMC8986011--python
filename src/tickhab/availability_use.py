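"""Availability proportions, expected use, and survey composition summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .survey_model import (
    METHODS,
    SEASONS,
    STAGES,
    CountMatrix,
    HabitatSet,
    SurveyDataError,
    UseProfile,
)

__all__ = [
    "AvailabilityVector",
    "ExpectedUse",
    "CompositionSummary",
    "availability",
    "expected_use",
    "composition_summary",
]


@dataclass(frozen=True)
class AvailabilityVector:
    """Proportional availability per habitat; sums to 1, all entries > 0."""

    names: tuple[str, ...]
    p: np.ndarray
    source: str = "areas"  # {"areas", "explicit"}

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or len(p) != len(self.names):
            raise SurveyDataError("availability/habitat dimension mismatch")
        if (p <= 0).any():
            raise SurveyDataError("availability proportions must be positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise SurveyDataError(
                f"availability proportions sum to {p.sum():.12f}, expected 1"
            )
        object.__setattr__(self, "p", p / p.sum())

    @classmethod
    def explicit(
        cls, values: Sequence[float], names: Sequence[str]
    ) -> "AvailabilityVector":
        return cls(names=tuple(names), p=np.asarray(values, float), source="explicit")


@dataclass(frozen=True)
class ExpectedUse:
    """Expected counts under availability: E_i = N * p_i."""

    names: tuple[str, ...]
    E: np.ndarray
    N: int
    p: AvailabilityVector


def availability(habitats: HabitatSet) -> AvailabilityVector:
    """Area-derived availability: p_i = A_i / sum(A)."""
    areas = np.asarray(habitats.areas, dtype=float)
    return AvailabilityVector(
        names=habitats.names, p=areas / areas.sum(), source="areas"
    )


def expected_use(profile: UseProfile, p: AvailabilityVector) -> ExpectedUse:
    """Expected per-habitat counts for a profile under the null of no selection."""
    if profile.names != p.names:
        raise SurveyDataError("profile and availability habitats differ")
    return ExpectedUse(names=profile.names, E=profile.N * p.p, N=profile.N, p=p)


@dataclass(frozen=True)
class CompositionSummary:
    """Descriptive composition of a survey.

    stage_shares: per season, each stage's percent of the season total.
    sex_ratio: females/males pooled over seasons (None when no males).
    method_totals: per season, captures by method.
    method_ratio: per season, larger method subtotal / smaller (None when a
    method subtotal is zero).
    """

    stage_shares: Mapping[str, Mapping[str, float]]
    sex_ratio: Optional[float]
    method_totals: Mapping[str, Mapping[str, int]]
    method_ratio: Mapping[str, Optional[float]]
    season_totals: Mapping[str, int]


def composition_summary(counts: CountMatrix) -> CompositionSummary:
    if counts.total() == 0:
        raise SurveyDataError("composition of an all-zero survey is undefined")

    stage_shares: dict[str, dict[str, float]] = {}
    method_totals: dict[str, dict[str, int]] = {}
    method_ratio: dict[str, Optional[float]] = {}
    season_totals: dict[str, int] = {}
    for season in SEASONS:
        season_total = counts.total(season=season)
        season_totals[season] = season_total
        shares: dict[str, float] = {}
        for stage in STAGES:
            shares[stage] = (
                100.0 * counts.total(group=stage, season=season) / season_total
                if season_total
                else float("nan")
            )
        if season_total:
            shares["adults"] = (
                100.0 * counts.total(group="adults", season=season) / season_total
            )
        stage_shares[season] = shares

        totals = {m: counts.total(season=season, method=m) for m in METHODS}
        method_totals[season] = totals
        lo, hi = sorted(totals.values())
        method_ratio[season] = hi / lo if lo > 0 else None

    males = counts.total(group="male")
    females = counts.total(group="female")
    sex_ratio = females / males if males > 0 else None
    return CompositionSummary(
        stage_shares=stage_shares,
        sex_ratio=sex_ratio,
        method_totals=method_totals,
        method_ratio=method_ratio,
        season_totals=season_totals,
    )
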
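"""Domain types and CSV I/O for habitat-availability and capture-count surveys.

The data model follows the classic design-II use/availability layout: a fixed
set of habitats with known available areas, and capture counts indexed by
life stage, habitat, season, and collection method.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "STAGES",
    "SEASONS",
    "METHODS",
    "SurveyDataError",
    "EmptyProfileError",
    "HabitatSet",
    "CountMatrix",
    "UseProfile",
    "load_habitats",
    "load_counts",
    "write_counts",
    "use_profile",
    "resolve_group",
]

STAGES = ("larva", "nymph", "female", "male")
SEASONS = ("dry", "wet")
METHODS = ("trap", "transect")

#: selector aliases accepted anywhere a group is named
_GROUP_ALIASES = {
    "larvae": "larva",
    "nymphs": "nymph",
    "females": "female",
    "males": "male",
    "adult": "adults",
    "total": "all",
}


class SurveyDataError(ValueError):
    """Invalid survey input (bad file, unknown token, broken invariant)."""


class EmptyProfileError(SurveyDataError):
    """A use profile was requested for a group-season with zero captures."""


def resolve_group(selector: str) -> tuple[str, ...]:
    """Expand a group selector into the stage labels it covers.

    ``"adults"`` means female + male; ``"all"`` means every stage; a stage
    name selects itself. Plural aliases are accepted.
    """
    sel = _GROUP_ALIASES.get(selector.strip().lower(), selector.strip().lower())
    if sel == "all":
        return STAGES
    if sel == "adults":
        return ("female", "male")
    if sel in STAGES:
        return (sel,)
    raise SurveyDataError(f"unknown group selector: {selector!r}")


@dataclass(frozen=True)
class HabitatSet:
    """Ordered habitats with strictly positive available areas (m^2)."""

    names: tuple[str, ...]
    areas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.areas):
            raise SurveyDataError("names and areas length mismatch")
        if len(self.names) < 2:
            raise SurveyDataError("a habitat set needs at least 2 habitats")
        if len(set(self.names)) != len(self.names):
            raise SurveyDataError("duplicate habitat names")
        for name, area in zip(self.names, self.areas):
            if not np.isfinite(area) or area <= 0:
                raise SurveyDataError(
                    f"habitat {name!r} has non-positive area {area!r}"
                )

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def total_area(self) -> float:
        return float(sum(self.areas))

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SurveyDataError(f"unknown habitat: {name!r}") from None


Key = tuple[str, str, str, str]  # (group, habitat, season, method)


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer captures by (stage, habitat, season, method).

    Missing combinations are zero. Habitats are always referenced by name
    against the associated :class:`HabitatSet`, never by position.
    """

    habitats: HabitatSet
    counts: Mapping[Key, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[Key, int] = {}
        for (group, habitat, season, method), value in self.counts.items():
            if group not in STAGES:
                raise SurveyDataError(f"unknown stage: {group!r}")
            if habitat not in self.habitats.names:
                raise SurveyDataError(f"unknown habitat: {habitat!r}")
            if season not in SEASONS:
                raise SurveyDataError(f"unknown season: {season!r}")
            if method not in METHODS:
                raise SurveyDataError(f"unknown method: {method!r}")
            if isinstance(value, float) and not float(value).is_integer():
                raise SurveyDataError(f"fractional count {value!r}")
            ivalue = int(value)
            if ivalue < 0:
                raise SurveyDataError(f"negative count {value!r}")
            clean[(group, habitat, season, method)] = ivalue
        object.__setattr__(self, "counts", clean)

    def get(self, group: str, habitat: str, season: str, method: str) -> int:
        return self.counts.get((group, habitat, season, method), 0)

    def total(
        self,
        group: Union[str, None] = None,
        habitat: Union[str, None] = None,
        season: Union[str, None] = None,
        method: Union[str, None] = None,
    ) -> int:
        """Sum of counts over all cells matching the given filters.

        ``group`` accepts a selector (stage name, ``"adults"``, ``"all"``).
        """
        stages = resolve_group(group) if group is not None else STAGES
        tot = 0
        for (g, h, s, m), v in self.counts.items():
            if g not in stages:
                continue
            if habitat is not None and h != habitat:
                continue
            if season is not None and s != season:
                continue
            if method is not None and m != method:
                continue
            tot += v
        return tot

    def habitat_counts(
        self,
        group: str,
        season: str,
        method: Union[str, None] = None,
    ) -> np.ndarray:
        """Counts per habitat (habitat-set order), methods pooled by default."""
        return np.array(
            [
                self.total(group=group, habitat=h, season=season, method=method)
                for h in self.habitats.names
            ],
            dtype=np.int64,
        )


@dataclass(frozen=True)
class UseProfile:
    """Observed use for one group-season: counts O, total N, proportions r."""

    group: str
    season: str
    names: tuple[str, ...]
    O: np.ndarray

    def __post_init__(self) -> None:
        O = np.asarray(self.O, dtype=np.int64)
        if O.ndim != 1 or len(O) != len(self.names):
            raise SurveyDataError("counts/habitat dimension mismatch")
        if (O < 0).any():
            raise SurveyDataError("negative counts in profile")
        if O.sum() == 0:
            raise EmptyProfileError(
                f"empty profile for group={self.group!r} season={self.season!r}"
            )
        object.__setattr__(self, "O", O)

    @property
    def N(self) -> int:
        return int(self.O.sum())

    @property
    def r(self) -> np.ndarray:
        """Use proportions O/N (sums to 1)."""
        return self.O / self.N


def use_profile(counts: CountMatrix, group: str, season: str) -> UseProfile:
    """Pool methods and selected stages into a per-habitat use profile."""
    stages = resolve_group(group)
    O = np.zeros(counts.habitats.k, dtype=np.int64)
    for stage in stages:
        O += counts.habitat_counts(stage, season)
    return UseProfile(group=group, season=season, names=counts.habitats.names, O=O)


def load_habitats(path: Union[str, Path]) -> HabitatSet:
    """Read ``habitat,area_m2`` CSV; row order defines habitat order."""
    path = Path(path)
    names: list[str] = []
    areas: list[float] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"habitat", "area_m2"} <= set(reader.fieldnames):
            raise SurveyDataError(
                f"{path}: expected header 'habitat,area_m2', got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            name = (row["habitat"] or "").strip()
            if not name:
                raise SurveyDataError(f"{path}:{lineno}: empty habitat name")
            try:
                area = float(row["area_m2"])
            except (TypeError, ValueError):
                raise SurveyDataError(
                    f"{path}:{lineno}: non-numeric area {row['area_m2']!r}"
                ) from None
            names.append(name)
            areas.append(area)
    if len(names) < 2:
        raise SurveyDataError(f"{path}: fewer than 2 habitats")
    return HabitatSet(names=tuple(names), areas=tuple(areas))


def load_counts(path: Union[str, Path], habitats: HabitatSet) -> CountMatrix:
    """Read ``group,habitat,season,method,count`` CSV into a CountMatrix.

    Missing combinations default to zero; duplicate keys accumulate.
    """
    path = Path(path)
    counts: dict[Key, int] = {}
    expected = {"group", "habitat", "season", "method", "count"}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not expected <= set(reader.fieldnames):
            raise SurveyDataError(
                f"{path}: expected header 'group,habitat,season,method,count', "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            group = row["group"].strip().lower()
            group = _GROUP_ALIASES.get(group, group)
            habitat = row["habitat"].strip()
            season = row["season"].strip().lower()
            method = row["method"].strip().lower()
            raw = row["count"].strip()
            if group not in STAGES:
                raise SurveyDataError(f"{path}:{lineno}: unknown stage {row['group']!r}")
            if habitat not in habitats.names:
                raise SurveyDataError(f"{path}:{lineno}: unknown habitat {habitat!r}")
            if season not in SEASONS:
                raise SurveyDataError(f"{path}:{lineno}: unknown season {season!r}")
            if method not in METHODS:
                raise SurveyDataError(f"{path}:{lineno}: unknown method {method!r}")
            try:
                value = int(raw)
            except ValueError:
                raise SurveyDataError(
                    f"{path}:{lineno}: non-integer count {raw!r}"
                ) from None
            if value < 0:
                raise SurveyDataError(f"{path}:{lineno}: negative count {raw!r}")
            key = (group, habitat, season, method)
            counts[key] = counts.get(key, 0) + value
    return CountMatrix(habitats=habitats, counts=counts)


def write_counts(matrix: CountMatrix, path: Union[str, Path]) -> None:
    """Write a CountMatrix as the standard counts CSV (all cells, zeros kept)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "habitat", "season", "method", "count"])
        for group in STAGES:
            for habitat in matrix.habitats.names:
                for season in SEASONS:
                    for method in METHODS:
                        writer.writerow(
                            [group, habitat, season, method,
                             matrix.get(group, habitat, season, method)]
                        )
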
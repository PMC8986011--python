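"""Bundled example survey: the four-habitat tick study tables as CSV fixtures."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .survey_model import CountMatrix, HabitatSet, load_counts, load_habitats

__all__ = [
    "example_areas_path",
    "example_counts_path",
    "example_sim_config_path",
    "load_example_survey",
    "WET_AVAILABILITY_OVERRIDE",
]

#: Explicit wet-season availability implied by the study's published expected
#: counts. Its provenance is not stated in the source; it is shipped only so
#: the wet-season columns can be reproduced on request, never applied by
#: default.
WET_AVAILABILITY_OVERRIDE = (0.1545, 0.6579, 0.1368, 0.0508)


def _data_path(name: str) -> Path:
    return Path(resources.files("tickhab").joinpath("data", name))  # type: ignore[arg-type]


def example_areas_path() -> Path:
    return _data_path("areas.csv")


def example_counts_path() -> Path:
    return _data_path("counts.csv")


def example_sim_config_path() -> Path:
    return _data_path("sim_default.yaml")


def load_example_survey() -> tuple[HabitatSet, CountMatrix]:
    habitats = load_habitats(example_areas_path())
    return habitats, load_counts(example_counts_path(), habitats)
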
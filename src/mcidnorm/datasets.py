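"""Accessors for the data shipped with the package.

Four tables travel with the code so the full workflow runs out of the box:

* ``default_registry`` — ten hip instruments with scale bounds, orientation
  and, for the six leading ones, the most frequently reported MCID.
* ``incidence_matrix`` — which of 100 recent hip-arthroscopy studies reported
  which instrument (long format, one row per mention).
* ``default_ranking`` — the literature-frequency ranking derived from that
  matrix; row order encodes the operative tie-break (NAHS ahead of HOS-ADL).
* ``demo_measurements`` — the seven-study two-arm demonstration dataset of
  postoperative summaries used in the worked example.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .frequency import FrequencyRanking, IncidenceMatrix
from .normalize import MeasurementRecord
from .registry import PromRegistry, load_registry

__all__ = [
    "default_registry",
    "incidence_matrix",
    "default_ranking",
    "demo_measurements",
    "demo_measurements_frame",
]


def _data(name: str):
    return resources.files("mcidnorm.data").joinpath(name)


def default_registry() -> PromRegistry:
    """The packaged instrument registry (MCIDs for mHHS, iHOT-12, HOS-SSS, NAHS, HOS-ADL, iHOT-33)."""
    with resources.as_file(_data("prom_registry.csv")) as p:
        return load_registry(p)


def incidence_matrix() -> IncidenceMatrix:
    """The packaged 100-study incidence matrix (218 PROM mentions)."""
    with resources.as_file(_data("prom_incidence.csv")) as p:
        return IncidenceMatrix.from_file(p)


def default_ranking() -> FrequencyRanking:
    """The packaged frequency ranking; prioritization's default governing input."""
    with resources.as_file(_data("prom_ranking.csv")) as p:
        return FrequencyRanking.from_file(p)


def demo_measurements_frame() -> pd.DataFrame:
    with resources.as_file(_data("demo_measurements.csv")) as p:
        return pd.read_csv(p, dtype={"study_id": str, "arm_id": str, "prom": str})


def demo_measurements() -> list[MeasurementRecord]:
    """The seven-study demonstration dataset (postoperative summaries only)."""
    from .io import measurements_from_frame

    return measurements_from_frame(demo_measurements_frame())
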
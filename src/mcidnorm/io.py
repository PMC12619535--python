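"""Delimited-table I/O: schema validation and record <-> DataFrame conversion.

All tables are comma-separated UTF-8 with a header row and a decimal point.
Blank cells mean "missing".  Schema errors name the offending column so a user
can fix the file without reading the source.
"""

from __future__ import annotations

from os import PathLike
from typing import Sequence

import pandas as pd

from .errors import SchemaError
from .meta import EffectSize, MetaResult
from .normalize import MeasurementRecord, NormalizedOutcome
from .prioritize import UnifiedOutcome

__all__ = [
    "read_measurements",
    "measurements_from_frame",
    "measurements_to_frame",
    "normalized_to_frame",
    "normalized_from_frame",
    "read_normalized",
    "unified_to_frame",
    "unified_from_frame",
    "read_unified",
    "effects_to_frame",
    "result_to_frame",
]

MEASUREMENT_COLUMNS = ("study_id", "arm_id", "prom", "timepoint", "n", "mean")


def _require(df: pd.DataFrame, columns: Sequence[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing column(s): {', '.join(missing)}")


def _opt(row, col) -> float | None:
    if col not in row or pd.isna(row[col]) or str(row[col]).strip() == "":
        return None
    return float(row[col])


def measurements_from_frame(df: pd.DataFrame) -> list[MeasurementRecord]:
    _require(df, MEASUREMENT_COLUMNS, "measurements")
    records = []
    for _, row in df.iterrows():
        records.append(
            MeasurementRecord(
                study_id=str(row["study_id"]),
                arm_id=str(row["arm_id"]),
                prom=str(row["prom"]),
                timepoint=str(row["timepoint"]),
                n=int(row["n"]),
                mean=float(row["mean"]),
                sd=_opt(row, "sd"),
                range_min=_opt(row, "range_min"),
                range_max=_opt(row, "range_max"),
            )
        )
    return records


def read_measurements(path: str | PathLike) -> list[MeasurementRecord]:
    """Read a measurements table (columns study_id, arm_id, prom, timepoint, n, mean[, sd, range_min, range_max])."""
    return measurements_from_frame(
        pd.read_csv(path, dtype={"study_id": str, "arm_id": str, "prom": str})
    )


def measurements_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study_id": r.study_id,
                "arm_id": r.arm_id,
                "prom": r.prom,
                "timepoint": r.timepoint.value,
                "n": r.n,
                "mean": r.mean,
                "sd": r.sd,
                "range_min": r.range_min,
                "range_max": r.range_max,
            }
            for r in records
        ]
    )


def normalized_to_frame(outcomes: Sequence[NormalizedOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study_id": o.study_id,
                "arm_id": o.arm_id,
                "prom": o.prom,
                "n": o.n,
                "mean_mcid": o.mean_mcid,
                "sd_mcid": o.sd_mcid,
                "sd_provenance": o.sd_provenance.value,
            }
            for o in outcomes
        ]
    )


def normalized_from_frame(df: pd.DataFrame) -> list[NormalizedOutcome]:
    _require(df, ("study_id", "arm_id", "prom", "n", "mean_mcid", "sd_mcid"), "normalized")
    return [
        NormalizedOutcome(
            study_id=str(row["study_id"]),
            arm_id=str(row["arm_id"]),
            prom=str(row["prom"]),
            n=int(row["n"]),
            mean_mcid=float(row["mean_mcid"]),
            sd_mcid=float(row["sd_mcid"]),
            sd_provenance=str(row.get("sd_provenance", "reported")),
        )
        for _, row in df.iterrows()
    ]


def read_normalized(path: str | PathLike) -> list[NormalizedOutcome]:
    return normalized_from_frame(
        pd.read_csv(path, dtype={"study_id": str, "arm_id": str, "prom": str})
    )


def unified_to_frame(outcomes: Sequence[UnifiedOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study_id": o.study_id,
                "arm_id": o.arm_id,
                "n": o.n,
                "source_prom": o.source_prom,
                "mean_mcid": o.mean_mcid,
                "sd_mcid": o.sd_mcid,
                "discarded": ";".join(o.discarded),
            }
            for o in outcomes
        ]
    )


def unified_from_frame(df: pd.DataFrame) -> list[UnifiedOutcome]:
    _require(df, ("study_id", "arm_id", "n", "source_prom", "mean_mcid", "sd_mcid"), "unified")
    out = []
    for _, row in df.iterrows():
        raw = row.get("discarded", "")
        discarded = tuple(x for x in str(raw).split(";") if x) if not pd.isna(raw) else ()
        out.append(
            UnifiedOutcome(
                study_id=str(row["study_id"]),
                arm_id=str(row["arm_id"]),
                n=int(row["n"]),
                source_prom=str(row["source_prom"]),
                mean_mcid=float(row["mean_mcid"]),
                sd_mcid=float(row["sd_mcid"]),
                discarded=discarded,
            )
        )
    return out


def read_unified(path: str | PathLike) -> list[UnifiedOutcome]:
    return unified_from_frame(
        pd.read_csv(path, dtype={"study_id": str, "arm_id": str, "source_prom": str})
    )


def effects_to_frame(effects: Sequence[EffectSize]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"study_id": e.study_id, "md": e.md, "variance": e.variance, "se": e.se} for e in effects]
    )


def result_to_frame(result: MetaResult, effects: Sequence[EffectSize]) -> pd.DataFrame:
    """One-row summary table followed by nothing: weights go in their own columns."""
    row = {
        "mu": result.mu,
        "se_mu": result.se_mu,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "tau2": result.tau2,
        "q": result.q,
        "df": result.df,
        "i2": result.i2,
        "band": result.band,
    }
    for e, w in zip(effects, result.weights):
        row[f"weight_{e.study_id}"] = w
    return pd.DataFrame([row])
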
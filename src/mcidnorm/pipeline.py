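"""End-to-end workflow: normalize -> prioritize -> pool, with artifacts on disk.

``run_pipeline`` is the library entry point the CLI wraps.  Every stage
writes its intermediate table, the audit log captures each discretionary
decision, and the pooled result plus forest plot land in the output
directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Sequence

import yaml

from . import datasets, io
from .audit import AuditLog
from .errors import ConfigurationError, McidNormError
from .frequency import FrequencyRanking, IncidenceMatrix, count_mentions, rank_proms
from .meta import (
    MetaResult,
    effects_from_unified,
    forest_data,
    pool_random_effects,
    render_forest,
    reml_tau2,
)
from .normalize import DEFAULT_CHANGE_CORRELATION, MeasurementRecord, normalize_measurements
from .prioritize import prioritize_all
from .registry import PromRegistry, load_registry

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full pipeline run.

    ``ranking_path`` may be a file path, ``"auto"`` (derive the ranking from
    the incidence matrix at run time) or ``None`` (use the packaged default).
    ``reference_arm`` is the subtrahend arm label; the pooled effect is
    (other arm) - (reference arm).
    """

    reference_arm: str = "2"
    registry_path: str | None = None
    ranking_path: str | None = None
    r_default: float = DEFAULT_CHANGE_CORRELATION
    rounding: int = 1
    seed: int = 0
    output_dir: str = "mcidnorm-out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not -1.0 <= self.r_default <= 1.0:
            raise ConfigurationError("r_default must lie in [-1, 1]")
        if self.rounding < 0:
            raise ConfigurationError("rounding must be >= 0")

    @classmethod
    def from_file(cls, path: str | PathLike, **overrides) -> "RunConfig":
        """Load a key-value YAML config file; keyword overrides win."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a key-value mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class PipelineError(McidNormError):
    """Wraps a stage failure with the stage name for actionable messages."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage!r} failed: {original}")


def _resolve_ranking(
    config: RunConfig, incidence: IncidenceMatrix | None, registry: PromRegistry, audit: AuditLog
) -> FrequencyRanking:
    if config.ranking_path not in (None, "auto"):
        return FrequencyRanking.from_file(config.ranking_path)
    if config.ranking_path == "auto":
        if incidence is None:
            raise ConfigurationError("ranking_path='auto' requires an incidence matrix")
        counts = count_mentions(incidence, registry, audit)
        ranking = rank_proms(counts)
        audit.record("frequency", "tie_break", f"tie rule applied: {ranking.tie_rule}")
        return ranking
    return datasets.default_ranking()


def run_pipeline(
    config: RunConfig,
    measurements: Sequence[MeasurementRecord],
    incidence: IncidenceMatrix | None = None,
) -> tuple[MetaResult, AuditLog]:
    """Run normalize -> prioritize -> meta and write all artifacts.

    Writes into ``config.output_dir``: the normalized and unified outcome
    tables, the per-study effect table, the pooled-result table, the audit
    log and a forest plot (SVG).  Returns the pooled result and the audit
    log; any stage error is re-raised as :class:`PipelineError` naming the
    stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit = AuditLog()

    registry = (
        datasets.default_registry()
        if config.registry_path is None
        else load_registry(config.registry_path)
    )

    ranking = _resolve_ranking(config, incidence, registry, audit)
    ranking.to_frame().to_csv(out / "ranking.csv", index=False)

    try:
        normalized = normalize_measurements(
            measurements, registry, audit, on_non_normalizable="drop"
        )
    except McidNormError as exc:
        raise PipelineError("normalize", exc) from exc
    io.normalized_to_frame(normalized).to_csv(out / "normalized.csv", index=False)

    try:
        unified = prioritize_all(normalized, ranking, audit)
    except McidNormError as exc:
        raise PipelineError("prioritize", exc) from exc
    io.unified_to_frame(unified).to_csv(out / "unified.csv", index=False)

    try:
        effects = effects_from_unified(unified, reference_arm=config.reference_arm)
        tau2 = reml_tau2(effects) if len(effects) >= 2 else 0.0
        result = pool_random_effects(effects, tau2)
    except McidNormError as exc:
        raise PipelineError("meta", exc) from exc
    io.effects_to_frame(effects).to_csv(out / "effects.csv", index=False)
    io.result_to_frame(result, effects).to_csv(out / "meta_result.csv", index=False)

    rows = forest_data(effects, result)
    render_forest(rows, out / "forest.svg", result=result)
    audit.write(out / "audit.csv")
    return result, audit
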
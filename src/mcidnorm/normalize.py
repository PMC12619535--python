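"""Scale arithmetic: SD estimation/imputation and conversion into MCID units.

An observed PROM summary (mean, SD, in scale points) is divided by the
instrument's minimal clinically important difference so that a value of 1.0
means "one clinically meaningful improvement", regardless of the instrument.
Change scores are paired data, so their SD uses the pre/post correlation
``r`` rather than a naive difference of SDs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .audit import AuditLog
from .errors import ImputationError, NonNormalizableError, ValidationError
from .registry import PROMDefinition, Orientation, PromRegistry

__all__ = [
    "Timepoint",
    "SdProvenance",
    "MeasurementRecord",
    "NormalizedOutcome",
    "ChangeOutcome",
    "sd_from_range",
    "impute_missing_sd",
    "normalize_mean",
    "normalize_sd",
    "change_mcid",
    "sd_change",
    "sd_change_mcid",
    "normalize_measurements",
    "change_outcomes",
    "DEFAULT_CHANGE_CORRELATION",
    "SENSITIVITY_CORRELATIONS",
]

#: Pre/post correlation assumed when a study does not report one.  0.5 is the
#: conventional conservative midpoint; a sensitivity sweep over
#: SENSITIVITY_CORRELATIONS should accompany any change-score synthesis.
DEFAULT_CHANGE_CORRELATION = 0.5
SENSITIVITY_CORRELATIONS = (0.2, 0.5, 0.8)


class Timepoint(str, enum.Enum):
    pre = "pre"
    post = "post"


class SdProvenance(str, enum.Enum):
    reported = "reported"
    from_range = "from_range"
    imputed = "imputed"


@dataclass(frozen=True)
class MeasurementRecord:
    """One arm x PROM x timepoint summary on the instrument's raw scale."""

    study_id: str
    arm_id: str
    prom: str
    timepoint: Timepoint
    n: int
    mean: float
    sd: float | None = None
    range_min: float | None = None
    range_max: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoint", Timepoint(self.timepoint))
        if self.n < 1:
            raise ValidationError(f"{self.study_id}/{self.arm_id}/{self.prom}: n must be >= 1")
        if self.sd is not None and self.sd < 0:
            raise ValidationError(f"{self.study_id}/{self.arm_id}/{self.prom}: sd must be >= 0")
        if (self.range_min is None) != (self.range_max is None):
            raise ValidationError(
                f"{self.study_id}/{self.arm_id}/{self.prom}: range must give both bounds"
            )
        if self.range_min is not None and self.range_min > self.range_max:
            raise ValidationError(
                f"{self.study_id}/{self.arm_id}/{self.prom}: range_min > range_max"
            )

    @property
    def has_sd(self) -> bool:
        return self.sd is not None

    @property
    def has_range(self) -> bool:
        return self.range_min is not None


@dataclass(frozen=True)
class NormalizedOutcome:
    """A measurement re-expressed in MCID units."""

    study_id: str
    arm_id: str
    prom: str
    n: int
    mean_mcid: float
    sd_mcid: float
    sd_provenance: SdProvenance = SdProvenance.reported

    def __post_init__(self) -> None:
        object.__setattr__(self, "sd_provenance", SdProvenance(self.sd_provenance))
        if not math.isfinite(self.mean_mcid):
            raise ValidationError("mean_mcid must be finite")
        if self.sd_mcid < 0:
            raise ValidationError("sd_mcid must be >= 0")


@dataclass(frozen=True)
class ChangeOutcome:
    """Pre-to-post improvement in MCID units, with correlation-adjusted SD."""

    study_id: str
    arm_id: str
    prom: str
    n: int
    delta_mcid: float
    sd_delta_mcid: float
    r_used: float

    def __post_init__(self) -> None:
        if self.sd_delta_mcid < 0:
            raise ValidationError("sd_delta_mcid must be >= 0")
        if not -1.0 <= self.r_used <= 1.0:
            raise ValidationError("r_used must lie in [-1, 1]")


def sd_from_range(range_min: float, range_max: float) -> float:
    """Estimate an SD from a reported range as (max - min) / 4."""
    if range_min > range_max:
        raise ValidationError(f"range_min ({range_min}) exceeds range_max ({range_max})")
    return (range_max - range_min) / 4.0


def impute_missing_sd(
    target: MeasurementRecord,
    donors: Iterable[MeasurementRecord],
    strategy: str = "max",
) -> float:
    """Borrow an SD for a record that reports neither SD nor range.

    Donors must share the target's instrument and timepoint and carry an SD of
    their own.  The default takes the largest donor SD (conservative: the
    pooled weight of the study can only shrink); ``strategy="mean"`` averages
    donors instead.
    """
    eligible = [
        d.sd
        for d in donors
        if d.has_sd
        and d.prom == target.prom
        and d.timepoint == target.timepoint
        and not (d.study_id == target.study_id and d.arm_id == target.arm_id)
    ]
    if not eligible:
        raise ImputationError(
            f"no eligible donor SD for {target.study_id}/{target.arm_id}/{target.prom}"
        )
    if strategy == "max":
        return max(eligible)
    if strategy == "mean":
        return sum(eligible) / len(eligible)
    raise ValidationError(f"unknown imputation strategy {strategy!r}")


def _require_mcid(prom: PROMDefinition) -> float:
    if prom.mcid is None:
        raise NonNormalizableError(
            f"{prom.name} has no published MCID and cannot be normalized"
        )
    return prom.mcid


def normalize_mean(mean: float, prom: PROMDefinition) -> float:
    """Observed mean (scale points) -> MCID units: mean / MCID."""
    return mean / _require_mcid(prom)


def normalize_sd(sd: float, prom: PROMDefinition) -> float:
    """Observed SD (scale points) -> MCID units: sd / MCID."""
    if sd < 0:
        raise ValidationError(f"sd must be >= 0, got {sd}")
    return sd / _require_mcid(prom)


def change_mcid(pre_mean: float, post_mean: float, prom: PROMDefinition) -> float:
    """Pre-to-post change in MCID units, signed so positive means improvement.

    For instruments where higher scores are worse (e.g. WOMAC) the difference
    is flipped before dividing by the MCID.
    """
    mcid = _require_mcid(prom)
    raw = post_mean - pre_mean
    if prom.orientation is Orientation.higher_worse:
        raw = -raw
    return raw / mcid


def sd_change(sd_pre: float, sd_post: float, r: float) -> float:
    """SD of a paired change score: sqrt(sd_pre^2 + sd_post^2 - 2 r sd_pre sd_post)."""
    if sd_pre < 0 or sd_post < 0:
        raise ValidationError("SDs must be >= 0")
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"correlation r must lie in [-1, 1], got {r}")
    # clamp tiny negative round-off (r == 1 with equal SDs)
    return math.sqrt(max(0.0, sd_pre**2 + sd_post**2 - 2.0 * r * sd_pre * sd_post))


def sd_change_mcid(sd_pre: float, sd_post: float, r: float, prom: PROMDefinition) -> float:
    """Change-score SD in MCID units: sd_change / MCID."""
    return sd_change(sd_pre, sd_post, r) / _require_mcid(prom)


def _resolve_sd(
    rec: MeasurementRecord,
    donors: Sequence[MeasurementRecord],
    audit: AuditLog | None,
    imputation_strategy: str,
) -> tuple[float, SdProvenance]:
    if rec.has_sd:
        return rec.sd, SdProvenance.reported
    if rec.has_range:
        sd = sd_from_range(rec.range_min, rec.range_max)
        if audit is not None:
            audit.record(
                "normalize",
                "sd_from_range",
                f"SD estimated from range [{rec.range_min}, {rec.range_max}] -> {sd}",
                study_id=rec.study_id,
                arm_id=rec.arm_id,
                prom=rec.prom,
            )
        return sd, SdProvenance.from_range
    sd = impute_missing_sd(rec, donors, strategy=imputation_strategy)
    if audit is not None:
        audit.record(
            "normalize",
            "sd_imputed",
            f"SD imputed from donors ({imputation_strategy} rule) -> {sd}",
            study_id=rec.study_id,
            arm_id=rec.arm_id,
            prom=rec.prom,
        )
    return sd, SdProvenance.imputed


def normalize_measurements(
    records: Sequence[MeasurementRecord],
    registry: PromRegistry,
    audit: AuditLog | None = None,
    on_non_normalizable: str = "error",
    imputation_strategy: str = "max",
) -> list[NormalizedOutcome]:
    """Convert a batch of raw-scale measurements into MCID units.

    SD resolution order per record: reported SD, then range-based estimate,
    then conservative imputation from same-PROM same-timepoint donors.  A
    record whose SD cannot be resolved at all is excluded with an audited
    warning rather than aborting the batch.

    ``on_non_normalizable`` controls records whose instrument has no MCID:
    ``"error"`` (default, the single-record contract) or ``"drop"`` with an
    audited exclusion (the pipeline behaviour).
    """
    if on_non_normalizable not in ("error", "drop"):
        raise ValidationError("on_non_normalizable must be 'error' or 'drop'")
    out: list[NormalizedOutcome] = []
    for rec in records:
        prom = registry.lookup(rec.prom)
        if not prom.normalizable:
            if on_non_normalizable == "error":
                raise NonNormalizableError(
                    f"{prom.name} has no published MCID and cannot be normalized "
                    f"(record {rec.study_id}/{rec.arm_id})"
                )
            if audit is not None:
                audit.record(
                    "normalize",
                    "non_normalizable_dropped",
                    f"{prom.name} has no published MCID; record excluded",
                    study_id=rec.study_id,
                    arm_id=rec.arm_id,
                    prom=prom.name,
                )
            continue
        if not prom.scale_min <= rec.mean <= prom.scale_max and audit is not None:
            audit.record(
                "normalize",
                "out_of_scale",
                f"mean {rec.mean} outside [{prom.scale_min}, {prom.scale_max}]; kept with warning",
                study_id=rec.study_id,
                arm_id=rec.arm_id,
                prom=prom.name,
            )
        try:
            sd, provenance = _resolve_sd(rec, records, audit, imputation_strategy)
        except ImputationError as exc:
            if audit is not None:
                audit.record(
                    "normalize",
                    "sd_unresolvable_excluded",
                    str(exc),
                    study_id=rec.study_id,
                    arm_id=rec.arm_id,
                    prom=prom.name,
                )
            continue
        out.append(
            NormalizedOutcome(
                study_id=rec.study_id,
                arm_id=rec.arm_id,
                prom=prom.name,
                n=rec.n,
                mean_mcid=normalize_mean(rec.mean, prom),
                sd_mcid=normalize_sd(sd, prom),
                sd_provenance=provenance,
            )
        )
    return out


def change_outcomes(
    records: Sequence[MeasurementRecord],
    registry: PromRegistry,
    r: float = DEFAULT_CHANGE_CORRELATION,
    audit: AuditLog | None = None,
) -> list[ChangeOutcome]:
    """Pair pre/post records per (study, arm, PROM) and form change scores.

    Uses the supplied pre/post correlation ``r`` for every pair (studies
    rarely report it).  Arms lacking either timepoint are skipped with an
    audited note.
    """
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"correlation r must lie in [-1, 1], got {r}")
    by_key: dict[tuple[str, str, str], dict[Timepoint, MeasurementRecord]] = {}
    for rec in records:
        prom = registry.lookup(rec.prom)
        by_key.setdefault((rec.study_id, rec.arm_id, prom.name), {})[rec.timepoint] = rec
    out: list[ChangeOutcome] = []
    for (study, arm, prom_name), pair in by_key.items():
        if Timepoint.pre not in pair or Timepoint.post not in pair:
            if audit is not None:
                audit.record(
                    "normalize",
                    "change_pair_incomplete",
                    "missing pre or post timepoint; change score skipped",
                    study_id=study,
                    arm_id=arm,
                    prom=prom_name,
                )
            continue
        pre, post = pair[Timepoint.pre], pair[Timepoint.post]
        prom = registry.lookup(prom_name)
        sd_pre, _ = _resolve_sd(pre, records, audit, "max")
        sd_post, _ = _resolve_sd(post, records, audit, "max")
        out.append(
            ChangeOutcome(
                study_id=study,
                arm_id=arm,
                prom=prom.name,
                n=min(pre.n, post.n),
                delta_mcid=change_mcid(pre.mean, post.mean, prom),
                sd_delta_mcid=sd_change_mcid(sd_pre, sd_post, r, prom),
                r_used=r,
            )
        )
    return out
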
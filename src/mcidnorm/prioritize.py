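"""Collapse each study's multiple normalized PROMs into one unified outcome.

When a study reports several instruments, pooling all of them would let one
cohort enter the meta-analysis several times.  The rule here keeps exactly one
instrument per study — the one ranked highest in the literature-frequency
ranking — and the same instrument for both arms, so each cohort contributes a
single independent effect size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .audit import AuditLog
from .errors import PrioritizationError, RankingError
from .frequency import FrequencyRanking
from .normalize import NormalizedOutcome
from .registry import canonical_name

__all__ = ["UnifiedOutcome", "prioritize_study", "prioritize_all"]


@dataclass(frozen=True)
class UnifiedOutcome:
    """One arm's unified functional outcome in MCID units.

    ``source_prom`` is the retained instrument; everything else the study
    reported for this arm is listed in ``discarded``.
    """

    study_id: str
    arm_id: str
    n: int
    source_prom: str
    mean_mcid: float
    sd_mcid: float
    discarded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source_prom in self.discarded:
            raise PrioritizationError(
                f"{self.study_id}/{self.arm_id}: retained PROM also listed as discarded"
            )


def _pick_prom(
    by_arm: dict[str, dict[str, NormalizedOutcome]],
    ranking: FrequencyRanking,
    study_id: str,
) -> str:
    """Highest-ranked instrument among those present in every arm."""
    arm_sets = [set(proms) for proms in by_arm.values()]
    common = set.intersection(*arm_sets)
    if not common:
        raise PrioritizationError(
            f"study {study_id}: arms report disjoint PROM sets "
            f"({', '.join(sorted(set.union(*arm_sets)))}); no common instrument to retain"
        )
    try:
        return min(common, key=ranking.rank_of)
    except RankingError as exc:
        raise PrioritizationError(f"study {study_id}: {exc}") from exc


def prioritize_study(
    outcomes: Sequence[NormalizedOutcome],
    ranking: FrequencyRanking,
    audit: AuditLog | None = None,
) -> list[UnifiedOutcome]:
    """Retain one instrument for one study, returning one unified row per arm.

    The retained instrument is the highest-ranked PROM reported by *every*
    arm (an instrument present in only one arm cannot yield an effect size).
    Instruments present in one arm only are flagged in the audit log.
    """
    if not outcomes:
        raise PrioritizationError("no normalized outcomes supplied")
    study_ids = {o.study_id for o in outcomes}
    if len(study_ids) != 1:
        raise PrioritizationError(f"outcomes span several studies: {sorted(study_ids)}")
    study_id = next(iter(study_ids))

    by_arm: dict[str, dict[str, NormalizedOutcome]] = {}
    for o in outcomes:
        slot = by_arm.setdefault(o.arm_id, {})
        if o.prom in slot:
            raise PrioritizationError(
                f"{study_id}/{o.arm_id}: duplicate normalized outcome for {o.prom}"
            )
        slot[o.prom] = o

    retained = _pick_prom(by_arm, ranking, study_id)

    if audit is not None:
        all_proms = {p for proms in by_arm.values() for p in proms}
        partial = {
            p for p in all_proms if any(p not in proms for proms in by_arm.values())
        }
        for p in sorted(partial):
            audit.record(
                "prioritize",
                "prom_not_in_all_arms",
                f"{p} reported in only some arms; ineligible for retention",
                study_id=study_id,
                prom=p,
            )

    unified: list[UnifiedOutcome] = []
    for arm_id, proms in by_arm.items():
        chosen = proms[retained]
        discarded = tuple(sorted(p for p in proms if p != retained))
        if audit is not None:
            for p in discarded:
                audit.record(
                    "prioritize",
                    "discarded",
                    f"{p} discarded in favour of higher-ranked {retained}",
                    study_id=study_id,
                    arm_id=arm_id,
                    prom=p,
                )
        unified.append(
            UnifiedOutcome(
                study_id=study_id,
                arm_id=arm_id,
                n=chosen.n,
                source_prom=retained,
                mean_mcid=chosen.mean_mcid,
                sd_mcid=chosen.sd_mcid,
                discarded=discarded,
            )
        )
    unified.sort(key=lambda u: u.arm_id)
    return unified


def prioritize_all(
    outcomes: Sequence[NormalizedOutcome],
    ranking: FrequencyRanking,
    audit: AuditLog | None = None,
) -> list[UnifiedOutcome]:
    """Apply :func:`prioritize_study` study by study, preserving input order."""
    order: list[str] = []
    grouped: dict[str, list[NormalizedOutcome]] = {}
    for o in outcomes:
        if o.study_id not in grouped:
            order.append(o.study_id)
            grouped[o.study_id] = []
        grouped[o.study_id].append(o)
    unified: list[UnifiedOutcome] = []
    for study_id in order:
        unified.extend(prioritize_study(grouped[study_id], ranking, audit))
    return unified
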
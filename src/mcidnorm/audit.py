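"""Machine-readable audit trail.

Every discretionary numeric decision the pipeline takes — SD imputation,
range-based SD estimation, out-of-scale warnings, discarded instruments,
excluded studies, tie-breaks, truncation during simulation — is recorded as
one event so a reviewer can reconstruct why each number looks the way it does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike

import pandas as pd

logger = logging.getLogger("mcidnorm")

__all__ = ["AuditEvent", "AuditLog"]


@dataclass(frozen=True)
class AuditEvent:
    stage: str  # pipeline stage that took the decision
    kind: str  # e.g. sd_imputed, discarded, excluded, tie_break, truncated
    message: str
    study_id: str = ""
    arm_id: str = ""
    prom: str = ""


class AuditLog:
    """Append-only list of :class:`AuditEvent`, mirrored to the package logger."""

    def __init__(self) -> None:
        self.events: list[AuditEvent] = []

    def record(
        self,
        stage: str,
        kind: str,
        message: str,
        *,
        study_id: str = "",
        arm_id: str = "",
        prom: str = "",
    ) -> None:
        ev = AuditEvent(stage, kind, message, str(study_id), str(arm_id), str(prom))
        self.events.append(ev)
        logger.info("[%s/%s] %s %s %s: %s", stage, kind, ev.study_id, ev.arm_id, ev.prom, message)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def filter(self, *, stage: str | None = None, kind: str | None = None) -> list[AuditEvent]:
        return [
            e
            for e in self.events
            if (stage is None or e.stage == stage) and (kind is None or e.kind == kind)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": e.stage,
                    "kind": e.kind,
                    "study_id": e.study_id,
                    "arm_id": e.arm_id,
                    "prom": e.prom,
                    "message": e.message,
                }
                for e in self.events
            ],
            columns=["stage", "kind", "study_id", "arm_id", "prom", "message"],
        )

    def write(self, path: str | PathLike) -> None:
        self.to_frame().to_csv(path, index=False)
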
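"""Frequency ranking of PROMs from a study-by-instrument incidence matrix.

The prioritization rule downstream retains, per study, the instrument most
frequently reported across the literature.  This module counts mentions in a
long-format incidence table (one row per study x PROM) and turns the counts
into an ordered ranking with an explicit, recorded tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .audit import AuditLog
from .errors import RankingError, SchemaError, ValidationError
from .registry import PromRegistry, canonical_name

__all__ = [
    "IncidenceMatrix",
    "RankRow",
    "FrequencyRanking",
    "count_mentions",
    "rank_proms",
]


@dataclass(frozen=True)
class IncidenceMatrix:
    """Set of (study_id, prom) pairs; each pair means the study reported the PROM."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for study, prom in self.entries:
            key = (str(study), canonical_name(prom))
            if key in seen:
                raise ValidationError(f"duplicate incidence entry: {study!r} / {prom!r}")
            seen.add(key)

    @property
    def studies(self) -> tuple[str, ...]:
        out, seen = [], set()
        for s, _ in self.entries:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return tuple(out)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceMatrix":
        missing = [c for c in ("study_id", "prom") if c not in df.columns]
        if missing:
            raise SchemaError(f"incidence table missing column(s): {', '.join(missing)}")
        return cls(tuple((str(r.study_id), str(r.prom)) for r in df.itertuples()))

    @classmethod
    def from_file(cls, path: str | PathLike) -> "IncidenceMatrix":
        return cls.from_frame(pd.read_csv(path, dtype=str))


def count_mentions(
    matrix: IncidenceMatrix,
    registry: PromRegistry | None = None,
    audit: AuditLog | None = None,
) -> dict[str, int]:
    """Count distinct (study, PROM) pairs per instrument.

    A study reporting several PROMs contributes once to each of them.  When a
    registry is given, mentions that cannot be resolved against it (e.g. a bare
    "iHOT" with no version) are excluded from counting — the study itself stays
    in the matrix — and each exclusion is audited.
    """
    counts: dict[str, int] = {}
    for study, prom in matrix.entries:
        if registry is not None:
            if prom not in registry:
                if audit is not None:
                    audit.record(
                        "frequency",
                        "unspecified_prom_excluded",
                        f"mention {prom!r} not resolvable in registry; excluded from counts",
                        study_id=study,
                        prom=prom,
                    )
                continue
            name = registry.lookup(prom).name
        else:
            name = prom
        counts[name] = counts.get(name, 0) + 1
    return counts


@dataclass(frozen=True)
class RankRow:
    rank: int
    prom: str
    count: int
    percent: float


@dataclass(frozen=True)
class FrequencyRanking:
    """Instruments ordered by literature frequency, highest count first."""

    rows: tuple[RankRow, ...]
    tie_rule: str = "lexicographic"

    def __post_init__(self) -> None:
        counts = [r.count for r in self.rows]
        if any(c2 > c1 for c1, c2 in zip(counts, counts[1:])):
            raise ValidationError("ranking rows must be non-increasing in count")

    def rank_of(self, prom: str) -> int:
        key = canonical_name(prom)
        for r in self.rows:
            if canonical_name(r.prom) == key:
                return r.rank
        raise RankingError(f"PROM {prom!r} is not in the frequency ranking")

    def __contains__(self, prom: str) -> bool:
        key = canonical_name(prom)
        return any(canonical_name(r.prom) == key for r in self.rows)

    @property
    def proms(self) -> tuple[str, ...]:
        return tuple(r.prom for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"rank": r.rank, "prom": r.prom, "count": r.count, "percent": r.percent} for r in self.rows]
        )

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        tie_break: str = "lexicographic",
        tie_order: Sequence[str] | None = None,
    ) -> "FrequencyRanking":
        return rank_proms(counts, tie_break=tie_break, tie_order=tie_order)

    @classmethod
    def from_file(cls, path: str | PathLike) -> "FrequencyRanking":
        """Read a ranking table (columns prom, count; row order breaks ties)."""
        df = pd.read_csv(path)
        missing = [c for c in ("prom", "count") if c not in df.columns]
        if missing:
            raise SchemaError(f"ranking table missing column(s): {', '.join(missing)}")
        counts = {str(r.prom): int(r.count) for r in df.itertuples()}
        return rank_proms(counts, tie_break="file_order", tie_order=list(df["prom"]))


def rank_proms(
    counts: Mapping[str, int],
    tie_break: str = "lexicographic",
    tie_order: Sequence[str] | None = None,
) -> FrequencyRanking:
    """Order instruments by descending mention count.

    Ties are broken lexicographically on the canonical name by default; an
    explicit ``tie_order`` (a list of PROM names, earlier = higher priority)
    overrides that, which is how a published prioritization order that differs
    from alphabetical can be honoured.  The applied rule is recorded in
    ``tie_rule``.
    """
    if any(c < 0 for c in counts.values()):
        raise ValidationError("mention counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise RankingError("all mention counts are zero; no ranking possible")

    if tie_order is not None:
        pos = {canonical_name(p): i for i, p in enumerate(tie_order)}

        def key(item):
            name, count = item
            return (-count, pos.get(canonical_name(name), len(pos)), canonical_name(name))

        rule = tie_break if tie_break != "lexicographic" else "explicit_order"
    else:

        def key(item):
            name, count = item
            return (-count, canonical_name(name))

        rule = "lexicographic"

    ordered = sorted(counts.items(), key=key)
    rows = tuple(
        RankRow(rank=i + 1, prom=name, count=int(count), percent=100.0 * count / total)
        for i, (name, count) in enumerate(ordered)
    )
    return FrequencyRanking(rows=rows, tie_rule=rule)
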
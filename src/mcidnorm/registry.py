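"""Instrument registry: PROM metadata (scale, orientation, MCID) and name lookup.

Every downstream transform divides by an instrument's minimal clinically
important difference (MCID), so the registry is the single source of truth
for which instruments are normalizable and by what divisor.  Names in the
literature are inconsistent ("HOS-Sport" vs "HOS-SSS", Unicode hyphens from
copy-pasted tables), so lookup goes through a canonicalization step and an
optional synonym map carried in the registry file itself.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Iterator

import pandas as pd

from .errors import SchemaError, UnknownPromError, ValidationError

__all__ = [
    "Orientation",
    "PROMDefinition",
    "PromRegistry",
    "canonical_name",
    "load_registry",
]

_HYPHENS = "‐‑‒–—−"  # unicode hyphen/dash variants


def canonical_name(name: str) -> str:
    """Canonical lookup key for an instrument name.

    Case-insensitive, all dash variants unified to ASCII ``-``, whitespace
    runs collapsed to a single ``-``.  Idempotent by construction.
    """
    s = unicodedata.normalize("NFKC", str(name))
    for h in _HYPHENS:
        s = s.replace(h, "-")
    s = re.sub(r"\s+", "-", s.strip())
    s = re.sub(r"-+", "-", s)
    return s.casefold()


class Orientation(str, enum.Enum):
    """Direction of a PROM scale: whether higher scores mean better function."""

    higher_better = "higher_better"
    higher_worse = "higher_worse"


@dataclass(frozen=True)
class PROMDefinition:
    """One instrument: identity, scale bounds, orientation and MCID.

    ``mcid is None`` marks an instrument that appears in the literature but
    has no published MCID; it can be counted and ranked but not normalized.
    """

    name: str
    scale_min: float
    scale_max: float
    orientation: Orientation = Orientation.higher_better
    mcid: float | None = None
    mcid_source: str = ""

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValidationError("PROM name must be non-empty")
        if not self.scale_min < self.scale_max:
            raise ValidationError(
                f"{self.name}: scale_min ({self.scale_min}) must be below "
                f"scale_max ({self.scale_max})"
            )
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        if self.mcid is not None and not self.mcid > 0:
            raise ValidationError(f"{self.name}: MCID must be positive, got {self.mcid}")

    @property
    def normalizable(self) -> bool:
        return self.mcid is not None


REQUIRED_COLUMNS = ("name", "scale_min", "scale_max", "orientation", "mcid", "mcid_source")


class PromRegistry:
    """Collection of :class:`PROMDefinition` with canonicalized, synonym-aware lookup."""

    def __init__(
        self,
        definitions: Iterable[PROMDefinition],
        synonyms: dict[str, str] | None = None,
    ):
        self._defs: dict[str, PROMDefinition] = {}
        for d in definitions:
            key = canonical_name(d.name)
            if key in self._defs:
                raise ValidationError(f"duplicate PROM name in registry: {d.name!r}")
            self._defs[key] = d
        self._synonyms = {
            canonical_name(alias): canonical_name(target)
            for alias, target in (synonyms or {}).items()
        }

    def lookup(self, name: str) -> PROMDefinition:
        key = canonical_name(name)
        key = self._synonyms.get(key, key)
        try:
            return self._defs[key]
        except KeyError:
            raise UnknownPromError(name, self.names) from None

    def __contains__(self, name: str) -> bool:
        key = canonical_name(name)
        return self._synonyms.get(key, key) in self._defs

    def __iter__(self) -> Iterator[PROMDefinition]:
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self._defs.values())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PromRegistry":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"registry table missing column(s): {', '.join(missing)}")
        defs: list[PROMDefinition] = []
        synonyms: dict[str, str] = {}
        for idx, row in df.iterrows():
            mcid_raw = row["mcid"]
            if pd.isna(mcid_raw) or str(mcid_raw).strip() == "":
                mcid = None
            else:
                try:
                    mcid = float(mcid_raw)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"registry row {idx} ({row['name']!r}): "
                        f"mcid {mcid_raw!r} is not a number"
                    ) from None
                if not mcid > 0:
                    raise ValidationError(
                        f"registry row {idx} ({row['name']!r}): mcid must be positive"
                    )
            try:
                d = PROMDefinition(
                    name=str(row["name"]),
                    scale_min=float(row["scale_min"]),
                    scale_max=float(row["scale_max"]),
                    orientation=Orientation(str(row["orientation"])),
                    mcid=mcid,
                    mcid_source="" if pd.isna(row["mcid_source"]) else str(row["mcid_source"]),
                )
            except ValueError as exc:
                raise ValidationError(f"registry row {idx}: {exc}") from None
            defs.append(d)
            aliases = row.get("synonyms")
            if aliases is not None and not pd.isna(aliases):
                for alias in str(aliases).split(";"):
                    if alias.strip():
                        synonyms[alias] = d.name
        return cls(defs, synonyms)


def load_registry(path: str | PathLike) -> PromRegistry:
    """Load a registry from a comma-separated UTF-8 table.

    Columns: name, scale_min, scale_max, orientation, mcid, mcid_source and an
    optional semicolon-separated ``synonyms`` column.  An empty mcid cell means
    the instrument has no published MCID and is flagged non-normalizable.
    """
    df = pd.read_csv(path, dtype={"name": str})
    return PromRegistry.from_frame(df)
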
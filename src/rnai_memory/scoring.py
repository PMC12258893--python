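"""Data model and I/O for GFP scoring tables.

A scoring table is the raw quantitative record of a multigenerational RNAi
silencing-memory assay: for each experimental block, strain, environment and
replicate, ~100 individuals are scored at each generation as OFF, DIM or ON
according to germline GFP expression. Generation index 0 is the last
RNAi-exposed generation (G0); index 1 is the first trigger-free generation
(G1). Rows at index -1 (the first exposed generation, G-1) are accepted but
ignored by the analysis stages.

The on-disk format is a UTF-8 CSV with the fixed header
``block,strain,environment,replicate,generation,n_off,n_dim,n_on``. The
``n_dim`` column may be omitted for two-category (ON/OFF) assays, in which
case DIM counts are zero.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple

import pandas as pd

from .errors import SchemaError, ValidationError

CANONICAL_COLUMNS = (
    "block",
    "strain",
    "environment",
    "replicate",
    "generation",
    "n_off",
    "n_dim",
    "n_on",
)

#: Columns that may be absent on disk, with the value they default to.
_OPTIONAL_COLUMNS = {"n_dim": 0}


class GroupKey(NamedTuple):
    """Identifies one replicate line: a (block, strain, environment, replicate)."""

    block: str
    strain: str
    environment: str
    replicate: int


@dataclass(frozen=True)
class ScoringRecord:
    """One scored time point: identifiers plus OFF/DIM/ON counts."""

    block: str
    strain: str
    environment: str
    replicate: int
    generation: int
    n_off: int
    n_dim: int
    n_on: int

    def __post_init__(self) -> None:
        for name in ("n_off", "n_dim", "n_on"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
        if self.total < 1:
            raise ValidationError("a scoring record must count at least one individual")
        if not isinstance(self.replicate, int) or isinstance(self.replicate, bool):
            raise ValidationError(f"replicate must be an integer, got {self.replicate!r}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if not isinstance(self.generation, int) or isinstance(self.generation, bool):
            raise ValidationError(f"generation must be an integer, got {self.generation!r}")
        if self.generation < -1:
            raise ValidationError(
                f"generation must be >= -1 (G-1 is the earliest exposed generation), "
                f"got {self.generation}"
            )

    @property
    def total(self) -> int:
        return self.n_off + self.n_dim + self.n_on

    @property
    def group_key(self) -> GroupKey:
        return GroupKey(self.block, self.strain, self.environment, self.replicate)

    @property
    def key(self) -> tuple:
        return (*self.group_key, self.generation)


@dataclass(frozen=True)
class ScoringTable:
    """An ordered collection of unique scoring records plus provenance metadata."""

    records: tuple[ScoringRecord, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: dict[tuple, int] = {}
        for i, rec in enumerate(self.records):
            if rec.key in seen:
                raise ValidationError(
                    f"duplicate scoring key {rec.key} at rows {seen[rec.key]} and {i}"
                )
            seen[rec.key] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ScoringRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoringTable):
            return NotImplemented
        return self.records == other.records

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(r, c) for c in CANONICAL_COLUMNS] for r in self.records],
            columns=list(CANONICAL_COLUMNS),
        )


def _parse_int(value, column: str, row: int) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: column {column!r} is not a number: {value!r}")
    if f != int(f):
        raise ValidationError(f"row {row}: column {column!r} must be an integer, got {value!r}")
    return int(f)


def table_from_dataframe(df: pd.DataFrame, metadata: Mapping[str, str] | None = None) -> ScoringTable:
    """Validate a dataframe row by row and assemble a :class:`ScoringTable`."""
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            if col in _OPTIONAL_COLUMNS:
                df = df.assign(**{col: _OPTIONAL_COLUMNS[col]})
            else:
                raise SchemaError(f"missing required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                ScoringRecord(
                    block=str(getattr(row, "block")),
                    strain=str(getattr(row, "strain")),
                    environment=str(getattr(row, "environment")),
                    replicate=_parse_int(getattr(row, "replicate"), "replicate", i),
                    generation=_parse_int(getattr(row, "generation"), "generation", i),
                    n_off=_parse_int(getattr(row, "n_off"), "n_off", i),
                    n_dim=_parse_int(getattr(row, "n_dim"), "n_dim", i),
                    n_on=_parse_int(getattr(row, "n_on"), "n_on", i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return ScoringTable(records=tuple(records), metadata=dict(metadata or {}))


def read_scoring_table(path) -> ScoringTable:
    """Read the canonical scoring CSV, validating every row.

    Raises :class:`SchemaError` for a missing required column and
    :class:`ValidationError` (naming the row) for malformed counts or
    duplicate (block, strain, environment, replicate, generation) keys.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return table_from_dataframe(df)


def write_scoring_table(table: ScoringTable, path) -> None:
    """Write the canonical scoring CSV (fixed column order, UTF-8)."""
    table.to_dataframe().to_csv(path, index=False)


def group_replicates(table: ScoringTable) -> "OrderedDict[GroupKey, tuple[ScoringRecord, ...]]":
    """Partition a table into per-replicate groups sorted by generation.

    One group per (block, strain, environment, replicate), in first-appearance
    order; records within a group are sorted by generation index. Every record
    lands in exactly one group.
    """
    groups: OrderedDict[GroupKey, list[ScoringRecord]] = OrderedDict()
    for rec in table:
        groups.setdefault(rec.group_key, []).append(rec)
    return OrderedDict(
        (key, tuple(sorted(recs, key=lambda r: r.generation))) for key, recs in groups.items()
    )
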
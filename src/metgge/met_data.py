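"""Data model and I/O for balanced multi-environment trial (MET) data.

A MET observes ``g`` genotypes in ``e`` environments with ``r`` replicates;
the long format carries one row per plot observation, and analyses consume
the genotype x environment table of cell means (:class:`TraitMatrix`).
Labels are compared case-sensitively and whitespace-trimmed on load; missing
values are never imputed — unbalanced data is a hard error downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    BalanceError,
    DuplicateRecordError,
    ParseError,
    SchemaError,
)

ID_COLUMNS = ("genotype", "environment", "replicate")


@dataclass
class METDataset:
    """Long-format plot observations of a multi-environment trial.

    Parameters
    ----------
    data
        One row per (genotype, environment, replicate) record with the id
        columns ``genotype``, ``environment``, ``replicate`` followed by one
        numeric column per trait.
    trait_names
        Ordered trait labels (the non-id columns of ``data``).
    genotype_order, environment_order
        Stable label orders, defaulting to first appearance in ``data``.
    metadata
        Free-text annotations (units etc.); never interpreted.
    """

    data: pd.DataFrame
    trait_names: list[str]
    genotype_order: list[str] = field(default_factory=list)
    environment_order: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ID_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"missing id column {col!r}")
        for trait in self.trait_names:
            if trait not in self.data.columns:
                raise SchemaError(f"missing trait column {trait!r}")
            values = self.data[trait].to_numpy()
            if not np.issubdtype(values.dtype, np.number):
                raise ParseError(f"trait {trait!r} is not numeric")
            if not np.all(np.isfinite(values)):
                raise ParseError(f"trait {trait!r} contains non-finite values")
        if not self.genotype_order:
            self.genotype_order = list(dict.fromkeys(self.data["genotype"]))
        if not self.environment_order:
            self.environment_order = list(dict.fromkeys(self.data["environment"]))
        unknown_g = set(self.data["genotype"]) - set(self.genotype_order)
        unknown_e = set(self.data["environment"]) - set(self.environment_order)
        if unknown_g or unknown_e:
            raise SchemaError(
                f"labels outside declared order lists: {sorted(unknown_g | unknown_e)}"
            )
        dup = self.data.duplicated(subset=list(ID_COLUMNS))
        if dup.any():
            first = self.data.loc[dup, list(ID_COLUMNS)].iloc[0].tolist()
            raise DuplicateRecordError(
                f"duplicate (genotype, environment, replicate) record: {tuple(first)}"
            )

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_order)

    @property
    def n_environments(self) -> int:
        return len(self.environment_order)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class TraitMatrix:
    """Genotype x environment table of cell means for one trait.

    The two-way table is what the GGE model decomposes: ``Y_ij`` entries
    around a grand mean ``mu`` with environment deviations ``e_j``.
    """

    values: np.ndarray
    genotype_labels: list[str]
    environment_labels: list[str]
    trait_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g, e = self.values.shape
        if g != len(self.genotype_labels) or e != len(self.environment_labels):
            raise SchemaError("matrix shape does not match label lists")
        if g < 2 or e < 2:
            raise SchemaError("two-way table needs g >= 2 and e >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ParseError("two-way table contains non-finite cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.genotype_labels, columns=self.environment_labels
        )


@dataclass
class BalanceReport:
    """Result of :func:`validate_balance` — a report, not an exception."""

    complete: bool
    r: int | None
    offending_cells: list[tuple[str, str]]


DEFAULT_SCHEMA = {c: c for c in ID_COLUMNS}


def load_long_csv(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> METDataset:
    """Load a long-format MET CSV (one row per plot observation).

    ``schema`` maps the canonical roles ``genotype``/``environment``/
    ``replicate`` to the file's column names; all remaining columns are
    treated as traits and must parse as numbers.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    for role in ID_COLUMNS:
        col = schema[role]
        if col not in raw.columns:
            raise SchemaError(f"missing column {col!r} (role {role!r})")
    rename = {schema[role]: role for role in ID_COLUMNS}
    raw = raw.rename(columns=rename)
    trait_names = [c for c in raw.columns if c not in ID_COLUMNS]
    for col in ID_COLUMNS:
        raw[col] = raw[col].str.strip()
    for trait in trait_names:
        parsed = pd.to_numeric(raw[trait].str.strip(), errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise ParseError(
                f"non-numeric value {raw[trait][bad.idxmax()]!r} for trait "
                f"{trait!r} at line {row}",
                row=row,
            )
        raw[trait] = parsed
    return METDataset(data=raw, trait_names=trait_names)


def write_long_csv(dataset: METDataset, path: str | Path) -> None:
    """Write the canonical long CSV (UTF-8, '.' decimal separator)."""
    cols = list(ID_COLUMNS) + dataset.trait_names
    dataset.data[cols].to_csv(path, index=False)


def load_wide_csv(path: str | Path, trait_name: str = "trait") -> TraitMatrix:
    """Read a wide genotype x environment table (read-only interchange).

    First column holds genotype labels; remaining column headers are
    environment labels.
    """
    raw = pd.read_csv(path)
    genotypes = [str(v).strip() for v in raw.iloc[:, 0]]
    environments = [str(c).strip() for c in raw.columns[1:]]
    values = raw.iloc[:, 1:].to_numpy(dtype=float)
    return TraitMatrix(values, genotypes, environments, trait_name)


def write_wide_csv(matrix: TraitMatrix, path: str | Path) -> None:
    df = matrix.to_dataframe()
    df.index.name = "genotype"
    df.to_csv(path)


def validate_balance(dataset: METDataset) -> BalanceReport:
    """Check that every genotype x environment cell has the same replicate count."""
    counts = (
        dataset.data.groupby(["genotype", "environment"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=dataset.genotype_order, columns=dataset.environment_order)
        .fillna(0)
        .astype(int)
    )
    values = counts.to_numpy()
    r = int(values.max(initial=0))
    offending = [
        (g, e)
        for g in dataset.genotype_order
        for e in dataset.environment_order
        if counts.loc[g, e] != r
    ]
    complete = not offending and r >= 1
    return BalanceReport(complete=complete, r=r if complete else None,
                         offending_cells=offending)


def to_two_way(
    dataset: METDataset, trait: str, aggregator: str = "mean"
) -> TraitMatrix:
    """Collapse replicates into the genotype x environment table of cell means."""
    if trait not in dataset.trait_names:
        raise SchemaError(f"unknown trait {trait!r}")
    if aggregator != "mean":
        raise SchemaError(f"unsupported aggregator {aggregator!r}")
    cell = (
        dataset.data.groupby(["genotype", "environment"], sort=False)[trait]
        .mean()
        .unstack()
        .reindex(index=dataset.genotype_order, columns=dataset.environment_order)
    )
    missing = [
        (g, e)
        for g in dataset.genotype_order
        for e in dataset.environment_order
        if pd.isna(cell.loc[g, e])
    ]
    if missing:
        raise BalanceError(f"empty genotype x environment cells: {missing}", missing)
    return TraitMatrix(
        cell.to_numpy(), dataset.genotype_order, dataset.environment_order, trait
    )


def from_records(
    records: Iterable[tuple[str, str, str, Mapping[str, float]]]
) -> METDataset:
    """Build a dataset from (genotype, environment, replicate, traits) tuples."""
    rows = []
    for g, e, r, traits in records:
        rows.append({"genotype": g, "environment": e, "replicate": r, **traits})
    df = pd.DataFrame(rows)
    trait_names = [c for c in df.columns if c not in ID_COLUMNS]
    return METDataset(data=df, trait_names=trait_names)
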
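"""Base linear phenotypic selection index (BLPSI).

The base index scores each genotype by a weighted sum of its trait
phenotypes, ``I_i = sum_t w_t * y_it``, with economic weights supplied by
the breeder. The default is unit weights on the raw trait scales (the
classical base index); weights may also be standardized (z-scored traits)
or derived from a genetic-correlation vector supplied by the caller. Sign
conventions (e.g. negative weight on maturity for earliness) are the
caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError
from .met_data import METDataset


@dataclass
class IndexSpec:
    trait_names: list[str]
    weights: list[float] | None = None
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = [1.0] * len(self.trait_names)
        if len(self.weights) != len(self.trait_names):
            raise SchemaError("weights length must equal trait count")
        if not any(w != 0 for w in self.weights):
            raise SchemaError("at least one weight must be nonzero")


def blpsi(trait_table: pd.DataFrame, spec: IndexSpec) -> pd.Series:
    """Index value per genotype from a genotype x trait table of phenotypes."""
    missing = [t for t in spec.trait_names if t not in trait_table.columns]
    if missing:
        raise SchemaError(f"traits absent from table: {missing}")
    values = trait_table[spec.trait_names].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise SchemaError("missing trait values")
    if spec.standardize:
        sd = values.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [t for t, s in zip(spec.trait_names, sd) if s == 0]
            raise DomainError(f"zero-variance traits cannot be standardized: {bad}")
        values = (values - values.mean(axis=0)) / sd
    index = values @ np.asarray(spec.weights, dtype=float)
    return pd.Series(index, index=trait_table.index, name="BLPSI")


def append_index_trait(
    dataset: METDataset, spec: IndexSpec, name: str = "BLPSI"
) -> METDataset:
    """Attach the index as a pseudo-trait computed per plot record.

    The per-record index flows unchanged through cell-mean aggregation and
    the GGE engine because the index is linear in the traits.
    """
    if name in dataset.trait_names:
        raise SchemaError(f"trait {name!r} already present")
    table = dataset.data[spec.trait_names]
    data = dataset.data.copy()
    data[name] = blpsi(table, spec).to_numpy()
    return METDataset(
        data=data,
        trait_names=dataset.trait_names + [name],
        genotype_order=list(dataset.genotype_order),
        environment_order=list(dataset.environment_order),
        metadata=dict(dataset.metadata),
    )
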
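"""Bundled reference data: a published grasspea multi-location trial summary.

The package ships the genotype-mean summary of a trial of 64 grasspea
(*Lathyrus sativus*) genotypes evaluated at four Indian locations in one
winter season: per-genotype means of days to maturity (DTM, days),
biological yield (BY, t/ha), seed yield (SY, kg/ha) and a published
multi-trait selection index (BLPSI, treated as data — its exact weights
were not published); per-location trait means; the published ANOVA mean
squares with percent contributions; and the published genetic-parameter
table. Plot-level data were not released, so these summaries are the
finest-grained fixture available.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

TRAITS = ("DTM", "BY", "SY", "BLPSI")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("metgge.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_genotype_means() -> pd.DataFrame:
    """64 genotype-mean rows with DTM, BY, SY and the published BLPSI."""
    return _read("grasspea_genotype_means.csv")


def load_location_means() -> pd.DataFrame:
    """Trait means of the four testing locations (L1..L4)."""
    return _read("grasspea_location_means.csv")


def load_anova_mean_squares() -> pd.DataFrame:
    """Published mean squares (df, MS, percent contribution) per trait/source."""
    return _read("grasspea_anova_ms.csv")


def load_genetic_params() -> pd.DataFrame:
    """Published descriptives and genetic parameters per trait."""
    return _read("grasspea_genetic_params.csv")


def make_fixtures(outdir: str | Path) -> dict[str, str]:
    """Write the bundled tables to ``outdir`` and return name -> sha256."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    for name in (
        "grasspea_genotype_means.csv",
        "grasspea_location_means.csv",
        "grasspea_anova_ms.csv",
        "grasspea_genetic_params.csv",
    ):
        ref = resources.files("metgge.data").joinpath(name)
        content = ref.read_bytes()
        (outdir / name).write_bytes(content)
        checksums[name] = hashlib.sha256(content).hexdigest()
    return checksums
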
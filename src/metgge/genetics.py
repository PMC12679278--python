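"""Two-way ANOVA, variance components and genetic parameters for MET data.

The trial is analysed as a balanced two-way layout with replication.
Percent contribution of the three non-error sources defaults to the
mean-square share ``100 * MS_s / (MS_E + MS_G + MS_GE)``; the sum-of-squares
share is available behind ``basis="ss"``. Genetic parameters follow the
standard plant-breeding definitions: GCV/PCV are genotypic/phenotypic
coefficients of variation, broad-sense heritability h2 = var_g / var_p, and
genetic advance GA = k * h2 * sigma_p with selection intensity k (2.06 at
the conventional 5% selected fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BalanceError, DomainError, SchemaError
from .met_data import METDataset, validate_balance

SOURCES = ("environment", "genotype", "interaction", "error")
NON_ERROR = ("environment", "genotype", "interaction")


@dataclass
class AnovaTable:
    """Per-source df / SS / MS for a balanced two-way trial."""

    trait: str
    g: int
    e: int
    r: int
    df: dict[str, int]
    ss: dict[str, float]
    ms: dict[str, float]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"source": s, "df": self.df[s], "SS": self.ss[s], "MS": self.ms[s]}
            for s in self.df
        ]
        return pd.DataFrame(rows)


@dataclass
class VarianceComponents:
    var_g: float
    var_ge: float
    var_err: float
    truncated: list[str] = field(default_factory=list)


@dataclass
class GeneticParams:
    """Descriptive and genetic parameters for one trait."""

    mean: float
    var_g: float
    var_p: float
    h2: float
    gcv: float
    pcv: float
    ga: float
    ga_pct: float
    k: float
    minimum: float | None = None
    maximum: float | None = None


def two_way_anova(dataset: METDataset, trait: str) -> AnovaTable:
    """Definitional sums of squares of the balanced genotype x environment layout.

    SS_E = g*r * sum_j (ybar_.j. - ybar...)^2, SS_G = e*r * sum_i (ybar_i.. -
    ybar...)^2, SS_GE = r * sum_ij (ybar_ij. - ybar_i.. - ybar_.j. + ybar...)^2
    and SS_err = sum_ijr (y_ijr - ybar_ij.)^2; their total equals the overall
    sum of squares (identity checked). With r = 1 the error row is absent.
    """
    if trait not in dataset.trait_names:
        raise SchemaError(f"unknown trait {trait!r}")
    report = validate_balance(dataset)
    if not report.complete:
        raise BalanceError(
            f"unbalanced layout; offending cells: {report.offending_cells}",
            report.offending_cells,
        )
    r = report.r
    g, e = dataset.n_genotypes, dataset.n_environments
    cell = (
        dataset.data.groupby(["genotype", "environment"], sort=False)[trait]
        .mean()
        .unstack()
        .reindex(index=dataset.genotype_order, columns=dataset.environment_order)
        .to_numpy()
    )
    grand = cell.mean()
    gm = cell.mean(axis=1)  # genotype means ybar_i..
    em = cell.mean(axis=0)  # environment means ybar_.j.
    ss = {
        "environment": g * r * float(np.sum((em - grand) ** 2)),
        "genotype": e * r * float(np.sum((gm - grand) ** 2)),
        "interaction": r * float(
            np.sum((cell - gm[:, None] - em[None, :] + grand) ** 2)
        ),
    }
    df = {"environment": e - 1, "genotype": g - 1, "interaction": (g - 1) * (e - 1)}
    if r >= 2:
        y = dataset.data.set_index(["genotype", "environment"])[trait]
        cell_series = pd.DataFrame(
            cell, index=dataset.genotype_order, columns=dataset.environment_order
        ).stack()
        resid = y - cell_series.reindex(y.index).to_numpy()
        ss["error"] = float(np.sum(resid.to_numpy() ** 2))
        df["error"] = g * e * (r - 1)
    ms = {s: ss[s] / df[s] for s in ss}
    return AnovaTable(trait=trait, g=g, e=e, r=r, df=df, ss=ss, ms=ms)


def percent_contribution(
    anova: AnovaTable | Mapping[str, float], basis: str = "ms"
) -> dict[str, float]:
    """Share of the environment / genotype / interaction sources, in percent.

    ``basis="ms"`` (default) uses mean squares; ``basis="ss"`` uses sums of
    squares. Shares sum to exactly 100 before rounding.
    """
    if basis not in ("ms", "ss"):
        raise SchemaError(f"unknown basis {basis!r}")
    if isinstance(anova, AnovaTable):
        values = anova.ms if basis == "ms" else anova.ss
    else:
        values = anova
    try:
        parts = {s: float(values[s]) for s in NON_ERROR}
    except KeyError as exc:
        raise SchemaError(f"missing source {exc.args[0]!r}") from exc
    total = sum(parts.values())
    if total <= 0:
        raise DomainError("total of source terms is not positive")
    return {s: 100.0 * v / total for s, v in parts.items()}


def variance_components(anova: AnovaTable) -> VarianceComponents:
    """Method-of-moments estimates under the balanced random model.

    var_err = MS_err, var_ge = (MS_GE - MS_err) / r, var_g = (MS_G - MS_GE)
    / (e*r). Negative estimates are truncated to zero and flagged.
    """
    if "error" not in anova.ms:
        raise DomainError("error mean square absent (r = 1): components undefined")
    raw = {
        "var_err": anova.ms["error"],
        "var_ge": (anova.ms["interaction"] - anova.ms["error"]) / anova.r,
        "var_g": (anova.ms["genotype"] - anova.ms["interaction"]) / (anova.e * anova.r),
    }
    truncated = [k for k, v in raw.items() if v < 0]
    clipped = {k: max(v, 0.0) for k, v in raw.items()}
    return VarianceComponents(
        var_g=clipped["var_g"],
        var_ge=clipped["var_ge"],
        var_err=clipped["var_err"],
        truncated=truncated,
    )


def heritability_from_anova(components: VarianceComponents, e: int, r: int) -> float:
    """ANOVA-based broad-sense heritability on a genotype-mean basis.

    h2 = var_g / (var_g + var_ge/e + var_err/(e*r)). Offered as an
    alternative estimator; the default genetic-parameter path takes h2 as
    given and defines var_p = var_g / h2 for self-consistency with printed
    GCV/PCV/heritability triplets.
    """
    denom = components.var_g + components.var_ge / e + components.var_err / (e * r)
    if denom <= 0:
        raise DomainError("phenotypic variance is not positive")
    return components.var_g / denom


def genetic_parameters(
    var_g: float,
    h2: float,
    mean: float,
    k: float = 2.06,
    minimum: float | None = None,
    maximum: float | None = None,
) -> GeneticParams:
    """GCV, PCV, genetic advance and GA%% from var_g, heritability and the mean."""
    if var_g < 0:
        raise DomainError("var_g must be nonnegative")
    if not 0 < h2 <= 1:
        raise DomainError("h2 must lie in (0, 1]")
    if mean == 0:
        raise DomainError("mean must be nonzero")
    var_p = var_g / h2
    sigma_p = np.sqrt(var_p)
    gcv = 100.0 * np.sqrt(var_g) / mean
    pcv = 100.0 * sigma_p / mean
    ga = k * h2 * sigma_p
    return GeneticParams(
        mean=mean,
        var_g=var_g,
        var_p=var_p,
        h2=h2,
        gcv=float(gcv),
        pcv=float(pcv),
        ga=float(ga),
        ga_pct=float(100.0 * ga / mean),
        k=k,
        minimum=minimum,
        maximum=maximum,
    )


def descriptive_stats(values) -> tuple[float, float, float]:
    """Mean, minimum and maximum of a vector of genotype means."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise DomainError("empty input")
    return float(arr.mean()), float(arr.min()), float(arr.max())


def lsd(ms_err: float, df_err: int, n_per_mean: int, alpha: float = 0.05) -> float:
    """Least significant difference between two means, t * sqrt(2*MS_err/n).

    Reported as a yardstick only; not used for inference elsewhere.
    """
    if df_err < 1 or n_per_mean < 1:
        raise DomainError("df_err and n_per_mean must be positive")
    t = stats.t.ppf(1 - alpha / 2, df_err)
    return float(t * np.sqrt(2.0 * ms_err / n_per_mean))
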
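"""Balanced MET simulator with additive genotype/environment/GxE structure.

The generative model is the conventional two-way random-effects reading of a
multi-location variety trial::

    Y_ijr = mu + G_i + E_j + GE_ij + eps_ijr

with all effects i.i.d. normal and mutually independent. Optionally the
interaction is planted as a rank-1 crossover pattern ``GE_ij = c * s_i * d_j``
(genotype loadings times group-signed environment loadings), which makes the
two-axis GGE representation exact by construction and gives a known
mega-environment partition for testing the which-won-where machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, NotApplicableError
from .met_data import ID_COLUMNS, METDataset


@dataclass
class CrossoverSpec:
    """Planted crossover interaction.

    ``n_groups`` contiguous environment groups receive alternating signs
    ``(+1, -1, +1, ...)``; ``magnitude`` scales the group signs before the
    whole interaction matrix is rescaled to the requested ``var_ge``.
    """

    n_groups: int = 2
    magnitude: float = 1.0


@dataclass
class SimulationConfig:
    """Study conditions for one simulated balanced trial.

    Defaults mirror a 64-genotype, 4-location, 2-replicate seed-yield trial
    (kg/ha scale): genotypic variance 16,500, GxE variance 95,000, location
    variance 270,000 and plot error 28,000.
    """

    g: int = 64
    e: int = 4
    r: int = 2
    mu: float = 1233.74
    var_g: float = 16_500.0
    var_e: float = 270_000.0
    var_ge: float = 95_000.0
    var_err: float = 28_000.0
    crossover: CrossoverSpec | None = None
    seed: int = 0
    sum_to_zero: bool = False
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        if self.g < 2 or self.e < 2 or self.r < 1:
            raise ConfigError("need g >= 2, e >= 2, r >= 1")
        for name in ("var_g", "var_e", "var_ge", "var_err"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.crossover is not None:
            if not 1 <= self.crossover.n_groups <= self.e:
                raise ConfigError("crossover n_groups must be in [1, e]")


def _environment_groups(config: SimulationConfig) -> list[list[int]]:
    """Split environment indices 0..e-1 into n_groups contiguous blocks."""
    idx = np.arange(config.e)
    return [list(part) for part in np.array_split(idx, config.crossover.n_groups)]


def _interaction_matrix(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.var_ge == 0:
        return np.zeros((config.g, config.e))
    if config.crossover is None:
        ge = rng.normal(0.0, np.sqrt(config.var_ge), size=(config.g, config.e))
        if config.sum_to_zero:
            ge -= ge.mean(axis=0, keepdims=True)
            ge -= ge.mean(axis=1, keepdims=True)
        return ge
    # rank-1 crossover: genotype loadings x group-signed environment loadings
    s = rng.normal(0.0, 1.0, size=config.g)
    d = np.empty(config.e)
    for k, group in enumerate(_environment_groups(config)):
        d[group] = ((-1.0) ** k) * config.crossover.magnitude
    ge = np.outer(s, d)
    rms = np.sqrt(np.mean(ge**2))
    if rms > 0:
        ge *= np.sqrt(config.var_ge) / rms
    return ge


def simulate_met(config: SimulationConfig) -> METDataset:
    """Draw one balanced trial; a fixed seed gives a bit-identical dataset."""
    rng = np.random.default_rng(config.seed)
    G = rng.normal(0.0, np.sqrt(config.var_g), size=config.g)
    E = rng.normal(0.0, np.sqrt(config.var_e), size=config.e)
    if config.sum_to_zero:
        G -= G.mean()
        E -= E.mean()
    GE = _interaction_matrix(config, rng)
    eps = rng.normal(0.0, np.sqrt(config.var_err), size=(config.g, config.e, config.r))
    y = (
        config.mu
        + G[:, None, None]
        + E[None, :, None]
        + GE[:, :, None]
        + eps
    )
    genotypes = [f"G{i + 1}" for i in range(config.g)]
    environments = [f"E{j + 1}" for j in range(config.e)]
    rows = {
        "genotype": np.repeat(genotypes, config.e * config.r),
        "environment": np.tile(np.repeat(environments, config.r), config.g),
        "replicate": np.tile([f"R{k + 1}" for k in range(config.r)],
                             config.g * config.e),
        config.trait_name: y.ravel(),
    }
    data = pd.DataFrame(rows, columns=list(ID_COLUMNS) + [config.trait_name])
    return METDataset(
        data=data,
        trait_names=[config.trait_name],
        genotype_order=genotypes,
        environment_order=environments,
        metadata={"seed": config.seed},
    )


def plant_crossover_truth(config: SimulationConfig) -> list[list[str]]:
    """Return the environment partition the crossover generator planted.

    With groups of opposite sign and negligible noise, the which-won-where
    analysis must recover exactly this partition.
    """
    if config.crossover is None:
        raise NotApplicableError("configuration has no crossover spec")
    labels = [f"E{j + 1}" for j in range(config.e)]
    return [[labels[j] for j in group] for group in _environment_groups(config)]
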
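"""GGE biplot engine.

A GGE biplot displays genotype main effect plus genotype-by-environment
interaction: the genotype x environment table of cell means is
environment-centered (column means removed, no scaling) and decomposed by
SVD. Singular values are partitioned onto the genotype side
(genotype-focused SVP, used for genotype evaluation) or the environment
side (environment-focused SVP, used for test-environment evaluation).

Views implemented on the two retained axes:

* mean vs. stability via the Average Environment Coordination (AEC) frame —
  projection on the AEC abscissa proxies mean performance, the signed
  perpendicular projection proxies instability;
* ranking against the "ideal" genotype (maximal mean proxy, zero
  instability) by Euclidean distance;
* discriminativeness vs. representativeness of environments (vector length,
  cosine with the abscissa) and their combination into a desirability index;
* which-won-where: the convex hull of genotype points, sectors delimited by
  rays perpendicular to hull edges, environment-to-sector assignment, the
  winning vertex genotype per sector, and the induced mega-environment
  partition;
* Ward hierarchical clustering of arbitrary feature tables (genotypes or
  environments).

Axis signs are fixed so each environment-loading column sums to >= 0 (ties:
first nonzero loading positive); the SVD's sign ambiguity must not flip
plots between runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull

from .errors import DegenerateGeometryError, DomainError, SchemaError
from .met_data import TraitMatrix

GENOTYPE_FOCUSED = "genotype-focused"
ENVIRONMENT_FOCUSED = "environment-focused"

_ANGLE_TOL = 1e-12


def center_environment(matrix: TraitMatrix | np.ndarray) -> np.ndarray:
    """Remove column (environment) means; no scaling is applied."""
    values = matrix.values if isinstance(matrix, TraitMatrix) else np.asarray(matrix, float)
    if values.size == 0:
        raise SchemaError("empty matrix")
    if values.shape[0] < 2:
        raise SchemaError("centering needs at least two genotypes")
    return values - values.mean(axis=0, keepdims=True)


@dataclass
class GGEModel:
    centered: np.ndarray
    singular_values: np.ndarray
    genotype_scores: np.ndarray
    environment_scores: np.ndarray
    svp_mode: str
    variance_explained: np.ndarray
    n_axes: int
    genotype_labels: list[str]
    environment_labels: list[str]

    def scores_2d(self) -> tuple[np.ndarray, np.ndarray]:
        if self.n_axes < 2:
            raise DomainError("2-D views need two retained axes")
        return self.genotype_scores[:, :2], self.environment_scores[:, :2]


def fit_gge(
    matrix: TraitMatrix, svp_mode: str = GENOTYPE_FOCUSED, n_axes: int = 2
) -> GGEModel:
    """SVD of the environment-centered table with singular value partitioning.

    Genotype-focused mode scales genotype scores by the singular values
    (U * Lambda, environments get V); environment-focused mode is the
    transpose convention (genotypes U, environments V * Lambda). Variance
    explained per axis is lambda_n^2 / sum lambda^2, identical in both modes.
    """
    if svp_mode not in (GENOTYPE_FOCUSED, ENVIRONMENT_FOCUSED):
        raise SchemaError(f"unknown SVP mode {svp_mode!r}")
    centered = center_environment(matrix)
    g, e = centered.shape
    max_axes = min(g, e)
    if not 1 <= n_axes <= max_axes:
        raise DomainError(f"n_axes must be in [1, {max_axes}]")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt.T
    # sign convention: each environment-loading column sums to >= 0
    for n in range(v.shape[1]):
        col_sum = v[:, n].sum()
        if col_sum < 0:
            flip = True
        elif col_sum > 0:
            flip = False
        else:
            nonzero = v[np.nonzero(v[:, n])[0], n]
            flip = bool(nonzero.size) and nonzero[0] < 0
        if flip:
            v[:, n] = -v[:, n]
            u[:, n] = -u[:, n]
    total = float(np.sum(s**2))
    var_explained = s**2 / total if total > 0 else np.zeros_like(s)
    if svp_mode == GENOTYPE_FOCUSED:
        gscores, escores = u * s, v
    else:
        gscores, escores = u, v * s
    return GGEModel(
        centered=centered,
        singular_values=s,
        genotype_scores=gscores[:, :n_axes],
        environment_scores=escores[:, :n_axes],
        svp_mode=svp_mode,
        variance_explained=var_explained,
        n_axes=n_axes,
        genotype_labels=list(matrix.genotype_labels),
        environment_labels=list(matrix.environment_labels),
    )


@dataclass
class AECFrame:
    """Average Environment Coordination frame in the two retained axes."""

    average_environment: np.ndarray
    abscissa: np.ndarray  # unit vector toward the average environment
    ordinate: np.ndarray  # abscissa rotated +90 degrees


def aec_frame(model: GGEModel) -> AECFrame:
    _, env = model.scores_2d()
    avg = env.mean(axis=0)
    norm = np.linalg.norm(avg)
    if norm < 1e-12:
        raise DegenerateGeometryError("average environment lies at the origin")
    abscissa = avg / norm
    ordinate = np.array([-abscissa[1], abscissa[0]])
    return AECFrame(average_environment=avg, abscissa=abscissa, ordinate=ordinate)


def mean_stability(model: GGEModel, frame: AECFrame) -> pd.DataFrame:
    """Mean-performance proxy and signed instability per genotype.

    Projection of each genotype score on the AEC abscissa proxies its mean
    across environments; the signed perpendicular projection measures
    instability (longer = less stable). Genotype-focused SVP is the
    convention for genotype evaluation.
    """
    geno, _ = model.scores_2d()
    mean_proxy = geno @ frame.abscissa
    stability = geno @ frame.ordinate
    df = pd.DataFrame(
        {"mean_proxy": mean_proxy, "stability": stability},
        index=model.genotype_labels,
    )
    return df.sort_values("mean_proxy", ascending=False)


def rank_vs_ideal(ms: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance to the ideal genotype (max mean proxy, stability 0)."""
    if (ms["mean_proxy"] <= 0).all():
        import warnings

        warnings.warn("no genotype has positive mean proxy; ideal set at max anyway")
    ideal = np.array([ms["mean_proxy"].max(), 0.0])
    pts = ms[["mean_proxy", "stability"]].to_numpy()
    dist = np.linalg.norm(pts - ideal, axis=1)
    out = ms.copy()
    out["distance_to_ideal"] = dist
    out = out.sort_values("distance_to_ideal")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def environment_metrics(
    model: GGEModel, frame: AECFrame, desirability_rule: str = "projection"
) -> pd.DataFrame:
    """Discriminating power, representativeness and desirability per environment.

    Discriminating power is the environment vector length; representativeness
    the cosine of its angle with the AEC abscissa; the default desirability is
    their product (the projection of the vector onto the AEC axis).
    Environment-focused SVP is the convention for environment evaluation.
    """
    if desirability_rule not in ("projection",):
        raise SchemaError(f"unknown desirability rule {desirability_rule!r}")
    _, env = model.scores_2d()
    length = np.linalg.norm(env, axis=1)
    flags = length < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = np.where(flags, np.nan, (env @ frame.abscissa) / np.where(flags, 1, length))
    desirability = np.where(flags, np.nan, length * cosine)
    return pd.DataFrame(
        {
            "discriminating_power": length,
            "representativeness": cosine,
            "desirability": desirability,
            "degenerate": flags,
        },
        index=model.environment_labels,
    )


@dataclass
class MegaEnvironmentResult:
    """Which-won-where decomposition of the 2-D biplot."""

    hull_vertices: list[str]  # counter-clockwise order
    sectors: list[dict]  # {vertex, start_angle, end_angle}
    environment_assignment: dict[str, str]  # environment -> winning vertex
    winners: dict[int, str]  # sector index -> vertex genotype
    mega_environments: list[list[str]]
    boundary_flags: list[str] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)


def _ccw_hull(points: np.ndarray) -> list[int]:
    try:
        hull = ConvexHull(points)
    except Exception as exc:  # qhull raises on degenerate input
        raise DegenerateGeometryError(f"degenerate genotype cloud: {exc}") from exc
    return list(hull.vertices)  # scipy returns CCW order in 2-D


def which_won_where(model: GGEModel) -> MegaEnvironmentResult:
    """Convex hull, equality-line sectors, sector winners and mega-environments.

    From the origin, rays perpendicular to each hull edge (the "equality
    lines" between adjacent vertex genotypes) split the plane into sectors;
    the winner of each sector is its vertex genotype, because along any
    direction inside the sector that vertex maximizes the inner product —
    hence maximizes the modelled cell mean for every environment whose
    vector falls in the sector. Environments sharing a sector form a
    mega-environment. An environment lying exactly on a ray is assigned to
    the counter-clockwise sector and flagged.
    """
    if model.svp_mode != GENOTYPE_FOCUSED:
        raise SchemaError("which-won-where uses the genotype-focused model")
    geno, env = model.scores_2d()
    vertices = _ccw_hull(geno)
    k = len(vertices)
    # boundary ray between CCW-adjacent vertices a -> b: direction where
    # their inner products tie, i.e. perpendicular to (b - a), pointing
    # outward (for a CCW polygon containing the origin: rotate edge by -90).
    boundary_angles = []
    for idx in range(k):
        a = geno[vertices[idx]]
        b = geno[vertices[(idx + 1) % k]]
        edge = b - a
        ray = np.array([edge[1], -edge[0]])
        boundary_angles.append(math.atan2(ray[1], ray[0]) % (2 * math.pi))
    # sector of vertex v_i spans from the ray shared with its CW neighbour
    # to the ray shared with its CCW neighbour
    sectors = []
    for idx in range(k):
        sectors.append(
            {
                "vertex": model.genotype_labels[vertices[idx]],
                "start_angle": boundary_angles[(idx - 1) % k],
                "end_angle": boundary_angles[idx],
            }
        )

    two_pi = 2 * math.pi

    def sector_of(theta: float) -> tuple[int, bool]:
        # sectors tile the circle; half-open [start, end) so that a
        # direction exactly on a ray goes to the counter-clockwise sector
        for i, sec in enumerate(sectors):
            span = (sec["end_angle"] - sec["start_angle"]) % two_pi
            offset = (theta - sec["start_angle"]) % two_pi
            on_start = offset < _ANGLE_TOL or offset > two_pi - _ANGLE_TOL
            if on_start or offset < span - _ANGLE_TOL:
                return i, on_start
        raise DegenerateGeometryError("direction not covered by any sector")

    assignment: dict[str, str] = {}
    winners: dict[int, str] = {}
    groups: dict[int, list[str]] = {}
    flags: list[str] = []
    unassigned: list[str] = []
    for j, label in enumerate(model.environment_labels):
        w = env[j]
        if np.linalg.norm(w) < 1e-12:
            unassigned.append(label)
            continue
        theta = math.atan2(w[1], w[0]) % (2 * math.pi)
        sec_idx, on_boundary = sector_of(theta)
        if on_boundary:
            flags.append(label)
        vertex = sectors[sec_idx]["vertex"]
        assignment[label] = vertex
        winners[sec_idx] = vertex
        groups.setdefault(sec_idx, []).append(label)
    return MegaEnvironmentResult(
        hull_vertices=[model.genotype_labels[i] for i in vertices],
        sectors=sectors,
        environment_assignment=assignment,
        winners=winners,
        mega_environments=[groups[i] for i in sorted(groups)],
        boundary_flags=flags,
        unassigned=unassigned,
    )


@dataclass
class WardResult:
    labels: pd.Series  # item -> cluster id (1..k)
    merge_heights: np.ndarray
    linkage_matrix: np.ndarray


def ward_cluster(
    features: pd.DataFrame, k: int, standardize: bool = True
) -> WardResult:
    """Agglomerative clustering with Ward linkage on Euclidean distances.

    Features are z-scored by default so traits on different scales
    contribute comparably. Deterministic given input order (scipy's
    tie-breaking).
    """
    n = len(features)
    if not 1 <= k <= n:
        raise DomainError(f"k must be in [1, {n}]")
    values = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise SchemaError("features must be finite")
    if standardize:
        sd = values.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=0)) / sd
    Z = linkage(values, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return WardResult(
        labels=pd.Series(labels, index=features.index, name="cluster"),
        merge_heights=Z[:, 2].copy(),
        linkage_matrix=Z,
    )
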
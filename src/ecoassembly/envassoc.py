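"""Mantel and partial Mantel tests against environmental and geographic distance.

The community / environment association is measured by the Pearson Mantel
correlation of distance matrices; the partial Mantel test correlates
distance-corrected dissimilarities — community vs environment controlling
for great-circle geographic distance — using the residual method.  Both
permutation tests are one-sided (greater), matching the positive
associations the analyses probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel

from .community_data import SampleMetadata

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    controlled: str | None = None


def haversine_matrix(coords: np.ndarray, ids=None) -> DistanceMatrix:
    """Great-circle distances (km) between (latitude, longitude) points."""
    coords = np.asarray(coords, float)
    lat, lon = coords[:, 0], coords[:, 1]
    if (np.abs(lat) > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (np.abs(lon) > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    if ids is None:
        ids = [str(i) for i in range(len(coords))]
    return DistanceMatrix(d, ids)


def env_distance(
    meta: SampleMetadata, variables: list[str] | None = None
) -> DistanceMatrix:
    """Euclidean distance on z-standardized environmental covariates.

    Standardization (sample SD, ddof=1) puts heterogeneous units (PSU, degC,
    dbar, mg/l) on a common scale; zero-variance variables are dropped with
    a warning.  Samples with missing values in the chosen variables must be
    excluded by the caller beforehand.
    """
    variables = variables if variables is not None else meta.env_columns
    X = meta.frame[variables].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("missing values in environmental variables")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(variables, keep) if not k]
        logger.warning("env_distance: dropping zero-variance variables %s", dropped)
    if not keep.any():
        raise ValueError("no environmental variable with positive variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return DistanceMatrix(squareform(pdist(Z)), meta.sample_ids)


def _check_ids(*mats: DistanceMatrix) -> None:
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise ValueError("distance matrices have mismatched ids")


def mantel(
    A: DistanceMatrix, B: DistanceMatrix, n_perm: int = 999, seed: int = 0
) -> MantelResult:
    """Pearson Mantel correlation of two distance matrices.

    p by permuting the row/column order of A, one-sided (greater).
    """
    _check_ids(A, B)
    r, p, _ = _skbio_mantel(
        A, B, method="pearson", permutations=n_perm,
        alternative="greater", seed=seed,
    )
    return MantelResult(float(r), float(p), n_perm)


def _triu(m: DistanceMatrix | np.ndarray) -> np.ndarray:
    d = m.data if isinstance(m, DistanceMatrix) else np.asarray(m, float)
    return d[np.triu_indices(len(d), k=1)]


def _partial_r(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    rab = np.corrcoef(a, b)[0, 1]
    rac = np.corrcoef(a, c)[0, 1]
    rbc = np.corrcoef(b, c)[0, 1]
    denom = np.sqrt((1 - rac**2) * (1 - rbc**2))
    if denom == 0:
        return np.nan
    return (rab - rac * rbc) / denom


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    controlled_name: str = "C",
) -> MantelResult:
    """Partial Mantel r(A, B | C) with a one-sided permutation test.

    Partial Pearson correlation of the upper triangles; each permutation
    reorders A's rows/columns jointly and recomputes the partial r.  When C
    carries no pattern (all off-diagonal entries equal) this reduces to the
    simple Mantel correlation.
    """
    _check_ids(A, B, C)
    a, b, c = _triu(A), _triu(B), _triu(C)
    if np.ptp(c) == 0:
        # constant control: no shared variance to remove
        r_obs = float(np.corrcoef(a, b)[0, 1])
        stat = lambda av: np.corrcoef(av, b)[0, 1]  # noqa: E731
    else:
        r_obs = float(_partial_r(a, b, c))
        stat = lambda av: _partial_r(av, b, c)  # noqa: E731
    rng = np.random.default_rng(seed)
    n = len(A.ids)
    Ad = A.data
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        av = _triu(Ad[np.ix_(perm, perm)])
        if stat(av) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, float(p), n_perm, controlled=controlled_name)
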
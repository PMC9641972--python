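"""Alpha and beta diversity plus group-difference permutation tests.

Alpha indices: observed richness, bias-corrected Chao1, ACE (rare/abundant
cutoff 10), and Shannon entropy in nats.  Beta diversity is Bray–Curtis.
Group structure is tested by PERMANOVA (Anderson's pseudo-F) and ANOSIM,
both with permutation p-values using the (1 + count)/(1 + n_perm)
estimator, plus the Kruskal–Wallis rank test for alpha indices and a
within-group pairwise-distance summary of beta dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import alpha as skbio_alpha
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import permanova as _skbio_permanova

from .community_data import CommunityDataError, OtuTable, to_relative_abundance


@dataclass
class AlphaResult:
    sample_id: str
    observed: int
    chao1: float
    ace: float
    shannon: float


@dataclass
class PermTestResult:
    """Permutation-test outcome; p is floored at 1/(n_perm + 1)."""

    method: str
    statistic: float
    p_value: float
    n_perm: int


def alpha_indices(
    table: OtuTable, chao1_bias_corrected: bool = True, ace_rare_threshold: int = 10
) -> list[AlphaResult]:
    """Per-sample observed richness, Chao1, ACE, and Shannon (natural log).

    Chao1 uses the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) by
    default (the classic form via ``chao1_bias_corrected=False``).
    """
    out = []
    for j, sid in enumerate(table.sample_ids):
        counts = table.counts[:, j]
        if counts.sum() == 0:
            raise CommunityDataError(f"sample {sid!r} has zero total count")
        out.append(
            AlphaResult(
                sample_id=sid,
                observed=int((counts > 0).sum()),
                chao1=float(
                    skbio_alpha.chao1(counts, bias_corrected=chao1_bias_corrected)
                ),
                ace=float(skbio_alpha.ace(counts, rare_threshold=ace_rare_threshold)),
                shannon=float(skbio_alpha.shannon(counts, base=np.e)),
            )
        )
    return out


def alpha_frame(results: list[AlphaResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results]).set_index("sample_id")


def bray_curtis(table: OtuTable, use_relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity, BC = sum|x-y| / sum(x+y).

    With ``use_relative`` (default) samples are first normalized to
    proportions so uneven sequencing depth does not masquerade as turnover.
    """
    if table.n_samples < 2:
        raise CommunityDataError("Bray-Curtis needs at least 2 samples")
    X = to_relative_abundance(table).T if use_relative else table.counts.T.astype(float)
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis")), table.sample_ids)


def _check_groups(dist: DistanceMatrix, groups) -> np.ndarray:
    groups = np.asarray(list(groups))
    if len(groups) != len(dist.ids):
        raise ValueError("group labels must match distance-matrix ids")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2]
        raise ValueError(f"groups of size 1 not allowed: {list(small)}")
    return groups


def permanova(
    dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermTestResult:
    """PERMANOVA pseudo-F with label-permutation p-value."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = _check_groups(dist, groups)
    res = _skbio_permanova(dist, groups, permutations=n_perm, seed=seed)
    return PermTestResult(
        "PERMANOVA", float(res["test statistic"]), float(res["p-value"]), n_perm
    )


def anosim(
    dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermTestResult:
    """ANOSIM R in [-1, 1] with label-permutation p-value."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = _check_groups(dist, groups)
    res = _skbio_anosim(dist, groups, permutations=n_perm, seed=seed)
    return PermTestResult(
        "ANOSIM", float(res["test statistic"]), float(res["p-value"]), n_perm
    )


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    Degenerate all-equal input returns (0, 1) rather than scipy's error.
    """
    values = np.asarray(values, float)
    groups = np.asarray(list(groups))
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    parts = [values[groups == g] for g in labels]
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*parts)
    return float(h), float(p)


def beta_dispersion(dist: DistanceMatrix, groups) -> dict[str, np.ndarray]:
    """Within-group pairwise distances per group (beta-diversity spread)."""
    groups = _check_groups(dist, groups)
    d = dist.data
    out = {}
    for g in np.unique(groups):
        ix = np.flatnonzero(groups == g)
        iu = np.triu_indices(len(ix), k=1)
        out[str(g)] = d[np.ix_(ix, ix)][iu]
    return out
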
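"""Phylogenetic and taxonomic null models for community assembly inference.

The inference follows the two-metric framework used throughout microbial
ecology.  For every pair of communities:

* **βMNTD** — beta mean nearest taxon distance: for each taxon in one
  community, the phylogenetic distance to its closest relative in the other
  community, averaged with relative-abundance weights (or equal weights for
  the unweighted variant) and symmetrized over the two directions.

* **βNTI** — the z-score of the observed βMNTD against a null distribution
  obtained by shuffling taxon labels across the tips of the phylogeny
  (joint row/column permutation of the cophenetic matrix), 999
  randomizations by default.  |βNTI| > 2 indicates deterministic selection:
  βNTI < −2 homogeneous selection (less turnover than expected), βNTI > +2
  heterogeneous selection.

* **RC_bray** — the Raup–Crick metric on Bray–Curtis: the observed
  dissimilarity ranked within a null distribution of probabilistically
  reassembled communities that preserve each sample's richness and total
  abundance, drawing taxa by metacommunity occurrence frequency and
  individuals by metacommunity mean relative abundance.  For pairs with
  |βNTI| ≤ 2, RC_bray < −0.95 indicates homogenizing dispersal,
  RC_bray > +0.95 dispersal limitation, and |RC_bray| ≤ 0.95 drift.

Classifying all within-group pairs and tallying the five outcomes yields
the per-group partition of assembly processes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .community_data import OtuTable, cophenetic_distances, to_relative_abundance

logger = logging.getLogger(__name__)

PROCESSES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)

_EQ_TOL = 1e-10


@dataclass
class BntiResult:
    pair: tuple[str, str]
    beta_mntd_obs: float
    null_mean: float
    null_sd: float
    bnti: float  # NaN when degenerate
    degenerate: bool = False


@dataclass
class RcResult:
    pair: tuple[str, str]
    bc_obs: float
    rc: float


@dataclass
class ProcessPartition:
    group: str
    fractions: dict[str, float]
    n_pairs: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"process fractions sum to {total}, not 1")


# ---------------------------------------------------------------------------
# betaMNTD
# ---------------------------------------------------------------------------

def _align_dist(table: OtuTable, dist: DistanceMatrix | TreeNode) -> np.ndarray:
    """Cophenetic matrix reordered to the table's taxa."""
    if isinstance(dist, TreeNode):
        dist = cophenetic_distances(dist)
    missing = set(table.taxa_ids) - set(dist.ids)
    if missing:
        raise ValueError(
            f"{len(missing)} table taxa missing from the distance matrix, "
            f"e.g. {sorted(missing)[:3]}"
        )
    idx = [dist.ids.index(t) for t in table.taxa_ids]
    return dist.data[np.ix_(idx, idx)]


def _weights(table: OtuTable, weighted: bool) -> np.ndarray:
    """Per-taxon weights f_ik (columns sum to 1)."""
    if weighted:
        return to_relative_abundance(table)
    pres = (table.counts > 0).astype(float)
    return pres / pres.sum(axis=0)


def _mntd_cross(D: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """M[s, i] = distance from taxon i to its nearest taxon present in sample s."""
    n_samples = presence.shape[1]
    M = np.empty((n_samples, D.shape[0]))
    for s in range(n_samples):
        M[s] = D[:, presence[:, s]].min(axis=1)
    return M


def _beta_mntd_square(D: np.ndarray, F: np.ndarray, presence: np.ndarray) -> np.ndarray:
    A = _mntd_cross(D, presence) @ F  # A[m, k] = sum_i F[i,k] * M[m, i]
    return 0.5 * (A + A.T)


def beta_mntd(
    com1: np.ndarray,
    com2: np.ndarray,
    phylo_dist: np.ndarray,
    weighted: bool = True,
) -> float:
    """βMNTD between two abundance vectors aligned to ``phylo_dist``.

    βMNTD = ½ [ Σ_i f_i1 · min_{j∈2} d(i,j) + Σ_j f_j2 · min_{i∈1} d(j,i) ],
    the minima running over taxa present in the *other* community.
    Symmetric, zero when the two communities share their full taxon set.
    """
    com1 = np.asarray(com1, float)
    com2 = np.asarray(com2, float)
    D = np.asarray(phylo_dist, float)
    if com1.sum() == 0 or com2.sum() == 0:
        raise ValueError("empty community")
    p1, p2 = com1 > 0, com2 > 0
    if weighted:
        f1, f2 = com1 / com1.sum(), com2 / com2.sum()
    else:
        f1 = p1 / p1.sum()
        f2 = p2 / p2.sum()
    d12 = D[:, p2].min(axis=1)  # nearest taxon in community 2
    d21 = D[:, p1].min(axis=1)
    return 0.5 * (float(f1 @ d12) + float(f2 @ d21))


def beta_mntd_matrix(
    table: OtuTable,
    dist: DistanceMatrix | TreeNode,
    weighted: bool = True,
) -> pd.DataFrame:
    """All-pairs βMNTD for the samples of ``table``."""
    D = _align_dist(table, dist)
    F = _weights(table, weighted)
    B = _beta_mntd_square(D, F, table.counts > 0)
    return pd.DataFrame(B, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# betaNTI
# ---------------------------------------------------------------------------

def bnti_matrix(
    table: OtuTable,
    dist: DistanceMatrix | TreeNode,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
) -> list[BntiResult]:
    """βNTI for every sample pair under taxa-label randomization.

    Each of the ``n_null`` randomizations permutes the assignment of taxa
    to tips of the phylogeny (a joint row/column shuffle of the cophenetic
    matrix) and recomputes the full βMNTD matrix, so all pairs share the
    same null ensemble — the framework's standard scheme.  Pairs whose null
    distribution has zero spread (e.g. on a star phylogeny) are flagged
    degenerate with βNTI = NaN.
    """
    D = _align_dist(table, dist)
    F = _weights(table, weighted)
    presence = table.counts > 0
    obs = _beta_mntd_square(D, F, presence)
    n = table.n_taxa
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n)
        B = _beta_mntd_square(D[np.ix_(perm, perm)], F, presence)
        acc += B
        acc2 += B * B
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean**2, 0.0)
    sd = np.sqrt(var)
    out = []
    for a in range(table.n_samples):
        for b in range(a + 1, table.n_samples):
            degenerate = sd[a, b] <= _EQ_TOL
            z = np.nan if degenerate else (obs[a, b] - mean[a, b]) / sd[a, b]
            out.append(
                BntiResult(
                    pair=(table.sample_ids[a], table.sample_ids[b]),
                    beta_mntd_obs=float(obs[a, b]),
                    null_mean=float(mean[a, b]),
                    null_sd=float(sd[a, b]),
                    bnti=float(z),
                    degenerate=bool(degenerate),
                )
            )
    n_deg = sum(r.degenerate for r in out)
    if n_deg:
        logger.warning("bnti_matrix: %d degenerate pairs (null sd = 0)", n_deg)
    return out


def bnti_pair(
    com1: np.ndarray,
    com2: np.ndarray,
    phylo_dist: np.ndarray,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
    ids: tuple[str, str] = ("com1", "com2"),
) -> BntiResult:
    """βNTI for a single pair of abundance vectors (see :func:`bnti_matrix`)."""
    table = OtuTable(
        [f"t{i}" for i in range(len(com1))],
        list(ids),
        np.column_stack([com1, com2]).astype(int),
    )
    dm = DistanceMatrix(np.asarray(phylo_dist, float), table.taxa_ids)
    return bnti_matrix(table, dm, n_null=n_null, weighted=weighted, seed=seed)[0]


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------

def _bray(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bray–Curtis between relative-abundance rows (broadcasts over axis 0)."""
    return 0.5 * np.abs(x - y).sum(axis=-1)


def _null_assemblages(
    rng: np.random.Generator,
    occ_w: np.ndarray,
    abun_w: np.ndarray,
    richness: int,
    total: int,
    n_null: int,
) -> np.ndarray:
    """``n_null`` reassembled communities preserving richness and total count.

    Taxa are drawn without replacement with probability proportional to
    metacommunity occurrence frequency (Gumbel top-k), seeded with one
    individual each; the remaining individuals are allotted multinomially
    with probability proportional to metacommunity mean relative abundance
    restricted to the drawn taxa.  Returns relative abundances.
    """
    n_taxa = len(occ_w)
    logw = np.full(n_taxa, -np.inf)
    pos = occ_w > 0
    logw[pos] = np.log(occ_w[pos])
    keys = logw[None, :] + rng.gumbel(size=(n_null, n_taxa))
    chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    counts = np.zeros((n_null, n_taxa))
    rows = np.arange(n_null)[:, None]
    counts[rows, chosen] = 1.0
    if total > richness:
        pv = abun_w[chosen]
        pv = pv / pv.sum(axis=1, keepdims=True)
        counts[rows, chosen] += rng.multinomial(total - richness, pv)
    return counts / total


def rc_bray_pair(
    com1: np.ndarray,
    com2: np.ndarray,
    metacommunity: OtuTable,
    n_null: int = 999,
    seed: int = 0,
    ids: tuple[str, str] = ("com1", "com2"),
) -> RcResult:
    """Raup–Crick (Bray–Curtis) for one pair of count vectors.

    RC = 2·[(#{null < obs} + ½·#{null = obs}) / n_null] − 1 ∈ [−1, 1],
    equality meaning agreement within 1e-10.
    """
    com1 = np.asarray(com1)
    com2 = np.asarray(com2)
    occ_w = (metacommunity.counts > 0).mean(axis=1)
    abun_w = to_relative_abundance(metacommunity).mean(axis=1)
    pool_rich = int((occ_w > 0).sum())
    rng = np.random.default_rng(seed)
    rc, bc = _rc_one(rng, com1, com2, occ_w, abun_w, pool_rich, n_null)
    return RcResult(pair=ids, bc_obs=bc, rc=rc)


def _rc_one(rng, com1, com2, occ_w, abun_w, pool_rich, n_null):
    r1, r2 = int((com1 > 0).sum()), int((com2 > 0).sum())
    if r1 > pool_rich or r2 > pool_rich:
        raise ValueError("sample richness exceeds metacommunity richness")
    t1, t2 = int(com1.sum()), int(com2.sum())
    obs = float(_bray(com1 / t1, com2 / t2))
    null1 = _null_assemblages(rng, occ_w, abun_w, r1, t1, n_null)
    null2 = _null_assemblages(rng, occ_w, abun_w, r2, t2, n_null)
    null_bc = _bray(null1, null2)
    less = (null_bc < obs - _EQ_TOL).sum()
    equal = (np.abs(null_bc - obs) <= _EQ_TOL).sum()
    rc = 2.0 * ((less + 0.5 * equal) / n_null) - 1.0
    return float(rc), obs


def rc_bray_matrix(
    table: OtuTable,
    metacommunity: OtuTable | None = None,
    n_null: int = 999,
    seed: int = 0,
) -> list[RcResult]:
    """RC_bray for every sample pair; the table itself is the default pool."""
    meta = metacommunity if metacommunity is not None else table
    occ_w = (meta.counts > 0).mean(axis=1)
    abun_w = to_relative_abundance(meta).mean(axis=1)
    pool_rich = int((occ_w > 0).sum())
    rng = np.random.default_rng(seed)
    out = []
    for a in range(table.n_samples):
        for b in range(a + 1, table.n_samples):
            rc, bc = _rc_one(
                rng, table.counts[:, a], table.counts[:, b],
                occ_w, abun_w, pool_rich, n_null,
            )
            out.append(
                RcResult(
                    pair=(table.sample_ids[a], table.sample_ids[b]),
                    bc_obs=bc, rc=rc,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Classification and partition
# ---------------------------------------------------------------------------

def classify_pair(
    bnti: float,
    rc: float,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> str:
    """Five-way assembly-process call for one pair.

    βNTI < −2 → homogeneous selection; βNTI > +2 → heterogeneous selection;
    otherwise RC < −0.95 → homogenizing dispersal, RC > +0.95 → dispersal
    limitation, else drift.  Boundary values (|βNTI| = 2, |RC| = 0.95) fall
    to the stochastic/drift side, matching the strict inequalities.
    """
    if not np.isfinite(bnti) or not np.isfinite(rc):
        raise ValueError("classify_pair requires finite betaNTI and RC values")
    if bnti < -bnti_threshold:
        return "homogeneous_selection"
    if bnti > bnti_threshold:
        return "heterogeneous_selection"
    if rc < -rc_threshold:
        return "homogenizing_dispersal"
    if rc > rc_threshold:
        return "dispersal_limitation"
    return "drift"


def partition_processes(
    pairs: list[tuple[float, float]],
    group: str = "",
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> ProcessPartition:
    """Fraction of pairs assigned to each of the five processes."""
    if not pairs:
        raise ValueError("no classifiable pairs")
    tally = {p: 0 for p in PROCESSES}
    for bnti, rc in pairs:
        tally[classify_pair(bnti, rc, bnti_threshold, rc_threshold)] += 1
    n = len(pairs)
    return ProcessPartition(
        group=group,
        fractions={p: tally[p] / n for p in PROCESSES},
        n_pairs=n,
    )


def assembly_partition(
    table: OtuTable,
    dist: DistanceMatrix | TreeNode,
    groups: pd.Series | dict | None = None,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> tuple[pd.DataFrame, dict[str, ProcessPartition]]:
    """Full within-group βNTI + RC_bray analysis and process partition.

    Pairs are formed within each group; each group's own samples act as its
    metacommunity for the RC_bray reassembly.  Degenerate pairs (null βMNTD
    spread of zero) are excluded from the partition with a warning.
    Returns the per-pair table (βMNTD, βNTI, BC, RC, process) and one
    :class:`ProcessPartition` per group.
    """
    if isinstance(dist, TreeNode):
        dist = cophenetic_distances(dist)
    if groups is None:
        groups = pd.Series("all", index=table.sample_ids)
    elif isinstance(groups, dict):
        groups = pd.Series(groups)
    ss = np.random.SeedSequence(seed)
    rows = []
    partitions: dict[str, ProcessPartition] = {}
    group_names = list(dict.fromkeys(groups[s] for s in table.sample_ids))
    child_seeds = {
        g: [int(c.generate_state(1)[0] % 2**31) for c in s.spawn(2)]
        for g, s in zip(group_names, ss.spawn(len(group_names)))
    }
    for g in group_names:
        samples = [s for s in table.sample_ids if groups[s] == g]
        if len(samples) < 2:
            logger.warning("group %s has < 2 samples; skipped", g)
            continue
        sub = table.subset(samples=samples)
        s_bnti, s_rc = child_seeds[g]
        bres = bnti_matrix(sub, dist, n_null=n_null, weighted=weighted, seed=s_bnti)
        rres = rc_bray_matrix(sub, n_null=n_null, seed=s_rc)
        classified = []
        for br, rr in zip(bres, rres):
            assert br.pair == rr.pair
            if br.degenerate:
                process = "degenerate"
            else:
                process = classify_pair(
                    br.bnti, rr.rc, bnti_threshold, rc_threshold
                )
                classified.append((br.bnti, rr.rc))
            rows.append(
                dict(
                    group=g, sample_a=br.pair[0], sample_b=br.pair[1],
                    beta_mntd=br.beta_mntd_obs, bnti=br.bnti,
                    bc=rr.bc_obs, rc=rr.rc, process=process,
                )
            )
        if not classified:
            raise ValueError(f"all pairs degenerate in group {g}")
        partitions[g] = partition_processes(
            classified, group=g,
            bnti_threshold=bnti_threshold, rc_threshold=rc_threshold,
        )
    return pd.DataFrame(rows), partitions
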
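"""Core data containers and I/O for community analyses.

An analysis works on three aligned objects: an OTU count table
(taxa x samples, non-negative integers), a rooted phylogeny whose tips are
the OTU identifiers, and per-sample metadata (habitat group, coordinates,
environmental covariates).  This module defines the containers, their
readers/writers (TSV table, newick tree, CSV metadata) and the alignment of
the three to a shared identifier universe.  Phylogenetic distances are the
cophenetic (tip-to-tip path length) matrix of the tree.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

#: Habitat groups of the study layout: free-living (FL) and particle-
#: associated (PA) fractions of surface and bottom seawater, plus sediment.
GROUPS = ("Sur_FL", "Sur_PA", "Bot_FL", "Bot_PA", "Sed")

REQUIRED_META_COLUMNS = ("sample_id", "group", "latitude", "longitude")


class CommunityDataError(ValueError):
    """Raised on malformed tables, trees, or metadata."""


@dataclass
class OtuTable:
    """OTU counts, taxa x samples.

    Parameters
    ----------
    taxa_ids, sample_ids : list of str
        Unique identifiers for rows (taxa) and columns (samples).
    counts : ndarray of int, shape (n_taxa, n_samples)
        Non-negative counts; every sample must have a positive total.
        All-zero taxa are permitted but flagged via :attr:`zero_taxa`.
    """

    taxa_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxa_ids = [str(t) for t in self.taxa_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.taxa_ids),
            len(self.sample_ids),
        ):
            raise CommunityDataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxa_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise CommunityDataError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if len(set(self.taxa_ids)) != len(self.taxa_ids):
            raise CommunityDataError("duplicate taxon identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CommunityDataError("duplicate sample identifiers")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise CommunityDataError(
                f"negative count at taxon {self.taxa_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = self.sample_ids[int(np.argmax(totals == 0))]
            raise CommunityDataError(f"sample {bad!r} has zero total count")
        if self.zero_taxa:
            logger.warning(
                "%d taxa have all-zero counts: %s%s",
                len(self.zero_taxa),
                ", ".join(self.zero_taxa[:5]),
                "..." if len(self.zero_taxa) > 5 else "",
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def zero_taxa(self) -> list[str]:
        """Identifiers of taxa absent from every sample."""
        mask = self.counts.sum(axis=1) == 0
        return [t for t, z in zip(self.taxa_ids, mask) if z]

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset(
        self, taxa: list[str] | None = None, samples: list[str] | None = None
    ) -> "OtuTable":
        """Restrict to the given taxa and/or samples (order as given)."""
        tix = (
            [self.taxa_ids.index(t) for t in taxa]
            if taxa is not None
            else slice(None)
        )
        six = (
            [self.sample_ids.index(s) for s in samples]
            if samples is not None
            else slice(None)
        )
        return OtuTable(
            taxa if taxa is not None else list(self.taxa_ids),
            samples if samples is not None else list(self.sample_ids),
            self.counts[tix][:, six] if taxa is not None else self.counts[:, six],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.taxa_ids, columns=self.sample_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.taxa_ids == other.taxa_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Per-sample group label, coordinates, and environmental covariates.

    Backed by a DataFrame indexed by sample id with columns ``group``,
    ``latitude``, ``longitude`` plus any numeric covariates (which may hold
    NaN — e.g. CTD variables are unavailable for sediment samples).
    """

    frame: pd.DataFrame
    env_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise CommunityDataError("duplicate sample ids in metadata")
        missing = {"group", "latitude", "longitude"} - set(self.frame.columns)
        if missing:
            raise CommunityDataError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.frame["group"]) - set(GROUPS)
        if bad:
            raise CommunityDataError(
                f"unknown group labels {sorted(bad)}; expected one of {GROUPS}"
            )
        if not self.env_columns:
            self.env_columns = [
                c
                for c in self.frame.columns
                if c not in ("group", "latitude", "longitude")
                and pd.api.types.is_numeric_dtype(self.frame[c])
            ]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def groups(self) -> pd.Series:
        return self.frame["group"]

    def coords(self) -> np.ndarray:
        """(n_samples, 2) array of (latitude, longitude)."""
        return self.frame[["latitude", "longitude"]].to_numpy(float)

    def subset(self, samples: list[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[samples].copy(), list(self.env_columns))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, orientation: str = "taxa_rows") -> OtuTable:
    """Read a TSV count table; first column holds identifiers.

    ``orientation='taxa_rows'`` (the ``#OTU_ID`` convention) means rows are
    taxa; ``'samples_rows'`` transposes on read so the returned table is
    always taxa x samples.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise CommunityDataError(
                    f"non-integer count {raw!r} at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from None
            if v < 0:
                raise CommunityDataError(
                    f"negative count {v} at row {df.index[i]!r}, column {col!r}"
                )
            values[i, j] = v
    if orientation == "samples_rows":
        return OtuTable(list(df.columns), list(df.index), values.T)
    return OtuTable(list(df.index), list(df.columns), values)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = "#OTU_ID"
    df.to_csv(path, sep="\t")


def read_newick(path: str | Path) -> TreeNode:
    """Parse a rooted newick tree with branch lengths (skbio TreeNode)."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise CommunityDataError(f"invalid newick: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise CommunityDataError("duplicate tip labels in tree")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata CSV (sample_id, group, latitude, longitude, env...)."""
    df = pd.read_csv(path)
    missing = set(REQUIRED_META_COLUMNS) - set(df.columns)
    if missing:
        raise CommunityDataError(f"metadata missing columns: {sorted(missing)}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Derived quantities and alignment
# ---------------------------------------------------------------------------

def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distance matrix."""
    if tree.count(tips=True) < 2:
        raise CommunityDataError("cophenetic distances need at least 2 tips")
    return tree.tip_tip_distances()


def to_relative_abundance(table: OtuTable) -> np.ndarray:
    """Column-normalized proportions f_ik (each sample sums to 1)."""
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise CommunityDataError(f"sample {bad!r} has zero total count")
    return table.counts / totals.astype(float)


def align(
    table: OtuTable,
    tree: TreeNode | None = None,
    meta: SampleMetadata | None = None,
) -> tuple[OtuTable, TreeNode | None, SampleMetadata | None]:
    """Restrict table, tree and metadata to their shared identifiers.

    Taxa are intersected with the tree's tip labels and samples with the
    metadata index; dropped identifiers are reported through logging.
    Matching is exact and case-sensitive.  Raises on an empty intersection.
    """
    taxa = list(table.taxa_ids)
    samples = list(table.sample_ids)
    out_tree = tree
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        kept = [t for t in taxa if t in tips]
        if not kept:
            raise CommunityDataError("no taxa shared between table and tree")
        dropped_taxa = sorted(set(taxa) - set(kept))
        dropped_tips = sorted(tips - set(kept))
        if dropped_taxa:
            logger.warning(
                "align: dropping %d table taxa absent from tree: %s%s",
                len(dropped_taxa), ", ".join(dropped_taxa[:5]),
                "..." if len(dropped_taxa) > 5 else "",
            )
        if dropped_tips:
            logger.warning(
                "align: pruning %d tree tips absent from table", len(dropped_tips)
            )
            out_tree = tree.shear(kept)
        taxa = kept
    out_meta = meta
    if meta is not None:
        known = set(meta.sample_ids)
        kept_s = [s for s in samples if s in known]
        if not kept_s:
            raise CommunityDataError("no samples shared between table and metadata")
        dropped_s = sorted(set(samples) - set(kept_s))
        if dropped_s:
            logger.warning(
                "align: dropping %d table samples absent from metadata: %s",
                len(dropped_s), ", ".join(dropped_s[:5]),
            )
        extra = sorted(known - set(kept_s))
        if extra:
            logger.warning(
                "align: dropping %d metadata records absent from table", len(extra)
            )
        samples = kept_s
        out_meta = meta.subset(samples)
    out_table = table.subset(taxa=taxa, samples=samples)
    return out_table, out_tree, out_meta


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()
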
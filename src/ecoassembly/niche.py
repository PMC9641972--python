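"""Levins niche breadth.

For taxon j with abundance distributed over samples as proportions P_ij
(of the taxon's own total), Levins breadth is B_j = 1 / sum_i P_ij^2 — the
inverse Simpson concentration of the taxon across habitats, ranging from 1
(found in a single sample; specialist) to the number of samples (spread
evenly; generalist).  The community-level breadth of a sample is the
average B_j over the taxa present in it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .community_data import OtuTable

logger = logging.getLogger(__name__)


def levins_breadth(table: OtuTable) -> pd.Series:
    """Per-taxon Levins niche breadth B_j = 1 / sum_i P_ij^2.

    All-zero taxa are excluded with a warning (their breadth is undefined).
    B is invariant to rescaling a taxon's row by a positive constant.
    """
    totals = table.counts.sum(axis=1).astype(float)
    zero = totals == 0
    if zero.any():
        logger.warning(
            "levins_breadth: excluding %d all-zero taxa", int(zero.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        P = table.counts / totals[:, None]
        B = 1.0 / np.square(P).sum(axis=1)
    s = pd.Series(B, index=table.taxa_ids, name="levins_B")
    return s[~zero]


def community_breadth(
    table: OtuTable, per_taxon_B: pd.Series | None = None, weighted: bool = False
) -> pd.Series:
    """Community-level niche breadth: mean B_j over taxa present per sample.

    Presence means count > 0.  The unweighted arithmetic mean is the
    default; ``weighted`` averages B_j with relative-abundance weights.
    """
    if per_taxon_B is None:
        per_taxon_B = levins_breadth(table)
    B = per_taxon_B.reindex(table.taxa_ids).to_numpy()
    out = {}
    for j, sid in enumerate(table.sample_ids):
        counts = table.counts[:, j]
        present = (counts > 0) & ~np.isnan(B)
        if not present.any():
            raise ValueError(f"sample {sid!r} has no taxa with defined breadth")
        if weighted:
            w = counts[present] / counts[present].sum()
            out[sid] = float(np.sum(w * B[present]))
        else:
            out[sid] = float(B[present].mean())
    return pd.Series(out, name="community_B")
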
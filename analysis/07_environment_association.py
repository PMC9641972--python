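#!/usr/bin/env python
"""Mantel and partial Mantel tests: community vs environment, controlling
for geographic (great-circle) distance.  Uses the seawater samples, which
carry complete CTD covariates."""

from pathlib import Path

import json

from ecoassembly import (
    align,
    bray_curtis,
    env_distance,
    haversine_matrix,
    mantel,
    partial_mantel,
    read_metadata,
    read_otu_table,
)

DATA = Path("results/data")
OUT = Path("results/mantel")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = read_otu_table(DATA / "otu_table.tsv")
    meta = read_metadata(DATA / "metadata.csv")
    table, _, meta = align(table, None, meta)
    complete = meta.frame[meta.env_columns].notna().all(axis=1)
    samples = [s for s in table.sample_ids if complete[s]]
    sub = table.subset(samples=samples)
    sub_meta = meta.subset(samples)
    bc = bray_curtis(sub)
    env = env_distance(sub_meta)
    geo = haversine_matrix(sub_meta.coords(), ids=samples)
    res = {
        "community_vs_env": vars(mantel(bc, env, n_perm=999, seed=4)),
        "community_vs_geography": vars(mantel(bc, geo, n_perm=999, seed=5)),
        "community_vs_env_given_geo": vars(
            partial_mantel(bc, env, geo, n_perm=999, seed=6,
                           controlled_name="geography")
        ),
    }
    (OUT / "mantel.json").write_text(json.dumps(res, indent=2))
    for name, r in res.items():
        print(f"{name}: r={r['r']:.3f}, p={r['p_value']:.3f}")


if __name__ == "__main__":
    main()
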
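#!/usr/bin/env python
"""Levins niche breadth per OTU and community-level averages per habitat."""

from pathlib import Path

from ecoassembly import (
    align,
    community_breadth,
    kruskal_wallis,
    levins_breadth,
    read_metadata,
    read_otu_table,
)

DATA = Path("results/data")
OUT = Path("results/niche")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = read_otu_table(DATA / "otu_table.tsv")
    meta = read_metadata(DATA / "metadata.csv")
    table, _, meta = align(table, None, meta)
    B = levins_breadth(table)
    B.to_csv(OUT / "taxon_breadth.tsv", sep="\t")
    cb = community_breadth(table, B)
    cb.to_csv(OUT / "community_breadth.tsv", sep="\t")
    groups = meta.groups()
    h, p = kruskal_wallis(cb.loc[table.sample_ids], groups)
    print("community-level niche breadth (group means):")
    print(cb.groupby(groups).mean().round(2).to_string())
    print(f"Kruskal-Wallis: H={h:.2f}, p={p:.2e}")


if __name__ == "__main__":
    main()
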
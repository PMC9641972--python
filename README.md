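# ecoassembly

Community-assembly inference for microbial OTU tables.

Microbial ecologists routinely ask whether the communities observed across
habitats — say, free-living vs particle-associated fractions of surface
and bottom seawater, and the underlying sediment — are structured by
*deterministic* processes (environmental selection) or *stochastic* ones
(dispersal and drift).  This package implements the standard statistical
toolkit for that question as one tested, seedable pipeline:

* **Diversity** — observed richness, Chao1 (bias-corrected), ACE, Shannon
  (ln); Bray–Curtis β-diversity; PERMANOVA, ANOSIM, Kruskal–Wallis, and
  within-group dispersion.
* **Niche breadth** — Levins B_j = 1/Σ_i P_ij² per taxon and its
  community-level average.
* **Assembly null models** — βMNTD, its z-score βNTI under 999
  taxa-shuffle randomizations of the phylogeny, the Raup–Crick metric on
  Bray–Curtis (RC_bray) under 999 probabilistic reassemblies, and the
  five-way classification: βNTI < −2 homogeneous selection, βNTI > +2
  heterogeneous selection, then RC < −0.95 homogenizing dispersal,
  RC > +0.95 dispersal limitation, |RC| ≤ 0.95 drift.
* **Neutral community model (Sloan)** — occurrence frequency predicted
  from mean relative abundance via 1 − I_d(Nmp, Nm(1−p)); least-squares
  estimate of the migration rate m, with R² and per-taxon 95% bands.
* **Environment association** — Mantel and partial Mantel (Pearson, 999
  permutations), controlling community–environment correlation for
  great-circle geographic distance.
* **Co-occurrence networks** — Spearman correlations on the top-500 OTUs,
  |r| > 0.7 with BH-FDR q < 0.01; network/node topology, Freeman
  centralizations, greedy-modularity modules, habitat subnetworks.
* **Synthetic communities** — generators with known assembly regimes
  (neutral, homogeneous/heterogeneous selection, dispersal limitation) and
  a 75-sample five-habitat study layout, so every inference stage can be
  validated against ground truth.

`docs/methods.md` documents the models, defaults, and design choices.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
synthetic survey.  `analysis/01_simulate_communities.py` writes the input
files; the later steps each print their findings.  For example:

```text
$ python analysis/04_assembly_processes.py
Sur_FL: dominant process dispersal_limitation (72.4%)
Sur_PA: dominant process dispersal_limitation (91.4%)
Bot_FL: dominant process dispersal_limitation (99.0%)
Bot_PA: dominant process dispersal_limitation (87.6%)
Sed: dominant process homogeneous_selection (61.9%)

$ python analysis/05_neutral_model.py
Sur_FL: m=0.406  Nm=2031  R2=0.872  (400 taxa, 58% inside the 95% band)
Sur_PA: m=0.118  Nm=591   R2=0.334  (400 taxa, 77% inside the 95% band)
Bot_FL: m=0.297  Nm=1486  R2=0.842  (400 taxa, 58% inside the 95% band)
Bot_PA: m=0.088  Nm=439   R2=0.092  (399 taxa, 73% inside the 95% band)
Sed:    m=0.001  Nm=7     R2=0.529  (117 taxa, 79% inside the 95% band)
```

Reading these together: the four water-column groups — generated with
stochastic-heavy regimes — are dominated by dispersal limitation and
drift, and the neutrally generated free-living fractions fit the neutral
model well (R² > 0.8) with high migration rates; the sediment group —
generated under a shared environmental filter — is instead dominated by
homogeneous selection, with a tiny fitted m.  The null models recover the
processes that built the data.

Equivalently, one configuration runs everything and emits a single
machine-readable report (schema in `src/ecoassembly/schema/`):

```python
from ecoassembly import RunConfig, run_pipeline
report = run_pipeline(RunConfig(seed=1, out_dir="results/pipeline"))
```

Identical seeds give byte-identical reports.

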
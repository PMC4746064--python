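# funcodak

Infer the functional (metabolic) potential of a microbial community from its
16S-derived taxonomic abundance profile.

16S amplicon sequencing tells you *who* is in a sample but not *what* they
can do. Because the enzymes a taxon encodes are largely predictable from
reference genomes, a pre-compiled table of mean enzyme (EC) copy numbers per
taxon lets you reconstruct a community's expected pathway repertoire from
taxonomy alone. funcodak does this reconstruction and everything a
comparative study needs around it: filtering of weakly supported pathway
calls, per-taxon attribution of each predicted function, statistically
rigorous comparison of two environments, per-enzyme drill-down of single
pathways, and function-based microbial interaction networks. It is aimed at
microbiome researchers who have classifier output (QIIME/RDP-style genus or
lineage tables) and want KEGG-pathway-level answers without shotgun
sequencing.

## The model

Let `A(s,t)` be the percent relative abundance of taxon `t` in sample `s`,
`C(t,e)` the mean copy number of enzyme `e` (an EC number) in taxon `t`, and
`E(p)` the enzyme set of Level-3 KEGG pathway `p`. Two community models are
provided:

- **Co-metabolism** — community members pool their enzymes. The community
  enzyme pool is

  `Ep(s,e) = Σ_t A(s,t)/100 · C(t,e)`

  and the raw abundance of pathway `p` is `PA(s,p) = Σ_{e∈E(p)} Ep(s,e)`.

- **Independent contributions** — each taxon runs pathways alone. Taxon `t`
  contributes `A(s,t)/100 · Σ_{e∈E(p)} C(t,e)` to pathway `p` only if its own
  repertoire covers at least a threshold fraction of `E(p)`; the community
  abundance is the sum of these per-taxon terms, and the share of each taxon
  in each pathway (the contribution matrix, columns summing to 100%) comes
  for free.

Predictions are filtered by a **Pathway Exclusion Cut-off (PEC)**: a pathway
is reported in a sample only when at least PEC percent of its constituent
enzymes are present (profiles are produced at PEC = 30, 40, 50, 60, 70, 80
and 90). A blacklist of eukaryote-associated pathways can additionally be
removed. Retained Level-3 values are renormalized to 100% per sample and
summed up the KEGG hierarchy to Level-2 classes and Level-1 super-classes.

Environments are compared with a bootstrapped Wilcoxon procedure (**ISFA**):
each of `N = 1000` iterations draws 70% of each group's samples without
replacement and rank-sum-tests every feature at `α = 0.01`; a feature is
called significantly different only when flagged in at least 70% of
iterations. Microbial interaction networks correlate taxa by their
per-sample functional contribution vectors (Spearman, `|ρ| ≥ 0.6`,
BH-adjusted `p ≤ 0.05` by default), with positive edges marking functionally
synchronized taxa and negative edges antagonistic ones.

A synthetic-bundle generator (`funcodak.synth`) emulates the structure of a
real reference database — multi-rank taxonomy, sparse copy numbers with
small within-taxon dispersion, many-to-many EC↔pathway membership, a
eukaryote-associated pathway subset — so the whole chain is testable without
downloads.

## Worked example

```python
from funcodak import (SynthSpec, make_reference, make_abundance_tables,
                      pool_enzymes, cometabolism_profile, core_functions,
                      isfa_compare, ISFAParams)
from funcodak.synth import Effect

# two simulated environments; group 2 up-weights carriers of pathway pw005
spec = SynthSpec(seed=1, effect=Effect(pathways=("pw005",), multiplier=10.0))
copy_table, genomes, hierarchy = make_reference(spec)
group_a, group_b = make_abundance_tables(spec, copy_table, hierarchy)

profile_a = cometabolism_profile(pool_enzymes(group_a, copy_table), hierarchy, pec=60)
profile_b = cometabolism_profile(pool_enzymes(group_b, copy_table), hierarchy, pec=60)
print("pw005 abundance (%): %.2f" % profile_a.values.loc["grp1_s01", "pw005"])
print("core pathways:", len(core_functions(profile_a, 0.9).functions))

result = isfa_compare(profile_a, profile_b, ISFAParams(seed=1))
row = result.table.loc["pw005"]
print("pw005: consensus=%.2f significant=%s direction=%s"
      % (row["consensus_fraction"], row["significant"], row["direction"]))
```

prints

```
pw005 abundance (%): 30.11
core pathways: 5
pw005: consensus=1.00 significant=True direction=B_higher
```

i.e. pathway `pw005` makes up 30.11% of the first healthy-group sample's
retained functional profile at PEC 60, five pathways are "core" (nonzero in
≥ 90% of that group's samples), and the planted carrier-abundance shift is
recovered: `pw005` is flagged in 100% of the 1000 bootstrap iterations, with
the second group the higher one.

The same analyses are available from the shell:

```
funcodak simulate --seed 1 --out study/
funcodak global-mapper --abundance study/abundance_group1.tsv \
    --reference study/reference --out study/gm1
funcodak isfa --group-a study/gm1/cometabolism_L3_pec60.tsv \
    --group-b study/gm2/cometabolism_L3_pec60.tsv --seed 1 --out study/isfa.tsv
funcodak local-mapper --abundance study/abundance_group1.tsv \
    --reference study/reference --pathway pw005 --out study/lm
funcodak network --abundance study/abundance_group1.tsv \
    --reference study/reference --level L1 --out study/net
```

Every run writes a `manifest.json` recording parameters, input checksums and
the tool version.

## Layout

- `funcodak.reference` — reference-bundle data model, loaders/validators,
  per-taxon mean aggregation, z-score divergence diagnostic, taxon-label
  resolution.
- `funcodak.synth` — synthetic bundles and abundance tables.
- `funcodak.globalmapper` — enzyme pooling, both inference algorithms, PEC
  and blacklist filtering, hierarchy aggregation, contributions, core
  functions.
- `funcodak.isfa` — Wilcoxon rank-sum (exact where feasible) and the
  bootstrapped consensus comparison.
- `funcodak.localmapper` — per-enzyme pathway profiles, rank normalization,
  KEGG user-data mapping files.
- `funcodak.networks` — contribution stacking, correlation networks,
  summaries, Cytoscape export.
- `funcodak.io`, `funcodak.cli` — TSV readers/writers, manifests, the
  `funcodak` command.

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
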
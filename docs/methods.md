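# Methods

## Problem setting

Given a taxonomic relative-abundance table (samples × taxa, percent) from a
16S experiment and a reference bundle — per-taxon mean enzyme copy numbers
`C(t,e)` and a three-tier KEGG pathway hierarchy — funcodak predicts the
relative abundance of metabolic pathways per sample, attributes each
prediction to the taxa responsible, and compares environments. Enzymes (EC
numbers) are the atomic functional unit throughout; a pathway's abundance is
always derived from the abundances of its constituent enzymes.

## Reference bundle and taxon resolution

Copy numbers are stored per taxon at five ranks (genus, family, order,
class, phylum). When built from per-genome tables, the mean for a (taxon,
EC) cell is taken over *all* member genomes, counting genomes that lack the
enzyme as zero — the mean then reflects both dosage and prevalence, and a
rare enzyme in a large genus correctly gets a small expected copy number.

The appropriateness of summarising a taxon by its mean is monitored with a
z-score divergence diagnostic: per (group, EC) cell, each member genome
contributes `z = (x − mean)/sd` (sample SD, `n−1`); singleton groups and
zero-variance cells contribute `z = 0`, since identical copy numbers are
maximal agreement, and bands are reported disjointly (|z| ≤ 1, 1 < |z| ≤ 2,
|z| > 2) so they sum to one. A healthy bundle concentrates well over 90% of
observations in the inner band at every rank, which is what licenses using
means even at phylum level.

Input taxon labels are resolved case-insensitively after stripping
`g__`-style prefixes and collapsing whitespace. Lineage strings are walked
from the most specific component towards the root; when the terminal rank is
missing from the table the nearest resolvable ancestor is used and the
fallback flagged. Unresolved labels are not errors: they are dropped, the
remaining abundances renormalized to 100%, and the dropped mass reported per
sample. EC wildcards (`1.1.-.-`) are accepted in copy tables but never count
towards pathway coverage, because they cannot be matched to a pathway's
enzyme set reliably.

The Level-3 → Level-2 and Level-2 → Level-1 maps are functions (single
parent). A pathway belonging to several classes in an upstream source must
be duplicated under distinct ids at bundle-build time; this keeps hierarchy
aggregation an unambiguous group-by sum.

## Pathway inference

**Co-metabolism.** The community enzyme pool is abundance-weighted,
`Ep(s,e) = Σ_t A(s,t)/100 · C(t,e)`: a community's pooled dosage of an
enzyme scales with how much of each contributor is present, not merely with
presence. Raw pathway abundance is the summed pool over the pathway's
enzymes, without dividing by pathway size (large pathways genuinely command
more of the community's enzyme mass); a pathway-size-normalized variant is
exposed as an option.

**Independent contributions.** Each taxon's candidate contribution to
pathway `p` is `A(s,t)/100 · Σ_{e∈E(p)} C(t,e)`, credited only when the
taxon's own repertoire covers at least the PEC fraction of `E(p)` — under
the independence assumption, a pathway a single microbe cannot substantially
encode should not be credited to it. An option evaluates the cut-off on the
community enzyme union instead (co-metabolism semantics). Contribution
shares are percentages of each pathway's raw abundance, per sample and
pooled per environment (pooled shares use summed raw contributions, so large
samples weigh more); columns over taxa sum to 100% for every retained
function at every hierarchy level.

**Filtering and normalization order.** Coverage is the percent of a
pathway's enzymes with strictly positive pooled abundance, computed per
sample; the PEC comparison is `coverage ≥ PEC` retains (boundary ties
retain). Eukaryote-blacklist removal applies at Level 3, before hierarchy
aggregation, so Level-2/1 reflect the filtered profile. Renormalization to
100% per sample happens after all filtering; excluded mass is discarded, not
redistributed. Enzymes belonging to several pathways count fully in each —
the EC↔pathway map is many-to-many and no principled splitting rule exists
at this resolution. The PEC filter is applied per sample, not per dataset.

Consequences worth knowing: retained pathway sets are nested as PEC rises
(the filter only removes), the two algorithms coincide exactly on
single-taxon communities, and every per-sample profile at every level sums
to 100% or is identically zero.

**Core functions.** A function is core to an environment when it is nonzero
in at least `ceil(threshold · n_samples)` samples; the default threshold is
0.9, chosen as a conventional prevalence cut-off and configurable.

## Bootstrapped comparison (ISFA)

Defaults: subsample fraction 0.7, α = 0.01, 1000 iterations, consensus
threshold 0.7 — the standard operating point for this procedure. Subsampling
is without replacement (a random *subset*), independently per group per
iteration; subsample index streams are keyed by group size rather than
argument order, so swapping the group labels reproduces exactly the same
iteration pairs with directions flipped.

The rank-sum test handles the heavy ties of compositional profiles
explicitly: for pooled sizes ≤ 14 the two-sided p is computed by exhaustive
enumeration of group assignments of the mid-ranks,
`p = P(|W − E[W]| ≥ |w_obs − E[W]|)`; tie-free samples with one group ≤ 8
use the classical exact distribution; everything larger uses the
tie-corrected normal approximation with continuity correction. p is always
in (0, 1], and two identical groups give p = 1.

Direction is reported from full-data medians (ties → none). No
multiple-testing correction is applied inside the consensus procedure — the
consensus requirement is itself the guard against spurious calls — but
BH-adjusted q-values of the single full-data test are reported as a clearly
separate supplementary column.

## Local pathway drill-down

Per environment, the effective abundance of each enzyme in a chosen pathway
is the mean over samples of the pooled abundance `Ep(s,e)` (median available
as an option), restricted to `E(p)` and zero-filled so all environments list
the identical enzyme set. Rank normalization maps nonzero abundances to
mid-rank/m in (0, 1] (m = nonzero count) and pins zeros to 0, so "absent" is
visually distinguishable from "least abundant" and strictly larger abundance
always maps to a strictly larger value. The KEGG user-data mapping file uses
one `ec:<EC>\t<bg_hex>,<fg_hex>` line per enzyme — the dialect the KEGG
color-pathway text form accepts — with a linear white→saturated background
ramp over the rank-normalized value and a fixed black foreground; the exact
dialect is covered by a round-trip parser test.

## Interaction networks

Each taxon is described by the stacked vector of its per-sample percent
contributions to every function at one hierarchy level; pairwise Spearman
(or Pearson) correlation over taxa, BH adjustment over all pairs, and the
double threshold |ρ| ≥ 0.6 with adjusted p ≤ 0.05 define the edges. These
defaults are explicit, configurable choices in the spirit of published
co-occurrence analyses; no single canonical recipe exists. Correlations are
computed across per-sample vectors (at least 3 samples required) — an
environment-mean variant would leave nothing to correlate. Constant rows are
excluded with a warning (ρ undefined). Only degree and density are
summarized; betweenness and other centralities are out of scope. Because
contributions are compositional within each function, some background
correlation between taxa is structural; the significance-plus-magnitude
double threshold is what keeps such closure effects out of the edge set.
Note that taxa with disjoint function repertoires dilute rank correlation at
Level 3 (their vectors are mostly zeros in complementary positions);
planted-interaction recovery is therefore assessed at Level 1, where
repertoires overlap.

## Synthetic data generator

The generator emulates the *structure* of a real reference database, not any
particular organism set:

- **Taxonomy** — nested five-rank lineages over 40 genera by default.
- **Copy numbers** — enzyme presence (default sparsity 0.75) is fixed at the
  phylum level and inherited downward with a 1% per-rank chance of a ±1
  copy-number mutation per cell; each of the 4 genomes per genus additionally
  mutates cells at 4%, loses enzymes at 1% and re-acquires lost repertoire
  enzymes at 0.5%. These dispersion defaults are calibrated so the bundle
  sits in the empirically observed regime of the diagnostic above — over 90%
  of copy-number z-scores within ±1 at every rank (91–96% across seeds) —
  which is the property that justifies mean-based reference tables.
- **Hierarchy** — 25 pathways of 4–10 enzymes in 8 classes and 3
  super-classes by default; a 20% eukaryote-marked pathway subset draws 80%
  of its enzymes from a block that prokaryotic taxa carry 5× more rarely, so
  blacklist pathways have genuinely low community coverage and fall away as
  PEC rises.
- **Abundances** — normalized independent Gamma draws (a Dirichlet
  construction, concentration 3) around a shared lognormal base composition,
  with 30% per-(sample, taxon) structural zeros; rows sum to exactly 100.
- **Planted effects** — effects are planted on *taxa* (a multiplicative
  abundance shift on carriers of target pathways in the second group, before
  renormalization), never directly on functions, so any downstream
  functional signal must emerge through the inference chain. Because a
  random bundle need not contain strong carriers, the generator designates
  about 25% of genera as carriers (full enzyme complement of each target
  pathway) whenever an effect is requested.
- A separate fixture plants a per-sample latent factor driving two taxa up
  together and a third inversely, for network-recovery checks.

All randomness flows from one integer seed through NumPy's PCG64 generator;
fixed seed means byte-identical outputs.

What the generator does **not** emulate: 16S amplification and classifier
error, phylogenetic correlation of repertoires beyond simple inheritance,
realistic pathway size distributions, or overdispersed (zero-inflated
beyond structural zeros) count noise. Passing tests therefore demonstrate
correctness and statistical behaviour of the *procedures* under controlled
conditions, not predictive accuracy on real communities — that depends
entirely on the quality of the real reference bundle supplied.

## Numerical choices and degenerate inputs

- Percent (0–100) is the canonical abundance unit; fraction-scale input
  (column sums ≈ 1) is auto-converted with a logged notice, and all columns
  are renormalized to exactly 100 with deviations beyond ±0.5 warned.
- Profile conservation is enforced to 1e-6; oracle agreement to 1e-9; exact
  p-values to 1e-12.
- All-zero samples, empty pools, all-unresolved communities and all-zero
  profiles propagate as zeros (never NaN) and are reported, not raised.
- Duplicate taxon rows are summed with a warning; duplicate sample ids and
  negative abundances are errors naming the offending cell.
- Outputs are deterministically ordered (sorted functions/taxa,
  degree-then-name for network exports), so reruns are byte-identical.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script simulations use deliberately small
instances — 8–40 taxa, 24–120 enzymes, 8–40 pathways, 4–20 samples per
group, 10 replicate seeds, 1000 bootstrap iterations — sized so the full
chain (reference generation → inference → comparison → networks) runs in
seconds while leaving every statistical property measurable. Larger inputs
are handled by the same vectorized code paths.
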
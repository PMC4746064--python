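"""Synthetic reference bundles and community abundance tables.

The generator emulates the structure of the real back-end database — a
multi-rank prokaryotic taxonomy, sparse non-negative enzyme copy numbers
with small within-taxon (genome-level) dispersion, many-to-many EC-pathway
membership under a three-tier hierarchy, and a eukaryote-associated pathway
subset whose enzymes few prokaryotes carry — together with compositional
taxon abundance tables for one or two environments, optionally with a
planted multiplicative abundance shift on the taxa that carry chosen target
pathways. Everything is deterministic for a fixed seed (NumPy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from funcodak.globalmapper import TaxonAbundanceTable
from funcodak.reference import (
    CopyNumberTable,
    GenomeCopyTable,
    PathwayHierarchy,
    TaxonKey,
    build_copy_number_table,
    write_copy_number_table,
    write_genome_table,
    write_hierarchy,
)

# Within-group dispersion of the copy-number model (the "low-dispersion
# default"): most genomes agree with their taxon's base profile.
_LEVEL_JITTER = 0.01    # per-cell +-1 mutation prob at each taxonomic level
_GENOME_JITTER = 0.04   # per-cell +-1 mutation prob per genome
_GENOME_DROPOUT = 0.01  # per-cell enzyme-loss prob per genome
_GENOME_GAIN = 0.005    # per-cell enzyme-gain prob per genome
_EUK_PRESENCE_FACTOR = 0.2  # eukaryote-block enzymes are this much rarer


@dataclass(frozen=True)
class Effect:
    """A planted between-group functional effect: samples of the second
    group up- or down-weight the abundance of every taxon carrying (at least
    ``carrier_coverage`` of) a target pathway by ``multiplier``."""

    pathways: tuple[str, ...]
    multiplier: float = 10.0
    carrier_coverage: float = 0.5


@dataclass
class SynthSpec:
    """Parameters of one synthetic study.

    Defaults describe a small two-environment 16S study: 40 genera across a
    five-rank taxonomy, 120 enzymes, 25 pathways in 8 classes and 3
    super-classes, 4 genomes per genus, 20 samples per group.
    """

    n_taxa: int = 40
    n_enzymes: int = 120
    n_l3: int = 25
    n_l2: int = 8
    n_l1: int = 3
    enzymes_per_pathway: tuple[int, int] = (4, 10)
    sparsity: float = 0.75
    copy_mean: float = 1.5  # copy number = 1 + Poisson(copy_mean) where present
    eukaryote_fraction: float = 0.2
    genomes_per_taxon: int = 4
    n_samples_per_group: int = 20
    n_groups: int = 2
    dirichlet_scale: float = 3.0
    taxon_absence_prob: float = 0.3
    effect: Effect | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_l1 <= self.n_l2 <= self.n_l3):
            raise ValueError("need 1 <= n_l1 <= n_l2 <= n_l3")
        lo, hi = self.enzymes_per_pathway
        if lo < 1 or hi < lo:
            raise ValueError("enzymes_per_pathway must be a non-empty range with min >= 1")
        if hi > self.n_enzymes:
            raise ValueError("enzymes_per_pathway max exceeds n_enzymes")
        if min(self.n_taxa, self.n_enzymes, self.genomes_per_taxon,
               self.n_samples_per_group) < 1 or self.n_groups not in (1, 2):
            raise ValueError("all counts must be >= 1 and n_groups in {1, 2}")
        if not 0 <= self.sparsity <= 1:
            raise ValueError("sparsity must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthSpec":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "enzymes_per_pathway" in raw:
            raw["enzymes_per_pathway"] = tuple(raw["enzymes_per_pathway"])
        eff_paths = raw.pop("effect_pathways", None)
        if eff_paths:
            raw["effect"] = Effect(
                pathways=tuple(str(p) for p in str(eff_paths).split(",")),
                multiplier=float(raw.pop("effect_multiplier", 10.0)),
                carrier_coverage=float(raw.pop("effect_carrier_coverage", 0.5)),
            )
        return cls(**raw)


def _ec_name(i: int) -> str:
    return f"{i // 1000 + 1}.{(i // 100) % 10 + 1}.{(i // 10) % 10 + 1}.{i % 10 + 1}"


def _taxonomy(n_taxa: int) -> list[dict[str, str]]:
    """Nested five-rank lineages: contiguous blocks of genera share families,
    families share orders, and so on."""
    n_fam = max(2, n_taxa // 3) if n_taxa > 1 else 1
    n_ord = max(2, n_fam // 2) if n_fam > 1 else 1
    n_cls = max(2, n_ord // 2) if n_ord > 1 else 1
    n_phy = max(2, n_cls // 2) if n_cls > 1 else 1
    lineages = []
    for i in range(n_taxa):
        fam = i * n_fam // n_taxa
        ordr = fam * n_ord // n_fam
        cls = ordr * n_cls // n_ord
        phy = cls * n_phy // n_cls
        lineages.append(
            {
                "genus": f"Genus{i:03d}",
                "family": f"Family{fam:02d}",
                "order": f"Order{ordr:02d}",
                "class": f"Class{cls:02d}",
                "phylum": f"Phylum{phy:02d}",
            }
        )
    return lineages


def _jitter(profile: dict[int, int], prob: float, rng: np.random.Generator) -> None:
    """In-place +-1 perturbation of each nonzero cell with probability prob;
    values never drop below 1 here (presence is preserved)."""
    for e in list(profile):
        if rng.random() < prob:
            profile[e] = max(1, profile[e] + (1 if rng.random() < 0.5 else -1))


def make_reference(
    spec: SynthSpec,
) -> tuple[CopyNumberTable, GenomeCopyTable, PathwayHierarchy]:
    """Generate a full synthetic reference bundle.

    Enzyme presence patterns are fixed at the phylum level and inherited down
    the taxonomy with rare small copy-number mutations at each rank, plus
    per-genome jitter, loss and gain — so genomes within any group deviate
    little from the group mean. A eukaryote-marked subset of pathways draws
    its enzymes mostly from a block that prokaryotic taxa rarely carry. When
    ``spec.effect`` is set, about a quarter of the genera are designated
    carriers and given the full enzyme complement of each target pathway.
    """
    rng = np.random.default_rng([spec.seed, 17])
    lineages = _taxonomy(spec.n_taxa)

    # --- hierarchy ---------------------------------------------------------
    n_euk = int(round(spec.eukaryote_fraction * spec.n_l3))
    euk_pathways = {f"pw{i:03d}" for i in rng.choice(spec.n_l3, size=n_euk, replace=False)}
    euk_block = (
        list(range(spec.n_enzymes * 3 // 4, spec.n_enzymes)) if n_euk else []
    )
    general_block = [i for i in range(spec.n_enzymes) if i not in set(euk_block)]
    lo, hi = spec.enzymes_per_pathway
    ec_to_l3: dict[str, set[str]] = {}
    l3_enzymes: dict[str, set[str]] = {}
    l3_to_l2: dict[str, str] = {}
    l2_to_l1: dict[str, str] = {}
    for i in range(spec.n_l3):
        pid = f"pw{i:03d}"
        k = int(rng.integers(lo, hi + 1))
        if pid in euk_pathways and euk_block:
            n_from_euk = max(1, int(round(0.8 * k)))
            pool = list(rng.choice(euk_block, size=min(n_from_euk, len(euk_block)), replace=False))
            rest = k - len(pool)
            if rest > 0:
                pool += list(rng.choice(general_block, size=rest, replace=False))
        else:
            pool = list(rng.choice(general_block, size=min(k, len(general_block)), replace=False))
        members = {_ec_name(int(e)) for e in pool}
        l3_enzymes[pid] = members
        for ec in members:
            ec_to_l3.setdefault(ec, set()).add(pid)
        l3_to_l2[pid] = f"cl{i % spec.n_l2:02d}"
    for j in range(spec.n_l2):
        l2_to_l1[f"cl{j:02d}"] = f"sc{j % spec.n_l1}"
    hierarchy = PathwayHierarchy(
        ec_to_l3=ec_to_l3,
        l3_enzymes=l3_enzymes,
        l3_to_l2=l3_to_l2,
        l2_to_l1=l2_to_l1,
        eukaryote_l3=euk_pathways,
        l3_names={p: f"Pathway {p[2:]}" for p in l3_enzymes},
        l2_names={c: f"Class {c[2:]}" for c in l2_to_l1},
        l1_names={f"sc{i}": f"Super-class {i}" for i in range(spec.n_l1)},
    )

    # --- copy-number model: phylum base -> genus base -> genomes -----------
    presence_p = 1.0 - spec.sparsity
    phyla = sorted({lin["phylum"] for lin in lineages})
    phylum_base: dict[str, dict[int, int]] = {}
    for phy in phyla:
        prof: dict[int, int] = {}
        for e in range(spec.n_enzymes):
            p = presence_p * (_EUK_PRESENCE_FACTOR if e in set(euk_block) else 1.0)
            if rng.random() < p:
                prof[e] = 1 + int(rng.poisson(spec.copy_mean))
        phylum_base[phy] = prof
    genus_base: list[dict[int, int]] = []
    for lin in lineages:
        prof = dict(phylum_base[lin["phylum"]])
        for _ in ("class", "order", "family", "genus"):
            _jitter(prof, _LEVEL_JITTER, rng)
        genus_base.append(prof)

    if spec.effect is not None:
        n_carriers = max(2, int(round(0.25 * spec.n_taxa)))
        carrier_idx = sorted(rng.choice(spec.n_taxa, size=n_carriers, replace=False))
        ec_index = {_ec_name(i): i for i in range(spec.n_enzymes)}
        for pid in spec.effect.pathways:
            if pid not in l3_enzymes:
                raise ValueError(f"effect target pathway {pid!r} not in hierarchy")
            for t in carrier_idx:
                for ec in l3_enzymes[pid]:
                    genus_base[t].setdefault(ec_index[ec], 1 + int(rng.poisson(spec.copy_mean)))

    rows: list[tuple[str, dict[str, str], dict[str, float]]] = []
    for t, lin in enumerate(lineages):
        for g in range(spec.genomes_per_taxon):
            prof = dict(genus_base[t])
            for e in list(prof):
                r = rng.random()
                if r < _GENOME_DROPOUT:
                    del prof[e]
                elif r < _GENOME_DROPOUT + _GENOME_JITTER:
                    prof[e] = max(0, prof[e] + (1 if rng.random() < 0.5 else -1))
                    if prof[e] == 0:
                        del prof[e]
            # rare re-acquisition of enzymes from the taxon's own repertoire
            for e in genus_base[t]:
                if e not in prof and rng.random() < _GENOME_GAIN:
                    prof[e] = 1
            rows.append(
                (
                    f"{lin['genus']}_g{g}",
                    dict(lin),
                    {_ec_name(e): float(c) for e, c in sorted(prof.items())},
                )
            )
    genomes = GenomeCopyTable(rows=rows)
    table = build_copy_number_table(genomes)
    return table, genomes, hierarchy


def carriers_of(
    table: CopyNumberTable,
    hierarchy: PathwayHierarchy,
    pathways: tuple[str, ...],
    min_coverage: float = 0.5,
    rank: str = "genus",
) -> list[TaxonKey]:
    """Taxa at ``rank`` whose own repertoire covers at least ``min_coverage``
    of some target pathway's enzyme set."""
    out = []
    for key in table.taxa:
        if key.rank != rank:
            continue
        prof = table.get(key)
        for pid in pathways:
            members = hierarchy.enzymes_of(pid)
            cov = sum(1 for ec in members if prof.get(ec, 0.0) > 0) / len(members)
            if cov >= min_coverage:
                out.append(key)
                break
    return sorted(out)


def make_abundance_tables(
    spec: SynthSpec,
    reference: CopyNumberTable,
    hierarchy: PathwayHierarchy | None = None,
) -> list[TaxonAbundanceTable]:
    """One compositional abundance table per group (percent, rows sum to 100).

    Per-sample abundances are normalized independent Gamma draws (a Dirichlet
    construction) around a shared lognormal base composition, with structural
    zeros (a taxon absent from a sample with probability
    ``taxon_absence_prob``). Without an effect the groups are exchangeable;
    with one, carrier taxa in the second group are multiplied by
    ``effect.multiplier`` before renormalization, so the functional shift
    must emerge through the inference chain.
    """
    rng = np.random.default_rng([spec.seed, 29])
    genus_keys = sorted(
        (k for k in reference.taxa if k.rank == "genus"), key=lambda k: k.name
    )
    labels = [k.name for k in genus_keys]
    n = len(labels)
    w = rng.lognormal(0.0, 1.0, n)
    alpha = spec.dirichlet_scale * w / w.mean()
    carrier_mask = np.zeros(n, dtype=bool)
    if spec.effect is not None:
        if hierarchy is None:
            raise ValueError("hierarchy is required to locate effect carriers")
        carriers = set(
            carriers_of(
                reference, hierarchy, spec.effect.pathways,
                spec.effect.carrier_coverage,
            )
        )
        carrier_mask = np.array([k in carriers for k in genus_keys])
        if not carrier_mask.any():
            raise ValueError("no taxon carries the effect's target pathways")
    tables = []
    for g in range(spec.n_groups):
        mat = np.zeros((spec.n_samples_per_group, n))
        for s in range(spec.n_samples_per_group):
            x = rng.gamma(shape=np.maximum(alpha, 1e-3), scale=1.0)
            absent = rng.random(n) < spec.taxon_absence_prob
            x = np.where(absent, 0.0, x)
            if x.sum() == 0:
                x[int(np.argmax(w))] = 1.0
            if g >= 1 and spec.effect is not None:
                x = np.where(carrier_mask, x * spec.effect.multiplier, x)
            mat[s] = x
        frame = pd.DataFrame(
            mat,
            index=[f"grp{g + 1}_s{s + 1:02d}" for s in range(spec.n_samples_per_group)],
            columns=labels,
        )
        tables.append(TaxonAbundanceTable(data=frame))
    return tables


def make_correlated_abundances(
    reference: CopyNumberTable,
    n_samples: int = 12,
    seed: int = 0,
    factor_sigma: float = 1.0,
    special_noise_sigma: float = 0.15,
    background_noise_sigma: float = 1.0,
) -> tuple[TaxonAbundanceTable, tuple[str, str, str]]:
    """Abundance table with a planted functionally-synchronized taxon pair
    and an antagonistic taxon, for exercising the network module.

    A per-sample latent factor drives the first two genera up together and
    the third inversely; all other genera fluctuate independently. Returns
    the table and the three special labels (sync_a, sync_b, anti)."""
    rng = np.random.default_rng([seed, 41])
    genus_keys = sorted(
        (k for k in reference.taxa if k.rank == "genus"), key=lambda k: k.name
    )
    labels = [k.name for k in genus_keys]
    if len(labels) < 4:
        raise ValueError("need at least 4 genera in the reference")
    n = len(labels)
    w = rng.lognormal(0.0, 0.5, n)
    mat = np.zeros((n_samples, n))
    for s in range(n_samples):
        f = float(np.exp(rng.normal(0.0, factor_sigma)))
        noise = np.exp(rng.normal(0.0, background_noise_sigma, n))
        row = w * noise
        sp = np.exp(rng.normal(0.0, special_noise_sigma, 3))
        row[0] = w[0] * f * sp[0]
        row[1] = w[1] * f * sp[1]
        row[2] = w[2] / f * sp[2]
        mat[s] = row
    frame = pd.DataFrame(
        mat, index=[f"s{s + 1:02d}" for s in range(n_samples)], columns=labels
    )
    return TaxonAbundanceTable(data=frame), (labels[0], labels[1], labels[2])


def write_bundle(
    table: CopyNumberTable,
    genomes: GenomeCopyTable,
    hierarchy: PathwayHierarchy,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a bundle directory: copy_numbers.tsv, hierarchy.tsv,
    eukaryotic_pathways.tsv and genomes.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "copy_numbers": out_dir / "copy_numbers.tsv",
        "hierarchy": out_dir / "hierarchy.tsv",
        "blacklist": out_dir / "eukaryotic_pathways.tsv",
        "genomes": out_dir / "genomes.tsv",
    }
    write_copy_number_table(table, paths["copy_numbers"])
    write_hierarchy(hierarchy, paths["hierarchy"], paths["blacklist"])
    write_genome_table(genomes, paths["genomes"])
    return paths
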
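"""Back-end reference bundle: taxon→EC mean copy numbers and the KEGG hierarchy.

The reference bundle plays the role of a pre-compiled database linking
taxonomy to function: for every taxon (at genus, family, order, class or
phylum rank) it stores the mean gene copy number of each enzyme (EC number)
over the member genomes, and for every enzyme the Level-3 KEGG pathways it
belongs to, with single-parent maps up to Level-2 classes and Level-1
super-classes plus a blacklist of eukaryote-associated pathways.

The module loads and validates pre-parsed TSV bundles, aggregates per-genome
copy-number tables into per-taxon means, computes the z-score divergence
diagnostic that justifies using means at higher ranks, and resolves
classifier-style taxon labels (plain names or semicolon lineages) against a
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from funcodak._util import (
    RANKS,
    is_valid_ec,
    normalize_label,
    split_rank_prefix,
)

Z_BANDS: tuple[str, ...] = ("within_1", "1_to_2", "beyond_2")


class BundleValidationError(ValueError):
    """Raised with the full list of validation failures for a bundle."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "reference bundle validation failed:\n  " + "\n  ".join(self.errors)
        )


@dataclass(frozen=True, order=True)
class TaxonKey:
    """A taxon identified by canonical name and rank."""

    name: str
    rank: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("TaxonKey name must be non-empty")
        if self.rank not in RANKS:
            raise ValueError(f"unsupported rank {self.rank!r}; expected one of {RANKS}")

    @property
    def norm(self) -> tuple[str, str]:
        return (normalize_label(self.name), self.rank)


@dataclass
class CopyNumberTable:
    """Mean enzyme copy numbers per taxon: C(t, e).

    ``profiles`` maps each TaxonKey to a sparse {EC: mean copy number} map;
    an absent EC means copy number zero. ``parents`` optionally links a key
    to its ancestor at the next-higher rank.
    """

    profiles: dict[TaxonKey, dict[str, float]]
    parents: dict[TaxonKey, TaxonKey] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, str], TaxonKey] = {}
        for key in self.profiles:
            if key.norm in self._index:
                raise BundleValidationError(
                    [f"duplicate TaxonKey {key.name!r} at rank {key.rank}"]
                )
            self._index[key.norm] = key

    @property
    def taxa(self) -> list[TaxonKey]:
        return list(self.profiles)

    def ecs(self) -> set[str]:
        out: set[str] = set()
        for prof in self.profiles.values():
            out.update(prof)
        return out

    def get(self, key: TaxonKey) -> dict[str, float]:
        return self.profiles[key]

    def lookup(self, name: str, rank: str) -> TaxonKey | None:
        return self._index.get((normalize_label(name), rank))

    def lookup_any_rank(self, name: str) -> TaxonKey | None:
        """Most-specific-rank match for a bare name."""
        norm = normalize_label(name)
        for rank in RANKS:
            key = self._index.get((norm, rank))
            if key is not None:
                return key
        return None

    def validate(self) -> list[str]:
        errors: list[str] = []
        rank_order = {r: i for i, r in enumerate(RANKS)}
        for key, prof in self.profiles.items():
            for ec, cn in prof.items():
                if not is_valid_ec(ec):
                    errors.append(f"taxon {key.name!r}: malformed EC {ec!r}")
                if cn < 0 or not math.isfinite(cn):
                    errors.append(f"taxon {key.name!r}, EC {ec}: copy number {cn} invalid")
        for child, parent in self.parents.items():
            if rank_order[parent.rank] <= rank_order[child.rank]:
                errors.append(
                    f"parent link {child.name}({child.rank}) -> "
                    f"{parent.name}({parent.rank}) does not go up the hierarchy"
                )
        return errors


@dataclass
class GenomeCopyTable:
    """Per-genome EC copy numbers with a full five-rank lineage.

    ``rows`` is a list of (genome_id, lineage, profile) where lineage maps
    every rank in RANKS to a taxon name and profile maps EC -> copy number.
    """

    rows: list[tuple[str, dict[str, str], dict[str, float]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        errors: list[str] = []
        for gid, lineage, prof in self.rows:
            if gid in seen:
                errors.append(f"duplicate genome id {gid!r}")
            seen.add(gid)
            missing = [r for r in RANKS if r not in lineage]
            if missing:
                errors.append(f"genome {gid!r}: lineage missing ranks {missing}")
            for ec, cn in prof.items():
                if not is_valid_ec(ec):
                    errors.append(f"genome {gid!r}: malformed EC {ec!r}")
                if cn < 0:
                    errors.append(f"genome {gid!r}, EC {ec}: negative copy number")
        if errors:
            raise BundleValidationError(errors)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class PathwayHierarchy:
    """Three-tier KEGG hierarchy: ECs ↔ Level-3 pathways → Level-2 classes →
    Level-1 super-classes, plus the eukaryote-associated pathway blacklist."""

    ec_to_l3: dict[str, set[str]]
    l3_enzymes: dict[str, set[str]]
    l3_to_l2: dict[str, str]
    l2_to_l1: dict[str, str]
    eukaryote_l3: set[str] = field(default_factory=set)
    l3_names: dict[str, str] = field(default_factory=dict)
    l2_names: dict[str, str] = field(default_factory=dict)
    l1_names: dict[str, str] = field(default_factory=dict)

    @property
    def pathways(self) -> list[str]:
        return sorted(self.l3_enzymes)

    def enzymes_of(self, l3_id: str) -> set[str]:
        if l3_id not in self.l3_enzymes:
            raise KeyError(f"unknown Level-3 pathway id {l3_id!r}")
        return self.l3_enzymes[l3_id]

    def validate(self) -> list[str]:
        errors: list[str] = []
        inv: dict[str, set[str]] = {}
        for ec, l3s in self.ec_to_l3.items():
            if not is_valid_ec(ec):
                errors.append(f"hierarchy: malformed EC {ec!r}")
            for p in l3s:
                inv.setdefault(p, set()).add(ec)
        if inv != {p: s for p, s in self.l3_enzymes.items() if s}:
            errors.append("hierarchy: l3_enzymes is not the exact inverse of ec_to_l3")
        for p, ecs in self.l3_enzymes.items():
            if not ecs:
                errors.append(f"pathway {p!r} has no constituent enzymes")
            if p not in self.l3_to_l2:
                errors.append(f"Level-3 id {p!r} missing from l3_to_l2")
        for p, l2 in self.l3_to_l2.items():
            if l2 not in self.l2_to_l1:
                errors.append(f"Level-2 id {l2!r} (parent of {p!r}) missing from l2_to_l1")
        for p in self.eukaryote_l3:
            if p not in self.l3_to_l2:
                errors.append(f"blacklisted Level-3 id {p!r} not in hierarchy")
        return errors


@dataclass
class DivergenceSummary:
    """Proportion of per-genome copy-number observations per |z| band and rank.

    Bands are disjoint: |z| <= 1, 1 < |z| <= 2, |z| > 2; per rank the three
    proportions sum to one.
    """

    proportions: dict[str, dict[str, float]]
    n_observations: dict[str, int]

    def within_1(self, rank: str) -> float:
        return self.proportions[rank]["within_1"]


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def load_copy_number_table(path: str | Path) -> CopyNumberTable:
    """Read a copy-number TSV (`taxon  rank  ec  copy_number`)."""
    path = Path(path)
    errors: list[str] = []
    profiles: dict[TaxonKey, dict[str, float]] = {}
    index: dict[tuple[str, str], TaxonKey] = {}
    header_seen = False
    for lineno, fields in _data_lines(path):
        if not header_seen:
            header_seen = True
            if fields[:4] == ["taxon", "rank", "ec", "copy_number"]:
                continue
            errors.append(f"{path.name}:{lineno}: expected header taxon/rank/ec/copy_number")
            continue
        if len(fields) != 4:
            errors.append(f"{path.name}:{lineno}: expected 4 fields, got {len(fields)}")
            continue
        name, rank, ec, cn_str = fields
        if rank not in RANKS:
            errors.append(f"{path.name}:{lineno}: field 'rank': unsupported rank {rank!r}")
            continue
        if not is_valid_ec(ec):
            errors.append(f"{path.name}:{lineno}: field 'ec': malformed EC {ec!r}")
            continue
        try:
            cn = float(cn_str)
        except ValueError:
            errors.append(f"{path.name}:{lineno}: field 'copy_number': not a number {cn_str!r}")
            continue
        if cn < 0:
            errors.append(f"{path.name}:{lineno}: field 'copy_number': negative value {cn}")
            continue
        key = index.get((normalize_label(name), rank))
        if key is None:
            key = TaxonKey(name=name, rank=rank)
            index[key.norm] = key
            profiles[key] = {}
        if ec in profiles[key]:
            errors.append(f"{path.name}:{lineno}: duplicate (taxon, EC) row ({name!r}, {ec})")
            continue
        profiles[key][ec] = cn
    if errors:
        raise BundleValidationError(errors)
    return CopyNumberTable(profiles=profiles)


def load_hierarchy(
    hierarchy_path: str | Path, blacklist_path: str | Path | None = None
) -> PathwayHierarchy:
    """Read the hierarchy TSV (`ec l3_id l3_name l2_id l2_name l1_id l1_name`)
    and an optional blacklist file (one Level-3 id per line)."""
    hierarchy_path = Path(hierarchy_path)
    errors: list[str] = []
    ec_to_l3: dict[str, set[str]] = {}
    l3_enzymes: dict[str, set[str]] = {}
    l3_to_l2: dict[str, str] = {}
    l2_to_l1: dict[str, str] = {}
    l3_names: dict[str, str] = {}
    l2_names: dict[str, str] = {}
    l1_names: dict[str, str] = {}
    header_seen = False
    for lineno, fields in _data_lines(hierarchy_path):
        if not header_seen:
            header_seen = True
            if fields and fields[0] == "ec":
                continue
        if len(fields) != 7:
            errors.append(f"{hierarchy_path.name}:{lineno}: expected 7 fields, got {len(fields)}")
            continue
        ec, l3, l3n, l2, l2n, l1, l1n = fields
        if not is_valid_ec(ec):
            errors.append(f"{hierarchy_path.name}:{lineno}: field 'ec': malformed EC {ec!r}")
            continue
        if l3 in l3_to_l2 and l3_to_l2[l3] != l2:
            errors.append(
                f"{hierarchy_path.name}:{lineno}: Level-3 {l3!r} mapped to two classes "
                f"({l3_to_l2[l3]!r} and {l2!r})"
            )
            continue
        if l2 in l2_to_l1 and l2_to_l1[l2] != l1:
            errors.append(
                f"{hierarchy_path.name}:{lineno}: Level-2 {l2!r} mapped to two super-classes"
            )
            continue
        ec_to_l3.setdefault(ec, set()).add(l3)
        l3_enzymes.setdefault(l3, set()).add(ec)
        l3_to_l2[l3] = l2
        l2_to_l1[l2] = l1
        l3_names[l3] = l3n
        l2_names[l2] = l2n
        l1_names[l1] = l1n
    blacklist: set[str] = set()
    if blacklist_path is not None:
        blacklist_path = Path(blacklist_path)
        for lineno, fields in _data_lines(blacklist_path):
            pid = fields[0].strip()
            if pid == "l3_id":  # optional header
                continue
            if pid not in l3_to_l2:
                errors.append(
                    f"{blacklist_path.name}:{lineno}: blacklisted Level-3 id {pid!r} "
                    "missing from hierarchy"
                )
                continue
            blacklist.add(pid)
    if errors:
        raise BundleValidationError(errors)
    hierarchy = PathwayHierarchy(
        ec_to_l3=ec_to_l3,
        l3_enzymes=l3_enzymes,
        l3_to_l2=l3_to_l2,
        l2_to_l1=l2_to_l1,
        eukaryote_l3=blacklist,
        l3_names=l3_names,
        l2_names=l2_names,
        l1_names=l1_names,
    )
    post = hierarchy.validate()
    if post:
        raise BundleValidationError(post)
    return hierarchy


def load_reference_bundle(
    copy_number_path: str | Path,
    hierarchy_path: str | Path,
    blacklist_path: str | Path | None = None,
) -> tuple[CopyNumberTable, PathwayHierarchy]:
    """Load and validate a full reference bundle; failures from both files
    are collected and raised together as a BundleValidationError."""
    errors: list[str] = []
    table = hierarchy = None
    try:
        table = load_copy_number_table(copy_number_path)
    except BundleValidationError as exc:
        errors.extend(exc.errors)
    try:
        hierarchy = load_hierarchy(hierarchy_path, blacklist_path)
    except BundleValidationError as exc:
        errors.extend(exc.errors)
    if table is not None:
        errors.extend(table.validate())
    if errors:
        raise BundleValidationError(errors)
    assert table is not None and hierarchy is not None
    return table, hierarchy


def write_copy_number_table(table: CopyNumberTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon\trank\tec\tcopy_number\n")
        for key in sorted(table.profiles, key=lambda k: (k.rank, k.name)):
            for ec in sorted(table.profiles[key]):
                fh.write(f"{key.name}\t{key.rank}\t{ec}\t{table.profiles[key][ec]:.10g}\n")


def write_hierarchy(
    hierarchy: PathwayHierarchy,
    hierarchy_path: str | Path,
    blacklist_path: str | Path | None = None,
) -> None:
    with open(hierarchy_path, "w", encoding="utf-8") as fh:
        fh.write("ec\tl3_id\tl3_name\tl2_id\tl2_name\tl1_id\tl1_name\n")
        for l3 in sorted(hierarchy.l3_enzymes):
            l2 = hierarchy.l3_to_l2[l3]
            l1 = hierarchy.l2_to_l1[l2]
            for ec in sorted(hierarchy.l3_enzymes[l3]):
                fh.write(
                    f"{ec}\t{l3}\t{hierarchy.l3_names.get(l3, l3)}\t"
                    f"{l2}\t{hierarchy.l2_names.get(l2, l2)}\t"
                    f"{l1}\t{hierarchy.l1_names.get(l1, l1)}\n"
                )
    if blacklist_path is not None:
        with open(blacklist_path, "w", encoding="utf-8") as fh:
            fh.write("l3_id\n")
            for pid in sorted(hierarchy.eukaryote_l3):
                fh.write(pid + "\n")


def load_genome_table(path: str | Path) -> GenomeCopyTable:
    """Read the genome TSV
    (`genome_id phylum class order family genus ec copy_number`)."""
    path = Path(path)
    errors: list[str] = []
    rows: dict[str, tuple[dict[str, str], dict[str, float]]] = {}
    header_seen = False
    for lineno, fields in _data_lines(path):
        if not header_seen:
            header_seen = True
            if fields and fields[0] == "genome_id":
                continue
        if len(fields) != 8:
            errors.append(f"{path.name}:{lineno}: expected 8 fields, got {len(fields)}")
            continue
        gid, phylum, klass, order, family, genus, ec, cn_str = fields
        lineage = {
            "phylum": phylum, "class": klass, "order": order,
            "family": family, "genus": genus,
        }
        if gid in rows and rows[gid][0] != lineage:
            errors.append(f"{path.name}:{lineno}: genome {gid!r} has inconsistent lineage")
            continue
        if not is_valid_ec(ec):
            errors.append(f"{path.name}:{lineno}: field 'ec': malformed EC {ec!r}")
            continue
        try:
            cn = float(cn_str)
        except ValueError:
            errors.append(f"{path.name}:{lineno}: field 'copy_number': not a number")
            continue
        rows.setdefault(gid, (lineage, {}))[1][ec] = cn
    if errors:
        raise BundleValidationError(errors)
    return GenomeCopyTable(rows=[(g, lin, prof) for g, (lin, prof) in rows.items()])


def write_genome_table(genomes: GenomeCopyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tphylum\tclass\torder\tfamily\tgenus\tec\tcopy_number\n")
        for gid, lineage, prof in genomes.rows:
            for ec in sorted(prof):
                fh.write(
                    f"{gid}\t{lineage['phylum']}\t{lineage['class']}\t{lineage['order']}\t"
                    f"{lineage['family']}\t{lineage['genus']}\t{ec}\t{prof[ec]:.10g}\n"
                )


# ---------------------------------------------------------------------------
# Aggregation and the z-score diagnostic
# ---------------------------------------------------------------------------

def _group_genomes(
    genomes: GenomeCopyTable, rank: str
) -> dict[str, list[dict[str, float]]]:
    if rank not in RANKS:
        raise ValueError(f"unsupported rank {rank!r}")
    groups: dict[str, list[dict[str, float]]] = {}
    for _, lineage, prof in genomes.rows:
        groups.setdefault(lineage[rank], []).append(prof)
    return groups


def aggregate_mean_copy_numbers(genomes: GenomeCopyTable, rank: str) -> CopyNumberTable:
    """Mean copy number per (taxon group at `rank`, EC) over ALL member
    genomes, counting genomes that lack the EC as zero.

    The mean therefore reflects both dosage and prevalence of the enzyme
    within the group.
    """
    if len(genomes) == 0:
        raise ValueError("empty genome table")
    groups = _group_genomes(genomes, rank)
    profiles: dict[TaxonKey, dict[str, float]] = {}
    parents: dict[TaxonKey, TaxonKey] = {}
    parent_rank = RANKS[RANKS.index(rank) + 1] if rank != "phylum" else None
    parent_names: dict[str, str] = {}
    if parent_rank is not None:
        for _, lineage, _ in genomes.rows:
            parent_names[lineage[rank]] = lineage[parent_rank]
    for name, members in groups.items():
        n = len(members)
        sums: dict[str, float] = {}
        for prof in members:
            for ec, cn in prof.items():
                sums[ec] = sums.get(ec, 0.0) + cn
        key = TaxonKey(name=name, rank=rank)
        profiles[key] = {ec: s / n for ec, s in sums.items()}
        if parent_rank is not None:
            parents[key] = TaxonKey(name=parent_names[name], rank=parent_rank)
    return CopyNumberTable(profiles=profiles, parents=parents)


def build_copy_number_table(genomes: GenomeCopyTable) -> CopyNumberTable:
    """Aggregate at all five ranks into one table with parent links, so that
    taxon resolution can fall back from genus up to phylum."""
    profiles: dict[TaxonKey, dict[str, float]] = {}
    parents: dict[TaxonKey, TaxonKey] = {}
    for rank in RANKS:
        sub = aggregate_mean_copy_numbers(genomes, rank)
        profiles.update(sub.profiles)
        parents.update(sub.parents)
    return CopyNumberTable(profiles=profiles, parents=parents)


def zscore_divergence(
    genomes: GenomeCopyTable, ranks: str | Iterable[str] | None = None
) -> DivergenceSummary:
    """How far individual genomes deviate from their group mean copy number.

    For each taxon group at each rank and each EC observed in at least one
    member genome, every member genome contributes one observation
    z = (x - mean) / sd with the sample (n-1) standard deviation; genomes
    lacking the EC contribute x = 0. Singleton groups and zero-variance
    (group, EC) cells contribute z = 0 (identical copy numbers are maximal
    agreement). A predominance of |z| <= 1 justifies summarising a group by
    its mean.
    """
    if len(genomes) == 0:
        raise ValueError("empty genome table")
    if ranks is None:
        rank_list = list(RANKS)
    elif isinstance(ranks, str):
        rank_list = [ranks]
    else:
        rank_list = list(ranks)
    proportions: dict[str, dict[str, float]] = {}
    n_obs: dict[str, int] = {}
    for rank in rank_list:
        counts = {band: 0 for band in Z_BANDS}
        for members in _group_genomes(genomes, rank).values():
            ecs = sorted({ec for prof in members for ec in prof})
            if not ecs:
                continue
            mat = np.zeros((len(members), len(ecs)))
            for i, prof in enumerate(members):
                for j, ec in enumerate(ecs):
                    mat[i, j] = prof.get(ec, 0.0)
            if len(members) == 1:
                counts["within_1"] += mat.shape[1]
                continue
            mean = mat.mean(axis=0)
            sd = mat.std(axis=0, ddof=1)
            z = np.zeros_like(mat)
            nz = sd > 0
            z[:, nz] = (mat[:, nz] - mean[nz]) / sd[nz]
            absz = np.abs(z)
            counts["within_1"] += int((absz <= 1.0).sum())
            counts["1_to_2"] += int(((absz > 1.0) & (absz <= 2.0)).sum())
            counts["beyond_2"] += int((absz > 2.0).sum())
        total = sum(counts.values())
        n_obs[rank] = total
        proportions[rank] = {
            band: (counts[band] / total if total else 0.0) for band in Z_BANDS
        }
    return DivergenceSummary(proportions=proportions, n_observations=n_obs)


# ---------------------------------------------------------------------------
# Taxon resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResolvedTaxon:
    """Outcome of matching one input label against a CopyNumberTable."""

    key: TaxonKey
    profile: Mapping[str, float]
    fallback: bool  # True when resolution climbed above the terminal rank


def resolve_taxon(label: str, table: CopyNumberTable) -> ResolvedTaxon | None:
    """Match a plain name or a semicolon-delimited lineage string at the most
    specific rank shared by the label and the table.

    Lineage components may carry 'g__'-style prefixes; components outside the
    five supported ranks (kingdom, species) are skipped. When the terminal
    component cannot be matched, resolution falls back towards the root and
    the result is flagged; returns None when nothing matches (the caller
    reports unresolved labels, they are not errors).
    """
    if ";" in label:
        components = [c for c in (p.strip() for p in label.split(";")) if c]
        candidates: list[tuple[str | None, str]] = []
        for comp in components:
            rank, bare = split_rank_prefix(comp)
            if not bare:
                continue
            candidates.append((rank, bare))
        for i, (rank, bare) in enumerate(reversed(candidates)):
            if rank is not None:
                key = table.lookup(bare, rank)
            else:
                key = table.lookup_any_rank(bare)
            if key is not None:
                return ResolvedTaxon(key=key, profile=table.get(key), fallback=i > 0)
        return None
    key = table.lookup_any_rank(label)
    if key is None:
        return None
    return ResolvedTaxon(key=key, profile=table.get(key), fallback=False)
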
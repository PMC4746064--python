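"""Pathway-level functional inference from taxonomic abundance profiles.

Two community models are implemented. Under *co-metabolism* the enzymes
encoded by all community members pool together: the community enzyme pool is
Ep(s, e) = sum_t A(s, t)/100 * C(t, e), where A is the percent relative
abundance of taxon t in sample s and C the taxon's mean enzyme copy number,
and the raw abundance of pathway p is the summed pool over its constituent
enzymes E(p). Under *independent contributions* each taxon runs pathways
alone: taxon t contributes A(s, t)/100 * sum_{e in E(p)} C(t, e) to pathway
p, but only when the taxon's own repertoire covers at least a PEC fraction of
E(p); community pathway abundance is the sum of the per-taxon contributions.

Both models filter predictions with a Pathway Exclusion Cut-off (PEC): a
pathway is reported in a sample only when at least PEC percent of its
constituent enzymes are present. An optional blacklist removes
eukaryote-associated pathways. Filtered Level-3 profiles are renormalized to
100% per sample and aggregated up the KEGG hierarchy to Level-2 classes and
Level-1 super-classes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from funcodak._util import is_wildcard_ec
from funcodak.reference import (
    CopyNumberTable,
    PathwayHierarchy,
    ResolvedTaxon,
    TaxonKey,
    resolve_taxon,
)

DEFAULT_PEC_VALUES: tuple[int, ...] = (30, 40, 50, 60, 70, 80, 90)
LEVELS: tuple[str, ...] = ("L3", "L2", "L1")


@dataclass
class TaxonAbundanceTable:
    """Samples × taxa relative abundances in percent.

    Rows are renormalized to sum to exactly 100 on construction (all-zero
    rows stay zero). Taxon labels may be plain names or semicolon lineages.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.data = self.data.astype(float)
        sums = self.data.sum(axis=1)
        pos = sums > 0
        self.data.loc[pos] = self.data.loc[pos].div(sums[pos], axis=0) * 100.0

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ResolutionReport:
    """Book-keeping of taxon-label resolution against the reference table."""

    resolved: dict[str, ResolvedTaxon] = field(default_factory=dict)
    unresolved: dict[str, float] = field(default_factory=dict)  # label -> mean % abundance
    fallback_labels: set[str] = field(default_factory=set)
    dropped_mass: dict[str, float] = field(default_factory=dict)  # sample -> % dropped
    empty_samples: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "resolved": {
                lab: {"name": r.key.name, "rank": r.key.rank, "fallback": r.fallback}
                for lab, r in self.resolved.items()
            },
            "unresolved": dict(self.unresolved),
            "dropped_mass_percent": dict(self.dropped_mass),
            "empty_samples": list(self.empty_samples),
        }


@dataclass
class EnzymePool:
    """Per-sample pooled enzyme abundances Ep(s, e) (samples × ECs)."""

    data: pd.DataFrame
    resolution: ResolutionReport | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)


@dataclass
class FunctionProfile:
    """Samples × functions relative abundances (percent) at one KEGG level,
    one PEC and one algorithm; ``coverage`` (L3 only) holds the percent of
    each pathway's enzymes present per sample, before any filtering."""

    level: str
    pec: float
    algorithm: str
    values: pd.DataFrame
    coverage: pd.DataFrame | None = None
    names: dict[str, str] = field(default_factory=dict)
    raw: pd.DataFrame | None = None  # filtered but un-renormalized values

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def functions(self) -> list[str]:
        return list(self.values.columns)

    def retained(self, sample: str | None = None) -> set[str]:
        """Functions with nonzero abundance (in one sample or in any)."""
        if sample is not None:
            row = self.values.loc[sample]
            return set(row.index[row > 0])
        return set(self.values.columns[(self.values > 0).any(axis=0)])


@dataclass
class ContributionMatrix:
    """Percent share of each taxon in each function's abundance.

    ``per_sample`` maps sample id -> taxa × functions percent matrix;
    ``pooled`` is the environment-level analogue computed from summed raw
    contributions over all samples. Columns of functions with nonzero
    abundance sum to 100.
    """

    level: str
    pec: float
    per_sample: dict[str, pd.DataFrame]
    pooled: pd.DataFrame
    taxa: list[TaxonKey]


@dataclass
class CoreSet:
    """Functions whose prevalence (fraction of samples with nonzero
    abundance) reaches the threshold."""

    level: str
    threshold: float
    entries: pd.DataFrame  # index function id; columns prevalence, mean_abundance

    @property
    def functions(self) -> set[str]:
        return set(self.entries.index)


# ---------------------------------------------------------------------------
# Resolution and pooling
# ---------------------------------------------------------------------------

def _resolve_abundance(
    abundance: TaxonAbundanceTable, table: CopyNumberTable
) -> tuple[pd.DataFrame, list[TaxonKey], ResolutionReport]:
    """Resolve labels, merge duplicates, drop unresolved taxa and renormalize.

    Returns (samples × resolved-keys percent matrix, keys, report)."""
    report = ResolutionReport()
    key_cols: dict[TaxonKey, list[str]] = {}
    for label in abundance.taxa:
        res = resolve_taxon(label, table)
        if res is None:
            report.unresolved[label] = float(abundance.data[label].mean())
            continue
        report.resolved[label] = res
        if res.fallback:
            report.fallback_labels.add(label)
        key_cols.setdefault(res.key, []).append(label)
    keys = sorted(key_cols, key=lambda k: (k.rank, k.name))
    merged = pd.DataFrame(
        {i: abundance.data[cols].sum(axis=1) for i, cols in enumerate(key_cols[k] for k in keys)},
        index=abundance.data.index,
    )
    merged.columns = range(len(keys))
    sums = merged.sum(axis=1) if len(keys) else pd.Series(0.0, index=abundance.data.index)
    for s in abundance.samples:
        total = float(sums.get(s, 0.0)) if len(keys) else 0.0
        report.dropped_mass[s] = max(0.0, 100.0 - total)
        if total <= 0:
            report.empty_samples.append(s)
    if len(keys):
        pos = sums > 0
        merged.loc[pos] = merged.loc[pos].div(sums[pos], axis=0) * 100.0
    return merged, keys, report


def _copy_matrix(keys: list[TaxonKey], table: CopyNumberTable) -> tuple[np.ndarray, list[str]]:
    ecs = sorted({ec for k in keys for ec in table.get(k)})
    C = np.zeros((len(keys), len(ecs)))
    ec_index = {ec: j for j, ec in enumerate(ecs)}
    for i, k in enumerate(keys):
        for ec, cn in table.get(k).items():
            C[i, ec_index[ec]] = cn
    return C, ecs


def pool_enzymes(abundance: TaxonAbundanceTable, table: CopyNumberTable) -> EnzymePool:
    """Community enzyme pool Ep(s, e) = sum_t A(s, t)/100 * C(t, e).

    Unresolved taxa are dropped (and reported on the pool's ``resolution``
    attribute); the remaining abundances are renormalized to 100 first, so
    the dropped mass is logged rather than silently diluting the pool.
    """
    merged, keys, report = _resolve_abundance(abundance, table)
    if not keys:
        pool = pd.DataFrame(0.0, index=abundance.data.index, columns=[])
        return EnzymePool(data=pool, resolution=report)
    C, ecs = _copy_matrix(keys, table)
    ep = (merged.values / 100.0) @ C
    return EnzymePool(
        data=pd.DataFrame(ep, index=abundance.data.index, columns=ecs),
        resolution=report,
    )


# ---------------------------------------------------------------------------
# Coverage and the two inference algorithms
# ---------------------------------------------------------------------------

def pathway_coverage(
    present_ecs: set[str], pathway: str, hierarchy: PathwayHierarchy
) -> float:
    """Percent of pathway p's constituent enzymes present in the community:
    100 * |present ∩ E(p)| / |E(p)|. Wildcard ECs never count as present."""
    members = hierarchy.enzymes_of(pathway)
    present = {ec for ec in present_ecs if not is_wildcard_ec(ec)}
    return 100.0 * len(present & members) / len(members)


def _membership(
    hierarchy: PathwayHierarchy, ecs: list[str]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """0/1 EC × pathway membership matrix over `ecs`, pathway order, and
    pathway sizes |E(p)| (over the full hierarchy, not just present ECs)."""
    pathways = hierarchy.pathways
    M = np.zeros((len(ecs), len(pathways)))
    p_index = {p: j for j, p in enumerate(pathways)}
    for i, ec in enumerate(ecs):
        if is_wildcard_ec(ec):
            continue
        for p in hierarchy.ec_to_l3.get(ec, ()):
            M[i, p_index[p]] = 1.0
    sizes = np.array([len(hierarchy.l3_enzymes[p]) for p in pathways], dtype=float)
    return M, pathways, sizes


def _finalize_l3(
    raw: np.ndarray,
    coverage: np.ndarray,
    pathways: list[str],
    samples: list[str],
    pec: float,
    drop_eukaryotic: bool,
    hierarchy: PathwayHierarchy,
    algorithm: str,
) -> FunctionProfile:
    """Apply PEC and blacklist filters, renormalize each sample to 100%."""
    filtered = raw.copy()
    filtered[coverage < pec] = 0.0
    if drop_eukaryotic and hierarchy.eukaryote_l3:
        euk = np.array([p in hierarchy.eukaryote_l3 for p in pathways])
        filtered[:, euk] = 0.0
    sums = filtered.sum(axis=1, keepdims=True)
    values = np.divide(
        filtered, sums, out=np.zeros_like(filtered), where=sums > 0
    ) * 100.0
    return FunctionProfile(
        level="L3",
        pec=pec,
        algorithm=algorithm,
        values=pd.DataFrame(values, index=samples, columns=pathways),
        coverage=pd.DataFrame(coverage, index=samples, columns=pathways),
        names=dict(hierarchy.l3_names),
        raw=pd.DataFrame(filtered, index=samples, columns=pathways),
    )


def cometabolism_profile(
    pool: EnzymePool,
    hierarchy: PathwayHierarchy,
    pec: float,
    drop_eukaryotic: bool = True,
    pathway_size_normalize: bool = False,
) -> FunctionProfile:
    """Pathway abundances from the pooled community enzymes.

    Raw PA(s, p) = sum_{e in E(p)} Ep(s, e); a pathway is zeroed in samples
    where the community pool covers < pec percent of E(p) (coverage >= pec
    retains), blacklisted pathways are zeroed when requested, and the
    retained values are renormalized to 100% per sample.
    """
    ecs = list(pool.data.columns)
    samples = list(pool.data.index)
    M, pathways, sizes = _membership(hierarchy, ecs)
    ep = pool.data.values if ecs else np.zeros((len(samples), 0))
    raw = ep @ M if ecs else np.zeros((len(samples), len(pathways)))
    present = (ep > 0).astype(float) if ecs else np.zeros((len(samples), 0))
    coverage = (present @ M if ecs else np.zeros((len(samples), len(pathways)))) / sizes * 100.0
    if pathway_size_normalize:
        raw = raw / sizes
    return _finalize_l3(
        raw, coverage, pathways, samples, pec, drop_eukaryotic, hierarchy,
        "cometabolism",
    )


def independent_profile(
    abundance: TaxonAbundanceTable,
    table: CopyNumberTable,
    hierarchy: PathwayHierarchy,
    pec: float,
    drop_eukaryotic: bool = True,
    pec_scope: str = "taxon",
) -> tuple[FunctionProfile, ContributionMatrix]:
    """Pathway abundances as the sum of per-taxon pathway abundances.

    Taxon t contributes PA_t(s, p) = A(s, t)/100 * sum_{e in E(p)} C(t, e)
    to pathway p only when its own repertoire covers at least ``pec`` percent
    of E(p) (``pec_scope="taxon"``, the default); with ``pec_scope="union"``
    the cut-off is instead evaluated on the community enzyme union per
    sample, mirroring the co-metabolism semantics. Returns the filtered,
    renormalized Level-3 profile and the taxa × pathways contribution
    matrices (percent of each pathway's abundance attributable to each
    taxon, per sample and pooled over the environment).
    """
    if pec_scope not in ("taxon", "union"):
        raise ValueError("pec_scope must be 'taxon' or 'union'")
    merged, keys, report = _resolve_abundance(abundance, table)
    samples = list(abundance.data.index)
    if not keys:
        M, pathways, _ = _membership(hierarchy, [])
        zeros = np.zeros((len(samples), len(pathways)))
        profile = _finalize_l3(
            zeros, zeros, pathways, samples, pec, drop_eukaryotic, hierarchy,
            "independent",
        )
        empty = pd.DataFrame(0.0, index=pd.Index([], dtype=object), columns=pathways)
        return profile, ContributionMatrix(
            level="L3", pec=pec, per_sample={s: empty.copy() for s in samples},
            pooled=empty, taxa=[],
        )
    C, ecs = _copy_matrix(keys, table)
    M, pathways, sizes = _membership(hierarchy, ecs)
    # per-taxon pathway dosage and repertoire coverage
    S = C @ M                                    # taxa × pathways
    cov_t = ((C > 0).astype(float) @ M) / sizes * 100.0
    if pec_scope == "taxon":
        S_gated = np.where(cov_t >= pec, S, 0.0)
    else:
        S_gated = S
    A = merged.values / 100.0                    # samples × taxa (fractions)
    # PA_t(s, p): samples × taxa × pathways, separable product
    pa_t = A[:, :, None] * S_gated[None, :, :]
    raw = pa_t.sum(axis=1)
    if pec_scope == "taxon":
        # community-level coverage still reported; filtering already done per
        # taxon, so pathways with any gated contribution are retained.
        present = ((A @ (C > 0).astype(float)) > 0).astype(float)
        coverage = (present @ M) / sizes * 100.0
        profile = _finalize_l3(
            raw, np.full_like(raw, 100.0), pathways, samples, 0.0,
            drop_eukaryotic, hierarchy, "independent",
        )
        profile.coverage = pd.DataFrame(coverage, index=samples, columns=pathways)
        profile.pec = pec
    else:
        present = ((A @ (C > 0).astype(float)) > 0).astype(float)
        coverage = (present @ M) / sizes * 100.0
        profile = _finalize_l3(
            raw, coverage, pathways, samples, pec, drop_eukaryotic, hierarchy,
            "independent",
        )
        # zero the per-taxon tensor where the community filter removed p
        pa_t = pa_t * (profile.raw.values > 0)[:, None, :]
    if drop_eukaryotic and hierarchy.eukaryote_l3:
        euk = np.array([p in hierarchy.eukaryote_l3 for p in pathways])
        pa_t[:, :, euk] = 0.0
    per_sample: dict[str, pd.DataFrame] = {}
    taxon_index = pd.Index([f"{k.name} ({k.rank})" for k in keys])
    for i, s in enumerate(samples):
        totals = pa_t[i].sum(axis=0)
        contrib = np.divide(
            pa_t[i], totals, out=np.zeros_like(pa_t[i]), where=totals > 0
        ) * 100.0
        per_sample[s] = pd.DataFrame(contrib, index=taxon_index, columns=pathways)
    pooled_raw = pa_t.sum(axis=0)
    totals = pooled_raw.sum(axis=0)
    pooled = np.divide(
        pooled_raw, totals, out=np.zeros_like(pooled_raw), where=totals > 0
    ) * 100.0
    contributions = ContributionMatrix(
        level="L3",
        pec=pec,
        per_sample=per_sample,
        pooled=pd.DataFrame(pooled, index=taxon_index, columns=pathways),
        taxa=keys,
    )
    profile.values.attrs["resolution"] = report.to_dict()
    return profile, contributions


# ---------------------------------------------------------------------------
# Hierarchy aggregation, contributions at higher levels, core functions
# ---------------------------------------------------------------------------

def _rollup(values: pd.DataFrame, mapping: dict[str, str], what: str) -> pd.DataFrame:
    missing = [c for c in values.columns if c not in mapping]
    if missing:
        raise KeyError(f"{what} ids missing from hierarchy map: {missing}")
    parents = [mapping[c] for c in values.columns]
    return values.T.groupby(parents).sum().T


def aggregate_levels(
    l3: FunctionProfile, hierarchy: PathwayHierarchy
) -> tuple[FunctionProfile, FunctionProfile]:
    """Sum Level-3 pathway abundances into Level-2 classes and those into
    Level-1 super-classes; per-sample totals are conserved."""
    l2_values = _rollup(l3.values, hierarchy.l3_to_l2, "Level-3")
    l1_values = _rollup(l2_values, hierarchy.l2_to_l1, "Level-2")
    l2 = FunctionProfile(
        level="L2", pec=l3.pec, algorithm=l3.algorithm, values=l2_values,
        names=dict(hierarchy.l2_names),
    )
    l1 = FunctionProfile(
        level="L1", pec=l3.pec, algorithm=l3.algorithm, values=l1_values,
        names=dict(hierarchy.l1_names),
    )
    return l2, l1


def aggregate_contributions(
    contrib: ContributionMatrix, hierarchy: PathwayHierarchy
) -> tuple[ContributionMatrix, ContributionMatrix]:
    """Roll per-taxon contribution shares up the hierarchy.

    Shares are percent of a function's abundance, so rolling up must weight
    by the child-function abundances; equivalently we roll up the raw
    per-taxon abundances and re-normalize columns.
    """
    out = []
    for level, mapping in (("L2", hierarchy.l3_to_l2), ("L1", None)):
        per_sample: dict[str, pd.DataFrame] = {}
        if level == "L2":
            child_map = hierarchy.l3_to_l2
        else:
            child_map = {
                l3: hierarchy.l2_to_l1[l2] for l3, l2 in hierarchy.l3_to_l2.items()
            }
        pooled_raw = None
        for s, mat in contrib.per_sample.items():
            rolled = _rollup(mat, child_map, "Level-3")
            totals = rolled.sum(axis=0)
            per_sample[s] = rolled.div(totals.where(totals > 0, np.inf), axis=1) * 100.0
            pooled_raw = rolled if pooled_raw is None else pooled_raw + rolled
        if pooled_raw is None:
            pooled = pd.DataFrame()
        else:
            totals = pooled_raw.sum(axis=0)
            pooled = pooled_raw.div(totals.where(totals > 0, np.inf), axis=1) * 100.0
        out.append(
            ContributionMatrix(
                level=level, pec=contrib.pec, per_sample=per_sample,
                pooled=pooled, taxa=contrib.taxa,
            )
        )
    return out[0], out[1]


def core_functions(
    profile: FunctionProfile, prevalence_threshold: float = 0.9
) -> CoreSet:
    """Functions nonzero in at least ceil(threshold * n_samples) samples,
    with their prevalence and mean abundance."""
    if not 0 < prevalence_threshold <= 1:
        raise ValueError("prevalence threshold must be in (0, 1]")
    n = len(profile.values.index)
    if n < 1:
        raise ValueError("profile has no samples")
    nonzero = (profile.values > 0).sum(axis=0)
    need = math.ceil(prevalence_threshold * n)
    core = nonzero[nonzero >= need]
    entries = pd.DataFrame(
        {
            "prevalence": core / n,
            "mean_abundance": profile.values[core.index].mean(axis=0),
        }
    )
    return CoreSet(level=profile.level, threshold=prevalence_threshold, entries=entries)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class GlobalMapperResult:
    """All profiles, contributions and core sets from one run."""

    profiles: dict[tuple[str, str, int], FunctionProfile]  # (algorithm, level, pec)
    contributions: dict[tuple[str, int], ContributionMatrix]  # (level, pec)
    cores: dict[tuple[str, int], CoreSet]  # (algorithm, pec), L3 level
    resolution: ResolutionReport
    manifest: dict


def _profile_to_tsv(profile: FunctionProfile, path: Path) -> None:
    df = profile.values.T
    out = pd.DataFrame(
        {"function_name": [profile.names.get(f, f) for f in df.index]}, index=df.index
    ).join(df)
    out.index.name = "function_id"
    out.to_csv(path, sep="\t")


def run_global_mapper(
    abundance: TaxonAbundanceTable,
    table: CopyNumberTable,
    hierarchy: PathwayHierarchy,
    algorithms: tuple[str, ...] = ("cometabolism", "independent"),
    pec_values: tuple[int, ...] = DEFAULT_PEC_VALUES,
    drop_eukaryotic: bool = True,
    core_threshold: float = 0.9,
    pathway_size_normalize: bool = False,
    pec_scope: str = "taxon",
    out_dir: str | Path | None = None,
    reference_checksum: str | None = None,
) -> GlobalMapperResult:
    """Run the full pipeline: profiles at all three KEGG levels for every
    requested PEC and algorithm, contribution matrices (independent mode),
    core functions, and an unresolved-taxon report; optionally write the TSV
    outputs and a run manifest to ``out_dir``."""
    pool = pool_enzymes(abundance, table)
    assert pool.resolution is not None
    profiles: dict[tuple[str, str, int], FunctionProfile] = {}
    contributions: dict[tuple[str, int], ContributionMatrix] = {}
    cores: dict[tuple[str, int], CoreSet] = {}
    for pec in pec_values:
        if "cometabolism" in algorithms:
            l3 = cometabolism_profile(
                pool, hierarchy, pec, drop_eukaryotic=drop_eukaryotic,
                pathway_size_normalize=pathway_size_normalize,
            )
            l2, l1 = aggregate_levels(l3, hierarchy)
            profiles[("cometabolism", "L3", pec)] = l3
            profiles[("cometabolism", "L2", pec)] = l2
            profiles[("cometabolism", "L1", pec)] = l1
            cores[("cometabolism", pec)] = core_functions(l3, core_threshold)
        if "independent" in algorithms:
            l3, contrib = independent_profile(
                abundance, table, hierarchy, pec,
                drop_eukaryotic=drop_eukaryotic, pec_scope=pec_scope,
            )
            l2, l1 = aggregate_levels(l3, hierarchy)
            profiles[("independent", "L3", pec)] = l3
            profiles[("independent", "L2", pec)] = l2
            profiles[("independent", "L1", pec)] = l1
            contributions[("L3", pec)] = contrib
            c2, c1 = aggregate_contributions(contrib, hierarchy)
            contributions[("L2", pec)] = c2
            contributions[("L1", pec)] = c1
            cores[("independent", pec)] = core_functions(l3, core_threshold)
    manifest = {
        "tool": "funcodak",
        "algorithms": list(algorithms),
        "pec_values": list(pec_values),
        "drop_eukaryotic": drop_eukaryotic,
        "core_threshold": core_threshold,
        "pec_scope": pec_scope,
        "n_samples": len(abundance.samples),
        "n_taxa_input": len(abundance.taxa),
        "n_taxa_resolved": len(pool.resolution.resolved),
        "reference_checksum": reference_checksum,
    }
    result = GlobalMapperResult(
        profiles=profiles, contributions=contributions, cores=cores,
        resolution=pool.resolution, manifest=manifest,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (alg, level, pec), profile in profiles.items():
            _profile_to_tsv(profile, out_dir / f"{alg}_{level}_pec{pec}.tsv")
        for (level, pec), contrib in contributions.items():
            contrib.pooled.to_csv(
                out_dir / f"contributions_{level}_pec{pec}.tsv", sep="\t",
                index_label="taxon",
            )
        for (alg, pec), core in cores.items():
            core.entries.to_csv(
                out_dir / f"core_{alg}_L3_pec{pec}.tsv", sep="\t",
                index_label="function_id",
            )
        with open(out_dir / "unresolved_taxa.json", "w", encoding="utf-8") as fh:
            json.dump(pool.resolution.to_dict(), fh, indent=2)
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
    return result


def checksum_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
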
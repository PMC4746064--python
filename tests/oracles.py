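"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain nested loops over dictionaries, straight
from the defining formulas, deliberately sharing no code with the package's
vectorized implementations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from funcodak.reference import CopyNumberTable, PathwayHierarchy, TaxonKey


def naive_profiles(
    abundance_rows: dict[str, dict[str, float]],
    copy_numbers: dict[str, dict[str, float]],
    pathway_enzymes: dict[str, set[str]],
    blacklist: set[str],
    pec: float,
    algorithm: str,
    drop_eukaryotic: bool,
) -> dict[str, dict[str, float]]:
    """Per-sample pathway percentages computed by triple loops.

    ``abundance_rows``: sample -> taxon -> percent; ``copy_numbers``:
    taxon -> EC -> copy number. Taxon names must match exactly (resolution
    is not part of this oracle).
    """
    out: dict[str, dict[str, float]] = {}
    for sample, taxa in abundance_rows.items():
        raw: dict[str, float] = {}
        for p, members in pathway_enzymes.items():
            if algorithm == "cometabolism":
                pool = {}
                for ec in members:
                    total = 0.0
                    for taxon, pct in taxa.items():
                        total += pct / 100.0 * copy_numbers[taxon].get(ec, 0.0)
                    pool[ec] = total
                n_present = sum(1 for ec in members if pool[ec] > 0)
                coverage = 100.0 * n_present / len(members)
                value = sum(pool.values()) if coverage >= pec else 0.0
            else:
                value = 0.0
                for taxon, pct in taxa.items():
                    n_enc = sum(
                        1 for ec in members if copy_numbers[taxon].get(ec, 0.0) > 0
                    )
                    cov_t = 100.0 * n_enc / len(members)
                    if cov_t >= pec:
                        value += pct / 100.0 * sum(
                            copy_numbers[taxon].get(ec, 0.0) for ec in members
                        )
            if drop_eukaryotic and p in blacklist:
                value = 0.0
            raw[p] = value
        total = sum(raw.values())
        out[sample] = {
            p: (100.0 * v / total if total > 0 else 0.0) for p, v in raw.items()
        }
    return out


def enumerate_wilcoxon_p(x, y) -> float:
    """Exact two-sided rank-sum p-value by listing every assignment of the
    pooled observations to the two groups: with mid-ranks for ties,
    p = P(|W - E[W]| >= |w_obs - E[W]|) over all C(n, n1) assignments."""
    pooled = list(x) + list(y)
    n, n1 = len(pooled), len(x)
    # mid-ranks computed by hand
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    w_obs = sum(ranks[:n1])
    expect = n1 * (n + 1) / 2.0
    dev = abs(w_obs - expect)
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(sum(ranks[i] for i in idx) - expect) >= dev - 1e-12:
            hits += 1
    return hits / total


def random_small_instance(rng: np.random.Generator):
    """A random tiny problem (<= 5 taxa, <= 10 enzymes, <= 4 pathways) as
    plain dicts plus the package-typed equivalents."""
    n_taxa = int(rng.integers(1, 6))
    n_enzymes = int(rng.integers(2, 11))
    n_pathways = int(rng.integers(1, 5))
    n_samples = int(rng.integers(1, 4))
    ecs = [f"1.1.{1 + e // 10}.{1 + e % 10}" for e in range(n_enzymes)]
    taxa = [f"Taxon{t}" for t in range(n_taxa)]
    copy_numbers = {}
    for t in taxa:
        prof = {}
        for ec in ecs:
            if rng.random() < 0.6:
                prof[ec] = float(rng.integers(1, 5))
        copy_numbers[t] = prof
    pathway_enzymes = {}
    for p in range(n_pathways):
        k = int(rng.integers(1, n_enzymes + 1))
        members = set(rng.choice(ecs, size=k, replace=False))
        pathway_enzymes[f"P{p}"] = members
    blacklist = {p for p in pathway_enzymes if rng.random() < 0.25}
    abundance_rows = {}
    for s in range(n_samples):
        vals = rng.dirichlet(np.ones(n_taxa)) * 100.0
        abundance_rows[f"S{s}"] = dict(zip(taxa, vals))
    table = CopyNumberTable(
        profiles={TaxonKey(t, "genus"): dict(prof) for t, prof in copy_numbers.items()}
    )
    ec_to_l3: dict[str, set[str]] = {}
    for p, members in pathway_enzymes.items():
        for ec in members:
            ec_to_l3.setdefault(ec, set()).add(p)
    hierarchy = PathwayHierarchy(
        ec_to_l3=ec_to_l3,
        l3_enzymes={p: set(m) for p, m in pathway_enzymes.items()},
        l3_to_l2={p: "cl0" for p in pathway_enzymes},
        l2_to_l1={"cl0": "sc0"},
        eukaryote_l3=set(blacklist),
    )
    return abundance_rows, copy_numbers, pathway_enzymes, blacklist, table, hierarchy
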
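"""Per-enzyme abundance analysis of a single pathway.

For one user-chosen Level-3 pathway, the effective abundance of each
constituent enzyme is computed per environment exactly as in the
co-metabolism model — the abundance-weighted community enzyme pool — and
averaged over the environment's samples. Abundances are then rank-normalized
to (0, 1] and written as a KEGG "user data mapping" file (one
``ec:<EC>\\t<bg>,<fg>`` line per enzyme, with a white-to-saturated background
color ramp) ready for the KEGG color-pathway web interface, alongside a
quantitative TSV.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from funcodak.globalmapper import TaxonAbundanceTable, pool_enzymes
from funcodak.reference import CopyNumberTable, PathwayHierarchy

#: background color ramps: value 0 -> white floor, 1 -> saturated hue
_PALETTES = {
    "red": (255, 0, 0),
    "blue": (0, 0, 255),
    "green": (0, 160, 0),
}
_FLOOR_HEX = "#FFFFFF"
_FG_HEX = "#000000"


@dataclass
class EnzymeProfile:
    """Per-environment enzyme abundances of one pathway.

    ``abundance`` and ``rank_normalized`` are DataFrames with the pathway's
    enzymes as rows and environments as columns; every enzyme of E(p) is
    present, with zero for enzymes no community member encodes.
    """

    pathway: str
    abundance: pd.DataFrame
    rank_normalized: pd.DataFrame

    @property
    def enzymes(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def environments(self) -> list[str]:
        return list(self.abundance.columns)


def effective_enzyme_abundance(
    abundances: dict[str, TaxonAbundanceTable],
    table: CopyNumberTable,
    hierarchy: PathwayHierarchy,
    pathway: str,
    statistic: str = "mean",
) -> EnzymeProfile:
    """Environment-level effective abundance of each enzyme in E(p).

    Per environment, value(e) = mean (or median) over samples of the pooled
    abundance Ep(s, e), restricted to the pathway's enzymes; enzymes absent
    from every taxon are retained with value 0 so environments stay
    comparable side by side.
    """
    if pathway not in hierarchy.l3_enzymes:
        near = difflib.get_close_matches(pathway, hierarchy.pathways, n=3)
        raise KeyError(
            f"unknown pathway id {pathway!r}"
            + (f"; did you mean one of {near}?" if near else "")
        )
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    members = sorted(hierarchy.l3_enzymes[pathway])
    cols = {}
    for env, ab in abundances.items():
        pool = pool_enzymes(ab, table).data.reindex(columns=members, fill_value=0.0)
        cols[env] = pool.mean(axis=0) if statistic == "mean" else pool.median(axis=0)
    abundance = pd.DataFrame(cols, index=pd.Index(members, name="ec"))
    ranked = abundance.apply(lambda s: pd.Series(rank_normalize(dict(s)))[members])
    return EnzymeProfile(pathway=pathway, abundance=abundance, rank_normalized=ranked)


def rank_normalize(values: dict[str, float]) -> dict[str, float]:
    """Mid-rank normalization to (0, 1] over the nonzero entries.

    Nonzero abundances get mid-rank r scaled by the nonzero count m (so the
    largest maps to 1 and ties share a value); zero abundances are pinned to
    0, keeping "absent" distinguishable from "least abundant". Strictly
    larger abundance always maps to a strictly larger normalized value.
    """
    if not values:
        raise ValueError("rank_normalize needs at least one entry")
    keys = list(values)
    vals = np.array([values[k] for k in keys], dtype=float)
    out = dict.fromkeys(keys, 0.0)
    nz = vals > 0
    m = int(nz.sum())
    if m:
        ranks = stats.rankdata(vals[nz])  # mid-ranks
        for k, r in zip(np.array(keys, dtype=object)[nz], ranks / m):
            out[str(k)] = float(r)
    return out


def _ramp_hex(value: float, palette: str) -> str:
    """Linear white -> saturated-hue ramp; value must be in [0, 1]."""
    if palette not in _PALETTES:
        raise ValueError(f"unknown palette {palette!r}; choose from {sorted(_PALETTES)}")
    if value <= 0:
        return _FLOOR_HEX
    r, g, b = _PALETTES[palette]
    mix = lambda c: round(255 + (c - 255) * value)  # noqa: E731
    return f"#{mix(r):02X}{mix(g):02X}{mix(b):02X}"


def write_user_data_mapping(
    profile: EnzymeProfile,
    out_dir: str | Path,
    palette: str = "red",
    labels: dict[str, str] | None = None,
) -> list[Path]:
    """Write one KEGG user-data mapping file per environment plus the shared
    quantitative TSV; returns the written paths.

    Mapping-file lines are ``ec:<EC>\\t<bg_hex>,<fg_hex>`` — the dialect the
    KEGG color-pathway text form accepts for Enzyme-ID keyed coloring.
    Background intensity follows the rank-normalized value; zero-abundance
    enzymes get the white floor.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = labels or {env: env for env in profile.environments}
    written: list[Path] = []
    for env in profile.environments:
        path = out_dir / f"{profile.pathway}_{labels[env]}_userdata.txt"
        with open(path, "w", encoding="utf-8") as fh:
            for ec in profile.enzymes:
                bg = _ramp_hex(float(profile.rank_normalized.loc[ec, env]), palette)
                fh.write(f"ec:{ec}\t{bg},{_FG_HEX}\n")
        written.append(path)
    tsv = out_dir / f"{profile.pathway}_enzyme_profile.tsv"
    quant = profile.abundance.copy()
    for env in profile.environments:
        quant[f"{env}_rank_normalized"] = profile.rank_normalized[env]
    quant.to_csv(tsv, sep="\t")
    written.append(tsv)
    return written


def parse_user_data_mapping(path: str | Path) -> dict[str, tuple[str, str]]:
    """Parse a mapping file back into {EC: (bg_hex, fg_hex)} (round-trip
    check of the writer's dialect)."""
    out: dict[str, tuple[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                key, colors = line.split("\t")
                bg, fg = colors.split(",")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed mapping line") from exc
            if not key.startswith("ec:"):
                raise ValueError(f"{path}:{lineno}: expected 'ec:' prefix")
            out[key[3:]] = (bg, fg)
    return out
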
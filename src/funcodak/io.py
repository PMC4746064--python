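"""Readers and writers for abundance tables and profile files, plus run
manifests.

The canonical abundance unit everywhere is percent (0-100); fraction-scale
input (columns summing to about 1) is auto-detected and converted with a
logged notice. Every file the package writes is re-readable by these
readers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from funcodak.globalmapper import TaxonAbundanceTable, checksum_file
from funcodak.reference import (
    CopyNumberTable,
    PathwayHierarchy,
    load_reference_bundle,
)

logger = logging.getLogger("funcodak")


class AbundanceLoadError(ValueError):
    pass


def read_taxonomic_abundance(path: str | Path) -> TaxonAbundanceTable:
    """Read an abundance TSV: first column `taxon` (name or semicolon
    lineage), remaining columns sample ids, cells percent abundances.

    Duplicate taxon rows are summed with a warning; duplicate sample ids,
    negative values and non-numeric cells are errors naming the offending
    line; fraction-scale tables (column sums around 1) are converted to
    percent; columns are renormalized to exactly 100 with the deviation
    logged when it exceeds 0.5.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise AbundanceLoadError(f"{path.name}: need at least one sample column")
    samples = header[1:]
    dupes = {s for s in samples if samples.count(s) > 1}
    if dupes:
        raise AbundanceLoadError(f"{path.name}: duplicate sample ids {sorted(dupes)}")
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    values = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = values.isna().values
    if bad.any():
        i, j = map(int, next(zip(*bad.nonzero())))
        raise AbundanceLoadError(
            f"{path.name}:{i + 2}: non-numeric cell {raw.iloc[i, j]!r} "
            f"(taxon {raw.index[i]!r}, sample {raw.columns[j]!r})"
        )
    neg = (values.values < 0)
    if neg.any():
        i, j = map(int, next(zip(*neg.nonzero())))
        raise AbundanceLoadError(
            f"{path.name}:{i + 2}: negative abundance {values.iloc[i, j]} "
            f"(taxon {raw.index[i]!r}, sample {raw.columns[j]!r})"
        )
    if values.index.has_duplicates:
        dup = sorted(set(values.index[values.index.duplicated()]))
        logger.warning("%s: duplicate taxon rows summed: %s", path.name, dup)
        values = values.groupby(level=0, sort=False).sum()
    sums = values.sum(axis=0)
    if (sums > 0).all() and (sums < 2.0).all():
        logger.info("%s: fraction-scale input detected; converting to percent", path.name)
        values = values * 100.0
        sums = sums * 100.0
    for sample, total in sums.items():
        if abs(total - 100.0) > 0.5:
            logger.warning(
                "%s: sample %r sums to %.3f; renormalizing to 100", path.name, sample, total
            )
    return TaxonAbundanceTable(data=values.T)


def write_taxonomic_abundance(table: TaxonAbundanceTable, path: str | Path) -> None:
    out = table.data.T
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")


def read_function_profile(path: str | Path) -> pd.DataFrame:
    """Read a profile TSV written by the global mapper back into a samples ×
    functions DataFrame (the function_name column is dropped)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "function_name" in df.columns:
        df = df.drop(columns=["function_name"])
    return df.T


def load_reference_dir(
    ref_dir: str | Path,
) -> tuple[CopyNumberTable, PathwayHierarchy, dict[str, str]]:
    """Load a bundle directory (copy_numbers.tsv, hierarchy.tsv and an
    optional eukaryotic_pathways.tsv); returns the tables and the file
    checksums for the run manifest."""
    ref_dir = Path(ref_dir)
    cn = ref_dir / "copy_numbers.tsv"
    hi = ref_dir / "hierarchy.tsv"
    bl = ref_dir / "eukaryotic_pathways.tsv"
    table, hierarchy = load_reference_bundle(cn, hi, bl if bl.exists() else None)
    checksums = {p.name: checksum_file(p) for p in (cn, hi) if p.exists()}
    if bl.exists():
        checksums[bl.name] = checksum_file(bl)
    return table, hierarchy, checksums


def write_manifest(out_dir: str | Path, config: dict) -> Path:
    """Machine-readable record of a run: parameters, input checksums and the
    tool version."""
    from funcodak import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"tool": "funcodak", "version": __version__, **config}, fh, indent=2)
    return path
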
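"""File formats: tab-separated tables, blacklists, GMT gene sets, BED.

Dialects: tables are tab-separated with a header row and an explicit index
column; missing values are written as '.' and read back as NaN; the sample
sheet is comma-separated.  Manifest positions are 1-based (array-manifest
convention); BED output is 0-based half-open.  Every reader/writer pair
round-trips exactly.  Duplicate probe or sample ids are rejected.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import GeneSet
from .synthetic import CELL_TYPES, CellTypeReference

__all__ = [
    "read_beta_matrix", "write_beta_matrix",
    "read_sample_sheet", "write_sample_sheet",
    "read_manifest", "write_manifest",
    "read_blacklist", "write_blacklist",
    "read_reference", "write_reference",
    "read_gmt", "write_gmt",
    "write_bed",
    "read_table", "write_table",
]

_NA = "."


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique()[:3]
        raise ValueError(f"{path}: duplicate {what} id(s), e.g. {list(dups)}")


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, na_rep=_NA)


def read_table(path, index_col: int | str = 0, sep: str = "\t") -> pd.DataFrame:
    try:
        # round_trip parsing: written floats come back bit-identical
        return pd.read_csv(
            path, sep=sep, index_col=index_col, na_values=[_NA],
            float_precision="round_trip",
        )
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed table — {err}") from err


def write_beta_matrix(betas: pd.DataFrame, path) -> None:
    betas.rename_axis("probe_id").to_csv(path, sep="\t", na_rep=_NA)


def read_beta_matrix(path) -> pd.DataFrame:
    df = read_table(path)
    _check_unique(df.index, "probe", path)
    _check_unique(pd.Index(df.columns), "sample", path)
    df.columns.name = "sample_id"
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.rename_axis("sample_id").to_csv(path, na_rep=_NA)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, na_values=[_NA],
                     float_precision="round_trip")
    _check_unique(df.index, "sample", path)
    if "smoker" in df.columns:
        df["smoker"] = df["smoker"].astype(bool)
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    out = manifest.copy()
    if "gene" in out.columns:
        out["gene"] = out["gene"].fillna("")
    out.rename_axis("probe_id").to_csv(path, sep="\t", na_rep=_NA)


def read_manifest(path) -> pd.DataFrame:
    df = read_table(path)
    _check_unique(df.index, "probe", path)
    if "gene" in df.columns:
        df["gene"] = df["gene"].fillna("").astype(str)
    return df


def write_blacklist(probe_ids, path) -> None:
    Path(path).write_text("".join(f"{p}\n" for p in probe_ids))


def read_blacklist(path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def write_reference(reference: CellTypeReference, path) -> None:
    """Centroid matrix only (probe_id + one column per cell type)."""
    reference.centroids.rename_axis("probe_id").to_csv(path, sep="\t")


def read_reference(path, manifest: pd.DataFrame) -> CellTypeReference:
    """Assemble a reference from a centroid TSV plus a manifest for coordinates."""
    cent = read_table(path)
    _check_unique(cent.index, "probe", path)
    missing = [c for c in CELL_TYPES if c not in cent.columns]
    if missing:
        raise ValueError(f"{path}: reference lacks cell-type column(s) {missing}")
    man = manifest.loc[cent.index].copy()
    if "discriminatory" not in man.columns:
        man["discriminatory"] = False
    return CellTypeReference(manifest=man, centroids=cent[list(CELL_TYPES)])


def read_gmt(path, category: str = "") -> list[GeneSet]:
    """GMT: one set per line — id <tab> description <tab> gene1 <tab> ..."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs id, description and >= 1 gene"
            )
        sets.append(
            GeneSet(
                set_id=fields[0],
                name=fields[1],
                category=category,
                genes=frozenset(g for g in fields[2:] if g),
            )
        )
    ids = [s.set_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate gene-set ids")
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.genes)]) + "\n")


def write_bed(regions: pd.DataFrame, path, name_col: str | None = None) -> None:
    """Write chrom/start/end regions as BED (0-based half-open).

    ``regions`` carries 1-based inclusive start/end (probe positions); the
    emitted interval is [start - 1, end).
    """
    with open(path, "w") as fh:
        for i, (_, row) in enumerate(regions.iterrows()):
            name = str(row[name_col]) if name_col else f"region{i + 1}"
            fh.write(
                f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t{name}\n"
            )
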
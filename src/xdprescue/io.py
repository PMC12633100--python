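"""Readers and writers for the standard formats the analysis touches.

Count matrices as TSV (first column gene id, header sample ids) or
MatrixMarket with ``.rows``/``.cols`` name sidecars; sample sheets as CSV
with a fixed, case-sensitive categorical vocabulary; gene-set collections
as GMT. Validation is strict: silent coercion hides sheet errors.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
]

SHEET_COLUMNS = ["sample_id", "subject_id", "genotype", "edit_status",
                 "treatment", "pair_id", "batch"]
GENOTYPES = {"XDP", "CON"}
EDIT_STATUSES = {"naive", "unedited", "dSVA", "none"}


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s): {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s): {dups}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    bad = ~np.isfinite(arr) | (arr < 0) | (arr != np.floor(arr))
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer or negative count at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}: {arr[g, s]!r}")
    out = df.astype(np.int64)
    out.index.name = "gene"
    out.columns.name = "sample"
    return out


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count matrix (TSV, or MatrixMarket + sidecars).

    MatrixMarket input (``*.mtx``) expects name sidecars ``<path>.rows`` and
    ``<path>.cols`` with one identifier per line. Validation rejects
    duplicate identifiers and non-integer or negative entries, naming the
    offending location.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        m = mmread(path)
        genes = Path(f"{path}.rows").read_text().split()
        samples = Path(f"{path}.cols").read_text().split()
        df = pd.DataFrame(np.asarray(m.todense() if hasattr(m, "todense") else m),
                          index=genes, columns=samples)
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        dups = [h for h in header if header.count(h) > 1]
        if dups:
            raise ValueError(f"duplicate sample id(s) in header: {sorted(set(dups))}")
        df = pd.read_csv(path, sep="\t", index_col=0)
    return _validate_counts(df)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write counts as TSV, or MatrixMarket + name sidecars for ``*.mtx``."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(path, coo_matrix(counts.to_numpy()))
        Path(f"{path}.rows").write_text("\n".join(map(str, counts.index)) + "\n")
        Path(f"{path}.cols").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        counts.to_csv(path, sep="\t")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate sheet columns, categorical levels, and pairing references."""
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing column(s): {missing}")
    sheet = sheet[SHEET_COLUMNS].copy()
    sheet["pair_id"] = sheet["pair_id"].fillna("").astype(str)
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s): {dups}")
    bad_gt = sorted(set(sheet["genotype"]) - GENOTYPES)
    if bad_gt:
        raise ValueError(f"unknown genotype level(s) {bad_gt}; allowed: "
                         f"{sorted(GENOTYPES)} (case-sensitive)")
    bad_es = sorted(set(sheet["edit_status"]) - EDIT_STATUSES)
    if bad_es:
        raise ValueError(f"unknown edit_status level(s) {bad_es}; allowed: "
                         f"{sorted(EDIT_STATUSES)} (case-sensitive)")
    ids = set(sheet["sample_id"])
    orphans = [(s, p) for s, p in zip(sheet["sample_id"], sheet["pair_id"])
               if p and p not in ids]
    if orphans:
        raise ValueError(f"pair_id references missing sample(s): {orphans}")
    by_id = sheet.set_index("sample_id")
    unpartnered = []
    for _, row in sheet.iterrows():
        if row["treatment"] != "none":
            partner = row["pair_id"]
            if not partner or by_id.loc[partner, "treatment"] != "none":
                unpartnered.append(row["sample_id"])
    if unpartnered:
        raise ValueError(
            f"treated sample(s) without a resolvable untreated partner: {unpartnered}")
    return sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample sheet CSV."""
    sheet = pd.read_csv(path, dtype=str, keep_default_na=False)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: term, description, then genes.

    Duplicate genes within a term are dropped (order-preserving, logged);
    an empty file yields an empty collection with a warning; a line with
    fewer than 3 fields is an error naming the line number.
    """
    collection: dict[str, list[str]] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno} has fewer than 3 tab-separated fields")
        term, _description, *genes = fields
        unique = list(dict.fromkeys(g for g in genes if g))
        if len(unique) < len([g for g in genes if g]):
            logger.info("term %s: duplicate gene(s) deduplicated", term)
        collection[term] = unique
    if not collection:
        warnings.warn(f"{path}: empty GMT collection")
    return collection


def write_gmt(collection: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for term, genes in collection.items():
        desc = (descriptions or {}).get(term, "na")
        lines.append("\t".join([term, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")
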
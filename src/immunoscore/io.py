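"""Readers and writers for the tab-separated formats the pipeline touches.

Conventions
-----------
* Expression matrices are genes x samples DataFrames, log2-scale values.
* The sample order of the expression matrix is the canonical order for every
  downstream output.
* Gene-set collections follow the Broad GMT dialect
  (``name TAB description TAB gene TAB gene ...``).
* All writers prefix the file with ``#``-comment header lines recording the
  seed / config hash so a run can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("immunoscore")

VALID_N_STATUS = {"N-", "N+"}
VALID_T_STAGE = {"T1", "T2", "T3", "T4"}
MISSING_TOKENS = {"", "NA", "N/A", "NaN", "nan", "na", "None", "."}


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class EdgeList:
    """Undirected, de-duplicated edge list without self-loops."""

    edges: pd.DataFrame  # columns: node1, node2, weight

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_ids(self) -> list[str]:
        if self.edges.empty:
            return []
        return sorted(set(self.edges["node1"]) | set(self.edges["node2"]))


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Load a genes x samples expression TSV.

    First column holds gene ids, first row sample ids.  Rows with any missing
    value are dropped, duplicate gene ids are collapsed by their mean, and
    both actions are logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # locate non-numeric cells before coercing so the error can name them
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ValueError(
                f"non-numeric expression value for gene {gene!r} in sample {col!r}"
            )
        df[col] = coerced
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.info("dropping %d gene rows with missing values", n_missing)
        df = df.dropna(axis=0)
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene ids by mean", n_dup)
        order = df.index.drop_duplicates()
        df = df.groupby(level=0, sort=False).mean().loc[order]
    if df.shape[1] < 2:
        raise ValueError(f"expression matrix needs >=2 samples, got {df.shape[1]}")
    if df.shape[0] < 2:
        raise ValueError(f"expression matrix needs >=2 genes, got {df.shape[0]}")
    logger.info("loaded expression matrix: %d genes x %d samples", *df.shape)
    return df.astype(float)


def write_expression_matrix(
    df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None
) -> None:
    _write_tsv(df, path, header_lines, index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file into a :class:`GeneSetCollection`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 fields, got {len(fields)}")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(g for g in genes if g))
            if not deduped:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Load the clinical table (one row per sample).

    Required columns: ``sample_id``, ``pfs_time`` (months, > 0), ``pfs_event``
    (0 censored / 1 progressed).  Optional covariates: ``gleason``,
    ``n_status`` (N-/N+), ``hormone_therapy``, ``radiation_therapy`` (0/1),
    ``t_stage`` (T1..T4).  Unknown tokens become missing and are counted in
    the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["sample_id", "pfs_time", "pfs_event"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in clinical table")
    out = pd.DataFrame({"sample_id": df["sample_id"].astype(str)})
    out["pfs_time"] = pd.to_numeric(df["pfs_time"], errors="raise").astype(float)
    bad = out["pfs_time"] <= 0
    if bad.any():
        sample = out.loc[bad, "sample_id"].iloc[0]
        raise ValueError(f"non-positive pfs_time for sample {sample!r}")
    out["pfs_event"] = pd.to_numeric(df["pfs_event"], errors="raise").astype(int)
    if not out["pfs_event"].isin([0, 1]).all():
        raise ValueError("pfs_event must be 0 or 1")

    n_unknown = 0

    def _clean(col: str, valid: set[str] | None, numeric: bool) -> pd.Series:
        nonlocal n_unknown
        if col not in df.columns:
            return pd.Series([pd.NA] * len(df))
        raw = df[col].astype(str).str.strip()
        missing = raw.isin(MISSING_TOKENS) | df[col].isna()
        if numeric:
            vals = pd.to_numeric(raw.where(~missing), errors="coerce")
            n_unknown += int((vals.isna() & ~missing).sum())
            return vals.astype("Float64")
        vals = raw.where(~missing)
        if valid is not None:
            unknown = vals.notna() & ~vals.isin(valid)
            n_unknown += int(unknown.sum())
            vals = vals.where(~unknown)
        return vals

    out["gleason"] = _clean("gleason", None, numeric=True)
    out["n_status"] = _clean("n_status", VALID_N_STATUS, numeric=False)
    out["hormone_therapy"] = _clean("hormone_therapy", None, numeric=True)
    out["radiation_therapy"] = _clean("radiation_therapy", None, numeric=True)
    out["t_stage"] = _clean("t_stage", VALID_T_STAGE, numeric=False)
    if n_unknown:
        logger.info("clinical table: %d unknown tokens mapped to missing", n_unknown)
    logger.info("loaded clinical table: %d samples", len(out))
    return out


def write_clinical(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    _write_tsv(df.set_index("sample_id"), path, header_lines, index_label="sample_id")


def read_edge_list(path: str | Path) -> EdgeList:
    """Load an undirected edge list (two id columns, optional weight)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise ValueError(f"edge list line {lineno}: expected 2 or 3 fields")
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            try:
                w = float(fields[2]) if len(fields) == 3 else 1.0
            except ValueError as exc:
                raise ValueError(f"edge list line {lineno}: bad weight {fields[2]!r}") from exc
            lo, hi = sorted((a, b))
            rows.append((lo, hi, w))
    if n_self:
        logger.info("edge list: dropped %d self-loops", n_self)
    df = pd.DataFrame(rows, columns=["node1", "node2", "weight"])
    if not df.empty:
        df = df.drop_duplicates(subset=["node1", "node2"], keep="first").reset_index(drop=True)
    return EdgeList(edges=df)


def _write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    header_lines: list[str] | None,
    index_label: str | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        # %.17g guarantees binary64 round-trip through text
        df.to_csv(fh, sep="\t", index_label=index_label, float_format="%.17g")
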
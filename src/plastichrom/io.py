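"""Readers and writers for the plain-text formats the pipeline touches.

BED/narrowPeak (0-based half-open), promoter TSV, MTX triplet matrices with
row/column TSVs, GMT gene sets, dose-grid plate CSVs and spectral-count TSVs.
All tabular outputs carry a single ``#`` header line recording the tool
version and the parameters used, for provenance.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ParseError(ValueError):
    """A malformed input file; the message names file and line."""


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED/narrowPeak file (>=3 columns; extras ignored).

    Coordinates are 0-based half-open. Returns columns chrom, start, end
    (+ name/score/strand when present).
    """
    path = Path(path)
    rows: list[list] = []
    n_fields: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has {len(fields)} column(s), need >= 3")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinate") from exc
            if start < 0 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if n_fields is None:
                n_fields = min(len(fields), 6)
            rows.append([fields[0], start, end] + fields[3:n_fields])
    cols = BED_COLUMNS[: (n_fields or 3)]
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        df = pd.DataFrame(columns=cols[:3]).astype({"start": int, "end": int}, errors="ignore")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write a sorted BED file (tab-separated, no header)."""
    out = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_promoters(path: str | Path) -> pd.DataFrame:
    """Read a promoter annotation TSV: gene_id, chrom, tss (0-based), strand."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: promoter table missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()[:3]
        raise ParseError(f"{path}: duplicate gene_id values (e.g. {list(dups)})")
    if (df["tss"] < 0).any():
        raise ParseError(f"{path}: negative TSS coordinate")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, params: dict | None = None, index: bool = False) -> None:
    """Write a TSV with a one-line ``#`` provenance header."""
    from plastichrom import __version__

    header = {"tool": f"plastichrom {__version__}"}
    if params:
        header.update(params)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True, default=str) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# count matrices (MTX triplet + row/column TSVs)

def write_counts_mtx(counts, cell_ids, gene_ids, outdir: str | Path, prefix: str = "counts") -> None:
    """Write a cells x genes integer matrix as MTX plus cells.tsv / genes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.csr_matrix(np.asarray(counts))
    scipy.io.mmwrite(str(outdir / f"{prefix}.mtx"), mat, field="integer")
    pd.Series(cell_ids, name="cell_id").to_csv(outdir / "cells.tsv", sep="\t", index=False)
    pd.Series(gene_ids, name="gene_id").to_csv(outdir / "genes.tsv", sep="\t", index=False)


def read_counts_mtx(outdir: str | Path, prefix: str = "counts") -> pd.DataFrame:
    """Read an MTX triplet written by :func:`write_counts_mtx` as a dense frame."""
    outdir = Path(outdir)
    mat = scipy.io.mmread(str(outdir / f"{prefix}.mtx"))
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t")["cell_id"].tolist()
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t")["gene_id"].tolist()
    dense = np.asarray(scipy.sparse.csr_matrix(mat).todense())
    if dense.shape != (len(cells), len(genes)):
        raise ParseError(f"{outdir}/{prefix}.mtx: shape {dense.shape} does not match id files")
    return pd.DataFrame(dense, index=pd.Index(cells, name="cell_id"),
                        columns=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# gene sets

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT: one set per line — name, description, member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# dose-response plates

def read_plate_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a dose-grid plate CSV, possibly with replicate blocks.

    Dialect: first row holds doses of drug B (first cell blank or a label),
    first column doses of drug A; the body is raw luminescence. Replicate
    blocks are separated by one or more blank lines. Doses must start at 0;
    wells at dose (0, 0) are the plate controls.

    Returns ``(doses_a, doses_b, raw)`` with ``raw`` shaped
    (n_replicates, n_doses_a, n_doses_b).
    """
    text = Path(path).read_text()
    blocks = [b for b in text.replace("\r\n", "\n").split("\n\n") if b.strip()]
    doses_a = doses_b = None
    grids = []
    for block in blocks:
        df = pd.read_csv(_io.StringIO(block), index_col=0)
        db = df.columns.astype(float).to_numpy()
        da = df.index.astype(float).to_numpy()
        if doses_a is None:
            doses_a, doses_b = da, db
        elif not (np.array_equal(da, doses_a) and np.array_equal(db, doses_b)):
            raise ParseError(f"{path}: replicate blocks disagree on dose grids")
        grids.append(df.to_numpy(dtype=float))
    if not grids:
        raise ParseError(f"{path}: no plate blocks found")
    return doses_a, doses_b, np.stack(grids)


def write_plate_csv(doses_a, doses_b, raw: np.ndarray, path: str | Path) -> None:
    """Write replicate dose-grid blocks in the dialect of :func:`read_plate_csv`."""
    raw = np.asarray(raw)
    if raw.ndim == 2:
        raw = raw[None, :, :]
    parts = []
    for grid in raw:
        df = pd.DataFrame(grid, index=pd.Index(doses_a, name="dose_a"), columns=doses_b)
        parts.append(df.to_csv())
    Path(path).write_text("\n".join(parts))


# ---------------------------------------------------------------------------
# spectral counts

def read_spectral_counts(path: str | Path) -> pd.DataFrame:
    """Read a protein x replicate spectral-count TSV.

    Columns after ``protein_id`` are headed ``arm:sample:rep`` (arm in
    {bait, IgG}); e.g. ``bait:SKO:rep1``. Returns counts indexed by protein.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "protein_id":
        raise ParseError(f"{path}: first column must be 'protein_id'")
    df = df.set_index("protein_id")
    for col in df.columns:
        arm = col.split(":")[0]
        if arm not in ("bait", "IgG"):
            raise ParseError(f"{path}: column {col!r} does not start with 'bait:' or 'IgG:'")
    counts = df.astype(int)
    if (counts < 0).any().any():
        raise ParseError(f"{path}: negative spectral counts")
    return counts


def write_spectral_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("protein_id").to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
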
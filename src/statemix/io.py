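"""Readers/writers for the dense-TSV / MTX file interfaces.

Matrices are genes-as-rows throughout: bulk TSV/CSV has gene ids in the
first column and sample ids in the header; single-cell input is either a
dense TSV of the same shape (columns = barcodes) or a MatrixMarket MTX with
one-column gene and barcode sidecar files.  Cell labels come as a 2–3 column
TSV (barcode, cell_type[, cell_state]).  Gene ids are matched as exact
strings; duplicate gene rows are collapsed by summation with a warning.
Every CLI output is accompanied by a provenance JSON (input hashes,
parameters, package version).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .errors import FormatError
from .model import BulkMatrix
from .reference import SingleCellCounts


def _read_dense(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # malformed header/fields
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if frame.empty or frame.shape[1] == 0:
        raise FormatError(f"{path} has no data columns")
    values = frame.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise FormatError(
            f"non-numeric value at gene {frame.index[r]!r}, "
            f"column {frame.columns[c]!r} in {path}"
        )
    return values


def _check_nonnegative(frame: pd.DataFrame, path: Path) -> None:
    arr = frame.to_numpy()
    if np.any(arr < 0):
        r, c = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"negative entry at gene {frame.index[r]!r}, "
            f"column {frame.columns[c]!r} in {path}"
        )


def _collapse_duplicates(frame: pd.DataFrame) -> pd.DataFrame:
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        warnings.warn(
            f"collapsing duplicate gene ids by summation: {dups[:5]}"
            + ("…" if len(dups) > 5 else ""),
            stacklevel=3,
        )
        frame = frame.groupby(level=0, sort=False).sum()
    return frame


def read_bulk(path: str | Path) -> BulkMatrix:
    """Read a gene × sample bulk matrix from dense TSV/CSV."""
    path = Path(path)
    frame = _read_dense(path)
    _check_nonnegative(frame, path)
    frame = _collapse_duplicates(frame)
    return BulkMatrix(
        X=frame.to_numpy(dtype=float),
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
    )


def write_bulk(bulk: BulkMatrix, path: str | Path) -> None:
    bulk.to_frame().to_csv(Path(path), sep="\t", index_label="gene")


def _read_labels(path: Path, barcodes: list[str]) -> tuple[list[str], list[str] | None]:
    try:
        tab = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse labels {path}: {exc}") from exc
    if tab.shape[1] not in (2, 3):
        raise FormatError(
            f"labels file {path} must have 2 or 3 columns, found {tab.shape[1]}"
        )
    lookup = {row[0]: tuple(row[1:]) for row in tab.itertuples(index=False)}
    missing = [b for b in barcodes if b not in lookup]
    if missing:
        raise FormatError(f"labels missing for barcodes: {missing[:5]}")
    types = [lookup[b][0] for b in barcodes]
    if tab.shape[1] == 3:
        return types, [lookup[b][1] for b in barcodes]
    return types, None


def read_sc(
    counts_path: str | Path,
    labels_path: str | Path,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> SingleCellCounts:
    """Read single-cell counts from dense TSV/CSV or MTX + gene/barcode lists."""
    counts_path = Path(counts_path)
    if counts_path.suffix.lower() == ".mtx":
        if genes_path is None or barcodes_path is None:
            raise FormatError("MTX input requires genes and barcodes files")
        try:
            mat = mmread(str(counts_path))
        except Exception as exc:
            raise FormatError(f"cannot parse {counts_path}: {exc}") from exc
        counts = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        gene_ids = Path(genes_path).read_text().split()
        barcodes = Path(barcodes_path).read_text().split()
        if counts.shape != (len(gene_ids), len(barcodes)):
            raise FormatError(
                f"MTX shape {counts.shape} does not match "
                f"{len(gene_ids)} genes × {len(barcodes)} barcodes"
            )
        frame = pd.DataFrame(counts, index=gene_ids, columns=barcodes)
    else:
        frame = _read_dense(counts_path)
    _check_nonnegative(frame, counts_path)
    frame = _collapse_duplicates(frame)
    barcodes = [str(b) for b in frame.columns]
    types, states = _read_labels(Path(labels_path), barcodes)
    return SingleCellCounts(
        counts=frame.to_numpy(dtype=float),
        gene_ids=[str(g) for g in frame.index],
        cell_type_labels=types,
        cell_state_labels=states,
        cell_ids=barcodes,
    )


def write_sc(sc: SingleCellCounts, out_dir: str | Path, prefix: str = "sc") -> None:
    """Write single-cell counts as MTX + gene/barcode lists + labels TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out_dir / f"{prefix}.mtx"), csr_matrix(sc.counts))
    (out_dir / f"{prefix}.genes.txt").write_text("\n".join(sc.gene_ids) + "\n")
    (out_dir / f"{prefix}.barcodes.txt").write_text("\n".join(sc.cell_ids) + "\n")
    cols = {"barcode": sc.cell_ids, "cell_type": sc.cell_type_labels}
    if sc.cell_state_labels is not None:
        cols["cell_state"] = sc.cell_state_labels
    pd.DataFrame(cols).to_csv(
        out_dir / f"{prefix}.labels.tsv", sep="\t", header=False, index=False
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(
    out_path: str | Path, inputs: dict[str, str | Path], params: dict
) -> None:
    """Record input hashes, parameters and package version beside an output."""
    from . import __version__

    record = {
        "package": "statemix",
        "version": __version__,
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in inputs.items()
            if Path(p).exists()
        },
        "parameters": params,
    }
    Path(out_path).write_text(json.dumps(record, indent=1))
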
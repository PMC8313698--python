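"""Count-matrix I/O in the 10x Genomics MatrixMarket dialect.

A sample directory holds the standard triple ``matrix.mtx``, ``features.tsv``
(or ``genes.tsv``) and ``barcodes.tsv``, each optionally gzip-compressed.
Matrices are features x cells, non-negative integers.  RNA and ADT assays are
kept as separate matrices sharing barcodes; they are never concatenated into
one feature space because different normalizations apply.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, InputError

log = logging.getLogger(__name__)

#: Default CITE-seq antibody panel: CD99 plus six autosomally encoded markers.
DEFAULT_ADT_PANEL = ("CD99", "CD19", "CD14", "CD16", "CD56", "CD8", "CD4")

SAMPLE_SHEET_COLUMNS = ("barcode", "donor", "library_prep_batch", "sequencing_batch")


@dataclass
class CountMatrix:
    """Sparse features x cells matrix of non-negative integer counts."""

    matrix: sp.spmatrix
    feature_ids: list = field(default_factory=list)
    barcodes: list = field(default_factory=list)
    assay: str = "RNA"

    def __post_init__(self) -> None:
        m = sp.csr_matrix(self.matrix)
        if np.issubdtype(m.dtype, np.floating):
            if m.nnz and not np.allclose(m.data, np.round(m.data)):
                raise FormatError("count matrix contains non-integer entries")
            m = m.astype(np.int64)
        elif not np.issubdtype(m.dtype, np.integer):
            raise FormatError(f"count matrix has non-numeric dtype {m.dtype}")
        if m.nnz and m.data.min() < 0:
            raise FormatError("count matrix contains negative entries")
        self.matrix = m
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        if m.shape != (len(self.feature_ids), len(self.barcodes)):
            raise FormatError(
                f"matrix shape {m.shape} does not match {len(self.feature_ids)} "
                f"features x {len(self.barcodes)} barcodes"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def total(self) -> int:
        return int(self.matrix.sum())

    def subset_cells(self, keep_barcodes) -> "CountMatrix":
        """New matrix restricted to ``keep_barcodes`` in the given order."""
        index = {b: i for i, b in enumerate(self.barcodes)}
        try:
            cols = [index[b] for b in keep_barcodes]
        except KeyError as exc:
            raise InputError(f"unknown barcode {exc.args[0]!r}") from exc
        return CountMatrix(
            self.matrix[:, cols], list(self.feature_ids), list(keep_barcodes), self.assay
        )

    def row(self, feature: str) -> np.ndarray:
        """Dense per-cell counts of one feature."""
        try:
            i = self.feature_ids.index(feature)
        except ValueError as exc:
            raise InputError(f"feature {feature!r} not present") from exc
        return np.asarray(self.matrix[i].todense()).ravel()

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.feature_ids == other.feature_ids
            and self.barcodes == other.barcodes
            and self.matrix.shape == other.matrix.shape
            and (self.matrix != other.matrix).nnz == 0
        )


def validate_adt_panel(cm: CountMatrix, panel=DEFAULT_ADT_PANEL) -> None:
    """ADT matrices must carry exactly the configured antibody panel."""
    if set(cm.feature_ids) != set(panel):
        raise FormatError(
            f"ADT panel mismatch: expected {sorted(panel)}, got {sorted(cm.feature_ids)}"
        )


def _find(dir_path: Path, stems) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dir_path / name
            if p.exists():
                return p
    raise FormatError(f"none of {stems} found in {dir_path}")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, dtype=str)


def read_10x(dir_path, assay: str = "RNA") -> CountMatrix:
    """Read a 10x-style directory (matrix.mtx + features/genes.tsv + barcodes.tsv).

    Features files may have one column (symbol) or the 10x two/three column
    layout (id, symbol[, type]); the symbol column is used when present.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, ["matrix.mtx"])
    feat_path = _find(dir_path, ["features.tsv", "genes.tsv"])
    bc_path = _find(dir_path, ["barcodes.tsv"])

    opener = gzip.open if mtx_path.suffix == ".gz" else open
    with opener(mtx_path, "rb") as fh:
        try:
            m = scipy.io.mmread(fh)
        except ValueError as exc:
            raise FormatError(f"bad MatrixMarket file {mtx_path}: {exc}") from exc
    feats = _read_tsv(feat_path)
    symbols = feats.iloc[:, 1] if feats.shape[1] >= 2 else feats.iloc[:, 0]
    barcodes = _read_tsv(bc_path).iloc[:, 0]
    if m.shape != (len(symbols), len(barcodes)):
        raise FormatError(
            f"{mtx_path} declares shape {m.shape} but found "
            f"{len(symbols)} features and {len(barcodes)} barcodes"
        )
    return CountMatrix(m, list(symbols), list(barcodes), assay)


def write_10x(cm: CountMatrix, dir_path, compress: bool = False) -> Path:
    """Write the 10x triple; re-readable by :func:`read_10x` with exact equality."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""
    opener = gzip.open if compress else open

    with opener(dir_path / ("matrix.mtx" + suffix), "wb") as fh:
        scipy.io.mmwrite(fh, cm.matrix.tocoo(), field="integer")
    ftype = "Antibody Capture" if cm.assay == "ADT" else "Gene Expression"
    with opener(dir_path / ("features.tsv" + suffix), "wt") as fh:
        for f in cm.feature_ids:
            fh.write(f"{f}\t{f}\t{ftype}\n")
    with opener(dir_path / ("barcodes.tsv" + suffix), "wt") as fh:
        for b in cm.barcodes:
            fh.write(b + "\n")
    return dir_path


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the per-cell sample sheet CSV (barcode, donor, batches)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    if df["barcode"].duplicated().any():
        raise FormatError("sample sheet contains duplicate barcodes")
    return df.loc[:, list(SAMPLE_SHEET_COLUMNS)]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.loc[:, list(SAMPLE_SHEET_COLUMNS)].to_csv(path, index=False)


def merge_samples(matrices, sheets):
    """Pool per-sample matrices and sheets into one dataset.

    Barcodes are suffixed ``-<sample index>`` (1-based) so identical barcode
    strings from different samples stay unique.  Feature panels must match
    across samples within the assay.
    """
    matrices = list(matrices)
    sheets = list(sheets)
    if not matrices or len(matrices) != len(sheets):
        raise InputError("need one sample sheet per matrix")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.feature_ids != ref.feature_ids:
            raise InputError("feature panel mismatch between samples")
        if m.assay != ref.assay:
            raise InputError("assay mismatch between samples")
    pooled_barcodes = []
    pooled_sheets = []
    for i, (m, sheet) in enumerate(zip(matrices, sheets), start=1):
        if set(sheet["barcode"]) != set(m.barcodes):
            raise InputError(f"sample {i}: sheet barcodes do not match matrix")
        suffixed = [f"{b}-{i}" for b in m.barcodes]
        pooled_barcodes.extend(suffixed)
        s = sheet.set_index("barcode").loc[m.barcodes].reset_index()
        s["barcode"] = suffixed
        pooled_sheets.append(s)
    pooled = CountMatrix(
        sp.hstack([m.matrix for m in matrices]),
        list(ref.feature_ids),
        pooled_barcodes,
        ref.assay,
    )
    return pooled, pd.concat(pooled_sheets, ignore_index=True)
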